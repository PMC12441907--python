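"""Independent oracles and shared fixtures for the test suite.

The oracles here deliberately re-derive quantities by brute force
(explicit sorting, pairwise enumeration) so they stay independent of the
library code paths they check.
"""

from __future__ import annotations

import numpy as np

from grnkit import (
    ClassifierSpec,
    EncoderFeatures,
    ModelConfig,
    SyntheticSpec,
    build_feature_matrix,
    build_model,
    extract_features,
    fit_hybrid,
    generate_dataset,
    preprocess_features,
    roc_auc,
    sample_negative_pairs,
    split_holdout,
    train_model,
)


def oracle_tmm_factors(X: np.ndarray, logratio_trim=0.3, abs_expr_trim=0.05):
    """Brute-force TMM: explicit sorting for both trims, direct weighted mean.

    Returns (factors rescaled to geometric mean 1, reference index).
    """
    X = np.asarray(X, dtype=float)
    lib = X.sum(axis=0)
    uq = []
    for s in range(X.shape[1]):
        nz = X[X[:, s] > 0, s] / lib[s]
        uq.append(np.quantile(nz, 0.75) if nz.size else 0.0)
    uq = np.asarray(uq)
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for s in range(X.shape[1]):
        mask = (X[:, s] > 0) & (X[:, ref] > 0)
        yk, yr = X[mask, s], X[mask, ref]
        nk, nr = lib[s], lib[ref]
        m = np.log2((yk / nk) / (yr / nr))
        a = 0.5 * np.log2((yk / nk) * (yr / nr))
        n = len(m)
        keep = np.ones(n, dtype=bool)
        for vals, trim in ((m, logratio_trim), (a, abs_expr_trim)):
            lo = int(np.floor(n * trim))
            order = np.argsort(vals, kind="stable")
            ranks = np.empty(n, dtype=int)
            ranks[order] = np.arange(n)
            keep &= (ranks >= lo) & (ranks < n - lo)
        w = 1.0 / ((nk - yk[keep]) / (nk * yk[keep]) + (nr - yr[keep]) / (nr * yr[keep]))
        f = float(np.sum(w * m[keep]) / np.sum(w))
        factors.append(2.0**f)
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors))), ref


def oracle_concordance_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance probability (ties get 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


def random_count_matrix(seed: int, n_genes: int = 50, n_samples: int = 4) -> np.ndarray:
    rng = np.random.default_rng(seed)
    lam = rng.uniform(1, 50, size=n_genes)
    depth = rng.uniform(0.5, 2.0, size=n_samples)
    X = rng.poisson(lam[:, None] * depth[None, :]).astype(float)
    X[X.sum(axis=1) == 0, 0] = 1  # keep every gene observed somewhere
    return X


def run_transfer_study(seeds, divergence: float = 0.6, epochs: int = 100):
    """Two-species transfer comparison: one shared source CNN, seeded
    target draws; returns the per-mode metric table over all seeds."""
    import pandas as pd

    from grnkit import ModelConfig, TransferPlan
    from grnkit.synthetic import generate_species_pair
    from grnkit.transfer import run_transfer_experiment

    spec = SyntheticSpec(
        n_genes=1500, n_tfs=60, n_samples=200, n_positive_pairs=700,
        signal=2.0, noise_sd=0.5, seed=1,
    )
    src, tgt, _ = generate_species_pair(spec, divergence=divergence, fanout=1)

    def featurize(ds, seed):
        negs = sample_negative_pairs(
            ds.tf_ids, ds.compendium.gene_ids, ds.positives, len(ds.positives), seed=seed
        )
        F = build_feature_matrix(ds.positives + negs, ds.compendium)
        X, _ = preprocess_features(F.values)
        return X, F.labels

    Xs, ys = featurize(src, 11)
    Xt, yt = featurize(tgt, 12)
    cfg = ModelConfig(conv_kernels=(8, 8), epochs=epochs, seed=1)
    source = train_model(build_model(cfg, Xs.shape[1]), Xs, ys, epochs=epochs)
    frames = []
    for seed in seeds:
        plan = TransferPlan(
            source_model=source, target_train_size=100, target_test_size=500,
            epochs=epochs, seed=seed, config=cfg,
        )
        frames.append(run_transfer_experiment(plan, None, (Xt, yt)))
    return pd.concat(frames, ignore_index=True)


def run_hybrid_pipeline(
    signal: float,
    seed: int,
    n_genes: int = 2500,
    n_tfs: int = 100,
    n_samples: int = 200,
    n_pairs: int = 1000,
    epochs: int = 30,
    conv_kernels=(8, 8),
    permute_labels: bool = False,
):
    """Synthetic data -> CNN encoder -> random-forest hybrid; returns AUCs.

    Returns (hybrid holdout AUC, plain random-forest holdout AUC).
    """
    spec = SyntheticSpec(
        n_genes=n_genes,
        n_tfs=n_tfs,
        n_samples=n_samples,
        n_positive_pairs=n_pairs,
        signal=signal,
        noise_sd=0.5,
        seed=seed,
    )
    ds = generate_dataset(spec)
    negs = sample_negative_pairs(
        ds.tf_ids, ds.compendium.gene_ids, ds.positives, n_pairs, seed=seed + 100
    )
    train_p, test_p = split_holdout(ds.positives + negs, 0.2, seed)
    Ftr = build_feature_matrix(train_p, ds.compendium)
    Fte = build_feature_matrix(test_p, ds.compendium)
    Xtr, stats = preprocess_features(Ftr.values)
    Xte, _ = preprocess_features(Fte.values, stats=stats)
    ytr, yte = Ftr.labels, Fte.labels
    if permute_labels:
        ytr = np.random.default_rng(seed).permutation(ytr)
    cfg = ModelConfig(conv_kernels=conv_kernels, epochs=epochs, seed=seed)
    encoder = build_model(cfg, Xtr.shape[1])
    train_model(encoder, Xtr, ytr)
    hybrid = fit_hybrid(
        extract_features(encoder, Xtr), ytr, ClassifierSpec("random_forest", seed=seed)
    )
    hybrid_auc = roc_auc(hybrid.predict_proba(extract_features(encoder, Xte)), yte).auc
    plain = fit_hybrid(EncoderFeatures(Xtr, "raw"), ytr, ClassifierSpec("random_forest", seed=seed))
    plain_auc = roc_auc(plain.predict_proba(Xte), yte).auc
    return hybrid_auc, plain_auc
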