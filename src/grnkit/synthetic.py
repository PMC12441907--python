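"""Seeded synthetic expression compendia with planted regulatory structure.

The generator emulates the statistical premise of supervised TF-target
classification from co-expression: a regulated target's expression follows
a (possibly nonlinear) noisy function of its TF's expression across
samples, while unrelated genes are independent. Latent expression is
Gaussian; the observed compendium is exp(latent) — log-normal, like
normalized RNA-seq abundances — or, in count mode, overdispersed
negative-binomial counts with sample-specific sequencing depths spanning a
5-fold range (for exercising TMM normalization). A paired "second species"
shares the regulatory logic through an emitted homolog table, with
per-gene fan-out copies and a tunable expression divergence.

Per-pair coupling strengths are jittered +/-50% around the nominal signal
and carry a random sign (activation or repression), so classifiers cannot
key on a single constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionCompendium
from .pairs import HomologMap, RegulatoryPair, RegulatoryPairSet, map_pairs_by_homology

log = logging.getLogger("grnkit")

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_dataset", "generate_species_pair"]

_NONLINEARITIES = ("linear", "quadratic", "threshold")
_NB_DISPERSION = 0.1
_BASE_DEPTH = 20.0
_DEPTH_SPAN = 5.0


@dataclass
class SyntheticSpec:
    """Conditions of one synthetic study.

    ``signal`` is the nominal coupling coefficient beta (0 = no dependency);
    ``noise_sd`` the Gaussian noise on regulated targets (latent scale).
    """

    n_genes: int = 200
    n_tfs: int = 20
    n_samples: int = 200
    n_positive_pairs: int = 100
    signal: float = 2.0
    noise_sd: float = 0.5
    nonlinearity: str = "linear"
    count_mode: bool = False
    n_master_targets: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must be <= n_genes")
        if self.n_positive_pairs > self.n_tfs * (self.n_genes - 1):
            raise ValueError("n_positive_pairs exceeds the possible pair count")
        if self.n_positive_pairs > self.n_genes - self.n_tfs:
            raise ValueError(
                "n_positive_pairs must be <= n_genes - n_tfs "
                "(each target gets at most one regulator)"
            )
        if self.signal < 0 or self.noise_sd <= 0:
            raise ValueError("signal must be >= 0 and noise_sd > 0")
        if self.nonlinearity not in _NONLINEARITIES:
            raise ValueError(f"nonlinearity must be one of {_NONLINEARITIES}")
        if not 0 <= self.n_master_targets <= self.n_positive_pairs:
            raise ValueError("n_master_targets must be in [0, n_positive_pairs]")
        if min(self.n_genes, self.n_samples) < 2:
            raise ValueError("need at least 2 genes and 2 samples")


@dataclass
class SyntheticDataset:
    """A compendium plus its planted positives and the full truth map."""

    compendium: ExpressionCompendium
    positives: RegulatoryPairSet
    tf_ids: list[str]
    ground_truth: dict[tuple[str, str], int] = field(repr=False, default_factory=dict)

    def label_of(self, tf_id: str, target_id: str) -> int:
        return self.ground_truth.get((tf_id, target_id), 0)


def _apply_nonlinearity(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return x
    if kind == "quadratic":
        return x * x
    return (x > 0).astype(float)  # threshold


def _nonlinearity_moments(beta: float, kind: str) -> tuple[float, float]:
    """Analytic mean and variance of f(beta * Z) for Z ~ N(0, 1)."""
    if beta == 0:
        return 0.0, 0.0
    if kind == "linear":
        return 0.0, beta * beta
    if kind == "quadratic":  # (beta Z)^2 ~ beta^2 chi^2_1
        return beta * beta, 2.0 * beta**4
    return 0.5, 0.25  # threshold indicator


def _draw_couplings(spec: SyntheticSpec) -> list[tuple[int, int, float]]:
    """(tf index, target index, signed beta) triples; one regulator per target.

    The first ``n_master_targets`` pairs are all assigned to TF 0, planting a
    master regulator whose target set serves as a synthetic pathway.
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    non_tf = np.arange(spec.n_tfs, spec.n_genes)
    targets = rng.choice(non_tf, size=spec.n_positive_pairs, replace=False)
    tfs = rng.integers(0, spec.n_tfs, size=spec.n_positive_pairs)
    tfs[: spec.n_master_targets] = 0
    betas = spec.signal * rng.uniform(0.5, 1.5, size=spec.n_positive_pairs)
    signs = rng.choice((1.0, -1.0), size=spec.n_positive_pairs)
    return [(int(t), int(g), float(b * s)) for t, g, b, s in zip(tfs, targets, betas, signs)]


def _latent_matrix(
    spec: SyntheticSpec, couplings, rng: np.random.Generator
) -> np.ndarray:
    z = rng.normal(0.0, 1.0, size=(spec.n_genes, spec.n_samples))
    for tf_i, tgt_i, beta in couplings:
        f = _apply_nonlinearity(beta * z[tf_i], spec.nonlinearity)
        mu, var = _nonlinearity_moments(beta, spec.nonlinearity)
        eps = rng.normal(0.0, spec.noise_sd, size=spec.n_samples)
        # standardize analytically so a regulated target's marginal matches
        # unregulated genes; at beta = 0 this reduces to the exact null
        z[tgt_i] = (f - mu + eps) / np.sqrt(var + spec.noise_sd**2)
    return z


def _observe(
    spec: SyntheticSpec, latent: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Latent -> observed matrix; returns (values, normalized flag)."""
    if not spec.count_mode:
        return np.exp(latent), True
    u = rng.random(spec.n_samples)
    u = (u - u.min()) / max(u.max() - u.min(), 1e-12)
    depth = _DEPTH_SPAN**u  # library depths spanning exactly a 5-fold range
    mean = _BASE_DEPTH * depth[None, :] * np.exp(latent)
    lam = rng.gamma(shape=1.0 / _NB_DISPERSION, scale=mean * _NB_DISPERSION)
    return rng.poisson(lam).astype(float), False


def _gene_ids(spec: SyntheticSpec, prefix: str = "") -> list[str]:
    tfs = [f"{prefix}TF{i:04d}" for i in range(spec.n_tfs)]
    others = [f"{prefix}G{i:05d}" for i in range(spec.n_genes - spec.n_tfs)]
    return tfs + others


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate one seeded dataset; identical spec+seed gives identical bytes."""
    couplings = _draw_couplings(spec)
    rng = np.random.default_rng(spec.seed + 2_000_003)
    latent = _latent_matrix(spec, couplings, rng)
    values, normalized = _observe(spec, latent, rng)
    gene_ids = _gene_ids(spec)
    sample_ids = [f"S{j:04d}" for j in range(spec.n_samples)]
    comp = ExpressionCompendium(gene_ids, sample_ids, values, normalized=normalized)
    pairs = [
        RegulatoryPair(gene_ids[t], gene_ids[g], 1, "curated") for t, g, _ in couplings
    ]
    positives = RegulatoryPairSet(pairs, species="synthetic")
    truth = {p.key: 1 for p in pairs}
    return SyntheticDataset(comp, positives, gene_ids[: spec.n_tfs], truth)


def generate_species_pair(
    spec: SyntheticSpec, divergence: float = 0.1, fanout: int = 1
) -> tuple[SyntheticDataset, SyntheticDataset, tuple[HomologMap, HomologMap]]:
    """A source dataset plus a homolog-linked second species.

    The target species re-expresses the same regulatory program (identical
    couplings) in fresh samples; every source gene has ``fanout`` homolog
    copies, each perturbed by Gaussian noise of sd ``divergence`` on the
    latent scale. Homolog maps are returned separately for TFs and non-TF
    genes, and the target's positive pairs are produced by mapping the
    source positives through them.
    """
    if fanout < 1:
        raise ValueError("fanout must be >= 1")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    source = generate_dataset(spec)
    couplings = _draw_couplings(spec)
    rng = np.random.default_rng(spec.seed + 3_000_003)
    latent = _latent_matrix(spec, couplings, rng)
    src_ids = _gene_ids(spec)
    tgt_ids: list[str] = []
    tgt_rows: list[np.ndarray] = []
    tf_map: dict[str, set[str]] = {}
    gene_map: dict[str, set[str]] = {}
    for i, gid in enumerate(src_ids):
        copies = set()
        for j in range(fanout):
            cid = f"sp2_{gid}_h{j}"
            tgt_ids.append(cid)
            tgt_rows.append(latent[i] + rng.normal(0.0, divergence, size=spec.n_samples))
            copies.add(cid)
        (tf_map if i < spec.n_tfs else gene_map)[gid] = copies
    tgt_latent = np.vstack(tgt_rows)
    values, normalized = _observe(spec, tgt_latent, rng)
    sample_ids = [f"T{j:04d}" for j in range(spec.n_samples)]
    comp = ExpressionCompendium(tgt_ids, sample_ids, values, normalized=normalized)
    tf_hmap, gene_hmap = HomologMap(tf_map), HomologMap(gene_map)
    positives = map_pairs_by_homology(source.positives, tf_hmap, gene_hmap, species="sp2")
    target = SyntheticDataset(
        comp,
        positives,
        sorted({c for s in tf_map.values() for c in s}),
        {p.key: 1 for p in positives},
    )
    return source, target, (tf_hmap, gene_hmap)
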