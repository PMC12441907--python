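"""Cross-species transfer learning for CNN pair classifiers.

A CNN trained on a data-rich source species donates its convolutional
kernels to a model for a data-poor target species. The 3 x 3 kernels are
width-agnostic, so they transfer even when the two species' compendia have
different sample counts; the flatten/dense head is rebuilt for the new
input width and freshly initialized. The target model is then trained
either with the transferred kernels frozen (only the head learns) or with
the whole network fine-tuned. The "no transfer" baseline is the same
architecture trained from random initialization on the small target set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .evaluate import confusion_metrics, roc_auc
from .models import ModelConfig, NeuralNetwork, build_model, train_model

log = logging.getLogger("grnkit")

__all__ = ["TransferPlan", "transfer_encoder", "run_transfer_experiment"]

_MODES = ("scratch", "frozen", "fine_tune")


@dataclass
class TransferPlan:
    """Configuration of one small-data transfer experiment.

    ``target_train_size`` and ``target_test_size`` are per class; the test
    set is fixed and shared across all modes.
    """

    source_model: Optional[NeuralNetwork] = None
    modes: tuple[str, ...] = _MODES
    target_train_size: int = 100
    target_test_size: int = 500
    epochs: int = 100
    seed: int = 0
    config: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        for m in self.modes:
            if m not in _MODES:
                raise ValueError(f"unknown transfer mode {m!r}; valid: {list(_MODES)}")
        if self.target_train_size <= 0 or self.target_test_size <= 0:
            raise ValueError("target train/test sizes must be > 0")


def transfer_encoder(
    source: NeuralNetwork, target_input_width: int, seed: Optional[int] = None
) -> NeuralNetwork:
    """Copy a trained CNN's convolutional weights into a fresh model.

    The dense head is re-initialized (and re-dimensioned if the target
    species has a different sample count); only the conv kernels carry over.
    """
    if source.config.model_family != "cnn":
        raise ValueError("transfer requires a CNN source model")
    if target_input_width % 2:
        raise ValueError("target input width must be even")
    cfg = source.config if seed is None else replace(source.config, seed=seed)
    target = build_model(cfg, target_input_width)
    for src_l, tgt_l in zip(source.conv_layers, target.conv_layers):
        tgt_l.W[...] = src_l.W
        tgt_l.b[...] = src_l.b
    return target


def _draw_split(
    X: np.ndarray, y: np.ndarray, n_train: int, n_test: int, rng: np.random.Generator
):
    """Per-class disjoint draws: n_train training and n_test test rows each."""
    tr_idx, te_idx = [], []
    for c in (0, 1):
        members = np.flatnonzero(y == c)
        if members.size < n_train + n_test:
            raise ValueError(
                f"class {c} has {members.size} pairs; "
                f"{n_train}+{n_test} per class required"
            )
        perm = rng.permutation(members)
        tr_idx.extend(perm[:n_train])
        te_idx.extend(perm[n_train : n_train + n_test])
    tr_idx = np.asarray(tr_idx)
    te_idx = np.asarray(te_idx)
    return X[tr_idx], y[tr_idx], X[te_idx], y[te_idx]


def run_transfer_experiment(
    plan: TransferPlan,
    source_data: Optional[tuple[np.ndarray, np.ndarray]],
    target_data: tuple[np.ndarray, np.ndarray],
) -> pd.DataFrame:
    """Train per plan in each mode and score F1/AUC on one shared test set.

    ``source_data``/``target_data`` are ``(X, y)`` pair-feature arrays. If
    ``plan.source_model`` is None, a source CNN is first trained on
    ``source_data`` with the plan's config. Scratch mode ignores the source
    model entirely. Returns a table with columns mode, f1, auc, seed.
    """
    Xt, yt = np.asarray(target_data[0], dtype=float), np.asarray(target_data[1]).ravel()
    rng = np.random.default_rng(plan.seed)
    Xtr, ytr, Xte, yte = _draw_split(
        Xt, yt, plan.target_train_size, plan.target_test_size, rng
    )
    source = plan.source_model
    if source is None and any(m in ("frozen", "fine_tune") for m in plan.modes):
        if source_data is None:
            raise ValueError("source_data or a trained source_model is required")
        Xs, ys = source_data
        cfg = replace(plan.config, model_family="cnn", seed=plan.seed)
        source = build_model(cfg, np.asarray(Xs).shape[1])
        train_model(source, Xs, ys, epochs=plan.epochs)
    rows = []
    for mode in plan.modes:
        cfg = replace(plan.config, model_family="cnn", seed=plan.seed + 1)
        if mode == "scratch":
            model = build_model(cfg, Xtr.shape[1])
        else:
            model = transfer_encoder(source, Xtr.shape[1], seed=plan.seed + 1)
            if mode == "frozen":
                model.set_encoder_trainable(False)
        train_model(model, Xtr, ytr, epochs=plan.epochs)
        scores = model.predict_proba(Xte)
        f1 = confusion_metrics(scores, yte).f1
        auc = roc_auc(scores, yte).auc
        rows.append({"mode": mode, "f1": f1, "auc": auc, "seed": plan.seed})
        log.info("transfer mode %s: F1=%.4f AUC=%.4f", mode, f1 if f1 else np.nan, auc)
    return pd.DataFrame(rows)
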