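"""Regulator prioritization by top-k prediction frequency.

Candidate TF x pathway-gene pairs are scored (by a trained classifier's
class-1 probability, or by |Spearman rank correlation| as a statistical
baseline), the top-k highest-scoring pairs are taken, and each TF's
frequency among them — how many pathway genes it is predicted to regulate —
becomes its priority. Frequencies are conserved: they sum to
min(top_k, number of scored pairs), and no TF can exceed the pathway size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionCompendium
from .pairs import RegulatoryPairSet

log = logging.getLogger("grnkit")

__all__ = [
    "ScoredPairTable",
    "RankedTFTable",
    "rank_tfs_by_frequency",
    "spearman_score_pairs",
    "score_pairs_with_model",
    "known_tf_recovery",
]


@dataclass
class ScoredPairTable:
    """(tf_id, target_id, score) rows; ``scorer`` tags the scoring method."""

    table: pd.DataFrame
    scorer: str = "model"

    def __post_init__(self) -> None:
        required = {"tf_id", "target_id", "score"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"scored table needs columns {sorted(required)}")
        if self.table.duplicated(["tf_id", "target_id"]).any():
            raise ValueError("duplicate (tf_id, target_id) in scored table")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RankedTFTable:
    """TF frequency ranking: rows of (rank, tf_id, frequency), descending."""

    table: pd.DataFrame
    top_k: int
    pathway_size: int | None = None

    def __post_init__(self) -> None:
        freqs = self.table["frequency"].to_numpy()
        if np.any(np.diff(freqs) > 0):
            raise ValueError("frequencies must be sorted non-increasing")
        if self.pathway_size is not None and np.any(freqs > self.pathway_size):
            raise ValueError("a TF frequency exceeds the pathway size")

    def rank_of(self, tf_id: str) -> int | None:
        hit = self.table.index[self.table["tf_id"] == tf_id]
        return int(self.table.loc[hit[0], "rank"]) if len(hit) else None


def rank_tfs_by_frequency(
    scored: ScoredPairTable, top_k: int = 1000, pathway_size: int | None = None
) -> RankedTFTable:
    """Count each TF's occurrences among the top-k highest-scored pairs.

    Pairs are sorted by score descending with deterministic lexicographic
    tie-breaking (tf_id then target_id); TFs are then sorted by frequency
    descending, ties by first appearance in the sorted pair list. Pairs with
    missing scores are dropped with a warning.
    """
    if top_k <= 0:
        raise ValueError(f"top_k must be > 0, got {top_k}")
    df = scored.table
    if len(df) == 0:
        raise ValueError("scored table is empty")
    na = df["score"].isna()
    if na.any():
        warnings.warn(f"dropping {int(na.sum())} pairs with undefined scores")
        df = df[~na]
    df = df.sort_values(
        ["score", "tf_id", "target_id"], ascending=[False, True, True], kind="mergesort"
    ).head(top_k)
    freq = df.groupby("tf_id", sort=False)["target_id"].count()
    order = np.argsort(-freq.to_numpy(), kind="stable")  # stable: ties by appearance
    out = pd.DataFrame(
        {
            "rank": np.arange(1, len(freq) + 1),
            "tf_id": freq.index.to_numpy()[order],
            "frequency": freq.to_numpy()[order],
        }
    )
    return RankedTFTable(out, top_k=top_k, pathway_size=pathway_size)


def spearman_score_pairs(
    pairs: RegulatoryPairSet, comp: ExpressionCompendium
) -> ScoredPairTable:
    """|Spearman rank correlation| between TF and target expression vectors.

    Ranks use the average-rank tie convention. Pairs involving a constant
    expression vector get an undefined (NaN) score with a warning. Each
    gene is ranked once, so scoring large cross-pair tables stays cheap.
    """
    genes = sorted({g for p in pairs for g in (p.tf_id, p.target_id)})
    missing = [g for g in genes if g not in comp]
    if missing:
        raise KeyError(f"gene(s) not in compendium: {missing[:5]}")
    n = comp.n_samples
    ranks, const = {}, set()
    for g in genes:
        v = comp.expression_of(g)
        if np.ptp(v) == 0:
            const.add(g)
            ranks[g] = None
            continue
        r = rankdata(v, method="average")
        r = (r - r.mean()) / (np.linalg.norm(r - r.mean()) or 1.0)
        ranks[g] = r
    if const:
        warnings.warn(
            f"{len(const)} gene(s) have constant expression; their pair scores are undefined"
        )
    rows = []
    for p in pairs:
        a, b = ranks[p.tf_id], ranks[p.target_id]
        score = np.nan if a is None or b is None else abs(float(a @ b))
        rows.append({"tf_id": p.tf_id, "target_id": p.target_id, "score": score})
    return ScoredPairTable(pd.DataFrame(rows), scorer="spearman")


def score_pairs_with_model(
    pairs: RegulatoryPairSet, scores: np.ndarray, scorer: str = "model"
) -> ScoredPairTable:
    """Wrap model probabilities (aligned with ``pairs`` order) as a table."""
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size != len(pairs):
        raise ValueError(f"{scores.size} scores for {len(pairs)} pairs")
    rows = [
        {"tf_id": p.tf_id, "target_id": p.target_id, "score": s}
        for p, s in zip(pairs, scores)
    ]
    return ScoredPairTable(pd.DataFrame(rows), scorer=scorer)


def known_tf_recovery(
    ranked: RankedTFTable, known_ids: set[str], top_n: int = 50, bin_width: int = 5
) -> tuple[list[int], int]:
    """Count known TFs per rank interval (1-5, 6-10, ...) within the top n.

    Returns ``(per-bin counts, total within top_n)``.
    """
    if top_n % bin_width:
        raise ValueError("top_n must be a multiple of bin_width")
    head = ranked.table.head(top_n)
    bins = [0] * (top_n // bin_width)
    for _, row in head.iterrows():
        if row["tf_id"] in known_ids:
            bins[(int(row["rank"]) - 1) // bin_width] += 1
    return bins, sum(bins)
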