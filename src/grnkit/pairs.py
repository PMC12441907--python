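"""Labeled TF-target pair sets and pair feature matrices.

Training data for supervised regulatory-link prediction consists of positive
(curated or homology-mapped) TF-target pairs and an equal-sized set of
sampled negative pairs. A pair is featurized as the TF's expression vector
concatenated with the target's expression vector across all compendium
samples (2S columns for S samples); the TF block comes first, which the CNN
input reshaping relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .expression import ExpressionCompendium

log = logging.getLogger("grnkit")

__all__ = [
    "RegulatoryPair",
    "RegulatoryPairSet",
    "HomologMap",
    "PairFeatureMatrix",
    "sample_negative_pairs",
    "map_pairs_by_homology",
    "cross_pairs",
    "build_feature_matrix",
    "split_holdout",
    "read_pairs_tsv",
    "write_pairs_tsv",
]

_SOURCES = {"curated", "homolog_mapped", "sampled_negative", "cross_pair"}


@dataclass(frozen=True)
class RegulatoryPair:
    tf_id: str
    target_id: str
    label: Optional[int] = None  # 1 positive, 0 negative, None unlabeled
    source: str = "curated"

    def __post_init__(self) -> None:
        if self.label not in (0, 1, None):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source tag {self.source!r}")
        if self.source == "sampled_negative" and self.tf_id == self.target_id:
            raise ValueError(f"sampled negative must not self-pair: {self.tf_id!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.tf_id, self.target_id)


@dataclass
class RegulatoryPairSet:
    """Ordered collection of regulatory pairs for one species."""

    pairs: list[RegulatoryPair]
    species: str = "unknown"

    def __post_init__(self) -> None:
        pos: set[tuple[str, str]] = set()
        neg: set[tuple[str, str]] = set()
        for p in self.pairs:
            if p.label == 1:
                if p.key in pos:
                    raise ValueError(f"duplicate positive pair {p.key}")
                pos.add(p.key)
            elif p.label == 0:
                if p.key in neg:
                    raise ValueError(f"duplicate negative pair {p.key}")
                neg.add(p.key)
        overlap = pos & neg
        if overlap:
            raise ValueError(f"pair(s) labeled both positive and negative: {sorted(overlap)[:3]}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[RegulatoryPair]:
        return iter(self.pairs)

    def keys(self) -> list[tuple[str, str]]:
        return [p.key for p in self.pairs]

    def labels(self) -> Optional[np.ndarray]:
        if any(p.label is None for p in self.pairs):
            return None
        return np.array([p.label for p in self.pairs], dtype=int)

    def positives(self) -> "RegulatoryPairSet":
        return RegulatoryPairSet([p for p in self.pairs if p.label == 1], self.species)

    def negatives(self) -> "RegulatoryPairSet":
        return RegulatoryPairSet([p for p in self.pairs if p.label == 0], self.species)

    def __add__(self, other: "RegulatoryPairSet") -> "RegulatoryPairSet":
        return RegulatoryPairSet(self.pairs + other.pairs, self.species)


class HomologMap:
    """Mapping from source-species gene IDs to sets of target-species IDs."""

    def __init__(self, mapping: dict[str, Iterable[str]]):
        self._map: dict[str, set[str]] = {}
        for src, tgts in mapping.items():
            tgts = {str(t) for t in tgts if str(t)}
            if not str(src):
                raise ValueError("empty source ID in homolog map")
            if tgts:  # empty target sets are not stored
                self._map[str(src)] = tgts

    def __getitem__(self, gene_id: str) -> set[str]:
        return self._map.get(gene_id, set())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    @classmethod
    def from_tsv(cls, path, delimiter: str = "\t") -> "HomologMap":
        df = pd.read_csv(path, sep=delimiter, header=None, comment="#", dtype=str)
        mapping: dict[str, set[str]] = {}
        for src, tgt in zip(df.iloc[:, 0], df.iloc[:, 1]):
            mapping.setdefault(src, set()).add(tgt)
        return cls(mapping)

    def to_tsv(self, path, delimiter: str = "\t") -> None:
        rows = [(s, t) for s, tgts in sorted(self._map.items()) for t in sorted(tgts)]
        pd.DataFrame(rows).to_csv(path, sep=delimiter, header=False, index=False)


@dataclass
class PairFeatureMatrix:
    """One row per pair: TF expression (S values) then target expression (S)."""

    values: np.ndarray
    pairs: list[RegulatoryPair]
    sample_ids: list[str]
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2 * len(self.sample_ids):
            raise ValueError(
                f"feature matrix must have 2 x {len(self.sample_ids)} columns, "
                f"got shape {self.values.shape}"
            )
        if self.values.shape[0] != len(self.pairs):
            raise ValueError("row count does not match number of pairs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("labels length does not match rows")

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def sample_negative_pairs(
    tf_ids: list[str],
    gene_universe: list[str],
    positives: RegulatoryPairSet,
    n: int,
    seed: int,
    species: str = "unknown",
) -> RegulatoryPairSet:
    """Draw ``n`` distinct negative pairs uniformly from the admissible set.

    Admissible pairs are TF x gene-universe combinations excluding self-pairs
    and the supplied positive pairs. Reproducible for a fixed seed.
    """
    tf_ids = [str(t) for t in tf_ids]
    universe = [str(g) for g in gene_universe]
    if len(set(tf_ids)) != len(tf_ids) or len(set(universe)) != len(universe):
        raise ValueError("tf_ids and gene_universe must be duplicate-free")
    pos_keys = set(positives.keys())
    uni_set = set(universe)
    tf_set = set(tf_ids)
    n_self = sum(1 for t in tf_ids if t in uni_set)
    n_pos_excl = sum(1 for (t, g) in pos_keys if t in tf_set and g in uni_set and t != g)
    admissible = len(tf_ids) * len(universe) - n_self - n_pos_excl
    if n > admissible:
        raise ValueError(
            f"requested {n} negative pairs but only {admissible} admissible pairs exist"
        )
    rng = np.random.default_rng(seed)
    total = len(tf_ids) * len(universe)
    chosen: list[tuple[str, str]] = []
    if total <= 2_000_000:
        # exact: enumerate admissible pair indices and sample without replacement
        g_index = {g: i for i, g in enumerate(universe)}
        t_index = {t: i for i, t in enumerate(tf_ids)}
        excl_idx: set[int] = set()
        for ti, t in enumerate(tf_ids):
            if t in g_index:
                excl_idx.add(ti * len(universe) + g_index[t])
        for t, g in pos_keys:
            if t in t_index and g in g_index:
                excl_idx.add(t_index[t] * len(universe) + g_index[g])
        idx_ok = np.setdiff1d(
            np.arange(total), np.fromiter(excl_idx, dtype=int, count=len(excl_idx))
        )
        pick = rng.choice(idx_ok, size=n, replace=False)
        chosen = [(tf_ids[i // len(universe)], universe[i % len(universe)]) for i in pick]
    else:
        seen: set[tuple[str, str]] = set()
        while len(chosen) < n:
            ti = rng.integers(0, len(tf_ids), size=n)
            gi = rng.integers(0, len(universe), size=n)
            for a, b in zip(ti, gi):
                t, g = tf_ids[a], universe[b]
                if t == g or (t, g) in pos_keys or (t, g) in seen:
                    continue
                seen.add((t, g))
                chosen.append((t, g))
                if len(chosen) == n:
                    break
    pairs = [RegulatoryPair(t, g, 0, "sampled_negative") for t, g in chosen]
    return RegulatoryPairSet(pairs, species)


def map_pairs_by_homology(
    positives: RegulatoryPairSet,
    tf_map: HomologMap,
    gene_map: HomologMap,
    species: str = "mapped",
) -> RegulatoryPairSet:
    """Transfer positive pairs to another species through homolog maps.

    Each source pair expands to the cartesian product of its TF homologs and
    target homologs; duplicates are removed and pairs with no homolog on
    either side are dropped (logged, not fatal).
    """
    if any(p.label != 1 for p in positives):
        raise ValueError("homology mapping expects positive (label 1) pairs only")
    out: list[RegulatoryPair] = []
    seen: set[tuple[str, str]] = set()
    dropped = 0
    for p in positives:
        tf_h = tf_map[p.tf_id]
        tg_h = gene_map[p.target_id]
        if not tf_h or not tg_h:
            dropped += 1
            log.info("dropping pair (%s, %s): no homolog", p.tf_id, p.target_id)
            continue
        for t in sorted(tf_h):
            for g in sorted(tg_h):
                if (t, g) not in seen:
                    seen.add((t, g))
                    out.append(RegulatoryPair(t, g, 1, "homolog_mapped"))
    if dropped:
        log.warning("homology mapping dropped %d of %d pairs", dropped, len(positives))
    return RegulatoryPairSet(out, species)


def cross_pairs(
    tf_ids: list[str], pathway_gene_ids: list[str], species: str = "unknown"
) -> RegulatoryPairSet:
    """All |TFs| x |pathway genes| ordered pairs, unlabeled."""
    tf_ids = [str(t) for t in tf_ids]
    genes = [str(g) for g in pathway_gene_ids]
    if not tf_ids or not genes:
        raise ValueError("both lists must be nonempty")
    if len(set(tf_ids)) != len(tf_ids):
        raise ValueError("duplicate IDs in tf_ids")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate IDs in pathway_gene_ids")
    pairs = [RegulatoryPair(t, g, None, "cross_pair") for t in tf_ids for g in genes]
    return RegulatoryPairSet(pairs, species)


def build_feature_matrix(
    pairs: RegulatoryPairSet, comp: ExpressionCompendium
) -> PairFeatureMatrix:
    """Featurize pairs as TF expression || target expression (2S columns).

    Pairs whose TF or target is absent from the compendium are dropped with a
    logged count; row order is preserved among retained pairs.
    """
    if comp.n_samples < 1:
        raise ValueError("compendium has no samples")
    retained: list[RegulatoryPair] = []
    rows: list[int] = []
    idx = comp._gene_index
    for p in pairs:
        if p.tf_id in idx and p.target_id in idx:
            retained.append(p)
            rows.append(idx[p.tf_id])
            rows.append(idx[p.target_id])
    dropped = len(pairs) - len(retained)
    if dropped:
        log.warning("dropped %d of %d pairs missing from the compendium", dropped, len(pairs))
    if not retained:
        raise ValueError("no pairs remain after dropping genes absent from the compendium")
    mat = comp.values[np.asarray(rows)].reshape(len(retained), 2 * comp.n_samples)
    labels = None
    if all(p.label is not None for p in retained):
        labels = np.array([p.label for p in retained], dtype=int)
    return PairFeatureMatrix(mat, retained, list(comp.sample_ids), labels)


def split_holdout(
    pairs: RegulatoryPairSet, test_fraction: float = 0.2, seed: int = 0
) -> tuple[RegulatoryPairSet, RegulatoryPairSet]:
    """Stratified train/holdout split of a labeled pair set.

    Per class, ``round(test_fraction * n_class)`` pairs go to the holdout set;
    the split is disjoint, exhaustive and reproducible for a fixed seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    labels = pairs.labels()
    if labels is None:
        raise ValueError("split_holdout requires labeled pairs")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(labels == c)
        if members.size < 2:
            raise ValueError(f"class {c} has fewer than 2 members")
        n_test = int(round(test_fraction * members.size))
        n_test = min(max(n_test, 1), members.size - 1)
        test_idx.extend(rng.permutation(members)[:n_test].tolist())
    test_set = set(test_idx)
    train = [p for i, p in enumerate(pairs.pairs) if i not in test_set]
    test = [p for i, p in enumerate(pairs.pairs) if i in test_set]
    return (
        RegulatoryPairSet(train, pairs.species),
        RegulatoryPairSet(test, pairs.species),
    )


def read_pairs_tsv(path, delimiter: str = "\t", species: str = "unknown") -> RegulatoryPairSet:
    """Read a pair list TSV with columns tf_id, target_id and optional label."""
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str)
    cols = [c.lower() for c in df.columns]
    if "tf_id" not in cols or "target_id" not in cols:
        # headerless two/three column file
        df = pd.read_csv(path, sep=delimiter, comment="#", header=None, dtype=str)
        df.columns = ["tf_id", "target_id", "label"][: df.shape[1]]
    else:
        df.columns = cols
    pairs = []
    for _, row in df.iterrows():
        label = None
        if "label" in df.columns and pd.notna(row.get("label")):
            label = int(row["label"])
        source = "curated" if label == 1 else ("sampled_negative" if label == 0 else "cross_pair")
        pairs.append(RegulatoryPair(str(row["tf_id"]), str(row["target_id"]), label, source))
    return RegulatoryPairSet(pairs, species)


def write_pairs_tsv(pairs: RegulatoryPairSet, path, delimiter: str = "\t") -> None:
    rows = [
        {"tf_id": p.tf_id, "target_id": p.target_id, "label": p.label, "source": p.source}
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
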