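"""Expression compendium I/O and TMM between-sample normalization.

A compendium is a genes x samples matrix of non-negative expression values
(raw read counts or normalized expression). Raw-count compendia are placed on
a common scale with the weighted trimmed mean of M-values (TMM) procedure:
each sample receives a scaling factor computed from precision-weighted,
doubly-trimmed log expression ratios against a reference sample, and the
factors are rescaled to geometric mean 1 so the overall expression level is
preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("grnkit")

__all__ = [
    "ExpressionCompendium",
    "NormalizationFactors",
    "read_expression_matrix",
    "write_expression_matrix",
    "tmm_normalize",
]


@dataclass
class ExpressionCompendium:
    """Genes x samples matrix of non-negative expression values.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers, unique, in matrix order.
    sample_ids : list of str
        Column identifiers, unique, in matrix order.
    values : ndarray of shape (n_genes, n_samples)
        Non-negative, finite expression values.
    normalized : bool
        True when the values are normalized expression rather than raw counts.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    normalized: bool = False
    _gene_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} ID: {i!r}")
                seen.add(i)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def expression_of(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across all samples."""
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in compendium") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, normalized: bool = False) -> "ExpressionCompendium":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), normalized)

    def log1p(self) -> "ExpressionCompendium":
        """log(1 + x) transform; models that want log-scale input use this."""
        return ExpressionCompendium(
            list(self.gene_ids), list(self.sample_ids), np.log1p(self.values), self.normalized
        )


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors with geometric mean 1."""

    sample_ids: list[str]
    factors: np.ndarray
    library_sizes: np.ndarray
    reference_sample_id: str

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if np.any(self.factors <= 0):
            raise ValueError("all normalization factors must be > 0")
        if np.any(self.library_sizes <= 0):
            raise ValueError("all library sizes must be > 0")
        gm = np.exp(np.mean(np.log(self.factors)))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"geometric mean of factors is {gm}, expected 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "factor": self.factors})


def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionCompendium:
    """Read a delimited expression matrix (first row samples, first column genes).

    Raises
    ------
    ValueError
        On duplicate gene/sample IDs (naming the duplicate), non-numeric
        cells (with row/column coordinates) or negative values.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & df.notna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-numeric value {df.iat[r, c]!r} at gene {gene_ids[r]!r}, "
            f"sample {sample_ids[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value at gene {gene_ids[r]!r}, sample {sample_ids[c]!r}")
    return ExpressionCompendium(gene_ids, sample_ids, numeric.to_numpy(dtype=float))


def write_expression_matrix(comp: ExpressionCompendium, path, delimiter: str = "\t") -> None:
    comp.to_frame().to_csv(path, sep=delimiter, index_label="gene_id")


def _upper_quartile_reference(values: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Index of the sample whose upper quartile of library-size-scaled nonzero
    counts is closest to the mean upper quartile across samples."""
    uq = np.empty(values.shape[1])
    for s in range(values.shape[1]):
        col = values[:, s]
        nz = col[col > 0] / lib_sizes[s]
        uq[s] = np.quantile(nz, 0.75) if nz.size else 0.0
    return int(np.argmin(np.abs(uq - uq.mean())))


def _trim_keep(x: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping ranks in [floor(n*trim), n - floor(n*trim)).

    Ranks come from a stable sort, so ties are broken by gene order.
    """
    n = x.size
    lo = int(np.floor(n * trim))
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(x, kind="stable")] = np.arange(n)
    return (ranks >= lo) & (ranks < n - lo)


def tmm_factor_pair(
    y_k: np.ndarray,
    y_r: np.ndarray,
    n_k: float,
    n_r: float,
    logratio_trim: float,
    abs_expr_trim: float,
) -> float:
    """Unscaled TMM factor of one sample against the reference.

    Genes with a zero count in either sample are excluded; M (log2 ratio of
    library-size-scaled counts) and A (mean log2 abundance) are doubly
    trimmed; the factor is 2**(precision-weighted mean of surviving M) with
    weights 1 / [(N_k - y_k)/(N_k y_k) + (N_r - y_r)/(N_r y_r)].
    """
    mask = (y_k > 0) & (y_r > 0)
    if not mask.any():
        log.warning("no genes co-expressed with the reference; factor set to 1")
        return 1.0
    y_k = y_k[mask].astype(float)
    y_r = y_r[mask].astype(float)
    p_k = y_k / n_k
    p_r = y_r / n_r
    m = np.log2(p_k / p_r)
    a = 0.5 * np.log2(p_k * p_r)
    keep = _trim_keep(m, logratio_trim) & _trim_keep(a, abs_expr_trim)
    if not keep.any():
        return 1.0
    v = (n_k - y_k[keep]) / (n_k * y_k[keep]) + (n_r - y_r[keep]) / (n_r * y_r[keep])
    with np.errstate(divide="ignore"):
        w = 1.0 / v
    if not np.isfinite(w).all() or w.sum() == 0:
        # degenerate weights (e.g. a sample equal to its own library): plain mean
        f = m[keep].mean()
    else:
        f = float(np.sum(w * m[keep]) / np.sum(w))
    return float(2.0**f)


def tmm_normalize(
    comp: ExpressionCompendium,
    logratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> tuple[ExpressionCompendium, NormalizationFactors]:
    """TMM-normalize a raw-count compendium.

    Returns the normalized compendium (counts divided by effective library
    size ``library_size * factor`` and multiplied by the mean library size, so
    magnitudes stay on a counts-like scale) together with the per-sample
    factors, rescaled to geometric mean 1.
    """
    if comp.normalized:
        raise ValueError("compendium is already normalized; TMM expects raw counts")
    if comp.n_samples < 2:
        raise ValueError("TMM normalization needs at least 2 samples")
    for name, trim in (("logratio_trim", logratio_trim), ("abs_expr_trim", abs_expr_trim)):
        if not 0 <= trim < 0.5:
            raise ValueError(f"{name} must be in [0, 0.5), got {trim}")
    x = comp.values
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = comp.sample_ids[int(np.argmax(lib <= 0))]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    ref = _upper_quartile_reference(x, lib)
    factors = np.array(
        [
            tmm_factor_pair(x[:, s], x[:, ref], lib[s], lib[ref], logratio_trim, abs_expr_trim)
            for s in range(comp.n_samples)
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    normalized = x / (lib * factors) * lib.mean()
    norm_comp = ExpressionCompendium(
        list(comp.gene_ids), list(comp.sample_ids), normalized, normalized=True
    )
    nf = NormalizationFactors(
        list(comp.sample_ids), factors, lib, comp.sample_ids[ref]
    )
    return norm_comp, nf
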