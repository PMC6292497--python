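"""Expression normalization, binarization and tissue-specificity scoring.

Everything downstream (divergence matrices, fate classification, NACC)
consumes the containers defined here.  Matrices are genes x samples with
non-negative, finite values; the first TSV column is always ``gene_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "BinaryExpressionProfile",
    "TauScore",
    "compute_crpkm",
    "quantile_normalize",
    "binarize",
    "tau_index",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    units
        Free-text tag recording the unit/normalization state (e.g.
        ``"counts"``, ``"cRPKM"``, ``"TPM-qnorm"``).
    """

    values: pd.DataFrame
    units: str = "arbitrary"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @classmethod
    def from_tsv(cls, path, units: str = "arbitrary") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df, units=units)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class BinaryExpressionProfile:
    """On/off calls per gene across an ordered list of homologous domains."""

    values: pd.DataFrame  # boolean, genes x domains
    threshold: float = 5.0

    def __post_init__(self) -> None:
        if not self.values.dtypes.map(lambda d: d == bool).all():
            arr = self.values.to_numpy()
            if not np.isin(arr, [0, 1]).all():
                raise ValueError("binary profile must contain only 0/1 entries")
            self.values = self.values.astype(bool)

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def domain_ids(self) -> list:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path, threshold: float = 5.0) -> "BinaryExpressionProfile":
        df = pd.read_csv(path, sep="\t", index_col=0).astype(int)
        df.index.name = None
        return cls(df, threshold=threshold)

    def to_tsv(self, path) -> None:
        self.values.astype(int).to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class TauScore:
    """Tissue-specificity index for one gene: 0 = ubiquitous, 1 = single-domain."""

    gene_id: str
    tau: Optional[float]
    n: int
    xhat: Optional[np.ndarray] = field(default=None, repr=False)
    reason: Optional[str] = None


def compute_crpkm(
    counts: pd.DataFrame,
    mappable_len_bp: pd.Series,
    library_sizes: pd.Series,
) -> ExpressionMatrix:
    """Corrected reads per kb of mappable positions and million reads.

    value = reads / (mappable_len_bp / 1e3) / (library_size / 1e6)
    """
    counts = counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    lens = mappable_len_bp.reindex(counts.index)
    if lens.isna().any():
        missing = lens.index[lens.isna()].tolist()
        raise ValueError(f"missing mappable length for genes: {missing[:5]}")
    bad = lens.index[lens <= 0].tolist()
    if bad:
        raise ValueError(f"non-positive mappable length for genes: {bad[:5]}")
    libs = library_sizes.reindex(counts.columns)
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("library sizes must be positive for every sample")
    vals = counts.div(lens / 1e3, axis=0).div(libs / 1e6, axis=1)
    return ExpressionMatrix(vals, units="cRPKM")


def _qnorm_values(arr: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns of ``arr`` against the mean order statistic.

    Ties within a column receive the mean of the reference values over the
    rank span they occupy, so the result is deterministic and idempotent.
    """
    n, m = arr.shape
    order = np.argsort(arr, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(arr, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(arr, dtype=float)
    for j in range(m):
        col_sorted = sorted_vals[:, j]
        mapped = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col_sorted[k + 1] == col_sorted[i]:
                k += 1
            mapped[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order[:, j], j] = mapped
    return out


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the mean-order-statistic distribution."""
    df = matrix.values
    if df.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    out = _qnorm_values(df.to_numpy(dtype=float))
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    return ExpressionMatrix(res, units=f"{matrix.units}-qnorm")


def binarize(matrix: ExpressionMatrix, threshold: float = 5.0) -> BinaryExpressionProfile:
    """Strict threshold: on iff value > threshold (a value equal to the
    threshold is off)."""
    arr = matrix.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("cannot binarize negative expression values")
    return BinaryExpressionProfile(matrix.values > threshold, threshold=threshold)


def tau_index(expression_per_domain: Sequence[float], gene_id: str = "") -> TauScore:
    """Tissue-specificity index tau = sum(1 - x_i/max(x)) / (n - 1)."""
    x = np.asarray(expression_per_domain, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("tau requires at least 2 domains")
    if (x < 0).any():
        raise ValueError("tau requires non-negative expression")
    mx = x.max()
    if mx == 0:
        return TauScore(gene_id=gene_id, tau=None, n=n, reason="all-zero expression vector")
    xhat = x / mx
    tau = float((1.0 - xhat).sum() / (n - 1))
    return TauScore(gene_id=gene_id, tau=tau, n=n, xhat=xhat)
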