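"""Pairwise transcriptome divergence between developmental stages.

The distance is the Jensen-Shannon distance (square root of the
Jensen-Shannon divergence) between per-sample expression proportions over
a shared orthologue set, computed after joint quantile normalization.
With log base 2 the distance is bounded by 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, _qnorm_values

__all__ = [
    "DivergenceMatrix",
    "jsd",
    "stage_divergence_matrix",
    "bootstrap_divergence",
    "minimal_divergence_stages",
]

_LOG_FNS = {"log2": np.log2, "ln": np.log}


@dataclass
class DivergenceMatrix:
    """stagesA x stagesB Jensen-Shannon distances with optional bootstrap sd."""

    jsd: pd.DataFrame
    bootstrap_sd: Optional[pd.DataFrame] = None
    n_bootstrap: int = 0
    n_orthologues: int = 0
    log_base: str = "log2"

    @property
    def stagesA(self) -> list:
        return list(self.jsd.index)

    @property
    def stagesB(self) -> list:
        return list(self.jsd.columns)

    def to_tsv(self, path) -> None:
        self.jsd.to_csv(path, sep="\t", index_label="stageA")


def _jsd_terms(p: np.ndarray, q: np.ndarray, log) -> float:
    m = 0.5 * (p + q)
    div = 0.0
    for v in (p, q):
        mask = v > 0  # zero-probability terms contribute 0; m > 0 wherever v > 0
        div += 0.5 * float(np.sum(v[mask] * log(v[mask] / m[mask])))
    return float(np.sqrt(max(div, 0.0)))


def jsd(p: Sequence[float], q: Sequence[float], log_base: str = "log2", tol: float = 1e-6) -> float:
    """Jensen-Shannon distance between two probability vectors.

    Terms with a zero probability contribute 0 (continuity convention).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > tol or abs(q.sum() - 1.0) > tol:
        raise ValueError(f"inputs must sum to 1 (got {p.sum():.6g}, {q.sum():.6g})")
    return _jsd_terms(p, q, _LOG_FNS[log_base])


def _paired_arrays(
    exprA: ExpressionMatrix,
    exprB: ExpressionMatrix,
    pairs: Sequence[Tuple[str, str]],
) -> Tuple[np.ndarray, np.ndarray]:
    if not pairs:
        raise ValueError("empty orthologue set")
    genesA = [a for a, _ in pairs]
    genesB = [b for _, b in pairs]
    missingA = set(genesA) - set(exprA.values.index)
    missingB = set(genesB) - set(exprB.values.index)
    if missingA or missingB:
        raise ValueError(
            f"orthologue genes missing from matrices: "
            f"A={sorted(missingA)[:3]} B={sorted(missingB)[:3]}"
        )
    return (
        exprA.values.loc[genesA].to_numpy(dtype=float),
        exprB.values.loc[genesB].to_numpy(dtype=float),
    )


def _normalized_columns(
    a: np.ndarray, b: np.ndarray, normalization: str, joint: bool
) -> Tuple[np.ndarray, np.ndarray]:
    if normalization == "quantile":
        if joint:
            both = _qnorm_values(np.hstack([a, b]))
            a, b = both[:, : a.shape[1]], both[:, a.shape[1]:]
        else:
            a, b = _qnorm_values(a), _qnorm_values(b)
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    sa = a.sum(axis=0)
    sb = b.sum(axis=0)
    if (sa == 0).any() or (sb == 0).any():
        raise ValueError("a sample has zero total expression over the orthologue set")
    return a / sa, b / sb


def _jsd_matrix(pa: np.ndarray, pb: np.ndarray, log) -> np.ndarray:
    out = np.empty((pa.shape[1], pb.shape[1]))
    for i in range(pa.shape[1]):
        for j in range(pb.shape[1]):
            out[i, j] = _jsd_terms(pa[:, i], pb[:, j], log)
    return out


def stage_divergence_matrix(
    exprA: ExpressionMatrix,
    exprB: ExpressionMatrix,
    pairs: Sequence[Tuple[str, str]],
    normalization: str = "quantile",
    joint: bool = True,
    log_base: str = "log2",
) -> DivergenceMatrix:
    """JSD between every sample of A and every sample of B over the pairs.

    Samples are quantile-normalized (jointly across both species by
    default) and then rescaled to proportions before the distance.
    """
    a, b = _paired_arrays(exprA, exprB, pairs)
    pa, pb = _normalized_columns(a, b, normalization, joint)
    log = _LOG_FNS[log_base]
    mat = _jsd_matrix(pa, pb, log)
    df = pd.DataFrame(mat, index=exprA.values.columns, columns=exprB.values.columns)
    return DivergenceMatrix(jsd=df, n_orthologues=len(pairs), log_base=log_base)


def bootstrap_divergence(
    exprA: ExpressionMatrix,
    exprB: ExpressionMatrix,
    pairs: Sequence[Tuple[str, str]],
    B: int = 100,
    seed: int = 0,
    normalization: str = "quantile",
    joint: bool = True,
    log_base: str = "log2",
) -> DivergenceMatrix:
    """Point estimate from the full orthologue set plus the per-cell sd over
    B resamplings of the orthologue set (genes drawn with replacement)."""
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if len(pairs) < 10:
        warnings.warn(f"orthologue set has only {len(pairs)} pairs", stacklevel=2)
    point = stage_divergence_matrix(exprA, exprB, pairs, normalization, joint, log_base)
    a, b = _paired_arrays(exprA, exprB, pairs)
    log = _LOG_FNS[log_base]
    rng = np.random.default_rng(seed)
    n = len(pairs)
    reps = np.empty((B,) + point.jsd.shape)
    for r in range(B):
        idx = rng.integers(0, n, size=n)
        pa, pb = _normalized_columns(a[idx], b[idx], normalization, joint)
        reps[r] = _jsd_matrix(pa, pb, log)
    sd = pd.DataFrame(reps.std(axis=0, ddof=1), index=point.jsd.index, columns=point.jsd.columns)
    return DivergenceMatrix(
        jsd=point.jsd,
        bootstrap_sd=sd,
        n_bootstrap=B,
        n_orthologues=n,
        log_base=log_base,
    )


def minimal_divergence_stages(m: DivergenceMatrix) -> pd.DataFrame:
    """Per stage of A: the least-divergent stage of B plus the two-best range.

    Ties break toward the earlier (lower-index) stage of B and are flagged.
    """
    if m.jsd.empty:
        raise ValueError("empty divergence matrix")
    rows = []
    cols = list(m.jsd.columns)
    for stage_a, row in m.jsd.iterrows():
        vals = row.to_numpy()
        best = int(np.argmin(vals))
        tie = bool((vals == vals[best]).sum() > 1)
        order = np.argsort(vals, kind="stable")
        two_best = sorted(order[:2])
        rows.append(
            {
                "stageA": stage_a,
                "best_stageB": cols[best],
                "min_jsd": float(vals[best]),
                "range_low": cols[two_best[0]],
                "range_high": cols[two_best[1]],
                "tie": tie,
            }
        )
    return pd.DataFrame(rows).set_index("stageA")
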