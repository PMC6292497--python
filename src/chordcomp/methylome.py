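"""CpG methylation levels, category fractions, region summaries and the
two-cluster separation of tissue-specific regulatory elements."""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .landscapes import PeakSet
from .wgd_fates import rank_sum_test

__all__ = [
    "cpg_methylation_levels",
    "methylation_category_fractions",
    "region_methylation",
    "kmeans2_cluster",
    "cluster_expression_association",
]

CPG_COLUMNS = ["chrom", "pos", "strand", "meth_reads", "total_reads", "sample"]
CATEGORY_ORDER = ["zero", "low", "medium", "high"]


def cpg_methylation_levels(
    calls: pd.DataFrame, min_coverage: int = 5
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Per-CpG methylation levels with a coverage floor.

    ``calls`` needs columns chrom, pos, strand, meth_reads, total_reads,
    sample. Records with meth_reads > total_reads are rejected; records
    under the coverage floor are excluded. Returns (records, report).
    """
    missing = set(CPG_COLUMNS) - set(calls.columns)
    if missing:
        raise ValueError(f"CpG table missing columns {sorted(missing)}")
    if (calls["meth_reads"] < 0).any() or (calls["total_reads"] < 0).any():
        raise ValueError("read counts must be non-negative")
    bad = calls["meth_reads"] > calls["total_reads"]
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} records with methylated reads > total reads "
            f"(first at index {calls.index[bad][0]})"
        )
    kept = calls[calls["total_reads"] >= min_coverage].copy()
    kept["level"] = kept["meth_reads"] / kept["total_reads"]
    report = {
        "n_input": len(calls),
        "n_below_coverage": len(calls) - len(kept),
        "n_retained": len(kept),
    }
    return kept, report


def methylation_category_fractions(levels: Sequence[float]) -> pd.Series:
    """Fractions over {zero, low, medium, high}.

    zero: exactly 0; low: (0, 0.20]; medium: (0.20, 0.80]; high: (0.80, 1].
    """
    x = np.asarray(levels, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one methylation level")
    if ((x < 0) | (x > 1)).any():
        raise ValueError("levels must lie in [0, 1]")
    counts = pd.Series(
        {
            "zero": int((x == 0).sum()),
            "low": int(((x > 0) & (x <= 0.20)).sum()),
            "medium": int(((x > 0.20) & (x <= 0.80)).sum()),
            "high": int((x > 0.80).sum()),
        }
    )[CATEGORY_ORDER]
    return counts / counts.sum()


def region_methylation(
    records: pd.DataFrame,
    regions: PeakSet,
    min_cpgs: int = 3,
) -> pd.DataFrame:
    """Per-region per-sample unweighted mean CpG level.

    Cells backed by fewer than ``min_cpgs`` covered CpGs are NaN; regions
    with no covered CpGs in any sample are dropped and reported.
    """
    samples = sorted(records["sample"].unique())
    rows = {}
    dropped = []
    by_chrom = dict(tuple(records.groupby("chrom")))
    for _, region in regions.intervals.iterrows():
        sub = by_chrom.get(region["chrom"])
        if sub is not None:
            sub = sub[(sub["pos"] >= region["start"]) & (sub["pos"] < region["end"])]
        if sub is None or sub.empty:
            dropped.append(region["peak_id"])
            continue
        row = {}
        for s in samples:
            levels = sub.loc[sub["sample"] == s, "level"]
            row[s] = float(levels.mean()) if len(levels) >= min_cpgs else np.nan
        rows[region["peak_id"]] = row
    if dropped:
        warnings.warn(f"{len(dropped)} regions with zero covered CpGs dropped", stacklevel=2)
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


def kmeans2_cluster(
    matrix: pd.DataFrame,
    seed: int = 0,
    n_init: int = 20,
    defining_sample: Optional[str] = None,
) -> Tuple[pd.Series, pd.DataFrame]:
    """Two-cluster Euclidean k-means over region methylation profiles.

    Cluster 1 is the differential cluster: hypomethylated specifically in
    the defining tissue relative to the other samples (largest contrast of
    other-sample mean minus defining-tissue level, ties broken toward the
    lower defining-tissue level). Cluster 2 is the constitutive one. Rows
    with any NaN are excluded.
    """
    mat = matrix.dropna()
    if len(mat) < 2:
        raise ValueError("k=2 clustering needs at least 2 complete regions")
    x = mat.to_numpy(dtype=float)
    if np.unique(x, axis=0).shape[0] < 2:
        raise ValueError("k=2 clustering needs at least 2 distinct rows")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    raw = km.fit_predict(x)
    col = 0 if defining_sample is None else list(mat.columns).index(defining_sample)
    centers = km.cluster_centers_
    others = [j for j in range(centers.shape[1]) if j != col]
    if others:
        contrast = centers[:, others].mean(axis=1) - centers[:, col]
    else:
        contrast = -centers[:, col]
    # cluster 1 = differential (high contrast; tie -> lower defining level)
    key = list(zip(-contrast, centers[:, col]))
    if key[0] <= key[1]:
        labels = np.where(raw == 0, 1, 2)
        centers = km.cluster_centers_
    else:
        labels = np.where(raw == 0, 2, 1)
        centers = km.cluster_centers_[::-1]
    centroids = pd.DataFrame(centers, index=[1, 2], columns=mat.columns)
    return pd.Series(labels, index=mat.index, name="cluster"), centroids


def cluster_expression_association(
    labels: pd.Series,
    region_to_gene: pd.Series,
    gene_values: pd.Series,
) -> Tuple[Dict[int, np.ndarray], Optional[float]]:
    """Expression (level or breadth) distributions of genes linked to each
    methylation cluster, with a two-sided rank-sum comparison.

    ``region_to_gene`` maps region ids to gene ids; ``gene_values`` holds
    the per-gene statistic. Returns ({cluster: values}, p) with p None when
    a cluster has fewer than 2 associated genes.
    """
    out: Dict[int, np.ndarray] = {}
    for cl in (1, 2):
        regions = labels.index[labels == cl]
        genes = region_to_gene.reindex(regions).dropna()
        vals = gene_values.reindex(genes).dropna()
        out[cl] = vals.to_numpy(dtype=float)
    if len(out[1]) < 2 or len(out[2]) < 2:
        warnings.warn("a cluster has fewer than 2 associated genes; test skipped", stacklevel=2)
        return out, None
    return out, rank_sum_test(out[1], out[2], alternative="two-sided")
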