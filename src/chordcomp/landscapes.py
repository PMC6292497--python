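"""Peak classification, regulatory-domain construction and landscape metrics.

All coordinates are 0-based half-open (BED convention).  Peak membership is
by midpoint unless stated otherwise; the classification precedence is
promoter > gene_body > proximal > distal.

Regulatory domains follow the basal-plus-extension scheme: a strand-aware
basal window (-5 kb / +1 kb around the TSS) always belongs to its gene; each
side is then extended outward up to 1 Mb from the TSS, stopping earlier at
the nearest other gene's basal-region boundary or the chromosome end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

__all__ = [
    "GenomeAnnotation",
    "PeakSet",
    "RegulatoryDomain",
    "classify_apres",
    "tss_distance",
    "great_domains",
    "count_apres_per_gene",
    "stratified_match",
    "family_min_max_counts",
    "bidirectional_pairs",
    "mean_conservation",
]

CATEGORIES = ("promoter", "gene_body", "proximal", "distal")


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene intervals with strand-aware TSSs."""

    chromosomes: Dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, strand, start, end (0-based half-open)

    def __post_init__(self) -> None:
        g = self.genes
        required = {"gene_id", "chrom", "strand", "start", "end"}
        if not required.issubset(g.columns):
            raise ValueError(f"gene table needs columns {sorted(required)}")
        unknown = sorted(set(g["chrom"]) - set(self.chromosomes))
        if unknown:
            raise ValueError(f"genes on unknown chromosomes: {unknown}")
        if (g["start"] >= g["end"]).any():
            raise ValueError("gene start must be < end")
        for _, row in g.iterrows():
            if row["end"] > self.chromosomes[row["chrom"]] or row["start"] < 0:
                raise ValueError(f"gene {row['gene_id']} outside chromosome bounds")
        if "tss" not in g.columns:
            g = g.copy()
            g["tss"] = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
            self.genes = g

    @classmethod
    def from_gtf(cls, path, chromosomes: Optional[Dict[str, int]] = None) -> "GenomeAnnotation":
        """Read gene features from a GTF (1-based inclusive -> half-open)."""
        rows = []
        maxend: Dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                    for kv in f[8].rstrip(";").split(";")
                    if kv.strip()
                )
                start, end = int(f[3]) - 1, int(f[4])
                rows.append(
                    {
                        "gene_id": attrs.get("gene_id", f"gene{len(rows)}"),
                        "chrom": f[0],
                        "strand": f[6],
                        "start": start,
                        "end": end,
                    }
                )
                maxend[f[0]] = max(maxend.get(f[0], 0), end)
        if chromosomes is None:
            chromosomes = maxend
        return cls(chromosomes=chromosomes, genes=pd.DataFrame(rows))

    def to_gtf(self, path, source: str = "chordcomp") -> None:
        with open(path, "w") as fh:
            for _, row in self.genes.iterrows():
                fh.write(
                    f"{row['chrom']}\t{source}\tgene\t{row['start'] + 1}\t{row['end']}\t.\t"
                    f"{row['strand']}\t.\tgene_id \"{row['gene_id']}\";\n"
                )


@dataclass
class PeakSet:
    """BED-like intervals with unique ids and optional per-peak annotations."""

    intervals: pd.DataFrame  # chrom, start, end, peak_id [, category, mean_conservation]

    def __post_init__(self) -> None:
        p = self.intervals
        required = {"chrom", "start", "end", "peak_id"}
        if not required.issubset(p.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        if len(p) and (p["start"] >= p["end"]).any():
            raise ValueError("peak start must be < end")
        if p["peak_id"].duplicated().any():
            dups = p.loc[p["peak_id"].duplicated(), "peak_id"].tolist()
            raise ValueError(f"duplicate peak ids: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def midpoints(self) -> pd.Series:
        p = self.intervals
        return (p["start"] + p["end"]) // 2

    @classmethod
    def from_bed(cls, path) -> "PeakSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "peak_id", "score", "strand"],
            usecols=[0, 1, 2, 3],
        )
        return cls(intervals=df)

    def to_bed(self, path) -> None:
        cols = ["chrom", "start", "end", "peak_id"]
        df = self.intervals[cols].copy()
        df["score"] = 0
        df["strand"] = "."
        df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class RegulatoryDomain:
    gene_id: str
    chrom: str
    basal: Tuple[int, int]
    extended: Tuple[int, int]

    def __post_init__(self) -> None:
        bs, be = self.basal
        es, ee = self.extended
        if not (es <= bs < be <= ee):
            raise ValueError(f"basal {self.basal} not contained in extended {self.extended}")


def _basal_interval(tss: int, strand: str, up: int, down: int, chrom_len: int) -> Tuple[int, int]:
    if strand == "+":
        lo, hi = tss - up, tss + down
    else:
        lo, hi = tss - down + 1, tss + up + 1
    return max(0, lo), min(chrom_len, hi)


def _signed_offset(mid: int, tss: int, strand: str) -> int:
    """Midpoint offset from the TSS, positive downstream of transcription."""
    return mid - tss if strand == "+" else tss - mid


def classify_apres(
    peaks: PeakSet,
    annotation: GenomeAnnotation,
    promoter_up: int = 1000,
    promoter_down: int = 500,
    proximal_up: int = 5000,
) -> PeakSet:
    """Assign each peak exactly one category by midpoint location.

    promoter: within promoter_up upstream / promoter_down downstream of a
    TSS (strand-aware); gene_body: inside a gene; proximal: within
    proximal_up upstream of a TSS; distal: everything else.
    """
    unknown = sorted(set(peaks.intervals["chrom"]) - set(annotation.chromosomes))
    if unknown:
        raise ValueError(f"peaks on unknown chromosomes: {unknown}")
    genes_by_chrom = dict(tuple(annotation.genes.groupby("chrom")))
    cats = []
    mids = peaks.midpoints
    for (_, peak), mid in zip(peaks.intervals.iterrows(), mids):
        genes = genes_by_chrom.get(peak["chrom"])
        cat = "distal"
        if genes is not None:
            offs = [
                _signed_offset(mid, t, s)
                for t, s in zip(genes["tss"], genes["strand"])
            ]
            if any(-promoter_up <= o <= promoter_down for o in offs):
                cat = "promoter"
            elif ((genes["start"] <= mid) & (mid < genes["end"])).any():
                cat = "gene_body"
            elif any(-proximal_up <= o < 0 for o in offs):
                cat = "proximal"
        cats.append(cat)
    out = peaks.intervals.copy()
    out["category"] = cats
    return PeakSet(intervals=out)


def tss_distance(peaks: PeakSet, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Absolute midpoint-to-nearest-TSS distance per peak (NaN on gene-less
    chromosomes, with a warning)."""
    tss_by_chrom = {
        chrom: np.sort(grp["tss"].to_numpy())
        for chrom, grp in annotation.genes.groupby("chrom")
    }
    dists = []
    mids = peaks.midpoints
    for (_, peak), mid in zip(peaks.intervals.iterrows(), mids):
        tss = tss_by_chrom.get(peak["chrom"])
        if tss is None or len(tss) == 0:
            warnings.warn(f"peak {peak['peak_id']} on gene-less chromosome", stacklevel=2)
            dists.append(np.nan)
        else:
            dists.append(float(np.min(np.abs(tss - mid))))
    out = peaks.intervals[["peak_id", "chrom"]].copy()
    out["distance"] = dists
    return out


def great_domains(
    annotation: GenomeAnnotation,
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
) -> List[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains.

    The extended interval is the union of the basal window with the region
    reachable up to ``max_ext`` from the TSS on each side, truncated at the
    nearest other gene's basal boundary and at chromosome ends. Basal
    regions may overlap other domains.
    """
    domains: List[RegulatoryDomain] = []
    genes = annotation.genes
    basals: Dict[str, Tuple[int, int]] = {}
    for _, row in genes.iterrows():
        basals[row["gene_id"]] = _basal_interval(
            row["tss"], row["strand"], basal_up, basal_down,
            annotation.chromosomes[row["chrom"]],
        )
    by_chrom = dict(tuple(genes.groupby("chrom")))
    for _, row in genes.iterrows():
        gid, chrom, tss = row["gene_id"], row["chrom"], row["tss"]
        clen = annotation.chromosomes[chrom]
        bs, be = basals[gid]
        cap_lo = max(0, tss - max_ext)
        cap_hi = min(clen, tss + max_ext)
        lo, hi = min(cap_lo, bs), max(cap_hi, be)
        for _, other in by_chrom[chrom].iterrows():
            if other["gene_id"] == gid:
                continue
            obs, obe = basals[other["gene_id"]]
            # foreign basal intersecting the left extension ray
            if obe > lo and obs < bs:
                lo = min(bs, max(lo, obe))
            # foreign basal intersecting the right extension ray
            if obs < hi and obe > be:
                hi = max(be, min(hi, obs))
        domains.append(RegulatoryDomain(gene_id=gid, chrom=chrom, basal=(bs, be), extended=(lo, hi)))
    return domains


def count_apres_per_gene(domains: Sequence[RegulatoryDomain], peaks: PeakSet) -> pd.Series:
    """Peaks whose midpoint falls in each gene's extended domain.

    A peak inside several overlapping domains counts for every one of them.
    """
    counts = pd.Series(0, index=[d.gene_id for d in domains], dtype=int)
    if len(peaks) == 0:
        return counts
    mids = peaks.midpoints.to_numpy()
    chroms = peaks.intervals["chrom"].to_numpy()
    for d in domains:
        lo, hi = d.extended
        counts[d.gene_id] = int(np.sum((chroms == d.chrom) & (mids >= lo) & (mids < hi)))
    return counts


def stratified_match(
    sizesA: pd.Series,
    sizesB: pd.Series,
    bin_bp: int = 500,
    seed: int = 0,
) -> Tuple[pd.Index, pd.Index, pd.DataFrame]:
    """Down-sample both gene sets to equal per-size-bin counts.

    Sizes are binned in fixed windows of ``bin_bp``; within each shared bin
    both sets are sampled without replacement to the smaller count.
    Returns the two retained gene index sets plus per-bin bookkeeping.
    """
    if sizesA.empty or sizesB.empty:
        raise ValueError("both size sets must be non-empty")
    rng = np.random.default_rng(seed)
    binsA = (sizesA // bin_bp).astype(int)
    binsB = (sizesB // bin_bp).astype(int)
    keepA: List = []
    keepB: List = []
    rows = []
    for b in sorted(set(binsA) | set(binsB)):
        ga = sizesA.index[binsA == b]
        gb = sizesB.index[binsB == b]
        n = min(len(ga), len(gb))
        if n > 0:
            keepA.extend(rng.choice(ga, size=n, replace=False))
            keepB.extend(rng.choice(gb, size=n, replace=False))
        rows.append({"bin": b, "n_A": len(ga), "n_B": len(gb), "kept": n})
    if not keepA:
        raise ValueError("no populated shared size bin")
    return pd.Index(keepA), pd.Index(keepB), pd.DataFrame(rows).set_index("bin")


def family_min_max_counts(counts: pd.Series, fams) -> pd.DataFrame:
    """Per-family minimum and maximum peak counts over member genes.

    Families with any member missing a count are skipped with a warning.
    """
    rows = []
    for fam in fams:
        members = [g for genes in fam.members.values() for g in genes]
        if any(g not in counts.index for g in members):
            warnings.warn(f"family {fam.family_id} has members without counts; skipped", stacklevel=2)
            continue
        vals = counts[members]
        rows.append({"family_id": fam.family_id, "min": int(vals.min()), "max": int(vals.max())})
    return pd.DataFrame(rows).set_index("family_id") if rows else pd.DataFrame(
        columns=["min", "max"]
    )


def compare_count_distributions(x: Sequence[float], y: Sequence[float], alternative: str = "greater") -> float:
    """One-sided Mann-Whitney p-value that x is stochastically larger than y."""
    return float(mannwhitneyu(x, y, alternative=alternative).pvalue)


def bidirectional_pairs(
    annotation: GenomeAnnotation, max_sep_bp: int = 1000
) -> Tuple[pd.DataFrame, pd.Series]:
    """Divergently oriented adjacent gene pairs with nearby TSSs.

    A pair qualifies when, in TSS order, the upstream gene is on the minus
    strand, the downstream gene on the plus strand (TSSs facing away) and
    the TSS separation is <= max_sep_bp. Also returns the separation
    histogram over all divergent adjacent pairs (for periodicity checks).
    """
    rows = []
    seps = []
    for chrom, grp in annotation.genes.groupby("chrom"):
        grp = grp.sort_values("tss").reset_index(drop=True)
        for i in range(len(grp) - 1):
            g1, g2 = grp.iloc[i], grp.iloc[i + 1]
            if g1["strand"] == "-" and g2["strand"] == "+":
                sep = int(g2["tss"] - g1["tss"])
                seps.append(sep)
                if sep <= max_sep_bp:
                    rows.append(
                        {
                            "chrom": chrom,
                            "gene_minus": g1["gene_id"],
                            "gene_plus": g2["gene_id"],
                            "tss_separation": sep,
                        }
                    )
    pairs = pd.DataFrame(rows, columns=["chrom", "gene_minus", "gene_plus", "tss_separation"])
    return pairs, pd.Series(seps, name="tss_separation", dtype=int)


def mean_conservation(
    peaks: PeakSet,
    perbase_scores: pd.DataFrame,
    missing_as_zero: bool = False,
) -> pd.DataFrame:
    """Arithmetic mean of per-base scores across each peak.

    ``perbase_scores`` is bedGraph-like (chrom, start, end, score). Bases
    without a score are excluded from the mean unless ``missing_as_zero``;
    fully uncovered peaks get NaN with a warning.
    """
    required = {"chrom", "start", "end", "score"}
    if not required.issubset(perbase_scores.columns):
        raise ValueError(f"score table needs columns {sorted(required)}")
    by_chrom = dict(tuple(perbase_scores.groupby("chrom")))
    means = []
    for _, peak in peaks.intervals.iterrows():
        track = by_chrom.get(peak["chrom"])
        total, covered = 0.0, 0
        if track is not None:
            sel = track[(track["end"] > peak["start"]) & (track["start"] < peak["end"])]
            for _, seg in sel.iterrows():
                lo = max(seg["start"], peak["start"])
                hi = min(seg["end"], peak["end"])
                total += seg["score"] * (hi - lo)
                covered += hi - lo
        width = peak["end"] - peak["start"]
        if covered == 0 and not missing_as_zero:
            warnings.warn(f"peak {peak['peak_id']} entirely uncovered by score track", stacklevel=2)
            means.append(np.nan)
        elif missing_as_zero:
            means.append(total / width)
        else:
            means.append(total / covered)
    out = peaks.intervals.copy()
    out["mean_conservation"] = means
    return out


def conservation_group_summary(scored: pd.DataFrame, group_col: str = "category") -> pd.DataFrame:
    """Mean and interquartile range of per-peak means per group."""
    rows = []
    for grp, sub in scored.groupby(group_col):
        vals = sub["mean_conservation"].dropna()
        rows.append(
            {
                group_col: grp,
                "n": len(vals),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "q25": float(vals.quantile(0.25)) if len(vals) else np.nan,
                "q75": float(vals.quantile(0.75)) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index(group_col)
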