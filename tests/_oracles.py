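"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration, staying
deliberately independent of the library code paths it checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def brute_force_scan(
    sequences: Mapping[str, str],
    log_odds: np.ndarray,
    threshold: float,
) -> set:
    """All (seq_id, offset, strand) windows scoring >= threshold, scored
    base by base on both strands; windows containing N are skipped."""
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = log_odds.shape[1]
    hits = set()
    for sid, seq in sequences.items():
        seq = seq.upper()
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for off in range(len(s) - L + 1):
                window = s[off : off + L]
                if "N" in window:
                    continue
                score = sum(log_odds[base_index[b], j] for j, b in enumerate(window))
                if score >= threshold:
                    fwd_off = off if strand == "+" else len(s) - L - off
                    hits.add((sid, fwd_off, strand))
    return hits


def perbase_great_domain(
    tss: int,
    strand: str,
    chrom_len: int,
    own_basal: Tuple[int, int],
    foreign_basals: Sequence[Tuple[int, int]],
    max_ext: int,
) -> Tuple[int, int]:
    """Walk outward base by base from the basal window.

    A base extends the domain while it is within max_ext of the TSS, inside
    the chromosome, and not covered by another gene's basal region.
    """
    def covered(x: int) -> bool:
        return any(s <= x < e for s, e in foreign_basals)

    bs, be = own_basal
    lo = bs
    x = bs - 1
    while x >= 0 and x >= tss - max_ext and not covered(x):
        lo = x
        x -= 1
    hi = be
    x = be
    while x < chrom_len and x < tss + max_ext and not covered(x):
        hi = x + 1
        x += 1
    return lo, hi


def quadratic_peak_counts(
    domains: Sequence[Tuple[str, str, int, int]],
    peaks: Sequence[Tuple[str, int, int]],
) -> Dict[str, int]:
    """(gene_id, chrom, lo, hi) x (chrom, start, end) midpoint incidences."""
    counts = {gid: 0 for gid, _, _, _ in domains}
    for chrom_p, start, end in peaks:
        mid = (start + end) // 2
        for gid, chrom_d, lo, hi in domains:
            if chrom_d == chrom_p and lo <= mid < hi:
                counts[gid] += 1
    return counts


def hypergeom_upper_tail(M: int, n_m: int, n_n: int, k: int) -> float:
    """P(X >= k) by enumerating which universe items fall in module n."""
    universe = list(range(M))
    in_m = set(universe[:n_m])
    total = 0
    ge = 0
    for combo in itertools.combinations(universe, n_n):
        total += 1
        if len(in_m.intersection(combo)) >= k:
            ge += 1
    return ge / total


def exact_rank_sum_p(x: Sequence[float], y: Sequence[float], alternative: str = "greater") -> float:
    """One-sided rank-sum p by enumerating all group assignments of the
    pooled values (no ties assumed)."""
    pooled = list(x) + list(y)
    nx = len(x)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    obs = sum(ranks[v] for v in x)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        stat = sum(ranks[pooled[i]] for i in combo)
        total += 1
        if alternative == "greater" and stat >= obs:
            count += 1
        elif alternative == "less" and stat <= obs:
            count += 1
    return count / total


def brute_force_nacc(
    exprA: Dict[str, Sequence[float]],
    exprB: Dict[str, Sequence[float]],
    orthologs: Dict[str, str],
    k: int,
) -> Dict[str, float]:
    """NACC for 1-to-1 orthologues by direct enumeration.

    Expression vectors must already be in the transformed space used for
    distances (the oracle only does plain Euclidean arithmetic).
    """
    def dist(u, v):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(u, v)))

    inv = {b: a for a, b in orthologs.items()}
    out = {}
    for ga, gb in orthologs.items():
        dA = sorted(
            ((dist(exprA[ga], exprA[o]), o) for o in orthologs if o != ga)
        )[:k]
        a_bar = sum(d for d, _ in dA) / k
        ab_bar = sum(dist(exprB[gb], exprB[orthologs[o]]) for _, o in dA) / k
        dB = sorted(
            ((dist(exprB[gb], exprB[o]), o) for o in inv if o != gb)
        )[:k]
        b_bar = sum(d for d, _ in dB) / k
        ba_bar = sum(dist(exprA[ga], exprA[inv[o]]) for _, o in dB) / k
        out[ga] = 0.5 * ((ab_bar - a_bar) + (ba_bar - b_bar))
    return out


def best_two_partition_wcss(points: np.ndarray) -> float:
    """Minimum within-cluster sum of squares over all 2-partitions."""
    n = len(points)
    best = math.inf
    for mask in range(1, 2 ** (n - 1)):
        in1 = [i for i in range(n) if (mask >> i) & 1]
        in2 = [i for i in range(n) if not (mask >> i) & 1]
        if not in1 or not in2:
            continue
        wcss = 0.0
        for idx in (in1, in2):
            sub = points[idx]
            wcss += float(((sub - sub.mean(axis=0)) ** 2).sum())
        best = min(best, wcss)
    return best


def jsd_reference(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon distance via scipy (base-2), as an independent route."""
    from scipy.spatial.distance import jensenshannon

    return float(jensenshannon(p, q, base=2))
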