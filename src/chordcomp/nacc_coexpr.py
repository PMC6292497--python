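"""Conserved co-expression scoring (NACC) and cross-species module comparison.

NACC compares, for each orthologous family, the average expression-space
distance from a gene to its k nearest neighbours with the distance between
their orthologues in the other species:

    NACC = 1/2 [ (AB - A) + (BA - B) ]

where A is the mean distance from gene A to its k nearest species-1
neighbours, AB the mean species-2 distance from A's orthologue(s) to the
orthologues of those neighbours, and B / BA the reciprocal quantities.
Values near zero indicate conserved co-expression neighbourhoods.

Module assignments (WGCNA/Mfuzz labels) are inputs; only the comparison
statistics live here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import hypergeom, pearsonr

from .expression import ExpressionMatrix
from .orthology import FamilySet, GeneFamily

__all__ = [
    "NaccResult",
    "nacc_score",
    "nacc_null",
    "module_overlap_test",
    "module_motif_correlation",
]


@dataclass
class NaccResult:
    family_id: str
    gene_a: str
    genes_b: Tuple[str, ...]
    a_bar: float
    b_bar: float
    ab_bar: float
    ba_bar: float
    nacc: float
    k: int


def _transform(values: pd.DataFrame, metric: str) -> np.ndarray:
    """Per-gene z-scored log2(x+1) profile; constant genes map to zeros."""
    x = np.log2(values.to_numpy(dtype=float) + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    return z


def _distance(metric: str):
    if metric == "euclidean":
        return "euclidean"
    if metric == "correlation":
        return "correlation"
    raise ValueError(f"unknown metric {metric!r}")


def _eligible(fams: FamilySet, spA: str, spB: str, exprA, exprB, max_members_b: int):
    """Families scoreable for NACC plus the orthologue-bearing gene universes."""
    scored: List[GeneFamily] = []
    genesA: List[str] = []
    genesB: List[str] = []
    for fam in fams:
        a = [g for g in fam.members.get(spA, []) if g in exprA.values.index]
        b = [g for g in fam.members.get(spB, []) if g in exprB.values.index]
        if not a or not b:
            continue
        genesA.extend(a)
        genesB.extend(b)
        if len(a) == 1 and 1 <= len(b) <= max_members_b:
            scored.append(GeneFamily(fam.family_id, {spA: a, spB: b}))
    return scored, genesA, genesB


def nacc_score(
    exprA: ExpressionMatrix,
    exprB: ExpressionMatrix,
    fams: FamilySet,
    spA: str,
    spB: str,
    k: int = 20,
    metric: str = "euclidean",
    max_members_b: int = 8,
) -> List[NaccResult]:
    """Per-family NACC for families with a single species-A member.

    Neighbour candidates are restricted to genes carrying an orthologue in
    the other species; the query gene is excluded from its own neighbour
    list. Families with fewer than k eligible neighbours raise ValueError.
    """
    scored, genesA, genesB = _eligible(fams, spA, spB, exprA, exprB, max_members_b)
    if len(genesA) - 1 < k or len(genesB) - 1 < k:
        raise ValueError(
            f"fewer than k={k} eligible neighbours "
            f"({len(genesA)} A genes, {len(genesB)} B genes)"
        )
    metric = _distance(metric)
    idxA = {g: i for i, g in enumerate(genesA)}
    idxB = {g: i for i, g in enumerate(genesB)}
    za = _transform(exprA.values.loc[genesA], metric)
    zb = _transform(exprB.values.loc[genesB], metric)
    distA = cdist(za, za, metric=metric)
    distB = cdist(zb, zb, metric=metric)

    # gene -> orthologue indices in the other species (over scoreable universe)
    orthB_of_A: Dict[str, List[int]] = {}
    orthA_of_B: Dict[str, List[int]] = {}
    for fam in fams:
        a = [g for g in fam.members.get(spA, []) if g in idxA]
        b = [g for g in fam.members.get(spB, []) if g in idxB]
        for g in a:
            orthB_of_A[g] = [idxB[x] for x in b]
        for g in b:
            orthA_of_B[g] = [idxA[x] for x in a]

    results: List[NaccResult] = []
    for fam in scored:
        ga = fam.members[spA][0]
        gbs = fam.members[spB]
        ia = idxA[ga]
        ibs = [idxB[g] for g in gbs]

        # A-side neighbourhood
        da = distA[ia].copy()
        da[ia] = np.inf
        nbrA = np.argsort(da, kind="stable")[:k]
        a_bar = float(da[nbrA].mean())
        ab_terms = []
        for j in nbrA:
            orth = orthB_of_A[genesA[j]]
            ab_terms.append(float(np.mean([distB[ib, o] for ib in ibs for o in orth])))
        ab_bar = float(np.mean(ab_terms))

        # B-side neighbourhood (averaged over members for multi-copy families)
        b_terms, ba_terms = [], []
        for ib in ibs:
            db = distB[ib].copy()
            db[ib] = np.inf
            nbrB = np.argsort(db, kind="stable")[:k]
            b_terms.append(float(db[nbrB].mean()))
            for j in nbrB:
                orth = orthA_of_B[genesB[j]]
                ba_terms.append(float(np.mean([distA[ia, o] for o in orth])))
        b_bar = float(np.mean(b_terms))
        ba_bar = float(np.mean(ba_terms))

        nacc = 0.5 * ((ab_bar - a_bar) + (ba_bar - b_bar))
        results.append(
            NaccResult(
                family_id=fam.family_id,
                gene_a=ga,
                genes_b=tuple(gbs),
                a_bar=a_bar,
                b_bar=b_bar,
                ab_bar=ab_bar,
                ba_bar=ba_bar,
                nacc=nacc,
                k=k,
            )
        )
    return results


def _permuted_familyset(fams: FamilySet, spA: str, spB: str, rng: np.random.Generator) -> FamilySet:
    """Shuffle which species-B member set attaches to which species-A gene set,
    preserving the family-size structure."""
    families = list(fams)
    b_sets = [fam.members.get(spB, []) for fam in families]
    perm = rng.permutation(len(b_sets))
    shuffled = []
    for i, fam in enumerate(families):
        members = {sp: list(g) for sp, g in fam.members.items() if sp != spB}
        nb = list(b_sets[perm[i]])
        if nb:
            members[spB] = nb
        shuffled.append(GeneFamily(fam.family_id, members))
    return FamilySet(families=shuffled, species=fams.species, provenance="permuted")


def nacc_null(
    exprA: ExpressionMatrix,
    exprB: ExpressionMatrix,
    fams: FamilySet,
    spA: str,
    spB: str,
    k: int = 20,
    metric: str = "euclidean",
    n_permutations: int = 100,
    seed: int = 0,
    max_members_b: int = 8,
) -> Dict[str, object]:
    """Null distribution of the mean NACC under randomized orthology.

    Returns observed mean, per-permutation means, and the empirical p-value
    P(null mean <= observed mean) with the +1 correction.
    """
    if n_permutations < 1:
        raise ValueError("need at least 1 permutation")
    observed = nacc_score(exprA, exprB, fams, spA, spB, k, metric, max_members_b)
    obs_mean = float(np.mean([r.nacc for r in observed]))
    rng = np.random.default_rng(seed)
    null_means = []
    for _ in range(n_permutations):
        permuted = _permuted_familyset(fams, spA, spB, rng)
        res = nacc_score(exprA, exprB, permuted, spA, spB, k, metric, max_members_b)
        null_means.append(float(np.mean([r.nacc for r in res])))
    null_means = np.array(null_means)
    p = (1.0 + np.sum(null_means <= obs_mean)) / (n_permutations + 1.0)
    return {
        "observed_mean": obs_mean,
        "null_means": null_means,
        "p_value": float(p),
        "n_permutations": n_permutations,
    }


def module_overlap_test(
    assignA: pd.Series,
    assignB: pd.Series,
    pairs: Sequence[Tuple[str, str]],
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric test of orthologous overlap between modules.

    The universe is the set of orthologue pairs with both genes assigned to
    some module.  For modules (m, n): k = number of pairs with the A gene in
    m and the B gene in n; p = P(X >= k) under the hypergeometric with the
    universe margins.
    """
    universe = [
        (a, b) for a, b in pairs if a in assignA.index and b in assignB.index
    ]
    if not universe:
        raise ValueError("empty universe: no orthologue pair has both genes assigned")
    M = len(universe)
    ma = pd.Series([assignA[a] for a, _ in universe])
    mb = pd.Series([assignB[b] for _, b in universe])
    rows = []
    counts_a = ma.value_counts()
    counts_b = mb.value_counts()
    cross = pd.crosstab(ma, mb)
    for m in counts_a.index:
        for n in counts_b.index:
            k = int(cross.at[m, n]) if (m in cross.index and n in cross.columns) else 0
            p = float(hypergeom.sf(k - 1, M, int(counts_a[m]), int(counts_b[n])))
            rows.append({"moduleA": m, "moduleB": n, "overlap": k, "p_value": p})
    out = pd.DataFrame(rows)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        out["p_adj_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def module_motif_correlation(
    zA: pd.DataFrame, zB: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation of motif z-score profiles for every module pair.

    Returns the moduleA x moduleB correlation matrix (NaN where a profile
    has zero variance) and the best species-B correlation per A module.
    """
    shared = [m for m in zA.columns if m in zB.columns]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared motifs, got {len(shared)}")
    a = zA[shared].to_numpy(dtype=float)
    b = zB[shared].to_numpy(dtype=float)
    corr = np.full((a.shape[0], b.shape[0]), np.nan)
    for i in range(a.shape[0]):
        if np.std(a[i]) == 0:
            continue
        for j in range(b.shape[0]):
            if np.std(b[j]) == 0:
                continue
            corr[i, j] = pearsonr(a[i], b[j])[0]
    mat = pd.DataFrame(corr, index=zA.index, columns=zB.index)
    best_mod = [
        row.idxmax() if row.notna().any() else None for _, row in mat.iterrows()
    ]
    best = pd.DataFrame(
        {"best_moduleB": best_mod, "best_correlation": mat.max(axis=1)},
        index=mat.index,
    )
    return mat, best
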