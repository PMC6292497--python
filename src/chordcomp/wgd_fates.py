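"""Post-WGD paralogue fate classification from binarized expression domains.

A family is eligible when its single outgroup orthologue is expressed in
all configured domains and the union of the vertebrate members covers all
domains too (broad ancestral expression). Fates:

* redundancy        - every vertebrate member on in every domain
* subfunctionalization - no member on in every domain
* specialization    - at least one full member and at least one restricted

Restricted members of specialization families are 'spec_strong' when <= 2
expression domains remain, 'spec_mild' otherwise; full members are 'full'.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .expression import BinaryExpressionProfile, ExpressionMatrix
from .orthology import FamilySet

__all__ = [
    "DomainBias",
    "FateCall",
    "domain_bias",
    "neg_pos_log_ratio",
    "classify_fates",
    "specialization_domain_retention",
    "fates_vs_apre_counts",
    "divergence_vs_fate",
    "rank_sum_test",
]

FATES = ("redundancy", "subfunctionalization", "specialization")
BIAS_MODES = ("single_copy", "individual_ohnologue", "union", "sum_then_binarize")
SPEC_STRONG_MAX_DOMAINS = 2


@dataclass
class DomainBias:
    pair_id: str
    gene_outgroup: str
    entity_vertebrate: str
    domains_outgroup: int
    domains_vertebrate: int
    mode: str

    @property
    def bias(self) -> int:
        return self.domains_vertebrate - self.domains_outgroup


@dataclass
class FateCall:
    family_id: str
    fate: str
    member_subtypes: Dict[str, str]  # vertebrate gene -> subtype
    retained_domains: Dict[str, Tuple[str, ...]]  # vertebrate gene -> on domains

    def __post_init__(self) -> None:
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")


def _check_domains(binA: BinaryExpressionProfile, binB: BinaryExpressionProfile) -> List[str]:
    if list(binA.domain_ids) != list(binB.domain_ids):
        raise ValueError(
            f"domain lists differ: {binA.domain_ids} vs {binB.domain_ids}"
        )
    return list(binA.domain_ids)


def domain_bias(
    binA: BinaryExpressionProfile,
    binB: BinaryExpressionProfile,
    fams: FamilySet,
    spA: str,
    spB: str,
    mode: str = "individual_ohnologue",
    exprB_raw: Optional[ExpressionMatrix] = None,
    threshold: float = 5.0,
) -> List[DomainBias]:
    """Expression-breadth bias = vertebrate on-domains minus outgroup on-domains.

    Modes: single_copy uses 1-to-1 families member vs member;
    individual_ohnologue emits one record per vertebrate member of a
    single-outgroup family; union ORs the member rows; sum_then_binarize
    sums raw member expression and re-binarizes (requires exprB_raw).
    """
    if mode not in BIAS_MODES:
        raise ValueError(f"mode must be one of {BIAS_MODES}")
    if mode == "sum_then_binarize" and exprB_raw is None:
        raise ValueError("sum_then_binarize mode requires the raw vertebrate matrix")
    _check_domains(binA, binB)
    records: List[DomainBias] = []
    for fam in fams:
        a = [g for g in fam.members.get(spA, []) if g in binA.values.index]
        b = [g for g in fam.members.get(spB, []) if g in binB.values.index]
        if len(a) != 1 or not b:
            continue
        if mode == "single_copy" and len(b) != 1:
            continue
        n_out = int(binA.values.loc[a[0]].sum())
        if mode == "individual_ohnologue" or mode == "single_copy":
            for g in b:
                records.append(
                    DomainBias(
                        pair_id=f"{fam.family_id}:{g}",
                        gene_outgroup=a[0],
                        entity_vertebrate=g,
                        domains_outgroup=n_out,
                        domains_vertebrate=int(binB.values.loc[g].sum()),
                        mode=mode,
                    )
                )
        elif mode == "union":
            n_vert = int(binB.values.loc[b].any(axis=0).sum())
            records.append(
                DomainBias(
                    pair_id=fam.family_id,
                    gene_outgroup=a[0],
                    entity_vertebrate="+".join(b),
                    domains_outgroup=n_out,
                    domains_vertebrate=n_vert,
                    mode=mode,
                )
            )
        else:  # sum_then_binarize
            summed = exprB_raw.values.loc[b].sum(axis=0)
            n_vert = int((summed > threshold).sum())
            records.append(
                DomainBias(
                    pair_id=fam.family_id,
                    gene_outgroup=a[0],
                    entity_vertebrate="+".join(b),
                    domains_outgroup=n_out,
                    domains_vertebrate=n_vert,
                    mode=mode,
                )
            )
    return records


def bias_histogram(records: Sequence[DomainBias]) -> pd.Series:
    biases = pd.Series([r.bias for r in records], dtype=int)
    return biases.value_counts().sort_index()


def neg_pos_log_ratio(records: Sequence[DomainBias]) -> float:
    """log2(#negative-bias / #positive-bias), zero-bias records excluded.

    A one-sided-empty split returns a signed infinity with a warning.
    """
    neg = sum(1 for r in records if r.bias < 0)
    pos = sum(1 for r in records if r.bias > 0)
    if neg == 0 and pos == 0:
        raise ValueError("no nonzero-bias records")
    if pos == 0:
        warnings.warn("no positive-bias records; ratio is +inf", stacklevel=2)
        return math.inf
    if neg == 0:
        warnings.warn("no negative-bias records; ratio is -inf", stacklevel=2)
        return -math.inf
    return math.log2(neg / pos)


def classify_fates(
    binA: BinaryExpressionProfile,
    binB: BinaryExpressionProfile,
    fams: FamilySet,
    spA: str,
    spB: str,
) -> Tuple[List[FateCall], pd.Series, pd.DataFrame]:
    """Fate per eligible family, plus fate frequencies and the ineligibility log."""
    domains = _check_domains(binA, binB)
    n_domains = len(domains)
    calls: List[FateCall] = []
    skipped = []
    for fam in fams:
        a = [g for g in fam.members.get(spA, []) if g in binA.values.index]
        b = [g for g in fam.members.get(spB, []) if g in binB.values.index]
        missing_a = [g for g in fam.members.get(spA, []) if g not in binA.values.index]
        missing_b = [g for g in fam.members.get(spB, []) if g not in binB.values.index]
        if missing_a or missing_b:
            skipped.append((fam.family_id, "member missing expression data"))
            continue
        if len(a) != 1:
            skipped.append((fam.family_id, f"{len(a)} outgroup members (need 1)"))
            continue
        if not b:
            skipped.append((fam.family_id, "no vertebrate members"))
            continue
        if int(binA.values.loc[a[0]].sum()) != n_domains:
            skipped.append((fam.family_id, "outgroup gene not expressed in all domains"))
            continue
        member_rows = binB.values.loc[b]
        if int(member_rows.any(axis=0).sum()) != n_domains:
            skipped.append((fam.family_id, "vertebrate union does not cover all domains"))
            continue
        n_on = member_rows.sum(axis=1)
        full = n_on == n_domains
        if full.all():
            fate = "redundancy"
        elif not full.any():
            fate = "subfunctionalization"
        else:
            fate = "specialization"
        subtypes: Dict[str, str] = {}
        retained: Dict[str, Tuple[str, ...]] = {}
        for g in b:
            on = tuple(d for d, v in binB.values.loc[g].items() if v)
            retained[g] = on
            if len(on) == n_domains:
                subtypes[g] = "full"
            elif fate == "specialization":
                subtypes[g] = (
                    "spec_strong" if len(on) <= SPEC_STRONG_MAX_DOMAINS else "spec_mild"
                )
            else:
                subtypes[g] = "restricted"
        calls.append(
            FateCall(
                family_id=fam.family_id,
                fate=fate,
                member_subtypes=subtypes,
                retained_domains=retained,
            )
        )
    counts = pd.Series([c.fate for c in calls]).value_counts()
    freqs = (counts / counts.sum()).reindex(FATES).fillna(0.0) if len(calls) else pd.Series(
        0.0, index=FATES
    )
    log = pd.DataFrame(skipped, columns=["family_id", "reason"])
    return calls, freqs, log


def specialization_domain_retention(
    calls: Sequence[FateCall], domains: Sequence[str]
) -> pd.Series:
    """How many spec_strong members retain expression in each domain.

    A member retaining two domains contributes to both counts.
    """
    counts = pd.Series(0, index=list(domains), dtype=int)
    for call in calls:
        for gene, subtype in call.member_subtypes.items():
            if subtype == "spec_strong":
                for d in call.retained_domains[gene]:
                    counts[d] += 1
    return counts


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> float:
    """Wilcoxon rank-sum p-value: exact enumeration for small tie-free groups,
    normal approximation with continuity correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = len(x) <= 25 and len(y) <= 25
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(
        mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True).pvalue
    )


def _member_groups(calls: Sequence[FateCall]) -> Dict[str, List[str]]:
    groups: Dict[str, List[str]] = {
        "redundant": [],
        "subfunctionalized": [],
        "spec_equal": [],
        "spec_mild": [],
        "spec_strong": [],
    }
    for call in calls:
        for gene, subtype in call.member_subtypes.items():
            if call.fate == "redundancy":
                groups["redundant"].append(gene)
            elif call.fate == "subfunctionalization":
                groups["subfunctionalized"].append(gene)
            elif subtype == "full":
                groups["spec_equal"].append(gene)
            else:
                groups[subtype].append(gene)
    return groups


def _grouped_values(
    calls: Sequence[FateCall], values: pd.Series
) -> Dict[str, np.ndarray]:
    groups = _member_groups(calls)
    out: Dict[str, np.ndarray] = {}
    dropped = 0
    for name, genes in groups.items():
        vals = values.reindex(genes)
        dropped += int(vals.isna().sum())
        out[name] = vals.dropna().to_numpy(dtype=float)
    if dropped:
        warnings.warn(f"{dropped} member values missing and dropped", stacklevel=3)
    return out


def _run_contrasts(
    grouped: Dict[str, np.ndarray],
    contrasts: Sequence[Tuple[str, str, str]],
) -> pd.DataFrame:
    rows = []
    for g1, g2, alternative in contrasts:
        x, y = grouped.get(g1, np.array([])), grouped.get(g2, np.array([]))
        if len(x) < 2 or len(y) < 2:
            rows.append(
                {"group1": g1, "group2": g2, "alternative": alternative,
                 "n1": len(x), "n2": len(y), "p_value": np.nan,
                 "note": "group size < 2; test skipped"}
            )
            continue
        rows.append(
            {"group1": g1, "group2": g2, "alternative": alternative,
             "n1": len(x), "n2": len(y),
             "p_value": rank_sum_test(x, y, alternative=alternative), "note": ""}
        )
    return pd.DataFrame(rows)


def fates_vs_apre_counts(
    calls: Sequence[FateCall], apre_counts: pd.Series
) -> Tuple[Dict[str, np.ndarray], pd.DataFrame]:
    """Peak-count distributions per fate subtype plus one-sided rank tests
    contrasting restricted vs full members within specialization families."""
    grouped = _grouped_values(calls, apre_counts)
    contrasts = [
        ("spec_strong", "spec_equal", "greater"),
        ("spec_mild", "spec_equal", "greater"),
        ("spec_strong", "redundant", "greater"),
    ]
    return grouped, _run_contrasts(grouped, contrasts)


def divergence_vs_fate(
    similarities: pd.Series, calls: Sequence[FateCall]
) -> Tuple[Dict[str, np.ndarray], pd.DataFrame]:
    """Sequence-similarity distributions per fate subtype plus two-sided tests."""
    grouped = _grouped_values(calls, similarities)
    contrasts = [
        ("spec_strong", "spec_equal", "two-sided"),
        ("spec_mild", "spec_equal", "two-sided"),
        ("subfunctionalized", "redundant", "two-sided"),
    ]
    return grouped, _run_contrasts(grouped, contrasts)
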