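"""Synthetic two-species datasets with planted ground truth.

Every generator here emits both the analysis inputs (expression matrices,
family tables, toy genomes with peak landscapes, CpG methylation calls,
motif-seeded sequences) and a truth record, so each downstream stage can be
verified end-to-end without external data.

A single master seed spawns an independent, named random stream per
generator, so adding a generator never perturbs the output of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .landscapes import GenomeAnnotation, PeakSet, great_domains
from .motifs import PWM
from .orthology import FamilySet, GeneFamily

__all__ = [
    "SyntheticConfig",
    "TruthLabels",
    "generate_hourglass_series",
    "generate_fate_families",
    "generate_genome_with_peaks",
    "generate_methylome",
    "generate_motif_dataset",
    "write_fasta",
    "read_fasta",
]

FATE_NAMES = ("redundancy", "subfunctionalization", "specialization")


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named sub-stream of the master seed (stable across generator additions)."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclass
class SyntheticConfig:
    seed: int = 0
    # hourglass series
    n_genes_1to1: int = 2000
    n_stages: int = 5
    divergence_profile: Optional[Sequence[float]] = None
    stage_effect_sd: float = 0.1
    # ohnologue fates
    n_ohno_families: int = 200
    ohno_copy_distribution: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.6, 3: 0.3, 4: 0.1}
    )
    fate_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "redundancy": 0.2,
            "subfunctionalization": 0.3,
            "specialization": 0.5,
        }
    )
    n_domains: int = 9
    expression_noise_sd: float = 0.0
    binarization_threshold: float = 5.0
    # toy genome / peaks
    genome_length: int = 2_000_000
    n_genes_genome: int = 40
    peak_density_per_gene: Tuple[float, float] = (3.0, 8.0)
    n_background_peaks: int = 0
    peak_count_mode: str = "fixed"  # fixed | poisson
    # methylome
    methylation_modes: Tuple[float, float] = (0.05, 0.9)
    meth_samples: Tuple[str, ...] = ("hepatic", "neural", "muscle")
    cpgs_per_region: int = 8
    min_coverage: int = 5
    differential_fraction: float = 0.5
    # motifs
    n_motifs: int = 3
    motif_length: int = 8
    n_sequences_per_group: int = 40
    sequence_length: int = 500
    background_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        for name, probs in (
            ("ohno_copy_distribution", self.ohno_copy_distribution.values()),
            ("fate_mix", self.fate_mix.values()),
            ("background_composition", self.background_composition),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        if self.n_domains < 2:
            raise ValueError("n_domains must be >= 2")
        if self.divergence_profile is None:
            mid = self.n_stages // 2
            self.divergence_profile = [
                0.8 if i != mid else 0.2 for i in range(self.n_stages)
            ]
        if len(self.divergence_profile) != self.n_stages:
            raise ValueError("divergence_profile length must equal n_stages")
        if any(k not in (2, 3, 4) for k in self.ohno_copy_distribution):
            raise ValueError("ohnologue copy numbers must be in {2, 3, 4}")
        if self.peak_count_mode not in ("fixed", "poisson"):
            raise ValueError("peak_count_mode must be 'fixed' or 'poisson'")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ohno_copy_distribution" in raw:
            raw["ohno_copy_distribution"] = {
                int(k): v for k, v in raw["ohno_copy_distribution"].items()
            }
        for key in ("peak_density_per_gene", "methylation_modes", "background_composition", "meth_samples"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class TruthLabels:
    """Ground-truth tables keyed by what they label; serializable as TSVs."""

    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_tsv(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(os.path.join(outdir, f"truth_{name}.tsv"), sep="\t")


# ---------------------------------------------------------------------------
# hourglass series
# ---------------------------------------------------------------------------

def generate_hourglass_series(
    config: SyntheticConfig, require_minimum: bool = True
) -> Tuple[ExpressionMatrix, ExpressionMatrix, List[Tuple[str, str]], TruthLabels]:
    """Paired developmental series for two species of 1-to-1 orthologues.

    Species B equals species A at the homologous stage times multiplicative
    log-normal noise whose scale follows ``divergence_profile``; the truth
    records the stage of minimal planted divergence.
    """
    profile = np.asarray(config.divergence_profile, dtype=float)
    if config.n_stages < 3:
        raise ValueError("hourglass series needs at least 3 stages")
    if require_minimum:
        best = profile.argmin()
        if (profile == profile[best]).sum() > 1:
            raise ValueError(
                "divergence_profile must have exactly one strict minimum; "
                f"got {profile.tolist()} (flat or tied)"
            )
    rng = _rng(config.seed, "hourglass")
    n = config.n_genes_1to1
    genesA = [f"blaG{i:05d}" for i in range(n)]
    genesB = [f"vrtG{i:05d}" for i in range(n)]
    stages = [f"stage{i + 1}" for i in range(config.n_stages)]
    base = rng.lognormal(mean=3.0, sigma=1.2, size=(n, 1))
    stage_dev = rng.normal(0.0, config.stage_effect_sd, size=(n, config.n_stages))
    a = base * np.exp(stage_dev)
    noise = rng.normal(0.0, 1.0, size=(n, config.n_stages)) * profile[None, :]
    b = a * np.exp(noise)
    exprA = ExpressionMatrix(pd.DataFrame(a, index=genesA, columns=stages), units="TPM")
    exprB = ExpressionMatrix(pd.DataFrame(b, index=genesB, columns=stages), units="TPM")
    pairs = list(zip(genesA, genesB))
    truth = TruthLabels(
        tables={
            "hourglass": pd.DataFrame(
                {
                    "stage": stages,
                    "noise_scale": profile,
                    "is_planted_minimum": profile == profile.min(),
                }
            ).set_index("stage")
        }
    )
    return exprA, exprB, pairs, truth


# ---------------------------------------------------------------------------
# ohnologue fate families
# ---------------------------------------------------------------------------

def _subfunctionalization_pattern(
    n_copies: int, n_domains: int, rng: np.random.Generator
) -> np.ndarray:
    """Reciprocal-loss pattern: no copy full, union covers all domains."""
    order = rng.permutation(n_domains)
    groups = np.array_split(order, n_copies)
    pattern = np.ones((n_copies, n_domains), dtype=bool)
    for c, lost in enumerate(groups):
        pattern[c, lost] = False
    return pattern


def _specialization_pattern(
    n_copies: int, n_domains: int, rng: np.random.Generator
) -> np.ndarray:
    """At least one full copy; every other copy restricted."""
    pattern = np.zeros((n_copies, n_domains), dtype=bool)
    pattern[0, :] = True
    for c in range(1, n_copies):
        n_on = int(rng.integers(1, n_domains))  # 1..n_domains-1
        on = rng.choice(n_domains, size=n_on, replace=False)
        pattern[c, on] = True
    return pattern


def generate_fate_families(
    config: SyntheticConfig,
) -> Tuple[FamilySet, ExpressionMatrix, ExpressionMatrix, TruthLabels]:
    """Ohnologue families with planted post-WGD expression fates.

    The outgroup gene is on in every domain. On/off truth patterns become
    continuous values (on = 4x threshold, off = 0.1x threshold) times
    log-normal noise, so binarization at the configured threshold is exact
    at zero noise.
    """
    rng = _rng(config.seed, "fates")
    nd = config.n_domains
    domains = [f"domain{i + 1}" for i in range(nd)]
    fates = list(config.fate_mix)
    fate_p = np.array([config.fate_mix[f] for f in fates])
    copies = sorted(config.ohno_copy_distribution)
    copy_p = np.array([config.ohno_copy_distribution[c] for c in copies])

    on_value = config.binarization_threshold * 4.0
    off_value = config.binarization_threshold * 0.1

    fam_list: List[GeneFamily] = []
    rowsA, rowsB, idxA, idxB = [], [], [], []
    truth_rows = []
    member_rows = []
    for i in range(config.n_ohno_families):
        fid = f"fam{i:05d}"
        fate = fates[rng.choice(len(fates), p=fate_p)]
        n_copies = int(copies[rng.choice(len(copies), p=copy_p)])
        if n_copies < 2:
            raise ValueError("a planted fate requires at least 2 vertebrate copies")
        if fate == "redundancy":
            pattern = np.ones((n_copies, nd), dtype=bool)
        elif fate == "subfunctionalization":
            pattern = _subfunctionalization_pattern(n_copies, nd, rng)
        elif fate == "specialization":
            pattern = _specialization_pattern(n_copies, nd, rng)
        else:
            raise ValueError(f"unknown fate {fate!r}")
        ga = f"bla{fid}"
        idxA.append(ga)
        rowsA.append(np.full(nd, on_value))
        gbs = [f"vrt{fid}_{c}" for c in range(n_copies)]
        for c, gb in enumerate(gbs):
            idxB.append(gb)
            rowsB.append(np.where(pattern[c], on_value, off_value))
            member_rows.append(
                {
                    "gene_id": gb,
                    "family_id": fid,
                    "planted_on_domains": int(pattern[c].sum()),
                }
            )
        fam_list.append(GeneFamily(fid, {"outgroup": [ga], "vertebrate": gbs}))
        truth_rows.append({"family_id": fid, "planted_fate": fate, "n_copies": n_copies})

    a = np.vstack(rowsA)
    b = np.vstack(rowsB)
    if config.expression_noise_sd > 0:
        a = a * np.exp(rng.normal(0, config.expression_noise_sd, size=a.shape))
        b = b * np.exp(rng.normal(0, config.expression_noise_sd, size=b.shape))
    exprA = ExpressionMatrix(pd.DataFrame(a, index=idxA, columns=domains), units="cRPKM")
    exprB = ExpressionMatrix(pd.DataFrame(b, index=idxB, columns=domains), units="cRPKM")
    fams = FamilySet(families=fam_list, species=["outgroup", "vertebrate"], provenance="synthetic")
    truth = TruthLabels(
        tables={
            "fates": pd.DataFrame(truth_rows).set_index("family_id"),
            "fate_members": pd.DataFrame(member_rows).set_index("gene_id"),
        }
    )
    return fams, exprA, exprB, truth


# ---------------------------------------------------------------------------
# toy genome with peak landscapes
# ---------------------------------------------------------------------------

def generate_genome_with_peaks(
    config: SyntheticConfig,
) -> Tuple[GenomeAnnotation, PeakSet, PeakSet, TruthLabels]:
    """One toy chromosome with non-overlapping genes and two planted peak
    landscapes of unequal density (species B denser by default).

    Peak midpoints are placed inside the owning gene's basal region, which
    is exclusive territory under the basal-plus-extension rule as long as
    basal windows do not abut, so per-gene counting recovers the planted
    counts exactly. Background peaks (unassigned) are optional.
    """
    rng = _rng(config.seed, "genome")
    n = config.n_genes_genome
    slot = config.genome_length // n
    gene_len = max(200, slot // 10)
    if gene_len + 2 >= slot:
        placed = config.genome_length // (gene_len + 2)
        raise ValueError(
            f"genome_length too small: could place only {placed} of {n} genes"
        )
    rows = []
    for i in range(n):
        start = i * slot + slot // 2 - gene_len // 2
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            {
                "gene_id": f"gene{i:04d}",
                "chrom": "chrS",
                "strand": strand,
                "start": int(start),
                "end": int(start + gene_len),
            }
        )
    annotation = GenomeAnnotation(
        chromosomes={"chrS": config.genome_length}, genes=pd.DataFrame(rows)
    )
    domains = {d.gene_id: d for d in great_domains(annotation)}

    def make_peaks(mean_count: float, prefix: str, stream: str) -> Tuple[PeakSet, pd.Series]:
        prng = _rng(config.seed, stream)
        peak_rows = []
        planted = {}
        for _, gene in annotation.genes.iterrows():
            dom = domains[gene["gene_id"]]
            lo, hi = dom.basal
            if config.peak_count_mode == "fixed":
                count = int(round(mean_count))
            else:
                count = int(prng.poisson(mean_count))
            planted[gene["gene_id"]] = count
            for _ in range(count):
                width = int(prng.integers(100, 401))
                mid = int(prng.integers(lo + width // 2 + 1, hi - width // 2 - 1))
                peak_rows.append(
                    {
                        "chrom": "chrS",
                        "start": mid - width // 2,
                        "end": mid - width // 2 + width,
                        "peak_id": f"{prefix}_{len(peak_rows):05d}",
                    }
                )
        for _ in range(config.n_background_peaks):
            width = int(prng.integers(100, 401))
            start = int(prng.integers(0, config.genome_length - width))
            peak_rows.append(
                {
                    "chrom": "chrS",
                    "start": start,
                    "end": start + width,
                    "peak_id": f"{prefix}_bg{len(peak_rows):05d}",
                }
            )
        cols = ["chrom", "start", "end", "peak_id"]
        df = pd.DataFrame(peak_rows, columns=cols).sort_values(["start", "end"]).reset_index(drop=True)
        return PeakSet(intervals=df), pd.Series(planted, name="planted_count")

    peaksA, plantedA = make_peaks(config.peak_density_per_gene[0], "pkA", "peaksA")
    peaksB, plantedB = make_peaks(config.peak_density_per_gene[1], "pkB", "peaksB")
    truth = TruthLabels(
        tables={
            "peak_counts": pd.DataFrame(
                {"planted_A": plantedA, "planted_B": plantedB}
            )
        }
    )
    return annotation, peaksA, peaksB, truth


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def generate_methylome(
    config: SyntheticConfig, regions: PeakSet
) -> Tuple[pd.DataFrame, TruthLabels]:
    """Bimodal region methylation: differential regions are hypomethylated in
    the first (defining) sample and methylated elsewhere; constitutive
    regions are hypomethylated everywhere. Coverage respects the floor."""
    low, high = config.methylation_modes
    if abs(high - low) < 0.3:
        import warnings

        warnings.warn(
            f"methylation modes {config.methylation_modes} closer than 0.3; "
            "clusters may be unrecoverable",
            stacklevel=2,
        )
    rng = _rng(config.seed, "methylome")
    samples = list(config.meth_samples)
    rows = []
    truth_rows = []
    for _, region in regions.intervals.iterrows():
        differential = rng.random() < config.differential_fraction
        truth_rows.append(
            {
                "region_id": region["peak_id"],
                "planted_cluster": 1 if differential else 2,
            }
        )
        width = region["end"] - region["start"]
        n_cpg = max(config.cpgs_per_region, 1)
        positions = np.sort(
            rng.choice(max(width, n_cpg), size=min(n_cpg, width), replace=False)
        ) + region["start"]
        for s_i, sample in enumerate(samples):
            if differential:
                mode = low if s_i == 0 else high
            else:
                mode = low
            for pos in positions:
                level = float(np.clip(rng.normal(mode, 0.02), 0.0, 1.0))
                total = int(config.min_coverage + rng.poisson(10))
                meth = int(rng.binomial(total, level))
                rows.append(
                    {
                        "chrom": region["chrom"],
                        "pos": int(pos),
                        "strand": "+",
                        "meth_reads": meth,
                        "total_reads": total,
                        "sample": sample,
                    }
                )
    calls = pd.DataFrame(rows)
    truth = TruthLabels(
        tables={"methylation": pd.DataFrame(truth_rows).set_index("region_id")}
    )
    return calls, truth


# ---------------------------------------------------------------------------
# motif dataset
# ---------------------------------------------------------------------------

def _random_pwm(motif_id: str, length: int, rng: np.random.Generator) -> PWM:
    consensus = rng.integers(0, 4, size=length)
    mat = np.full((4, length), 0.05)
    mat[consensus, np.arange(length)] = 0.85
    return PWM(motif_id=motif_id, matrix=mat)


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    bases = "ACGT"
    return "".join(
        bases[rng.choice(4, p=pwm.matrix[:, j])] for j in range(pwm.length)
    )


def generate_motif_dataset(
    config: SyntheticConfig,
    insertion_rates: Optional[pd.DataFrame] = None,
) -> Tuple[Dict[str, Dict[str, str]], List[PWM], TruthLabels]:
    """Groups of background sequences with planted per-motif insertion rates.

    ``insertion_rates`` is a group x motif table of expected insertions per
    sequence; by default group ``g1`` is enriched 10x for the first motif.
    Returns ({group: {seq_id: sequence}}, pwms, truth).
    """
    if config.motif_length >= config.sequence_length:
        raise ValueError("motif length must be smaller than sequence length")
    rng = _rng(config.seed, "motifs")
    pwms = [
        _random_pwm(f"motif{m + 1}", config.motif_length, rng)
        for m in range(config.n_motifs)
    ]
    if insertion_rates is None:
        insertion_rates = pd.DataFrame(
            0.2, index=["g1", "g2"], columns=[p.motif_id for p in pwms]
        )
        insertion_rates.loc["g1", pwms[0].motif_id] = 2.0
    comp = np.asarray(config.background_composition)
    bases = np.array(list("ACGT"))
    groups: Dict[str, Dict[str, str]] = {}
    for group in insertion_rates.index:
        seqs: Dict[str, str] = {}
        for i in range(config.n_sequences_per_group):
            seq = list(rng.choice(bases, size=config.sequence_length, p=comp))
            for pwm in pwms:
                n_insert = rng.poisson(insertion_rates.loc[group, pwm.motif_id])
                for _ in range(n_insert):
                    site = _sample_site(pwm, rng)
                    if rng.random() < 0.5:
                        site = site.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                    pos = int(rng.integers(0, config.sequence_length - pwm.length + 1))
                    seq[pos : pos + pwm.length] = list(site)
            seqs[f"{group}_seq{i:04d}"] = "".join(seq)
        groups[group] = seqs
    truth = TruthLabels(tables={"motif_rates": insertion_rates.copy()})
    return groups, pwms, truth


# ---------------------------------------------------------------------------
# FASTA round-trip helpers
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
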