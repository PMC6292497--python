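import numpy as np
import pandas as pd
import pytest

from chordcomp.expression import ExpressionMatrix
from chordcomp.landscapes import GenomeAnnotation, PeakSet
from chordcomp.orthology import FamilySet, GeneFamily
from chordcomp.synthetic import SyntheticConfig


@pytest.fixture
def small_config():
    return SyntheticConfig(
        seed=7,
        n_genes_1to1=300,
        n_stages=3,
        divergence_profile=[0.8, 0.2, 0.8],
        n_ohno_families=60,
        n_genes_genome=10,
        genome_length=500_000,
        n_sequences_per_group=12,
        sequence_length=300,
    )


@pytest.fixture
def toy_annotation():
    genes = pd.DataFrame(
        [
            {"gene_id": "gA", "chrom": "chr1", "strand": "+", "start": 100_000, "end": 110_000},
            {"gene_id": "gB", "chrom": "chr1", "strand": "-", "start": 200_000, "end": 215_000},
            {"gene_id": "gC", "chrom": "chr2", "strand": "+", "start": 50_000, "end": 52_000},
        ]
    )
    return GenomeAnnotation(chromosomes={"chr1": 1_000_000, "chr2": 500_000}, genes=genes)


@pytest.fixture
def toy_peaks():
    rows = [
        ("chr1", 99_500, 99_900, "pk1"),     # midpoint 99700, 300 bp upstream of gA TSS
        ("chr1", 104_000, 104_400, "pk2"),   # inside gA body
        ("chr1", 96_800, 97_200, "pk3"),     # 3 kb upstream of gA, intergenic
        ("chr1", 500_000, 500_400, "pk4"),   # far from everything
    ]
    return PeakSet(intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"]))


@pytest.fixture
def mirror_universe():
    """Identical expression in both species with identity orthology."""
    rng = np.random.default_rng(42)
    n = 40
    samples = [f"s{i}" for i in range(5)]
    vals = rng.lognormal(2.0, 1.0, size=(n, 5))
    genesA = [f"a{i}" for i in range(n)]
    genesB = [f"b{i}" for i in range(n)]
    exprA = ExpressionMatrix(pd.DataFrame(vals, index=genesA, columns=samples))
    exprB = ExpressionMatrix(pd.DataFrame(vals.copy(), index=genesB, columns=samples))
    fams = FamilySet(
        families=[
            GeneFamily(f"f{i}", {"sp1": [genesA[i]], "sp2": [genesB[i]]}) for i in range(n)
        ],
        species=["sp1", "sp2"],
    )
    return exprA, exprB, fams
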