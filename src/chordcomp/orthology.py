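"""Gene-family containers and the relationship-class filters used downstream."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = ["GeneFamily", "FamilySet", "read_family_table", "one_to_one_pairs", "ohnologue_families"]


@dataclass
class GeneFamily:
    family_id: str
    members: Dict[str, List[str]]  # species -> gene ids

    def copies(self, species: str) -> int:
        return len(self.members.get(species, []))


@dataclass
class FamilySet:
    families: List[GeneFamily]
    species: List[str]
    provenance: str = ""
    _gene_index: Dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._gene_index:
            for fam in self.families:
                for sp, genes in fam.members.items():
                    if sp not in self.species:
                        raise ValueError(f"species {sp!r} not in registry {self.species}")
                    for g in genes:
                        if g in self._gene_index:
                            raise ValueError(
                                f"gene {g!r} appears in families "
                                f"{self._gene_index[g]!r} and {fam.family_id!r}"
                            )
                        self._gene_index[g] = fam.family_id

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families)

    def family_of(self, gene_id: str) -> Optional[str]:
        return self._gene_index.get(gene_id)

    def get(self, family_id: str) -> GeneFamily:
        for fam in self.families:
            if fam.family_id == family_id:
                return fam
        raise KeyError(family_id)

    def to_tsv(self, path) -> None:
        rows = [
            (fam.family_id, sp, g)
            for fam in self.families
            for sp, genes in sorted(fam.members.items())
            for g in genes
        ]
        pd.DataFrame(rows, columns=["family_id", "species", "gene_id"]).to_csv(
            path, sep="\t", index=False
        )


def read_family_table(path, species_registry: Optional[Sequence[str]] = None) -> FamilySet:
    """Assemble a FamilySet from a TSV with columns family_id, species, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "species", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"family table must have columns {sorted(required)}")
    if df.empty:
        warnings.warn("empty family table", stacklevel=2)
        return FamilySet(families=[], species=list(species_registry or []), provenance=str(path))
    if species_registry is not None:
        unknown = sorted(set(df["species"]) - set(species_registry))
        if unknown:
            raise ValueError(f"unknown species in family table: {unknown}")
        registry = list(species_registry)
    else:
        registry = sorted(df["species"].unique())
    fams: List[GeneFamily] = []
    for fid, grp in df.groupby("family_id", sort=True):
        members: Dict[str, List[str]] = {}
        for sp, sub in grp.groupby("species", sort=True):
            members[sp] = list(sub["gene_id"])
        fams.append(GeneFamily(family_id=str(fid), members=members))
    return FamilySet(families=fams, species=registry, provenance=str(path))


def one_to_one_pairs(fams: FamilySet, spA: str, spB: str) -> List[Tuple[str, str]]:
    """(geneA, geneB) for families with exactly one member in each species."""
    for sp in (spA, spB):
        if sp not in fams.species:
            raise ValueError(f"species {sp!r} not in registry")
    pairs = []
    for fam in fams:
        if fam.copies(spA) == 1 and fam.copies(spB) == 1:
            pairs.append((fam.members[spA][0], fam.members[spB][0]))
    return pairs


def ohnologue_families(
    fams: FamilySet,
    outgroup: str,
    vertebrate: str,
    min_copies: int = 2,
    max_copies: int = 4,
) -> FamilySet:
    """Families with a single outgroup member and min..max vertebrate copies."""
    if outgroup == vertebrate:
        raise ValueError("outgroup and vertebrate species must differ")
    kept = [
        fam
        for fam in fams
        if fam.copies(outgroup) == 1 and min_copies <= fam.copies(vertebrate) <= max_copies
    ]
    return FamilySet(families=kept, species=fams.species, provenance=fams.provenance)
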