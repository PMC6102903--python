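"""Taxonomic lineages and tiered reference databases.

A reference *tier* is one prioritized database in the iterative classification
cascade (default order: viral, archaeal, bacterial, whole). Lineages follow the
reporting convention of virome profiling: viruses are resolved at family and
species level, cellular organisms at genus and species level. Taxonomy is
supplied as a TSV side table (accession, realm, family, genus, species) rather
than parsed out of organism names.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import SequenceRecord, header_product, parse_refseq_header, read_fasta

REALMS = ("viral", "archaeal", "bacterial", "eukaryote")
CELLULAR_REALMS = ("archaeal", "bacterial", "eukaryote")
RANKS = ("family", "genus", "species")
DEFAULT_TIER_ORDER = ("viral", "archaeal", "bacterial", "whole")


@dataclass(frozen=True)
class TaxonomyLineage:
    """Lineage at the ranks this toolkit reports.

    Unknown ranks are stored empty and printed as ``Unclassified__<nearest>``.
    """

    realm: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if self.realm and self.realm not in REALMS:
            raise ValueError(f"unknown realm {self.realm!r}; expected one of {REALMS}")

    def is_empty(self) -> bool:
        return not (self.realm or self.family or self.genus or self.species)

    def is_viral(self) -> bool:
        return self.realm == "viral"

    def _nearest_known(self, rank: str) -> str:
        order = ["species", "genus", "family", "realm"]
        for r in order[order.index(rank) + 1:]:
            value = getattr(self, r)
            if value:
                return value
        return "Unclassified"

    def label(self, rank: str) -> str:
        """Printable taxon label at ``rank``; unknown ranks fall back to the
        nearest known higher rank, mirroring the ``Unclassified__<taxon>`` style."""
        if rank not in RANKS:
            raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
        value = getattr(self, rank)
        if value:
            return value
        return f"Unclassified__{self._nearest_known(rank)}"

    def vote_rank(self) -> str:
        """The rank at which a lineage contributes a contig vote: viral family
        for viruses, genus for cellular organisms."""
        return "family" if self.is_viral() else "genus"

    def pretty(self) -> str:
        parts = [p for p in (self.realm, self.family, self.genus, self.species) if p]
        return "; ".join(parts) if parts else "Unclassified"


EMPTY_LINEAGE = TaxonomyLineage()


@dataclass
class ReferenceEntry:
    """One database entry: a sequence with accession, annotation and lineage."""

    accession: str
    organism: str
    lineage: TaxonomyLineage
    seq: SequenceRecord
    kind: str = "nucleotide"  # nucleotide | protein
    product: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("nucleotide", "protein"):
            raise ValueError(f"entry kind must be nucleotide or protein, got {self.kind!r}")


@dataclass
class ReferenceTier:
    """An ordered, named reference database; priority 1 is consulted first."""

    name: str
    priority: int
    entries: list[ReferenceEntry] = field(default_factory=list)
    kind: str = "nucleotide"

    def __post_init__(self) -> None:
        if self.priority < 1:
            raise ValueError("tier priority must be ≥ 1")
        seen: set[str] = set()
        for e in self.entries:
            if e.accession in seen:
                raise ValueError(f"tier {self.name}: duplicate accession {e.accession!r}")
            seen.add(e.accession)

    def __len__(self) -> int:
        return len(self.entries)

    def lineage_of(self, accession: str) -> TaxonomyLineage:
        for e in self.entries:
            if e.accession == accession:
                return e.lineage
        raise KeyError(accession)


def check_tier_order(tiers: Sequence[ReferenceTier]) -> None:
    """Tier priorities must be unique and contiguous from 1."""
    priorities = sorted(t.priority for t in tiers)
    if priorities != list(range(1, len(tiers) + 1)):
        raise ValueError(f"tier priorities must be contiguous from 1, got {priorities}")


def read_taxonomy_table(path) -> dict[str, TaxonomyLineage]:
    """Load an accession → lineage TSV (accession, realm, family, genus, species)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"accession", "realm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table {path} lacks columns: {sorted(missing)}")
    out: dict[str, TaxonomyLineage] = {}
    for row in df.itertuples(index=False):
        out[row.accession] = TaxonomyLineage(
            realm=row.realm,
            family=getattr(row, "family", ""),
            genus=getattr(row, "genus", ""),
            species=getattr(row, "species", ""),
        )
    return out


def write_taxonomy_table(lineages: Mapping[str, TaxonomyLineage], path) -> None:
    rows = [
        {"accession": acc, "realm": lin.realm, "family": lin.family,
         "genus": lin.genus, "species": lin.species}
        for acc, lin in lineages.items()
    ]
    pd.DataFrame(rows, columns=["accession", "realm", "family", "genus", "species"]) \
        .to_csv(path, sep="\t", index=False)


def load_tier(name: str, priority: int, fasta_path, taxonomy_path=None,
              kind: str = "nucleotide") -> ReferenceTier:
    """Build a tier from a FASTA with RefSeq-style headers plus a taxonomy TSV."""
    lineages = read_taxonomy_table(taxonomy_path) if taxonomy_path else {}
    entries = []
    for rec in read_fasta(fasta_path):
        accession, organism = parse_refseq_header(rec.description or rec.id)
        entries.append(ReferenceEntry(
            accession=accession,
            organism=organism,
            lineage=lineages.get(accession, EMPTY_LINEAGE),
            seq=rec,
            kind=kind,
            product=header_product(rec.description or rec.id),
        ))
    return ReferenceTier(name=name, priority=priority, entries=entries, kind=kind)


def merge_tiers(base: ReferenceTier, extra: Iterable[ReferenceEntry],
                name: str | None = None) -> ReferenceTier:
    """Union of a tier with additional entries, deduplicated by accession.

    Entries in ``extra`` whose accession already exists in ``base`` are dropped
    (the revised base entry wins), so merging N entries with M additional unique
    ones yields N + M.
    """
    seen = {e.accession for e in base.entries}
    merged = list(base.entries)
    for e in extra:
        if e.accession not in seen:
            merged.append(e)
            seen.add(e.accession)
    return ReferenceTier(name=name or base.name, priority=base.priority,
                         entries=merged, kind=base.kind)
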