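"""CRISPR-spacer host prediction and marker-based novel-phage screening.

A CRISPR spacer found (near-)verbatim in a viral contig is a protospacer:
evidence that the spacer's bacterial or archaeal host has encountered that
phage. Matching is substitution-only (Hamming) on both strands — spacers are
short, and tolerating indels would inflate false host links.

Novel (pro)phage screening flags bacterial or unclassified contigs whose ORFs
hit marker proteins spanning several distinct phage genomic modules
(replication, packaging, head, tail, lysis, lysogeny); such contigs encode
phage-like gene architecture even when no database homolog classifies them as
viral. Lysogeny-module presence is reported separately — a clear lysogeny
module (e.g. an integrase) distinguishes temperate candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentParams, build_index, search
from .orfs import ORF
from .seqio import SequenceRecord, read_fasta, parse_refseq_header, reverse_complement
from .taxonomy import (EMPTY_LINEAGE, ReferenceEntry, ReferenceTier,
                       TaxonomyLineage, read_taxonomy_table)

PHAGE_MODULES = ("replication", "packaging", "head", "tail", "lysis", "lysogeny")


@dataclass
class SpacerDatabase:
    """CRISPR spacers (20–60 nt) with the lineage of their host organism."""

    spacers: list[tuple[str, str, TaxonomyLineage]]  # (spacer_id, seq, host lineage)

    def __post_init__(self) -> None:
        for sid, seq, lineage in self.spacers:
            if not (20 <= len(seq) <= 60):
                raise ValueError(f"spacer {sid}: length {len(seq)} outside [20, 60]")
            if not (lineage.genus or lineage.species):
                raise ValueError(f"spacer {sid}: host lineage needs genus or species")


def load_spacer_database(fasta_path, host_table_path) -> SpacerDatabase:
    hosts = read_taxonomy_table(host_table_path)
    spacers = []
    for rec in read_fasta(fasta_path):
        sid, _ = parse_refseq_header(rec.description or rec.id)
        if sid not in hosts:
            raise ValueError(f"spacer {sid} missing from host table")
        spacers.append((sid, rec.seq.upper(), hosts[sid]))
    return SpacerDatabase(spacers)


@dataclass
class SpacerMatch:
    contig_id: str
    spacer_id: str
    host: TaxonomyLineage
    mismatches: int
    position: int  # 0-based start on the forward contig strand
    strand: str


def _hamming_positions(contig: np.ndarray, spacer: str, max_mismatches: int) -> list[tuple[int, int]]:
    """(position, mismatches) for every window of the encoded contig within
    Hamming distance ``max_mismatches`` of ``spacer``."""
    m = len(spacer)
    n = contig.size
    if n < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(contig, m)
    pattern = np.frombuffer(spacer.encode(), dtype=np.uint8)
    mismatches = (windows != pattern).sum(axis=1)
    hits = np.flatnonzero(mismatches <= max_mismatches)
    return [(int(p), int(mismatches[p])) for p in hits]


def predict_hosts(viral_contigs: Sequence[SequenceRecord], spacer_db: SpacerDatabase,
                  max_mismatches: int = 1) -> list[SpacerMatch]:
    """Every spacer occurrence on either contig strand with ≤ ``max_mismatches``
    substitutions (no indels), sorted by (contig, mismatches, position)."""
    matches: list[SpacerMatch] = []
    for contig in viral_contigs:
        seq = contig.seq.upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        n = len(seq)
        for sid, spacer, host in spacer_db.spacers:
            for strand, probe in (("+", spacer), ("-", reverse_complement(spacer))):
                for pos, mm in _hamming_positions(arr, probe, max_mismatches):
                    matches.append(SpacerMatch(contig_id=contig.id, spacer_id=sid,
                                               host=host, mismatches=mm,
                                               position=pos, strand=strand))
    matches.sort(key=lambda m: (m.contig_id, m.mismatches, m.position, m.spacer_id, m.strand))
    return matches


@dataclass
class PhageMarkerSet:
    """Protein markers of phage genomic modules; every marker belongs to
    exactly one module."""

    markers: list[ReferenceEntry]
    module_map: dict[str, str]  # accession -> module

    def __post_init__(self) -> None:
        for e in self.markers:
            module = self.module_map.get(e.accession)
            if module not in PHAGE_MODULES:
                raise ValueError(f"marker {e.accession}: module {module!r} not in {PHAGE_MODULES}")

    def tier(self) -> ReferenceTier:
        return ReferenceTier(name="phage-markers", priority=1,
                             entries=self.markers, kind="protein")


def load_marker_set(fasta_path, module_table_path) -> PhageMarkerSet:
    df = pd.read_csv(module_table_path, sep="\t", dtype=str).fillna("")
    module_map = dict(zip(df["accession"], df["module"]))
    markers = []
    for rec in read_fasta(fasta_path):
        acc, organism = parse_refseq_header(rec.description or rec.id)
        markers.append(ReferenceEntry(accession=acc, organism=organism,
                                      lineage=EMPTY_LINEAGE, seq=rec, kind="protein"))
    return PhageMarkerSet(markers, module_map)


@dataclass
class NovelPhageCandidate:
    contig_id: str
    modules: list[str]
    has_lysogeny_module: bool
    supporting_orfs: list[tuple[str, str, str]]  # (orf id, marker accession, module)
    note: str = ""


def screen_novel_phage(contigs_with_orfs: Sequence[tuple[SequenceRecord, Sequence[ORF]]],
                       marker_set: PhageMarkerSet,
                       params: AlignmentParams | None = None,
                       min_modules: int = 3) -> list[NovelPhageCandidate]:
    """Flag contigs whose ORFs hit markers spanning ≥ ``min_modules`` distinct
    phage modules. Input contigs should already be classified non-viral or
    unclassified; contigs without ORFs are skipped with a note."""
    if params is None:
        params = AlignmentParams.protein_defaults()
    index = build_index(marker_set.tier(), params)
    candidates: list[NovelPhageCandidate] = []
    for contig, orfs in contigs_with_orfs:
        if not orfs:
            candidates.append(NovelPhageCandidate(
                contig_id=contig.id, modules=[], has_lysogeny_module=False,
                supporting_orfs=[], note="no ORFs; skipped"))
            continue
        supporting: list[tuple[str, str, str]] = []
        modules: set[str] = set()
        for orf in orfs:
            hits = search(orf.record(), index, params)
            if not hits:
                continue
            marker = hits[0].subject_accession
            module = marker_set.module_map[marker]
            modules.add(module)
            supporting.append((orf.id, marker, module))
        if len(modules) >= min_modules:
            candidates.append(NovelPhageCandidate(
                contig_id=contig.id,
                modules=sorted(modules),
                has_lysogeny_module="lysogeny" in modules,
                supporting_orfs=supporting,
            ))
    return candidates


def candidate_table(candidates: Sequence[NovelPhageCandidate]) -> pd.DataFrame:
    rows = [{
        "contig_id": c.contig_id,
        "n_modules": len(c.modules),
        "modules": ";".join(c.modules),
        "lysogeny_module": c.has_lysogeny_module,
        "n_supporting_orfs": len(c.supporting_orfs),
        "note": c.note,
    } for c in candidates]
    return pd.DataFrame(rows, columns=["contig_id", "n_modules", "modules",
                                       "lysogeny_module", "n_supporting_orfs", "note"])
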