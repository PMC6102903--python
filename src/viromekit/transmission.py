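"""Mother–infant phage transmission detection by stringent read mapping.

Viral contigs longer than 5000 bp assembled from an infant's virome serve as
backbones; the mother's reads are mapped at a stringent 99% identity cut-off
(tolerating ~1% sequencing error, nothing more). A contig with at least one
stringently mapping mother read is called shared — evidence that mother and
infant carry the same phage genotype. Cross-pair controls map each mother's
reads on *unrelated* infants' contigs; with genuine vertical transmission and
no contamination those off-diagonal counts are zero. Run the contamination
screen first: a reagent contaminant present in every sample would light up
the whole matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .align import AlignmentParams, build_index, search
from .seqio import SequenceRecord
from .taxonomy import EMPTY_LINEAGE, ReferenceEntry, ReferenceTier, TaxonomyLineage

BACKBONE_LENGTH_GATE = 5000


@dataclass
class ContigMapping:
    contig_id: str
    length: int
    lineage: TaxonomyLineage
    mapped_reads: int
    breadth: float  # % of contig covered at least 1×


@dataclass
class TransmissionReport:
    pair_id: str
    rows: list[ContigMapping]
    shared_contigs: list[str]
    reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        data = [{
            "contig_id": r.contig_id, "length": r.length,
            "lineage": r.lineage.pretty(), "mapped_reads": r.mapped_reads,
            "breadth_pct": round(r.breadth, 2),
            "shared": r.contig_id in self.shared_contigs,
        } for r in self.rows]
        return pd.DataFrame(data, columns=["contig_id", "length", "lineage",
                                           "mapped_reads", "breadth_pct", "shared"])


def map_reads_stringent(reads: Sequence[SequenceRecord],
                        contigs: Sequence[SequenceRecord],
                        min_identity: float = 99.0, min_read_cov: float = 90.0,
                        params: AlignmentParams | None = None,
                        ) -> dict[str, tuple[list[str], float]]:
    """Map reads on contigs at ≥ ``min_identity`` % identity over
    ≥ ``min_read_cov`` % of the read; each read counts toward at most one
    contig (its best-scoring one, ties by accession). Returns
    {contig_id: (mapped read ids, breadth %)}."""
    if not contigs:
        return {}
    if params is None:
        params = AlignmentParams(min_identity=min_identity,
                                 min_query_coverage=min_read_cov,
                                 max_evalue_proxy=float("inf"))
    tier = ReferenceTier(name="backbones", priority=1, entries=[
        ReferenceEntry(accession=c.id, organism="", lineage=EMPTY_LINEAGE, seq=c)
        for c in contigs
    ])
    index = build_index(tier, params)
    lengths = {c.id: len(c.seq) for c in contigs}
    mapped: dict[str, list[str]] = {c.id: [] for c in contigs}
    intervals: dict[str, list[tuple[int, int]]] = {c.id: [] for c in contigs}
    for read in reads:
        hits = [h for h in search(read, index, params)
                if h.percent_identity >= min_identity and h.query_coverage >= min_read_cov]
        if not hits:
            continue
        best = hits[0]  # search is sorted by (score desc, evalue asc, accession asc)
        mapped[best.subject_accession].append(read.id)
        lo, hi = sorted((best.subject_start, best.subject_end))
        intervals[best.subject_accession].append((lo - 1, hi))
    out: dict[str, tuple[list[str], float]] = {}
    for cid in mapped:
        covered = 0
        last_end = -1
        for lo, hi in sorted(intervals[cid]):
            lo = max(lo, last_end)
            if hi > lo:
                covered += hi - lo
                last_end = hi
            last_end = max(last_end, hi)
        out[cid] = (mapped[cid], 100.0 * covered / lengths[cid])
    return out


def detect_transmission(infant_viral_contigs: Sequence[tuple[SequenceRecord, TaxonomyLineage]],
                        mother_reads: Sequence[SequenceRecord],
                        min_len_nt: int = BACKBONE_LENGTH_GATE, min_reads: int = 1,
                        min_identity: float = 99.0, min_read_cov: float = 90.0,
                        pair_id: str = "pair",
                        params: AlignmentParams | None = None) -> TransmissionReport:
    """Flag infant viral contigs (> ``min_len_nt`` bp) that recruit at least
    ``min_reads`` stringently mapping mother reads as shared genotypes."""
    backbones = [(rec, lin) for rec, lin in infant_viral_contigs
                 if lin.is_viral() and len(rec.seq) > min_len_nt]
    if not backbones:
        return TransmissionReport(pair_id=pair_id, rows=[], shared_contigs=[],
                                  reason=f"no viral contigs > {min_len_nt} nt")
    mapping = map_reads_stringent(mother_reads, [rec for rec, _ in backbones],
                                  min_identity=min_identity,
                                  min_read_cov=min_read_cov, params=params)
    rows = []
    shared = []
    for rec, lin in backbones:
        read_ids, breadth = mapping.get(rec.id, ([], 0.0))
        rows.append(ContigMapping(contig_id=rec.id, length=len(rec.seq),
                                  lineage=lin, mapped_reads=len(read_ids),
                                  breadth=breadth))
        if len(read_ids) >= min_reads:
            shared.append(rec.id)
    return TransmissionReport(pair_id=pair_id, rows=rows, shared_contigs=shared)


def cross_pair_control(pairs: Sequence[tuple[Sequence[SequenceRecord],
                                             Sequence[tuple[SequenceRecord, TaxonomyLineage]]]],
                       min_len_nt: int = BACKBONE_LENGTH_GATE,
                       min_identity: float = 99.0, min_read_cov: float = 90.0,
                       params: AlignmentParams | None = None) -> pd.DataFrame:
    """Full mother × infant matrix of stringently mapped read totals.

    ``pairs[i]`` is (mother_reads, infant_viral_contigs) for pair i. The
    diagonal holds matched pairs; off-diagonal entries diagnose contamination
    (they are zero for clean, unrelated pairs)."""
    if len(pairs) < 2:
        raise ValueError("cross-pair control requires ≥ 2 mother-infant pairs")
    n = len(pairs)
    matrix = pd.DataFrame(0, index=[f"mother_{i}" for i in range(n)],
                          columns=[f"infant_{j}" for j in range(n)])
    for j, (_, contig_set) in enumerate(pairs):
        backbones = [rec for rec, lin in contig_set
                     if lin.is_viral() and len(rec.seq) > min_len_nt]
        for i, (mother_reads, _) in enumerate(pairs):
            mapping = map_reads_stringent(mother_reads, backbones,
                                          min_identity=min_identity,
                                          min_read_cov=min_read_cov, params=params)
            matrix.iloc[i, j] = sum(len(ids) for ids, _ in mapping.values())
    return matrix
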