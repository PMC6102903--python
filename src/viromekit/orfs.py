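"""Six-frame open reading frame calling.

A stop-to-stop scanner over both strands of a contig: within each stop-bounded
segment the first start codon (ATG/GTG/TTG) opens the longest possible ORF for
that stop. This is a deterministic stand-in for a trained gene finder with the
same downstream contract (coordinates, strand, translation). Codons containing
N never match start or stop codons and translate to X; the initiator codon is
translated as M.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .align import HitRecord
from .seqio import SequenceRecord, reverse_complement
from .taxonomy import EMPTY_LINEAGE, TaxonomyLineage

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# standard genetic code
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

HYPOTHETICAL = "hypothetical protein"


def translate(codons: str, initiator: bool = False) -> str:
    """Translate an in-frame nucleotide string; unknown/ambiguous codons → X."""
    aas = []
    for i in range(0, len(codons) - len(codons) % 3, 3):
        codon = codons[i:i + 3]
        if initiator and i == 0 and codon in START_CODONS:
            aas.append("M")
        else:
            aas.append(_CODON_TABLE.get(codon, "X"))
    return "".join(aas)


@dataclass
class ORF:
    """A called open reading frame; start/end are 0-based half-open on the
    forward strand and include the stop codon, so (end − start) is divisible
    by 3 and len(aa_seq) == (end − start)/3 − 1."""

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    aa_seq: str
    product: str = HYPOTHETICAL
    lineage: TaxonomyLineage = EMPTY_LINEAGE
    best_hit: HitRecord | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a whole number of codons")
        if len(self.aa_seq) != (self.end - self.start) // 3 - 1:
            raise ValueError("aa_seq length inconsistent with coordinates")

    @property
    def id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"

    def record(self) -> SequenceRecord:
        return SequenceRecord(self.id.replace("(", "").replace(")", ""), self.aa_seq)


def _scan_strand(seq: str, n: int, contig_id: str, strand: str,
                 min_len_aa: int) -> Iterator[ORF]:
    """Scan the three frames of one strand (seq is already oriented 5'→3')."""
    for frame in range(3):
        segment_start = frame  # first codon offset after the previous stop
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                yield from _emit(seq, segment_start, i + 3, contig_id, strand,
                                 frame, n, min_len_aa)
                segment_start = i + 3
            i += 3
        # trailing segment has no stop codon: not a complete ORF, skipped


def _emit(seq: str, seg_start: int, seg_end: int, contig_id: str, strand: str,
          frame: int, n: int, min_len_aa: int) -> Iterator[ORF]:
    """Emit the longest ORF in a stop-bounded segment (first start codon)."""
    for i in range(seg_start, seg_end - 3, 3):
        if seq[i:i + 3] in START_CODONS:
            aa = translate(seq[i:seg_end], initiator=True)[:-1]
            if len(aa) < min_len_aa:
                return
            if strand == "+":
                start, end = i, seg_end
            else:  # map back to forward-strand coordinates
                start, end = n - seg_end, n - i
            yield ORF(contig_id=contig_id, start=start, end=end, strand=strand,
                      frame=frame, aa_seq=aa)
            return


def find_orfs(contig: SequenceRecord, min_len_aa: int = 60) -> list[ORF]:
    """All maximal complete ORFs on both strands, sorted by (start, end, strand).

    Start codons: ATG/GTG/TTG; standard genetic code; only stop-terminated ORFs
    are reported; ORFs shorter than ``min_len_aa`` amino acids are discarded.
    """
    seq = contig.seq.upper().replace("U", "T")
    n = len(seq)
    orfs = list(_scan_strand(seq, n, contig.id, "+", min_len_aa))
    orfs.extend(_scan_strand(reverse_complement(seq), n, contig.id, "-", min_len_aa))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs
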