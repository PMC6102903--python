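"""Seed-and-extend local homology search.

One deterministic hit-provider contract backs every analysis: exact k-mer
seeds against an indexed reference tier, gapped extension on a subject window
around each seed cluster, explicit score/length/identity/e-value-proxy
filters, and a fixed tie-break (score desc, e-value asc, accession asc) so
identical inputs always yield byte-identical hit lists. Externally computed
hit tables in a 14-column outfmt-6 dialect can be imported under the same
contract.

The e-value proxy is an explicit stand-in, not a Karlin–Altschul statistic:
``evalue = N_db × query_len × 2^(−score/2)``. All thresholds are parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import Align

from .seqio import SequenceRecord, reverse_complement
from .taxonomy import ReferenceTier


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and filtering knobs for the search engine.

    A gap of length L costs ``gap_open + (L−1)·gap_extend``. ``band`` pads the
    subject window extracted around each seed cluster before extension.
    """

    k: int = 11
    match: int = 1
    mismatch: int = -1
    gap_open: int = -5
    gap_extend: int = -2
    min_identity: float = 0.0
    min_query_coverage: float = 0.0
    min_alignment_length: int = 30
    max_evalue_proxy: float = 1e-5
    band: int = 15

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ValueError("word size k must be ≥ 4")
        if self.match <= 0 or self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("match must be positive; penalties must be ≤ 0")

    @staticmethod
    def protein_defaults(**overrides) -> "AlignmentParams":
        # match = +2: on the fixed 2^(−score/2) e-value scale a residue match
        # carries one bit, far below its information content in a 20-letter
        # alphabet; doubling the match score lets short translated-read
        # alignments (~40 aa) reach significance without touching the scale.
        base = dict(k=4, match=2, min_alignment_length=30)
        base.update(overrides)
        return AlignmentParams(**base)


@dataclass
class HitRecord:
    """One local-alignment hit linking a query to a reference entry.

    Coordinates are 1-based inclusive; ``query_start ≤ query_end`` always
    (minus-strand nucleotide hits are flagged by subject_start > subject_end,
    as in tabular BLAST output).
    """

    query_id: str
    subject_accession: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    score: float
    evalue_proxy: float
    query_coverage: float
    tier_name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"percent identity out of range: {self.percent_identity}")
        if self.query_end < self.query_start:
            raise ValueError("query_end must be ≥ query_start")
        if self.evalue_proxy < 0:
            raise ValueError("evalue_proxy must be nonnegative")

    def sort_key(self):
        return (-self.score, self.evalue_proxy, self.subject_accession,
                self.query_start, self.subject_start)


@dataclass
class KmerIndex:
    """Exact k-mer positions over the plus strand of every tier entry."""

    k: int
    kind: str
    tier_name: str
    entries: list  # ReferenceEntry
    positions: dict[str, list[tuple[int, int]]]  # k-mer -> [(entry index, offset)]
    total_residues: int


def build_index(tier: ReferenceTier, params: AlignmentParams | None = None) -> KmerIndex:
    """Index every k-mer of every entry (plus strand only; the minus strand is
    searched via the reverse-complemented query). Entries shorter than k are
    skipped with a warning."""
    if params is None:
        params = AlignmentParams() if tier.kind == "nucleotide" else AlignmentParams.protein_defaults()
    k = params.k
    positions: dict[str, list[tuple[int, int]]] = {}
    total = 0
    kept_entries = []
    for entry in tier.entries:
        seq = entry.seq.seq.upper()
        if len(seq) < k:
            warnings.warn(f"tier {tier.name}: entry {entry.accession} shorter than k={k}; skipped")
            continue
        idx = len(kept_entries)
        kept_entries.append(entry)
        total += len(seq)
        for off in range(len(seq) - k + 1):
            positions.setdefault(seq[off:off + k], []).append((idx, off))
    return KmerIndex(k=k, kind=tier.kind, tier_name=tier.name,
                     entries=kept_entries, positions=positions, total_residues=total)


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def evalue_proxy(score: float, n_db: int, query_len: int) -> float:
    return n_db * query_len * 2.0 ** (-0.5 * score)


def _score_floor(params: AlignmentParams, n_db: int, query_len: int) -> float:
    """Smallest score a hit can have and still pass the filters.

    Combines the e-value bound with a provable identity/coverage bound: at
    identity ≥ I% every column scores at least I/100·match −
    (1 − I/100)·max(|mismatch|, |gap_open|), and coverage ≥ C% forces
    ≥ C/100·query_len columns. Windows scoring below the floor (checked with
    the cheap score-only pass) are discarded without a traceback.
    """
    import math
    floor = 1.0
    if params.max_evalue_proxy != float("inf") and n_db * query_len > 0:
        floor = max(floor,
                    2.0 * math.log2(max(n_db * query_len, 1) / params.max_evalue_proxy))
    if params.min_identity > 0 and params.min_query_coverage > 0:
        worst = max(-params.mismatch, -params.gap_open)
        per_column = (params.min_identity / 100.0) * params.match \
            - (1.0 - params.min_identity / 100.0) * worst
        if per_column > 0:
            floor = max(floor,
                        per_column * (params.min_query_coverage / 100.0) * query_len)
    return floor


def _seed_windows(qseq: str, index: KmerIndex, pad: int) -> dict[int, list[tuple[int, int, int]]]:
    """Merged subject windows per entry, derived from exact k-mer seeds.

    Each seed at query offset i / subject offset s projects the subject window
    ``[s − i − pad, s + (qlen − i) + pad]``; overlapping windows are merged so
    each (entry, window) pair is extended at most once. Windows carry their
    supporting seed count.
    """
    k = index.k
    qlen = len(qseq)
    raw: dict[int, list[tuple[int, int]]] = {}
    lookup = index.positions
    for i in range(qlen - k + 1):
        for entry_idx, off in lookup.get(qseq[i:i + k], ()):
            lo = off - i - pad
            hi = off + (qlen - i) + pad
            raw.setdefault(entry_idx, []).append((lo, hi))
    merged: dict[int, list[tuple[int, int, int]]] = {}
    for entry_idx, wins in raw.items():
        wins.sort()
        out = [[wins[0][0], wins[0][1], 1]]
        for lo, hi in wins[1:]:
            if lo <= out[-1][1]:
                out[-1][1] = max(out[-1][1], hi)
                out[-1][2] += 1
            else:
                out.append([lo, hi, 1])
        merged[entry_idx] = [(max(0, lo), hi, n) for lo, hi, n in out]
    return merged


def _min_seeds(params: AlignmentParams, qlen: int, k: int) -> int:
    """Provable lower bound on the exact k-mer seeds any passing hit contains.

    With identity ≥ I% a hit has at most nm = ⌊c·(1 − I/100)⌋ non-match
    columns (c bounded above via the identity itself), and with query
    coverage ≥ C% it spans ≥ C/100·qlen query positions, so its longest
    exact run has ≥ (C/100·qlen − nm)/(nm + 1) bases → run − k + 1 seeds.
    Windows with fewer seeds cannot hold a passing hit and are skipped
    before any alignment. Inactive (returns 1) unless both thresholds are set.
    """
    if params.min_identity <= 0 or params.min_query_coverage <= 0:
        return 1
    frac_bad = 1.0 - params.min_identity / 100.0
    if frac_bad >= 0.5:
        return 1
    c_upper = qlen / (1.0 - frac_bad)
    nm = int(c_upper * frac_bad)
    span = params.min_query_coverage / 100.0 * qlen
    longest_run = int((span - nm) / (nm + 1))
    return max(1, longest_run - k + 1)


def _alignment_stats(alignment) -> tuple[int, int, int, int, int, int, int, int]:
    """(matches, mismatches, gap_columns, gap_opens, qstart, qend, sstart, send)
    from a Biopython local alignment; coordinates 0-based half-open on the
    aligned (target=subject, query) strings."""
    sub_blocks, q_blocks = alignment.aligned
    target = alignment.target
    query = alignment.query
    matches = mismatches = 0
    gap_cols = gap_opens = 0
    prev_send = prev_qend = None
    for (ss, se), (qs, qe) in zip(sub_blocks, q_blocks):
        if prev_send is not None:
            dq = qs - prev_qend
            ds = ss - prev_send
            if dq:
                gap_cols += dq
                gap_opens += 1
            if ds:
                gap_cols += ds
                gap_opens += 1
        for a, b in zip(target[ss:se], query[qs:qe]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
        prev_send, prev_qend = se, qe
    qstart = int(q_blocks[0][0])
    qend = int(q_blocks[-1][1])
    sstart = int(sub_blocks[0][0])
    send = int(sub_blocks[-1][1])
    return matches, mismatches, gap_cols, gap_opens, qstart, qend, sstart, send


def search(query: SequenceRecord, index: KmerIndex,
           params: AlignmentParams | None = None) -> list[HitRecord]:
    """All passing local hits of ``query`` against an indexed tier.

    Nucleotide queries are searched on both strands (the minus strand via the
    reverse-complemented query; coordinates are reported on the forward
    query, with subject_start > subject_end marking minus-strand hits).
    Identity is 100 × matches / alignment columns, gap columns counting as
    non-matches. Hits failing min_alignment_length, min_identity or
    max_evalue_proxy are discarded; output is sorted by
    (score desc, e-value asc, accession asc).
    """
    if params is None:
        params = AlignmentParams() if index.kind == "nucleotide" else AlignmentParams.protein_defaults()
    qseq = query.seq.upper()
    qlen = len(qseq)
    if qlen < index.k:
        return []
    aligner = _aligner(params)
    floor = _score_floor(params, index.total_residues, qlen)
    # For short queries the pad guarantees the full optimal local alignment
    # through any seed fits the window; for long queries (contig-vs-contig)
    # it is capped, bounding extension like a conventional band.
    pad = qlen + params.band if qlen <= 256 else 256 + params.band
    strands = ["+"]
    if index.kind == "nucleotide":
        strands.append("-")

    min_seeds = _min_seeds(params, qlen, index.k)
    hits: list[HitRecord] = []
    seen: set[tuple] = set()
    for strand in strands:
        sseq_query = qseq if strand == "+" else reverse_complement(qseq)
        windows = _seed_windows(sseq_query, index, pad)
        for entry_idx, wins in windows.items():
            entry = index.entries[entry_idx]
            subject = entry.seq.seq.upper()
            for lo, hi, n_seeds in wins:
                window = subject[lo:hi]
                if len(window) < index.k or n_seeds < min_seeds:
                    continue
                # seed-sparse windows get a cheap score-only pass before any
                # traceback; seed-dense ones are almost surely real hits and
                # go straight to the single traceback DP
                dense = n_seeds >= max(min_seeds, (qlen - index.k + 1) // 3, 2)
                if not dense and aligner.score(window, sseq_query) < max(floor, 1.0):
                    continue
                alignment = next(iter(aligner.align(window, sseq_query)))
                score = alignment.score
                if score < max(floor, 1.0):
                    continue
                (matches, mismatches, gap_cols, gap_opens,
                 aqs, aqe, ass_, ase) = _alignment_stats(alignment)
                columns = matches + mismatches + gap_cols
                if columns < params.min_alignment_length:
                    continue
                identity = 100.0 * matches / columns if columns else 0.0
                if identity < params.min_identity:
                    continue
                if params.min_query_coverage and \
                        100.0 * (aqe - aqs) / qlen < params.min_query_coverage:
                    continue
                ev = evalue_proxy(score, index.total_residues, qlen)
                if ev > params.max_evalue_proxy:
                    continue
                # map to 1-based forward-query / subject coordinates
                if strand == "+":
                    q_start, q_end = aqs + 1, aqe
                    s_start, s_end = lo + ass_ + 1, lo + ase
                else:
                    q_start, q_end = qlen - aqe + 1, qlen - aqs
                    s_start, s_end = lo + ase, lo + ass_ + 1
                key = (entry.accession, q_start, q_end, s_start, s_end)
                if key in seen:
                    continue
                seen.add(key)
                coverage = 100.0 * (q_end - q_start + 1) / qlen
                hits.append(HitRecord(
                    query_id=query.id,
                    subject_accession=entry.accession,
                    percent_identity=identity,
                    alignment_length=columns,
                    mismatches=mismatches,
                    gap_opens=gap_opens,
                    query_start=q_start,
                    query_end=q_end,
                    subject_start=s_start,
                    subject_end=s_end,
                    score=float(score),
                    evalue_proxy=ev,
                    query_coverage=coverage,
                    tier_name=index.tier_name,
                ))
    hits.sort(key=HitRecord.sort_key)
    return hits


_HIT_COLUMNS = [
    "query_id", "subject_accession", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "query_start", "query_end",
    "subject_start", "subject_end", "evalue_proxy", "score",
    "query_coverage", "tier_name",
]


def export_hits(hits: Iterable[HitRecord], path) -> None:
    """Write hits as a 14-column outfmt-6 dialect table (the 12 standard
    columns plus query_coverage and tier_name)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(v) for v in (
                h.query_id, h.subject_accession,
                f"{h.percent_identity:.3f}", h.alignment_length, h.mismatches,
                h.gap_opens, h.query_start, h.query_end, h.subject_start,
                h.subject_end, f"{h.evalue_proxy:.3e}", f"{h.score:.1f}",
                f"{h.query_coverage:.3f}", h.tier_name,
            )) + "\n")


def import_hits(path, tier_name: str = "",
                query_lengths: dict[str, int] | None = None) -> list[HitRecord]:
    """Load hits from an outfmt-6 dialect table (12–14 columns).

    query_coverage is recomputed from ``query_lengths`` when the column is
    absent. Malformed rows raise ValueError naming the line number.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected ≥12 columns, got {len(fields)}")
            try:
                identity = float(fields[2])
                aln_len = int(fields[3])
                mism = int(fields[4])
                gaps = int(fields[5])
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                ev = float(fields[10])
                score = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if len(fields) >= 13 and fields[12] != "":
                coverage = float(fields[12])
            elif query_lengths and fields[0] in query_lengths:
                coverage = 100.0 * (qe - qs + 1) / query_lengths[fields[0]]
            else:
                coverage = 0.0
            row_tier = fields[13] if len(fields) >= 14 else tier_name
            try:
                hits.append(HitRecord(
                    query_id=fields[0], subject_accession=fields[1],
                    percent_identity=identity, alignment_length=aln_len,
                    mismatches=mism, gap_opens=gaps,
                    query_start=qs, query_end=qe,
                    subject_start=ss, subject_end=se,
                    score=score, evalue_proxy=ev,
                    query_coverage=coverage, tier_name=row_tier or tier_name,
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return hits
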