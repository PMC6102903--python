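"""Best-hit functional category profiling.

Reads (via six-frame translated search) or ORF proteins are assigned the
category of their best passing hit in a user-mounted functional database —
COG-style functional categories, carbohydrate-active enzyme families, or
metabolic pathways. Entries mapped to k categories contribute 1/k to each, so
category totals are conserved. Databases are supplied as a protein FASTA plus
a category TSV; none are bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignmentParams, KmerIndex, build_index, search
from .orfs import translate
from .seqio import SequenceRecord, header_product, parse_refseq_header, read_fasta, reverse_complement
from .taxonomy import EMPTY_LINEAGE, ReferenceEntry, ReferenceTier, TaxonomyLineage

SCHEMES = ("cog-category", "cazy-family", "pathway")


@dataclass
class FunctionalDatabase:
    scheme: str
    entries: list[ReferenceEntry]
    category_map: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        for e in self.entries:
            cats = self.category_map.get(e.accession)
            if not cats or any(not c for c in cats):
                raise ValueError(f"entry {e.accession} lacks a non-empty category")

    def tier(self) -> ReferenceTier:
        return ReferenceTier(name=f"functional-{self.scheme}", priority=1,
                             entries=self.entries, kind="protein")


def load_functional_database(scheme: str, fasta_path, categories_path) -> FunctionalDatabase:
    """Database layout: entries.faa + categories.tsv (accession, category[,category...])."""
    df = pd.read_csv(categories_path, sep="\t", dtype=str).fillna("")
    if "accession" not in df.columns or "category" not in df.columns:
        raise ValueError(f"{categories_path}: need 'accession' and 'category' columns")
    category_map = {
        row.accession: tuple(c.strip() for c in row.category.split(",") if c.strip())
        for row in df.itertuples(index=False)
    }
    entries = []
    for rec in read_fasta(fasta_path):
        accession, organism = parse_refseq_header(rec.description or rec.id)
        entries.append(ReferenceEntry(accession=accession, organism=organism,
                                      lineage=EMPTY_LINEAGE, seq=rec, kind="protein",
                                      product=header_product(rec.description or rec.id)))
    return FunctionalDatabase(scheme=scheme, entries=entries, category_map=category_map)


@dataclass
class FunctionalProfile:
    scheme: str
    counts: dict[str, float]
    total_assigned: int
    unassigned: int

    @property
    def relative_abundance(self) -> dict[str, float]:
        if self.total_assigned == 0:
            return {}
        return {c: 100.0 * n / self.total_assigned for c, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        ra = self.relative_abundance
        rows = [{"category": c, "weight": round(n, 4),
                 "relative_abundance_pct": round(ra[c], 4)}
                for c, n in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))]
        return pd.DataFrame(rows, columns=["category", "weight", "relative_abundance_pct"])


def six_frame_frames(seq: str) -> list[str]:
    """The six conceptual translations of a nucleotide sequence."""
    seq = seq.upper().replace("U", "T")
    rc = reverse_complement(seq)
    return [translate(s[f:]) for s in (seq, rc) for f in range(3)]


def _best_protein_hit(query: SequenceRecord, index: KmerIndex,
                      params: AlignmentParams, nucleotide: bool):
    if nucleotide:
        best = None
        for i, frame in enumerate(six_frame_frames(query.seq)):
            if len(frame) < index.k:
                continue
            hits = search(SequenceRecord(f"{query.id}.f{i}", frame), index, params)
            if hits and (best is None or hits[0].sort_key() < best.sort_key()):
                best = hits[0]
        return best
    hits = search(query, index, params)
    return hits[0] if hits else None


def functional_profile(queries: Sequence[SequenceRecord], db: FunctionalDatabase,
                       params: AlignmentParams | None = None,
                       translated: bool = True) -> FunctionalProfile:
    """Assign each query its best passing hit's category (fractional for
    multi-category entries). ``translated=True`` treats queries as nucleotide
    reads and searches all six frames; otherwise queries are proteins."""
    if not db.entries:
        raise ValueError("functional database is empty")
    if params is None:
        params = AlignmentParams.protein_defaults()
    index = build_index(db.tier(), params)
    counts: dict[str, float] = {}
    assigned = 0
    for query in queries:
        best = _best_protein_hit(query, index, params, nucleotide=translated)
        if best is None:
            continue
        assigned += 1
        cats = db.category_map[best.subject_accession]
        for c in cats:
            counts[c] = counts.get(c, 0.0) + 1.0 / len(cats)
    return FunctionalProfile(scheme=db.scheme, counts=counts,
                             total_assigned=assigned,
                             unassigned=len(queries) - assigned)


def gene_database_abundance(reads: Sequence[SequenceRecord],
                            user_gene_db: ReferenceTier,
                            params: AlignmentParams | None = None) -> pd.DataFrame:
    """Per-gene best-hit read counts against a user-mounted nucleotide gene
    database: (gene, read_count, relative_abundance_pct, lineage)."""
    if params is None:
        params = AlignmentParams()
    index = build_index(user_gene_db, params)
    counts: dict[str, int] = {}
    for read in reads:
        hits = search(read, index, params)
        if hits:
            gene = hits[0].subject_accession
            counts[gene] = counts.get(gene, 0) + 1
    total = sum(counts.values())
    lineages = {e.accession: e.lineage for e in user_gene_db.entries}
    rows = [{
        "gene": gene,
        "read_count": n,
        "relative_abundance_pct": round(100.0 * n / total, 4),
        "lineage": lineages.get(gene, EMPTY_LINEAGE).pretty(),
    } for gene, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["gene", "read_count",
                                       "relative_abundance_pct", "lineage"])
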