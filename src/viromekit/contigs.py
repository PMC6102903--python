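"""Majority-vote taxonomic classification of assembled contigs.

Each ORF on a contig is classified through the same tiered cascade as reads
(at the protein level); the contig inherits the most frequent taxonomy among
its classified ORFs, counted at viral-family / cellular-genus level. Only
contigs longer than 5000 nt are eligible (strict gate). Ties are broken by
summed best-hit score, then lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .align import AlignmentParams, KmerIndex
from .orfs import HYPOTHETICAL, ORF, find_orfs
from .reads import _classify_one, build_tier_indexes
from .seqio import SequenceRecord
from .taxonomy import EMPTY_LINEAGE, ReferenceTier, TaxonomyLineage

CONTIG_LENGTH_GATE = 5000


@dataclass
class ContigClassification:
    contig_id: str
    length: int
    lineage: TaxonomyLineage = EMPTY_LINEAGE
    votes: dict[str, int] = field(default_factory=dict)
    n_orfs: int = 0
    support_fraction: float = 0.0
    reason: str = ""

    @property
    def classified(self) -> bool:
        return not self.lineage.is_empty()


def classify_orfs(orfs: Sequence[ORF], tiers: Sequence[ReferenceTier],
                  params: AlignmentParams | None = None,
                  indexes: Sequence[KmerIndex] | None = None) -> list[ORF]:
    """Assign each ORF a lineage via the iterative tiered protein search.

    The ORF's product string becomes the best hit's annotation text when a
    passing hit exists, else "hypothetical protein". Returns the same ORF
    objects, annotated in place.
    """
    tiers = sorted(tiers, key=lambda t: t.priority)
    if params is None:
        params = AlignmentParams.protein_defaults()
    if indexes is None:
        indexes = build_tier_indexes(tiers, params)
    lineage_maps = [{e.accession: e.lineage for e in t.entries} for t in tiers]
    product_maps = [{e.accession: (e.product or e.organism) for e in t.entries} for t in tiers]
    tier_by_name = {t.name: i for i, t in enumerate(tiers)}
    for orf in orfs:
        result = _classify_one(orf.record(), indexes, lineage_maps, params)
        if result.classified:
            orf.lineage = result.lineage
            orf.best_hit = result.best_hit
            tier_idx = tier_by_name[result.tier_name]
            product = product_maps[tier_idx].get(result.best_hit.subject_accession, "")
            orf.product = product or HYPOTHETICAL
        else:
            orf.lineage = EMPTY_LINEAGE
            orf.best_hit = None
            orf.product = HYPOTHETICAL
    return list(orfs)


def _vote_label(lineage: TaxonomyLineage) -> str:
    """Votes are counted at viral-family / cellular-genus level, prefixed by
    realm so e.g. a viral family and a bacterial genus never collide."""
    return f"{lineage.realm or 'unknown'}|{lineage.label(lineage.vote_rank())}"


def classify_contig(contig: SequenceRecord, classified_orfs: Sequence[ORF],
                    min_len_nt: int = CONTIG_LENGTH_GATE) -> ContigClassification:
    """Majority vote over classified ORFs; contigs not longer than
    ``min_len_nt`` are returned unclassified with reason "below-length-gate".

    Winner = label with most votes; ties broken by summed best-hit score, then
    lexicographic label. Species is recorded when the winning group's most
    frequent species is consistent with the winning family/genus.
    """
    length = len(contig.seq)
    n_orfs = len(classified_orfs)
    if length <= min_len_nt:
        return ContigClassification(contig.id, length, n_orfs=n_orfs,
                                    reason="below-length-gate")
    votes: dict[str, int] = {}
    scores: dict[str, float] = {}
    members: dict[str, list[ORF]] = {}
    for orf in classified_orfs:
        if orf.lineage.is_empty():
            continue
        label = _vote_label(orf.lineage)
        votes[label] = votes.get(label, 0) + 1
        scores[label] = scores.get(label, 0.0) + (orf.best_hit.score if orf.best_hit else 0.0)
        members.setdefault(label, []).append(orf)
    if not votes:
        return ContigClassification(contig.id, length, n_orfs=n_orfs,
                                    reason="no-classified-orfs")
    winner = min(votes, key=lambda lab: (-votes[lab], -scores[lab], lab))
    group = members[winner]
    realm = group[0].lineage.realm
    rank = group[0].lineage.vote_rank()
    upper = getattr(group[0].lineage, rank)
    # species: plurality within the winning group, ties lexicographic
    species_votes: dict[str, int] = {}
    for orf in group:
        if orf.lineage.species:
            species_votes[orf.lineage.species] = species_votes.get(orf.lineage.species, 0) + 1
    species = ""
    if species_votes:
        species = min(species_votes, key=lambda s: (-species_votes[s], s))
    lineage = TaxonomyLineage(
        realm=realm,
        family=upper if rank == "family" else _common(group, "family"),
        genus=upper if rank == "genus" else _common(group, "genus"),
        species=species,
    )
    classifiable = sum(votes.values())
    return ContigClassification(
        contig_id=contig.id, length=length, lineage=lineage, votes=votes,
        n_orfs=n_orfs, support_fraction=votes[winner] / classifiable,
    )


def _common(group: Sequence[ORF], rank: str) -> str:
    values = {getattr(o.lineage, rank) for o in group if getattr(o.lineage, rank)}
    return values.pop() if len(values) == 1 else ""


def annotate_contigs(contigs: Sequence[SequenceRecord], tiers: Sequence[ReferenceTier],
                     params: AlignmentParams | None = None, min_len_aa: int = 60,
                     min_len_nt: int = CONTIG_LENGTH_GATE,
                     ) -> list[tuple[SequenceRecord, ContigClassification, list[ORF]]]:
    """End-to-end contig path: call ORFs, classify them, vote per contig."""
    if params is None:
        params = AlignmentParams.protein_defaults()
    tiers = sorted(tiers, key=lambda t: t.priority)
    indexes = build_tier_indexes(tiers, params)
    out = []
    for contig in contigs:
        orfs = find_orfs(contig, min_len_aa=min_len_aa)
        classify_orfs(orfs, tiers, params, indexes=indexes)
        out.append((contig, classify_contig(contig, orfs, min_len_nt=min_len_nt), orfs))
    return out


def hypothetical_fraction(orfs: Sequence[ORF]) -> tuple[int, int]:
    """(number of ORFs, number whose product is "hypothetical protein")."""
    n = len(orfs)
    return n, sum(1 for o in orfs if o.product == HYPOTHETICAL)


def classification_table(classifications: Sequence[ContigClassification]) -> pd.DataFrame:
    rows = []
    for c in classifications:
        rows.append({
            "contig_id": c.contig_id,
            "length": c.length,
            "lineage": c.lineage.pretty() if c.classified else "Unclassified",
            "votes": ";".join(f"{k}={v}" for k, v in sorted(c.votes.items())),
            "n_orfs": c.n_orfs,
            "support_fraction": round(c.support_fraction, 4),
            "reason": c.reason,
        })
    return pd.DataFrame(rows, columns=["contig_id", "length", "lineage", "votes",
                                       "n_orfs", "support_fraction", "reason"])
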