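"""Read-level quality control, subsampling and iterative tiered classification.

Reads are classified against an ordered cascade of reference tiers (default:
viral, archaeal, bacterial, whole). The highest-priority tier with at least
one passing hit wins and lower tiers are never consulted for that read — this
deliberately biases assignment toward viruses so prophage-derived reads inside
bacterial genomes are still counted as viral. Viral assignments report family
and species; cellular assignments report genus and species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentParams, HitRecord, KmerIndex, build_index, search
from .seqio import SequenceRecord
from .taxonomy import EMPTY_LINEAGE, RANKS, ReferenceTier, TaxonomyLineage, check_tier_order


@dataclass
class ReadClassification:
    read_id: str
    tier_name: str = "unclassified"
    lineage: TaxonomyLineage = EMPTY_LINEAGE
    best_hit: HitRecord | None = None

    def __post_init__(self) -> None:
        unclassified = self.tier_name == "unclassified"
        if unclassified != self.lineage.is_empty() or unclassified != (self.best_hit is None):
            raise ValueError(
                f"read {self.read_id}: tier/lineage/hit must be all set or all empty"
            )

    @property
    def classified(self) -> bool:
        return self.tier_name != "unclassified"


@dataclass
class TaxonomicProfile:
    """Taxon counts and relative abundances (% of classified reads) at one rank.

    Unclassified reads are reported alongside but never enter the denominator.
    """

    rank: str
    counts: dict[str, int]
    unclassified_count: int = 0

    @property
    def total_classified(self) -> int:
        return sum(self.counts.values())

    @property
    def relative_abundance(self) -> dict[str, float]:
        total = self.total_classified
        if total == 0:
            return {}
        return {taxon: 100.0 * n / total for taxon, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        ra = self.relative_abundance
        rows = [{"taxon": t, "count": n, "relative_abundance_pct": ra[t]}
                for t, n in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))]
        return pd.DataFrame(rows, columns=["taxon", "count", "relative_abundance_pct"])


def quality_filter(reads: Iterable[SequenceRecord], min_len: int = 50,
                   min_mean_q: float = 20.0) -> tuple[list[SequenceRecord], int]:
    """Keep reads with length ≥ min_len and mean Phred ≥ min_mean_q (both
    inclusive); returns (kept, n_removed). Reads without qualities pass the
    length check only, with a warning."""
    kept: list[SequenceRecord] = []
    removed = 0
    warned = False
    for read in reads:
        if len(read.seq) < min_len:
            removed += 1
            continue
        if read.quals is None:
            if not warned:
                warnings.warn("reads without qualities: applying length filter only")
                warned = True
            kept.append(read)
            continue
        if float(np.mean(read.quals)) >= min_mean_q:
            kept.append(read)
        else:
            removed += 1
    return kept, removed


def subsample(reads: Sequence[SequenceRecord], n: int, seed: int) -> list[SequenceRecord]:
    """Uniform sample of n reads without replacement, preserving pool order;
    deterministic for a fixed seed."""
    if n > len(reads):
        raise ValueError(f"cannot subsample {n} reads from a pool of {len(reads)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    idx.sort()
    return [reads[i] for i in idx]


def build_tier_indexes(tiers: Sequence[ReferenceTier],
                       params: AlignmentParams | None = None) -> list[KmerIndex]:
    check_tier_order(tiers)
    ordered = sorted(tiers, key=lambda t: t.priority)
    return [build_index(t, params) for t in ordered]


def _classify_one(query: SequenceRecord, indexes: Sequence[KmerIndex],
                  lineage_maps: Sequence[dict[str, TaxonomyLineage]],
                  params: AlignmentParams | None) -> ReadClassification:
    for index, lineages in zip(indexes, lineage_maps):
        hits = search(query, index, params)
        if hits:
            best = hits[0]
            lineage = lineages.get(best.subject_accession, EMPTY_LINEAGE)
            if lineage.is_empty():
                continue
            return ReadClassification(query.id, index.tier_name, lineage, best)
    return ReadClassification(query.id)


def classify_reads(reads: Iterable[SequenceRecord], tiers: Sequence[ReferenceTier],
                   params: AlignmentParams | None = None,
                   indexes: Sequence[KmerIndex] | None = None) -> list[ReadClassification]:
    """Iterative priority classification: each read is searched tier by tier in
    priority order and assigned the best passing hit of the first tier that
    yields one; lower tiers are never consulted for that read. Prebuilt
    ``indexes`` may be passed to amortize indexing across calls."""
    tiers = sorted(tiers, key=lambda t: t.priority)
    if not tiers:
        raise ValueError("at least one reference tier is required")
    if indexes is None:
        indexes = build_tier_indexes(tiers, params)
    lineage_maps = [
        {e.accession: e.lineage for e in t.entries} for t in tiers
    ]
    return [_classify_one(r, indexes, lineage_maps, params) for r in reads]


def profile(classifications: Iterable[ReadClassification], rank: str) -> TaxonomicProfile:
    """Aggregate classified reads into taxon counts at ``rank``; relative
    abundance is over classified reads only."""
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    counts: dict[str, int] = {}
    unclassified = 0
    for c in classifications:
        if not c.classified:
            unclassified += 1
            continue
        label = c.lineage.label(rank)
        counts[label] = counts.get(label, 0) + 1
    return TaxonomicProfile(rank=rank, counts=counts, unclassified_count=unclassified)


def viral_profile(classifications: Iterable[ReadClassification], rank: str = "species") -> TaxonomicProfile:
    """Profile restricted to reads classified in the viral realm."""
    viral = [c for c in classifications if c.classified and c.lineage.is_viral()]
    nonviral = sum(1 for c in classifications if not (c.classified and c.lineage.is_viral()))
    out = profile(viral, rank)
    out.unclassified_count = nonviral
    return out


def shared_taxa(profile_a: TaxonomicProfile, profile_b: TaxonomicProfile,
                min_abundance_pct: float = 0.01) -> list[str]:
    """Taxa with relative abundance strictly above ``min_abundance_pct`` in
    BOTH profiles, sorted lexicographically. The default 0.01% threshold is the
    shared-taxon rule used for mother–infant virome comparison."""
    if profile_a.rank != profile_b.rank:
        raise ValueError(f"profiles at different ranks: {profile_a.rank} vs {profile_b.rank}")
    ra, rb = profile_a.relative_abundance, profile_b.relative_abundance
    return sorted(t for t in ra.keys() & rb.keys()
                  if ra[t] > min_abundance_pct and rb[t] > min_abundance_pct)


def depth_adequacy(n_filtered_reads: int, target_depth: int) -> float:
    """Percent of the target sequencing depth achieved, to one decimal
    (e.g. 46,269 quality-filtered reads against a 1,000,000-read target → 4.6)."""
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    return round(100.0 * n_filtered_reads / target_depth, 1)


def write_profile(p: TaxonomicProfile, path) -> None:
    p.to_frame().to_csv(path, sep="\t", index=False)


def write_assignments(classifications: Iterable[ReadClassification], path) -> None:
    rows = []
    for c in classifications:
        rows.append({
            "read_id": c.read_id,
            "tier": c.tier_name,
            "realm": c.lineage.realm,
            "family": c.lineage.family,
            "genus": c.lineage.genus,
            "species": c.lineage.species,
            "subject": c.best_hit.subject_accession if c.best_hit else "",
            "identity_pct": f"{c.best_hit.percent_identity:.3f}" if c.best_hit else "",
        })
    pd.DataFrame(rows, columns=["read_id", "tier", "realm", "family", "genus",
                                "species", "subject", "identity_pct"]) \
        .to_csv(path, sep="\t", index=False)
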