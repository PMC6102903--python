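"""Cross-sample contaminant ("kitome") detection and read scrubbing.

Reagent or lab contaminants show up as near-identical contigs recurring in
*unrelated* samples. Contigs sharing ≥ 99% identity over ≥ 90% of the shorter
contig are single-linkage clustered across samples; reads mapping to a
contaminant contig at ≥ 99% identity are then scrubbed from every dataset.
The inclusive 99% threshold deliberately admits the ~1% substitution error of
short-read sequencing, so reads truly derived from the contaminant backbone
are removed while anything more divergent is kept. Related samples (e.g. a
mother–infant pair) must not be cross-checked against each other: genuinely
shared biology would be flagged as contamination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .align import AlignmentParams, build_index, search
from .reads import depth_adequacy, quality_filter
from .seqio import SequenceRecord
from .taxonomy import ReferenceEntry, ReferenceTier, EMPTY_LINEAGE


@dataclass
class ContaminantCluster:
    members: list[tuple[str, str]]            # (sample_id, contig_id)
    representative: str                        # longest member contig id
    pairwise_identity: float                   # min % identity among linked pairs
    n_samples: int


def _contig_tier(contigs: Iterable[tuple[str, SequenceRecord]]) -> ReferenceTier:
    entries = [
        ReferenceEntry(accession=f"{sample}::{rec.id}", organism=sample,
                       lineage=EMPTY_LINEAGE, seq=rec)
        for sample, rec in contigs
    ]
    return ReferenceTier(name="contigs", priority=1, entries=entries)


def find_shared_contigs(contig_sets: Mapping[str, Sequence[SequenceRecord]],
                        min_identity: float = 99.0, min_cov: float = 90.0,
                        min_samples: int = 2,
                        params: AlignmentParams | None = None) -> list[ContaminantCluster]:
    """Single-linkage clusters of near-identical contigs across samples.

    Two contigs from different samples are linked when a hit of identity
    ≥ ``min_identity`` covers ≥ ``min_cov`` % of the shorter contig. Clusters
    spanning ≥ ``min_samples`` distinct samples are returned, sorted by
    n_samples (desc) then representative id.
    """
    if len(contig_sets) < 2:
        raise ValueError("cross-sample contaminant detection requires ≥ 2 samples")
    if params is None:
        # the coverage floor doubles as a seed-count prefilter: pairs without
        # the long exact runs a ≥99%/≥90% link implies are never aligned
        params = AlignmentParams(min_identity=min_identity,
                                 min_query_coverage=min_cov)
    labeled = [(s, rec) for s, recs in sorted(contig_sets.items()) for rec in recs]
    lengths = {f"{s}::{rec.id}": len(rec.seq) for s, rec in labeled}
    records = {f"{s}::{rec.id}": rec for s, rec in labeled}
    indexes = {
        key: build_index(_contig_tier([(key.split("::", 1)[0], rec)]), params)
        for key, rec in records.items()
    }

    parent: dict[str, str] = {key: key for key in lengths}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    keys = sorted(lengths)
    link_identity: dict[frozenset, float] = {}
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            if a.split("::", 1)[0] == b.split("::", 1)[0]:
                continue  # never link contigs within one sample
            if find(a) == find(b):
                continue  # already in the same single-linkage component
            # query with the shorter contig so query coverage = span/shorter
            qkey, skey = (a, b) if lengths[a] <= lengths[b] else (b, a)
            query = SequenceRecord(qkey.replace("::", "__"), records[qkey].seq)
            for hit in search(query, indexes[skey], params):
                if hit.percent_identity < min_identity:
                    continue
                if hit.query_coverage < min_cov:
                    continue
                union(a, b)
                pair = frozenset((a, b))
                link_identity[pair] = max(link_identity.get(pair, 0.0),
                                          hit.percent_identity)
                break

    groups: dict[str, list[str]] = {}
    for key in lengths:
        groups.setdefault(find(key), []).append(key)

    clusters: list[ContaminantCluster] = []
    for keys in groups.values():
        if len(keys) < 2:
            continue
        samples = {k.split("::", 1)[0] for k in keys}
        if len(samples) < min_samples:
            continue
        members = sorted(tuple(k.split("::", 1)) for k in keys)
        rep = max(keys, key=lambda k: (lengths[k], k)).split("::", 1)[1]
        idents = [v for pair, v in link_identity.items() if pair <= set(keys)]
        clusters.append(ContaminantCluster(
            members=members, representative=rep,
            pairwise_identity=min(idents) if idents else 0.0,
            n_samples=len(samples),
        ))
    clusters.sort(key=lambda c: (-c.n_samples, c.representative))
    return clusters


def scrub_reads(reads: Sequence[SequenceRecord],
                contaminant_contigs: Sequence[SequenceRecord],
                min_identity: float = 99.0, min_read_cov: float = 90.0,
                params: AlignmentParams | None = None,
                ) -> tuple[list[SequenceRecord], list[SequenceRecord], int]:
    """Remove reads mapping to any contaminant contig at ≥ ``min_identity`` %
    identity over ≥ ``min_read_cov`` % of the read. Returns (kept, removed,
    removed_count); kept + removed always partitions the input."""
    if not contaminant_contigs:
        return list(reads), [], 0
    if params is None:
        params = AlignmentParams(min_identity=min_identity,
                                 min_query_coverage=min_read_cov,
                                 max_evalue_proxy=float("inf"))
    tier = _contig_tier(("contaminant", c) for c in contaminant_contigs)
    index = build_index(tier, params)
    kept: list[SequenceRecord] = []
    removed: list[SequenceRecord] = []
    for read in reads:
        hits = search(read, index, params)
        if any(h.percent_identity >= min_identity and h.query_coverage >= min_read_cov
               for h in hits):
            removed.append(read)
        else:
            kept.append(read)
    return kept, removed, len(removed)


@dataclass
class ShamReport:
    n_input_reads: int
    n_filtered_reads: int
    depth_adequacy_pct: float
    n_contigs: int
    verdict: str  # "background" | "non-background"


def sham_report(reads: Sequence[SequenceRecord], target_depth: int,
                assembler_adapter: Callable[[Sequence[SequenceRecord]], Sequence[SequenceRecord]],
                min_contig_len: int = 1000, min_len: int = 50,
                min_mean_q: float = 20.0) -> ShamReport:
    """Account for a sham (no-sample) control: quality-filter, report the
    fraction of the target sequencing depth reached, attempt assembly, and
    call the run "background" iff no contig of reportable length emerges."""
    filtered, _ = quality_filter(reads, min_len=min_len, min_mean_q=min_mean_q)
    contigs = [c for c in assembler_adapter(filtered) if len(c.seq) >= min_contig_len] \
        if filtered else []
    return ShamReport(
        n_input_reads=len(reads),
        n_filtered_reads=len(filtered),
        depth_adequacy_pct=depth_adequacy(len(filtered), target_depth),
        n_contigs=len(contigs),
        verdict="background" if not contigs else "non-background",
    )


def cluster_table(clusters: Sequence[ContaminantCluster]) -> pd.DataFrame:
    rows = [{
        "representative": c.representative,
        "n_samples": c.n_samples,
        "n_members": len(c.members),
        "min_pairwise_identity": round(c.pairwise_identity, 3),
        "members": ";".join(f"{s}:{cid}" for s, cid in c.members),
    } for c in clusters]
    return pd.DataFrame(rows, columns=["representative", "n_samples", "n_members",
                                       "min_pairwise_identity", "members"])
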