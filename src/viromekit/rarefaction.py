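"""Rarefaction of viral taxon richness versus sequencing depth.

Read-based curves count distinct viral taxa among classified reads at each
subsampled depth; contig-based curves count taxa owning at least one contig
longer than 5000 nt after (mock or real) assembly of the subsample. A
logarithmic trend y = a·ln(x) + b fitted to a curve yields the marginal value
of deeper sequencing: the relative richness gain from doubling the read count
at depth x is 100·a·ln2 / (a·ln x + b).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentParams
from .contigs import annotate_contigs
from .reads import classify_reads, ReadClassification
from .seqio import SequenceRecord
from .taxonomy import ReferenceTier


@dataclass
class RarefactionCurve:
    depths: list[int]
    taxa_counts: list[float]                 # mean over replicates per depth
    mode: str                                # "read" | "contig"
    n_replicates: int = 1
    per_replicate: list[list[int]] = field(default_factory=list)
    fit: tuple[float, float] | None = None   # (a, b) of y = a·ln x + b
    full_pool_taxa: int = 0

    def __post_init__(self) -> None:
        if len(self.depths) != len(self.taxa_counts):
            raise ValueError("depths and taxa_counts must have equal length")
        if any(d2 <= d1 for d1, d2 in zip(self.depths, self.depths[1:])):
            raise ValueError("depths must be strictly increasing")
        if any(t < 0 for t in self.taxa_counts):
            raise ValueError("taxa counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, depth in enumerate(self.depths):
            reps = self.per_replicate[i] if self.per_replicate else [self.taxa_counts[i]]
            for r, taxa in enumerate(reps):
                rows.append({"depth": depth, "replicate": r, "taxa_count": taxa})
        return pd.DataFrame(rows, columns=["depth", "replicate", "taxa_count"])


def _distinct_viral_taxa(classifications: Sequence[ReadClassification],
                         rank: str) -> set[str]:
    return {c.lineage.label(rank) for c in classifications
            if c.classified and c.lineage.is_viral()}


def read_rarefaction(reads: Sequence[SequenceRecord], depths: Sequence[int],
                     seed: int, tiers: Sequence[ReferenceTier] | None = None,
                     n_replicates: int = 3, rank: str = "species",
                     params: AlignmentParams | None = None,
                     classifications: Sequence[ReadClassification] | None = None,
                     ) -> RarefactionCurve:
    """Distinct viral taxa (default: species) among classified reads at each
    subsampled depth, averaged over seeded replicates.

    Classification of a read does not depend on which other reads were drawn,
    so the full pool is classified once and each subsample counts taxa among
    its own reads — identical results to classify-after-subsample. Pass
    ``classifications`` (aligned with ``reads``) to reuse an existing full-pool
    classification across many curves.
    """
    depths = sorted(depths)
    if not depths or depths[0] <= 0:
        raise ValueError("depths must be positive")
    if depths[-1] > len(reads):
        raise ValueError(f"max depth {depths[-1]} exceeds pool size {len(reads)}")
    if classifications is None:
        if tiers is None:
            raise ValueError("either tiers or precomputed classifications required")
        classifications = classify_reads(reads, tiers, params)
    elif len(classifications) != len(reads):
        raise ValueError("classifications must align with the read pool")
    taxa_of = [(_distinct_viral_taxa([c], rank) or None) for c in classifications]
    labels = [next(iter(t)) if t else None for t in taxa_of]

    per_replicate: list[list[int]] = []
    means: list[float] = []
    for depth in depths:
        reps = []
        for r in range(n_replicates):
            rng = np.random.default_rng(seed + r)
            idx = rng.choice(len(reads), size=depth, replace=False)
            reps.append(len({labels[i] for i in idx if labels[i] is not None}))
        per_replicate.append(reps)
        means.append(float(np.mean(reps)))
    full = len({lab for lab in labels if lab is not None})
    return RarefactionCurve(depths=list(depths), taxa_counts=means, mode="read",
                            n_replicates=n_replicates, per_replicate=per_replicate,
                            full_pool_taxa=full)


def contig_rarefaction(reads: Sequence[SequenceRecord], depths: Sequence[int],
                       seed: int,
                       assembler_adapter: Callable[[Sequence[SequenceRecord]], Sequence[SequenceRecord]],
                       tiers: Sequence[ReferenceTier], min_len_nt: int = 5000,
                       rank: str = "species", n_replicates: int = 1,
                       params: AlignmentParams | None = None) -> RarefactionCurve:
    """Distinct viral taxa owning ≥ 1 classified contig > ``min_len_nt`` after
    assembling each subsampled read set."""
    from .reads import subsample

    depths = sorted(depths)
    if not depths or depths[0] <= 0:
        raise ValueError("depths must be positive")
    if depths[-1] > len(reads):
        raise ValueError(f"max depth {depths[-1]} exceeds pool size {len(reads)}")

    def taxa_at(depth: int, rep: int) -> int:
        sub = subsample(reads, depth, seed + rep)
        try:
            contigs = [c for c in assembler_adapter(sub) if len(c.seq) > min_len_nt]
        except Exception as exc:
            raise RuntimeError(f"assembler failed at depth {depth}: {exc}") from exc
        if not contigs:
            return 0
        annotated = annotate_contigs(contigs, tiers, params, min_len_nt=min_len_nt)
        taxa = {cls.lineage.label(rank) for _, cls, _ in annotated
                if cls.classified and cls.lineage.is_viral()}
        return len(taxa)

    per_replicate = [[taxa_at(d, r) for r in range(n_replicates)] for d in depths]
    means = [float(np.mean(reps)) for reps in per_replicate]
    return RarefactionCurve(depths=list(depths), taxa_counts=means, mode="contig",
                            n_replicates=n_replicates, per_replicate=per_replicate,
                            full_pool_taxa=int(max(means)) if means else 0)


def fit_log_trend(curve: RarefactionCurve) -> tuple[float, float, float]:
    """Least-squares fit of y = a·ln(x) + b to (depth, taxa_count); returns
    (a, b, r_squared). Noiseless logarithmic data is recovered exactly."""
    if len(curve.depths) < 3:
        raise ValueError("log-trend fit needs ≥ 3 depths")
    x = np.log(np.asarray(curve.depths, dtype=float))
    y = np.asarray(curve.taxa_counts, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all depths equal; fit is singular")
    result = stats.linregress(x, y)
    curve.fit = (float(result.slope), float(result.intercept))
    return float(result.slope), float(result.intercept), float(result.rvalue ** 2)


def doubling_gain(fit: tuple[float, float], x: float) -> float:
    """Relative richness increase (%) from doubling the read count at depth x
    under y = a·ln(x) + b: 100·a·ln2 / (a·ln x + b)."""
    a, b = fit
    predicted = a * np.log(x) + b
    if predicted <= 0:
        raise ValueError(f"predicted richness at depth {x} is nonpositive ({predicted:.3g})")
    return float(100.0 * a * np.log(2.0) / predicted)


def coverage_fraction(curve: RarefactionCurve, depth: int) -> float:
    """Percent of the full-pool taxon richness recovered at ``depth``."""
    if curve.full_pool_taxa == 0:
        raise ValueError("full-pool taxon count is zero")
    if depth not in curve.depths:
        raise ValueError(f"depth {depth} not in curve depths {curve.depths}")
    return 100.0 * curve.taxa_counts[curve.depths.index(depth)] / curve.full_pool_taxa


def average_curve(curves: Sequence[RarefactionCurve]) -> RarefactionCurve:
    """Arithmetic mean of per-sample curves at each shared depth."""
    if not curves:
        raise ValueError("no curves to average")
    shared = sorted(set.intersection(*(set(c.depths) for c in curves)))
    if not shared:
        raise ValueError("curves share no depths")
    means = [float(np.mean([c.taxa_counts[c.depths.index(d)] for c in curves]))
             for d in shared]
    return RarefactionCurve(depths=shared, taxa_counts=means, mode=curves[0].mode,
                            n_replicates=1,
                            full_pool_taxa=int(round(float(np.mean([c.full_pool_taxa for c in curves])))))


class MockAssembler:
    """Synthetic coverage-gated stand-in for a metagenomic assembler.

    Built from the truth genomes of a simulated community: reads are assigned
    to their most plausible source genome by sampled exact k-mer matching, and
    a genome is "assembled" (emitted in full as one contig) iff its estimated
    mean coverage reaches ``min_coverage``. This reproduces the
    coverage-dependent emergence of contigs with depth; it is not an assembly
    algorithm, and real assemblers plug in through the same callable contract
    (reads in, contigs out).
    """

    def __init__(self, genomes: Sequence[SequenceRecord], min_coverage: float = 5.0,
                 k: int = 21, stride: int = 8, min_kmer_hits: int = 2):
        self.genomes = list(genomes)
        self.min_coverage = min_coverage
        self.k = k
        self.stride = stride
        self.min_kmer_hits = min_kmer_hits
        self._index: dict[str, set[int]] = {}
        for gi, g in enumerate(self.genomes):
            seq = g.seq.upper()
            rc = None
            for off in range(0, len(seq) - k + 1):
                self._index.setdefault(seq[off:off + k], set()).add(gi)

    def __call__(self, reads: Sequence[SequenceRecord]) -> list[SequenceRecord]:
        from .seqio import reverse_complement

        assigned_bases = np.zeros(len(self.genomes))
        for read in reads:
            votes = np.zeros(len(self.genomes), dtype=int)
            for seq in (read.seq.upper(), reverse_complement(read.seq.upper())):
                for off in range(0, len(seq) - self.k + 1, self.stride):
                    for gi in self._index.get(seq[off:off + self.k], ()):
                        votes[gi] += 1
            if votes.max() >= self.min_kmer_hits:
                assigned_bases[int(votes.argmax())] += len(read.seq)
        contigs = []
        for gi, genome in enumerate(self.genomes):
            if assigned_bases[gi] / len(genome.seq) >= self.min_coverage:
                contigs.append(SequenceRecord(f"{genome.id}_contig", genome.seq,
                                              f"{genome.id}_contig mock assembly"))
        return contigs
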