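"""Seeded generators for every input the toolkit consumes.

These emulate the statistical structure the analyses assume: multi-genome
communities with skewed (log-normal) abundances, phage genomes with modular
gene architecture, short reads with ~1% i.i.d. substitution error (the error
rate of Illumina sequencing that motivates the 99% mapping threshold),
mother–infant pairs sharing near-identical phage genotypes, and cross-sample
contaminant spiking. Every generator is a pure function of its seed and spec;
truth tables are exhaustive. The error model is substitution-only — indels
can be layered on later without changing any contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hosts import PHAGE_MODULES, PhageMarkerSet
from .seqio import SequenceRecord, reverse_complement
from .taxonomy import (DEFAULT_TIER_ORDER, EMPTY_LINEAGE, ReferenceEntry,
                       ReferenceTier, TaxonomyLineage)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(*seed_parts) -> np.random.Generator:
    return np.random.default_rng(list(seed_parts))


def make_genome(length: int, gc: float, seed) -> SequenceRecord:
    """Random i.i.d. genome with P(G) + P(C) = gc; deterministic per seed."""
    if length < 1:
        raise ValueError("genome length must be ≥ 1")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(BASES, size=length, p=p).tobytes().decode()
    return SequenceRecord(f"genome_{seed if isinstance(seed, int) else 'x'}", seq)


def mutate(seq: str, divergence: float, seed) -> str:
    """Substitute each base independently with probability ``divergence``
    (always to a different base)."""
    if divergence == 0:
        return seq
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < divergence)
    for i in hit:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


# Back-translation tables. Leucine and serine always use TTA / TCA, whose
# reverse complements are stop codons, so coding regions are dense in
# minus-strand stops and spurious reverse ORFs stay short. Other amino acids
# rotate deterministically through synonymous codons by position, so two
# proteins sharing a few residues by chance do not share long nucleotide
# k-mers.
_AA_SYNONYMS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"], "L": ["TTA"],
    "M": ["ATG"], "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG"], "S": ["TCA"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "*": ["TAA"],
}
_AA_CODON = {aa: codons[0] for aa, codons in _AA_SYNONYMS.items()}

_MODULE_PRODUCTS = {
    "replication": ["DNA polymerase", "replicative helicase", "primase",
                    "single-stranded DNA-binding protein"],
    "packaging": ["terminase large subunit", "terminase small subunit",
                  "portal protein", "HNH endonuclease"],
    "head": ["major capsid protein", "prohead protease", "head scaffolding protein",
             "head-tail connector protein"],
    "tail": ["tail fiber protein", "tape measure protein", "major tail protein",
             "baseplate protein"],
    "lysis": ["endolysin", "holin", "spanin"],
    "lysogeny": ["integrase", "CI repressor", "excisionase"],
}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def back_translate(aa_seq: str) -> str:
    return "".join(_AA_SYNONYMS[a][i % len(_AA_SYNONYMS[a])]
                   for i, a in enumerate(aa_seq))


def make_protein(aa_len: int, rng: np.random.Generator) -> str:
    body = "".join(rng.choice(list(AA_ALPHABET), size=aa_len - 1))
    return "M" + body


def make_marker_set(n_per_module: int = 2, aa_len: int = 120, seed: int = 0,
                    modules: Sequence[str] = PHAGE_MODULES) -> PhageMarkerSet:
    """Synthetic phage-module marker proteins with realistic product names."""
    rng = np.random.default_rng(seed)
    markers: list[ReferenceEntry] = []
    module_map: dict[str, str] = {}
    for module in modules:
        products = _MODULE_PRODUCTS[module]
        for i in range(n_per_module):
            acc = f"MRK_{module.upper()}_{i:02d}"
            aa = make_protein(aa_len, rng)
            product = products[i % len(products)]
            rec = SequenceRecord(acc, aa, f"{acc} {product} [synthetic phage]")
            markers.append(ReferenceEntry(accession=acc, organism="synthetic phage",
                                          lineage=EMPTY_LINEAGE, seq=rec,
                                          kind="protein", product=product))
            module_map[acc] = module
    return PhageMarkerSet(markers, module_map)


def make_phage(n_genes_per_module: int, marker_set: PhageMarkerSet, seed: int,
               modules: Sequence[str] = ("replication", "packaging", "head",
                                         "tail", "lysis"),
               n_filler: int = 0, filler_aa_len: int = 100,
               label: str = "phage") -> tuple[SequenceRecord, pd.DataFrame]:
    """A phage genome with module-ordered genes plus optional unannotatable
    filler genes, and an exhaustive truth table of gene coordinates.

    Genes are marker back-translations ("ATG" start, "TAA" stop) separated by
    random intergenic spacers ending in a gene-frame stop, so each designed
    gene is a maximal complete ORF on the plus strand (minus-strand stops are
    guaranteed by the TTA/TCA codon choices of the back-translation).
    """
    rng = np.random.default_rng(seed)
    by_module: dict[str, list] = {}
    for e in marker_set.markers:
        by_module.setdefault(marker_set.module_map[e.accession], []).append(e)

    parts: list[str] = []
    rows: list[dict] = []
    pos = 0

    def add_spacer() -> None:
        nonlocal pos
        spacer = "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 25))))
        chunk = spacer + "TAA"  # in-frame stop directly upstream of the next start
        parts.append(chunk)
        pos += len(chunk)

    def add_gene(gene_id: str, module: str, aa: str, product: str) -> None:
        nonlocal pos
        add_spacer()
        nt = back_translate(aa) + _AA_CODON["*"]
        rows.append({"gene_id": gene_id, "module": module, "product": product,
                     "start": pos, "end": pos + len(nt), "strand": "+", "aa": aa})
        parts.append(nt)
        pos += len(nt)

    for module in modules:
        pool = by_module.get(module, [])
        if not pool:
            raise ValueError(f"marker set has no markers for module {module!r}")
        for g in range(n_genes_per_module):
            marker = pool[g % len(pool)]
            add_gene(f"{label}_{module}_{g}", module, marker.seq.seq, marker.product)
    for f in range(n_filler):
        aa = make_protein(filler_aa_len, rng)
        add_gene(f"{label}_filler_{f}", "filler", aa, "")
    add_spacer()
    genome = SequenceRecord(label, "".join(parts))
    truth = pd.DataFrame(rows, columns=["gene_id", "module", "product",
                                        "start", "end", "strand", "aa"])
    return genome, truth


@dataclass(frozen=True)
class GenomeSpec:
    label: str
    lineage: TaxonomyLineage
    length: int = 8000
    gc: float = 0.45


@dataclass
class CommunitySpec:
    """Study conditions for a simulated shotgun community.

    Abundances default to log-normal weights (σ = 1); reads are 150 nt with
    1% i.i.d. substitution error and constant Q30 qualities.
    """

    genomes: list[GenomeSpec]
    abundances: list[float] | None = None
    read_length: int = 150
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.abundances is not None:
            if len(self.abundances) != len(self.genomes):
                raise ValueError("one abundance weight per genome required")
            if any(w <= 0 for w in self.abundances):
                raise ValueError("abundance weights must be positive")
        for g in self.genomes:
            if g.length < self.read_length:
                raise ValueError(f"genome {g.label} shorter than the read length")


def build_genomes(spec: CommunitySpec) -> dict[str, SequenceRecord]:
    out = {}
    for i, g in enumerate(spec.genomes):
        rec = make_genome(g.length, g.gc, [spec.seed, 7, i])
        out[g.label] = SequenceRecord(g.label, rec.seq)
    return out


def community_weights(spec: CommunitySpec) -> np.ndarray:
    if spec.abundances is not None:
        w = np.asarray(spec.abundances, dtype=float)
    else:
        w = _rng(spec.seed, 11).lognormal(mean=0.0, sigma=1.0, size=len(spec.genomes))
    return w / w.sum()


def _draw_reads(genomes: Mapping[str, str], weights: np.ndarray,
                read_length: int, error_rate: float, n_reads: int,
                rng: np.random.Generator, id_prefix: str = "read",
                ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    labels = list(genomes)
    sources = rng.choice(len(labels), size=n_reads, p=weights)
    reads: list[SequenceRecord] = []
    rows: list[dict] = []
    quals = [30] * read_length
    for i, src in enumerate(sources):
        label = labels[src]
        seq = genomes[label]
        pos = int(rng.integers(0, len(seq) - read_length + 1))
        fragment = seq[pos:pos + read_length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            fragment = reverse_complement(fragment)
        n_errors = 0
        if error_rate > 0:
            arr = np.frombuffer(fragment.encode(), dtype=np.uint8).copy()
            hit = np.flatnonzero(rng.random(read_length) < error_rate)
            for j in hit:
                arr[j] = rng.choice(BASES[BASES != arr[j]])
            n_errors = hit.size
            fragment = arr.tobytes().decode()
        rid = f"{id_prefix}_{i:07d}"
        reads.append(SequenceRecord(rid, fragment, rid, list(quals)))
        rows.append({"read_id": rid, "source": label, "position": pos,
                     "strand": strand, "n_errors": n_errors})
    truth = pd.DataFrame(rows, columns=["read_id", "source", "position",
                                        "strand", "n_errors"])
    return reads, truth


def draw_reads(genomes: Mapping[str, SequenceRecord], n_reads: int, seed: int,
               weights: Sequence[float] | None = None, read_length: int = 150,
               error_rate: float = 0.01, id_prefix: str = "read",
               ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Draw reads from explicit genome sequences (e.g. gene-structured phages
    from make_phage) rather than from a CommunitySpec."""
    labels = sorted(genomes)
    if weights is None:
        w = np.ones(len(labels))
    else:
        w = np.asarray(weights, dtype=float)
    seqs = {label: genomes[label].seq for label in labels}
    return _draw_reads(seqs, w / w.sum(), read_length, error_rate, n_reads,
                       _rng(seed, 37), id_prefix)


def simulate_reads(spec: CommunitySpec, n_reads: int, seed: int,
                   id_prefix: str = "read") -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Draw reads from a community: sources by abundance weight, positions
    uniform, strands fair, substitutions i.i.d. at the spec's error rate.
    Returns (reads, exhaustive truth table)."""
    if n_reads < 1:
        raise ValueError("n_reads must be ≥ 1")
    genomes = {k: v.seq for k, v in build_genomes(spec).items()}
    weights = community_weights(spec)
    rng = _rng(seed, 13)
    return _draw_reads(genomes, weights, spec.read_length, spec.error_rate,
                       n_reads, rng, id_prefix)


def make_reference_tiers(genomes: Mapping[str, SequenceRecord],
                         lineages: Mapping[str, TaxonomyLineage],
                         tile: int = 1600, step: int = 1400,
                         ) -> tuple[list[ReferenceTier], dict[str, TaxonomyLineage]]:
    """Miniature four-tier reference stack from labeled genomes.

    Genomes are tiled into overlapping entries (the ``tile − step`` overlap
    exceeds the read length, so any read lies wholly inside some entry) with
    RefSeq-style headers. Realms
    map to tiers viral(1)/archaeal(2)/bacterial(3); the whole tier(4) holds
    every entry, mirroring a comprehensive database consulted last.
    """
    realm_entries: dict[str, list[ReferenceEntry]] = {
        "viral": [], "archaeal": [], "bacterial": [], "whole": []}
    taxonomy: dict[str, TaxonomyLineage] = {}
    for label in sorted(genomes):
        seq = genomes[label].seq
        lineage = lineages[label]
        n = len(seq)
        if n <= tile:
            starts = [0]
        else:
            starts = list(range(0, n - tile + 1, step))
            if starts[-1] != n - tile:
                starts.append(n - tile)
        organism = lineage.species or label
        for i, s in enumerate(starts):
            acc = f"{label.upper()}_{i:04d}"
            rec = SequenceRecord(acc, seq[s:s + tile],
                                 f"{acc} genomic segment {i} [{organism}]")
            entry = ReferenceEntry(accession=acc, organism=organism,
                                   lineage=lineage, seq=rec,
                                   product=f"genomic segment {i}")
            taxonomy[acc] = lineage
            if lineage.realm in realm_entries:
                realm_entries[lineage.realm].append(entry)
            realm_entries["whole"].append(entry)
    tiers = [
        ReferenceTier(name=name, priority=p + 1, entries=realm_entries[name])
        for p, name in enumerate(("viral", "archaeal", "bacterial", "whole"))
    ]
    return tiers, taxonomy


def make_protein_tiers(gene_sets: Mapping[str, tuple[pd.DataFrame, TaxonomyLineage]],
                       ) -> list[ReferenceTier]:
    """Protein reference tiers from phage/organism gene truth tables
    (as produced by make_phage); filler genes are excluded so they stay
    unannotatable."""
    realm_entries: dict[str, list[ReferenceEntry]] = {
        "viral": [], "archaeal": [], "bacterial": [], "whole": []}
    for label in sorted(gene_sets):
        truth, lineage = gene_sets[label]
        organism = lineage.species or label
        for row in truth.itertuples(index=False):
            if row.module == "filler":
                continue
            acc = f"{label.upper()}_{row.gene_id.upper()}"
            rec = SequenceRecord(acc, row.aa, f"{acc} {row.product} [{organism}]")
            entry = ReferenceEntry(accession=acc, organism=organism,
                                   lineage=lineage, seq=rec, kind="protein",
                                   product=row.product)
            if lineage.realm in realm_entries:
                realm_entries[lineage.realm].append(entry)
            realm_entries["whole"].append(entry)
    return [
        ReferenceTier(name=name, priority=p + 1, entries=realm_entries[name],
                      kind="protein")
        for p, name in enumerate(("viral", "archaeal", "bacterial", "whole"))
    ]


@dataclass
class PairSpec:
    """Mother–infant fixture design: which community phages are shared, and
    the per-base identity between the mother and infant copies of shared
    genomes (divergence is split evenly between the two copies)."""

    shared_phages: tuple[str, ...]
    infant_only: tuple[str, ...] = ()
    mother_only: tuple[str, ...] = ()
    shared_identity: float = 99.5

    def __post_init__(self) -> None:
        if not (0 < self.shared_identity <= 100):
            raise ValueError("shared_identity is a percentage in (0, 100]")


@dataclass
class PairFixture:
    mother_reads: list[SequenceRecord]
    infant_reads: list[SequenceRecord]
    infant_contigs: list[tuple[SequenceRecord, TaxonomyLineage]]
    shared_contig_ids: list[str]
    mother_truth: pd.DataFrame
    infant_truth: pd.DataFrame


def make_pair(pair_spec: PairSpec, community_spec: CommunitySpec,
              n_mother: int, n_infant: int, seed: int) -> PairFixture:
    """Generate a mother–infant sample pair sharing near-identical phage
    genotypes. Shared genomes are copied into both samples with total
    divergence 100 − shared_identity (half applied to each copy); infant
    contigs are emitted directly from the infant genotypes."""
    labels = {g.label for g in community_spec.genomes}
    wanted = set(pair_spec.shared_phages) | set(pair_spec.infant_only) | set(pair_spec.mother_only)
    missing = wanted - labels
    if missing:
        raise ValueError(f"pair spec references unknown genomes: {sorted(missing)}")
    ancestors = build_genomes(community_spec)
    lineage_of = {g.label: g.lineage for g in community_spec.genomes}
    weights = dict(zip([g.label for g in community_spec.genomes],
                       community_weights(community_spec)))
    half = (100.0 - pair_spec.shared_identity) / 200.0  # per-copy divergence

    mother_genomes: dict[str, str] = {}
    infant_genomes: dict[str, str] = {}
    for i, label in enumerate(sorted(pair_spec.shared_phages)):
        mother_genomes[label] = mutate(ancestors[label].seq, half, [seed, 3, i])
        infant_genomes[label] = mutate(ancestors[label].seq, half, [seed, 5, i])
    for label in pair_spec.mother_only:
        mother_genomes[label] = ancestors[label].seq
    for label in pair_spec.infant_only:
        infant_genomes[label] = ancestors[label].seq

    def sample(genomes: dict[str, str], n: int, sub_seed: int, prefix: str):
        w = np.array([weights[l] for l in genomes], dtype=float)
        return _draw_reads(genomes, w / w.sum(), community_spec.read_length,
                           community_spec.error_rate, n, _rng(seed, sub_seed), prefix)

    mother_reads, mother_truth = sample(mother_genomes, n_mother, 17, "mother")
    infant_reads, infant_truth = sample(infant_genomes, n_infant, 19, "infant")
    infant_contigs = [
        (SequenceRecord(f"{label}_contig", seq), lineage_of[label])
        for label, seq in sorted(infant_genomes.items())
    ]
    shared = [f"{label}_contig" for label in sorted(pair_spec.shared_phages)]
    return PairFixture(mother_reads=mother_reads, infant_reads=infant_reads,
                       infant_contigs=infant_contigs, shared_contig_ids=shared,
                       mother_truth=mother_truth, infant_truth=infant_truth)


def spike_contaminant(sample_read_sets: Mapping[str, Sequence[SequenceRecord]],
                      contaminant_genome: SequenceRecord, fraction: float,
                      seed: int, divergence: float = 0.005,
                      read_length: int = 150,
                      ) -> tuple[dict[str, list[SequenceRecord]],
                                 dict[str, list[str]],
                                 dict[str, SequenceRecord]]:
    """Spike each sample with contaminant-derived reads.

    Each sample receives floor(fraction × its read count) reads drawn from its
    own copy of the contaminant (copies diverge pairwise by ``divergence``,
    half applied per copy — emulating a reagent contaminant re-assembled
    slightly differently per dataset). Returns (spiked sets, truth read ids
    per sample, per-sample contaminant contigs)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    spiked: dict[str, list[SequenceRecord]] = {}
    truth: dict[str, list[str]] = {}
    copies: dict[str, SequenceRecord] = {}
    for i, sample in enumerate(sorted(sample_read_sets)):
        reads = list(sample_read_sets[sample])
        copy_seq = mutate(contaminant_genome.seq, divergence / 2.0, [seed, 23, i])
        copy = SequenceRecord(f"{sample}_contaminant_contig", copy_seq)
        copies[sample] = copy
        n_spike = int(fraction * len(reads))
        rng = _rng(seed, 29, i)
        contam_reads, _ = _draw_reads({sample: copy_seq}, np.array([1.0]),
                                      read_length, 0.0, max(n_spike, 1), rng,
                                      f"{sample}_contam")
        contam_reads = contam_reads[:n_spike]
        spiked[sample] = reads + contam_reads
        truth[sample] = [r.id for r in contam_reads]
    return spiked, truth, copies
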