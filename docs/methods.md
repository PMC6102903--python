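# Methods

This note documents the models and procedures implemented in viromekit, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Tiered read classification

Reads are classified by local homology search against an ordered list of
reference *tiers* — by default viral (priority 1), archaeal (2), bacterial
(3) and a comprehensive "whole" tier (4). For each read the tiers are
consulted in priority order; the first tier producing at least one passing
hit assigns the read that tier's best hit's lineage, and lower tiers are
never consulted for that read. This ordering is a deliberate bias: a
prophage region present in both a viral and a bacterial reference is counted
as viral, which maximizes sensitivity for virome profiling at the cost of
over-calling integrated elements. Read-level data cannot distinguish free
virions from prophages; that caveat applies to any read-based virome
profile.

A "passing hit" is one that survives the engine filters (below). Viral
assignments are reported at family + species, cellular assignments at
genus + species; unknown ranks print as `Unclassified__<nearest known>`.
Relative abundances are computed over classified reads only, with the
unclassified count always reported alongside, so the denominators are
explicit.

Contig ORFs are classified the same way at the protein level, and a contig
longer than the 5000-nt gate (strict inequality) takes the most frequent
taxonomy among its classified ORFs. Votes are counted at viral-family /
cellular-genus rank — the same ranks used to group annotated GenBank output —
with species recorded from the winning group's plurality. Ties break by
summed best-hit score, then lexicographic label; every tie-break in the
package is total, so outputs are byte-reproducible.

## The homology engine

The built-in engine is a seed-and-extend local aligner chosen for
determinism and testability, not throughput parity with production tools:

- **Seeding.** Exact k-mer matches (default k = 11 nucleotide, 4 protein)
  against a plus-strand index; the minus strand is searched via the
  reverse-complemented query, with hit coordinates mapped back to the
  forward query (minus-strand hits carry subject_start > subject_end, as in
  tabular BLAST output).
- **Extension.** Seeds project merged subject windows sized to contain any
  positive-scoring alignment through the seed (for queries ≤ 256 residues;
  longer queries use a capped pad that acts like a conventional band).
  Each window is aligned once with an affine-gap local DP
  (match +1, mismatch −1; a gap of length L costs 5 + 2(L−1)). The DP itself
  is delegated to Biopython's C `PairwiseAligner`; the test suite checks the
  whole route against an independently hand-written full-matrix
  Smith–Waterman oracle: engine scores never exceed the optimum and equal it
  whenever an exact seed lies on the optimal path.
- **Filters and statistics.** Identity = matches / alignment columns (gap
  columns count as non-matches). The significance proxy is
  `evalue = N_db · query_len · 2^(−score/2)` — an explicit, documented
  stand-in, not a Karlin–Altschul statistic; its default ceiling is 1e−5 and
  every threshold (identity, coverage, alignment length, e-value, word size)
  is a configuration key. Protein searches use match +2 because on the fixed
  2^(−score/2) scale a +1 residue match under-weights the information content
  of a 20-letter alphabet; without it, correct ~40-aa translated-read
  alignments cannot reach significance.
- **Performance bounds, not heuristics-for-accuracy.** When a caller demands
  identity ≥ I and query coverage ≥ C (the stringent-mapping ops), any
  passing hit provably contains a long exact run (pigeonhole over its ≤
  (1 − I) non-match columns), so windows with fewer seeds than that bound are
  skipped before any DP. This prunes only windows that cannot hold a passing
  hit.

Ranking is score desc → e-value asc → accession asc everywhere.

## Stringent mapping: scrubbing and transmission

Both decontamination and transmission detection map reads at ≥ 99% identity
over ≥ 90% of the read. The 99% threshold is inclusive by intent: a 100-nt
read with exactly one mismatch (99.0%) maps, with two (98.0%) it does not —
i.e. the threshold admits the ~1% substitution error of short-read
sequencing and nothing looser.

**Contaminant screen.** Contigs from *unrelated* samples are cross-aligned;
pairs with ≥ 99% identity over ≥ 90% of the shorter contig are single-linkage
clustered, and clusters spanning ≥ 2 samples are reported as putative reagent
contaminants. Reads mapping to any contaminant contig at the stringent
threshold are then scrubbed from every dataset. Related samples (a
mother–infant pair) must never be cross-checked against each other — the
whole design rests on the contrast between sharing across unrelated samples
(contamination) and sharing within a pair (transmission). A sham (no-sample)
control is summarized by its quality-filtered read count, the fraction of
the target sequencing depth it represents, and an assembly check: a run
whose reads assemble into no contig of reportable length is called
"background".

**Transmission.** Infant viral contigs > 5000 bp serve as backbones; a
backbone with at least one stringently mapping mother read (min_reads = 1 by
default) is a shared genotype. Breadth of coverage is reported per contig so
stricter post-hoc evidence rules can be applied. The cross-pair control maps
every mother on every infant; on synthetic pairs with disjoint private
phages the off-diagonal totals are exactly zero. Decontamination runs before
transmission in the pipeline preset — a reagent contaminant present in all
samples would otherwise light up the whole matrix. One empirical subtlety:
at 95% genotype identity a small fraction (~0.5%) of 150-nt reads falls in
locally conserved windows and legitimately passes the 99% cut-off, so the
hard "no cross-mapping" guarantee applies to genuinely unrelated genotypes
(≳ 10% divergence), not to near-threshold ones.

## Rarefaction and depth sizing

Read-based curves count distinct viral taxa (species by default; the rank is
switchable) among classified reads at each subsampled depth, averaged over
seeded replicates (default 3) whose per-replicate values are retained.
Because a read's classification does not depend on which other reads were
drawn, the implementation classifies the full pool once and counts taxa
within each subsample — exactly equivalent to classify-after-subsample and
far cheaper. Contig-based curves subsample, assemble via a pluggable adapter,
classify contigs and count viral taxa owning ≥ 1 contig > 5000 nt.

The fitted trend is S(x) = a·ln(x) + b by least squares on (ln depth,
richness); noiseless logarithmic data is recovered exactly. The doubling
gain 100·a·ln2 / S(x) equals the finite difference (S(2x) − S(x))/S(x)
identically. Coverage fractions are reported against the full-pool richness.

**The mock assembler is a declared synthetic stand-in**, not an assembly
algorithm: built from the truth genomes of a simulated community, it assigns
reads to genomes by sampled exact k-mer matching (k = 21, stride 8) and
emits a genome, whole, as a "contig" iff its estimated mean coverage reaches
5×. This reproduces the one behavior the depth analyses need — contigs
emerge when coverage crosses a threshold — while assembly internals remain
out of scope; any real assembler plugs in through the same callable contract
(reads in, contigs out).

## Functional profiling, host prediction, novel-phage screening

Functional profiling assigns each read (via six-frame translated search) or
ORF protein the category of its best passing hit in a user-mounted database
(COG-style categories, CAZy-style families, or pathways; layout:
`entries.faa` + `categories.tsv`). Entries mapped to k categories contribute
1/k to each so totals are conserved; reads (not base pairs) are the counting
unit. No category databases are bundled.

Host prediction scans viral contigs for CRISPR protospacers: substitution-
only (Hamming) matching of 20–60-nt spacers on both strands, default
max_mismatches = 1. Indel tolerance is deliberately excluded — spacers are
short and gapped matching would inflate false host links.

Novel-phage screening searches the ORFs of bacterial or unclassified contigs
against a marker-protein set partitioned into phage genomic modules
(replication, packaging, head, tail, lysis, lysogeny). A contig whose ORFs
hit ≥ min_modules distinct modules (default 3) is flagged; lysogeny-module
presence is reported as a separate boolean because its absence distinguishes
candidate virulent phages.

## Synthetic communities and what passing tests show

The generators produce, deterministically per seed: i.i.d. random genomes
with controlled GC; gene-structured phage genomes whose designed genes are
provably maximal ORFs (back-translation fixes leucine → TTA and serine →
TCA so reverse-strand stops are dense, rotates other codons by position so
unrelated proteins share no long nucleotide k-mers, and ends each intergenic
spacer with an in-frame stop); reads with abundance-weighted sources,
uniform positions, fair strands, i.i.d. substitutions (default 1%, constant
Q30) and exhaustive truth tables; mother–infant pairs whose shared genomes
diverge by a set percentage split evenly between the two copies; and
per-sample contaminant copies for spike-in designs. Reference tiers are
built by tiling genomes into overlapping RefSeq-style entries whose overlap
exceeds the read length, so every read lies wholly within some entry.

What this does *not* emulate: indels and quality-dependent errors, PCR
duplicates and coverage bias, repeat structure and horizontal transfer
between genomes, strain mixtures, and real assembly fragmentation. Passing
tests therefore demonstrate that the analytical logic is correct under its
stated model — priority ordering, thresholds, vote counting, clustering,
curve fitting — not that real-data sensitivity/specificity will match the
synthetic figures.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| quality filter | len ≥ 50, mean Q ≥ 20 | both inclusive |
| word size k | 11 nt / 4 aa | seed length |
| scores | +1/−1 (nt), +2/−1 (aa); gap 5 + 2(L−1) | see engine section |
| min alignment length | 30 columns | engine filter |
| e-value proxy ceiling | 1e−5 | `N_db·q_len·2^(−score/2)` |
| stringent mapping | 99% identity, 90% read coverage | inclusive |
| contig gate | > 5000 nt | strict |
| contig cross-link | 99% identity over 90% of shorter contig | contaminants |
| shared-taxa rule | abundance > 0.01% in both profiles | strict |
| ORF minimum | 60 aa | keeps random-ORF noise low |
| spacer mismatches | ≤ 1 | Hamming only |
| novel-phage modules | ≥ 3 distinct | lysogeny reported separately |
| mock assembler | ≥ 5× mean coverage | coverage gate |
| rarefaction replicates | 3 | seeded as seed + replicate index |

All of these are reachable from `PipelineConfig`; no stage hides a numeric
constant.

## Numerical and design choices

- Internal coordinates are 0-based half-open; GenBank output and hit tables
  use their native 1-based inclusive conventions. GenBank records carry a
  fixed date stamp so pipeline reruns are byte-identical.
- The ORF caller is a stop-to-stop six-frame scanner (starts ATG/GTG/TTG,
  initiator translated as M, N-containing codons translate to X and never
  match start/stop). It is a stand-in for a trained gene finder with
  identical downstream contracts.
- Degenerate inputs: empty queries return empty hit lists; contigs with no
  classified ORFs, or not exceeding the length gate, return an explicit
  unclassified reason; an empty contaminant set scrubs nothing; profiles of
  zero classified reads are empty with the unclassified count set.
- Subsampling is uniform without replacement, order-preserving, and a pure
  function of its seed; rarefaction replicates derive seeds as
  seed + replicate index.
- Problem sizes in the test suite and acceptance script (thousands to tens
  of thousands of reads, genomes of 6–9 kb, five-sample contaminant designs,
  two mother–infant pairs at 20k reads/sample) are chosen as the smallest
  scales at which the statistical contracts are sharp — binomial tolerances
  at 3–4σ, exact zero cross-pair counts, ≥ 99% scrub rates.

## Known limitations

- The e-value proxy is uncalibrated; absolute values are only comparable
  within a fixed database and scoring scheme.
- The engine's long-query extension cap (≈ 256 + band) can truncate optimal
  alignments with very large indels in contig-vs-contig comparisons; for the
  near-identical alignments the pipeline relies on this has no effect.
- Paired-end structure is ignored (reads are independent fragments), there
  is no LCA-style reconciliation of conflicting hits, no abundance
  correction for genome length, and no richness extrapolation beyond the
  fitted log trend.
- Transmission directionality (mother → infant vs. shared environment) is
  not inferable from this design and is not claimed.
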