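"""CRISPR-spacer host prediction and marker-based novel-phage screening.

Plants a protospacer from a known bacterial host into a phage contig, then
screens a set of bacterial contigs for one hiding phage-module genes
(packaging + head + tail + lysis) without any viral database homolog.
"""

from viromekit.hosts import SpacerDatabase, candidate_table, predict_hosts, screen_novel_phage
from viromekit.orfs import find_orfs
from viromekit.seqio import SequenceRecord
from viromekit.simulate import make_genome, make_marker_set, make_phage
from viromekit.taxonomy import TaxonomyLineage

# --- host prediction -------------------------------------------------------
host = TaxonomyLineage(realm="bacterial", genus="Bifidobacterium",
                       species="Bifidobacterium breve")
spacer = make_genome(32, 0.5, 11).seq
phage_contig = make_genome(6000, 0.45, 12)
with_protospacer = SequenceRecord(
    "viral_contig_1", phage_contig.seq[:3000] + spacer + phage_contig.seq[3000:])

db = SpacerDatabase([("CRISPR_sp1", spacer, host)])
for m in predict_hosts([with_protospacer], db, max_mismatches=1):
    print(f"{m.contig_id}: spacer {m.spacer_id} at {m.position} "
          f"({m.mismatches} mismatches, strand {m.strand}) -> host {m.host.pretty()}")

# --- novel-phage screening -------------------------------------------------
markers = make_marker_set(n_per_module=2, aa_len=120, seed=7)
hidden, _ = make_phage(2, markers, seed=21,
                       modules=("packaging", "head", "tail", "lysis"),
                       label="hidden_phage")
contigs = [make_genome(6000, 0.5, 30 + i) for i in range(4)]
for i, rec in enumerate(contigs):
    rec.id = f"bacterial_contig_{i}"
contigs.append(hidden)

pairs = [(rec, find_orfs(rec)) for rec in contigs]
candidates = screen_novel_phage(pairs, markers, min_modules=3)
print()
print(candidate_table([c for c in candidates if not c.note]).to_string(index=False))
# A protospacer match links a phage to the host whose CRISPR array recorded
# it; a contig spanning ≥3 phage modules without a lysogeny gene looks like a
# novel virulent (pro)phage missed by homology-based classification.
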