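"""ORF calling and majority-vote taxonomy for an assembled phage contig.

Generates a modular phage genome (replication, packaging, head, tail and
lysis genes plus unannotatable filler), calls its ORFs, classifies each ORF
against a protein reference tier, votes the contig's taxonomy and writes a
grouped GenBank file.
"""

import tempfile

from viromekit.contigs import annotate_contigs, hypothetical_fraction
from viromekit.seqio import write_annotated_contigs
from viromekit.simulate import make_marker_set, make_phage, make_protein_tiers
from viromekit.taxonomy import TaxonomyLineage

lineage = TaxonomyLineage(realm="viral", family="Myoviridae",
                          species="Infant phage 36549")
markers = make_marker_set(n_per_module=2, aa_len=120, seed=7)
genome, truth = make_phage(2, markers, seed=5, n_filler=4, label="contig36549")
tiers = make_protein_tiers({"contig36549": (truth, lineage)})

((contig, classification, orfs),) = annotate_contigs([genome], tiers)
n_genes, n_hypothetical = hypothetical_fraction(orfs)
print(f"contig {contig.id}: {len(contig.seq)} nt, {n_genes} ORFs called")
print(f"classified as: {classification.lineage.pretty()} "
      f"(support {classification.support_fraction:.2f}, votes {classification.votes})")
print(f"hypothetical proteins: {n_hypothetical}/{n_genes}")

with tempfile.TemporaryDirectory() as out:
    paths = write_annotated_contigs([(contig, classification, orfs)], out,
                                    group_rank="family")
    print(f"GenBank written per family: {sorted(paths)}")
# The contig inherits the most frequent taxonomy among its classified ORFs;
# filler genes stay "hypothetical protein", mirroring how most phage genes
# lack database annotation.
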