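"""Best-hit functional category profiling of reads (translated search).

Builds a tiny COG-style protein database where one entry belongs to two
categories, simulates reads from the underlying genes and profiles them;
multi-category entries contribute fractionally so totals are conserved.
"""

import numpy as np

from viromekit.functional import FunctionalDatabase, functional_profile
from viromekit.seqio import SequenceRecord
from viromekit.simulate import back_translate, make_protein
from viromekit.taxonomy import EMPTY_LINEAGE, ReferenceEntry

rng = np.random.default_rng(9)
proteins = {
    "COG_REP": (make_protein(150, rng), ("L",)),          # replication
    "COG_CAP": (make_protein(150, rng), ("M",)),          # capsid/envelope
    "COG_DUAL": (make_protein(150, rng), ("L", "M")),     # bifunctional
}
db = FunctionalDatabase(
    scheme="cog-category",
    entries=[ReferenceEntry(accession=acc, organism="", lineage=EMPTY_LINEAGE,
                            seq=SequenceRecord(acc, aa), kind="protein")
             for acc, (aa, _) in proteins.items()],
    category_map={acc: cats for acc, (aa, cats) in proteins.items()},
)

reads = []
for acc, (aa, _) in proteins.items():
    nt = back_translate(aa)
    for i in range(6):
        reads.append(SequenceRecord(f"{acc}_r{i}", nt[i * 40:i * 40 + 150]))

profile = functional_profile(reads, db, translated=True)
print(profile.to_frame().to_string(index=False))
print(f"assigned: {profile.total_assigned}, unassigned: {profile.unassigned}")
# Reads from the bifunctional gene add 0.5 to each of its two categories, so
# category weights always sum to the number of assigned reads.
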