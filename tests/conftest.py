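import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from viromekit.simulate import (CommunitySpec, GenomeSpec, build_genomes,
                                make_marker_set, make_reference_tiers)
from viromekit.taxonomy import TaxonomyLineage


def viral_lineage(i: int) -> TaxonomyLineage:
    return TaxonomyLineage(realm="viral", family="Siphoviridae",
                           species=f"Synthetic phage {i}")


def bacterial_lineage(i: int) -> TaxonomyLineage:
    return TaxonomyLineage(realm="bacterial", family="Lactobacillaceae",
                           genus="Lactobacillus", species=f"Lactobacillus sp{i}")


@pytest.fixture(scope="session")
def marker_set():
    return make_marker_set(n_per_module=2, aa_len=120, seed=7)


@pytest.fixture(scope="session")
def mixed_community():
    """Four-realm community: 2 phages, 1 archaeon, 2 bacteria, 1 eukaryote."""
    genomes = [
        GenomeSpec("phageA", viral_lineage(1), length=8000),
        GenomeSpec("phageB", viral_lineage(2), length=8000),
        GenomeSpec("arch1", TaxonomyLineage(realm="archaeal", family="Methanobacteriaceae",
                                            genus="Methanobrevibacter",
                                            species="Methanobrevibacter smithii"),
                   length=9000),
        GenomeSpec("bact1", bacterial_lineage(1), length=9000),
        GenomeSpec("bact2", TaxonomyLineage(realm="bacterial", family="Enterobacteriaceae",
                                            genus="Escherichia", species="Escherichia coli"),
                   length=9000),
        GenomeSpec("euk1", TaxonomyLineage(realm="eukaryote", family="Saccharomycetaceae",
                                           genus="Saccharomyces",
                                           species="Saccharomyces cerevisiae"),
                   length=9000),
    ]
    return CommunitySpec(genomes=genomes, seed=101)


@pytest.fixture(scope="session")
def mixed_tiers(mixed_community):
    genomes = build_genomes(mixed_community)
    lineages = {g.label: g.lineage for g in mixed_community.genomes}
    tiers, taxonomy = make_reference_tiers(genomes, lineages)
    return tiers
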