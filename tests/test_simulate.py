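import numpy as np
import pytest

from viromekit.orfs import find_orfs, translate
from viromekit.reads import classify_reads
from viromekit.seqio import parse_refseq_header
from viromekit.simulate import (CommunitySpec, GenomeSpec, PairSpec, back_translate,
                                build_genomes, community_weights, draw_reads,
                                make_genome, make_marker_set, make_pair, make_phage,
                                make_reference_tiers, mutate, simulate_reads,
                                spike_contaminant)
from viromekit.taxonomy import TaxonomyLineage
from viromekit.transmission import detect_transmission


def _viral(i):
    return TaxonomyLineage(realm="viral", family="Siphoviridae",
                           species=f"phage sp {i}")


class TestMakeGenome:
    def test_seed_determinism(self):
        assert make_genome(1000, 0.5, 3).seq == make_genome(1000, 0.5, 3).seq

    def test_gc_content_within_binomial_bound(self):
        seq = make_genome(10 ** 5, 0.7, 9).seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.7) < 0.006  # 4 sigma

    def test_length_one(self):
        assert len(make_genome(1, 0.5, 1).seq) == 1

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            make_genome(0, 0.5, 1)
        with pytest.raises(ValueError):
            make_genome(10, 1.0, 1)


class TestMutate:
    def test_zero_divergence_identity(self):
        seq = make_genome(500, 0.5, 2).seq
        assert mutate(seq, 0.0, 1) == seq

    def test_divergence_rate_realized(self):
        seq = make_genome(10 ** 5, 0.5, 4).seq
        mutated = mutate(seq, 0.02, 5)
        diffs = sum(a != b for a, b in zip(seq, mutated))
        assert abs(diffs / len(seq) - 0.02) < 4 * np.sqrt(0.02 * 0.98 / len(seq))


class TestBackTranslate:
    def test_translation_roundtrip(self):
        aa = "MKLVSTANQRGHWDEFCIPY"
        assert translate(back_translate(aa)) == aa

    def test_leucine_serine_create_reverse_stops(self):
        nt = back_translate("LS")
        assert nt == "TTATCA"  # reverse complement contains TGA/TAA stops


class TestMakePhage:
    def test_designed_genes_recovered_by_orf_caller(self, marker_set):
        genome, truth = make_phage(2, marker_set, seed=11,
                                   modules=("replication", "packaging",
                                            "head", "tail"))
        found = {(o.start, o.end, o.strand) for o in find_orfs(genome, 60)}
        for row in truth.itertuples(index=False):
            assert (row.start, row.end, "+") in found
        assert len(truth) == 8

    def test_seed_reproducibility(self, marker_set):
        g1, t1 = make_phage(2, marker_set, seed=12)
        g2, t2 = make_phage(2, marker_set, seed=12)
        assert g1.seq == g2.seq and t1.equals(t2)

    def test_truth_table_exhaustive_and_unique(self, marker_set):
        _, truth = make_phage(2, marker_set, seed=13, n_filler=3)
        assert truth["gene_id"].is_unique
        assert len(truth) == 10 + 3


@pytest.fixture(scope="module")
def community():
    genomes = [GenomeSpec("a", _viral(0), 4000), GenomeSpec("b", _viral(1), 4000)]
    return CommunitySpec(genomes=genomes, abundances=[0.9, 0.1],
                         error_rate=0.0, seed=71)


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, community):
        reads, truth = simulate_reads(community, 200, seed=72)
        genomes = {k: v.seq for k, v in build_genomes(community).items()}
        from viromekit.seqio import reverse_complement

        for read, row in zip(reads, truth.itertuples(index=False)):
            fragment = genomes[row.source][row.position:row.position + 150]
            expected = fragment if row.strand == "+" else reverse_complement(fragment)
            assert read.seq == expected

    def test_abundance_shares_within_binomial_bound(self, community):
        _, truth = simulate_reads(community, 10 ** 4, seed=73)
        share = (truth["source"] == "a").mean()
        assert abs(share - 0.9) < 0.012  # 4 sigma at n=1e4

    def test_error_rate_realized(self):
        genomes = [GenomeSpec("a", _viral(0), 4000)]
        spec = CommunitySpec(genomes=genomes, error_rate=0.01, seed=74)
        _, truth = simulate_reads(spec, 2000, seed=75)
        rate = truth["n_errors"].sum() / (2000 * 150)
        assert rate == pytest.approx(0.01, abs=4 * np.sqrt(0.01 * 0.99 / (2000 * 150)))

    def test_truth_table_exhaustive(self, community):
        reads, truth = simulate_reads(community, 300, seed=76)
        assert list(truth["read_id"]) == [r.id for r in reads]
        assert truth["read_id"].is_unique

    def test_seeded_byte_identity(self, community):
        r1, t1 = simulate_reads(community, 100, seed=77)
        r2, t2 = simulate_reads(community, 100, seed=77)
        assert [r.seq for r in r1] == [r.seq for r in r2] and t1.equals(t2)

    def test_lognormal_weights_default(self, community):
        spec = CommunitySpec(genomes=community.genomes, seed=71)
        w = community_weights(spec)
        assert w.sum() == pytest.approx(1.0) and (w > 0).all()


class TestSpikeSeries:
    def test_spike_fractions_recovered_in_profiles(self, mixed_community, mixed_tiers):
        """Decreasing viral spike-in fractions are recovered by read
        profiling within sampling error — the sensitivity design."""
        labels = [g.label for g in mixed_community.genomes]
        for spike in (0.05, 0.01, 0.002):
            rest = (1 - spike) / 4
            weights = []
            for g in mixed_community.genomes:
                if g.label == "phageA":
                    weights.append(spike)
                elif g.label == "phageB":
                    weights.append(1e-9)  # absent
                else:
                    weights.append(rest)
            spec = CommunitySpec(genomes=mixed_community.genomes,
                                 abundances=weights, seed=mixed_community.seed)
            n = 4000
            reads, truth = simulate_reads(spec, n, seed=82)
            cls = classify_reads(reads, mixed_tiers)
            detected = sum(1 for c in cls if c.classified
                           and c.lineage.species == "Synthetic phage 1") / n
            true_frac = (truth["source"] == "phageA").mean()
            sigma = np.sqrt(spike * (1 - spike) / n)
            assert abs(detected - true_frac) <= 3 * sigma + 0.002


class TestSpikeContaminant:
    def test_exact_spike_counts_rounded_down(self):
        reads = {f"s{i}": [make_genome(200, 0.5, j * 10 + i)
                           for j in range(1, 101)] for i in range(2)}
        for sample in reads:
            for j, rec in enumerate(reads[sample]):
                rec.id = f"{sample}_r{j}"
        contaminant = make_genome(6000, 0.45, 99)
        spiked, truth, copies = spike_contaminant(reads, contaminant, 0.05, seed=1)
        for sample in spiked:
            assert len(truth[sample]) == 5  # floor(0.05 * 100)
            assert len(spiked[sample]) == 105

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            spike_contaminant({}, make_genome(100, 0.5, 1), 1.5, seed=0)


class TestMakePair:
    def _spec(self, seed):
        genomes = [GenomeSpec(f"p{i}", _viral(i), 6000) for i in range(4)]
        return CommunitySpec(genomes=genomes, error_rate=0.0, seed=seed)

    def test_identical_shared_genomes_detected_exactly(self):
        spec = self._spec(201)
        pair = PairSpec(shared_phages=("p0",), infant_only=("p1",),
                        mother_only=("p2", "p3"), shared_identity=100.0)
        fx = make_pair(pair, spec, 800, 800, seed=202)
        report = detect_transmission(fx.infant_contigs, fx.mother_reads)
        assert report.shared_contigs == fx.shared_contig_ids == ["p0_contig"]

    def test_divergent_negative_control(self):
        spec = self._spec(203)
        pair = PairSpec(shared_phages=("p0",), infant_only=("p1",),
                        mother_only=("p2", "p3"), shared_identity=90.0)
        fx = make_pair(pair, spec, 800, 800, seed=204)
        report = detect_transmission(fx.infant_contigs, fx.mother_reads)
        assert report.shared_contigs == []

    def test_unknown_label_rejected(self):
        spec = self._spec(205)
        with pytest.raises(ValueError, match="unknown"):
            make_pair(PairSpec(shared_phages=("nope",)), spec, 10, 10, seed=1)


class TestMakeReferenceTiers:
    def test_realm_routing_and_headers(self, mixed_community):
        genomes = build_genomes(mixed_community)
        lineages = {g.label: g.lineage for g in mixed_community.genomes}
        tiers, taxonomy = make_reference_tiers(genomes, lineages)
        by_name = {t.name: t for t in tiers}
        assert [t.name for t in tiers] == ["viral", "archaeal", "bacterial", "whole"]
        viral_accs = {e.accession for e in by_name["viral"].entries}
        assert all(acc.startswith(("PHAGEA", "PHAGEB")) for acc in viral_accs)
        assert len(by_name["whole"].entries) == sum(
            len(by_name[n].entries) for n in ("viral", "archaeal", "bacterial")
        ) + sum(1 for acc in taxonomy if acc.startswith("EUK1"))
        for entry in by_name["viral"].entries:
            acc, organism = parse_refseq_header(entry.seq.description)
            assert acc == entry.accession and organism == entry.lineage.species

    def test_error_free_classification_is_exact(self, mixed_community, mixed_tiers):
        spec = CommunitySpec(genomes=mixed_community.genomes, error_rate=0.0,
                             seed=mixed_community.seed)
        reads, truth = simulate_reads(spec, 400, seed=91)
        cls = classify_reads(reads, mixed_tiers)
        species_of = {g.label: g.lineage.species for g in mixed_community.genomes}
        assert all(c.classified for c in cls)
        assert all(c.lineage.species == species_of[src]
                   for c, src in zip(cls, truth["source"]))
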