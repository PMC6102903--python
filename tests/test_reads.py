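import numpy as np
import pytest

from viromekit.align import AlignmentParams
from viromekit.reads import (ReadClassification, TaxonomicProfile, classify_reads,
                             depth_adequacy, profile, quality_filter, shared_taxa,
                             subsample, viral_profile)
from viromekit.seqio import SequenceRecord
from viromekit.simulate import build_genomes, simulate_reads
from viromekit.taxonomy import EMPTY_LINEAGE, ReferenceEntry, ReferenceTier, TaxonomyLineage


def _read(rid, length=80, q=30):
    return SequenceRecord(rid, "ACGT" * (length // 4), rid, [q] * length)


class TestQualityFilter:
    def test_length_boundary_exclusive_below(self):
        kept, removed = quality_filter([_read("a", 48), _read("b", 52)], min_len=50)
        assert [r.id for r in kept] == ["b"] and removed == 1

    def test_mean_quality_boundary_inclusive(self):
        read = _read("a", 80, q=20)
        kept, _ = quality_filter([read], min_len=50, min_mean_q=20.0)
        assert kept == [read]

    def test_reads_without_quals_pass_length_only(self):
        read = SequenceRecord("a", "ACGT" * 20)
        with pytest.warns(UserWarning):
            kept, _ = quality_filter([read], min_len=50, min_mean_q=20.0)
        assert kept == [read]

    def test_matches_oneline_oracle_on_random_reads(self):
        rng = np.random.default_rng(3)
        reads = []
        for i in range(1000):
            n = int(rng.integers(30, 120))
            quals = list(rng.integers(2, 41, n))
            reads.append(SequenceRecord(f"r{i}", "A" * n, quals=quals))
        kept, removed = quality_filter(reads, min_len=50, min_mean_q=20.0)
        oracle = [r for r in reads if len(r.seq) >= 50 and np.mean(r.quals) >= 20.0]
        assert kept == oracle
        assert removed == len(reads) - len(oracle)


class TestSubsample:
    def test_full_pool_is_identity(self):
        reads = [_read(f"r{i}") for i in range(10)]
        assert subsample(reads, 10, seed=1) == reads

    def test_seed_determinism(self):
        reads = [_read(f"r{i}") for i in range(50)]
        assert subsample(reads, 7, seed=9) == subsample(reads, 7, seed=9)

    def test_order_preserved(self):
        reads = [_read(f"r{i}") for i in range(50)]
        sample = subsample(reads, 20, seed=4)
        positions = [reads.index(r) for r in sample]
        assert positions == sorted(positions)

    def test_oversample_rejected_naming_both_numbers(self):
        with pytest.raises(ValueError, match="11.*10|10.*11"):
            subsample([_read(f"r{i}") for i in range(10)], 11, seed=0)

    def test_uniformity_binomial_bound(self):
        reads = [_read(f"r{i}") for i in range(10)]
        counts = {r.id: 0 for r in reads}
        for rep in range(2000):
            for r in subsample(reads, 3, seed=rep):
                counts[r.id] += 1
        # each read drawn with p=0.3; 4 sigma on 2000 trials
        sigma = np.sqrt(0.3 * 0.7 / 2000)
        for rid, n in counts.items():
            assert abs(n / 2000 - 0.3) < 4 * sigma, rid


def _single_entry_tier(name, priority, seq, lineage, acc=None):
    acc = acc or f"{name.upper()}1"
    return ReferenceTier(name=name, priority=priority, entries=[
        ReferenceEntry(accession=acc, organism="", lineage=lineage,
                       seq=SequenceRecord(acc, seq))
    ])


@pytest.fixture(scope="module")
def viral_vs_bacterial_tiers():
    rng = np.random.default_rng(11)
    shared = "".join(rng.choice(list("ACGT"), 600))
    viral = TaxonomyLineage(realm="viral", family="Myoviridae", species="Phage X")
    bact = TaxonomyLineage(realm="bacterial", genus="Escherichia", species="E. coli X")
    tiers = [
        _single_entry_tier("viral", 1, shared, viral),
        _single_entry_tier("bacterial", 2, shared, bact),
    ]
    return tiers, shared


class TestClassifyReads:
    def test_viral_priority_wins_over_bacterial(self, viral_vs_bacterial_tiers):
        tiers, shared = viral_vs_bacterial_tiers
        (c,) = classify_reads([SequenceRecord("r", shared[100:250])], tiers)
        assert c.tier_name == "viral"
        assert c.lineage.family == "Myoviridae" and c.lineage.species == "Phage X"

    def test_bacterial_only_read_gets_genus_species(self, viral_vs_bacterial_tiers):
        tiers, shared = viral_vs_bacterial_tiers
        rng = np.random.default_rng(12)
        bact_only = "".join(rng.choice(list("ACGT"), 600))
        tiers = [
            _single_entry_tier("viral", 1, shared, tiers[0].entries[0].lineage),
            _single_entry_tier("bacterial", 2, bact_only,
                               tiers[1].entries[0].lineage),
        ]
        (c,) = classify_reads([SequenceRecord("r", bact_only[50:200])], tiers)
        assert c.tier_name == "bacterial"
        assert c.lineage.genus == "Escherichia"

    def test_unclassified_read(self, viral_vs_bacterial_tiers):
        tiers, _ = viral_vs_bacterial_tiers
        rng = np.random.default_rng(13)
        alien = "".join(rng.choice(list("ACGT"), 150))
        (c,) = classify_reads([SequenceRecord("r", alien)], tiers)
        assert not c.classified and c.best_hit is None

    def test_empty_tier_list_rejected(self):
        with pytest.raises(ValueError):
            classify_reads([_read("r")], [])

    def test_error_reads_recover_source_species(self, mixed_community, mixed_tiers):
        reads, truth = simulate_reads(mixed_community, 500, seed=21)
        classifications = classify_reads(reads, mixed_tiers)
        species_of = {g.label: g.lineage.species for g in mixed_community.genomes}
        classified = [(c, src) for c, src in zip(classifications, truth["source"])
                      if c.classified]
        assert len(classified) > 400
        correct = sum(c.lineage.species == species_of[src] for c, src in classified)
        assert correct / len(classified) >= 0.95

    def test_priority_monotonicity_under_lower_tier_growth(self, viral_vs_bacterial_tiers):
        """Adding entries to lower-priority tiers never changes assignments
        already made in a higher tier."""
        tiers, shared = viral_vs_bacterial_tiers
        rng = np.random.default_rng(14)
        reads = [SequenceRecord(f"r{i}", shared[i * 40:i * 40 + 150]) for i in range(8)]
        before = classify_reads(reads, tiers)
        grown = [tiers[0],
                 ReferenceTier(name="bacterial", priority=2,
                               entries=tiers[1].entries + [
                                   ReferenceEntry(
                                       accession=f"NEW{j}", organism="",
                                       lineage=tiers[1].entries[0].lineage,
                                       seq=SequenceRecord(
                                           f"NEW{j}", shared + "".join(rng.choice(list("ACGT"), 50))))
                                   for j in range(3)])]
        after = classify_reads(reads, grown)
        assert [(c.tier_name, c.lineage) for c in before] == \
            [(c.tier_name, c.lineage) for c in after]

    def test_conservation(self, mixed_community, mixed_tiers):
        reads, _ = simulate_reads(mixed_community, 200, seed=33)
        classifications = classify_reads(reads, mixed_tiers)
        n_classified = sum(c.classified for c in classifications)
        n_unclassified = sum(not c.classified for c in classifications)
        assert n_classified + n_unclassified == len(reads)


def _classification(rid, species, family="Myoviridae", realm="viral"):
    from viromekit.align import HitRecord

    lineage = TaxonomyLineage(realm=realm, family=family, species=species)
    hit = HitRecord(rid, "X", 100.0, 100, 0, 0, 1, 100, 1, 100, 100.0, 1e-30, 100.0)
    return ReadClassification(rid, "viral", lineage, hit)


class TestProfile:
    def test_relative_abundance_arithmetic(self):
        cls = [_classification(f"r{i}", "A") for i in range(3)] + \
            [_classification("r3", "B")]
        prof = profile(cls, "species")
        assert prof.counts == {"A": 3, "B": 1}
        assert prof.relative_abundance == {"A": 75.0, "B": 25.0}
        assert abs(sum(prof.relative_abundance.values()) - 100.0) < 1e-9

    def test_all_unclassified(self):
        cls = [ReadClassification(f"r{i}") for i in range(5)]
        prof = profile(cls, "species")
        assert prof.counts == {} and prof.unclassified_count == 5

    def test_unclassified_not_in_denominator(self):
        cls = [_classification("r0", "A"), ReadClassification("r1")]
        prof = profile(cls, "species")
        assert prof.relative_abundance["A"] == 100.0
        assert prof.unclassified_count == 1

    def test_spiked_viral_fraction_recovered(self, mixed_community, mixed_tiers):
        """A mixture with a known viral share yields a matching viral read %."""
        from viromekit.simulate import CommunitySpec

        spec = CommunitySpec(genomes=mixed_community.genomes,
                             abundances=[0.023, 0.023, 0.10, 0.37, 0.37, 0.114],
                             seed=mixed_community.seed)
        reads, truth = simulate_reads(spec, 2000, seed=55)
        classifications = classify_reads(reads, mixed_tiers)
        viral_frac = sum(1 for c in classifications
                         if c.classified and c.lineage.is_viral()) / len(reads)
        true_frac = (truth["source"].isin(["phageA", "phageB"])).mean()
        assert viral_frac == pytest.approx(true_frac, abs=0.01)
        assert true_frac == pytest.approx(0.046, abs=0.02)


class TestSharedTaxa:
    def _profile(self, counts):
        return TaxonomicProfile(rank="species", counts=counts)

    def test_shared_above_threshold(self):
        a = self._profile({"A": 2, "fillerA": 9998})   # A at 0.02%
        b = self._profile({"A": 3, "fillerB": 9997})   # A at 0.03%
        assert shared_taxa(a, b) == ["A"]

    def test_exact_boundary_excluded(self):
        a = self._profile({"A": 1, "fillerA": 9999})   # A at exactly 0.01%
        b = self._profile({"A": 50, "fillerB": 9950})
        assert shared_taxa(a, b) == []

    def test_disjoint_profiles(self):
        assert shared_taxa(self._profile({"A": 5}), self._profile({"B": 5})) == []

    def test_rank_mismatch_rejected(self):
        a = TaxonomicProfile(rank="species", counts={"A": 1})
        b = TaxonomicProfile(rank="family", counts={"A": 1})
        with pytest.raises(ValueError):
            shared_taxa(a, b)


class TestDepthAdequacy:
    def test_sham_control_fraction(self):
        assert depth_adequacy(46269, 1_000_000) == 4.6

    def test_zero_and_full(self):
        assert depth_adequacy(0, 10 ** 6) == 0.0
        assert depth_adequacy(10 ** 6, 10 ** 6) == 100.0

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            depth_adequacy(100, 0)
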