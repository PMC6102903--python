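import itertools

import numpy as np
import pytest

from viromekit.align import HitRecord
from viromekit.contigs import (annotate_contigs, classify_contig, classify_orfs,
                               hypothetical_fraction)
from viromekit.orfs import HYPOTHETICAL, ORF, find_orfs, translate
from viromekit.seqio import SequenceRecord, reverse_complement
from viromekit.simulate import make_phage, make_protein_tiers
from viromekit.taxonomy import TaxonomyLineage

from _oracles import majority_vote_oracle, six_frame_orfs_oracle, translate_oracle


class TestFindOrfs:
    def test_constructed_single_orf(self):
        rng = np.random.default_rng(8)
        codons = []
        while len(codons) < 60:
            c = "".join(rng.choice(list("ACGT"), 3))
            if c not in {"TAA", "TAG", "TGA", "ATG", "GTG", "TTG"}:
                codons.append(c)
        body = "".join(codons)
        contig = SequenceRecord("c", "TAA" + "ATG" + body + "TAA" + "CC")
        orfs = [o for o in find_orfs(contig, min_len_aa=60) if o.strand == "+"]
        assert len(orfs) == 1
        (orf,) = orfs
        assert (orf.start, orf.end) == (3, 3 + 3 + 180 + 3)
        assert len(orf.aa_seq) == 61
        assert orf.aa_seq.startswith("M")

    def test_reverse_complement_mirrors_coordinates(self):
        genome, truth = make_phage(1, _marker_set(), seed=3)
        fwd = find_orfs(genome, min_len_aa=60)
        rev = find_orfs(SequenceRecord("c", reverse_complement(genome.seq)),
                        min_len_aa=60)
        n = len(genome.seq)
        mirrored = {(n - o.end, n - o.start, "-" if o.strand == "+" else "+")
                    for o in rev}
        assert {(o.start, o.end, o.strand) for o in fwd} == mirrored

    def test_matches_independent_six_frame_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(30):
            seq = "".join(rng.choice(list("ACGT"), 3000))
            got = {(o.start, o.end, o.strand)
                   for o in find_orfs(SequenceRecord("c", seq), min_len_aa=30)}
            assert got == six_frame_orfs_oracle(seq, min_len_aa=30), f"trial {trial}"

    def test_ambiguous_bases_translate_to_x_and_break_codons(self):
        contig = SequenceRecord("c", "ATG" + "GCN" + "GCT" * 60 + "TAA")
        (orf,) = [o for o in find_orfs(contig, min_len_aa=30) if o.strand == "+"]
        assert orf.aa_seq[1] == "X"

    def test_translation_agrees_with_biopython(self):
        rng = np.random.default_rng(23)
        nt = "".join(rng.choice(list("ACGT"), 300))
        assert translate(nt) == translate_oracle(nt)


def _marker_set():
    from viromekit.simulate import make_marker_set

    return make_marker_set(n_per_module=2, aa_len=120, seed=7)


@pytest.fixture(scope="module")
def phage_fixture(marker_set):
    viral = TaxonomyLineage(realm="viral", family="Myoviridae", species="Phage M")
    genome, truth = make_phage(2, marker_set, seed=5, n_filler=4, label="phageM")
    tiers = make_protein_tiers({"phageM": (truth, viral)})
    return genome, truth, tiers, viral


class TestClassifyOrfs:
    def test_marker_orfs_get_lineage_and_product(self, phage_fixture):
        genome, truth, tiers, viral = phage_fixture
        orfs = find_orfs(genome, min_len_aa=60)
        classify_orfs(orfs, tiers)
        truth_by_start = {row.start: row for row in truth.itertuples(index=False)}
        n_checked = 0
        for orf in orfs:
            row = truth_by_start.get(orf.start)
            if row is None or row.module == "filler":
                continue
            n_checked += 1
            assert orf.lineage.species == "Phage M"
            assert orf.product == row.product
        assert n_checked == 10  # 5 modules x 2 genes

    def test_unmatched_orf_stays_hypothetical(self, phage_fixture):
        genome, truth, tiers, _ = phage_fixture
        orfs = find_orfs(genome, min_len_aa=60)
        classify_orfs(orfs, tiers)
        fillers = {row.start for row in truth.itertuples(index=False)
                   if row.module == "filler"}
        for orf in orfs:
            if orf.start in fillers:
                assert orf.lineage.is_empty()
                assert orf.product == HYPOTHETICAL

    def test_hypothetical_fraction_counts(self, phage_fixture):
        genome, truth, tiers, _ = phage_fixture
        orfs = find_orfs(genome, min_len_aa=60)
        classify_orfs(orfs, tiers)
        designed = {row.start for row in truth.itertuples(index=False)}
        designed_orfs = [o for o in orfs if o.start in designed]
        n, n_hyp = hypothetical_fraction(designed_orfs)
        assert (n, n_hyp) == (14, 4)  # 10 markers annotated, 4 fillers not

    def test_zero_orfs(self):
        assert hypothetical_fraction([]) == (0, 0)


def _fake_orf(i, lineage, score):
    hit = None
    if lineage is not None:
        hit = HitRecord(f"o{i}", "X", 100.0, 60, 0, 0, 1, 60, 1, 60,
                        score, 1e-30, 100.0)
    return ORF(contig_id="c", start=i * 300, end=i * 300 + 189, strand="+",
               frame=0, aa_seq="M" + "A" * 61,
               lineage=lineage if lineage is not None else TaxonomyLineage(),
               best_hit=hit)


_LINEAGES = {
    "A": TaxonomyLineage(realm="viral", family="Afamviridae", species="a sp"),
    "B": TaxonomyLineage(realm="viral", family="Bfamviridae", species="b sp"),
    "C": TaxonomyLineage(realm="viral", family="Cfamviridae", species="c sp"),
}


class TestClassifyContig:
    def _contig(self, length=6000):
        return SequenceRecord("c", "ACGT" * (length // 4))

    def test_simple_majority(self):
        orfs = [_fake_orf(0, _LINEAGES["A"], 10), _fake_orf(1, _LINEAGES["A"], 10),
                _fake_orf(2, _LINEAGES["B"], 10)]
        cls = classify_contig(self._contig(), orfs)
        assert cls.lineage.family == "Afamviridae"
        assert cls.support_fraction == pytest.approx(2 / 3)

    def test_tie_broken_by_summed_hit_score(self):
        orfs = [_fake_orf(0, _LINEAGES["A"], 50), _fake_orf(1, _LINEAGES["B"], 10)]
        cls = classify_contig(self._contig(), orfs)
        assert cls.lineage.family == "Afamviridae"
        orfs = [_fake_orf(0, _LINEAGES["A"], 10), _fake_orf(1, _LINEAGES["B"], 50)]
        assert classify_contig(self._contig(), orfs).lineage.family == "Bfamviridae"

    def test_exact_gate_boundary_5000_unclassified(self):
        orfs = [_fake_orf(0, _LINEAGES["A"], 10)]
        cls = classify_contig(self._contig(5000), orfs)
        assert not cls.classified and cls.reason == "below-length-gate"
        assert classify_contig(self._contig(5004), orfs).classified

    def test_zero_classified_orfs(self):
        cls = classify_contig(self._contig(), [_fake_orf(0, None, 0)])
        assert not cls.classified and cls.reason == "no-classified-orfs"

    def test_vote_conservation(self):
        orfs = [_fake_orf(0, _LINEAGES["A"], 1), _fake_orf(1, None, 0),
                _fake_orf(2, _LINEAGES["B"], 1)]
        cls = classify_contig(self._contig(), orfs)
        unclassified = sum(1 for o in orfs if o.lineage.is_empty())
        assert sum(cls.votes.values()) + unclassified == cls.n_orfs

    def test_matches_exhaustive_vote_oracle(self):
        """All ORF-lineage assignments with ≤ 6 ORFs over 3 lineages."""
        labels = ["A", "B", "C", None]
        for n in range(0, 7):
            for combo in itertools.product(labels, repeat=n):
                scores = [10.0 + i for i in range(n)]
                orfs = [_fake_orf(i, _LINEAGES.get(lab), scores[i])
                        for i, lab in enumerate(combo)]
                cls = classify_contig(self._contig(), orfs)
                exp_winner, exp_votes = majority_vote_oracle(
                    [f"viral|{lab}famviridae".replace("viral|Nonefamviridae", "")
                     if lab else None for lab in combo],
                    scores)
                oracle_winner, _ = majority_vote_oracle(
                    [f"{lab}famviridae" if lab else None for lab in combo], scores)
                if oracle_winner is None:
                    assert not cls.classified
                else:
                    assert cls.lineage.family == oracle_winner

    def test_strand_invariance_end_to_end(self, phage_fixture, marker_set):
        genome, truth, tiers, viral = phage_fixture
        fwd = annotate_contigs([genome], tiers)[0][1]
        rc = SequenceRecord(genome.id,
                            reverse_complement(genome.seq))
        rev = annotate_contigs([rc], tiers)[0][1]
        assert fwd.classified and fwd.lineage == rev.lineage
        assert fwd.votes == rev.votes
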