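"""K2P distances: closed form, counting oracle, group summaries."""

import math

import numpy as np
import pytest

from swimkit import AlignedSequences, gen_sequences, k2p_distance, pairwise_matrix
from swimkit.errors import InsufficientDataError, InvalidParameterError, SaturationError
from swimkit.popgen import group_mean_distances, k2p_from_pq, pooled_within_distance


def oracle_k2p(s1, s2):
    """Independent site-counting oracle for the K2P distance."""
    ts_pairs = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    valid = ts = tv = 0
    for a, b in zip(s1.upper(), s2.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        valid += 1
        if a != b:
            if (a, b) in ts_pairs:
                ts += 1
            else:
                tv += 1
    p, q = ts / valid, tv / valid
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


class TestK2pDistance:
    def test_identical_sequences_distance_zero(self):
        d, diff = k2p_distance("ACGTACGT", "ACGTACGT")
        assert d == 0.0
        assert diff.P == diff.Q == 0.0

    def test_ten_transitions_over_100_sites_closed_form(self):
        s1 = "A" * 100
        s2 = "G" * 10 + "A" * 90
        d, diff = k2p_distance(s1, s2)
        assert diff.P == pytest.approx(0.10)
        assert diff.Q == 0.0
        assert d == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)
        assert d == pytest.approx(0.11157, abs=5e-6)

    def test_random_pairs_match_counting_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(25):
            s1 = "".join(rng.choice(bases, 200))
            s2 = "".join(np.where(rng.random(200) < 0.05, rng.choice(bases, 200), list(s1)))
            try:
                d, _ = k2p_distance(s1, s2)
            except SaturationError:
                continue
            assert d == pytest.approx(oracle_k2p(s1, s2), abs=1e-12)

    def test_pairwise_deletion_of_gaps_and_ambiguity(self):
        # gapped/N sites must not count as differences or valid sites
        d_full, diff = k2p_distance("AAG-N", "AAAAC")
        assert diff.valid_sites == 3
        assert diff.P == pytest.approx(1 / 3)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_from_pq(0.5, 0.2)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InvalidParameterError):
            k2p_distance("ACGT", "ACG")

    def test_distance_exceeds_p_distance_for_small_divergence(self, rng):
        aln = gen_sequences(1, 6, 2000, within_d=0.02, between_d=0.03, seed=8)
        for i in range(5):
            d, diff = k2p_distance(aln.sequences[i], aln.sequences[i + 1])
            assert d >= diff.P + diff.Q - 1e-12


class TestPairwiseMatrix:
    def test_identical_sequences_all_zero(self):
        aln = AlignedSequences(ids=list("abc"), sequences=["ACGT"] * 3, groups=["g"] * 3)
        dm = pairwise_matrix(aln)
        assert np.all(dm.d == 0.0)

    def test_symmetry_and_zero_diagonal(self):
        aln = gen_sequences(2, 4, 500, 0.005, 0.02, seed=1)
        dm = pairwise_matrix(aln)
        np.testing.assert_array_equal(dm.d, dm.d.T)
        assert np.all(np.diag(dm.d) == 0)

    def test_two_group_mean_converges_to_target(self):
        aln = gen_sequences(2, 6, 5000, within_d=0.004, between_d=0.02, seed=2)
        summary = group_mean_distances(pairwise_matrix(aln), aln.groups)
        between = list(summary.between.values())[0]
        assert between == pytest.approx(0.02, rel=0.15)
        for v in summary.within.values():
            assert v == pytest.approx(0.004, rel=0.5)


class TestGroupSummaries:
    def test_hand_computed_four_sequence_toy(self):
        # 100 sites; pairwise transitions only, so d = -1/2 ln(1 - 2P)
        base = "A" * 100
        seqs = [
            base,                      # g1
            "G" * 4 + "A" * 96,        # g1; P=0.04 vs seq0
            "G" * 10 + "A" * 90,       # g2
            "G" * 14 + "A" * 86,       # g2; P=0.04 vs seq2
        ]
        aln = AlignedSequences(ids=list("abcd"), sequences=seqs,
                               groups=["g1", "g1", "g2", "g2"])
        summary = group_mean_distances(pairwise_matrix(aln), aln.groups)
        d04 = -0.5 * math.log(1 - 0.08)
        assert summary.within["g1"] == pytest.approx(d04, abs=1e-12)
        assert summary.within["g2"] == pytest.approx(d04, abs=1e-12)
        # the four between pairs have P = .10, .14, .06, .10
        expected_between = np.mean([-0.5 * math.log(1 - 2 * p) for p in [0.10, 0.14, 0.06, 0.10]])
        assert summary.between[("g1", "g2")] == pytest.approx(expected_between, abs=1e-12)
        all_p = [0.04, 0.10, 0.14, 0.06, 0.10, 0.04]
        assert summary.overall_mean == pytest.approx(
            np.mean([-0.5 * math.log(1 - 2 * p) for p in all_p]), abs=1e-12)

    def test_singleton_group_within_mean_flagged_nan(self):
        aln = AlignedSequences(ids=list("abc"), sequences=["ACGT"] * 3,
                               groups=["g1", "g1", "g2"])
        summary = group_mean_distances(pairwise_matrix(aln), aln.groups)
        assert math.isnan(summary.within["g2"])

    def test_summaries_invariant_to_sequence_order(self):
        aln = gen_sequences(2, 4, 400, 0.005, 0.02, seed=3)
        dm = pairwise_matrix(aln)
        s1 = group_mean_distances(dm, aln.groups)
        order = np.random.default_rng(0).permutation(aln.n)
        aln2 = AlignedSequences(ids=[aln.ids[i] for i in order],
                                sequences=[aln.sequences[i] for i in order],
                                groups=[aln.groups[i] for i in order])
        s2 = group_mean_distances(pairwise_matrix(aln2), aln2.groups)
        assert s1.within == s2.within
        assert s1.overall_mean == pytest.approx(s2.overall_mean)

    def test_pooled_within_excluding_a_group(self):
        aln = gen_sequences(3, 3, 400, 0.004, 0.02, seed=4)
        dm = pairwise_matrix(aln)
        val = pooled_within_distance(dm, aln.groups, exclude="pop1")
        keep = [i for i, g in enumerate(aln.groups) if g != "pop1"]
        manual = np.mean([dm.d[i, j] for i in keep for j in keep if i < j])
        assert val == pytest.approx(manual)
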