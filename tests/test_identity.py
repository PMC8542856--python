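"""Global alignment, percent identity, identity matrices, and the
intra/inter partition statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from markergauge import (IdentityMatrix, SpeciesPartition, correlate,
                         global_align, identity_matrix, pair_identity,
                         partition_stats, percent_identity)
from markergauge.identity import PairwiseAlignment
from markergauge.amplicon import MarkerSequence
from markergauge.sequences import random_sequence

from conftest import exhaustive_align_score

DNA = st.text(alphabet="ACGT", min_size=1, max_size=8)


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.score == 8.0
        assert (aln.aligned_a, aln.aligned_b) == ("ACGT", "ACGT")

    def test_single_deletion(self):
        aln = global_align("ACGT", "AGT")
        assert sum(1 for a, b in zip(aln.aligned_a, aln.aligned_b)
                   if "-" in (a, b)) == 1

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            global_align("ACGT", "ACXT")

    @given(DNA, DNA)
    @settings(max_examples=60, deadline=None)
    def test_score_symmetry(self, a, b):
        assert global_align(a, b).score == global_align(b, a).score

    @given(DNA, DNA)
    @settings(max_examples=40, deadline=None)
    def test_matches_exhaustive_enumerator(self, a, b):
        assert global_align(a, b).score == pytest.approx(
            exhaustive_align_score(a, b))


class TestPercentIdentity:
    def test_identical_windows(self):
        seq = "ACGT" * 250
        assert pair_identity(seq, seq) == 100.0

    def test_single_substitution_hand_count(self):
        # 9 of 10 columns match
        assert pair_identity("ACGTACGTAC", "ACGTACGTAT") == pytest.approx(90.0)

    def test_internal_gap_counts_in_denominator(self):
        aln = PairwiseAlignment("ACGTTACGTA", "ACGT-ACGTA", 0.0)
        assert percent_identity(aln) == pytest.approx(90.0)

    def test_terminal_gaps_excluded(self):
        aln = PairwiseAlignment("--ACGT", "GGACGT", 0.0)
        assert percent_identity(aln) == pytest.approx(100.0)
        assert percent_identity(aln, exclude_terminal_gaps=False) == pytest.approx(
            100 * 4 / 6)

    def test_all_gap_overlap_is_error(self):
        aln = PairwiseAlignment("AA--", "--TT", 0.0)
        with pytest.raises(ValueError, match="zero-length"):
            percent_identity(aln)

    @given(DNA, DNA)
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_identity_condition(self, a, b):
        pid = pair_identity(a, b)
        assert 0.0 <= pid <= 100.0
        if a == b:
            assert pid == 100.0


class TestIdentityMatrix:
    def test_identical_pair(self):
        m = identity_matrix([MarkerSequence("a", "window", "ACGTACGT"),
                             MarkerSequence("b", "window", "ACGTACGT")])
        assert m.get("a", "b") == 100.0

    def test_reorder_invariance(self, small_windows):
        sub = small_windows[:5]
        m1 = identity_matrix(sub)
        m2 = identity_matrix(sub[::-1]).reorder(m1.strain_ids)
        np.testing.assert_allclose(m1.values, m2.values)

    def test_planted_substitutions_reproduced_exactly(self, rng):
        base = random_sequence(rng, 400)
        seqs = {"a": base}
        for name, k in (("b", 4), ("c", 13)):
            arr = np.array(list(base))
            pos = rng.choice(len(arr), size=k, replace=False)
            for i in pos:
                arr[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[i]]
            seqs[name] = "".join(arr)
        m = identity_matrix([MarkerSequence(n, "window", s) for n, s in seqs.items()])
        assert m.get("a", "b") == pytest.approx(100 * (1 - 4 / 400))
        assert m.get("a", "c") == pytest.approx(100 * (1 - 13 / 400))
        # per-pair oracle: matrix value equals direct pair alignment
        for x, y in itertools.combinations(seqs, 2):
            assert m.get(x, y) == pytest.approx(pair_identity(seqs[x], seqs[y]))

    def test_duplicate_ids_rejected(self):
        ms = [MarkerSequence("a", "window", "ACGT"),
              MarkerSequence("a", "window", "ACGG")]
        with pytest.raises(ValueError, match="duplicate"):
            identity_matrix(ms)

    def test_mixed_regions_rejected(self):
        ms = [MarkerSequence("a", "window", "ACGT"),
              MarkerSequence("b", "complete_gene", "ACGG")]
        with pytest.raises(ValueError, match="region"):
            identity_matrix(ms)


def _toy_matrix():
    # intra pairs (A,B),(A,C),(B,C) = 1,2,3 ; inter (A,D),(B,D),(C,D) = 4,5,6
    ids = list("ABCD")
    v = np.full((4, 4), 100.0)
    v[0, 1] = v[1, 0] = 1.0
    v[0, 2] = v[2, 0] = 2.0
    v[1, 2] = v[2, 1] = 3.0
    v[0, 3] = v[3, 0] = 4.0
    v[1, 3] = v[3, 1] = 5.0
    v[2, 3] = v[3, 2] = 6.0
    return IdentityMatrix(ids, v)


class TestPartitionStats:
    def test_welch_t_on_toy_values(self):
        part = SpeciesPartition({"A": "x", "B": "x", "C": "x", "D": "y"}, 70.0)
        stats_ = partition_stats(_toy_matrix(), part)
        assert sorted(stats_.intra_values) == [1.0, 2.0, 3.0]
        assert sorted(stats_.inter_values) == [4.0, 5.0, 6.0]
        # Welch formula by hand: means 2 and 5, s^2 = 1, n = 3 each
        assert stats_.t_statistic == pytest.approx(-3.674, abs=1e-3)

    def test_single_species_no_test(self):
        part = SpeciesPartition({s: "x" for s in "ABCD"}, 70.0)
        stats_ = partition_stats(_toy_matrix(), part)
        assert stats_.inter_values == ()
        assert stats_.t_statistic is None

    def test_overlap_interval_construction(self):
        ids = list("ABCD")
        v = np.full((4, 4), 100.0)
        # intra pair (A,B) at 97.6; inter pairs include a 99.1
        pairs = {(0, 1): 97.6, (0, 2): 99.1, (0, 3): 90.0,
                 (1, 2): 91.0, (1, 3): 90.5, (2, 3): 98.0}
        for (i, j), val in pairs.items():
            v[i, j] = v[j, i] = val
        m = IdentityMatrix(ids, v)
        part = SpeciesPartition({"A": "x", "B": "x", "C": "y", "D": "z"}, 70.0)
        stats_ = partition_stats(m, part)
        assert stats_.overlap_interval == pytest.approx((97.6, 99.1))

    def test_separated_ranges_have_no_overlap(self, small_panel, small_windows):
        m = identity_matrix(small_windows)
        stats_ = partition_stats(m, small_panel.partition)
        assert stats_.intra_mean > stats_.inter_mean
        assert stats_.overlap_interval is None

    def test_partition_must_cover_matrix(self):
        part = SpeciesPartition({"A": "x"}, 70.0)
        with pytest.raises(ValueError, match="cover"):
            partition_stats(_toy_matrix(), part)


class TestCorrelate:
    def test_perfect_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        slope, intercept, r2 = correlate(x, [2 * v + 1 for v in x])
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_five_point_cloud_matches_normal_equations(self, rng):
        x = rng.uniform(0, 10, 5)
        y = 1.5 * x - 2 + rng.normal(0, 0.5, 5)
        slope, intercept, r2 = correlate(x, y)
        # closed-form OLS
        xm, ym = x.mean(), y.mean()
        b = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
        a = ym - b * xm
        ss_res = ((y - (b * x + a)) ** 2).sum()
        ss_tot = ((y - ym) ** 2).sum()
        assert slope == pytest.approx(b)
        assert intercept == pytest.approx(a)
        assert r2 == pytest.approx(1 - ss_res / ss_tot)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
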