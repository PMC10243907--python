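import itertools

import numpy as np
import pytest

from dyadsync import (frequency_f_stats, paired_condition_test,
                      permutation_band_selection, pseudo_pair_permutation,
                      score_correlation)
from dyadsync.stats import _merge_clusters, find_clusters


class TestFrequencyF:
    def test_matches_hand_computed_toy_table(self):
        """3 dyads x 2 conditions, worked through the repeated-measures
        sums of squares by hand: F = 3.0."""
        y = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 3.0]])
        assert frequency_f_stats(y)[0] == pytest.approx(3.0, abs=1e-12)

    def test_two_conditions_equals_squared_paired_t(self, rng):
        from scipy import stats as sstats

        y = rng.standard_normal((8, 2, 5))
        f = frequency_f_stats(y)
        for k in range(5):
            t, _ = sstats.ttest_rel(y[:, 0, k], y[:, 1, k])
            assert f[k] == pytest.approx(t**2, abs=1e-9)

    def test_degenerate_returns_zero_with_warning(self):
        y = np.ones((4, 3))
        with pytest.warns(UserWarning, match="degenerate"):
            assert frequency_f_stats(y)[0] == 0.0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            frequency_f_stats(np.ones((1, 2, 3)))


class TestClusters:
    def test_toy_run_finding(self):
        f = np.array([1, 5, 6, 2, 7, 8, 9, 1])
        assert find_clusters(f, 4.0) == [(1, 2), (4, 6)]

    def test_merge_nearby(self):
        # gap of one scale merges; larger gaps stay separate
        assert _merge_clusters([(1, 2), (4, 6)], max_gap=1) == [(1, 6)]
        assert _merge_clusters([(1, 2), (5, 6)], max_gap=1) == [(1, 2), (5, 6)]


class TestBandSelection:
    def test_recovers_injected_band(self, rng):
        """A condition effect confined to scales 10-14 is selected."""
        n_dyads, n_scales = 12, 30
        y = rng.standard_normal((n_dyads, 2, n_scales)) * 0.3
        y[:, 1, 10:15] += 2.0
        freqs = np.geomspace(0.1, 0.01, n_scales)
        res = permutation_band_selection(y, freqs, n_perm=300, seed=5)
        assert res.n_bands >= 1
        sel_f = [f for lo, hi in res.merged_bands
                 for f in freqs if lo - 1e-12 <= f <= hi + 1e-12]
        assert any(np.isclose(sel_f, freqs[12]).tolist())

    def test_seed_required(self, rng):
        y = rng.standard_normal((4, 2, 6))
        with pytest.raises(ValueError, match="seed"):
            permutation_band_selection(y, np.linspace(0.1, 0.01, 6))

    def test_reproducible(self, rng):
        y = rng.standard_normal((6, 2, 10))
        freqs = np.geomspace(0.1, 0.01, 10)
        r1 = permutation_band_selection(y, freqs, n_perm=200, seed=9)
        r2 = permutation_band_selection(y, freqs, n_perm=200, seed=9)
        assert r1.threshold == r2.threshold
        assert r1.merged_bands == r2.merged_bands


class TestPairedConditionTest:
    def test_zero_differences(self):
        vals = {(("CH1", "CH1"), 0): np.array([1.0, 2.0, 3.0])}
        res = paired_condition_test(vals, vals)
        assert res.t_values[(("CH1", "CH1"), 0)] == 0.0
        assert res.p_values[(("CH1", "CH1"), 0)] == 1.0

    def test_hand_computed_t(self):
        """Differences {1, 2, 3}: t = 2*sqrt(3), two-sided p from t(2)."""
        key = (("CH1", "CH2"), 3)
        a = {key: np.array([2.0, 4.0, 6.0])}
        b = {key: np.array([1.0, 2.0, 3.0])}
        res = paired_condition_test(a, b)
        assert res.t_values[key] == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.p_values[key] == pytest.approx(0.07417990022744857,
                                                  abs=1e-9)

    def test_full_scan_family_size(self, rng):
        pairs = [(f"CH{i}", f"CH{j}") for i in range(1, 27)
                 for j in range(1, 27)]
        lags = range(-26, 27)
        assert len(pairs) * len(list(lags)) == 35828

    def test_bonferroni_monotonicity(self, rng):
        """Adding comparisons to the family never creates new
        significant results."""
        keys = [(("CH1", f"CH{j}"), 0) for j in range(1, 9)]
        a = {k: rng.standard_normal(6) for k in keys}
        b = {k: rng.standard_normal(6) for k in keys}
        a[keys[0]] = b[keys[0]] + 1.0  # strong effect at one key
        small = paired_condition_test({keys[0]: a[keys[0]]},
                                      {keys[0]: b[keys[0]]})
        full = paired_condition_test(a, b)
        assert set(full.significant) <= set(small.significant)

    def test_dyad_mismatch_rejected(self):
        key = (("CH1", "CH1"), 0)
        with pytest.raises(ValueError):
            paired_condition_test({key: np.ones(4)}, {key: np.ones(5)})


class TestPseudoPair:
    def test_exhaustive_three_dyads(self, rng):
        """With 3 dyads the null has 3! = 6 pairings (identity included)
        and must equal direct enumeration."""
        M = rng.standard_normal((3, 3))

        def stat(assign):
            return float(np.mean([M[i, j] for i, j in enumerate(assign)]))

        res = pseudo_pair_permutation(stat, n_dyads=3, n_perm=1000, seed=0)
        assert res["exhaustive"]
        expected = sorted(
            float(np.mean([M[i, j] for i, j in enumerate(p)]))
            for p in itertools.permutations(range(3))
        )
        np.testing.assert_allclose(sorted(res["null"]), expected, atol=1e-12)
        assert res["observed"] in res["null"]

    def test_true_coupling_is_extreme(self, rng):
        """When only true pairings carry signal, the observed statistic
        sits in the tail of the pseudo-pair null."""
        n = 6
        M = rng.standard_normal((n, n)) * 0.1
        M[np.diag_indices(n)] += 3.0

        def stat(assign):
            return float(np.mean([M[i, j] for i, j in enumerate(assign)]))

        res = pseudo_pair_permutation(stat, n_dyads=n, n_perm=720, seed=1)
        assert res["significant"]
        assert res["p_two_tailed"] < 0.05

    def test_sampling_flag_when_overdrawn(self, rng):
        M = rng.standard_normal((4, 4))

        def stat(assign):
            return float(M[0, assign[0]])

        res = pseudo_pair_permutation(stat, n_dyads=4, n_perm=100, seed=2,
                                      exhaustive=False)
        assert res["sampled_with_replacement"]


class TestScoreCorrelation:
    def test_perfect_linear(self):
        r, p = score_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_five_points(self):
        """{(1,2),(2,4),(3,5),(4,4),(5,5)}: r = sqrt(0.6) by direct
        computation of the covariance quotient."""
        r, p = score_correlation([1, 2, 3, 4, 5], [2, 4, 5, 4, 5])
        assert r == pytest.approx(0.7745966692414834, abs=1e-9)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            score_correlation([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestPermutationCalibration:
    def test_type_i_error_at_ins_level(self, rng):
        """Under an exchangeable null the band search fires at roughly
        its nominal 1% rate (checked on synthetic INS arrays, which
        isolates the permutation logic from the wavelet stage)."""
        from scipy import stats as sstats

        n_runs, hits = 150, 0
        freqs = np.geomspace(0.1, 0.01, 16)
        for run in range(n_runs):
            y = rng.standard_normal((8, 2, 16))
            res = permutation_band_selection(y, freqs, n_perm=120,
                                             seed=1000 + run)
            hits += res.n_bands > 0
        lo, hi = sstats.binom.interval(0.999, n_runs, 0.01)
        assert lo <= hits <= hi
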