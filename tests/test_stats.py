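"""Bootstrapped Bayes factors: resampling, exceedance, labels, clusters."""

import numpy as np
import pytest
from scipy.stats import norm

import ssvepbf as s
from ssvepbf.errors import ConfigurationError, DegenerateDataError
from ssvepbf.stats import (ClusterSummary, _resample_counts, bootstrap_effect,
                           exceedance_probability, jeffreys_label,
                           log_bayes_factor, paired_ttest, permutation_null,
                           transitive_bf, ztransform_joint)


def brute_force_exceedance(e, n):
    """O(B^2) oracle for the all-pairs strictly-greater fraction."""
    return sum(1 for ei in e for nj in n if ei > nj) / (len(e) * len(n))


class TestBootstrap:
    def test_identical_subjects_give_constant_draws(self):
        d = np.tile([[1.5, -2.0]], (6, 1))
        draws = bootstrap_effect(d, n_boot=50, rng=0)
        np.testing.assert_allclose(draws, np.tile([1.5, -2.0], (50, 1)))

    def test_draw_mean_approaches_sample_mean(self, rng):
        d = rng.standard_normal((12, 3)) + 1.0
        draws = bootstrap_effect(d, n_boot=2000, rng=1)
        se = d.std(axis=0, ddof=1) / np.sqrt(12)
        # bootstrap mean within 3 monte-carlo SEs of the sample mean
        np.testing.assert_allclose(draws.mean(axis=0), d.mean(axis=0),
                                   atol=3 * se.max() / np.sqrt(2000) * 3)

    def test_seed_reproducibility(self, rng):
        d = rng.standard_normal((8, 5))
        a = bootstrap_effect(d, 100, np.random.default_rng(42))
        b = bootstrap_effect(d, 100, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_counts_matrix_rows_sum_to_n(self):
        counts = _resample_counts(9, 40, np.random.default_rng(0))
        np.testing.assert_array_equal(counts.sum(axis=1), 9.0)

    def test_too_few_subjects(self):
        with pytest.raises(ConfigurationError):
            bootstrap_effect(np.ones((1, 3)), 10, 0)


class TestPermutationNull:
    def test_null_mean_near_zero(self, rng):
        d = rng.standard_normal((10, 4)) + 5.0  # strong effect
        draws = permutation_null(d, n_boot=4000, rng=2)
        # sign-flipping destroys the location
        assert np.abs(draws.mean(axis=0)).max() < 5 * draws.std(axis=0).max() / np.sqrt(4000) * 5

    def test_null_variance_closed_form(self, rng):
        """Variance of the sign-flipped bootstrap mean.

        Sign flips alone give (sum d_i^2 / n) / n; resampling subjects
        with replacement on top multiplies it by E[c_i^2] = 2 - 1/n
        (multinomial second moment), since the cross terms vanish under
        independent signs.
        """
        n = 15
        d = rng.standard_normal((n, 1)) * 2.0
        draws = permutation_null(d, n_boot=20000, rng=3)
        want = (2 - 1 / n) * np.sum(d**2) / n**2
        assert draws.var() == pytest.approx(want, rel=0.05)

    def test_seed_reproducibility(self, rng):
        d = rng.standard_normal((8, 5))
        a = permutation_null(d, 100, np.random.default_rng(42))
        b = permutation_null(d, 100, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)


class TestExceedance:
    def test_sorted_rank_equals_brute_force_exactly(self, rng):
        for trial in range(5):
            e = rng.standard_normal(200)
            n = rng.standard_normal(200)
            assert exceedance_probability(e, n) == brute_force_exceedance(e, n)

    def test_ties_do_not_count(self):
        e = np.array([1.0, 1.0, 2.0])
        n = np.array([1.0, 0.0])
        assert exceedance_probability(e, n) == brute_force_exceedance(e, n) == 4 / 6

    def test_identical_distributions_bf_zero(self):
        x = np.arange(100.0)
        # identical draw sets: p = (B^2 - B)/2 / B^2 ~ 0.5, BF ~ 1
        assert abs(log_bayes_factor(x, x)) < 0.01

    def test_total_separation_hits_clip_bound(self):
        e = np.full(2000, 10.0)
        n = np.zeros(2000)
        assert log_bayes_factor(e, n) == pytest.approx(np.log10(2000), abs=1e-12)
        assert log_bayes_factor(n, e) == pytest.approx(-np.log10(2000), abs=1e-12)

    def test_gaussian_closed_form(self, rng):
        """effect ~ N(d, s^2), null ~ N(0, s^2): p -> Phi(d / (s*sqrt(2)))."""
        d, sig = 0.8, 1.3
        e = rng.normal(d, sig, 20000)
        n = rng.normal(0, sig, 20000)
        assert exceedance_probability(e, n) == pytest.approx(
            norm.cdf(d / (sig * np.sqrt(2))), abs=0.01
        )

    def test_non_finite_draws_rejected(self):
        with pytest.raises(DegenerateDataError):
            exceedance_probability(np.array([np.nan]), np.array([0.0]))


class TestJeffreysLabels:
    @pytest.mark.parametrize(
        "value, label",
        [
            (2.22, "decisive"),   # early conditioning peak magnitude
            (2.0, "decisive"),
            (1.84, "very strong"),
            (1.5, "very strong"),
            (1.2, "strong"),
            (0.7, "substantial"),
            (0.49, "anecdotal/none"),
            (-1.0, "anecdotal/none"),
        ],
    )
    def test_scale_boundaries(self, value, label):
        assert jeffreys_label(value) == label

    def test_vectorised(self):
        out = jeffreys_label(np.array([2.4, 0.1]))
        assert out.tolist() == ["decisive", "anecdotal/none"]


class TestTransitive:
    def test_subtraction_rule_and_antisymmetry(self, rng):
        a = rng.standard_normal((4, 6))
        b = rng.standard_normal((4, 6))
        t = transitive_bf(a, b)
        np.testing.assert_allclose(t, a - b)
        np.testing.assert_allclose(transitive_bf(b, a), -t)
        np.testing.assert_array_equal(transitive_bf(a, a), 0.0)

    def test_magnitude_example(self):
        assert transitive_bf(np.array(2.4), np.array(0.0)) == pytest.approx(2.40)

    def test_grid_mismatch(self):
        with pytest.raises(ConfigurationError):
            transitive_bf(np.zeros((2, 2)), np.zeros((3, 2)))


class TestZTransform:
    def test_pooled_moments_and_rank_preservation(self, rng):
        e = rng.normal(2, 3, 500)
        n = rng.normal(0, 1, 400)
        ze, zn = ztransform_joint(e, n)
        pooled = np.concatenate([ze, zn])
        assert pooled.mean() == pytest.approx(0.0, abs=1e-12)
        assert pooled.std() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(np.argsort(ze), np.argsort(e))
        # exceedance p invariant under the common monotone map
        assert exceedance_probability(ze, zn) == exceedance_probability(e, n)

    def test_zero_pooled_sd(self):
        with pytest.raises(DegenerateDataError):
            ztransform_joint(np.ones(5), np.ones(5))


class TestPairedTTest:
    def test_hand_computed_example(self):
        r = paired_ttest(np.array([1.0, 2.0, 3.0]))
        assert r.t == pytest.approx(2 * np.sqrt(3))
        assert r.df == 2
        assert r.cohens_d == pytest.approx(2.0)

    def test_identical_pairs(self):
        r = paired_ttest(np.array([4.0, 4.0, 4.0]), np.array([4.0, 4.0, 4.0]))
        assert r.t == 0.0 and r.cohens_d == 0.0

    def test_df_is_n_minus_one(self, rng):
        r = paired_ttest(rng.standard_normal(50), rng.standard_normal(50))
        assert r.df == 49

    def test_matches_scipy(self, rng):
        from scipy.stats import ttest_rel

        x, y = rng.standard_normal(20), rng.standard_normal(20)
        r = paired_ttest(x, y)
        ref = ttest_rel(x, y)
        assert r.t == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)


class TestModelResults:
    def _fit(self, diff, **kw):
        model = s.ConditioningBFModel(diff, times_ms=np.arange(diff.shape[2]) * 100.0)
        return model.fit(n_boot=400, n_null=400, seed=5, **kw)

    def test_monotone_in_effect_size(self, rng):
        noise = rng.standard_normal((10, 1, 1))
        bfs = []
        for shift in (0.0, 0.4, 0.8, 1.6):
            res = self._fit(noise + shift)
            bfs.append(res.log10_bf[0, 0])
        assert all(b2 >= b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_fit_reproducible_and_draws_recoverable(self, rng):
        diff = rng.standard_normal((8, 2, 3)) + 0.5
        r1 = self._fit(diff)
        r2 = self._fit(diff)
        np.testing.assert_array_equal(r1.log10_bf, r2.log10_bf)
        e1, n1 = r1.draws_at(0, 100.0)
        r3 = self._fit(diff, keep_draws=True)
        e3, n3 = r3.draws_at(0, 100.0)
        np.testing.assert_array_equal(e1, e3)
        np.testing.assert_array_equal(n1, n3)

    def test_direction_modes(self, rng):
        diff = rng.standard_normal((12, 1, 1)) - 1.0  # negative effect
        model = s.ConditioningBFModel(diff)
        greater = model.fit(300, 300, seed=1).log10_bf[0, 0]
        less = s.ConditioningBFModel(diff, direction="less").fit(300, 300, seed=1)
        two = s.ConditioningBFModel(diff, direction="two_sided").fit(300, 300, seed=1)
        assert greater < 0 < less.log10_bf[0, 0]
        assert two.log10_bf[0, 0] == pytest.approx(less.log10_bf[0, 0])

    def test_cluster_summary_exact_block(self, montage32):
        """A supra-threshold block at 5 adjacent occipital sensors comes
        back as exactly one cluster with exactly those sensors."""
        ids = montage32.ids
        times = np.arange(0, 1001, 100.0)
        bf = np.zeros((32, len(times)))
        block = ["65", "66", "69", "70", "75"]
        for sid in block:
            bf[ids.index(sid)] = 2.5
        res = _make_results(bf, ids, times)
        clusters = res.clusters((0, 1000), montage32, threshold=2.0)
        assert len(clusters) == 1
        assert sorted(clusters[0].sensors) == sorted(block)
        assert clusters[0].window_avg_log10_bf == pytest.approx(2.5)

    def test_cluster_threshold_is_strict(self, montage32):
        ids = montage32.ids
        times = np.arange(0, 1001, 100.0)
        bf = np.zeros((32, len(times)))
        bf[ids.index("75")] = 2.0  # exactly at threshold: excluded
        res = _make_results(bf, ids, times)
        assert res.clusters((0, 1000), montage32, threshold=2.0) == []

    def test_all_zero_map_no_clusters(self, montage32):
        times = np.arange(0, 1001, 100.0)
        res = _make_results(np.zeros((32, len(times))), montage32.ids, times)
        assert res.clusters((0, 1000), montage32) == []

    def test_peak_latency_constrained_to_window(self, montage32):
        ids = montage32.ids
        times = np.arange(0, 2001, 100.0)
        bf = np.zeros((32, len(times)))
        i = ids.index("75")
        bf[i, :] = 2.5
        bf[i, times == 1800.0] = 9.9  # larger peak outside the window
        res = _make_results(bf, ids, times)
        (c,) = res.clusters((0, 1000), montage32)
        assert c.peak_latency_ms <= 1000.0
        assert c.peak_log10_bf == pytest.approx(2.5)

    def test_transitive_on_results_antisymmetric(self, rng):
        d1 = rng.standard_normal((8, 3, 4)) + 0.3
        d2 = rng.standard_normal((8, 3, 4))
        r1, r2 = self._fit(d1), self._fit(d2)
        np.testing.assert_allclose(r1.transitive(r2), -r2.transitive(r1))

    def test_summary_mentions_peak(self, rng):
        res = self._fit(rng.standard_normal((8, 2, 3)) + 1.0)
        text = res.summary(windows={"early": (0.0, 200.0)})
        assert "peak log10BF" in text and "effect draws: 400" in text


def _make_results(bf, ids, times):
    diff = np.zeros((2, bf.shape[0], bf.shape[1]))
    model = s.ConditioningBFModel(diff, channel_ids=ids, times_ms=times)
    return s.BFMapResults(model=model, log10_bf=bf, exceedance_p=np.full_like(bf, 0.5),
                          n_boot=10, n_null=10)
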