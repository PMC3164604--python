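import math
import subprocess

import numpy as np
import pytest
from scipy import stats

from bmfilter import (
    DataError,
    ModeratedTParams,
    chi_squared,
    discretize,
    estimate_variance_prior,
    info_gain,
    moderated_t,
    relief_f,
    welch_t,
    window_t,
)
from bmfilter.comparators import Discretization, pooled_variance

from conftest import build_dataset


def binary_dataset(ctr_zeros, ctr_ones, exp_zeros, exp_ones):
    """One 0/1-valued feature realizing a fixed bins x groups table."""
    ctr = [0.0] * ctr_zeros + [1.0] * ctr_ones
    exp = [0.0] * exp_zeros + [1.0] * exp_ones
    ds = build_dataset([ctr], [exp])
    disc = Discretization(method="equal_width", cuts=[np.array([0.5])])
    return ds, disc


class TestInfoGain:
    def test_perfect_alignment_one_bit(self):
        ds, disc = binary_dataset(5, 0, 0, 5)
        assert info_gain(ds, disc).scores[0] == pytest.approx(1.0)

    def test_independent_feature_zero(self):
        ds, disc = binary_dataset(5, 5, 5, 5)
        assert info_gain(ds, disc).scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_partial_alignment_entropy_arithmetic(self):
        # counts [[8,2],[2,8]] -> IG = 1 - H(0.8)
        ds, disc = binary_dataset(8, 2, 2, 8)
        h08 = -(0.8 * math.log2(0.8) + 0.2 * math.log2(0.2))
        assert info_gain(ds, disc).scores[0] == pytest.approx(1 - h08, abs=1e-12)

    def test_single_bin_scores_zero(self):
        ds = build_dataset([[1, 2, 3]], [[4, 5, 6]])
        disc = Discretization(method="mdl", cuts=[np.array([])])
        assert info_gain(ds, disc).scores[0] == 0.0

    def test_nonnegative_on_random_data(self):
        rng = np.random.default_rng(0)
        ds = build_dataset(rng.normal(8, 1, (20, 8)), rng.normal(8, 1, (20, 8)))
        assert (info_gain(ds, discretize(ds, "equal_width", bins=4)).scores >= 0).all()


class TestChiSquared:
    def test_observed_equals_expected_zero(self):
        ds, disc = binary_dataset(10, 10, 10, 10)
        assert chi_squared(ds, disc).scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_shortcut(self):
        # [[20,10],[10,20]] -> n(ad-bc)^2/(r1 r2 c1 c2) = 20/3
        ds, disc = binary_dataset(20, 10, 10, 20)
        assert chi_squared(ds, disc).scores[0] == pytest.approx(20 / 3, abs=1e-9)

    def test_matches_scipy_without_correction(self):
        ds, disc = binary_dataset(13, 4, 6, 11)
        expected = stats.chi2_contingency(
            np.array([[13, 6], [4, 11]]), correction=False
        ).statistic
        assert chi_squared(ds, disc).scores[0] == pytest.approx(expected, abs=1e-10)

    def test_empty_bin_dropped_without_effect(self):
        ds, _ = binary_dataset(20, 10, 10, 20)
        disc1 = Discretization("equal_width", [np.array([0.5])])
        disc2 = Discretization("equal_width", [np.array([-1.0, 0.5])])  # empty first bin
        assert chi_squared(ds, disc1).scores[0] == pytest.approx(
            chi_squared(ds, disc2).scores[0], abs=1e-12
        )


def relief_oracle(values, y, k):
    """Exhaustive Relief-F with m = all probes (pure-python enumeration)."""
    values = np.asarray(values, float)
    nf, n = values.shape
    X = np.zeros_like(values)
    for f in range(nf):
        lo, hi = values[f].min(), values[f].max()
        if hi > lo:
            X[f] = (values[f] - lo) / (hi - lo)
    w = np.zeros(nf)
    for i in range(n):
        dists = [(sum(abs(X[f, i] - X[f, j]) for f in range(nf)), j)
                 for j in range(n) if j != i]
        hits = sorted((d, j) for d, j in dists if y[j] == y[i])[:k]
        misses = sorted((d, j) for d, j in dists if y[j] != y[i])[:k]
        for f in range(nf):
            w[f] += sum(abs(X[f, i] - X[f, j]) for _, j in misses) / len(misses)
            w[f] -= sum(abs(X[f, i] - X[f, j]) for _, j in hits) / len(hits)
    return w / n


class TestReliefF:
    def test_separating_vs_constant_feature(self):
        ds = build_dataset([[1, 2, 3, 2], [5, 5, 5, 5]], [[8, 9, 10, 9], [5, 5, 5, 5]])
        t = relief_f(ds, k=2)
        assert t.scores[0] > 0 and t.scores[1] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        ctr = rng.normal(0, 1, (2, 3))
        exp = rng.normal(1, 1, (2, 3))
        ds = build_dataset(ctr, exp)
        expected = relief_oracle(ds.values, ds.y, k=1)
        np.testing.assert_allclose(relief_f(ds, k=1).scores, expected, atol=1e-12)

    def test_duplicated_samples_match_oracle(self):
        rng = np.random.default_rng(4)
        ctr = rng.normal(0, 1, (2, 3))
        exp = rng.normal(1.5, 1, (2, 3))
        base = build_dataset(ctr, exp)
        dup = build_dataset(np.hstack([ctr, ctr]), np.hstack([exp, exp]))
        w_dup = relief_f(dup, k=1).scores
        np.testing.assert_allclose(w_dup, relief_oracle(dup.values, dup.y, 1), atol=1e-12)
        # ranking of the informative feature is preserved
        assert np.argmax(w_dup) == np.argmax(relief_f(base, k=1).scores)

    def test_k_too_large_rejected(self):
        ds = build_dataset([[1, 2, 3]], [[4, 5, 6]])
        with pytest.raises(DataError, match="k=3"):
            relief_f(ds, k=3)

    def test_weights_bounded(self):
        rng = np.random.default_rng(9)
        ds = build_dataset(rng.normal(0, 1, (5, 10)), rng.normal(0.5, 2, (5, 10)))
        w = relief_f(ds, k=3).scores
        assert (w >= -1).all() and (w <= 1).all()


class TestWelchT:
    def test_closed_form(self):
        ds = build_dataset([[1, 2, 3]], [[4, 5, 6]])
        assert welch_t(ds).scores[0] == pytest.approx(3 / math.sqrt(2 / 3), abs=1e-9)

    def test_matches_scipy(self):
        rng = np.random.default_rng(2)
        ctr, exp = rng.normal(8, 1, (6, 9)), rng.normal(8.4, 1.5, (6, 7))
        ds = build_dataset(ctr, exp)
        expected = np.abs(stats.ttest_ind(exp, ctr, axis=1, equal_var=False).statistic)
        np.testing.assert_allclose(welch_t(ds).scores, expected, atol=1e-10)

    def test_identical_groups_zero(self):
        ds = build_dataset([[1, 2, 3]], [[1, 2, 3]])
        assert welch_t(ds).scores[0] == 0.0

    def test_label_swap_flips_direction_keeps_rank(self):
        rng = np.random.default_rng(8)
        ctr, exp = rng.normal(8, 1, (4, 6)), rng.normal(9, 1, (4, 6))
        fwd = welch_t(build_dataset(ctr, exp))
        rev = welch_t(build_dataset(exp, ctr))
        np.testing.assert_allclose(fwd.scores, rev.scores, atol=1e-12)
        np.testing.assert_array_equal(fwd.ranks, rev.ranks)
        flip = {"up": "down", "down": "up", "none": "none"}
        assert [flip[d] for d in fwd.directions] == rev.directions

    def test_zero_variance_convention(self):
        ds = build_dataset([[2, 2, 2], [2, 2, 2]], [[5, 5, 5], [2, 2, 2]])
        t = welch_t(ds)
        assert t.scores[0] == np.inf and t.scores[1] == 0.0


class TestModeratedT:
    def test_d0_zero_recovers_student_t(self):
        rng = np.random.default_rng(3)
        ds = build_dataset(rng.normal(8, 1, (10, 6)), rng.normal(8.5, 1, (10, 6)))
        table, _ = moderated_t(ds, ModeratedTParams(d0=0.0, s0_sq=1.0))
        s2, df = pooled_variance(ds)
        m_ctr = ds.values[:, ds.control_mask].mean(axis=1)
        m_exp = ds.values[:, ds.experiment_mask].mean(axis=1)
        student = np.abs((m_exp - m_ctr) / np.sqrt(s2 * (1 / 6 + 1 / 6)))
        np.testing.assert_allclose(table.scores, student, atol=1e-10)

    def test_d0_infinite_ranks_by_mean_difference(self):
        rng = np.random.default_rng(6)
        ds = build_dataset(rng.normal(8, 1, (15, 6)), rng.normal(8, 1.4, (15, 6)))
        table, _ = moderated_t(ds, ModeratedTParams(d0=math.inf, s0_sq=2.0))
        m_ctr = ds.values[:, ds.control_mask].mean(axis=1)
        m_exp = ds.values[:, ds.experiment_mask].mean(axis=1)
        from bmfilter.data_model import rank_descending

        np.testing.assert_array_equal(table.ranks, rank_descending(np.abs(m_exp - m_ctr)))

    def test_homogeneous_variances_give_infinite_prior(self):
        # all gene variances exactly equal -> complete shrinkage, no crash
        base = np.array([1.0, 2.0, 3.0, 4.0])
        ds = build_dataset([base, base + 1], [base + 2, base + 5])
        table, params = moderated_t(ds)
        assert math.isinf(params.d0)
        # complete shrinkage: s0^2 is the bias-corrected geometric mean variance
        from scipy.special import digamma

        s2, df = pooled_variance(ds)
        expected = s2[0] * math.exp(math.log(df / 2) - digamma(df / 2))
        assert params.s0_sq == pytest.approx(expected)
        assert np.isfinite(table.scores).all()

    def test_prior_recovery_from_inverse_chisq(self):
        # genes simulated from the model's own prior: d0=4, s0^2=1, n=10+10
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sigma2 = 1.0 * 4.0 / rng.chisquare(4.0, 500)
            vals = rng.normal(0, np.sqrt(sigma2)[:, None], (500, 20))
            ds = build_dataset(vals[:, :10], vals[:, 10:])
            p = estimate_variance_prior(*pooled_variance(ds))
            if 2.5 <= p.d0 <= 6.5 and 0.7 <= p.s0_sq <= 1.4:
                hits += 1
        assert hits >= 9

    def test_matches_limma_squeezevar(self, tmp_path):
        """Independent cross-check of the empirical-Bayes fit against limma."""
        rng = np.random.default_rng(42)
        sigma2 = 1.0 * 4.0 / rng.chisquare(4.0, 150)
        vals = rng.normal(0, np.sqrt(sigma2)[:, None], (150, 12))
        ds = build_dataset(vals[:, :6], vals[:, 6:])
        s2, df = pooled_variance(ds)
        np.savetxt(tmp_path / "s2.txt", s2)
        script = (
            f's2 <- scan("{tmp_path}/s2.txt", quiet=TRUE);'
            "suppressMessages(library(limma));"
            f"out <- squeezeVar(s2, df={df});"
            'cat(sprintf("%.10f %.10f\\n", out$df.prior, out$var.prior));'
            'cat(sprintf("%.10f\\n", out$var.post))'
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        lines = res.stdout.strip().splitlines()
        d0_r, s0_r = map(float, lines[0].split())
        post_r = np.array([float(x) for x in lines[1:]])
        params = estimate_variance_prior(s2, df)
        assert params.d0 == pytest.approx(d0_r, rel=1e-6)
        assert params.s0_sq == pytest.approx(s0_r, rel=1e-6)
        post_py = (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)
        np.testing.assert_allclose(post_py, post_r, rtol=1e-6)


class TestWindowT:
    def test_window_one_equals_student_t(self):
        rng = np.random.default_rng(5)
        ds = build_dataset(rng.normal(8, 1, (12, 5)), rng.normal(8.3, 1, (12, 5)))
        s2, _ = pooled_variance(ds)
        m_ctr = ds.values[:, ds.control_mask].mean(axis=1)
        m_exp = ds.values[:, ds.experiment_mask].mean(axis=1)
        student = np.abs((m_exp - m_ctr) / np.sqrt(s2 * (1 / 5 + 1 / 5)))
        np.testing.assert_allclose(window_t(ds, window=1).scores, student, atol=1e-10)

    def test_full_window_ranks_by_mean_difference(self):
        rng = np.random.default_rng(7)
        ds = build_dataset(rng.normal(8, 1, (9, 6)), rng.normal(8, 1.2, (9, 6)))
        table = window_t(ds, window=2 * 9 - 1)
        m_ctr = ds.values[:, ds.control_mask].mean(axis=1)
        m_exp = ds.values[:, ds.experiment_mask].mean(axis=1)
        from bmfilter.data_model import rank_descending

        np.testing.assert_array_equal(table.ranks, rank_descending(np.abs(m_exp - m_ctr)))

    def test_smoothed_variance_moving_average_oracle(self):
        rng = np.random.default_rng(1)
        ds = build_dataset(rng.normal(8, 1, (5, 4)), rng.normal(8.5, 1, (5, 4)))
        s2, _ = pooled_variance(ds)
        order = np.argsort(ds.values.mean(axis=1), kind="stable")
        s2_sorted = s2[order]
        # window=3 truncated moving average, by explicit enumeration
        expected_sorted = np.array(
            [s2_sorted[max(0, p - 1): p + 2].mean() for p in range(5)]
        )
        m_ctr = ds.values[:, ds.control_mask].mean(axis=1)
        m_exp = ds.values[:, ds.experiment_mask].mean(axis=1)
        smoothed = np.empty(5)
        smoothed[order] = expected_sorted
        expected_t = np.abs((m_exp - m_ctr) / np.sqrt(smoothed * 0.5))
        np.testing.assert_allclose(window_t(ds, window=3).scores, expected_t, atol=1e-12)

    def test_even_window_rounded_up(self):
        rng = np.random.default_rng(2)
        ds = build_dataset(rng.normal(8, 1, (6, 4)), rng.normal(8, 1, (6, 4)))
        np.testing.assert_allclose(
            window_t(ds, window=2).scores, window_t(ds, window=3).scores
        )


class TestDiscretize:
    def test_mdl_accepts_perfect_split(self):
        ds = build_dataset([[1, 2, 3, 4, 5]], [[10, 11, 12, 13, 14]])
        cuts = discretize(ds, "mdl").cuts[0]
        assert len(cuts) == 1 and 5 < cuts[0] < 10

    def test_mdl_rejects_noise(self):
        rejections = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ds = build_dataset([rng.normal(0, 1, 15)], [rng.normal(0, 1, 15)])
            if len(discretize(ds, "mdl").cuts[0]) == 0:
                rejections += 1
        assert rejections >= 8

    def test_equal_width_cut_arithmetic(self):
        ds = build_dataset([[0.0, 2.0, 4.0]], [[6.0, 7.0, 8.0]])
        np.testing.assert_allclose(
            discretize(ds, "equal_width", bins=4).cuts[0], [2.0, 4.0, 6.0]
        )

    def test_equal_width_needs_two_bins(self):
        ds = build_dataset([[1, 2, 3]], [[4, 5, 6]])
        with pytest.raises(ValueError, match="bins"):
            discretize(ds, "equal_width", bins=1)


class TestSharedProperties:
    METHODS = {
        "ig": lambda d: info_gain(d, discretize(d, "equal_width", bins=4)),
        "chi2": lambda d: chi_squared(d, discretize(d, "equal_width", bins=4)),
        "relieff": lambda d: relief_f(d, k=2),
        "ttest": welch_t,
        "modt": lambda d: moderated_t(d)[0],
        "windowt": lambda d: window_t(d, window=3),
    }

    @pytest.mark.parametrize("method", sorted(METHODS))
    def test_sample_permutation_leaves_scores_unchanged(self, method):
        rng = np.random.default_rng(10)
        ds = build_dataset(rng.normal(8, 1, (8, 6)), rng.normal(8.5, 1.2, (8, 6)))
        perm = np.random.default_rng(0).permutation(ds.n_samples)
        shuffled = ds.subset_samples(np.ones(ds.n_samples, bool))
        shuffled.values = ds.values[:, perm]
        shuffled.sample_ids = [ds.sample_ids[i] for i in perm]
        base = self.METHODS[method](ds).scores
        np.testing.assert_allclose(self.METHODS[method](shuffled).scores, base, atol=1e-9)

    @pytest.mark.parametrize("method", sorted(METHODS))
    def test_feature_permutation_permutes_scores(self, method):
        rng = np.random.default_rng(12)
        ds = build_dataset(rng.normal(8, 1, (8, 6)), rng.normal(8.5, 1.2, (8, 6)))
        perm = np.random.default_rng(1).permutation(ds.n_features)
        permuted = ds.subset_features([ds.feature_ids[i] for i in perm])
        base = self.METHODS[method](ds).scores
        np.testing.assert_allclose(self.METHODS[method](permuted).scores, base[perm], atol=1e-9)

    def test_t_family_agrees_under_homoscedastic_balance(self):
        # equal gene variances + balanced groups: all t variants rank by |dmean|
        base = np.array([1.0, 2.0, 3.0, 4.0])
        ctr = np.stack([base, base + 1, base - 1])
        exp = np.stack([base + 2, base + 0.5, base + 4])
        ds = build_dataset(ctr, exp)
        r1 = welch_t(ds).ranks
        r2 = moderated_t(ds)[0].ranks
        r3 = window_t(ds, window=5).ranks
        np.testing.assert_array_equal(r1, r2)
        np.testing.assert_array_equal(r2, r3)
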