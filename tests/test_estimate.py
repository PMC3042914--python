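"""Reweighting, blocking errors, the modified-Gumbel fit, p-/E-values."""

import math

import numpy as np
import pytest

from raretail.estimate import (
    DistributionEstimate,
    ModifiedGumbelFit,
    blocking_errors,
    estimate_from_scores,
    evalue,
    fit_modified_gumbel,
    interpolate_params,
    pvalue,
    reweight,
)
from raretail.wang_landau import ScoreHistogram, ScoreWindow


def _make_hist(counts, log_w=None, series=None):
    counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    window = ScoreWindow(0, counts.shape[1] - 1, tuple(range(counts.shape[0])))
    return ScoreHistogram(
        window=window,
        counts=counts,
        log_w=np.zeros_like(counts, dtype=float) if log_w is None else log_w,
        n_samples=int(counts.sum()),
        thinning=1,
        series=series,
    )


class TestReweight:
    def test_uniform_weights_give_relative_counts(self):
        est = reweight(_make_hist([10, 30, 60]))
        assert np.allclose(np.exp(est.log_prob[0]), [0.1, 0.3, 0.6])

    def test_weights_divided_out_in_log_domain(self):
        # equal counts under weights spanning 40+ decades: the estimate is
        # proportional to 1/w, far beyond what linear arithmetic could hold
        log_w = np.array([[0.0, 50.0, 100.0]])
        est = reweight(_make_hist([100, 100, 100], log_w=log_w))
        lp = est.log_prob[0]
        assert lp[1] - lp[0] == pytest.approx(-50.0, abs=1e-9)
        assert lp[2] - lp[0] == pytest.approx(-100.0, abs=1e-9)
        assert est.total() == pytest.approx(1.0, abs=1e-9)

    def test_normalization_always_one(self, rng):
        counts = rng.integers(0, 50, size=(3, 8))
        counts[0, 0] = 5
        est = reweight(_make_hist(counts, log_w=rng.normal(size=(3, 8))))
        assert est.total() == pytest.approx(1.0, abs=1e-9)

    def test_marginal_equals_class_sum(self, rng):
        counts = rng.integers(1, 50, size=(3, 5))
        est = reweight(_make_hist(counts))
        marg = np.exp(est.log_prob_marginal)
        direct = np.exp(est.log_prob).sum(axis=0)
        assert np.allclose(marg, direct, rtol=1e-12)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            reweight(_make_hist([0, 0, 0]))


class TestBlockingErrors:
    def test_iid_gaussian_plateau_is_sigma_over_sqrt_n(self, rng):
        n, sigma = 2**14, 2.0
        series = rng.normal(0, sigma, size=n)
        out = blocking_errors(series)
        assert out.converged
        assert out.plateau == pytest.approx(sigma / math.sqrt(n), rel=0.2)

    def test_constant_series_has_zero_error(self):
        out = blocking_errors(np.full(1024, 3.14))
        assert out.plateau == 0.0

    def test_ar1_plateau_matches_effective_variance(self, rng):
        rho, sigma, n = 0.9, 1.0, 2**16
        eps = rng.normal(0, sigma * math.sqrt(1 - rho**2), size=n)
        x = np.empty(n)
        x[0] = rng.normal(0, sigma)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expected = sigma * math.sqrt((1 + rho) / (1 - rho)) / math.sqrt(n)
        out = blocking_errors(x)
        assert out.plateau == pytest.approx(expected, rel=0.25)

    def test_too_short_series_flagged(self, rng):
        out = blocking_errors(rng.normal(size=8), min_blocks=32)
        assert not out.converged
        assert out.plateau > 0


def _synthetic_estimate(s0, lam, lam2, scores, rel_err, rng=None):
    lp = np.log(lam) - lam * (scores - s0) - lam2 * (scores - s0) ** 2
    if rng is not None:
        lp = lp + rng.normal(0, rel_err, size=scores.size)
    window = ScoreWindow(int(scores[0]), int(scores[-1]))
    return DistributionEstimate(
        window=window,
        log_prob=lp[None, :],
        log_z=0.0,
        rel_errors=np.full((1, scores.size), rel_err),
    )


class TestModifiedGumbelFit:
    def test_exact_recovery_without_noise(self):
        scores = np.arange(20, 70, dtype=float)
        est = _synthetic_estimate(20.0, 0.27, 1e-4, scores, rel_err=0.02)
        fit = fit_modified_gumbel(est)
        assert fit.s0 == pytest.approx(20.0, abs=1e-5)
        assert fit.lam == pytest.approx(0.27, abs=1e-6)
        assert fit.lam2 == pytest.approx(1e-4, abs=1e-9)
        assert fit.valid

    def test_noisy_recovery_within_three_sigma(self, rng):
        scores = np.arange(20, 70, dtype=float)  # 50 bins
        est = _synthetic_estimate(20.0, 0.27, 1e-4, scores, rel_err=0.02, rng=rng)
        fit = fit_modified_gumbel(est)
        assert abs(fit.s0 - 20.0) < 3 * fit.errors["s0"]
        assert abs(fit.lam - 0.27) < 3 * fit.errors["lam"]
        assert abs(fit.lam2 - 1e-4) < 3 * fit.errors["lam2"]
        assert fit.chi2_reduced == pytest.approx(1.0, abs=0.6)

    def test_pure_gumbel_data_yields_lam2_consistent_with_zero(self, rng):
        scores = np.arange(10, 60, dtype=float)
        est = _synthetic_estimate(10.0, 0.3, 0.0, scores, rel_err=0.02, rng=rng)
        fit = fit_modified_gumbel(est)
        assert abs(fit.lam2) < 3 * max(fit.errors["lam2"], 1e-12)

    def test_nested_fit_never_beats_free_fit(self, rng):
        scores = np.arange(15, 60, dtype=float)
        est = _synthetic_estimate(15.0, 0.25, 3e-4, scores, rel_err=0.05, rng=rng)
        free = fit_modified_gumbel(est)
        fixed = fit_modified_gumbel(est, fix_lam2_zero=True)
        assert fixed.fixed_lam2 and fixed.lam2 == 0.0
        n_free = free.n_bins - 3
        n_fixed = fixed.n_bins - 2
        assert fixed.chi2_reduced * n_fixed >= free.chi2_reduced * n_free - 1e-9

    def test_amplitude_from_lengths(self):
        scores = np.arange(20, 70, dtype=float)
        est = _synthetic_estimate(30.0, 0.27, 1e-4, scores, rel_err=0.02)
        fit = fit_modified_gumbel(est, query_length=348, subject_length=348)
        assert fit.K == pytest.approx(math.exp(0.27 * 30.0) / 348**2, rel=1e-4)
        assert "K" in fit.errors

    def test_too_few_bins_rejected(self):
        scores = np.arange(20, 24, dtype=float)
        est = _synthetic_estimate(20.0, 0.27, 0.0, scores, rel_err=0.02)
        with pytest.raises(ValueError, match="at least 5"):
            fit_modified_gumbel(est)


class TestPValues:
    def test_window_minimum_has_pvalue_one(self, tiny_exact_marginal, tiny_window):
        est = DistributionEstimate(
            window=tiny_window,
            log_prob=np.log(np.maximum(tiny_exact_marginal, 1e-300))[None, :],
            log_z=0.0,
            rel_errors=np.full((1, tiny_window.n_bins), 0.01),
        )
        assert pvalue(est, tiny_window.s_min) == pytest.approx(1.0, abs=1e-9)

    def test_matches_exact_tail_sums(self, tiny_exact_marginal, tiny_window):
        est = DistributionEstimate(
            window=tiny_window,
            log_prob=np.log(np.maximum(tiny_exact_marginal, 1e-300))[None, :],
            log_z=0.0,
            rel_errors=np.full((1, tiny_window.n_bins), 0.01),
        )
        for s in range(tiny_window.s_min, tiny_window.s_max + 1):
            exact_tail = tiny_exact_marginal[s - tiny_window.s_min :].sum()
            assert pvalue(est, s) == pytest.approx(exact_tail, rel=1e-9, abs=1e-12)

    def test_monotone_non_increasing(self, rng):
        scores = np.arange(10, 80, dtype=float)
        est = _synthetic_estimate(10.0, 0.3, 1e-4, scores, rel_err=0.02)
        fit = fit_modified_gumbel(est)
        ps = [pvalue(est, s, fit=fit) for s in np.arange(10, 120)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_below_window_returns_one_with_warning(self, tiny_exact_marginal, tiny_window):
        est = DistributionEstimate(
            window=tiny_window,
            log_prob=np.log(np.maximum(tiny_exact_marginal, 1e-300))[None, :],
            log_z=0.0,
            rel_errors=np.full((1, tiny_window.n_bins), 0.01),
        )
        with pytest.warns(UserWarning, match="below"):
            assert pvalue(est, tiny_window.s_min - 5) == 1.0

    def test_parametric_tail_continuation(self):
        fit = ModifiedGumbelFit(
            s0=30.0, lam=0.27, lam2=1e-4, errors={}, covariance=np.zeros((3, 3)),
            chi2_reduced=1.0, fit_window=(23, 150), n_bins=100,
        )
        # tail sums decay monotonically and roughly geometrically
        p1, p2 = fit.pvalue(100), fit.pvalue(101)
        assert 0 < p2 < p1 < 1
        assert p2 / p1 == pytest.approx(math.exp(-0.27 - 2e-4 * 70), rel=0.05)


class TestEValue:
    def test_linearity_and_edge_cases(self):
        assert evalue(0.0, 10**6) == 0.0
        assert evalue(0.3, 1) == pytest.approx(0.3)
        assert evalue(1e-5, 2000) + evalue(1e-5, 3000) == pytest.approx(
            evalue(1e-5, 5000)
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            evalue(1.2, 10)
        with pytest.raises(ValueError):
            evalue(0.5, -1)


def _fit_for(ls, lam, lam2, K, lq=348):
    s0 = math.log(K * lq * ls) / lam
    return ModifiedGumbelFit(
        s0=s0, lam=lam, lam2=lam2, K=K,
        errors={"s0": 0.1, "lam": 0.001, "lam2": 1e-6, "K": 1e-4},
        covariance=np.diag([0.01, 1e-6, 1e-12]),
        chi2_reduced=1.0, fit_window=(23, 150), n_bins=100,
        query_length=lq, subject_length=ls,
    )


class TestInterpolation:
    def test_grid_point_is_identity(self):
        fits = {100: _fit_for(100, 0.28, 3e-4, 0.046), 200: _fit_for(200, 0.27, 2e-4, 0.03)}
        out = interpolate_params(fits, 200)
        assert out.lam == pytest.approx(0.27)
        assert out.lam2 == pytest.approx(2e-4)
        assert out.K == pytest.approx(0.03)

    def test_linear_parameter_recovered_at_midpoint(self):
        fits = {
            100: _fit_for(100, 0.30, 4e-4, 0.05),
            300: _fit_for(300, 0.26, 2e-4, 0.03),
        }
        out = interpolate_params(fits, 200)
        assert out.lam == pytest.approx(0.28)
        assert out.lam2 == pytest.approx(3e-4)
        assert out.s0 == pytest.approx(math.log(0.04 * 348 * 200) / 0.28)

    def test_plateau_beyond_query_length(self):
        """lambda2 interpolates as near-constant where it has plateaued."""
        grid = {ls: _fit_for(ls, 0.268, 1.0e-4 + 1e-7 * (500 - ls), 0.03)
                for ls in (360, 400, 500, 600)}
        out = interpolate_params(grid, 450)
        assert out.lam2 == pytest.approx(1.0e-4, rel=0.1)

    def test_far_extrapolation_flagged(self):
        fits = {100: _fit_for(100, 0.28, 3e-4, 0.046), 200: _fit_for(200, 0.27, 2e-4, 0.03)}
        with pytest.warns(UserWarning, match="outside"):
            interpolate_params(fits, 400)
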