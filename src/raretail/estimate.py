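"""Importance reweighting, blocking errors, and modified-Gumbel fitting.

A production histogram counted under the biased pmf q = w(S) p is turned
into an estimate of the null score distribution by dividing out the bias,
P(s, n) ~ counts(s, n) / w(s, n), normalized over the window.  All of this
happens in log domain: the weights span many tens of decades.

The tail is summarized by a modified Gumbel law

    log P(S = s) = log(lambda) - lambda (s - s0) - lambda2 (s - s0)^2,

an extreme-value pmf with a Gaussian finite-size correction.  lambda2 -> 0
recovers the pure Gumbel tail; matching exponents with the asymptotic form
c = K Lq Ls yields the amplitude K = exp(lambda s0) / (Lq Ls).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.special import logsumexp

from .wang_landau import ScoreHistogram, ScoreWindow

__all__ = [
    "DistributionEstimate",
    "BlockingErrorEstimate",
    "ModifiedGumbelFit",
    "reweight",
    "blocking_errors",
    "fit_modified_gumbel",
    "pvalue",
    "evalue",
    "interpolate_params",
    "estimate_from_scores",
]

_NEG_INF = float("-inf")


@dataclass
class DistributionEstimate:
    """Normalized log-probability estimate per (score, class) bin."""

    window: ScoreWindow
    log_prob: np.ndarray  # (n_classes, n_bins); -inf where unobserved
    log_z: float
    rel_errors: np.ndarray  # relative standard error per bin (inf if unknown)

    @property
    def scores(self) -> np.ndarray:
        return self.window.scores

    @property
    def log_prob_marginal(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return logsumexp(self.log_prob, axis=0)

    def class_slice(self, n_tm: int) -> np.ndarray:
        c, _ = self.window.bin(self.window.s_min, n_tm)
        return self.log_prob[c]

    def total(self) -> float:
        finite = self.log_prob[np.isfinite(self.log_prob)]
        return float(np.exp(logsumexp(finite))) if finite.size else 0.0


@dataclass
class BlockingErrorEstimate:
    """Flyvbjerg-Petersen blocking analysis of a correlated series."""

    errors: np.ndarray  # naive standard error of the mean per blocking level
    block_sizes: np.ndarray
    plateau: float
    converged: bool  # False when the series was too short for a plateau


def blocking_errors(series, min_blocks: int = 32) -> BlockingErrorEstimate:
    """Standard error of the mean of a correlated scalar series.

    The series is repeatedly halved by pairwise averaging; at each level the
    naive standard error is recorded.  The error rises with block size until
    blocks are longer than the correlation time and then plateaus; the
    estimate is the mean over the last (up to three) levels that still hold
    ``min_blocks`` blocks.  Series shorter than ``min_blocks`` get the naive
    error with ``converged=False``.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        return BlockingErrorEstimate(
            np.array([0.0]), np.array([1]), 0.0, False
        )
    errors, sizes = [], []
    level = x
    size = 1
    while level.size >= 2:
        se = float(level.std(ddof=1) / math.sqrt(level.size))
        errors.append(se)
        sizes.append(size)
        if level.size % 2:
            level = level[:-1]
        level = 0.5 * (level[0::2] + level[1::2])
        size *= 2
    errors = np.array(errors)
    sizes = np.array(sizes)
    valid = np.array([x.size // s >= min_blocks for s in sizes])
    if not valid.any():
        return BlockingErrorEstimate(errors, sizes, float(errors[0]), False)
    tail = errors[valid][-3:]
    plateau = float(tail.mean())
    converged = bool(
        tail.size >= 2
        and (plateau == 0 or (tail.max() - tail.min()) <= 0.5 * plateau)
    )
    return BlockingErrorEstimate(errors, sizes, plateau, converged)


def _per_bin_rel_errors(
    series: np.ndarray, n_flat_bins: int, counts_flat: np.ndarray, min_blocks: int = 32
) -> np.ndarray:
    """Relative blocking error of every bin frequency, vectorized.

    ``series`` holds flat bin indices, one per production sample.  For each
    bin the indicator series is blocked exactly as in
    :func:`blocking_errors`; the plateau is taken over levels with at least
    ``min_blocks`` blocks.
    """
    n = series.size
    levels = []
    n_blocks = n
    block = 1
    while n_blocks >= min_blocks:
        usable = (n // block) * block
        blk_idx = np.arange(usable) // block
        flat = blk_idx * n_flat_bins + series[:usable]
        bc = np.bincount(flat, minlength=(n // block) * n_flat_bins).reshape(
            n // block, n_flat_bins
        )
        means = bc / block
        nb = means.shape[0]
        levels.append(means.std(axis=0, ddof=1) / math.sqrt(nb))
        block *= 2
        n_blocks = n // block
    if levels:
        best = np.mean(levels[-3:], axis=0)
    else:
        best = np.zeros(n_flat_bins)
    freq = counts_flat / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(freq > 0, best / freq, np.inf)
    return rel


def reweight(hist: ScoreHistogram) -> DistributionEstimate:
    """Importance-reweight a production histogram into a pmf estimate.

    P(s, n) = counts(s, n) / w(s, n) / Z with Z summing the same quantity
    over all bins; everything in log domain.  Per-bin relative errors come
    from blocking the recorded sample series when available, otherwise from
    the multinomial 1/sqrt(count) approximation.
    """
    counts = hist.counts
    if counts.sum() == 0:
        raise ValueError("empty histogram cannot be reweighted")
    with np.errstate(divide="ignore"):
        log_unnorm = np.where(
            counts > 0, np.log(np.maximum(counts, 1)) - hist.log_w, _NEG_INF
        )
    log_z = float(logsumexp(log_unnorm[np.isfinite(log_unnorm)]))
    log_prob = log_unnorm - log_z
    if hist.series is not None:
        rel = _per_bin_rel_errors(
            hist.series, counts.size, counts.ravel().astype(float)
        ).reshape(counts.shape)
    else:
        with np.errstate(divide="ignore"):
            rel = np.where(counts > 0, 1.0 / np.sqrt(np.maximum(counts, 1)), np.inf)
    return DistributionEstimate(
        window=hist.window, log_prob=log_prob, log_z=log_z, rel_errors=rel
    )


def estimate_from_scores(
    scores: np.ndarray, window: ScoreWindow
) -> DistributionEstimate:
    """Simple-sampling estimate: bin plain null-model scores on a window.

    Scores outside the window are dropped (the estimate is the conditional
    pmf on the window, which is what bulk fits consume).
    """
    s = np.asarray(scores)
    inside = s[(s >= window.s_min) & (s <= window.s_max)]
    if inside.size == 0:
        raise ValueError("no scores inside the window")
    counts = np.bincount(inside - window.s_min, minlength=window.n_bins).astype(
        np.int64
    )[None, :]
    hist = ScoreHistogram(
        window=window,
        counts=counts,
        log_w=np.zeros_like(counts, dtype=float),
        n_samples=int(counts.sum()),
        thinning=1,
        series=None,
    )
    return reweight(hist)


# --------------------------------------------------------------------------
# Modified Gumbel fit
# --------------------------------------------------------------------------


@dataclass
class ModifiedGumbelFit:
    """Parameters of log P(S=s) = log(lam) - lam (s-s0) - lam2 (s-s0)^2."""

    s0: float
    lam: float
    lam2: float
    errors: dict  # standard errors for s0, lam, lam2 (and K when defined)
    covariance: np.ndarray
    chi2_reduced: float
    fit_window: tuple[int, int]
    n_bins: int
    fixed_lam2: bool = False
    valid: bool = True
    query_length: int | None = None
    subject_length: int | None = None
    K: float | None = None
    interpolated: bool = False

    def log_pmf(self, s) -> np.ndarray:
        d = np.asarray(s, dtype=float) - self.s0
        return math.log(self.lam) - self.lam * d - self.lam2 * d * d

    def pvalue(self, s: float, max_terms: int = 200_000) -> float:
        """P(S >= s) by summing the fitted pmf over integer scores."""
        s = math.ceil(s)
        # terms decay at least like exp(-lam d); sum until negligible
        width = min(max_terms, int(200.0 / self.lam) + 1000)
        grid = np.arange(s, s + width)
        return float(np.exp(logsumexp(self.log_pmf(grid))))


def _model(s, s0, lam, lam2):
    d = s - s0
    return np.log(lam) - lam * d - lam2 * d * d


def _model_pure(s, s0, lam):
    return np.log(lam) - lam * (s - s0)


def _poly_seed(s, y, w):
    """Weighted quadratic fit -> (s0, lam, lam2) via exact reparametrization.

    log P = a + b s + c s^2 with c = -lam2, b = -lam + 2 lam2 s0 and
    a = log(lam) + lam s0 - lam2 s0^2; the quadratic WLS optimum therefore
    *is* the (s0, lam, lam2) optimum, up to the reparametrization.
    """
    c2, c1, c0 = np.polyfit(s, y, 2, w=w)
    lam2 = max(-c2, 0.0)
    if lam2 < 1e-12:
        lam = -c1
        if lam <= 0:
            return None
        return (c0 - math.log(lam)) / lam, lam, 0.0

    def g(s0):
        lam = 2 * lam2 * s0 - c1
        if lam <= 0:
            return np.inf
        return math.log(lam) + lam * s0 - lam2 * s0 * s0 - c0

    lo = (c1 + 1e-9) / (2 * lam2)  # lam > 0 boundary
    hi = lo + abs(lo) + 1e4
    try:
        s0 = brentq(g, lo + 1e-6, hi)
    except ValueError:
        return None
    return s0, 2 * lam2 * s0 - c1, lam2


def fit_modified_gumbel(
    est: DistributionEstimate,
    fit_window: tuple[int, int] | None = None,
    fix_lam2_zero: bool = False,
    n_tm: int | None = None,
    max_rel_error: float = 0.5,
    query_length: int | None = None,
    subject_length: int | None = None,
) -> ModifiedGumbelFit:
    """Weighted least squares of the log-pmf against the modified Gumbel law.

    Bins with relative error above ``max_rel_error`` are excluded; per-bin
    sigma on the log scale is the relative error of the probability.  With
    ``fix_lam2_zero`` the pure Gumbel tail (lambda2 = 0) is fitted instead;
    a free fit whose optimum has negative curvature parameter falls back to
    that boundary fit (lambda2 >= 0 by construction).
    When the query/subject lengths are given, the Karlin-Altschul-style
    amplitude K = exp(lam*s0)/(Lq*Ls) and its propagated error are filled in.
    """
    if n_tm is None:
        y_all = est.log_prob_marginal
        rel_all = (
            est.rel_errors[0]
            if est.rel_errors.shape[0] == 1
            else _marginal_rel_errors(est)
        )
    else:
        c, _ = est.window.bin(est.window.s_min, n_tm)
        y_all = est.log_prob[c]
        rel_all = est.rel_errors[c]
    s_all = est.scores.astype(float)
    lo, hi = fit_window if fit_window else (est.window.s_min, est.window.s_max)
    keep = (
        (s_all >= lo)
        & (s_all <= hi)
        & np.isfinite(y_all)
        & np.isfinite(rel_all)
        & (rel_all > 0)
        & (rel_all <= max_rel_error)
    )
    s, y, sig = s_all[keep], y_all[keep], rel_all[keep]
    if s.size < 5:
        raise ValueError(
            f"only {s.size} usable bins in the fit window; need at least 5"
        )
    seed = _poly_seed(s, y, 1.0 / sig)
    if seed is None:
        seed = (float(s[np.argmax(y)]), 0.3, 1e-5)
    if fix_lam2_zero:
        p0 = (seed[0], max(seed[1], 1e-3))
        popt, pcov = curve_fit(
            _model_pure, s, y, p0=p0, sigma=sig, absolute_sigma=True, maxfev=20000
        )
        s0, lam = (float(v) for v in popt)
        lam2 = 0.0
        resid = (y - _model_pure(s, *popt)) / sig
        dof = max(s.size - 2, 1)
        cov = np.zeros((3, 3))
        cov[:2, :2] = pcov
    else:
        p0 = (seed[0], max(seed[1], 1e-3), max(seed[2], 0.0))
        popt, pcov = curve_fit(
            _model, s, y, p0=p0, sigma=sig, absolute_sigma=True, maxfev=20000
        )
        s0, lam, lam2 = (float(v) for v in popt)
        if lam2 < 0:
            # the optimum sits outside lam2 >= 0: the constrained optimum is
            # on the boundary, i.e. the pure Gumbel fit
            return fit_modified_gumbel(
                est,
                fit_window=fit_window,
                fix_lam2_zero=True,
                n_tm=n_tm,
                max_rel_error=max_rel_error,
                query_length=query_length,
                subject_length=subject_length,
            )
        resid = (y - _model(s, *popt)) / sig
        dof = max(s.size - 3, 1)
        cov = pcov
    chi2_red = float((resid**2).sum() / dof)
    err = {
        "s0": math.sqrt(max(cov[0, 0], 0.0)),
        "lam": math.sqrt(max(cov[1, 1], 0.0)),
        "lam2": math.sqrt(max(cov[2, 2], 0.0)),
    }
    valid = lam > 0 and lam2 >= -1e-12
    K = None
    if query_length and subject_length and valid:
        K = math.exp(lam * s0) / (query_length * subject_length)
        grad = np.array([lam * K, s0 * K, 0.0])
        err["K"] = math.sqrt(max(grad @ cov @ grad, 0.0))
    return ModifiedGumbelFit(
        s0=s0,
        lam=lam,
        lam2=max(lam2, 0.0),
        errors=err,
        covariance=cov,
        chi2_reduced=chi2_red,
        fit_window=(int(lo), int(hi)),
        n_bins=int(s.size),
        fixed_lam2=fix_lam2_zero,
        valid=bool(valid),
        query_length=query_length,
        subject_length=subject_length,
        K=K,
    )


def _marginal_rel_errors(est: DistributionEstimate) -> np.ndarray:
    """Combine per-class errors into marginal ones (independent-bin approx)."""
    with np.errstate(over="ignore", invalid="ignore"):
        p = np.exp(est.log_prob)
        var = np.where(np.isfinite(est.rel_errors), (p * est.rel_errors) ** 2, 0.0)
        pm = p.sum(axis=0)
        rel = np.where(pm > 0, np.sqrt(var.sum(axis=0)) / np.maximum(pm, 1e-300), np.inf)
    return rel


# --------------------------------------------------------------------------
# p-values / E-values
# --------------------------------------------------------------------------


def pvalue(obj, s: float, fit: ModifiedGumbelFit | None = None) -> float:
    """P(S >= s) under the null model.

    ``obj`` may be a :class:`DistributionEstimate` (tail-summed over its
    window, analytically continued with ``fit`` beyond it) or a
    :class:`ModifiedGumbelFit` (pure parametric tail).  Scores below the
    supported range return 1 with a warning.
    """
    if isinstance(obj, ModifiedGumbelFit):
        return min(obj.pvalue(s), 1.0)
    est: DistributionEstimate = obj
    w = est.window
    if s <= w.s_min:
        if s < w.s_min:
            warnings.warn("score below the estimated window; p-value = 1")
        return 1.0
    lp = est.log_prob_marginal
    idx = int(np.ceil(s)) - w.s_min
    finite = lp[idx:][np.isfinite(lp[idx:])]
    p = float(np.exp(logsumexp(finite))) if finite.size else 0.0
    if fit is not None:
        p += fit.pvalue(w.s_max + 1)
    return min(p, 1.0)


def evalue(p: float, db_size: int) -> float:
    """Expected number of database hits: db_size * p (linear convention)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    if db_size < 0:
        raise ValueError("database size must be non-negative")
    return db_size * p


def interpolate_params(
    fits: dict[int, ModifiedGumbelFit], target_subject_length: int
) -> ModifiedGumbelFit:
    """Piecewise-linear interpolation of fit parameters in subject length.

    lambda, lambda2 and K are interpolated; s0 is recomputed from K and
    lambda via s0 = ln(K Lq Ls)/lambda.  Extrapolating more than 20% beyond
    the covered range is flagged with a warning.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to interpolate")
    ls = np.array(sorted(fits))
    if any(fits[l].K is None for l in ls):
        raise ValueError("all fits must carry K (fit with lengths given)")
    lq = fits[int(ls[0])].query_length
    span = ls[-1] - ls[0]
    t = float(target_subject_length)
    if t < ls[0] - 0.2 * span or t > ls[-1] + 0.2 * span:
        warnings.warn("target length far outside the calibrated range")
    lam = float(np.interp(t, ls, [fits[int(l)].lam for l in ls]))
    lam2 = float(np.interp(t, ls, [fits[int(l)].lam2 for l in ls]))
    K = float(np.interp(t, ls, [fits[int(l)].K for l in ls]))
    s0 = math.log(K * lq * t) / lam
    # linear error propagation through the interpolation weights
    j = int(np.clip(np.searchsorted(ls, t) - 1, 0, len(ls) - 2))
    u = 0.0 if ls[j + 1] == ls[j] else (t - ls[j]) / (ls[j + 1] - ls[j])
    u = float(np.clip(u, 0.0, 1.0))
    f1, f2 = fits[int(ls[j])], fits[int(ls[j + 1])]
    cov = (1 - u) ** 2 * f1.covariance + u**2 * f2.covariance
    err = {
        k: math.sqrt(
            max((1 - u) ** 2 * f1.errors.get(k, 0) ** 2 + u**2 * f2.errors.get(k, 0) ** 2, 0)
        )
        for k in ("s0", "lam", "lam2", "K")
    }
    return ModifiedGumbelFit(
        s0=s0,
        lam=lam,
        lam2=lam2,
        errors=err,
        covariance=cov,
        chi2_reduced=float("nan"),
        fit_window=(0, 0),
        n_bins=0,
        valid=lam > 0,
        query_length=lq,
        subject_length=int(t),
        K=K,
    )
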