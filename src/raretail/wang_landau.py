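"""Flat-histogram (Wang-Landau) weight estimation and production sampling.

The sampler targets q(x, y) = w(S(x, y), n) * p(x, y) on a score window
[s_min, s_max] (integer bins of width 1, optionally resolved by the
transmembrane-helix class n of the query).  The Wang-Landau phase adapts the
log-weights: after every update the visited bin's weight is divided by the
current modification factor phi (making it less attractive), its histogram
count incremented; once the histogram is flat (every bin above a fraction of
the mean) the histogram is zeroed, phi <- sqrt(phi), and the weights are
kept.  The converged weights approximate w(s, n) ~ 1/P(s, n).  Because the
adaptation violates detailed balance, data production is a separate fixed
weight (phi = 1) Metropolis-Hastings run whose histogram is afterwards
importance-reweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mcmc import (
    Configuration,
    NullModelPair,
    ProposalPolicy,
    make_configuration,
    mh_update,
    propose,
)
from .null_models import FixedQueryModel, HiddenMarkovModel, IIDModel
from .scoring import PositionSpecificScheme, smith_waterman_score

__all__ = [
    "ScoreWindow",
    "ScoreHistogram",
    "WLSchedule",
    "WLState",
    "is_flat",
    "initial_configuration",
    "wl_estimate",
    "steps_to_round_trip",
    "production_run",
    "warm_start_weights",
    "weights_from_fit",
]


@dataclass(frozen=True)
class ScoreWindow:
    """An integer score range [s_min, s_max] and the classes it covers."""

    s_min: int
    s_max: int
    classes: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        if self.s_min >= self.s_max:
            raise ValueError("need s_min < s_max")
        if len(set(self.classes)) != len(self.classes) or not self.classes:
            raise ValueError("classes must be non-empty and unique")
        object.__setattr__(
            self, "_class_index", {int(c): i for i, c in enumerate(self.classes)}
        )

    @property
    def n_bins(self) -> int:
        return self.s_max - self.s_min + 1

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def scores(self) -> np.ndarray:
        return np.arange(self.s_min, self.s_max + 1)

    def contains(self, score: int, n_tm: int = 0) -> bool:
        return self.s_min <= score <= self.s_max and int(n_tm) in self._class_index

    def bin(self, score: int, n_tm: int = 0) -> tuple[int, int]:
        return self._class_index[int(n_tm)], score - self.s_min


@dataclass
class ScoreHistogram:
    """Counts of sampled (score, class) bins from a production run."""

    window: ScoreWindow
    counts: np.ndarray  # (n_classes, n_bins)
    log_w: np.ndarray  # sampling log-weights in force during the run
    n_samples: int
    thinning: int
    series: np.ndarray | None = None  # flat bin index per sample, for blocking

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n_samples:
            raise ValueError("histogram counts must sum to n_samples")


@dataclass(frozen=True)
class WLSchedule:
    """Modification-factor schedule phi_0 -> phi_final with phi <- sqrt(phi).

    Defaults follow the standard choice exp(0.1) -> exp(0.0002).  A level is
    run at every factor until the factor in force is <= phi_final, which for
    the defaults makes exactly 10 levels (0.1 / 2^k, k = 0..9).
    """

    log_phi_initial: float = 0.1
    log_phi_final: float = 0.0002
    flatness_fraction: float = 0.6
    flatness_interval: int = 1000
    criterion: str = "flatness"  # or "round_trips"
    round_trips_per_level: int = 2

    def __post_init__(self) -> None:
        if self.log_phi_initial <= 0 or self.log_phi_final <= 0:
            raise ValueError("phi factors must exceed 1 (positive logs)")
        if not 0 < self.flatness_fraction < 1:
            raise ValueError("flatness fraction must be in (0, 1)")
        if self.criterion not in ("flatness", "round_trips"):
            raise ValueError(self.criterion)

    def levels(self) -> list[float]:
        """Factors actually run: halving stops once a level is <= final.

        For the defaults this is 0.1/2^k for k = 0..9, i.e. 10 levels; the
        last level is the first one at or below ``log_phi_final``.
        """
        out = [self.log_phi_initial]
        while out[-1] > self.log_phi_final:
            out.append(out[-1] / 2.0)
        return out


class WLState:
    """Log-weights, visit histogram and round-trip diagnostics.

    Also serves as the weight table consumed by :func:`raretail.mcmc.mh_update`
    (``log_w_at`` returns ``None`` outside the window, which the kernel turns
    into a rejection).
    """

    def __init__(
        self,
        window: ScoreWindow,
        log_w: np.ndarray | None = None,
        support_mask: np.ndarray | None = None,
    ):
        self.window = window
        shape = (window.n_classes, window.n_bins)
        self.log_w = (
            np.zeros(shape) if log_w is None else np.array(log_w, dtype=float)
        )
        if self.log_w.shape != shape:
            raise ValueError("log_w shape does not match the window")
        self.H = np.zeros(shape, dtype=np.int64)
        self.support_mask = (
            np.ones(shape, dtype=bool)
            if support_mask is None
            else np.array(support_mask, dtype=bool)
        )
        self.ever_visited = np.zeros(shape, dtype=bool)
        self.log_phi = 0.0
        self.iteration = 0
        self.steps = 0
        self.round_trip_steps: list[int] = []  # step stamp per completed trip
        self.level_log: list[dict] = []
        self._rt_phase = 0  # 0: before first s_min touch; 1: to top; 2: to bottom

    # -- weight-table protocol -------------------------------------------
    def log_w_at(self, score: int, n_tm: int) -> float | None:
        if not self.window.contains(score, n_tm):
            return None
        c, b = self.window.bin(score, n_tm)
        return float(self.log_w[c, b])

    # -- bookkeeping ------------------------------------------------------
    @property
    def round_trips(self) -> int:
        return len(self.round_trip_steps)

    def record_visit(self, score: int, n_tm: int) -> None:
        c, b = self.window.bin(score, n_tm)
        self.H[c, b] += 1
        self.ever_visited[c, b] = True
        if self.log_phi > 0.0:
            self.log_w[c, b] -= self.log_phi
        self.steps += 1
        if score == self.window.s_min:
            if self._rt_phase == 0:
                self._rt_phase = 1
            elif self._rt_phase == 2:
                self.round_trip_steps.append(self.steps)
                self._rt_phase = 1
        elif score == self.window.s_max and self._rt_phase == 1:
            self._rt_phase = 2

    def reset_histogram(self) -> None:
        self.H[:] = 0


def is_flat(
    H: np.ndarray, fraction: float = 0.6, mask: np.ndarray | None = None
) -> bool:
    """True iff every (unmasked) bin exceeds ``fraction`` times the mean.

    ``H`` is the histogram slice of one class over the score window.
    """
    h = np.asarray(H, dtype=float)
    if mask is not None:
        h = h[np.asarray(mask, dtype=bool)]
    if h.size == 0:
        return True
    return bool(np.all(h > fraction * h.mean()))


def _sample_query(models: NullModelPair, length: int, rng: np.random.Generator):
    qm = models.query_model
    if isinstance(qm, FixedQueryModel):
        return qm.query_codes.copy()
    if isinstance(qm, HiddenMarkovModel):
        sym, _ = qm.sample(length, rng)
        return sym
    return qm.sample(length, rng)


def initial_configuration(
    models: NullModelPair,
    scheme: PositionSpecificScheme,
    query_length: int,
    subject_length: int,
    rng: np.random.Generator,
    window: ScoreWindow | None = None,
    policy: ProposalPolicy | None = None,
    max_steps: int = 2_000_000,
) -> Configuration:
    """Draw a null-model pair and greedily hill-climb into the window.

    Moves that strictly reduce the distance of the score to [s_min, s_max]
    are accepted, everything else rejected; the null model typically starts
    far below s_min, so this is a score ascent.
    """
    x = _sample_query(models, query_length, rng)
    y = models.subject_model.sample(subject_length, rng)
    config = make_configuration(models, scheme, x, y)
    if window is None:
        return config
    policy = policy or models.default_policy()

    def distance(s: int) -> int:
        return max(window.s_min - s, 0) + max(s - window.s_max, 0)

    d = distance(config.score)
    steps = 0
    while d > 0 or not window.contains(config.score, config.n_tm):
        if steps >= max_steps:
            raise RuntimeError(
                "hill-climb failed to reach the score window; widen the "
                "window or check the scheme"
            )
        prop = propose(config, policy, models, rng)
        from .mcmc import _candidate_state

        x2, y2, s2, n2, lp2, path2 = _candidate_state(config, prop, models, scheme)
        d2 = distance(s2)
        better = d2 < d or (d2 == d and window.contains(s2, n2))
        if better:
            config = Configuration(x2, y2, s2, n2, lp2, path2)
            d = d2
        steps += 1
    return config


def wl_estimate(
    models: NullModelPair,
    scheme: PositionSpecificScheme,
    window: ScoreWindow,
    schedule: WLSchedule,
    rng: np.random.Generator,
    config: Configuration | None = None,
    initial_log_w: np.ndarray | None = None,
    policy: ProposalPolicy | None = None,
    support_mask: np.ndarray | None = None,
    query_length: int | None = None,
    subject_length: int | None = None,
    max_steps_per_level: int = 50_000_000,
) -> tuple[WLState, Configuration]:
    """Run the Wang-Landau iteration until phi reaches the final factor.

    Returns the state (converged ``log_w``, per-level diagnostics,
    round-trip stamps) together with the last chain configuration, which can
    seed the production run.
    """
    policy = policy or models.default_policy()
    if config is None:
        if query_length is None or subject_length is None:
            raise ValueError("need sequence lengths when no configuration given")
        config = initial_configuration(
            models, scheme, query_length, subject_length, rng, window, policy
        )
    if not window.contains(config.score, config.n_tm):
        raise ValueError("initial configuration outside the score window")

    state = WLState(window, log_w=initial_log_w, support_mask=support_mask)
    for log_phi in schedule.levels():
        state.log_phi = log_phi
        state.reset_histogram()
        level_steps = 0
        rt_at_start = state.round_trips
        done = False
        while not done:
            for _ in range(schedule.flatness_interval):
                config, _acc = mh_update(config, state, models, scheme, policy, rng)
                state.record_visit(config.score, config.n_tm)
            level_steps += schedule.flatness_interval
            if schedule.criterion == "flatness":
                done = all(
                    is_flat(
                        state.H[c],
                        schedule.flatness_fraction,
                        state.support_mask[c],
                    )
                    for c in range(window.n_classes)
                )
            else:
                done = (
                    state.round_trips - rt_at_start
                    >= schedule.round_trips_per_level
                )
            if level_steps >= max_steps_per_level:
                warnings.warn(
                    f"phi-level {state.iteration}: step cap reached before "
                    "the flatness criterion; weights carried on as-is"
                )
                break
        state.level_log.append(
            {
                "iteration": state.iteration,
                "log_phi": log_phi,
                "steps": level_steps,
                "round_trips": state.round_trips - rt_at_start,
                "flat": done,
            }
        )
        state.iteration += 1
    state.log_phi = 0.0
    return state, config


def steps_to_round_trip(
    models: NullModelPair,
    scheme: PositionSpecificScheme,
    window: ScoreWindow,
    rng: np.random.Generator,
    query_length: int,
    subject_length: int,
    initial_log_w: np.ndarray | None = None,
    n_trips: int = 1,
    log_phi: float = 0.1,
    max_steps: int = 20_000_000,
    policy: ProposalPolicy | None = None,
) -> list[int]:
    """Step counts at which the walker completes its first round trips.

    Runs the weight-adapting walk at a fixed modification factor (no level
    changes) until ``n_trips`` traversals s_min -> s_max -> s_min are done; a
    mixing-time diagnostic.  With a good warm start the first trip is far
    cheaper than from uniform weights.
    """
    policy = policy or models.default_policy()
    config = initial_configuration(
        models, scheme, query_length, subject_length, rng, window, policy
    )
    state = WLState(window, log_w=initial_log_w)
    state.log_phi = log_phi
    while state.round_trips < n_trips:
        if state.steps >= max_steps:
            raise RuntimeError(f"no round trip within {max_steps} steps")
        config, _ = mh_update(config, state, models, scheme, policy, rng)
        state.record_visit(config.score, config.n_tm)
    return state.round_trip_steps


def production_run(
    models: NullModelPair,
    scheme: PositionSpecificScheme,
    window: ScoreWindow,
    log_w: np.ndarray | WLState,
    n_samples: int,
    thinning: int,
    rng: np.random.Generator,
    config: Configuration | None = None,
    policy: ProposalPolicy | None = None,
    query_length: int | None = None,
    subject_length: int | None = None,
    burn_in: int = 0,
    keep_series: bool = True,
) -> tuple[ScoreHistogram, Configuration]:
    """Fixed-weight (phi = 1) detailed-balance run; records every k-th state.

    Returns the score/class histogram (with the raw thinned series for
    blocking-error analysis) and the final configuration.
    """
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    policy = policy or models.default_policy()
    state = log_w if isinstance(log_w, WLState) else WLState(window, log_w=log_w)
    weights = WLState(window, log_w=state.log_w.copy())  # frozen, phi = 0
    if config is None:
        if query_length is None or subject_length is None:
            raise ValueError("need sequence lengths when no configuration given")
        config = initial_configuration(
            models, scheme, query_length, subject_length, rng, window, policy
        )
    counts = np.zeros((window.n_classes, window.n_bins), dtype=np.int64)
    series = np.empty(n_samples, dtype=np.int64) if keep_series else None
    n_accept = 0
    for _ in range(burn_in):
        config, _ = mh_update(config, weights, models, scheme, policy, rng)
    for i in range(n_samples):
        for _ in range(thinning):
            config, acc = mh_update(config, weights, models, scheme, policy, rng)
            n_accept += acc
        c, b = window.bin(config.score, config.n_tm)
        counts[c, b] += 1
        if keep_series:
            series[i] = c * window.n_bins + b
    hist = ScoreHistogram(
        window=window,
        counts=counts,
        log_w=weights.log_w,
        n_samples=n_samples,
        thinning=thinning,
        series=series,
    )
    hist.acceptance_rate = n_accept / max(n_samples * thinning, 1)
    return hist, config


def warm_start_weights(
    source_scores: np.ndarray,
    source_log_w: np.ndarray,
    new_window: ScoreWindow,
) -> np.ndarray:
    """Carry log-weights from one window onto another.

    Inside the overlap the weights are linearly interpolated; beyond the
    source range they are extrapolated linearly with the slope of the
    outermost source segment (flat sources therefore extend as constants).
    Disjoint source/target ranges fall back to uniform weights with a
    warning.
    """
    s = np.asarray(source_scores, dtype=float)
    w = np.asarray(source_log_w, dtype=float)
    if s.ndim != 1 or s.shape != w.shape or s.size == 0:
        raise ValueError("source table must be two equal 1-d arrays")
    order = np.argsort(s)
    s, w = s[order], w[order]
    target = new_window.scores.astype(float)
    out = np.empty((new_window.n_classes, new_window.n_bins))
    if s[-1] < target[0] or s[0] > target[-1]:
        warnings.warn("source and target windows are disjoint; using uniform weights")
        out[:] = 0.0
        return out
    row = np.interp(target, s, w)
    if s.size >= 2:
        lo_slope = (w[1] - w[0]) / (s[1] - s[0])
        hi_slope = (w[-1] - w[-2]) / (s[-1] - s[-2])
        below = target < s[0]
        above = target > s[-1]
        row[below] = w[0] + lo_slope * (target[below] - s[0])
        row[above] = w[-1] + hi_slope * (target[above] - s[-1])
    out[:] = row  # same guess for every class
    return out


def weights_from_fit(fit, window: ScoreWindow) -> np.ndarray:
    """Initial log-weights w = 1/P from a modified-Gumbel fit."""
    s = window.scores.astype(float)
    log_p = fit.log_pmf(s)
    out = np.tile(-log_p, (window.n_classes, 1))
    return out - out.max()
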