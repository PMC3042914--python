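"""Metropolis-Hastings kernel over pairs of sequences.

The chain moves through the space ``Sigma^Lq x Sigma^Ls`` of sequence pairs
with five length-preserving elementary moves (substitution; insertion with
left/right shift; deletion with right/left shift).  Each move replaces
exactly one symbol, so under an i.i.d. null model with symbols proposed from
the background composition the proposal ratio cancels the null-probability
ratio exactly and acceptance depends on the score (and class) weights only.
For an HMM query the symbol is proposed uniformly and the forward probability
of the mutated query enters the acceptance ratio explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Optional

import numpy as np

from .null_models import (
    FixedQueryModel,
    HiddenMarkovModel,
    IIDModel,
    count_tm_helices,
    forward_log_prob,
    viterbi_path,
)
from .scoring import PositionSpecificScheme, smith_waterman_score

__all__ = [
    "MoveKind",
    "MOVE_PROBABILITIES",
    "ProposalPolicy",
    "NullModelPair",
    "Configuration",
    "Proposal",
    "apply_move",
    "propose",
    "mh_update",
    "make_configuration",
]


class MoveKind(IntEnum):
    SUBSTITUTE = 0
    INSERT_LEFT_SHIFT = 1
    INSERT_RIGHT_SHIFT = 2
    DELETE_RIGHT_SHIFT = 3
    DELETE_LEFT_SHIFT = 4


#: Substitution with probability 1/2, the four shift moves with 1/8 each.
MOVE_PROBABILITIES = np.array([0.5, 0.125, 0.125, 0.125, 0.125])
_MOVE_CUM = np.cumsum(MOVE_PROBABILITIES)

#: The reverse move kind for each move (same proposal probability each way).
_REVERSE = {
    MoveKind.SUBSTITUTE: MoveKind.SUBSTITUTE,
    MoveKind.INSERT_LEFT_SHIFT: MoveKind.DELETE_RIGHT_SHIFT,
    MoveKind.DELETE_RIGHT_SHIFT: MoveKind.INSERT_LEFT_SHIFT,
    MoveKind.INSERT_RIGHT_SHIFT: MoveKind.DELETE_LEFT_SHIFT,
    MoveKind.DELETE_LEFT_SHIFT: MoveKind.INSERT_RIGHT_SHIFT,
}


def apply_move(seq, kind: MoveKind, position: int, symbol):
    """Apply one elementary move; ``position`` is 1-based.

    Strings in, strings out; integer code arrays in, arrays out.  Every move
    keeps the length: one symbol leaves the sequence, the proposed one enters.
    """
    as_str = isinstance(seq, str)
    n = len(seq)
    if not (1 <= position <= n):
        raise ValueError(f"position {position} out of range 1..{n}")
    k = position - 1
    if as_str:
        s = seq
        if kind == MoveKind.SUBSTITUTE:
            return s[:k] + symbol + s[k + 1 :]
        if kind == MoveKind.INSERT_LEFT_SHIFT:
            # drop the first symbol, insert the new one at `position`
            return s[1 : k + 1] + symbol + s[k + 1 :]
        if kind == MoveKind.INSERT_RIGHT_SHIFT:
            # insert the new symbol at `position`, drop the last symbol
            return s[:k] + symbol + s[k:-1]
        if kind == MoveKind.DELETE_RIGHT_SHIFT:
            # delete at `position`, prefix shifts right, new symbol up front
            return symbol + s[:k] + s[k + 1 :]
        if kind == MoveKind.DELETE_LEFT_SHIFT:
            # delete at `position`, suffix shifts left, new symbol at the end
            return s[:k] + s[k + 1 :] + symbol
        raise ValueError(f"unknown move kind {kind!r}")  # pragma: no cover
    s = np.asarray(seq)
    out = np.empty(n, dtype=s.dtype)
    if kind == MoveKind.SUBSTITUTE:
        out[:] = s
        out[k] = symbol
    elif kind == MoveKind.INSERT_LEFT_SHIFT:
        out[:k] = s[1 : k + 1]
        out[k] = symbol
        out[k + 1 :] = s[k + 1 :]
    elif kind == MoveKind.INSERT_RIGHT_SHIFT:
        out[:k] = s[:k]
        out[k] = symbol
        out[k + 1 :] = s[k:-1]
    elif kind == MoveKind.DELETE_RIGHT_SHIFT:
        out[0] = symbol
        out[1 : k + 1] = s[:k]
        out[k + 1 :] = s[k + 1 :]
    elif kind == MoveKind.DELETE_LEFT_SHIFT:
        out[:k] = s[:k]
        out[k:-1] = s[k + 1 :]
        out[-1] = symbol
    else:  # pragma: no cover
        raise ValueError(f"unknown move kind {kind!r}")
    return out


def _removed_symbol(s: list | np.ndarray, kind: MoveKind, k: int):
    """Which symbol the move removes (0-based position k)."""
    if kind == MoveKind.SUBSTITUTE or kind in (
        MoveKind.DELETE_RIGHT_SHIFT,
        MoveKind.DELETE_LEFT_SHIFT,
    ):
        return s[k]
    if kind == MoveKind.INSERT_LEFT_SHIFT:
        return s[0]
    return s[-1]  # INSERT_RIGHT_SHIFT


@dataclass(frozen=True)
class ProposalPolicy:
    """How proposals are drawn.

    ``which_sequence``: "both_with_prob_half" mutates query or subject with
    probability 1/2 each; "subject_only" never touches the query (fixed-query
    mode).  ``symbol_distribution``: "null_freqs" draws replacement symbols
    from the i.i.d. background (ratio cancels in the acceptance), "uniform"
    draws them uniformly (required for HMM queries).
    """

    which_sequence: str = "both_with_prob_half"
    symbol_distribution: str = "null_freqs"

    def __post_init__(self) -> None:
        if self.which_sequence not in ("both_with_prob_half", "subject_only"):
            raise ValueError(self.which_sequence)
        if self.symbol_distribution not in ("null_freqs", "uniform"):
            raise ValueError(self.symbol_distribution)


class NullModelPair:
    """The factorized null model p(x, y) = f_query(x) * f_subject(y)."""

    def __init__(self, query_model, subject_model: IIDModel):
        self.query_model = query_model
        self.subject_model = subject_model
        if isinstance(query_model, HiddenMarkovModel):
            self.mode = "HMM"
        elif isinstance(query_model, FixedQueryModel):
            self.mode = "FQPS"
        elif isinstance(query_model, IIDModel):
            self.mode = "RQGS"
        else:
            raise TypeError(f"unsupported query model {type(query_model)!r}")

    def default_policy(self) -> ProposalPolicy:
        if self.mode == "FQPS":
            return ProposalPolicy("subject_only", "null_freqs")
        if self.mode == "HMM":
            return ProposalPolicy("both_with_prob_half", "uniform")
        return ProposalPolicy("both_with_prob_half", "null_freqs")

    def log_null(self, x, y) -> float:
        return float(self.query_model.log_prob(x) + self.subject_model.log_prob(y))


@dataclass
class Configuration:
    """Current sampler state: the pair, its score, class and null log-prob."""

    x: np.ndarray
    y: np.ndarray
    score: int
    n_tm: int
    log_null: float
    hidden_path: Optional[np.ndarray] = None

    def copy(self) -> "Configuration":
        return Configuration(
            self.x.copy(),
            self.y.copy(),
            self.score,
            self.n_tm,
            self.log_null,
            None if self.hidden_path is None else self.hidden_path.copy(),
        )


@dataclass
class Proposal:
    target: str  # "query" | "subject"
    kind: MoveKind
    position: int  # 1-based
    symbol: int
    removed: int
    new_seq: np.ndarray
    log_proposal_ratio: float  # log(P_rev / P_fwd)


def make_configuration(
    models: NullModelPair,
    scheme: PositionSpecificScheme,
    x: np.ndarray,
    y: np.ndarray,
) -> Configuration:
    """Assemble a consistent Configuration for a given pair."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    score = smith_waterman_score(x, y, scheme)
    if models.mode == "HMM":
        vit = viterbi_path(models.query_model, x)
        n_tm = count_tm_helices(vit.path, models.query_model)
        path = vit.path
    else:
        n_tm, path = 0, None
    return Configuration(x, y, score, n_tm, models.log_null(x, y), path)


def propose(
    config: Configuration,
    policy: ProposalPolicy,
    models: NullModelPair,
    rng: np.random.Generator,
) -> Proposal:
    """Draw one proposal; returns enough to evaluate the acceptance ratio.

    For ``null_freqs`` symbol draws the returned log-proposal ratio cancels
    the null-probability ratio of i.i.d. sequences exactly (float-exactly,
    both being differences of the same two log-frequency values).
    """
    if policy.which_sequence == "subject_only" or rng.random() < 0.5:
        target, seq = "subject", config.y
    else:
        target, seq = "query", config.x
    kind = MoveKind(int(np.searchsorted(_MOVE_CUM, rng.random(), side="right")))
    position = int(rng.integers(1, seq.shape[0] + 1))
    subject_model = models.subject_model
    log_freqs = subject_model.log_freqs
    if policy.symbol_distribution == "null_freqs":
        cum = getattr(subject_model, "_cum_freqs", None)
        if cum is None:
            cum = np.cumsum(subject_model.freqs)
            subject_model._cum_freqs = cum
        symbol = min(
            int(np.searchsorted(cum, rng.random(), side="right")),
            log_freqs.shape[0] - 1,
        )
    else:
        symbol = int(rng.integers(0, log_freqs.shape[0]))
    removed = int(_removed_symbol(seq, kind, position - 1))
    new_seq = apply_move(seq, kind, position, symbol)
    if policy.symbol_distribution == "null_freqs":
        log_ratio = float(log_freqs[removed] - log_freqs[symbol])
    else:
        log_ratio = 0.0
    return Proposal(target, kind, position, symbol, removed, new_seq, log_ratio)


def _candidate_state(
    config: Configuration,
    prop: Proposal,
    models: NullModelPair,
    scheme: PositionSpecificScheme,
):
    """Score, class, null log-prob and hidden path of the proposed pair."""
    log_freqs = models.subject_model.log_freqs
    if prop.target == "subject":
        x, y = config.x, prop.new_seq
        n_tm, path = config.n_tm, config.hidden_path
        log_null = config.log_null + float(
            log_freqs[prop.symbol] - log_freqs[prop.removed]
        )
    else:
        x, y = prop.new_seq, config.y
        if models.mode == "HMM":
            vit = viterbi_path(models.query_model, x)
            n_tm = count_tm_helices(vit.path, models.query_model)
            path = vit.path
            log_null = float(
                forward_log_prob(models.query_model, x).log_prob
            ) + float(models.subject_model.log_prob(config.y))
        else:
            n_tm, path = 0, None
            log_null = config.log_null + float(
                log_freqs[prop.symbol] - log_freqs[prop.removed]
            )
    score = smith_waterman_score(x, y, scheme)
    return x, y, score, n_tm, log_null, path


def mh_update(
    config: Configuration,
    weights,
    models: NullModelPair,
    scheme: PositionSpecificScheme,
    policy: ProposalPolicy,
    rng: np.random.Generator,
) -> tuple[Configuration, bool]:
    """One Metropolis-Hastings update; returns (configuration, accepted).

    ``weights`` must provide ``log_w_at(score, n_tm) -> float | None``; a
    proposal whose (score, class) falls outside the supported window is
    rejected (the current configuration is re-counted by the caller), never
    raised.  The acceptance ratio is
    ``min{1, w[s',n'] p' P_rev / (w[s,n] p P_fwd)}``; with background-frequency
    symbol proposals the p/P factors cancel and the reduced Metropolis form
    ``w(s')/w(s)`` results.
    """
    prop = propose(config, policy, models, rng)
    x, y, score, n_tm, log_null, path = _candidate_state(
        config, prop, models, scheme
    )
    lw_new = weights.log_w_at(score, n_tm)
    if lw_new is None:
        return config, False
    lw_old = weights.log_w_at(config.score, config.n_tm)
    if lw_old is None:
        raise RuntimeError("current configuration outside the score window")
    log_alpha = (
        lw_new - lw_old + (log_null - config.log_null) + prop.log_proposal_ratio
    )
    if log_alpha >= 0.0 or math.log(rng.random()) < log_alpha:
        return Configuration(x, y, score, n_tm, log_null, path), True
    return config, False


class UniformWeights:
    """Flat weights: the chain samples the null model itself."""

    def log_w_at(self, score: int, n_tm: int) -> float:
        return 0.0
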