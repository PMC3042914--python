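"""Brute-force oracles on tiny sequence universes.

Everything here re-derives quantities by exhaustive enumeration, on universes
small enough that |Sigma|^(Lq+Ls) stays below a million configurations: the
exact score (and class) distribution, optimal alignment scores maximized
over every non-crossing pair set, and the explicit Metropolis-Hastings
transition matrix.  These serve as independent ground truth for the sampler,
the aligner and the reweighting estimator; none of them call the dynamic
programming or chain code they are used to check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .mcmc import (
    MOVE_PROBABILITIES,
    MoveKind,
    NullModelPair,
    ProposalPolicy,
    apply_move,
)
from .null_models import (
    Alphabet,
    FixedQueryModel,
    HiddenMarkovModel,
    IIDModel,
    count_tm_helices,
    viterbi_path,
)
from .scoring import GapPenalty, PositionSpecificScheme

__all__ = [
    "ToyUniverse",
    "enumerate_alignments",
    "exact_score_distribution",
    "chain_transition_matrix",
]

_MAX_CONFIGS = 1_000_000


@dataclass
class ToyUniverse:
    """A fully enumerable space of sequence pairs."""

    models: NullModelPair
    scheme: PositionSpecificScheme
    query_length: int
    subject_length: int

    def __post_init__(self) -> None:
        a = len(self.scheme.alphabet)
        fixed = isinstance(self.models.query_model, FixedQueryModel)
        n = a ** (self.subject_length + (0 if fixed else self.query_length))
        if n > _MAX_CONFIGS:
            raise ValueError(f"{n} configurations exceed the enumeration bound")
        self.n_configs = n

    def queries(self):
        if isinstance(self.models.query_model, FixedQueryModel):
            yield tuple(int(c) for c in self.models.query_model.query_codes)
            return
        a = len(self.scheme.alphabet)
        yield from itertools.product(range(a), repeat=self.query_length)

    def subjects(self):
        a = len(self.scheme.alphabet)
        yield from itertools.product(range(a), repeat=self.subject_length)

    def configurations(self):
        for x in self.queries():
            for y in self.subjects():
                yield x, y


def enumerate_alignments(x, y, scheme: PositionSpecificScheme) -> int:
    """Optimal local score by exhaustive search over all pair sets.

    Non-crossing pair sets between sorted row and column subsets of equal
    size are in bijection with the subset pairs themselves; affine gap costs
    are charged for unpaired stretches strictly between consecutive pairs.
    Deliberately naive (no DP) so it is an independent check.
    """
    xa = [scheme.alphabet.index(c) for c in x] if isinstance(x, str) else list(x)
    ya = [scheme.alphabet.index(c) for c in y] if isinstance(y, str) else list(y)
    lq, ls = len(xa), len(ya)
    if max(lq, ls) > 6:
        raise ValueError("enumeration oracle limited to sequences of length <= 6")
    row_mat = scheme.row_matrix_index(lq) if lq else np.zeros(0, int)
    mats = scheme._stack
    a_open, a_ext = scheme.gaps.open, scheme.gaps.extend
    if scheme.gaps.convention == "open_plus_len":
        gap_cost = lambda l: a_open + a_ext * l
    else:
        gap_cost = lambda l: a_open + a_ext * (l - 1)
    best = 0  # the empty alignment is always feasible
    for k in range(1, min(lq, ls) + 1):
        for rows in itertools.combinations(range(lq), k):
            for cols in itertools.combinations(range(ls), k):
                s = 0
                for i, j in zip(rows, cols):
                    s += int(mats[row_mat[i]][xa[i], ya[j]])
                for t in range(k - 1):
                    gx = rows[t + 1] - rows[t] - 1
                    gy = cols[t + 1] - cols[t] - 1
                    if gx:
                        s -= gap_cost(gx)
                    if gy:
                        s -= gap_cost(gy)
                if s > best:
                    best = s
    return best


def _config_log_prob(models: NullModelPair, x, y) -> float:
    return models.log_null(np.array(x, dtype=np.int64), np.array(y, dtype=np.int64))


def _config_class(models: NullModelPair, x) -> int:
    if models.mode != "HMM":
        return 0
    vit = viterbi_path(models.query_model, np.array(x, dtype=np.int64))
    return count_tm_helices(vit.path, models.query_model)


def exact_score_distribution(
    universe: ToyUniverse, scorer=None
) -> dict[tuple[int, int], float]:
    """Exact joint pmf P(S = s, n_TM = n) by full enumeration.

    ``scorer(x, y, scheme)`` defaults to the brute-force alignment
    enumeration; pass a faster scorer for larger toys once it has been
    validated against the oracle.
    """
    scorer = scorer or enumerate_alignments
    pmf: dict[tuple[int, int], float] = {}
    for x in universe.queries():
        n = _config_class(universe.models, x)
        lpx = float(
            universe.models.query_model.log_prob(np.array(x, dtype=np.int64))
        )
        for y in universe.subjects():
            lp = lpx + float(
                universe.models.subject_model.log_prob(np.array(y, dtype=np.int64))
            )
            s = scorer(x, y, universe.scheme)
            pmf[(s, n)] = pmf.get((s, n), 0.0) + math.exp(lp)
    return pmf


def chain_transition_matrix(
    universe: ToyUniverse,
    weights,
    policy: ProposalPolicy | None = None,
    scorer=None,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Explicit transition matrix of the Metropolis-Hastings kernel.

    Assembles T[a, b] = sum over proposals leading a -> b of
    (proposal probability) x (acceptance), with rejected probability mass on
    the diagonal.  Returns (T, stationary q from the left eigenvector,
    ordered configuration list).  ``weights`` follows the
    ``log_w_at(score, n)`` protocol; proposals outside its window are
    rejected, mirroring the sampler.
    """
    models = universe.models
    policy = policy or models.default_policy()
    scorer = scorer or enumerate_alignments
    configs = list(universe.configurations())
    index = {c: i for i, c in enumerate(configs)}
    n = len(configs)

    info = []
    for x, y in configs:
        info.append(
            (
                scorer(x, y, universe.scheme),
                _config_class(models, x),
                _config_log_prob(models, x, y),
            )
        )

    freqs = models.subject_model.freqs
    log_freqs = models.subject_model.log_freqs
    a_size = len(freqs)
    T = np.zeros((n, n))
    for ai, (x, y) in enumerate(configs):
        s_a, n_a, lp_a = info[ai]
        lw_a = weights.log_w_at(s_a, n_a)
        if lw_a is None:
            raise ValueError("a configuration lies outside the weight window")
        targets = (
            [("subject", 1.0)]
            if policy.which_sequence == "subject_only"
            else [("query", 0.5), ("subject", 0.5)]
        )
        for target, p_target in targets:
            seq = x if target == "query" else y
            length = len(seq)
            for kind in MoveKind:
                p_kind = MOVE_PROBABILITIES[kind]
                for pos in range(1, length + 1):
                    removed = _oracle_removed(seq, kind, pos)
                    for sym in range(a_size):
                        if policy.symbol_distribution == "null_freqs":
                            p_sym = freqs[sym]
                            log_ratio = float(log_freqs[removed] - log_freqs[sym])
                        else:
                            p_sym = 1.0 / a_size
                            log_ratio = 0.0
                        p_prop = p_target * p_kind * (1.0 / length) * p_sym
                        new_seq = tuple(
                            int(v)
                            for v in apply_move(
                                np.array(seq, dtype=np.int64), kind, pos, sym
                            )
                        )
                        b = (new_seq, y) if target == "query" else (x, new_seq)
                        bi = index[b]
                        s_b, n_b, lp_b = info[bi]
                        lw_b = weights.log_w_at(s_b, n_b)
                        if lw_b is None:
                            alpha = 0.0
                        else:
                            log_alpha = lw_b - lw_a + (lp_b - lp_a) + log_ratio
                            alpha = min(1.0, math.exp(min(log_alpha, 0.0)))
                        T[ai, bi] += p_prop * alpha
                        T[ai, ai] += p_prop * (1.0 - alpha)
    row_sums = T.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-10):
        raise AssertionError(f"transition rows do not sum to 1: {row_sums}")
    evals, evecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(evals - 1.0)))
    q = np.real(evecs[:, k])
    q = q / q.sum()
    return T, q, configs


def _oracle_removed(seq, kind: MoveKind, position: int) -> int:
    k = position - 1
    if kind in (MoveKind.SUBSTITUTE, MoveKind.DELETE_RIGHT_SHIFT, MoveKind.DELETE_LEFT_SHIFT):
        return int(seq[k])
    if kind == MoveKind.INSERT_LEFT_SHIFT:
        return int(seq[0])
    return int(seq[-1])
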