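"""Deterministic toy models shared by the test-suite and the oracle command.

The standard toy universe uses a 2-letter alphabet with a +2/-1 match/mismatch
matrix and affine gaps 2 + 1*l; its expected score under the default biased
background (0.6/0.4) is negative, mirroring the standing assumption for real
substitution matrices.
"""

from __future__ import annotations

import numpy as np

from .mcmc import NullModelPair
from .null_models import Alphabet, HiddenMarkovModel, IIDModel
from .oracles import ToyUniverse
from .scoring import GapPenalty, PositionSpecificScheme, ScoringMatrix

__all__ = ["toy_alphabet", "toy_scheme", "toy_models", "toy_universe", "toy_hmm"]


def toy_alphabet(size: int = 2) -> Alphabet:
    return Alphabet.from_string("ABCDEF"[:size])


def toy_matrix(alphabet: Alphabet, match: int = 2, mismatch: int = -1) -> ScoringMatrix:
    n = len(alphabet)
    m = np.full((n, n), mismatch, dtype=np.int64)
    np.fill_diagonal(m, match)
    return ScoringMatrix(alphabet, m, "toy")


def toy_scheme(
    alphabet_size: int = 2,
    match: int = 2,
    mismatch: int = -1,
    gap_open: int = 2,
    gap_extend: int = 1,
) -> PositionSpecificScheme:
    alphabet = toy_alphabet(alphabet_size)
    return PositionSpecificScheme(
        toy_matrix(alphabet, match, mismatch), GapPenalty(gap_open, gap_extend)
    )


def toy_freqs(size: int) -> np.ndarray:
    w = np.linspace(1.5, 1.0, size)
    return w / w.sum()


def toy_models(alphabet_size: int = 2) -> NullModelPair:
    alphabet = toy_alphabet(alphabet_size)
    bg = IIDModel(alphabet, toy_freqs(alphabet_size))
    return NullModelPair(bg, bg)


def toy_universe(alphabet_size: int = 2, length: int = 3) -> ToyUniverse:
    return ToyUniverse(
        models=toy_models(alphabet_size),
        scheme=toy_scheme(alphabet_size),
        query_length=length,
        subject_length=length,
    )


def toy_hmm(n_states: int = 2, alphabet_size: int = 2, seed: int = 7) -> HiddenMarkovModel:
    """A small random (but seed-deterministic) HMM with dense parameters."""
    rng = np.random.default_rng(seed)
    alphabet = toy_alphabet(alphabet_size)
    init = rng.dirichlet(np.ones(n_states) * 3)
    emis = rng.dirichlet(np.ones(alphabet_size) * 3, size=n_states)
    trans = rng.dirichlet(np.ones(n_states) * 3, size=n_states)
    names = [f"s{i}" for i in range(n_states)]
    return HiddenMarkovModel(
        alphabet, names, init, emis, trans,
        helix_core_states=[names[0]],
    )
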