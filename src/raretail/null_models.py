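"""Null models for sequence pairs: i.i.d., fixed-query and hidden-Markov.

The score statistics of local alignment are always relative to a null model
for the pair (query, subject).  Three families are supported:

* ``IIDModel`` -- every position drawn independently from a background
  composition (both sequences random: the classical "RQGS" setting);
* ``FixedQueryModel`` -- the query is a given sequence, only the subject is
  random i.i.d. ("FQPS");
* ``HiddenMarkovModel`` -- the query is drawn from an HMM (here: a
  transmembrane-topology architecture), the subject is i.i.d.

All probabilities are handled in log domain throughout; raw path
probabilities underflow double precision around sequence length 350.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.special import logsumexp

__all__ = [
    "Alphabet",
    "PROTEIN_ALPHABET",
    "IIDModel",
    "FixedQueryModel",
    "HiddenMarkovModel",
    "ForwardResult",
    "ViterbiResult",
    "iid_log_prob",
    "sample_iid",
    "forward_log_prob",
    "viterbi_path",
    "count_tm_helices",
    "load_hmm",
    "save_hmm",
    "sample_hmm",
    "TMHMMArchitecture",
    "build_tmhmm_layout",
    "count_free_parameters",
    "load_frequencies",
    "swissprot_frequencies",
]

_NEG_INF = float("-inf")


class AlphabetError(ValueError):
    """A symbol outside the model alphabet was encountered."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of single-character symbols."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if any(len(s) != 1 for s in self.symbols):
            raise ValueError("alphabet symbols must be single characters")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.symbols)})

    @classmethod
    def from_string(cls, s: str) -> "Alphabet":
        return cls(tuple(s))

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, sym: str) -> bool:
        return sym in self._index

    def index(self, sym: str) -> int:
        try:
            return self._index[sym]
        except KeyError:
            raise AlphabetError(f"symbol {sym!r} not in alphabet") from None

    def encode(self, seq: str) -> np.ndarray:
        """Map a string to an int array; reports the offending position."""
        out = np.empty(len(seq), dtype=np.int64)
        for i, c in enumerate(seq):
            j = self._index.get(c)
            if j is None:
                raise AlphabetError(
                    f"symbol {c!r} at position {i + 1} not in alphabet"
                )
            out[i] = j
        return out

    def decode(self, codes: Iterable[int]) -> str:
        return "".join(self.symbols[int(c)] for c in codes)


#: The 20 standard amino acids, alphabetical by one-letter code.
PROTEIN_ALPHABET = Alphabet.from_string("ACDEFGHIKLMNPQRSTVWY")


def _as_codes(seq, alphabet: Alphabet) -> np.ndarray:
    if isinstance(seq, str):
        return alphabet.encode(seq)
    return np.asarray(seq, dtype=np.int64)


class IIDModel:
    """Independent draws from a fixed background composition."""

    def __init__(self, alphabet: Alphabet, freqs: Mapping[str, float] | np.ndarray):
        self.alphabet = alphabet
        if isinstance(freqs, Mapping):
            missing = [s for s in alphabet.symbols if s not in freqs]
            if missing:
                raise ValueError(f"missing frequencies for {missing}")
            f = np.array([float(freqs[s]) for s in alphabet.symbols])
        else:
            f = np.asarray(freqs, dtype=float)
            if f.shape != (len(alphabet),):
                raise ValueError("frequency vector length mismatch")
        if np.any(f <= 0):
            raise ValueError("all frequencies must be strictly positive")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError(f"frequencies sum to {f.sum()!r}, not 1")
        self.freqs = f
        self.log_freqs = np.log(f)

    def log_prob(self, seq) -> float:
        codes = _as_codes(seq, self.alphabet)
        return float(self.log_freqs[codes].sum()) if codes.size else 0.0

    def sample(self, length: int, rng: np.random.Generator) -> np.ndarray:
        if length < 0:
            raise ValueError("length must be >= 0")
        return rng.choice(len(self.alphabet), size=length, p=self.freqs).astype(
            np.int64
        )


@dataclass
class FixedQueryModel:
    """A fixed query sequence; randomness lives only in the subject."""

    query: str
    subject_model: IIDModel
    query_codes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(self.query) < 1:
            raise ValueError("query must be non-empty")
        self.query_codes = self.subject_model.alphabet.encode(self.query)

    def log_prob(self, seq) -> float:
        """log 1{x = query}: 0 for the query itself, -inf otherwise."""
        codes = _as_codes(seq, self.subject_model.alphabet)
        if codes.shape == self.query_codes.shape and np.array_equal(
            codes, self.query_codes
        ):
            return 0.0
        return _NEG_INF


def iid_log_prob(model: IIDModel, seq) -> float:
    """Log-probability of ``seq`` under an i.i.d. model (0 for empty)."""
    return model.log_prob(seq)


def sample_iid(model: IIDModel, length: int, rng: np.random.Generator) -> np.ndarray:
    return model.sample(length, rng)


# --------------------------------------------------------------------------
# Hidden Markov model
# --------------------------------------------------------------------------


@dataclass
class ForwardResult:
    log_prob: float
    table: np.ndarray  # (L, n_states) log f_mu(i)


@dataclass
class ViterbiResult:
    path: np.ndarray  # (L,) state indices
    log_prob: float
    table: np.ndarray  # (L, n_states) log v_mu(i)


class HMMSpecError(ValueError):
    """Malformed HMM specification."""


class HiddenMarkovModel:
    """A discrete HMM with tied emission groups and helix-core labels.

    Parameters
    ----------
    alphabet : Alphabet
        Output symbols (amino acids).
    states : sequence of str
        Ordered state names.
    initial : array (n_states,)
        Initial state distribution pi.
    emissions : array (n_states, n_symbols)
        Row-stochastic emission probabilities p(sigma | mu).
    transitions : array (n_states, n_states)
        Row-stochastic transition matrix p(mu -> tau).
    tie_groups : mapping group name -> list of state names
        Partition of the states; states in a group share (bit-identical)
        emission rows.
    helix_core_states : iterable of state names
        States whose maximal runs in a path count as transmembrane helices.
    """

    def __init__(
        self,
        alphabet: Alphabet,
        states: Sequence[str],
        initial: np.ndarray,
        emissions: np.ndarray,
        transitions: np.ndarray,
        tie_groups: Mapping[str, Sequence[str]] | None = None,
        helix_core_states: Iterable[str] = (),
    ):
        self.alphabet = alphabet
        self.states = tuple(states)
        if len(set(self.states)) != len(self.states):
            raise HMMSpecError("duplicate state names")
        self.state_index = {s: i for i, s in enumerate(self.states)}
        n, a = len(self.states), len(alphabet)

        self.initial = np.asarray(initial, dtype=float)
        self.emissions = np.asarray(emissions, dtype=float)
        self.transitions = np.asarray(transitions, dtype=float)
        if self.initial.shape != (n,):
            raise HMMSpecError("initial vector has wrong shape")
        if self.emissions.shape != (n, a):
            raise HMMSpecError("emission matrix has wrong shape")
        if self.transitions.shape != (n, n):
            raise HMMSpecError("transition matrix has wrong shape")
        if abs(self.initial.sum() - 1.0) > 1e-12 or np.any(self.initial < 0):
            raise HMMSpecError("initial probabilities must be a distribution")
        for i, row in enumerate(self.emissions):
            if abs(row.sum() - 1.0) > 1e-12 or np.any(row < 0):
                raise HMMSpecError(
                    f"emission row for state {self.states[i]!r} is not stochastic"
                )
        for i, row in enumerate(self.transitions):
            if abs(row.sum() - 1.0) > 1e-12 or np.any(row < 0):
                raise HMMSpecError(
                    f"transition row for state {self.states[i]!r} sums to "
                    f"{row.sum()!r}"
                )

        if tie_groups is None:
            tie_groups = {s: [s] for s in self.states}
        self.tie_groups = {g: tuple(members) for g, members in tie_groups.items()}
        seen: set[str] = set()
        for g, members in self.tie_groups.items():
            for s in members:
                if s not in self.state_index:
                    raise HMMSpecError(f"tie group {g!r} references unknown state {s!r}")
                if s in seen:
                    raise HMMSpecError(f"state {s!r} appears in two tie groups")
                seen.add(s)
        if seen != set(self.states):
            raise HMMSpecError("tie groups must partition the states")
        for g, members in self.tie_groups.items():
            rows = self.emissions[[self.state_index[s] for s in members]]
            if not (rows == rows[0]).all():
                raise HMMSpecError(f"tied states in group {g!r} have unequal emissions")

        self.helix_core_states = frozenset(helix_core_states)
        for s in self.helix_core_states:
            if s not in self.state_index:
                raise HMMSpecError(f"unknown helix-core state {s!r}")
        self.helix_core_mask = np.array(
            [s in self.helix_core_states for s in self.states]
        )

        with np.errstate(divide="ignore"):
            self.log_initial = np.log(self.initial)
            self.log_emissions = np.log(self.emissions)
            self.log_transitions = np.log(self.transitions)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def log_prob(self, seq) -> float:
        return forward_log_prob(self, seq).log_prob

    def sample(self, length: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw (symbol sequence, state path) of the given length."""
        n = self.n_states
        path = np.empty(length, dtype=np.int64)
        sym = np.empty(length, dtype=np.int64)
        if length == 0:
            return sym, path
        z = rng.choice(n, p=self.initial)
        for i in range(length):
            path[i] = z
            sym[i] = rng.choice(len(self.alphabet), p=self.emissions[z])
            z = rng.choice(n, p=self.transitions[z])
        return sym, path


def forward_log_prob(hmm: HiddenMarkovModel, seq) -> ForwardResult:
    """Total log-probability of the symbol sequence over all state paths.

    Implements the forward recursion
    ``f_mu(i) = p(x_i | mu) * sum_tau f_tau(i-1) p(tau -> mu)`` with
    ``f_mu(1) = pi_mu p(x_1 | mu)``, in log domain.  A sequence with zero
    probability yields -inf (no exception).
    """
    codes = _as_codes(seq, hmm.alphabet)
    if codes.size == 0:
        raise ValueError("sequence must be non-empty")
    L, n = codes.size, hmm.n_states
    table = np.empty((L, n))
    table[0] = hmm.log_initial + hmm.log_emissions[:, codes[0]]
    logT = hmm.log_transitions
    for i in range(1, L):
        prev = table[i - 1][:, None] + logT  # (tau, mu)
        with np.errstate(invalid="ignore"):
            table[i] = hmm.log_emissions[:, codes[i]] + logsumexp(prev, axis=0)
    lp = float(logsumexp(table[-1]))
    return ForwardResult(log_prob=lp, table=table)


def viterbi_path(hmm: HiddenMarkovModel, seq) -> ViterbiResult:
    """Most probable state path (ties broken by lowest state index)."""
    codes = _as_codes(seq, hmm.alphabet)
    if codes.size == 0:
        raise ValueError("sequence must be non-empty")
    L, n = codes.size, hmm.n_states
    table = np.empty((L, n))
    back = np.zeros((L, n), dtype=np.int64)
    table[0] = hmm.log_initial + hmm.log_emissions[:, codes[0]]
    logT = hmm.log_transitions
    for i in range(1, L):
        cand = table[i - 1][:, None] + logT  # (tau, mu)
        # argmax returns the lowest index on ties, which is the tie rule
        back[i] = np.argmax(cand, axis=0)
        table[i] = hmm.log_emissions[:, codes[i]] + cand[back[i], np.arange(n)]
    path = np.empty(L, dtype=np.int64)
    path[-1] = int(np.argmax(table[-1]))
    lp = float(table[-1, path[-1]])
    for i in range(L - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return ViterbiResult(path=path, log_prob=lp, table=table)


def count_tm_helices(path, hmm: HiddenMarkovModel) -> int:
    """Number of maximal runs of helix-core states in a state path."""
    p = np.asarray(path, dtype=np.int64)
    if p.size == 0:
        return 0
    core = hmm.helix_core_mask[p]
    starts = core & ~np.concatenate(([False], core[:-1]))
    return int(starts.sum())


# --------------------------------------------------------------------------
# Serialization (YAML-based structured text)
# --------------------------------------------------------------------------


def save_hmm(hmm: HiddenMarkovModel, path) -> None:
    doc = {
        "alphabet": "".join(hmm.alphabet.symbols),
        "states": list(hmm.states),
        "initial": {s: float(p) for s, p in zip(hmm.states, hmm.initial) if p > 0},
        "tie_groups": {g: list(m) for g, m in hmm.tie_groups.items()},
        # one emission row per tie group (rows are identical within a group)
        "emissions": {
            g: [float(v) for v in hmm.emissions[hmm.state_index[m[0]]]]
            for g, m in hmm.tie_groups.items()
        },
        "transitions": {
            s: {
                t: float(p)
                for t, p in zip(hmm.states, hmm.transitions[i])
                if p > 0
            }
            for i, s in enumerate(hmm.states)
        },
        "helix_core_states": sorted(hmm.helix_core_states),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_hmm(path) -> HiddenMarkovModel:
    """Load an HMM spec file; all stochasticity invariants are re-checked."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        alphabet = Alphabet.from_string(doc["alphabet"])
        states = list(doc["states"])
        index = {s: i for i, s in enumerate(states)}
        n, a = len(states), len(alphabet)
        initial = np.zeros(n)
        for s, p in doc.get("initial", {}).items():
            if s not in index:
                raise HMMSpecError(f"initial references unknown state {s!r}")
            initial[index[s]] = p
        tie_groups = doc.get("tie_groups") or {s: [s] for s in states}
        emissions = np.zeros((n, a))
        for g, members in tie_groups.items():
            if g not in doc["emissions"]:
                raise HMMSpecError(f"no emission row for tie group {g!r}")
            row = np.asarray(doc["emissions"][g], dtype=float)
            for s in members:
                if s not in index:
                    raise HMMSpecError(
                        f"tie group {g!r} references unknown state {s!r}"
                    )
                emissions[index[s]] = row
        transitions = np.zeros((n, n))
        for s, row in doc["transitions"].items():
            if s not in index:
                raise HMMSpecError(f"transition row for unknown state {s!r}")
            for t, p in row.items():
                if t not in index:
                    raise HMMSpecError(
                        f"transition {s!r} -> unknown state {t!r}"
                    )
                transitions[index[s], index[t]] = p
    except KeyError as exc:
        raise HMMSpecError(f"missing section {exc}") from None
    return HiddenMarkovModel(
        alphabet,
        states,
        initial,
        emissions,
        transitions,
        tie_groups=tie_groups,
        helix_core_states=doc.get("helix_core_states", ()),
    )


def sample_hmm(
    hmm: HiddenMarkovModel, length: int, rng: np.random.Generator
) -> np.ndarray:
    sym, _ = hmm.sample(length, rng)
    return sym


# --------------------------------------------------------------------------
# Transmembrane-topology architecture
# --------------------------------------------------------------------------


@dataclass
class TMHMMArchitecture:
    """An assembled transmembrane-topology HMM plus parameter bookkeeping.

    ``parameter_groups`` lists every independent probability simplex of the
    architecture as ``(name, n_outcomes, kind)``; the number of free
    parameters of a simplex with k outcomes is k - 1.
    """

    hmm: HiddenMarkovModel
    parameter_groups: list[tuple[str, int, str]]

    def free_parameter_breakdown(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for name, k, kind in self.parameter_groups:
            out.setdefault(kind, 0)
            out[kind] += k - 1
        return out


def count_free_parameters(arch: TMHMMArchitecture) -> int:
    """Total number of independent free parameters of the architecture."""
    return sum(k - 1 for _, k, _ in arch.parameter_groups)


# Default (synthetic) parameter values for the architecture.  The original
# trained parameter set is not public; these values only have to produce a
# valid, qualitatively reasonable model so that sampling and Viterbi
# classification can be exercised.  Emission tilts are expressed as odds
# multipliers on the background composition.
_HYDROPHOBIC = "AILMFVWY"

_DEFAULT_TMHMM_PARAMS = {
    "core_length": None,  # filled below: discretized normal around 21
    "loop_jump_in": 0.15,  # ladder state -> globular
    "loop_self": {"cyt": 0.90, "short": 0.85, "long": 0.96},
    "loop_jump_out": 0.15,  # out-ladder state -> module exit
    "branch_short": 0.5,  # short vs long non-cytoplasmic loop
    "initial": {"cyt": 0.5, "short": 0.3, "long": 0.2},
    "emission_tilt": {
        "helix_core": {s: 4.0 for s in _HYDROPHOBIC},
        "cap_cyt": {"W": 2.0, "Y": 2.0, "F": 1.5, "R": 1.5, "K": 1.5},
        "cap_ncyt": {"W": 2.0, "Y": 2.0, "F": 1.5, "N": 1.3},
        "loop_cyt": {"R": 1.8, "K": 1.8},
        "loop_short_ncyt": {},
        "loop_long_ncyt": {},
        "globular": {},
    },
}


def _core_length_distribution() -> np.ndarray:
    """Length distribution over helix-core lengths 5..25 (21 outcomes)."""
    lengths = np.arange(5, 26)
    w = np.exp(-0.5 * ((lengths - 21) / 3.0) ** 2)
    return w / w.sum()


def _tilted(background: np.ndarray, alphabet: Alphabet, tilt: Mapping[str, float]) -> np.ndarray:
    f = background.copy()
    for sym, mult in tilt.items():
        f[alphabet.index(sym)] *= mult
    return f / f.sum()


def build_tmhmm_layout(
    params: Mapping | None = None,
    background: np.ndarray | None = None,
    alphabet: Alphabet = PROTEIN_ALPHABET,
) -> TMHMMArchitecture:
    """Assemble the transmembrane-topology HMM layout.

    The architecture follows the classical transmembrane HMM: a cycle of
    cytoplasmic loop -> helix (cap / 25-state core with entry jumps / cap) ->
    non-cytoplasmic side with either a short or a long loop -> mirrored helix
    back to the cytoplasmic side.  Loops are 10+10 state ladders with a
    self-looping globular state in the middle; caps have fixed length 5;
    helix-core lengths 5..25 are modelled by the core entry distribution.
    Emissions are tied in 7 groups (helix core, the two cap sides, the three
    loop types, globular); the two helix directions share all parameters.

    Free-parameter accounting (one simplex constraint per distribution):
    7 x 19 emission + 20 core-length + 3 x (10 in-ladder + 1 globular
    self-loop + 9 out-ladder) + 1 short/long branch + 2 initial = 216.

    Parameters are synthetic stand-ins by default (the published trained
    values are not redistributable); pass ``params`` (same structure as the
    default table, e.g. loaded from YAML) to override.
    """
    p = dict(_DEFAULT_TMHMM_PARAMS)
    if params:
        p.update(params)
    if background is None:
        background = swissprot_frequencies(alphabet).freqs
    core_len = (
        np.asarray(p["core_length"], dtype=float)
        if p.get("core_length") is not None
        else _core_length_distribution()
    )
    if core_len.shape != (21,) or abs(core_len.sum() - 1.0) > 1e-9:
        raise HMMSpecError("core_length must be a 21-point distribution")
    core_len = core_len / core_len.sum()

    emis = {
        g: _tilted(background, alphabet, tilt)
        for g, tilt in p["emission_tilt"].items()
    }

    states: list[str] = []
    groups: dict[str, list[str]] = {g: [] for g in emis}

    def add(name: str, group: str) -> str:
        states.append(name)
        groups[group].append(name)
        return name

    # --- loops: in-ladder (10), globular, out-ladder (10)
    loop_group = {
        "cyt": "loop_cyt",
        "short": "loop_short_ncyt",
        "long": "loop_long_ncyt",
    }
    for loop in ("cyt", "short", "long"):
        for k in range(1, 11):
            add(f"{loop}_in{k}", loop_group[loop])
        add(f"{loop}_glob", "globular")
        for k in range(1, 11):
            add(f"{loop}_out{k}", loop_group[loop])

    # --- two helix directions (cyt->ncyt and ncyt->cyt), tied to each other
    for d in ("f", "b"):  # forward: cyt->ncyt, backward: ncyt->cyt
        entry_cap, exit_cap = (
            ("cap_cyt", "cap_ncyt") if d == "f" else ("cap_ncyt", "cap_cyt")
        )
        for k in range(1, 6):
            add(f"{d}_capin{k}", entry_cap)
        for k in range(1, 26):
            add(f"{d}_core{k}", "helix_core")
        for k in range(1, 6):
            add(f"{d}_capout{k}", exit_cap)

    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    T = np.zeros((n, n))

    def link(a: str, b: str, prob: float = 1.0) -> None:
        T[index[a], index[b]] += prob

    jump_in = float(p["loop_jump_in"])
    jump_out = float(p["loop_jump_out"])
    branch_short = float(p["branch_short"])
    loop_exit_target = {"cyt": "f_capin1", "short": "b_capin1", "long": "b_capin1"}
    for loop in ("cyt", "short", "long"):
        glob = f"{loop}_glob"
        for k in range(1, 10):
            link(f"{loop}_in{k}", f"{loop}_in{k + 1}", 1 - jump_in)
            link(f"{loop}_in{k}", glob, jump_in)
        # last in-ladder state: enter the globular domain or skip it
        link(f"{loop}_in10", glob, jump_in)
        link(f"{loop}_in10", f"{loop}_out1", 1 - jump_in)
        self_p = float(p["loop_self"][loop])
        link(glob, glob, self_p)
        link(glob, f"{loop}_out1", 1 - self_p)
        exit_t = loop_exit_target[loop]
        for k in range(1, 10):
            link(f"{loop}_out{k}", f"{loop}_out{k + 1}", 1 - jump_out)
            link(f"{loop}_out{k}", exit_t, jump_out)
        link(f"{loop}_out10", exit_t, 1.0)  # tail length capped: forced exit

    for d in ("f", "b"):
        for k in range(1, 5):
            link(f"{d}_capin{k}", f"{d}_capin{k + 1}")
        # core entry distribution: entering at core state 26-l gives length l
        for i, length in enumerate(range(5, 26)):
            link(f"{d}_capin5", f"{d}_core{26 - length}", core_len[i])
        for k in range(1, 25):
            link(f"{d}_core{k}", f"{d}_core{k + 1}")
        link(f"{d}_core25", f"{d}_capout1")
        for k in range(1, 5):
            link(f"{d}_capout{k}", f"{d}_capout{k + 1}")
    link("f_capout5", "short_in1", branch_short)
    link("f_capout5", "long_in1", 1 - branch_short)
    link("b_capout5", "cyt_in1", 1.0)

    init = np.zeros(n)
    init[index["cyt_in1"]] = p["initial"]["cyt"]
    init[index["short_in1"]] = p["initial"]["short"]
    init[index["long_in1"]] = p["initial"]["long"]
    if abs(init.sum() - 1.0) > 1e-12:
        raise HMMSpecError("initial loop-entry probabilities must sum to 1")

    emissions = np.zeros((n, len(alphabet)))
    for g, members in groups.items():
        for s in members:
            emissions[index[s]] = emis[g]

    core_states = [s for s in states if "_core" in s]
    hmm = HiddenMarkovModel(
        alphabet,
        states,
        init,
        emissions,
        T,
        tie_groups=groups,
        helix_core_states=core_states,
    )

    param_groups: list[tuple[str, int, str]] = [
        (f"emissions[{g}]", len(alphabet), "emission") for g in sorted(emis)
    ]
    param_groups.append(("core_entry_length", 21, "transition"))
    for loop in ("cyt", "short", "long"):
        for k in range(1, 11):
            param_groups.append((f"{loop}_in{k}_branch", 2, "transition"))
        param_groups.append((f"{loop}_glob_self", 2, "transition"))
        for k in range(1, 10):  # out10 is forced, hence not a parameter
            param_groups.append((f"{loop}_out{k}_branch", 2, "transition"))
    param_groups.append(("short_vs_long_branch", 2, "transition"))
    param_groups.append(("initial_loop_entry", 3, "initial"))

    return TMHMMArchitecture(hmm=hmm, parameter_groups=param_groups)


# --------------------------------------------------------------------------
# Background frequencies
# --------------------------------------------------------------------------


def load_frequencies(path, alphabet: Alphabet = PROTEIN_ALPHABET) -> IIDModel:
    """Read a two-column (symbol, frequency) table; renormalizes to sum 1."""
    freqs: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'symbol frequency'")
            freqs[parts[0]] = float(parts[1])
    total = sum(freqs.values())
    if total <= 0:
        raise ValueError("frequencies must be positive")
    f = {s: v / total for s, v in freqs.items()}
    return IIDModel(alphabet, f)


def swissprot_frequencies(alphabet: Alphabet = PROTEIN_ALPHABET) -> IIDModel:
    """Bundled average Swiss-Prot amino-acid composition."""
    from importlib.resources import files

    path = files("raretail.data").joinpath("swissprot_freqs.txt")
    freqs: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sym, val = line.split()
        freqs[sym] = float(val)
    total = sum(freqs.values())
    return IIDModel(alphabet, {s: v / total for s, v in freqs.items()})
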