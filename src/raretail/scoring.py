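"""Substitution matrices, position-specific schemes and local alignment.

Scores follow the classical conventions: an integer substitution matrix with
negative expected score under the background composition, and affine gap
costs where a gap of length ``l`` costs ``open + extend * l`` (a length-1 gap
with the standard 12/1 parameters costs 13).  Because the literature is split
on whether the first gap position is charged the extension penalty, the
convention is switchable per :class:`GapPenalty`.

The query axis may be *bipartite*: rows that fall inside annotated
transmembrane-helix intervals of the query are scored with a helix-specific
matrix (which may be non-symmetric), all other rows with a general-purpose
matrix.  Subject positions are homogeneous.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .null_models import Alphabet, AlphabetError, PROTEIN_ALPHABET, _as_codes

__all__ = [
    "ScoringMatrix",
    "GapPenalty",
    "PositionSpecificScheme",
    "Alignment",
    "load_matrix",
    "save_matrix",
    "blosum62",
    "tm_synthetic_matrix",
    "smith_waterman_score",
    "smith_waterman_traceback",
    "score_alignment",
    "gap_lengths",
]

_NEG = -(2**28)  # "minus infinity" for integer DP


class MatrixFormatError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringMatrix:
    """An integer substitution matrix over an alphabet.

    Symmetry is *not* enforced: transmembrane-specific matrices are
    non-symmetric by design.
    """

    alphabet: Alphabet
    scores: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        n = len(self.alphabet)
        if s.shape != (n, n):
            raise ValueError("score matrix shape does not match alphabet")
        if not np.issubdtype(s.dtype, np.integer):
            if not np.all(s == np.round(s)):
                raise MatrixFormatError("matrix entries must be integers")
            s = s.astype(np.int64)
        object.__setattr__(self, "scores", np.ascontiguousarray(s, dtype=np.int32))

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self.alphabet.index(a), self.alphabet.index(b)])

    def expected_score(self, freqs: np.ndarray) -> float:
        f = np.asarray(freqs)
        return float(f @ self.scores @ f)

    def restrict(self, alphabet: Alphabet) -> "ScoringMatrix":
        """Project onto a sub-alphabet (e.g. drop B/Z/X/* columns)."""
        idx = [self.alphabet.index(s) for s in alphabet.symbols]
        return ScoringMatrix(alphabet, self.scores[np.ix_(idx, idx)], self.name)


@dataclass(frozen=True)
class GapPenalty:
    """Affine gap cost: open ``a`` >= 0, extend ``b`` >= 0.

    ``convention="open_plus_len"`` charges ``a + b*l`` for a length-l gap
    (default; BLAST's gap-init/gap-extend reading).  The alternative
    ``"open_plus_len_minus_1"`` charges ``a + b*(l-1)``.
    """

    open: int
    extend: int
    convention: str = "open_plus_len"

    def __post_init__(self) -> None:
        if self.open < 0 or self.extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.convention not in ("open_plus_len", "open_plus_len_minus_1"):
            raise ValueError(f"unknown gap cost convention {self.convention!r}")

    def cost(self, length: int) -> int:
        """Cost (a positive number to subtract) of a gap of length >= 1."""
        if length < 1:
            raise ValueError("gap length must be >= 1")
        if self.convention == "open_plus_len":
            return self.open + self.extend * length
        return self.open + self.extend * (length - 1)

    @property
    def first(self) -> int:
        """Cost of the first gapped position."""
        return self.cost(1)


class PositionSpecificScheme:
    """Bipartite scoring: per-query-row matrix choice plus affine gaps.

    ``query_regions`` are 1-based inclusive intervals on the query where
    ``region_matrix`` applies; everywhere else ``default_matrix`` is used.
    With no regions (or ``region_matrix is None``) the scheme is an ordinary
    position-independent one.
    """

    def __init__(
        self,
        default_matrix: ScoringMatrix,
        gaps: GapPenalty,
        region_matrix: ScoringMatrix | None = None,
        query_regions: Sequence[tuple[int, int]] = (),
    ):
        self.default_matrix = default_matrix
        self.region_matrix = region_matrix
        self.gaps = gaps
        regions = sorted(tuple(map(int, r)) for r in query_regions)
        for start, end in regions:
            if start < 1 or end < start:
                raise ValueError(f"bad interval ({start}, {end})")
        for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
            if s2 <= e1:
                raise ValueError("query regions must not overlap")
        if regions and region_matrix is None:
            raise ValueError("query_regions given without a region matrix")
        self.query_regions = tuple(regions)
        self.alphabet = default_matrix.alphabet
        if region_matrix is not None and region_matrix.alphabet != self.alphabet:
            raise ValueError("matrices must share one alphabet")
        mats = [default_matrix.scores]
        if region_matrix is not None:
            mats.append(region_matrix.scores)
        self._stack = np.ascontiguousarray(np.stack(mats), dtype=np.int32)

    def row_matrix_index(self, query_length: int) -> np.ndarray:
        """0 = default matrix, 1 = region matrix, per query row (0-based)."""
        idx = np.zeros(query_length, dtype=np.int32)
        for start, end in self.query_regions:
            if start > query_length:
                raise ValueError(
                    f"interval ({start}, {end}) outside query of length {query_length}"
                )
            idx[start - 1 : min(end, query_length)] = 1
        return idx


@dataclass(frozen=True)
class Alignment:
    """A set of non-crossing index pairs (1-based) between two sequences."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple(sorted((int(i), int(j)) for i, j in self.pairs))
        for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
            if i2 <= i1 or j2 <= j1:
                raise ValueError(f"crossing or duplicate pairs: {(i1, j1)}, {(i2, j2)}")
        object.__setattr__(self, "pairs", pairs)


# --------------------------------------------------------------------------
# Matrix I/O (NCBI tabular format, via Biopython's reader)
# --------------------------------------------------------------------------


def load_matrix(path, name: str | None = None) -> ScoringMatrix:
    """Read an NCBI-style whitespace-delimited substitution matrix."""
    from Bio.Align import substitution_matrices

    try:
        with open(path) as fh:
            m = substitution_matrices.read(fh)
    except Exception as exc:  # ragged rows, etc.
        raise MatrixFormatError(f"cannot parse matrix file {path}: {exc}") from exc
    rows = "".join(str(c) for c in m.alphabet)
    arr = np.asarray(m)
    if not np.all(arr == np.round(arr)):
        raise MatrixFormatError(f"{path}: non-integer matrix entries")
    alphabet = Alphabet.from_string(rows)
    return ScoringMatrix(alphabet, arr.astype(np.int64), name or str(path))


def save_matrix(matrix: ScoringMatrix, path) -> None:
    syms = matrix.alphabet.symbols
    with open(path, "w") as fh:
        fh.write("   " + "  ".join(syms) + "\n")
        for i, a in enumerate(syms):
            fh.write(a + " " + " ".join("%3d" % v for v in matrix.scores[i]) + "\n")


def _bundled(name: str) -> ScoringMatrix:
    from importlib.resources import files

    text = files("raretail.data").joinpath(name).read_text()
    from Bio.Align import substitution_matrices

    m = substitution_matrices.read(io.StringIO(text))
    alphabet = Alphabet.from_string("".join(str(c) for c in m.alphabet))
    return ScoringMatrix(alphabet, np.asarray(m).astype(np.int64), name)


def blosum62(alphabet: Alphabet = PROTEIN_ALPHABET) -> ScoringMatrix:
    """The bundled BLOSUM62 matrix, restricted to the given alphabet."""
    return _bundled("blosum62.mat").restrict(alphabet)


def tm_synthetic_matrix(alphabet: Alphabet = PROTEIN_ALPHABET) -> ScoringMatrix:
    """Bundled synthetic transmembrane-region matrix (non-symmetric).

    A stand-in for helix-specific matrices such as SLIM, whose values are not
    redistributable here: BLOSUM62 with a hydrophobic-pair bonus and an
    asymmetric query-side hydrophobicity term.
    """
    return _bundled("tm_synthetic.mat").restrict(alphabet)


# --------------------------------------------------------------------------
# Smith-Waterman (score-only, numba hot path)
# --------------------------------------------------------------------------

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency normally
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _sw_score_kernel(y, prof, go, ge):  # pragma: no cover - jit compiled
    # prof[i] = substitution scores of query row i against every symbol
    lq = prof.shape[0]
    ls = y.shape[0]
    H = np.zeros(ls + 1, np.int32)
    F = np.full(ls + 1, _NEG, np.int32)
    best = np.int32(0)
    for i in range(lq):
        xr = prof[i]
        diag = np.int32(0)  # H[i-1][j-1]
        e = np.int32(_NEG)
        h_prev = np.int32(0)
        for j in range(1, ls + 1):
            up = H[j]
            # F: gap in the subject (vertical), E: gap in the query
            f = up - go
            f2 = F[j] - ge
            if f2 > f:
                f = f2
            F[j] = f
            e2 = h_prev - go
            e3 = e - ge
            if e3 > e2:
                e2 = e3
            e = e2
            h = diag + xr[y[j - 1]]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0:
                h = np.int32(0)
            diag = up
            H[j] = h
            h_prev = h
            if h > best:
                best = h
    return best


def smith_waterman_score(x, y, scheme: PositionSpecificScheme) -> int:
    """Optimal local alignment score (score-only Gotoh DP).

    ``x`` plays the query role: its rows select the substitution matrix when
    the scheme is bipartite.  Empty input yields 0.
    """
    xa = _as_codes(x, scheme.alphabet)
    ya = _as_codes(y, scheme.alphabet)
    if xa.size == 0 or ya.size == 0:
        return 0
    row_mat = scheme.row_matrix_index(xa.size)
    prof = np.ascontiguousarray(scheme._stack[row_mat, xa])
    return int(
        _sw_score_kernel(
            ya.astype(np.int32),
            prof,
            np.int32(scheme.gaps.first),
            np.int32(scheme.gaps.extend),
        )
    )


def smith_waterman_traceback(
    x, y, scheme: PositionSpecificScheme
) -> tuple[int, Alignment]:
    """Score plus one optimal alignment (inspection path, pure numpy)."""
    xa = _as_codes(x, scheme.alphabet)
    ya = _as_codes(y, scheme.alphabet)
    lq, ls = xa.size, ya.size
    if lq == 0 or ls == 0:
        return 0, Alignment(())
    go, ge = scheme.gaps.first, scheme.gaps.extend
    row_mat = scheme.row_matrix_index(lq)
    mats = scheme._stack
    H = np.zeros((lq + 1, ls + 1), dtype=np.int64)
    E = np.full((lq + 1, ls + 1), _NEG, dtype=np.int64)
    F = np.full((lq + 1, ls + 1), _NEG, dtype=np.int64)
    for i in range(1, lq + 1):
        xr = mats[row_mat[i - 1]][xa[i - 1]]
        for j in range(1, ls + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            H[i, j] = max(0, H[i - 1, j - 1] + xr[ya[j - 1]], E[i, j], F[i, j])
    best = int(H.max())
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    pairs: list[tuple[int, int]] = []
    state = "H"
    while i > 0 and j > 0 and H[i, j] > 0:
        if state == "H":
            if H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                pairs.append((i, j))
                i, j = i - 1, j - 1
        elif state == "E":
            if E[i, j] == E[i, j - 1] - ge:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:
            if F[i, j] == F[i - 1, j] - ge:
                i -= 1
            else:
                i -= 1
                state = "H"
    return best, Alignment(tuple(reversed(pairs)))


# --------------------------------------------------------------------------
# Alignment scoring & gap utilities
# --------------------------------------------------------------------------


def score_alignment(x, y, alignment: Alignment, scheme: PositionSpecificScheme) -> int:
    """Score of a given alignment: pair scores minus internal gap costs.

    Gaps are maximal runs of unpaired positions *between* consecutive aligned
    pairs; unaligned flanks carry no cost (local alignment).  May be
    negative for suboptimal alignments.
    """
    xa = _as_codes(x, scheme.alphabet)
    ya = _as_codes(y, scheme.alphabet)
    pairs = alignment.pairs
    if not pairs:
        return 0
    if pairs[-1][0] > xa.size or pairs[-1][1] > ya.size:
        raise ValueError("alignment pair outside the sequences")
    row_mat = scheme.row_matrix_index(xa.size)
    mats = scheme._stack
    total = 0
    for i, j in pairs:
        total += int(mats[row_mat[i - 1]][xa[i - 1], ya[j - 1]])
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        gx = i2 - i1 - 1
        gy = j2 - j1 - 1
        if gx > 0:
            total -= scheme.gaps.cost(gx)
        if gy > 0:
            total -= scheme.gaps.cost(gy)
    return total


def gap_lengths(aligned_x: str, aligned_y: str, gap_char: str = "-") -> list[int]:
    """Lengths of maximal gap runs in a pair of gapped display strings."""
    if len(aligned_x) != len(aligned_y):
        raise ValueError("gapped strings must have equal display length")
    lengths: list[int] = []
    for row, other in ((aligned_x, aligned_y), (aligned_y, aligned_x)):
        run = 0
        for k, (a, b) in enumerate(zip(row, other)):
            if a == gap_char and b == gap_char:
                raise ValueError(f"column {k + 1} is gapped in both rows")
            if a == gap_char:
                run += 1
            elif run:
                lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    return sorted(lengths)
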