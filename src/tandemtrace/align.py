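"""Pairwise DNA alignment with affine gap costs and free end gaps.

This module implements the scoring scheme used throughout the package for
measuring residual homology between genomic segments: Needleman-Wunsch
global alignment under the NUC.4.4 (EDNAFULL) substitution matrix with
raised affine gap penalties (gap open 25, gap extend 10) and free end gaps
("overlap" mode), summarised as PID3 — percent identity normalised by the
length of the shorter input.  High gap penalties force contiguous blocks of
similarity, which is what makes intergenic percent identity informative
about duplication recency.

The dynamic program is written here from first principles (three-state
affine DP with full traceback); the inner loops are compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

IUPAC_DNA = "ATGCSWRYKMBVHDN"
_CHAR_TO_IDX = {c: i for i, c in enumerate(IUPAC_DNA)}

_NEG = -(10**9)


def _default_matrix() -> dict[tuple[str, str], int]:
    """The NUC.4.4 / EDNAFULL substitution scores as a symmetric dict."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("NUC.4.4")
    out = {}
    for x in IUPAC_DNA:
        for y in IUPAC_DNA:
            out[(x, y)] = int(m[x, y])
    return out


@dataclass
class ScoringParams:
    """Alignment scoring parameters.

    A gap run of length L costs ``gap_open + gap_extend * L``; runs touching
    either sequence end are free when ``free_end_gaps`` is true.
    """

    substitution_matrix: dict[tuple[str, str], int] = field(default_factory=_default_matrix)
    gap_open: int = 25
    gap_extend: int = 10
    free_end_gaps: bool = True

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        for (x, y), s in self.substitution_matrix.items():
            if self.substitution_matrix.get((y, x)) != s:
                raise ValueError(f"substitution matrix not symmetric at ({x},{y})")

    def matrix_array(self) -> np.ndarray:
        arr = getattr(self, "_arr", None)
        if arr is None:
            arr = np.full((len(IUPAC_DNA), len(IUPAC_DNA)), _NEG, dtype=np.int64)
            for (x, y), s in self.substitution_matrix.items():
                arr[_CHAR_TO_IDX[x], _CHAR_TO_IDX[y]] = s
            self._arr = arr
        return arr

    def to_dict(self) -> dict:
        return {
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
            "free_end_gaps": self.free_end_gaps,
            "substitution_matrix": {f"{x}{y}": s for (x, y), s in self.substitution_matrix.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringParams":
        kwargs = {k: d[k] for k in ("gap_open", "gap_extend", "free_end_gaps") if k in d}
        if "substitution_matrix" in d:
            kwargs["substitution_matrix"] = {
                (k[0], k[1]): int(v) for k, v in d["substitution_matrix"].items()
            }
        return cls(**kwargs)


@dataclass
class AlignmentResult:
    """An overlap alignment and its percent-identity summary."""

    aligned_a: str
    aligned_b: str
    score: int
    n_identical: int
    len_shorter: int

    @property
    def pid3(self) -> float:
        """100 * identical positions / length of the shorter sequence."""
        return 100.0 * self.n_identical / self.len_shorter


@dataclass
class DotMatrix:
    """Window-summed substitution scores of a sequence against itself."""

    window: int
    scores: np.ndarray
    threshold: int


def _encode(seq: str, name: str) -> np.ndarray:
    if not seq:
        raise ValueError(f"sequence {name} is empty")
    seq = seq.upper()
    idx = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        j = _CHAR_TO_IDX.get(c)
        if j is None:
            raise ValueError(f"non-IUPAC character {c!r} in sequence {name}")
        idx[i] = j
    return idx


@njit(cache=False)
def _affine_dp(a, b, sub, gap_open, gap_extend, free_ends):  # pragma: no cover - jit
    n = a.shape[0]
    m = b.shape[0]
    NEG = -(10**15)
    open_cost = gap_open + gap_extend

    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (consume a; "up")
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (consume b; "left")
    pM = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pX = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pY = np.zeros((n + 1, m + 1), dtype=np.uint8)

    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = 0 if free_ends else -(gap_open + gap_extend * i)
        pX[i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = 0 if free_ends else -(gap_open + gap_extend * j)
        pY[0, j] = 2

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            # M: prefer diagonal-from-M, then X, then Y (deterministic ties)
            best = M[i - 1, j - 1]
            bp = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                bp = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                bp = 2
            M[i, j] = best + s
            pM[i, j] = bp

            best = M[i - 1, j] - open_cost
            bp = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                bp = 1
            if Y[i - 1, j] - open_cost > best:
                best = Y[i - 1, j] - open_cost
                bp = 2
            X[i, j] = best
            pX[i, j] = bp

            best = M[i, j - 1] - open_cost
            bp = 0
            if X[i, j - 1] - open_cost > best:
                best = X[i, j - 1] - open_cost
                bp = 1
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                bp = 2
            Y[i, j] = best
            pY[i, j] = bp

    # pick alignment end: (n, m) or, with free ends, anywhere on the last
    # row/column (the unconsumed suffix is appended as a free end gap)
    end_i, end_j, end_s = n, m, 0
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
        end_s = 1
    if Y[n, m] > best:
        best = Y[n, m]
        end_s = 2
    if free_ends:
        for i in range(n + 1):
            for s_ in range(3):
                v = M[i, m] if s_ == 0 else (X[i, m] if s_ == 1 else Y[i, m])
                if v > best:
                    best = v
                    end_i, end_j, end_s = i, m, s_
        for j in range(m + 1):
            for s_ in range(3):
                v = M[n, j] if s_ == 0 else (X[n, j] if s_ == 1 else Y[n, j])
                if v > best:
                    best = v
                    end_i, end_j, end_s = n, j, s_

    # traceback: 0 = diagonal, 1 = up (gap in b), 2 = left (gap in a)
    moves = np.empty(n + m, dtype=np.uint8)
    k = 0
    i, j, st = end_i, end_j, end_s
    while i > 0 or j > 0:
        if st == 0:
            if i == 0 and j == 0:
                break
            prev = pM[i, j]
            moves[k] = 0
            k += 1
            i -= 1
            j -= 1
            st = prev
        elif st == 1:
            prev = pX[i, j]
            moves[k] = 1
            k += 1
            i -= 1
            st = prev
        else:
            prev = pY[i, j]
            moves[k] = 2
            k += 1
            j -= 1
            st = prev
    return best, end_i, end_j, moves[:k]


def align_overlap(a: str, b: str, params: ScoringParams | None = None) -> AlignmentResult:
    """Globally align two DNA sequences under affine gap costs.

    With ``params.free_end_gaps`` (the default) gap runs touching either
    sequence end are not penalised, so a short sequence may sit anywhere
    inside a longer one at no cost ("overlap" alignment).  Ties in the
    traceback are broken diagonal > up > left.
    """
    if params is None:
        params = ScoringParams()
    a = a.upper()
    b = b.upper()
    ia = _encode(a, "a")
    ib = _encode(b, "b")
    sub = params.matrix_array()
    score, end_i, end_j, moves = _affine_dp(
        ia, ib, sub, np.int64(params.gap_open), np.int64(params.gap_extend), params.free_end_gaps
    )

    parts_a: list[str] = []
    parts_b: list[str] = []
    i = j = 0
    for mv in moves[::-1]:
        if mv == 0:
            parts_a.append(a[i])
            parts_b.append(b[j])
            i += 1
            j += 1
        elif mv == 1:
            parts_a.append(a[i])
            parts_b.append("-")
            i += 1
        else:
            parts_a.append("-")
            parts_b.append(b[j])
            j += 1
    # free trailing end gap for whatever was not consumed
    if end_i < len(a):
        parts_a.append(a[end_i:])
        parts_b.append("-" * (len(a) - end_i))
    if end_j < len(b):
        parts_a.append("-" * (len(b) - end_j))
        parts_b.append(b[end_j:])
    aligned_a = "".join(parts_a)
    aligned_b = "".join(parts_b)

    n_identical = sum(1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-")
    len_shorter = min(len(a), len(b))
    if n_identical > len_shorter:
        raise AssertionError("identity count exceeded the shorter sequence length")
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=int(score),
        n_identical=n_identical,
        len_shorter=len_shorter,
    )


def pid3(result: AlignmentResult) -> float:
    """Percent identity: 100 * identical positions / shorter input length."""
    return result.pid3


def dotplot_self(seq: str, window: int, min_score: int = 0) -> DotMatrix:
    """Self-comparison dot matrix of window-summed substitution scores.

    ``scores[i, j]`` sums the substitution scores of the window of width
    ``window`` centred on positions (i, j); near the edges the sum runs over
    the in-range part of the window only.
    """
    seq = seq.upper()
    L = len(seq)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > L:
        raise ValueError("window larger than sequence")
    params = ScoringParams()
    sub = params.matrix_array()
    idx = _encode(seq, "seq")
    S = sub[idx[:, None], idx[None, :]]
    h = window // 2
    out = np.zeros((L, L), dtype=np.int64)
    for k in range(-h, h + 1):
        a0 = max(0, -k)
        b0 = L - max(0, k)
        out[a0:b0, a0:b0] += S[a0 + k : b0 + k, a0 + k : b0 + k]
    return DotMatrix(window=window, scores=out, threshold=min_score)
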