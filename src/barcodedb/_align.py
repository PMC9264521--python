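"""Affine-gap local alignment kernel (Gotoh) with IUPAC-aware matching.

Bases are encoded as 4-bit sets (A=1, C=2, G=4, T=8; ambiguity codes are
unions); two columns match when their sets intersect, so N matches anything.
Scoring follows the megablast-style convention: match +2, mismatch -3, and a
gap of length L costs ``gap_open + gap_extend * L`` (open charged once, extend
per gap column).

Traceback tie-order is pinned for determinism: when cell scores tie, the local
zero wins over diagonal, diagonal over a vertical gap, vertical over
horizontal; within a gap state, opening wins over extending.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["encode", "revcomp", "local_align", "AlignmentResult"]

_CODE = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

_ENCODE_LUT = np.zeros(128, dtype=np.uint8)
for _c, _v in _CODE.items():
    _ENCODE_LUT[ord(_c)] = _v

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase IUPAC string as a uint8 bit-set array."""
    arr = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        bad = sorted({c for c in seq if c not in _CODE})
        raise ValueError(f"non-IUPAC characters in sequence: {bad}")
    return arr


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC string."""
    return seq.translate(_COMPLEMENT)[::-1]


@njit(cache=True)
def _gotoh(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    neg = -(1 << 30)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), neg, dtype=np.int32)  # gap in subject (vertical)
    F = np.full((n + 1, m + 1), neg, dtype=np.int32)  # gap in query (horizontal)
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.int8)   # 0 stop, 1 diag, 2 E, 3 F
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.int8)   # 1 open, 2 extend
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.int8)
    first_gap = gap_open + gap_extend

    best = 0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_open = H[i - 1, j] - first_gap
            e_ext = E[i - 1, j] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptr_e[i, j] = 1
            else:
                E[i, j] = e_ext
                ptr_e[i, j] = 2
            f_open = H[i, j - 1] - first_gap
            f_ext = F[i, j - 1] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptr_f[i, j] = 1
            else:
                F[i, j] = f_ext
                ptr_f[i, j] = 2
            s = match if (ai & b[j - 1]) != 0 else mismatch
            diag = H[i - 1, j - 1] + s
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                best_i = i
                best_j = j

    # traceback
    matches = 0
    columns = 0
    i = best_i
    j = best_j
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if (a[i - 1] & b[j - 1]) != 0:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            p = ptr_e[i, j]
            columns += 1
            i -= 1
            state = 0 if p == 1 else 1
        else:
            p = ptr_f[i, j]
            columns += 1
            j -= 1
            state = 0 if p == 1 else 2

    return best, matches, columns, i, best_i, j, best_j


class AlignmentResult:
    """Score and summary statistics of one local alignment."""

    __slots__ = ("score", "matches", "columns", "q_start", "q_end",
                 "s_start", "s_end")

    def __init__(self, score, matches, columns, q_start, q_end, s_start, s_end):
        self.score = int(score)
        self.matches = int(matches)
        self.columns = int(columns)
        self.q_start = int(q_start)
        self.q_end = int(q_end)
        self.s_start = int(s_start)
        self.s_end = int(s_end)

    @property
    def identity_pct(self) -> float:
        if self.columns == 0:
            return 0.0
        return 100.0 * self.matches / self.columns

    def query_coverage_pct(self, query_length: int) -> float:
        return 100.0 * (self.q_end - self.q_start) / query_length


def local_align(query: str | np.ndarray, subject: str | np.ndarray, *,
                match: int = 2, mismatch: int = -3,
                gap_open: int = 5, gap_extend: int = 2) -> AlignmentResult:
    """Best local alignment of ``query`` against ``subject``.

    Accepts raw IUPAC strings or pre-encoded arrays.  Gap penalties are given
    as positive costs.  An empty alignment (no positive-scoring pair) returns
    score 0 with zero columns.
    """
    a = encode(query) if isinstance(query, str) else query
    b = encode(subject) if isinstance(subject, str) else subject
    out = _gotoh(a, b, np.int32(match), np.int32(mismatch),
                 np.int32(gap_open), np.int32(gap_extend))
    return AlignmentResult(*out)
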