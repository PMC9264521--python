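"""Brute-force full-matrix Smith-Waterman (Gotoh affine) oracle.

Independent pure-Python implementation used only to cross-check the package's
alignment kernel on small pairs.  Scoring convention matches the package's
documented one (match +2, mismatch -3, gap of length L costs 5 + 2L;
IUPAC bit-set intersection counts as a match) with the same pinned traceback
tie-order, so score, match count and column count are comparable exactly.
"""

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

NEG = float("-inf")


def smith_waterman(query, subject, match=2, mismatch=-3, gap_open=5,
                   gap_extend=2):
    """Return (score, matches, columns, q_start, q_end) of the best local
    alignment, via full dynamic-programming matrices and traceback."""
    n, m = len(query), len(subject)
    first_gap = gap_open + gap_extend
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    ph = [[0] * (m + 1) for _ in range(n + 1)]
    pe = [[0] * (m + 1) for _ in range(n + 1)]
    pf = [[0] * (m + 1) for _ in range(n + 1)]

    def is_match(a, b):
        return bool(IUPAC_SETS[a] & IUPAC_SETS[b])

    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i - 1][j] - first_gap
            e_ext = E[i - 1][j] - gap_extend
            if e_open >= e_ext:
                E[i][j], pe[i][j] = e_open, 1
            else:
                E[i][j], pe[i][j] = e_ext, 2
            f_open = H[i][j - 1] - first_gap
            f_ext = F[i][j - 1] - gap_extend
            if f_open >= f_ext:
                F[i][j], pf[i][j] = f_open, 1
            else:
                F[i][j], pf[i][j] = f_ext, 2
            s = match if is_match(query[i - 1], subject[j - 1]) else mismatch
            diag = H[i - 1][j - 1] + s
            h, p = 0, 0
            if diag > h:
                h, p = diag, 1
            if E[i][j] > h:
                h, p = E[i][j], 2
            if F[i][j] > h:
                h, p = F[i][j], 3
            H[i][j], ph[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j

    matches = columns = 0
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            p = ph[i][j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if is_match(query[i - 1], subject[j - 1]):
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            p = pe[i][j]
            columns += 1
            i -= 1
            state = "H" if p == 1 else "E"
        else:
            p = pf[i][j]
            columns += 1
            j -= 1
            state = "H" if p == 1 else "F"
    return best, matches, columns, i, bi
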