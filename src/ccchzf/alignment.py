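"""Pairwise protein alignment with affine gaps (Gotoh three-state DP).

Both the local (Smith-Waterman) and global (Needleman-Wunsch) variants share
this machinery. Gap costs follow the EMBOSS convention used by the EBI
pairwise-alignment tools: a gap of length L costs ``gap_open +
(L-1)*gap_extend``, with defaults BLOSUM62 / 10 / 0.5.

Traceback is fully deterministic: the local alignment starts from the
highest-scoring cell (ties resolved to the smallest row, then column) and at
every step prefers diagonal over up (gap in b) over left (gap in a).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import substitution_matrices

NEG_INF = float("-inf")

# DP states: match, gap-in-b (up, consumes a), gap-in-a (left, consumes b)
_M, _X, _Y = 0, 1, 2
_FRESH = -1  # local-mode marker: alignment opens at this cell


@lru_cache(maxsize=None)
def blosum62():
    return substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment: gapped rows, score and column statistics.

    ``identity_pct`` counts identical columns over all alignment columns;
    ``similarity_pct`` additionally counts substitutions with a positive
    substitution-matrix score, matching what the EBI tools report.
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    start_a: int = 0  # 0-based offsets where the local alignment begins
    start_b: int = 0

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped rows differ in length")


def _column_stats(aligned_a: str, aligned_b: str, matrix) -> tuple[float, float]:
    ncols = len(aligned_a)
    if ncols == 0:
        return 0.0, 0.0
    ident = similar = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            ident += 1
            similar += 1
        elif matrix[ca, cb] > 0:
            similar += 1
    return 100.0 * ident / ncols, 100.0 * similar / ncols


def _gotoh(a, b, matrix, gap_open, gap_extend, local):
    """Fill the three-state DP tables and predecessor pointers.

    ptr[s][i][j] holds the predecessor state of state s at (i, j); ties are
    resolved with the preference M > X > Y, which realizes the
    diagonal > up > left move order.
    """
    la, lb = len(a), len(b)
    M = [[NEG_INF] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG_INF] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG_INF] * (lb + 1) for _ in range(la + 1)]
    ptr = [[[_M] * (lb + 1) for _ in range(la + 1)] for _ in range(3)]

    M[0][0] = 0.0
    for i in range(1, la + 1):
        if local:
            M[i][0] = 0.0
        else:
            X[i][0] = -(gap_open + (i - 1) * gap_extend)
            ptr[_X][i][0] = _M if i == 1 else _X
    for j in range(1, lb + 1):
        if local:
            M[0][j] = 0.0
        else:
            Y[0][j] = -(gap_open + (j - 1) * gap_extend)
            ptr[_Y][0][j] = _M if j == 1 else _Y

    for i in range(1, la + 1):
        row_m, row_x, row_y = M[i], X[i], Y[i]
        prev_m, prev_x, prev_y = M[i - 1], X[i - 1], Y[i - 1]
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cands = (prev_m[j - 1], prev_x[j - 1], prev_y[j - 1])
            best = max(cands)
            src = cands.index(best)
            if local and best <= 0.0:
                # opening the alignment here is never worse than carrying a
                # non-positive prefix, and makes fresh starts explicit
                best, src = 0.0, _FRESH
            row_m[j] = best + float(matrix[ai, b[j - 1]])
            ptr[_M][i][j] = src

            xc = (prev_m[j] - gap_open, prev_x[j] - gap_extend,
                  prev_y[j] - gap_open)
            row_x[j] = max(xc)
            ptr[_X][i][j] = xc.index(row_x[j])

            yc = (row_m[j - 1] - gap_open, row_x[j - 1] - gap_open,
                  row_y[j - 1] - gap_extend)
            row_y[j] = max(yc)
            ptr[_Y][i][j] = yc.index(row_y[j])
    return M, X, Y, ptr


def smith_waterman(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal local alignment under affine gaps.

    The traceback starts at the maximal match-state cell (an optimal local
    alignment never ends in a gap when gap costs are positive), ties broken
    toward the smallest row then column, and unwinds until the recorded
    opening of the local path.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    matrix = blosum62() if matrix is None else matrix
    M, X, Y, ptr = _gotoh(a, b, matrix, gap_open, gap_extend, local=True)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    if best <= 0:
        return AlignmentResult("", "", 0.0, 0.0, 0.0)
    cols_a: list[str] = []
    cols_b: list[str] = []
    i, j, state = bi, bj, _M
    while True:
        if state == _M:
            src = ptr[_M][i][j]
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if src == _FRESH or i == 0 or j == 0:
                break
            state = src
        elif state == _X:
            src = ptr[_X][i][j]
            cols_a.append(a[i - 1])
            cols_b.append("-")
            i -= 1
            state = src
        else:
            src = ptr[_Y][i][j]
            cols_a.append("-")
            cols_b.append(b[j - 1])
            j -= 1
            state = src
    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))
    ident, simil = _column_stats(aligned_a, aligned_b, matrix)
    return AlignmentResult(aligned_a, aligned_b, best, ident, simil, i, j)


def needleman_wunsch(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal global alignment under affine gaps (same conventions)."""
    if not a or not b:
        raise ValueError("empty sequence")
    matrix = blosum62() if matrix is None else matrix
    M, X, Y, ptr = _gotoh(a, b, matrix, gap_open, gap_extend, local=False)
    la, lb = len(a), len(b)
    finals = (M[la][lb], X[la][lb], Y[la][lb])
    score = max(finals)
    state = finals.index(score)
    cols_a: list[str] = []
    cols_b: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if state == _M:
            src = ptr[_M][i][j]
            cols_a.append(a[i - 1])
            cols_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = src
        elif state == _X:
            src = ptr[_X][i][j]
            cols_a.append(a[i - 1])
            cols_b.append("-")
            i -= 1
            state = src
        else:
            src = ptr[_Y][i][j]
            cols_a.append("-")
            cols_b.append(b[j - 1])
            j -= 1
            state = src
    aligned_a = "".join(reversed(cols_a))
    aligned_b = "".join(reversed(cols_b))
    ident, simil = _column_stats(aligned_a, aligned_b, matrix)
    return AlignmentResult(aligned_a, aligned_b, score, ident, simil)
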