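"""Exhaustive affine-gap local alignment oracle (plain Gotoh DP, no banding).

Deliberately slow and simple: three full score matrices over the whole
reference, explicit traceback. Used only to cross-check the package's
seed-and-extend mapper on small instances. Scoring convention: a gap of
length L costs gap_open + (L-1)*gap_extend.
"""

from __future__ import annotations

NEG = float("-inf")


def local_align(
    ref: str,
    read: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
):
    """Best local alignment of read against ref.

    Returns (score, ref_start, ref_end, unique_end) with 1-based inclusive
    reference coordinates of the best-scoring alignment; ``unique_end`` is
    False when several cells tie for the maximum score (the reported
    interval then follows the smallest (i, j) end cell).
    """
    n, m = len(ref), len(read)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (consumes ref)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (consumes read)
    best, best_cell, n_best = 0.0, None, 0
    for i in range(1, n + 1):
        ri = ref[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            s = match if ri == read[j - 1] else mismatch
            h = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, best_cell, n_best = h, (i, j), 1
            elif h == best and h > 0:
                n_best += 1
    if best_cell is None:
        return 0.0, 0, 0, True
    # traceback from the first best cell to the start of the local alignment
    i, j = best_cell
    ref_end = i
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i][j]
            if h == 0:
                break
            s = match if ref[i - 1] == read[j - 1] else mismatch
            if h == H[i - 1][j - 1] + s:
                i, j = i - 1, j - 1
            elif h == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            if E[i][j] == H[i - 1][j] + gap_open:
                i, state = i - 1, "H"
            else:
                i = i - 1
        else:
            if F[i][j] == H[i][j - 1] + gap_open:
                j, state = j - 1, "H"
            else:
                j = j - 1
    return best, i + 1, ref_end, n_best == 1
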