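"""Independent oracles used by the test suite.

The affine-gap aligner oracle is a plain-Python Gotoh dynamic program with
free end gaps, written without reference to the package's alignment engine
so the two can check each other.
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    end_gaps_free: bool = True,
) -> float:
    """Optimal global affine-gap alignment score.

    A gap of length k costs gap_open + gap_extend * k; terminal gap runs
    are free when end_gaps_free.  Three-state Gotoh recurrence; the free
    end gaps are realized by zero-cost initialization and by taking the
    maximum over the last row and column.
    """
    n, m = len(a), len(b)
    go = -(gap_open + gap_extend)
    ge = -gap_extend

    M = [[NEG] * (m + 1) for _ in range(n + 1)]  # last column is a match/mismatch
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a char over '-')
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0 if end_gaps_free else go + ge * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = 0.0 if end_gaps_free else go + ge * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go)
            Y[i][j] = max(M[i][j - 1] + go, Y[i][j - 1] + ge, X[i][j - 1] + go)

    if not end_gaps_free:
        return max(M[n][m], X[n][m], Y[n][m])
    best = max(M[n][m], X[n][m], Y[n][m])
    for i in range(n + 1):  # free trailing gap in b
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):  # free trailing gap in a
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


def best_nonoverlapping_subset(candidates):
    """Exhaustive overlap-resolution oracle for small candidate sets.

    Candidates are (start, end, p_value, divergence).  Enumerates every
    maximal non-overlapping subset and returns the one whose sorted rank
    sequence (rank = position in the (p, divergence, start) order) is
    lexicographically smallest — i.e. the subset retaining the
    best-ranked candidates possible.  Returned as start-sorted indices.
    """
    from itertools import combinations

    n = len(candidates)
    rank_of = {
        i: r
        for r, i in enumerate(
            sorted(
                range(n),
                key=lambda i: (candidates[i][2], candidates[i][3], candidates[i][0]),
            )
        )
    }

    def compatible(subset):
        for x, y in combinations(subset, 2):
            if candidates[x][0] < candidates[y][1] and candidates[y][0] < candidates[x][1]:
                return False
        return True

    best_key, best_subset = None, ()
    for size in range(n, -1, -1):
        for subset in combinations(range(n), size):
            if not compatible(subset):
                continue
            # maximality: no candidate can be added
            if any(compatible(subset + (extra,)) for extra in range(n) if extra not in subset):
                continue
            key = tuple(sorted(rank_of[i] for i in subset))
            if best_key is None or key < best_key:
                best_key, best_subset = key, subset
    return sorted(best_subset, key=lambda i: candidates[i][0])
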