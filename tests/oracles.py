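"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (full dynamic programming, exhaustive
search) and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
from collections import Counter

NEG = float("-inf")


def brute_edit_distance(a: str, b: str) -> int:
    """Textbook O(nm) unit-cost global edit distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


def brute_semiglobal_edits(pattern: str, text: str) -> int:
    """Min edit distance of pattern against any substring of text
    (free end-gaps in the text), by exhaustive substring enumeration."""
    best = len(pattern)
    n = len(text)
    for i in range(n + 1):
        for j in range(i, min(n, i + 2 * len(pattern)) + 1):
            best = min(best, brute_edit_distance(pattern, text[i:j]))
            if best == 0:
                return 0
    return best


def gotoh_score(
    query: str,
    truth: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -2,
    gap_extend: int = -1,
    free_query_ends: bool = True,
) -> float:
    """Affine-gap global alignment score (Gotoh), gap of length k costing
    open + (k-1)*extend.  With ``free_query_ends`` the query's overhangs
    (gaps inserted into the truth at either end) are free, while the truth
    must be spanned."""
    m, n = len(truth), len(query)

    def go(k: int) -> int:  # cost of a gap of length k
        return gap_open + (k - 1) * gap_extend if k else 0

    # M[i][j]: best score aligning truth[:i] / query[:j] ending in a match col
    # X: ending in gap-in-query (truth consumed), Y: gap-in-truth (query consumed)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = go(i)
    for j in range(1, n + 1):
        Y[0][j] = 0.0 if free_query_ends else go(j)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if truth[i - 1] == query[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            end_free = free_query_ends and i == m
            y_open = 0.0 if end_free else gap_open
            y_ext = 0.0 if end_free else gap_extend
            Y[i][j] = max(M[i][j - 1] + y_open, Y[i][j - 1] + y_ext)
    return max(M[m][n], X[m][n], Y[m][n])


def exhaustive_msa_columns(seqs: list[str]) -> list[tuple[str, ...]]:
    """Optimal multiple alignment of k short sequences by exhaustive DP over
    the k-dimensional lattice with unit sum-of-pairs cost; returns columns."""
    k = len(seqs)
    lens = tuple(len(s) for s in seqs)
    moves = [m for m in itertools.product((0, 1), repeat=k) if any(m)]

    def col_cost(chars: tuple[str, ...]) -> int:
        cost = 0
        for a, b in itertools.combinations(chars, 2):
            if a == "-" and b == "-":
                continue
            cost += (a == "-") != (b == "-") or (a != "-" and a != b)
        return cost

    start = tuple([0] * k)
    best: dict[tuple[int, ...], float] = {start: 0.0}
    back: dict[tuple[int, ...], tuple[tuple[int, ...], tuple[str, ...]]] = {}
    for state in itertools.product(*(range(L + 1) for L in lens)):
        if state == start:
            continue
        best_cost, best_prev, best_col = NEG, None, None
        for mv in moves:
            prev = tuple(s - d for s, d in zip(state, mv))
            if any(p < 0 for p in prev) or prev not in best:
                continue
            chars = tuple(
                seqs[i][prev[i]] if mv[i] else "-" for i in range(k)
            )
            c = best[prev] + col_cost(chars)
            if best_prev is None or c < best_cost:
                best_cost, best_prev, best_col = c, prev, chars
        best[state] = best_cost
        back[state] = (best_prev, best_col)
    cols: list[tuple[str, ...]] = []
    state = lens
    while state != start:
        prev, col = back[state]
        cols.append(col)
        state = prev
    cols.reverse()
    return cols


def msa_majority_consensus(seqs: list[str]) -> str:
    """Column-majority consensus over the exhaustive optimal MSA; gap-majority
    columns are dropped, ties break A<C<G<T with gap last."""
    order = {b: i for i, b in enumerate("ACGTN-")}
    out = []
    for col in exhaustive_msa_columns(seqs):
        tally = Counter(col)
        winner = max(tally.items(), key=lambda kv: (kv[1], -order.get(kv[0], 9)))[0]
        if winner != "-":
            out.append(winner)
    return "".join(out)


def interval_union_coverage(intervals: list[tuple[int, int]], length: int) -> float:
    """Fraction of [0, length) covered by the union of intervals, by
    position-wise marking."""
    covered = [False] * length
    for s, e in intervals:
        for i in range(max(0, s), min(length, e)):
            covered[i] = True
    return sum(covered) / length if length else 0.0
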