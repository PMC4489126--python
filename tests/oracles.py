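"""Independent brute-force reference implementations used by the tests.

Everything here is written against the math directly — dict-based counting
over explicit row pairs, closed-form probability formulas, and alignment
scoring by explicit path enumeration / recursion over move sequences — and
deliberately shares no code with the package's vectorised implementations.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import combinations

AA = "ARNDCQEGHILKMFPSTWYV"


# ---------------------------------------------------------------------------
# pair counting and probabilities
# ---------------------------------------------------------------------------

def brute_pair_counts(blocks: list[list[str]]) -> dict[tuple[str, str], int]:
    """Count unordered residue pairs per column by explicit enumeration.

    ``blocks`` is a list of blocks, each a list of equal-length row strings.
    Returns counts keyed by sorted residue pair.
    """
    f: dict[tuple[str, str], int] = {}
    for rows in blocks:
        width = len(rows[0])
        for c in range(width):
            for r1, r2 in combinations(range(len(rows)), 2):
                x, y = rows[r1][c], rows[r2][c]
                if x in AA and y in AA:
                    key = tuple(sorted((x, y)))
                    f[key] = f.get(key, 0) + 1
    return f


def brute_observed(f: dict[tuple[str, str], int]) -> dict[tuple[str, str], float]:
    total = sum(f.values())
    return {k: v / total for k, v in f.items()}


def brute_background(obs: dict[tuple[str, str], float]) -> dict[str, float]:
    p = {a: 0.0 for a in AA}
    for (x, y), v in obs.items():
        if x == y:
            p[x] += v
        else:
            p[x] += v / 2
            p[y] += v / 2
    return p


def brute_expected(p: dict[str, float]) -> dict[tuple[str, str], float]:
    e = {}
    for i, x in enumerate(AA):
        for y in AA[: i + 1]:
            a, b = tuple(sorted((x, y)))
            e[(a, b)] = p[a] ** 2 if a == b else 2 * p[a] * p[b]
    return e


def brute_scores(
    obs: dict[tuple[str, str], float],
    e: dict[tuple[str, str], float],
    scale: float = 2.0,
) -> dict[tuple[str, str], float]:
    """Log-odds over observed cells only (no floor policy)."""
    return {
        k: scale * math.log2(v / e[k]) for k, v in obs.items() if v > 0
    }


def brute_relative_entropy(
    obs: dict[tuple[str, str], float], e: dict[tuple[str, str], float]
) -> float:
    return sum(v * math.log2(v / e[k]) for k, v in obs.items() if v > 0)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def enumerate_alignments(a: str, b: str):
    """Yield every gapped alignment of a and b as (row_a, row_b) strings.

    No column may have gaps in both rows; this is the complete alignment
    space for global alignment.
    """
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def score_columns(row_a: str, row_b: str, score, open_pen: float, ext_pen: float) -> float:
    """Score a fixed alignment: BLAST-style gap runs, explicit column walk."""
    total = 0.0
    run_a = run_b = 0
    for x, y in zip(row_a, row_b):
        if x == "-":
            run_a += 1
            run_b = 0
            total -= open_pen if run_a == 1 else ext_pen
        elif y == "-":
            run_b += 1
            run_a = 0
            total -= open_pen if run_b == 1 else ext_pen
        else:
            run_a = run_b = 0
            total += score(x, y)
    return total


def brute_global_enumerate(a, b, score, open_pen=15.0, ext_pen=2.0) -> float:
    """Exhaustive maximum over all gapped alignments (tiny lengths only)."""
    return max(
        score_columns(ra, rb, score, open_pen, ext_pen)
        for ra, rb in enumerate_alignments(a, b)
    )


def brute_global(a, b, score, open_pen=15.0, ext_pen=2.0) -> float:
    """Brute-force optimum via memoised recursion over (position, last move).

    Computes exactly the maximum of ``score_columns`` over the complete
    alignment space, tracking whether the previous column extended a gap so
    gap runs cost open + ext * (L - 1).
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        out = -math.inf
        if i < len(a) and j < len(b):
            out = max(out, score(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = ext_pen if prev == "X" else open_pen
            out = max(out, -cost + best(i + 1, j, "X"))
        if j < len(b):
            cost = ext_pen if prev == "Y" else open_pen
            out = max(out, -cost + best(i, j + 1, "Y"))
        return out

    result = best(0, 0, "start")
    best.cache_clear()
    return result


def brute_local(a, b, score, open_pen=15.0, ext_pen=2.0) -> float:
    """Best global score over all substring pairs, floored at 0."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = brute_global(a[i1:i2], b[j1:j2], score, open_pen, ext_pen)
                    best = max(best, s)
    return best


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def is_ultrametric(d, labels, tol=1e-9) -> bool:
    """Three-point condition: max of the two largest sides equal."""
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                sides = sorted([d[i][j], d[i][k], d[j][k]])
                if sides[2] - sides[1] > tol:
                    return False
    return True
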