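"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's implementations: the aligner oracle
is a memoized recursion straight from the affine-gap recurrences, and the
GO oracle recomputes ancestor sets, information content, Lin similarity and
the best-match average with naive loops.
"""

from __future__ import annotations

import math
from functools import lru_cache

NEG = float("-inf")


def oracle_local_align(a: str, b: str, score_fn, gap_open=10.0, gap_extend=0.5):
    """Best local affine-gap score and one optimal alignment.

    States: H = last column aligns a residue pair; E = gap in `a`
    (consuming b); F = gap in `b` (consuming a).  A gap of length L costs
    gap_open + (L-1) * gap_extend.  Traceback preference: diagonal > up >
    left, gaps closed as early as possible; the best cell is the first in
    row-major order.
    """
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def E(i, j):
        if j == 0:
            return NEG
        return max(H(i, j - 1) - gap_open, E(i, j - 1) - gap_extend)

    @lru_cache(maxsize=None)
    def F(i, j):
        if i == 0:
            return NEG
        return max(H(i - 1, j) - gap_open, F(i - 1, j) - gap_extend)

    @lru_cache(maxsize=None)
    def H(i, j):
        if i == 0 or j == 0:
            return 0.0
        return max(
            0.0,
            H(i - 1, j - 1) + score_fn(a[i - 1], b[j - 1]),
            E(i, j),
            F(i, j),
        )

    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if H(i, j) > best:
                best, bi, bj = H(i, j), i, j

    cols = []
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            if H(i, j) == 0.0:
                break
            if H(i, j) == H(i - 1, j - 1) + score_fn(a[i - 1], b[j - 1]):
                cols.append((a[i - 1], b[j - 1]))
                i, j = i - 1, j - 1
            elif H(i, j) == F(i, j):
                state = "F"
            else:
                state = "E"
        elif state == "F":
            cols.append((a[i - 1], "-"))
            state = "H" if F(i, j) == H(i - 1, j) - gap_open else "F"
            i -= 1
        else:
            cols.append(("-", b[j - 1]))
            state = "H" if E(i, j) == H(i, j - 1) - gap_open else "E"
            j -= 1
    cols.reverse()
    aligned_a = "".join(x for x, _ in cols)
    aligned_b = "".join(y for _, y in cols)
    identity = (
        100.0 * sum(1 for x, y in cols if x == y and x != "-") / len(cols) if cols else 0.0
    )
    return best, aligned_a, aligned_b, identity


def oracle_ancestors(term, parents):
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in parents.get(t, set()):
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def oracle_ic(assignments, parents):
    """assignments: gene -> set of terms (direct).  Returns term -> ic."""
    instances = [(g, t) for g, terms in assignments.items() for t in terms]
    total = len(instances)
    counts = {}
    all_terms = set(parents)
    for term in all_terms:
        c = 0
        for _g, t in instances:
            if term in oracle_ancestors(t, parents):
                c += 1
        if c:
            counts[term] = c
    return {t: -math.log(c / total) for t, c in counts.items()}, total


def oracle_lin(t1, t2, parents, ic):
    if t1 == t2:
        return 1.0 if ic[t1] > 0 else 0.0
    denom = ic[t1] + ic[t2]
    if denom == 0:
        return 0.0
    common = oracle_ancestors(t1, parents) & oracle_ancestors(t2, parents)
    mica = max((ic[t] for t in common if t in ic), default=0.0)
    return 2.0 * mica / denom


def oracle_bma(terms_a, terms_b, parents, ic):
    a = sorted(t for t in terms_a if t in ic)
    b = sorted(t for t in terms_b if t in ic)
    if not a or not b:
        return None
    row = sum(max(oracle_lin(ta, tb, parents, ic) for tb in b) for ta in a) / len(a)
    col = sum(max(oracle_lin(ta, tb, parents, ic) for ta in a) for tb in b) / len(b)
    return (row + col) / 2.0
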