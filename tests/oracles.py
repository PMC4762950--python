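"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths: a quadratic Gotoh DP for
alignment scores, sliding-window donor-tract enumeration, an exhaustive
minimum-event-count assignment search, maximal-run enumeration for bisulfite
patches, and full-permutation enumeration for the Mann-Whitney test.
"""

from __future__ import annotations

import itertools
import math

NEG = -math.inf


def gotoh_score(a: str, b: str, match=1.0, mismatch=-2.0, open_=-5.0, extend=-1.0) -> float:
    """Optimal global affine-gap alignment score by full Gotoh DP.

    Gap of length L costs open_ + (L-1)*extend (the first gapped position
    carries the open score), matching the aligner configuration under test.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Iy[0][j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] + open_, Ix[i - 1][j] + extend, Iy[i - 1][j] + open_)
            Iy[i][j] = max(M[i][j - 1] + open_, Iy[i][j - 1] + extend, Ix[i][j - 1] + open_)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def window_tracts(mutseq: str, ref: str, donor: str) -> list[tuple[int, int, tuple[int, ...]]]:
    """All maximal donor-identical intervals holding >= 1 donor-ref marker,
    found by sliding every (start, end) window and keeping the maximal ones."""
    n = len(ref)
    identical = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n + 1)
        if all(mutseq[k] == donor[k] for k in range(i, j))
    ]
    maximal = [
        (i, j) for (i, j) in identical
        if not any((x <= i and j <= y and (x, y) != (i, j)) for (x, y) in identical)
    ]
    out = []
    for i, j in maximal:
        markers = tuple(p for p in range(i, j) if donor[p] != ref[p])
        if markers:
            out.append((i, j, markers))
    return out


def min_event_count(call_positions: set[int], candidate_sets: list[frozenset[int]],
                    min_support: int = 2) -> int:
    """Exhaustive minimum number of events partitioning the calls.

    Each chosen candidate set (>= min_support of the still-uncovered calls)
    forms one conversion event; every uncovered call costs one event
    (ambiguous or point). Searches all candidate subsets.
    """
    cands = [frozenset(c & call_positions) for c in candidate_sets]
    cands = [c for c in cands if len(c) >= min_support]
    best = len(call_positions)  # all singletons

    def rec(uncovered: frozenset[int], used: int, avail: list[frozenset[int]]) -> None:
        nonlocal best
        best = min(best, used + len(uncovered))  # stop here: singletons for the rest
        for k, c in enumerate(avail):
            live = c & uncovered
            if len(live) >= min_support and used + 1 < best:
                rec(uncovered - live, used + 1, avail[k:])

    rec(frozenset(call_positions), 0, cands)
    return best


def enumerate_patches(positions: tuple[int, ...], converted: tuple[bool, ...],
                      patch_minimum: int = 2):
    """All maximal qualifying runs by checking every (i, j) index pair."""
    n = len(positions)
    out = []
    for i in range(n):
        for j in range(i + patch_minimum - 1, n):
            if all(converted[k] for k in range(i, j + 1)) \
                    and (i == 0 or not converted[i - 1]) \
                    and (j == n - 1 or not converted[j + 1]):
                out.append((positions[i], positions[j], j - i + 1))
    return out


def mann_whitney_u(a: list[float], b: list[float]) -> float:
    """U statistic of group a with mid-rank ties, by direct pair counting."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mann_whitney_exact_p(a: list[float], b: list[float]) -> float:
    """Exact two-sided p by enumerating every labeling of the pooled values.

    Uses the symmetry of the null U distribution about nm/2: p is the
    fraction of labelings at least as far from the center as observed.
    """
    pooled = list(a) + list(b)
    na = len(a)
    center = na * len(b) / 2.0
    obs = abs(mann_whitney_u(a, b) - center)
    total = extreme = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        total += 1
        if abs(mann_whitney_u(ga, gb) - center) >= obs - 1e-12:
            extreme += 1
    return extreme / total
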