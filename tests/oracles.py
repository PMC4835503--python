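"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: direct enumeration with exact integer arithmetic,
double loops, and per-offset recomputation. Nothing here imports from the
package's statistical code paths.
"""

from __future__ import annotations

import math
from functools import lru_cache


@lru_cache(maxsize=None)
def _hypergeom_pmf_table(row1: int, col1: int, total: int) -> tuple:
    """All P(X = k) for the 2x2 margin (row1, col1, total), exact rationals
    collapsed to floats at the end."""
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    denom = math.comb(total, col1)
    return tuple(
        (k, math.comb(row1, k) * math.comb(total - row1, col1 - k) / denom)
        for k in range(lo, hi + 1)
    )


def fisher_two_tail(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p by summing every table with probability
    no greater than the observed one (with a tiny relative tolerance for
    float round-off), at fixed margins."""
    total = a + b + c + d
    if total == 0:
        return 1.0
    pmf = _hypergeom_pmf_table(a + b, a + c, total)
    p_obs = next(p for k, p in pmf if k == a)
    return min(1.0, sum(p for _, p in pmf if p <= p_obs * (1 + 1e-9)))


def brute_force_rbh(score_ab: dict[tuple[str, str], float],
                    score_ba: dict[tuple[str, str], float]) -> set[tuple[str, str]]:
    """Reciprocal best hits by double loop over all query-subject pairs,
    ties broken by lexicographically smaller subject."""

    def best(scores: dict[tuple[str, str], float]) -> dict[str, str]:
        out: dict[str, str] = {}
        for (q, s), sc in scores.items():
            if q not in out:
                out[q] = s
            else:
                cur = scores[(q, out[q])]
                if sc > cur or (sc == cur and s < out[q]):
                    out[q] = s
        return out

    ab, ba = best(score_ab), best(score_ba)
    return {(a, b) for a, b in ab.items() if ba.get(b) == a}


def naive_window_means(values: list[float], window: int) -> list[float]:
    """Window means recomputed from scratch at every offset."""
    return [
        sum(values[i:i + window]) / window
        for i in range(len(values) - window + 1)
    ]


def venn_regions(sets: list[set[str]]) -> dict[tuple[bool, ...], int]:
    """Exhaustive membership enumeration over the union."""
    union = set().union(*sets)
    counts: dict[tuple[bool, ...], int] = {}
    for g in union:
        key = tuple(g in s for s in sets)
        counts[key] = counts.get(key, 0) + 1
    return counts
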