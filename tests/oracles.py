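"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: exact integer
binomial coefficients via math.comb, direct summation, and plain bisection.
"""

from __future__ import annotations

import math
from itertools import permutations


# ---------------------------------------------------------------------------
# exact Fisher test by enumeration
# ---------------------------------------------------------------------------

def fisher_enumeration(a: int, b: int, c: int, d: int):
    """Two-sided minimum-likelihood p and conditional-MLE OR by direct
    enumeration over all tables with the observed margins.

    Returns (p_value, or_cmle) with or_cmle in {0.0, inf, finite} and
    None for degenerate (single-table) margins.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    if lo == hi:
        return 1.0, None
    xs = list(range(lo, hi + 1))
    coef = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in xs]
    total = sum(coef)
    probs = [w / total for w in coef]
    p_obs = probs[a - lo]
    p = sum(pr for pr in probs if pr <= p_obs * (1 + 1e-7))

    if a == lo:
        return min(p, 1.0), 0.0
    if a == hi:
        return min(p, 1.0), math.inf

    def mean(psi: float) -> float:
        # scale weights to avoid overflow: use psi^(x - a)
        ws = [w * psi ** (x - a) for w, x in zip(coef, xs)]
        s = sum(ws)
        return sum(x * w for x, w in zip(xs, ws)) / s

    lo_psi, hi_psi = 1e-12, 1e12
    while mean(lo_psi) > a:
        lo_psi /= 1e6
    while mean(hi_psi) < a:
        hi_psi *= 1e6
    for _ in range(200):
        mid = math.sqrt(lo_psi * hi_psi)
        if mean(mid) < a:
            lo_psi = mid
        else:
            hi_psi = mid
    return min(p, 1.0), math.sqrt(lo_psi * hi_psi)


def conditional_mean_exact(a: int, b: int, c: int, d: int, psi: float) -> float:
    """E_psi[X] with exact integer coefficients (for verifying an MLE)."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(c1, r1)
    xs = range(lo, hi + 1)
    ws = [math.comb(r1, x) * math.comb(r2, c1 - x) * psi ** (x - a) for x in xs]
    s = sum(ws)
    return sum(x * w for x, w in zip(xs, ws)) / s


# ---------------------------------------------------------------------------
# Mann-Whitney U by full label permutation
# ---------------------------------------------------------------------------

def mwu_permutation(x: list, y: list):
    """(U, two-sided p) by enumerating every assignment of the pooled
    values to the two groups (distinct permutations of the label vector)."""

    def u_stat(g1, g2):
        u = 0.0
        for xi in g1:
            for yi in g2:
                if xi > yi:
                    u += 1.0
                elif xi == yi:
                    u += 0.5
        return u

    n1 = len(x)
    pooled = list(x) + list(y)
    center = n1 * len(y) / 2.0
    u_obs = u_stat(x, y)
    dev = abs(u_obs - center)
    labels = [0] * n1 + [1] * len(y)
    seen = set(permutations(labels))
    hits = 0
    for lab in seen:
        g1 = [v for v, l in zip(pooled, lab) if l == 0]
        g2 = [v for v, l in zip(pooled, lab) if l == 1]
        if abs(u_stat(g1, g2) - center) >= dev - 1e-9:
            hits += 1
    return u_obs, hits / len(seen)


# ---------------------------------------------------------------------------
# ACMG combining rules as an explicit clause table
# ---------------------------------------------------------------------------

_P_CLAUSES = [
    {"PVS": 1, "PS": 1}, {"PVS": 1, "PM": 2}, {"PVS": 1, "PM": 1, "PP": 1},
    {"PVS": 1, "PP": 2},
    {"PS": 2},
    {"PS": 1, "PM": 3}, {"PS": 1, "PM": 2, "PP": 2}, {"PS": 1, "PM": 1, "PP": 4},
]
_LP_CLAUSES = [
    {"PVS": 1, "PM": 1},
    {"PS": 1, "PM": 1},
    {"PS": 1, "PP": 2},
    {"PM": 3}, {"PM": 2, "PP": 2}, {"PM": 1, "PP": 4},
]
_B_CLAUSES = [{"BA": 1}, {"BS": 2}]
_LB_CLAUSES = [{"BS": 1, "BP": 1}, {"BP": 2}]


def _strength(code: str) -> str:
    for pref in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(pref):
            return pref
    raise ValueError(code)


def _matches(counts: dict, clause: dict) -> bool:
    return all(counts.get(k, 0) >= v for k, v in clause.items())


def combine_clause_oracle(codes) -> str:
    """5-tier call from the explicit clause table (conflict -> VUS)."""
    counts: dict[str, int] = {}
    for code in codes:
        counts[_strength(code)] = counts.get(_strength(code), 0) + 1
    is_p = any(_matches(counts, cl) for cl in _P_CLAUSES)
    is_lp = any(_matches(counts, cl) for cl in _LP_CLAUSES)
    is_b = "BA" in counts or any(_matches(counts, cl) for cl in _B_CLAUSES)
    is_lb = any(_matches(counts, cl) for cl in _LB_CLAUSES)
    if (is_p or is_lp) and (is_b or is_lb):
        return "VUS"
    if is_p:
        return "P"
    if is_lp:
        return "LP"
    if is_b:
        return "B"
    if is_lb:
        return "LB"
    return "VUS"
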