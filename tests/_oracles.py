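"""Independent reference implementations used to validate the package.

These deliberately use different machinery from the implementation:
plain nested loops for mass decomposition, exact rational arithmetic with
full-length convolution for isotope patterns, and a literal running-sum
walk plus exhaustive placement enumeration for the KS statistic.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Dict, List, Tuple

from metaseed.chem import DEFAULT_ISOTOPES, Formula

# principal-nuclide masses for the oracle's own arithmetic
_M = {e: DEFAULT_ISOTOPES.principal_mass(e) for e in ("C", "H", "N", "O", "P", "S")}


def brute_force_decompose(mass: float, tol_ppm: float,
                          caps: Dict[str, int]) -> List[str]:
    """All CHNOPS formulas in the ppm window, by exhaustive nested loops.

    Hydrogen is closed out by checking the three integer counts nearest
    the mass residue; every accepted candidate is re-verified against the
    exact window.
    """
    lo = mass * (1 - tol_ppm * 1e-6)
    hi = mass * (1 + tol_ppm * 1e-6)
    out = []
    for s in range(caps.get("S", 0) + 1):
        ms = s * _M["S"]
        if ms > hi:
            break
        for p in range(caps.get("P", 0) + 1):
            mp = ms + p * _M["P"]
            if mp > hi:
                break
            for o in range(caps.get("O", 0) + 1):
                mo = mp + o * _M["O"]
                if mo > hi:
                    break
                for n in range(caps.get("N", 0) + 1):
                    mn = mo + n * _M["N"]
                    if mn > hi:
                        break
                    for c in range(caps.get("C", 0) + 1):
                        mc = mn + c * _M["C"]
                        if mc > hi:
                            break
                        h_guess = int(round((mass - mc) / _M["H"]))
                        for h in (h_guess - 1, h_guess, h_guess + 1):
                            if h < 0 or h > caps.get("H", 0):
                                continue
                            total = mc + h * _M["H"]
                            if lo <= total <= hi:
                                out.append(str(Formula(
                                    {"C": c, "H": h, "N": n, "O": o, "P": p, "S": s})))
    return sorted(set(out))


# exact isotope abundances as rationals (same published values as the
# implementation's float table, but exact arithmetic and no truncation)
_RATIONAL_ISOTOPES: Dict[str, List[Tuple[int, Fraction]]] = {
    "H": [(0, Fraction("0.999885")), (1, Fraction("0.000115"))],
    "C": [(0, Fraction("0.9893")), (1, Fraction("0.0107"))],
    "N": [(0, Fraction("0.99636")), (1, Fraction("0.00364"))],
    "O": [(0, Fraction("0.99757")), (1, Fraction("0.00038")), (2, Fraction("0.00205"))],
    "P": [(0, Fraction(1))],
    "S": [(0, Fraction("0.9499")), (1, Fraction("0.0075")),
          (2, Fraction("0.0425")), (4, Fraction("0.0001"))],
    "Na": [(0, Fraction(1))],
    "Cl": [(0, Fraction("0.7576")), (2, Fraction("0.2424"))],
}


def exact_isotope_pattern(formula: Formula, depth: int = 3) -> Dict[int, float]:
    """M+k relative abundances by full-length exact rational convolution."""
    dist: Dict[int, Fraction] = {0: Fraction(1)}
    for elem, count in formula.counts.items():
        single = _RATIONAL_ISOTOPES[elem]
        for _ in range(count):
            new: Dict[int, Fraction] = {}
            for off1, a1 in dist.items():
                for off2, a2 in single:
                    new[off1 + off2] = new.get(off1 + off2, Fraction(0)) + a1 * a2
            dist = new
    base = dist[0]
    return {k: float(v / base) for k, v in sorted(dist.items()) if k <= depth}


def ks_walk(ranked_ids: List[str], members: set) -> float:
    """Literal running-sum walk; signed maximal |excursion| (ties -> +)."""
    n, h = len(ranked_ids), len(members)
    running, best = 0.0, 0.0
    for fid in ranked_ids:
        running += 1.0 / h if fid in members else -1.0 / (n - h)
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def exhaustive_ks_pvalue(n: int, h: int, es_obs: float) -> float:
    """Exact two-sided p over all C(n, h) member placements."""
    ids = [str(i) for i in range(n)]
    count = total = 0
    for combo in itertools.combinations(ids, h):
        es = ks_walk(ids, set(combo))
        count += abs(es) >= abs(es_obs) - 1e-12
        total += 1
    return count / total
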