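"""Molecular-formula inference for monoisotopic features.

Candidate elemental compositions for a neutral accurate mass are found by
exhaustive bounded enumeration over CHNOPS counts (vectorized, with
arithmetic window pruning and a direct hydrogen solve, so the output set
is provably complete within the ppm window). Candidates then pass the
"seven golden rules" heuristics (element-count caps, RDBE, element-ratio
and multi-element plausibility checks), get a theoretical isotopologue
pattern by exact per-element convolution, and are scored against the
experimental pattern with a Gaussian mass + intensity likelihood under a
uniform prior. Only the top three candidates per feature are kept.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .chem import DEFAULT_ISOTOPES, ElementIsotopeTable, Formula, monoisotopic_mass
from .preprocess import IsotopePattern

__all__ = [
    "ElementBounds",
    "FormulaCandidate",
    "ScoringParams",
    "decompose_mass",
    "rdbe",
    "golden_rules_filter",
    "simulate_isotope_pattern",
    "score_candidates",
    "infer_formulas",
]


@dataclass(frozen=True)
class ElementBounds:
    """Maximum element counts for decomposition (golden rule 1).

    The default CHNOPS caps depend on the mass regime: small metabolites
    (<= 500 Da) use tighter caps than the 500-1000 Da range.
    """

    caps: Mapping[str, int]

    def __post_init__(self) -> None:
        for elem, cap in self.caps.items():
            if cap <= 0:
                raise ValueError(f"cap for {elem} must be positive")

    @classmethod
    def default_for_mass(cls, mass: float) -> "ElementBounds":
        if mass <= 500.0:
            return cls({"C": 39, "H": 72, "N": 20, "O": 20, "P": 9, "S": 10})
        return cls({"C": 78, "H": 126, "N": 25, "O": 27, "P": 9, "S": 14})


@dataclass
class FormulaCandidate:
    formula: Formula
    mass: float
    ppm_error: float
    rdbe: float
    flags: Dict[str, str] = field(default_factory=dict)  # rule -> "ok"|"soft"
    log_likelihood: float = 0.0
    posterior: float = 0.0
    rank: int = 0


@dataclass(frozen=True)
class ScoringParams:
    """Gaussian likelihood widths for the Bayesian pattern comparison."""

    sigma_mass: float = 2.0  # ppm
    sigma_intensity: float = 0.05  # relative fraction
    depth: int = 3  # isotopologue offsets M+0..M+depth

    def __post_init__(self) -> None:
        if self.sigma_mass <= 0 or self.sigma_intensity <= 0:
            raise ValueError("sigmas must be positive")
        if self.depth < 1:
            raise ValueError("pattern depth must cover at least M+1")


def decompose_mass(
    mass: float,
    tol_ppm: float,
    bounds: Optional[ElementBounds] = None,
    isotopes: ElementIsotopeTable = DEFAULT_ISOTOPES,
) -> List[Formula]:
    """All formulas within ``bounds`` whose monoisotopic mass is within
    ``tol_ppm`` of ``mass``, sorted by |ppm error| (ties by Hill string).

    Non-hydrogen counts are enumerated as a growing grid, pruned at each
    element by the reachable-mass window; hydrogen counts are then solved
    directly from the residual mass, so no candidate inside the window
    can be missed.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    if bounds is None:
        bounds = ElementBounds.default_for_mass(mass)
    if not bounds.caps:
        raise ValueError("empty element bounds")

    lo = mass * (1.0 - tol_ppm * 1e-6)
    hi = mass * (1.0 + tol_ppm * 1e-6)

    elems = [e for e in bounds.caps if e != "H"]
    elems.sort(key=lambda e: -isotopes.principal_mass(e))  # heavy first
    masses = {e: isotopes.principal_mass(e) for e in elems}
    cap_h = bounds.caps.get("H", 0)
    m_h = isotopes.principal_mass("H")

    # max mass still addable after position k (remaining elements + H)
    tail = np.zeros(len(elems) + 1)
    tail[len(elems)] = cap_h * m_h
    for k in range(len(elems) - 1, -1, -1):
        tail[k] = tail[k + 1] + bounds.caps[elems[k]] * masses[elems[k]]

    counts = np.zeros((1, 0), dtype=np.int64)
    partial = np.zeros(1)
    for k, elem in enumerate(elems):
        m_e = masses[elem]
        cap = bounds.caps[elem]
        c_max = np.minimum(cap, np.floor((hi - partial) / m_e)).astype(np.int64)
        c_min = np.maximum(
            0, np.ceil((lo - tail[k + 1] - partial) / m_e)).astype(np.int64)
        width = np.maximum(c_max - c_min + 1, 0)
        keep = width > 0
        counts, partial = counts[keep], partial[keep]
        c_min, width = c_min[keep], width[keep]
        rep = np.repeat(np.arange(len(width)), width)
        offs = np.arange(width.sum()) - np.repeat(np.cumsum(width) - width, width)
        c = c_min[rep] + offs
        counts = np.hstack([counts[rep], c[:, None]])
        partial = partial[rep] + c * m_e

    results: List[Tuple[float, str, Formula]] = []
    if cap_h > 0:
        n_lo = np.maximum(0, np.ceil((lo - partial) / m_h)).astype(np.int64)
        n_hi = np.minimum(cap_h, np.floor((hi - partial) / m_h)).astype(np.int64)
        rows, = np.nonzero(n_lo <= n_hi)
        for r in rows:
            for n_h in range(int(n_lo[r]), int(n_hi[r]) + 1):
                total = partial[r] + n_h * m_h
                f = Formula({**{e: int(counts[r, k]) for k, e in enumerate(elems)},
                             "H": n_h})
                results.append((abs(total - mass) / mass * 1e6, str(f), f))
    else:
        rows, = np.nonzero((partial >= lo) & (partial <= hi))
        for r in rows:
            f = Formula({e: int(counts[r, k]) for k, e in enumerate(elems)})
            results.append((abs(partial[r] - mass) / mass * 1e6, str(f), f))
    results.sort(key=lambda t: (t[0], t[1]))
    return [f for _err, _s, f in results]


def rdbe(formula: Formula) -> float:
    """Ring-and-double-bond equivalents: C - H/2 + (N+P)/2 + 1."""
    return (formula["C"] - formula["H"] / 2.0
            + (formula["N"] + formula["P"]) / 2.0 + 1.0)


# (rule-6 style) multi-element plausibility caps: when every element in
# the key exceeds its trigger count, each must stay below the cap.
_MULTI_ELEMENT_CHECKS = [
    ({"N": 1, "O": 1, "P": 1, "S": 1}, {"N": 10, "O": 20, "P": 4, "S": 3}),
    ({"N": 3, "O": 3, "P": 3}, {"N": 11, "O": 22, "P": 6}),
    ({"O": 1, "P": 1, "S": 1}, {"O": 14, "P": 3, "S": 3}),
    ({"P": 1, "S": 1, "N": 1}, {"P": 3, "S": 3, "N": 4}),
    ({"N": 6, "O": 6, "S": 6}, {"N": 19, "O": 14, "S": 8}),
]


def golden_rules_filter(
    candidates: Sequence[Formula],
    observed_mass: Optional[float] = None,
    isotopes: ElementIsotopeTable = DEFAULT_ISOTOPES,
) -> List[FormulaCandidate]:
    """Apply the golden-rules heuristics; hard failures are dropped,
    soft failures survive with a flag.

    Hard: RDBE >= 0 and integer-valued (neutral even-electron molecule);
    H/C in [0.1, 6]; N/C <= 1.3, O/C <= 1.2, P/C <= 0.3, S/C <= 0.8;
    multi-element NOPS caps. Soft: H/C outside [0.2, 3.1].
    Element-count caps (rule 1) are enforced upstream by ElementBounds.
    """
    if not candidates:
        raise ValueError("no candidates to filter")
    out: List[FormulaCandidate] = []
    for f in candidates:
        flags: Dict[str, str] = {}
        r = rdbe(f)
        if r < 0 or abs(r - round(r)) > 1e-9:
            continue
        flags["rdbe"] = "ok"
        c = f["C"]
        if c > 0:
            hc = f["H"] / c
            if not (0.1 <= hc <= 6.0):
                continue
            flags["h_c_ratio"] = "ok" if 0.2 <= hc <= 3.1 else "soft"
            ratios = {"N": 1.3, "O": 1.2, "P": 0.3, "S": 0.8}
            if any(f[e] / c > cap for e, cap in ratios.items()):
                continue
            flags["element_ratios"] = "ok"
        bad = False
        for trigger, caps in _MULTI_ELEMENT_CHECKS:
            if all(f[e] > t for e, t in trigger.items()):
                if any(f[e] >= caps[e] for e in caps):
                    bad = True
                    break
        if bad:
            continue
        flags["multi_element"] = "ok"
        mass = monoisotopic_mass(f, isotopes)
        ppm = 0.0 if observed_mass is None else (mass - observed_mass) / observed_mass * 1e6
        out.append(FormulaCandidate(f, mass, ppm, r, flags))
    return out


def _element_offset_dist(element: str, isotopes: ElementIsotopeTable,
                         depth: int) -> np.ndarray:
    """Single-atom isotope distribution over nominal mass offsets 0..depth."""
    nuclides = isotopes.nuclides(element)
    base = nuclides[0][0]
    dist = np.zeros(depth + 1)
    for m, a in nuclides:
        off = int(round(m - base))
        if off <= depth:
            dist[off] += a
    return dist


def simulate_isotope_pattern(
    formula: Formula,
    isotopes: ElementIsotopeTable = DEFAULT_ISOTOPES,
    depth: int = 3,
) -> IsotopePattern:
    """Exact nominal-mass-aggregated isotopologue distribution.

    Per-element single-atom distributions are raised to the atom count by
    repeated convolution (exponentiation by squaring) and multiplied
    across elements, truncating at ``depth`` offsets throughout — the
    truncation is exact for the retained entries because heavier
    isotopologues can never feed back into lighter ones. Intensities are
    normalized so M+0 = 1; zero entries are dropped.
    """
    if not formula:
        raise ValueError("empty formula")

    def conv(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.convolve(a, b)[: depth + 1]

    total = np.zeros(depth + 1)
    total[0] = 1.0
    for elem, n in formula.counts.items():
        single = _element_offset_dist(elem, isotopes, depth)
        power = np.zeros(depth + 1)
        power[0] = 1.0
        base = single
        k = n
        while k:
            if k & 1:
                power = conv(power, base)
            k >>= 1
            if k:
                base = conv(base, base)
        total = conv(total, power)
    if total[0] <= 0:
        raise ValueError("M+0 abundance vanished; formula too exotic for depth")
    rel = total / total[0]
    entries = [(f"M+{k}", float(rel[k])) for k in range(depth + 1) if rel[k] > 0]
    return IsotopePattern(entries)


_OFFSET_RE = re.compile(r"M\+(\d+)")


def _observed_by_offset(pattern: IsotopePattern) -> Dict[int, float]:
    """Sum experimental relative intensities per nominal offset.

    Experimental labels carry the assigned nuclide, e.g. 'M+1(13C)';
    entries sharing an offset (13C and 15N both at M+1) are summed before
    comparison with the aggregated theoretical value.
    """
    out: Dict[int, float] = {}
    for label, ri in pattern.entries:
        m = _OFFSET_RE.match(label)
        if not m:
            raise ValueError(f"unparsable isotope label {label!r}")
        k = int(m.group(1))
        if k > 0:
            out[k] = out.get(k, 0.0) + ri
    return out


def score_candidates(
    observed_mass: float,
    observed_pattern: Optional[IsotopePattern],
    candidates: Sequence[FormulaCandidate],
    params: ScoringParams = ScoringParams(),
    isotopes: ElementIsotopeTable = DEFAULT_ISOTOPES,
    top_n: int = 3,
) -> List[FormulaCandidate]:
    """Posterior-rank candidates against the observed mass and pattern.

    log L = log N(ppm error; 0, sigma_mass) + sum over *observed* offsets
    of log N(observed - theoretical relative intensity; 0,
    sigma_intensity); offsets with no observed partner contribute nothing
    (below detection is not evidence of absence). Posteriors use a
    uniform prior and are normalized over the full candidate set; the
    ``top_n`` best are returned in rank order.
    """
    if not candidates:
        return []
    obs = _observed_by_offset(observed_pattern) if observed_pattern else {}
    log2pi = math.log(2.0 * math.pi)

    for cand in candidates:
        ppm = (cand.mass - observed_mass) / observed_mass * 1e6
        cand.ppm_error = ppm
        ll = -0.5 * (ppm / params.sigma_mass) ** 2 \
            - math.log(params.sigma_mass) - 0.5 * log2pi
        if obs:
            theo = simulate_isotope_pattern(cand.formula, isotopes, params.depth)
            theo_by_offset = {int(lab[2:]): ri for lab, ri in theo.entries}
            for k, obs_ri in obs.items():
                d = obs_ri - theo_by_offset.get(k, 0.0)
                ll += -0.5 * (d / params.sigma_intensity) ** 2 \
                    - math.log(params.sigma_intensity) - 0.5 * log2pi
        cand.log_likelihood = ll

    lls = np.array([c.log_likelihood for c in candidates])
    w = np.exp(lls - lls.max())
    post = w / w.sum()
    for cand, p in zip(candidates, post):
        cand.posterior = float(p)
    ranked = sorted(candidates,
                    key=lambda c: (-c.posterior, abs(c.ppm_error), str(c.formula)))
    for i, cand in enumerate(ranked, start=1):
        cand.rank = i
    return ranked[:top_n]


def infer_formulas(
    neutral_mass: float,
    pattern: Optional[IsotopePattern],
    tol_ppm: float = 5.0,
    params: ScoringParams = ScoringParams(),
    bounds: Optional[ElementBounds] = None,
    isotopes: ElementIsotopeTable = DEFAULT_ISOTOPES,
) -> List[FormulaCandidate]:
    """Decompose, filter, and score one feature's neutral mass; top 3."""
    formulas = decompose_mass(neutral_mass, tol_ppm, bounds, isotopes)
    if not formulas:
        return []
    survivors = golden_rules_filter(formulas, neutral_mass, isotopes)
    if not survivors:
        return []
    return score_candidates(neutral_mass, pattern, survivors, params, isotopes)
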