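"""Peak-list deconvolution, tier classification and differential statistics.

The raw peak list is refined by a fixed cascade of filters, each peak
receiving the status of the first stage that rejects it:

1. retention-time validity (void volume / column wash exclusion),
2. adduct/multimer (artifact) removal via the all-by-all mass-difference
   matrix with co-elution gating,
3. the mass-defect (non-biological signal) filter,
4. isotopologue grouping (13C, 15N, 18O, 34S partners are folded into
   their monoisotopic peak's isotope pattern and removed from the list).

Surviving ("refined") features get per-feature differential statistics
and a three-tier classification: primary = visible isotope pattern and
>20 % abundance change, secondary = pattern but <=20 % change, tertiary =
no visible pattern.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .chem import DEFAULT_ISOTOPES, ElementIsotopeTable, PROTON_MASS, neutral_mass_from_mz
from .compound_db import IN_REGION, OUT_OF_RANGE, MassDefectModel
from .peak_io import Peak, PeakTable, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ToleranceConfig",
    "IsotopePattern",
    "FeatureRecord",
    "AccountingSummary",
    "DEFAULT_ADDUCT_RULES",
    "ISOTOPOLOGUE_OFFSETS",
    "filter_rt",
    "MassDifferenceMatrix",
    "mass_difference_matrix",
    "remove_adducts_multimers",
    "detect_isotopologues",
    "apply_mass_defect_filter",
    "differential_stats",
    "classify_tiers",
    "accounting_summary",
    "preprocess_table",
]

# statuses
RETAINED = "retained"
INVALID_RT = "invalid_rt"
ARTIFACT = "artifact"
NON_BIOLOGICAL = "non_biological"
ISOTOPOLOGUE = "isotopologue"

# tiers
PRIMARY = "primary"
SECONDARY = "secondary"
TERTIARY = "tertiary"
NO_TIER = "none"


@dataclass(frozen=True)
class ToleranceConfig:
    """Tolerances of the deconvolution cascade.

    ppm_group gates pair matching (adducts, isotopologues); ppm_search is
    the database search tolerance; rt_window is the VALID retention-time
    interval in seconds (closed); change_threshold is the percent-change
    cut separating primary from secondary features.
    """

    ppm_group: float = 2.0
    ppm_search: float = 5.0
    rt_tol: float = 60.0
    rt_window: Tuple[float, float] = (120.0, 2030.0)
    change_threshold: float = 20.0
    min_isotope_intensity: float = 0.01  # relative floor for "visible" partners

    def __post_init__(self) -> None:
        if min(self.ppm_group, self.ppm_search, self.rt_tol, self.change_threshold) <= 0:
            raise ValueError("tolerances must be strictly positive")
        if not self.rt_window[0] < self.rt_window[1]:
            raise ValueError("rt_window must be ordered (lo, hi)")


@dataclass
class IsotopePattern:
    """Relative isotopologue intensities anchored at M+0 = 1.

    entries: (label, intensity relative to M+0) sorted by mass offset;
    source_ids: the peak ids the partners came from (empty for
    theoretical patterns).
    """

    entries: List[Tuple[str, float]]
    source_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, ri in self.entries:
            if ri <= 0:
                raise ValueError(f"non-positive relative intensity for {label}")

    def relative(self, label: str) -> Optional[float]:
        for lab, ri in self.entries:
            if lab == label:
                return ri
        return None

    def __bool__(self) -> bool:
        return bool(self.entries)


@dataclass
class FeatureRecord:
    """A peak's fate through the cascade plus its downstream annotations."""

    peak_id: str
    mz: float
    rt: float
    neutral_mass: float
    status: str = RETAINED
    artifact_label: Optional[str] = None
    reason: Optional[str] = None
    tier: str = NO_TIER
    percent_change: Optional[float] = None
    fold_change: Optional[float] = None
    p_value: Optional[float] = None
    t_stat: Optional[float] = None
    pattern: Optional[IsotopePattern] = None
    candidates: Optional[list] = None  # FormulaCandidate list, filled later

    @property
    def has_visible_pattern(self) -> bool:
        return self.pattern is not None and bool(self.pattern)


# Negative-mode ESI artifact rules: label -> m/z offset from the [M-H]- anchor.
DEFAULT_ADDUCT_RULES: Dict[str, float] = {
    "[M+Cl]-": 35.976129,
    "[M+HCOO]-": 46.005480,
    "[M+CH3COO]-": 60.021130,
    "[M+Na-2H]-": 21.981944,
    "[M-H2O-H]-": -18.010565,
}

# Isotopologue mass offsets (Da) from the monoisotopic peak, derived from
# the nuclide masses in chem.DEFAULT_ISOTOPES.
ISOTOPOLOGUE_OFFSETS: Dict[str, float] = {
    "M+1(13C)": 13.00335483780 - 12.0,
    "M+1(15N)": 15.00010889820 - 14.00307400480,
    "M+2(18O)": 17.99916100 - 15.99491461956,
    "M+2(34S)": 33.96786690 - 31.97207100,
}


def filter_rt(table: PeakTable, cfg: ToleranceConfig) -> Tuple[List[Peak], List[Peak]]:
    """Split peaks into (inside valid RT window, flagged invalid_rt)."""
    lo, hi = cfg.rt_window
    kept = [p for p in table.peaks if lo <= p.rt <= hi]
    flagged = [p for p in table.peaks if not (lo <= p.rt <= hi)]
    return kept, flagged


class MassDifferenceMatrix:
    """All-by-all pairwise m/z differences, optionally RT-windowed.

    Access is symmetric: delta(i, j) = mz[j] - mz[i] = -delta(j, i).
    For large peak lists (> ``sparse_threshold``) only co-eluting pairs
    are enumerated, which is what every downstream consumer needs anyway.
    """

    def __init__(self, peaks: Sequence[Peak], rt_window: Optional[float] = None,
                 sparse_threshold: int = 20000):
        self.peaks = list(peaks)
        self.mz = np.array([p.mz for p in self.peaks])
        self.rt = np.array([p.rt for p in self.peaks])
        if rt_window is None and len(self.peaks) > sparse_threshold:
            rt_window = 60.0
            logger.info("large peak list (n=%d): RT-windowed sparse mode (%.0f s)",
                        len(self.peaks), rt_window)
        self.rt_window = rt_window

    def delta(self, i: int, j: int) -> float:
        return float(self.mz[j] - self.mz[i])

    @property
    def n_pairs(self) -> int:
        n = len(self.peaks)
        if self.rt_window is None:
            return n * (n - 1) // 2
        return sum(1 for _ in self.pairs())

    def pairs(self) -> Iterable[Tuple[int, int, float]]:
        n = len(self.peaks)
        for i in range(n):
            for j in range(i + 1, n):
                if self.rt_window is not None and abs(self.rt[j] - self.rt[i]) > self.rt_window:
                    continue
                yield i, j, float(self.mz[j] - self.mz[i])


def mass_difference_matrix(peaks: Sequence[Peak],
                           rt_window: Optional[float] = None) -> MassDifferenceMatrix:
    if len(peaks) == 0:
        raise ValueError("need at least one peak")
    return MassDifferenceMatrix(peaks, rt_window=rt_window)


def _match_tol(mz_light: float, ppm: float) -> float:
    return mz_light * ppm * 1e-6


def remove_adducts_multimers(
    peaks: Sequence[Peak],
    cfg: ToleranceConfig,
    rules: Optional[Dict[str, float]] = None,
) -> Tuple[List[Peak], List[Tuple[Peak, str]]]:
    """Flag adduct/dimer peaks explained by a co-eluting [M-H]- anchor.

    A peak j is an artifact when some kept, co-eluting (|dRT| <= rt_tol)
    peak i explains it by a rule offset or the dimer relation within the
    grouping ppm tolerance (ppm taken on the lighter peak's m/z). Anchors
    of accepted matches are never themselves flagged: positive-offset and
    dimer rules are resolved lightest-first, the water-loss rule (heavier
    anchor) heaviest-first, so every anchor's status is final when used.
    """
    rules = dict(DEFAULT_ADDUCT_RULES if rules is None else rules)
    order = sorted(range(len(peaks)), key=lambda k: peaks[k].mz)
    mz_sorted = [peaks[k].mz for k in order]
    kept = [True] * len(peaks)
    label: Dict[int, str] = {}

    def anchors_near(target_mz: float, tol: float) -> Iterable[int]:
        lo = bisect.bisect_left(mz_sorted, target_mz - tol)
        hi = bisect.bisect_right(mz_sorted, target_mz + tol)
        return (order[r] for r in range(lo, hi))

    def try_flag(j: int, anchor_mz: float, tol: float, rule: str) -> bool:
        for i in anchors_near(anchor_mz, tol):
            if i == j or not kept[i]:
                continue
            if abs(peaks[i].rt - peaks[j].rt) <= cfg.rt_tol:
                kept[j] = False
                label[j] = rule
                return True
        return False

    pos_rules = {lab: off for lab, off in rules.items() if off > 0}
    neg_rules = {lab: off for lab, off in rules.items() if off < 0}

    # lightest-first: anchors (lighter) already final
    for j in order:
        if not kept[j]:
            continue
        for lab, off in pos_rules.items():
            anchor_mz = peaks[j].mz - off
            if anchor_mz <= 0:
                continue
            if try_flag(j, anchor_mz, _match_tol(anchor_mz, cfg.ppm_group), lab):
                break
        else:
            # dimer: mz_j = 2*mz_i + proton
            anchor_mz = (peaks[j].mz - PROTON_MASS) / 2.0
            if anchor_mz > 0:
                try_flag(j, anchor_mz, _match_tol(anchor_mz, cfg.ppm_group), "[2M-H]-")

    # heaviest-first: water-loss anchors (heavier) already final
    for j in reversed(order):
        if not kept[j]:
            continue
        for lab, off in neg_rules.items():
            anchor_mz = peaks[j].mz - off  # anchor is heavier
            try_flag(j, anchor_mz, _match_tol(peaks[j].mz, cfg.ppm_group), lab)

    kept_peaks = [p for k, p in zip(kept, peaks) if k]
    flagged = [(peaks[j], label[j]) for j in sorted(label)]
    return kept_peaks, flagged


def detect_isotopologues(
    peaks: Sequence[Peak],
    isotopes: ElementIsotopeTable = DEFAULT_ISOTOPES,
    cfg: ToleranceConfig = ToleranceConfig(),
) -> Tuple[List[Tuple[Peak, Optional[IsotopePattern]]], List[Peak]]:
    """Group isotopologue partners onto their monoisotopic peaks.

    A co-eluting peak j becomes an isotopologue of i when mz_j - mz_i
    matches one of the 13C/15N/18O/34S offsets within the grouping ppm
    tolerance (computed on mz_i) and j is less intense than i. Each
    partner is assigned to at most one parent (smallest |ppm error| wins,
    then closest RT) and removed from the retained list; parents collect
    an IsotopePattern of their partners.
    """
    n = len(peaks)
    mean_int = [p.mean_intensity() for p in peaks]
    order = sorted(range(n), key=lambda k: peaks[k].mz)
    mz_sorted = [peaks[k].mz for k in order]

    # candidate matches: (|ppm err|, |dRT|, parent, partner, label, rel int)
    matches = []
    for pos, i in enumerate(order):
        for lab, off in ISOTOPOLOGUE_OFFSETS.items():
            target = peaks[i].mz + off
            tol = _match_tol(peaks[i].mz, cfg.ppm_group)
            lo = bisect.bisect_left(mz_sorted, target - tol, lo=pos + 1)
            hi = bisect.bisect_right(mz_sorted, target + tol, lo=pos + 1)
            for r in range(lo, hi):
                j = order[r]
                if abs(peaks[j].rt - peaks[i].rt) > cfg.rt_tol:
                    continue
                if not mean_int[j] < mean_int[i]:
                    continue
                ppm_err = abs(peaks[j].mz - target) / peaks[i].mz * 1e6
                matches.append((ppm_err, abs(peaks[j].rt - peaks[i].rt), i, j, lab))

    assigned_to: Dict[int, Tuple[int, str]] = {}  # partner -> (parent, label)
    is_partner = set()
    for ppm_err, _drt, i, j, lab in sorted(matches, key=lambda m: (m[0], m[1], m[2], m[3])):
        if j in assigned_to or i in is_partner:
            continue
        assigned_to[j] = (i, lab)
        is_partner.add(j)

    patterns: Dict[int, List[Tuple[float, str, float, str]]] = {}
    for j, (i, lab) in assigned_to.items():
        ri = mean_int[j] / mean_int[i] if mean_int[i] > 0 else 0.0
        patterns.setdefault(i, []).append(
            (ISOTOPOLOGUE_OFFSETS[lab], lab, ri, peaks[j].peak_id))

    mono: List[Tuple[Peak, Optional[IsotopePattern]]] = []
    flagged: List[Peak] = []
    for k, p in enumerate(peaks):
        if k in is_partner:
            flagged.append(p)
            continue
        pat = None
        if k in patterns:
            entries = sorted(patterns[k])
            visible = [(lab, ri) for _off, lab, ri, _src in entries
                       if ri >= cfg.min_isotope_intensity]
            if visible:
                pat = IsotopePattern(visible, [src for *_ignored, src in entries])
        mono.append((p, pat))
    return mono, flagged


def apply_mass_defect_filter(
    peaks: Sequence[Peak], model: MassDefectModel
) -> Tuple[List[Peak], List[Tuple[Peak, str]]]:
    """Drop peaks whose neutral mass falls outside the biological region."""
    kept: List[Peak] = []
    flagged: List[Tuple[Peak, str]] = []
    for p in peaks:
        code = model.classify(neutral_mass_from_mz(p.mz))
        if code == IN_REGION:
            kept.append(p)
        else:
            flagged.append((p, code))
    return kept, flagged


def differential_stats(
    peak: Peak,
    design: SampleDesign,
    timepoint: float,
) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """(percent change, signed fold change, Welch p) for one feature.

    percent change = (mean_treat - mean_ctrl)/mean_ctrl * 100; the signed
    fold change reports the ratio r = mean_treat/mean_ctrl as +r for
    r >= 1 and -1/r otherwise. The p-value is a Welch two-sample t-test
    on log10(intensity + 1). A zero control mean yields an undefined
    percent change and a +inf fold sentinel.
    """
    ctrl_ids = design.sample_ids("control", timepoint)
    treat_ids = design.sample_ids("treatment", timepoint)
    if not treat_ids:
        raise ValueError(f"no treatment samples at timepoint {timepoint}")
    if not ctrl_ids:
        raise ValueError(f"no control samples at timepoint {timepoint}")
    ctrl = np.array([peak.intensities.get(s, 0.0) for s in ctrl_ids])
    treat = np.array([peak.intensities.get(s, 0.0) for s in treat_ids])
    mc, mt = float(ctrl.mean()), float(treat.mean())

    if mc == 0.0:
        pct: Optional[float] = None
        fold: Optional[float] = math.inf if mt > 0 else None
    else:
        pct = (mt - mc) / mc * 100.0
        r = mt / mc
        if r >= 1:
            fold = r
        elif r > 0:
            fold = -1.0 / r
        else:
            fold = -math.inf

    _t, p = _welch_on_logs(ctrl, treat)
    return pct, fold, p


def _welch_on_logs(ctrl: np.ndarray, treat: np.ndarray
                   ) -> Tuple[Optional[float], Optional[float]]:
    """Welch t and p on log10(x+1); identical groups give (0, 1)."""
    log_c, log_t = np.log10(ctrl + 1.0), np.log10(treat + 1.0)
    if np.allclose(log_c.mean(), log_t.mean()) and np.allclose(
            np.concatenate([log_c, log_t]).var(), 0.0):
        return 0.0, 1.0
    with np.errstate(all="ignore"):
        res = stats.ttest_ind(log_t, log_c, equal_var=False)
    t = float(res.statistic) if math.isfinite(res.statistic) else None
    p = float(res.pvalue) if math.isfinite(res.pvalue) else None
    return t, p


def classify_tiers(features: Sequence[FeatureRecord],
                   cfg: ToleranceConfig = ToleranceConfig()) -> None:
    """Assign tiers in place to retained features.

    primary: visible isotope pattern and |percent change| > threshold
    (an undefined percent change with a +inf fold sentinel counts as a
    change beyond any threshold); secondary: pattern but small change;
    tertiary: no visible pattern.
    """
    for f in features:
        if f.status != RETAINED:
            f.tier = NO_TIER
            continue
        if f.percent_change is None:
            big_change = f.fold_change is not None and math.isinf(f.fold_change)
        else:
            big_change = abs(f.percent_change) > cfg.change_threshold
        if f.has_visible_pattern:
            f.tier = PRIMARY if big_change else SECONDARY
        else:
            f.tier = TERTIARY


@dataclass(frozen=True)
class AccountingSummary:
    """Category counts of the deconvolution cascade, in report row order."""

    n_features: int
    n_invalid_rt: int
    n_artifacts: int
    n_non_biological: int
    n_isotopologues: int
    n_formulas: int = 0

    @property
    def n_eliminated(self) -> int:
        return (self.n_invalid_rt + self.n_artifacts
                + self.n_non_biological + self.n_isotopologues)

    @property
    def n_retained(self) -> int:
        return self.n_features - self.n_eliminated

    def _pct(self, n: int) -> float:
        if self.n_features == 0:
            return 0.0
        return round(n / self.n_features * 100.0, 1)

    @property
    def pct_non_biological(self) -> float:
        return self._pct(self.n_non_biological)

    @property
    def pct_retained(self) -> float:
        return self._pct(self.n_retained)

    @property
    def pct_formulas(self) -> float:
        return self._pct(self.n_formulas)

    def footer_rows(self) -> List[Tuple[str, str]]:
        return [
            ("No. of features", str(self.n_features)),
            ("Invalid RT", str(self.n_invalid_rt)),
            ("No. of artifact features (adducts and multimers)", str(self.n_artifacts)),
            ("No. of non-biological signals (mass distribution filter)",
             f"{self.n_non_biological} ({self.pct_non_biological}%)"),
            ("No. of isotopes", str(self.n_isotopologues)),
            ("Total no. of eliminated features", str(self.n_eliminated)),
            ("No. of refined features for further analysis",
             f"{self.n_retained} ({self.pct_retained}%)"),
            ("No. of predicted molecular formulas",
             f"{self.n_formulas} ({self.pct_formulas}%)"),
        ]


def accounting_summary(features: Sequence[FeatureRecord]) -> AccountingSummary:
    """Tally statuses into the standard accounting block."""
    count = {INVALID_RT: 0, ARTIFACT: 0, NON_BIOLOGICAL: 0, ISOTOPOLOGUE: 0}
    n_formulas = 0
    for f in features:
        if f.status in count:
            count[f.status] += 1
        if f.status == RETAINED and f.candidates:
            n_formulas += 1
    return AccountingSummary(
        n_features=len(features),
        n_invalid_rt=count[INVALID_RT],
        n_artifacts=count[ARTIFACT],
        n_non_biological=count[NON_BIOLOGICAL],
        n_isotopologues=count[ISOTOPOLOGUE],
        n_formulas=n_formulas,
    )


def preprocess_table(
    table: PeakTable,
    model: MassDefectModel,
    cfg: ToleranceConfig = ToleranceConfig(),
    timepoint: Optional[float] = None,
    isotopes: ElementIsotopeTable = DEFAULT_ISOTOPES,
) -> Tuple[List[FeatureRecord], AccountingSummary]:
    """Run the full cascade and return one FeatureRecord per input peak.

    Statuses follow the fixed filter order (RT, artifact, mass defect,
    isotopologue); retained features carry differential statistics at the
    requested timepoint (default: first design timepoint) and a tier.
    """
    if timepoint is None:
        timepoint = table.design.timepoints()[0]

    records: Dict[str, FeatureRecord] = {}
    for p in table.peaks:
        records[p.peak_id] = FeatureRecord(
            p.peak_id, p.mz, p.rt, neutral_mass_from_mz(p.mz))

    kept, bad_rt = filter_rt(table, cfg)
    for p in bad_rt:
        records[p.peak_id].status = INVALID_RT

    kept, artifacts = remove_adducts_multimers(kept, cfg)
    for p, lab in artifacts:
        rec = records[p.peak_id]
        rec.status = ARTIFACT
        rec.artifact_label = lab

    kept, non_bio = apply_mass_defect_filter(kept, model)
    for p, code in non_bio:
        rec = records[p.peak_id]
        rec.status = NON_BIOLOGICAL
        rec.reason = code

    mono, iso = detect_isotopologues(kept, isotopes, cfg)
    for p in iso:
        records[p.peak_id].status = ISOTOPOLOGUE

    peaks_by_id = {p.peak_id: p for p in table.peaks}
    for p, pattern in mono:
        rec = records[p.peak_id]
        rec.pattern = pattern
        peak = peaks_by_id[p.peak_id]
        pct, fold, pval = differential_stats(peak, table.design, timepoint)
        rec.percent_change, rec.fold_change, rec.p_value = pct, fold, pval
        ctrl = np.array([peak.intensities.get(s, 0.0)
                         for s in table.design.sample_ids("control", timepoint)])
        treat = np.array([peak.intensities.get(s, 0.0)
                          for s in table.design.sample_ids("treatment", timepoint)])
        rec.t_stat, _ = _welch_on_logs(ctrl, treat)

    features = [records[p.peak_id] for p in table.peaks]  # input order
    classify_tiers(features, cfg)
    return features, accounting_summary(features)
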