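"""Synthetic compound databases and decorated peak tables with ground truth.

The generator emulates the data layer of a negative-mode LC-MS feeding
experiment: a miniature compound/pathway database of random but
chemically plausible CHNOPS formulas, and a peak table of [M-H]- ions
decorated with natural-abundance 13C isotopologues, adduct/dimer
artifacts and non-biological noise peaks, with one pathway's members
multiplicatively perturbed in the treatment condition. Everything is
deterministic given the seed, and the ground truth records every peak's
origin so each pipeline stage can be tested without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import DEFAULT_ISOTOPES, Formula, monoisotopic_mass, mz_from_neutral_mass
from .compound_db import Compound, CompoundDB, build_mass_defect_model
from .formulas import golden_rules_filter, simulate_isotope_pattern
from .peak_io import Peak, PeakTable, SampleDesign, SampleInfo
from .preprocess import DEFAULT_ADDUCT_RULES, PRIMARY, SECONDARY, TERTIARY

__all__ = ["SimulationConfig", "GroundTruth", "make_mini_db", "simulate_peak_table"]

NOISE_FORBIDDEN = "forbidden-region"
NOISE_BIOLOGICAL = "biological-like"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic feeding experiment."""

    seed: int
    n_pathways: int = 20
    compounds_per_pathway: int = 8
    pathway_overlap: float = 0.0  # fraction of compounds in a 2nd pathway
    emit_fraction: float = 1.0  # fraction of compounds emitted as peaks
    n_planted: int = 1  # perturbed pathways
    effect_percent: float = 150.0
    replicates: int = 3
    timepoint: float = 10.0  # minutes
    intensity_cv: float = 0.10
    p_13c: float = 0.8
    p_adduct: float = 0.2
    p_dimer: float = 0.1
    n_noise: int = 50
    noise_mode: str = NOISE_FORBIDDEN
    rt_window: Tuple[float, float] = (120.0, 2030.0)
    mass_range: Tuple[float, float] = (100.0, 1000.0)

    def __post_init__(self) -> None:
        for name in ("pathway_overlap", "emit_fraction", "p_13c", "p_adduct", "p_dimer"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_mode not in (NOISE_FORBIDDEN, NOISE_BIOLOGICAL):
            raise ValueError(f"unknown noise mode {self.noise_mode!r}")


@dataclass
class GroundTruth:
    """What each synthetic peak really is."""

    # peak id -> ("compound", compound id) | ("noise", "") |
    #            ("decoration", parent peak id) with decoration_label set
    origin: Dict[str, Tuple[str, str]] = field(default_factory=dict)
    decoration_label: Dict[str, str] = field(default_factory=dict)
    planted_pathways: List[str] = field(default_factory=list)
    true_tier: Dict[str, str] = field(default_factory=dict)

    def peaks_of_kind(self, kind: str) -> List[str]:
        return [pid for pid, (k, _ref) in self.origin.items() if k == kind]

    def decorations_with_label(self, label_prefix: str) -> List[str]:
        return [pid for pid, lab in self.decoration_label.items()
                if lab.startswith(label_prefix)]

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("peak_id\tkind\tref\tlabel\ttrue_tier\n")
            for pid, (kind, ref) in self.origin.items():
                fh.write("\t".join([
                    pid, kind, ref,
                    self.decoration_label.get(pid, ""),
                    self.true_tier.get(pid, ""),
                ]) + "\n")


def _random_formula(rng: np.random.Generator) -> Optional[Formula]:
    """One random CHNO(PS) composition; None if chemically implausible."""
    c = int(rng.integers(4, 31))
    h = int(round(c * rng.uniform(1.0, 2.2)))
    n = int(rng.choice([0, 0, 0, 1, 1, 2, 3]))
    o = int(rng.integers(0, 11))
    p = int(rng.random() < 0.10)
    s = int(rng.random() < 0.10)
    # even-electron neutral molecule: H - N - P must be even
    if (h - n - p) % 2:
        h += 1
    f = Formula({"C": c, "H": h, "N": n, "O": o, "P": p, "S": s})
    try:
        survivors = golden_rules_filter([f])
    except ValueError:
        return None
    return f if survivors else None


def make_mini_db(cfg: SimulationConfig) -> CompoundDB:
    """Random golden-rule-clean compounds partitioned into pathways.

    Masses stay inside the model range, at least 25 ppm apart (so
    annotation ground truth is unambiguous), and away from the upper edge
    of their 10-Da mass-defect pooling slab, keeping a compound and its
    M+1/M+2 isotopologues in the same slab.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_pathways * cfg.compounds_per_pathway
    lo, hi = cfg.mass_range
    compounds: List[Tuple[Formula, float]] = []
    masses: List[float] = []
    attempts = 0
    while len(compounds) < n_total:
        attempts += 1
        if attempts > 200 * n_total:
            raise RuntimeError("could not sample enough distinct plausible formulas")
        f = _random_formula(rng)
        if f is None:
            continue
        mass = monoisotopic_mass(f)
        if not lo <= mass <= hi:
            continue
        if (mass - lo) % 10.0 > 10.0 - 2.1:  # keep isotopologues in the slab
            continue
        if any(abs(mass - m) / m * 1e6 < 25.0 for m in masses):
            continue
        compounds.append((f, mass))
        masses.append(mass)

    order = rng.permutation(n_total)
    out: List[Compound] = []
    for k, idx in enumerate(order):
        f, mass = compounds[idx]
        pid = f"P{k // cfg.compounds_per_pathway + 1:02d}"
        pathways = {pid}
        if rng.random() < cfg.pathway_overlap:
            other = f"P{int(rng.integers(1, cfg.n_pathways + 1)):02d}"
            pathways.add(other)
        out.append(Compound(f"C{k + 1:04d}", f"compound-{k + 1}", mass, f,
                            frozenset(pathways)))
    return CompoundDB(out)


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_peak_table(
    db: CompoundDB, cfg: SimulationConfig
) -> Tuple[PeakTable, GroundTruth]:
    """Decorated [M-H]- peak table plus ground truth for a mini database."""
    rng = np.random.default_rng(cfg.seed + 1)
    planted = sorted(db.pathways)[: cfg.n_planted]
    planted_members = set()
    for pid in planted:
        planted_members |= set(db.pathways[pid].member_ids)

    ctrl_ids = [f"ctrl_{r + 1}" for r in range(cfg.replicates)]
    treat_ids = [f"treat_{r + 1}" for r in range(cfg.replicates)]
    design = SampleDesign({
        **{s: SampleInfo("control", cfg.timepoint, r + 1)
           for r, s in enumerate(ctrl_ids)},
        **{s: SampleInfo("treatment", cfg.timepoint, r + 1)
           for r, s in enumerate(treat_ids)},
    })

    truth = GroundTruth(planted_pathways=list(planted))
    peaks: List[Peak] = []
    counter = [0]

    def next_id() -> str:
        counter[0] += 1
        return f"F{counter[0]:06d}"

    def emit(mz: float, rt: float, ctrl: np.ndarray, treat: np.ndarray) -> Peak:
        p = Peak(next_id(), mz, rt,
                 {**dict(zip(ctrl_ids, ctrl.tolist())),
                  **dict(zip(treat_ids, treat.tolist()))})
        peaks.append(p)
        return p

    rt_lo, rt_hi = cfg.rt_window
    adduct_rules = [(lab, off) for lab, off in DEFAULT_ADDUCT_RULES.items() if off > 0]

    for cid in sorted(db.compounds):
        comp = db.compounds[cid]
        if rng.random() >= cfg.emit_fraction and comp.compound_id not in planted_members:
            continue
        rt = float(rng.uniform(rt_lo + 10.0, rt_hi - 10.0))
        base = 10.0 ** rng.uniform(4.0, 6.0)
        fold = 1.0 + cfg.effect_percent / 100.0 if cid in planted_members else 1.0
        ctrl = base * _lognormal_noise(rng, cfg.intensity_cv, cfg.replicates)
        treat = base * fold * _lognormal_noise(rng, cfg.intensity_cv, cfg.replicates)
        parent = emit(mz_from_neutral_mass(comp.mass), rt, ctrl, treat)
        truth.origin[parent.peak_id] = ("compound", cid)

        decorated = False
        if rng.random() < cfg.p_13c:
            pattern = simulate_isotope_pattern(comp.formula, DEFAULT_ISOTOPES, depth=1)
            ri = pattern.relative("M+1") or 0.0
            if ri > 0:
                jitter = float(rng.uniform(-5.0, 5.0))
                iso = emit(parent.mz + 1.0033548, rt + jitter, ctrl * ri, treat * ri)
                truth.origin[iso.peak_id] = ("decoration", parent.peak_id)
                truth.decoration_label[iso.peak_id] = "13C"
                decorated = True
        if rng.random() < cfg.p_adduct:
            lab, off = adduct_rules[int(rng.integers(len(adduct_rules)))]
            frac = rng.uniform(0.1, 0.5)
            jitter = float(rng.uniform(-5.0, 5.0))
            add = emit(parent.mz + off, rt + jitter, ctrl * frac, treat * frac)
            truth.origin[add.peak_id] = ("decoration", parent.peak_id)
            truth.decoration_label[add.peak_id] = f"adduct:{lab}"
        if rng.random() < cfg.p_dimer:
            frac = rng.uniform(0.05, 0.2)
            jitter = float(rng.uniform(-5.0, 5.0))
            dim = emit(2.0 * parent.mz + 1.00727646, rt + jitter,
                       ctrl * frac, treat * frac)
            truth.origin[dim.peak_id] = ("decoration", parent.peak_id)
            truth.decoration_label[dim.peak_id] = "dimer:[2M-H]-"

        perturbed = cid in planted_members
        if decorated:
            truth.true_tier[parent.peak_id] = PRIMARY if perturbed else SECONDARY
        else:
            truth.true_tier[parent.peak_id] = TERTIARY

    if cfg.n_noise > 0:
        model = build_mass_defect_model(db, mass_range=cfg.mass_range)
        db_masses = np.array(db.masses)
        n_made = 0
        while n_made < cfg.n_noise:
            if cfg.noise_mode == NOISE_FORBIDDEN:
                mass = float(rng.uniform(*cfg.mass_range))
                if model.is_biological(mass):
                    continue
            else:
                mass = float(rng.choice(db_masses) + rng.uniform(-0.004, 0.004))
                if not model.is_biological(mass):
                    continue
            rt = float(rng.uniform(rt_lo + 10.0, rt_hi - 10.0))
            base = 10.0 ** rng.uniform(3.5, 5.0)
            ctrl = base * _lognormal_noise(rng, cfg.intensity_cv, cfg.replicates)
            treat = base * _lognormal_noise(rng, cfg.intensity_cv, cfg.replicates)
            p = emit(mz_from_neutral_mass(mass), rt, ctrl, treat)
            truth.origin[p.peak_id] = ("noise", "")
            n_made += 1

    return PeakTable(peaks, design, source=f"synthetic(seed={cfg.seed})"), truth
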