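"""Reference compound/pathway database and the mass-defect filter model.

The database is a small TSV stand-in for a public compound resource
(columns: id, name, formula, mass, pathways). Besides exact-mass lookups it
supports an empirical "mass defect" model: biological elemental
compositions confine the fractional part of the monoisotopic mass to
narrow, mass-dependent bands, so a 2-D histogram of (integer part,
fractional part) over database compounds separates plausible metabolite
masses from non-biological signals (solvent clusters, instrument noise).
"""

from __future__ import annotations

import bisect
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .chem import (
    DEFAULT_ISOTOPES,
    ElementIsotopeTable,
    Formula,
    monoisotopic_mass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Compound",
    "PathwayDef",
    "CompoundDB",
    "load_compound_table",
    "MassDefectModel",
    "build_mass_defect_model",
    "is_biological_mass",
]


@dataclass(frozen=True)
class Compound:
    compound_id: str
    name: str
    mass: float  # neutral monoisotopic, Da
    formula: Optional[Formula] = None
    pathway_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"{self.compound_id}: mass must be positive")


@dataclass(frozen=True)
class PathwayDef:
    pathway_id: str
    name: str
    member_ids: frozenset

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"pathway {self.pathway_id} has no members")


class CompoundDB:
    """Compounds and pathways with a sorted mass index and a formula index."""

    def __init__(self, compounds: Sequence[Compound],
                 pathway_names: Optional[Dict[str, str]] = None):
        self.compounds: Dict[str, Compound] = {}
        for c in compounds:
            if c.compound_id in self.compounds:
                raise ValueError(f"duplicate compound id {c.compound_id!r}")
            self.compounds[c.compound_id] = c

        members: Dict[str, Set[str]] = {}
        for c in compounds:
            for pid in c.pathway_ids:
                members.setdefault(pid, set()).add(c.compound_id)
        pathway_names = pathway_names or {}
        self.pathways: Dict[str, PathwayDef] = {
            pid: PathwayDef(pid, pathway_names.get(pid, pid), frozenset(ids))
            for pid, ids in sorted(members.items())
        }

        order = sorted(self.compounds.values(), key=lambda c: (c.mass, c.compound_id))
        self._mass_index: List[float] = [c.mass for c in order]
        self._mass_order: List[Compound] = order
        self._formula_index: Dict[str, List[Compound]] = {}
        for c in order:
            if c.formula is not None:
                self._formula_index.setdefault(str(c.formula), []).append(c)

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def masses(self) -> List[float]:
        return list(self._mass_index)

    def compounds_in_mass_window(self, lo: float, hi: float) -> List[Compound]:
        i = bisect.bisect_left(self._mass_index, lo)
        j = bisect.bisect_right(self._mass_index, hi)
        return self._mass_order[i:j]

    def compounds_by_formula(self, formula: Formula | str) -> List[Compound]:
        return list(self._formula_index.get(str(formula), []))


def load_compound_table(
    path: str | Path,
    isotopes: ElementIsotopeTable = DEFAULT_ISOTOPES,
    pathway_names_path: str | Path | None = None,
) -> CompoundDB:
    """Load the compound TSV (id, name, formula, mass, pathways).

    ``formula`` may be blank (mass-only compound). When both formula and
    mass are given, the mass is recomputed from the formula; a mismatch
    beyond 1e-4 Da triggers a warning and the computed value wins.
    ``pathways`` is a semicolon-separated list. '#' lines are comments.
    """
    path = Path(path)
    compounds: List[Compound] = []
    seen = set()
    header: Optional[List[str]] = None
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                required = {"id", "name", "formula", "mass", "pathways"}
                missing = required - set(header)
                if missing:
                    raise ValueError(
                        f"{path}:{lineno}: missing columns {sorted(missing)}")
                continue
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            row = dict(zip(header, fields))
            cid = row["id"].strip()
            if not cid:
                raise ValueError(f"{path}:{lineno}: blank compound id")
            if cid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate compound id {cid!r}")
            seen.add(cid)
            formula_text = row["formula"].strip()
            formula = Formula.parse(formula_text) if formula_text else None
            mass_text = row["mass"].strip()
            try:
                stated = float(mass_text) if mass_text else None
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric mass {mass_text!r}") from None
            if formula is not None:
                computed = monoisotopic_mass(formula, isotopes)
                if stated is not None and abs(stated - computed) > 1e-4:
                    warnings.warn(
                        f"{path}:{lineno}: stated mass {stated} differs from "
                        f"computed {computed:.6f} for {cid}; keeping computed")
                mass = computed
            elif stated is not None:
                mass = stated
            else:
                raise ValueError(f"{path}:{lineno}: neither formula nor mass for {cid!r}")
            pathways = frozenset(
                p.strip() for p in row["pathways"].split(";") if p.strip())
            compounds.append(Compound(cid, row["name"].strip(), mass, formula, pathways))
    if header is None:
        raise ValueError(f"{path}: empty file")

    names: Dict[str, str] = {}
    if pathway_names_path is not None:
        with Path(pathway_names_path).open(encoding="utf-8") as fh:
            first = True
            for raw in fh:
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if first and parts[0].strip().lower() == "id":
                    first = False
                    continue
                first = False
                names[parts[0].strip()] = parts[1].strip() if len(parts) > 1 else parts[0]
    return CompoundDB(compounds, names)


# Reason codes for is_biological_mass
IN_REGION = "in-region"
OUT_OF_REGION = "empty-region"
OUT_OF_RANGE = "out-of-range"


@dataclass
class MassDefectModel:
    """Occupancy histogram of (integer mass, mass defect) over DB compounds.

    Masses are pooled into ``integer_pool``-Da slabs along the integer
    axis and ``frac_bin``-wide bins along the fractional axis. A query
    mass is plausible ("biological") when its bin falls in the allowed
    mask: occupied bins dilated by ``margin_bins`` along the fractional
    axis. The fractional axis wraps modulo 1 so the occupied band can
    straddle the 0/1 seam at high mass without special-casing.
    """

    mass_min: float
    mass_max: float
    integer_pool: float
    frac_bin: float
    margin_bins: int
    occupancy: np.ndarray  # (n_int_bins, n_frac_bins) counts
    allowed: np.ndarray = field(init=False)  # boolean mask, same shape

    def __post_init__(self) -> None:
        occ = self.occupancy > 0
        allowed = occ.copy()
        for k in range(1, self.margin_bins + 1):
            allowed |= np.roll(occ, k, axis=1) | np.roll(occ, -k, axis=1)
        self.allowed = allowed

    def _bin(self, mass: float) -> Tuple[int, int]:
        i = int((mass - self.mass_min) // self.integer_pool)
        frac = mass - np.floor(mass)
        j = int(frac // self.frac_bin) % self.occupancy.shape[1]
        return i, j

    def classify(self, mass: float) -> str:
        if not (self.mass_min <= mass <= self.mass_max):
            return OUT_OF_RANGE
        i, j = self._bin(mass)
        i = min(i, self.occupancy.shape[0] - 1)  # mass == mass_max edge
        return IN_REGION if self.allowed[i, j] else OUT_OF_REGION

    def is_biological(self, mass: float) -> bool:
        return self.classify(mass) == IN_REGION


def build_mass_defect_model(
    db: CompoundDB,
    integer_pool: float = 10.0,
    frac_bin: float = 0.01,
    margin_bins: int = 1,
    mass_range: Tuple[float, float] = (100.0, 1000.0),
) -> MassDefectModel:
    """Build the non-biological-signal filter from database masses."""
    if len(db) == 0:
        raise ValueError("cannot build a mass-defect model from an empty database")
    lo, hi = mass_range
    n_int = int(np.ceil((hi - lo) / integer_pool))
    n_frac = int(round(1.0 / frac_bin))
    occupancy = np.zeros((n_int, n_frac), dtype=np.int64)
    n_in = 0
    for mass in db.masses:
        if not (lo <= mass <= hi):
            continue
        n_in += 1
        i = min(int((mass - lo) // integer_pool), n_int - 1)
        j = int((mass - np.floor(mass)) // frac_bin) % n_frac
        occupancy[i, j] += 1
    if n_in == 0:
        raise ValueError("no database masses inside the model range")
    logger.debug("mass-defect model: %d masses in range, %d occupied bins",
                 n_in, int((occupancy > 0).sum()))
    return MassDefectModel(lo, hi, integer_pool, frac_bin, margin_bins, occupancy)


def is_biological_mass(model: MassDefectModel, mass: float) -> bool:
    """True iff the mass falls in the model's allowed (biological) region."""
    return model.is_biological(mass)
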