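"""Seed-metabolite annotation and dynamic metabolite-set build-up.

Primary-tier features (visible isotope pattern, >20 % change) are
searched against the compound database by monoisotopic mass and by their
top-3 predicted formulas; hits become *seed metabolites* and their
pathways the *implicated* set. Secondary features are then matched by
formula+mass and tertiary features by mass only, both restricted to the
implicated pathways, growing pathway-keyed metabolite sets for the
enrichment stage. Annotation confidence is summarized by the hit ratio
per peak (HRPP): total hits / peaks with at least one hit (lower is
better, >= 1 when defined).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .chem import Formula
from .compound_db import CompoundDB
from .preprocess import PRIMARY, SECONDARY, TERTIARY, FeatureRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationHit",
    "SeedMetabolite",
    "MetaboliteSet",
    "SearchReport",
    "search_by_mass",
    "find_seeds",
    "expand_sets",
    "hrpp",
    "annotate_features",
    "AnnotationResult",
]

FORMULA_MASS = "formula+mass"
MASS_ONLY = "mass-only"

SEED = "seed"
SECONDARY_EXPANSION = "secondary-expansion"
TERTIARY_EXPANSION = "tertiary-expansion"


@dataclass(frozen=True)
class AnnotationHit:
    feature_id: str
    compound_id: str
    mode: str  # formula+mass | mass-only
    ppm_error: float
    restricted_to: Optional[str] = None  # pathway id, None for the seed round


@dataclass
class SeedMetabolite:
    feature_id: str
    compound_ids: List[str]
    pathway_ids: Set[str]


@dataclass
class MetaboliteSet:
    pathway_id: str
    members: Dict[str, str] = field(default_factory=dict)  # feature id -> provenance
    hits: List[AnnotationHit] = field(default_factory=list)

    def add(self, hit: AnnotationHit, provenance: str) -> None:
        self.hits.append(hit)
        # seed provenance wins if a feature re-enters during expansion
        if hit.feature_id not in self.members or provenance == SEED:
            self.members[hit.feature_id] = provenance

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SearchReport:
    n_peaks: int
    n_peaks_with_hit: int
    n_hits: int

    @property
    def hrpp(self) -> Optional[float]:
        if self.n_peaks_with_hit == 0:
            return None
        return self.n_hits / self.n_peaks_with_hit


def search_by_mass(
    db: CompoundDB,
    neutral_mass: float,
    tol_ppm: float = 5.0,
    restrict_pathways: Optional[Set[str]] = None,
) -> List[Tuple[str, float]]:
    """(compound id, ppm error) for all DB compounds within the window,
    optionally restricted to members of the given pathways; sorted by
    |ppm error| then compound id."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    delta = neutral_mass * tol_ppm * 1e-6
    hits = []
    for comp in db.compounds_in_mass_window(neutral_mass - delta, neutral_mass + delta):
        if restrict_pathways is not None and not (comp.pathway_ids & restrict_pathways):
            continue
        ppm = (neutral_mass - comp.mass) / comp.mass * 1e6
        hits.append((comp.compound_id, ppm))
    hits.sort(key=lambda h: (abs(h[1]), h[0]))
    return hits


def _search_feature(
    db: CompoundDB,
    feature: FeatureRecord,
    tol_ppm: float,
    use_formulas: bool,
    restrict: Optional[Set[str]] = None,
) -> List[AnnotationHit]:
    """Mass search, upgraded to formula+mass where a top-3 formula matches."""
    mass_hits = search_by_mass(db, feature.neutral_mass, tol_ppm, restrict)
    formula_strings: Set[str] = set()
    if use_formulas and feature.candidates:
        formula_strings = {str(c.formula) for c in feature.candidates[:3]}
    hits = []
    for cid, ppm in mass_hits:
        comp = db.compounds[cid]
        mode = MASS_ONLY
        if comp.formula is not None and str(comp.formula) in formula_strings:
            mode = FORMULA_MASS
        hits.append(AnnotationHit(feature.peak_id, cid, mode, ppm,
                                  restricted_to=None))
    return hits


def find_seeds(
    primary_features: Sequence[FeatureRecord],
    db: CompoundDB,
    tol_ppm: float = 5.0,
) -> Tuple[List[SeedMetabolite], Set[str], List[AnnotationHit], List[FeatureRecord]]:
    """Search primary-tier features; hits seed the implicated pathways.

    Returns (seeds, implicated pathway ids, all hits, unannotated queue).
    Features with no database hit go to the unannotated queue for manual
    follow-up (they are highly perturbed but unexplained).
    """
    seeds: List[SeedMetabolite] = []
    implicated: Set[str] = set()
    all_hits: List[AnnotationHit] = []
    unannotated: List[FeatureRecord] = []
    for f in primary_features:
        if f.tier != PRIMARY:
            raise ValueError(f"{f.peak_id}: find_seeds expects primary-tier features")
        hits = _search_feature(db, f, tol_ppm, use_formulas=True)
        if not hits:
            unannotated.append(f)
            continue
        all_hits.extend(hits)
        pathways: Set[str] = set()
        for h in hits:
            pathways |= set(db.compounds[h.compound_id].pathway_ids)
        seeds.append(SeedMetabolite(f.peak_id, [h.compound_id for h in hits], pathways))
        implicated |= pathways
    return seeds, implicated, all_hits, unannotated


def expand_sets(
    seeds: Sequence[SeedMetabolite],
    seed_hits: Sequence[AnnotationHit],
    secondary_features: Sequence[FeatureRecord],
    tertiary_features: Sequence[FeatureRecord],
    db: CompoundDB,
    tol_ppm: float = 5.0,
    min_set_size: int = 2,
) -> Tuple[Dict[str, MetaboliteSet], List[AnnotationHit]]:
    """Grow pathway-keyed metabolite sets from the implicated pathways.

    Secondary features require a formula+mass match, tertiary features a
    mass-only match; both rounds are restricted to seed pathways. Sets
    smaller than ``min_set_size`` are dropped (a running-sum statistic on
    a singleton is uninformative). Returns the sets and the expansion
    hits (for HRPP bookkeeping).
    """
    implicated: Set[str] = set()
    for s in seeds:
        implicated |= s.pathway_ids

    sets: Dict[str, MetaboliteSet] = {}

    def set_for(pid: str) -> MetaboliteSet:
        if pid not in sets:
            sets[pid] = MetaboliteSet(pid)
        return sets[pid]

    for h in seed_hits:
        for pid in db.compounds[h.compound_id].pathway_ids:
            set_for(pid).add(h, SEED)

    expansion_hits: List[AnnotationHit] = []
    if implicated:
        for f in secondary_features:
            hits = _search_feature(db, f, tol_ppm, use_formulas=True,
                                   restrict=implicated)
            for h in hits:
                if h.mode != FORMULA_MASS:
                    continue  # secondary round needs the formula to agree
                expansion_hits.append(h)
                for pid in db.compounds[h.compound_id].pathway_ids & implicated:
                    set_for(pid).add(h, SECONDARY_EXPANSION)
        for f in tertiary_features:
            hits = _search_feature(db, f, tol_ppm, use_formulas=False,
                                   restrict=implicated)
            for h in hits:
                expansion_hits.append(h)
                for pid in db.compounds[h.compound_id].pathway_ids & implicated:
                    set_for(pid).add(h, TERTIARY_EXPANSION)

    kept = {pid: s for pid, s in sorted(sets.items()) if len(s) >= min_set_size}
    for s in kept.values():
        s.hits.sort(key=lambda h: (abs(h.ppm_error), h.compound_id))
    return kept, expansion_hits


def hrpp(per_peak_hit_counts: Iterable[int]) -> SearchReport:
    """Hit-ratio-per-peak summary from per-peak hit counts."""
    counts = list(per_peak_hit_counts)
    n_with = sum(1 for c in counts if c > 0)
    report = SearchReport(len(counts), n_with, sum(counts))
    if n_with == 0:
        logger.warning("HRPP undefined: no peaks with database hits")
    return report


@dataclass
class AnnotationResult:
    seeds: List[SeedMetabolite]
    implicated_pathways: Set[str]
    sets: Dict[str, MetaboliteSet]
    report: SearchReport
    unannotated: List[FeatureRecord]
    hits: List[AnnotationHit]


def annotate_features(
    features: Sequence[FeatureRecord],
    db: CompoundDB,
    tol_ppm: float = 5.0,
    min_set_size: int = 2,
) -> AnnotationResult:
    """Run the full seed -> expansion annotation round over a feature list."""
    primary = [f for f in features if f.tier == PRIMARY]
    secondary = [f for f in features if f.tier == SECONDARY]
    tertiary = [f for f in features if f.tier == TERTIARY]

    seeds, implicated, seed_hits, unannotated = find_seeds(primary, db, tol_ppm)
    sets, expansion_hits = expand_sets(
        seeds, seed_hits, secondary, tertiary, db, tol_ppm, min_set_size)

    all_hits = list(seed_hits) + expansion_hits
    searched_ids = [f.peak_id for f in primary + secondary + tertiary]
    per_peak: Dict[str, int] = {fid: 0 for fid in searched_ids}
    for h in all_hits:
        per_peak[h.feature_id] = per_peak.get(h.feature_id, 0) + 1
    report = hrpp(per_peak[fid] for fid in searched_ids)
    return AnnotationResult(seeds, implicated, sets, report, unannotated, all_hits)
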