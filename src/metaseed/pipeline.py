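"""End-to-end orchestration: preprocess -> formulas -> annotate -> enrich.

A single PipelineConfig (YAML file or constructed in code) drives the
whole workflow; every run writes a manifest (config hash, seed, library
versions, stage timings) so results are reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .annotation import AnnotationResult, annotate_features
from .compound_db import CompoundDB, build_mass_defect_model, load_compound_table
from .enrichment import EnrichmentResult, msea, rank_features
from .formulas import ScoringParams, infer_formulas
from .peak_io import PeakTable, read_peak_table, write_feature_report
from .preprocess import (
    PRIMARY,
    RETAINED,
    SECONDARY,
    ToleranceConfig,
    accounting_summary,
    preprocess_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    peak_table: str
    design: str
    compound_db: str
    out_dir: str
    seed: int = 0
    timepoint: Optional[float] = None
    ranking_metric: str = "signed_percent_change"
    n_perm: int = 10000
    alpha: float = 0.05
    tolerances: ToleranceConfig = field(default_factory=ToleranceConfig)
    scoring: ScoringParams = field(default_factory=ScoringParams)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    tol_raw = raw.pop("tolerances", {})
    if "rt_window" in tol_raw:
        tol_raw["rt_window"] = tuple(tol_raw["rt_window"])
    scoring = ScoringParams(**raw.pop("scoring", {}))
    return PipelineConfig(tolerances=ToleranceConfig(**tol_raw),
                          scoring=scoring, **raw)


@dataclass
class PipelineResult:
    features: list
    accounting: object
    annotation: AnnotationResult
    enrichment: List[EnrichmentResult]
    outputs: Dict[str, str]


def _write_sets(result: AnnotationResult, db: CompoundDB, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("pathway\tfeature\tprovenance\tcompound\tppm_error\n")
        for pid in sorted(result.sets):
            s = result.sets[pid]
            for h in s.hits:
                if pid not in db.compounds[h.compound_id].pathway_ids:
                    continue
                fh.write(f"{pid}\t{h.feature_id}\t{s.members[h.feature_id]}\t"
                         f"{h.compound_id}\t{h.ppm_error:.3f}\n")


def _write_search_report(result: AnnotationResult, path: Path) -> None:
    r = result.report
    hrpp = "NA" if r.hrpp is None else f"{r.hrpp:.4f}"
    with path.open("w", encoding="utf-8") as fh:
        fh.write("n_peaks\tn_peaks_with_hit\tn_hits\thrpp\n")
        fh.write(f"{r.n_peaks}\t{r.n_peaks_with_hit}\t{r.n_hits}\t{hrpp}\n")


def _write_enrichment(results: List[EnrichmentResult], path: Path) -> None:
    rows = [{
        "pathway": r.pathway_id, "es": round(r.es, 6), "p_value": r.p_value,
        "q_value": round(r.q_value, 8), "n_members": r.n_members,
        "direction": r.direction, "active": r.active,
    } for r in results]
    pd.DataFrame(rows, columns=["pathway", "es", "p_value", "q_value",
                                "n_members", "direction", "active"]
                 ).to_csv(path, sep="\t", index=False)


def _write_unannotated(result: AnnotationResult, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write("feature\tneutral_mass\trt\tpercent_change\tp_value\n")
        for f in result.unannotated:
            pct = "NA" if f.percent_change is None else f"{f.percent_change:.2f}"
            p = "NA" if f.p_value is None else f"{f.p_value:.3g}"
            fh.write(f"{f.peak_id}\t{f.neutral_mass:.6f}\t{f.rt:.2f}\t{pct}\t{p}\n")


def run_pipeline(config: PipelineConfig,
                 table: Optional[PeakTable] = None,
                 db: Optional[CompoundDB] = None) -> PipelineResult:
    """Execute the full workflow and write the artifact bundle.

    Outputs in ``out_dir``: features.tsv (per-peak report + accounting
    footer), sets.tsv, search_report.tsv (HRPP), enrichment.tsv,
    unannotated.tsv, manifest.json. On stage failure the partial outputs
    are kept and the manifest records the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {
            "metaseed": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    stage = "load"
    try:
        if table is None:
            table = read_peak_table(config.peak_table, config.design)
        if db is None:
            db = load_compound_table(config.compound_db)
        model = build_mass_defect_model(db)

        stage = "preprocess"
        t0 = time.monotonic()
        features, _acct = preprocess_table(
            table, model, config.tolerances, timepoint=config.timepoint)
        manifest["stages"]["preprocess"] = round(time.monotonic() - t0, 3)

        stage = "formulas"
        t0 = time.monotonic()
        for f in features:
            if f.status == RETAINED and f.tier in (PRIMARY, SECONDARY):
                f.candidates = infer_formulas(
                    f.neutral_mass, f.pattern,
                    tol_ppm=config.tolerances.ppm_search,
                    params=config.scoring)
        accounting = accounting_summary(features)
        manifest["stages"]["formulas"] = round(time.monotonic() - t0, 3)

        stage = "annotate"
        t0 = time.monotonic()
        ann = annotate_features(features, db,
                                tol_ppm=config.tolerances.ppm_search)
        manifest["stages"]["annotate"] = round(time.monotonic() - t0, 3)

        stage = "enrich"
        t0 = time.monotonic()
        ranked = rank_features(features, config.ranking_metric)
        enr = msea(ranked, ann.sets, n_perm=config.n_perm, seed=config.seed,
                   alpha=config.alpha)
        manifest["stages"]["enrich"] = round(time.monotonic() - t0, 3)

        stage = "write"
        outputs = {
            "features": str(out / "features.tsv"),
            "sets": str(out / "sets.tsv"),
            "search_report": str(out / "search_report.tsv"),
            "enrichment": str(out / "enrichment.tsv"),
            "unannotated": str(out / "unannotated.tsv"),
            "manifest": str(out / "manifest.json"),
        }
        write_feature_report(features, accounting, outputs["features"])
        _write_sets(ann, db, Path(outputs["sets"]))
        _write_search_report(ann, Path(outputs["search_report"]))
        _write_enrichment(enr, Path(outputs["enrichment"]))
        _write_unannotated(ann, Path(outputs["unannotated"]))
        manifest["status"] = "ok"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return PipelineResult(features, accounting, ann, enr, outputs)
    except Exception:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
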