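"""Peak-table and sample-design I/O.

The pipeline's canonical ingress is a detected-peak table (any upstream
peak picker), CSV or TSV, with columns ``id`` (optional), ``mz``, ``rt``
(seconds) and one intensity column per sample. A separate design table
maps those columns to (condition, timepoint, replicate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleInfo",
    "SampleDesign",
    "Peak",
    "PeakTable",
    "read_sample_design",
    "read_peak_table",
    "write_peak_table",
    "write_feature_report",
]

CONDITIONS = ("control", "treatment")


@dataclass(frozen=True)
class SampleInfo:
    condition: str  # control | treatment
    timepoint: float  # minutes
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")


@dataclass
class SampleDesign:
    """Maps each intensity column to its experimental condition."""

    samples: Dict[str, SampleInfo]

    def __post_init__(self) -> None:
        for tp in self.timepoints():
            conds = {s.condition for s in self.samples.values() if s.timepoint == tp}
            if conds != set(CONDITIONS):
                raise ValueError(
                    f"timepoint {tp}: need at least one control and one treatment sample")

    def timepoints(self) -> List[float]:
        return sorted({s.timepoint for s in self.samples.values()})

    def sample_ids(self, condition: Optional[str] = None,
                   timepoint: Optional[float] = None) -> List[str]:
        out = []
        for sid, info in self.samples.items():
            if condition is not None and info.condition != condition:
                continue
            if timepoint is not None and info.timepoint != timepoint:
                continue
            out.append(sid)
        return out


@dataclass
class Peak:
    """One detected LC-MS feature (negative mode, singly charged)."""

    peak_id: str
    mz: float
    rt: float  # seconds
    intensities: Dict[str, float]

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"{self.peak_id}: mz must be positive")
        if self.rt < 0:
            raise ValueError(f"{self.peak_id}: rt must be non-negative")
        for sid, v in self.intensities.items():
            if v < 0 or math.isnan(v):
                raise ValueError(f"{self.peak_id}: bad intensity {v} for {sid}")

    def mean_intensity(self, sample_ids: Optional[Sequence[str]] = None) -> float:
        ids = sample_ids if sample_ids is not None else list(self.intensities)
        if not ids:
            return 0.0
        return sum(self.intensities[s] for s in ids) / len(ids)


@dataclass
class PeakTable:
    peaks: List[Peak]
    design: SampleDesign
    source: Optional[str] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for p in self.peaks:
            if p.peak_id in seen:
                raise ValueError(f"duplicate peak id {p.peak_id!r}")
            seen.add(p.peak_id)
            missing = set(p.intensities) - set(self.design.samples)
            if missing:
                raise ValueError(
                    f"{p.peak_id}: intensity columns {sorted(missing)} not in design")
        by_mz = sorted(self.peaks, key=lambda p: (p.mz, p.rt))
        for i, p in enumerate(by_mz):
            for q in by_mz[i + 1:]:
                if q.mz - p.mz > 1e-6:
                    break
                if abs(q.rt - p.rt) <= 1e-3:
                    raise ValueError(
                        f"duplicate peaks {p.peak_id}/{q.peak_id}: "
                        f"same (mz, rt) within 1e-6 Th / 1e-3 s")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def read_sample_design(path: str | Path) -> SampleDesign:
    """Read the design TSV (sample, condition, timepoint, replicate)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"sample", "condition", "timepoint", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design file missing columns {sorted(missing)}")
    samples: Dict[str, SampleInfo] = {}
    for _, row in df.iterrows():
        sid = str(row["sample"]).strip()
        if sid in samples:
            raise ValueError(f"{path}: duplicate sample id {sid!r}")
        samples[sid] = SampleInfo(
            condition=str(row["condition"]).strip().lower(),
            timepoint=float(row["timepoint"]),
            replicate=int(row["replicate"]),
        )
    return SampleDesign(samples)


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep, comment="#")


def read_peak_table(path: str | Path, design_path: str | Path) -> PeakTable:
    """Read a peak CSV/TSV plus its sample design.

    Row order is preserved; ids are auto-generated as F000001... when the
    ``id`` column is absent. Missing intensity cells become 0 with a
    warning (absent means not detected in that sample).
    """
    path = Path(path)
    design = read_sample_design(design_path)
    df = _read_table(path)
    df.columns = [str(c).strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    for col in ("mz", "rt"):
        if col not in lower:
            raise ValueError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns
                   if c.lower() not in ("id", "mz", "rt")]
    unmapped = [c for c in sample_cols if c not in design.samples]
    if unmapped:
        raise ValueError(
            f"{path}: intensity columns {unmapped} are not in the design file")

    n_missing = int(df[sample_cols].isna().sum().sum()) if sample_cols else 0
    if n_missing:
        logger.warning("%s: %d missing intensity cells treated as 0", path, n_missing)

    peaks: List[Peak] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        pid = str(rowd[lower["id"]]) if "id" in lower else f"F{i:06d}"
        try:
            mz = float(rowd[lower["mz"]])
            rt = float(rowd[lower["rt"]])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: row {i}: non-numeric mz/rt") from None
        if math.isnan(mz) or math.isnan(rt):
            raise ValueError(f"{path}: row {i}: non-numeric mz/rt")
        intens = {}
        for c in sample_cols:
            v = rowd[c]
            v = 0.0 if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
            intens[c] = v
        peaks.append(Peak(pid, mz, rt, intens))
    return PeakTable(peaks, design, source=str(path))


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    """Write the peak table back out (format chosen by extension)."""
    path = Path(path)
    sample_cols = list(table.design.samples)
    rows = []
    for p in table.peaks:
        row = {"id": p.peak_id, "mz": p.mz, "rt": p.rt}
        for s in sample_cols:
            row[s] = p.intensities.get(s, 0.0)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["id", "mz", "rt"] + sample_cols)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def write_feature_report(features: Iterable, accounting, path: str | Path) -> None:
    """Write the per-feature TSV report with the accounting footer.

    One row per input peak: status, tier, neutral mass, percent change,
    signed fold change, p-value, top formulas (pipe-separated). The footer
    block ('#' lines) restates the category counts in the fixed filter
    order so total = retained + eliminated always holds.
    """
    path = Path(path)
    cols = ["peak_id", "status", "artifact_label", "tier", "mz", "rt",
            "neutral_mass", "percent_change", "fold_change", "p_value",
            "formulas", "isotope_pattern"]
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for f in features:
            formulas = "|".join(str(c.formula) for c in (f.candidates or [])[:3])
            pattern = ";".join(
                f"{lab}:{ri:.4f}" for lab, ri in (f.pattern.entries if f.pattern else [])
            )
            vals = [
                f.peak_id, f.status, f.artifact_label or "", f.tier,
                f"{f.mz:.6f}", f"{f.rt:.2f}", f"{f.neutral_mass:.6f}",
                _fmt(f.percent_change), _fmt(f.fold_change), _fmt(f.p_value),
                formulas, pattern,
            ]
            fh.write("\t".join(vals) + "\n")
        for label, value in accounting.footer_rows():
            fh.write(f"# {label}\t{value}\n")


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return "NA"
    if math.isinf(x):
        return "+Inf" if x > 0 else "-Inf"
    return f"{x:.6g}"
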