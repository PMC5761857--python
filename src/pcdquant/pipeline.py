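"""Pipeline orchestration: simulate -> quantify -> analyze -> report.

``PipelineConfig`` gathers every tunable of the quantification and analysis
stages with defaults equal to the published values where one exists
(global threshold 0.55, adaptive window 15 px, density-map window/stride
16/8 px, ROI circles 1.95/3.45 mm, resize factor 6). A SHA-256 hash of the
config is recorded in every output, so identical hash + identical inputs
implies identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .errors import PCDQuantError, SchemaError
from .geometry import SECTORS
from .io import load_angiogram
from .metrics import PCDQuantifier, density_map, render_density_map
from .segmentation import CapillarySegmenter
from .simulate import COHORT_COLUMNS
from . import stats as cstats

log = logging.getLogger("pcdquant")

_PCD_OUTCOMES = ("pcd_whole_pct", "pcd_annulus_pct", "pcd_sup_pct",
                 "pcd_nas_pct", "pcd_inf_pct", "pcd_temp_pct")
_POOLS = {"poag_control": ("poag", "control"), "naion_fellow": ("naion", "fellow")}


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with published defaults."""

    width_mm: float = 4.5
    resize_factor: int = 6
    stretch_low_pct: float = 1.0
    stretch_high_pct: float = 99.0
    global_threshold: float = 0.55
    adaptive_window_px: int = 15
    vessel_caliber_cutoff_um: float = 40.0
    vessel_dilation_px: int = 2
    vessel_min_extent_mm: float = 1.0
    inner_mm: float = 1.95
    outer_mm: float = 3.45
    exclude_vessels_from_denominator: bool = True
    density_window_px: int = 16
    density_stride_px: int = 8
    bonferroni_family: int | None = None   # None = number of group pairs
    flip_nasal_temporal: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _segmenter(config: PipelineConfig) -> CapillarySegmenter:
    return CapillarySegmenter(
        resize_factor=config.resize_factor,
        global_threshold=config.global_threshold,
        adaptive_window_px=config.adaptive_window_px,
        vessel_caliber_cutoff_um=config.vessel_caliber_cutoff_um,
        vessel_dilation_px=config.vessel_dilation_px,
        vessel_min_extent_mm=config.vessel_min_extent_mm,
        stretch_low_pct=config.stretch_low_pct,
        stretch_high_pct=config.stretch_high_pct,
    )


def run_quantify(image_dir: str | Path, config: PipelineConfig,
                 out_dir: str | Path) -> pd.DataFrame:
    """Quantify every angiogram in a directory; write per-eye CSV + maps.

    Inputs are TIFF/PNG rasters with JSON metadata sidecars (files named
    ``*_mask.png`` are ignored). Per-image failures are logged and skipped;
    if every image fails (or none are found) the run errors out.
    """
    image_dir, out_dir = Path(image_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(p for p in image_dir.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff", ".png")
                   and not p.stem.endswith("_mask"))
    if not paths:
        raise PCDQuantError(f"no inputs: no TIFF/PNG images found in {image_dir}")
    segmenter = _segmenter(config)
    quantifier = PCDQuantifier(inner_mm=config.inner_mm, outer_mm=config.outer_mm,
                               exclude_vessels_from_denominator=config.exclude_vessels_from_denominator)
    rows, failures = [], []
    for p in paths:
        try:
            img = load_angiogram(p, width_mm=config.width_mm)
            if config.flip_nasal_temporal:
                img.laterality = "OS" if img.laterality == "OD" else "OD"
            seg = segmenter.fit(None).transform(img)
            row = quantifier.transform([seg]).iloc[0].to_dict()
            row["source"] = p.name
            rows.append(row)
            dm = density_map(seg, config.density_window_px, config.density_stride_px)
            render_density_map(dm, out_dir / f"{p.stem}_density.png")
        except Exception as exc:
            failures.append(p.name)
            log.warning("skipping %s: %s", p.name, exc)
    if not rows:
        raise PCDQuantError(f"all {len(paths)} images failed quantification: {failures}")
    results = pd.DataFrame(rows)
    results.insert(0, "config_hash", config.config_hash())
    results.to_csv(out_dir / "pcd_results.csv", index=False)
    (out_dir / "run_log.json").write_text(json.dumps({
        "config": config.to_dict(), "config_hash": config.config_hash(),
        "n_images": len(paths), "n_quantified": len(rows), "failed": failures,
    }, indent=1))
    return results


def validate_cohort_schema(table: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` listing any missing required columns."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table is missing required columns: {missing}")


def run_analyze(cohort: str | Path | pd.DataFrame, config: PipelineConfig,
                out_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Run the full statistics stage on a cohort table.

    Emits (as CSV plus a text report): adjusted pairwise group comparisons
    per PCD/RNFL outcome, within-group sector contrasts, univariate
    PCD-RNFL and PCD-MD regressions per analysis pool, and
    dependent-correlation differences between sector pairs per pool. With a
    single group the group comparison is skipped with a notice; the
    regressions still run.
    """
    if isinstance(cohort, (str, Path)):
        cohort = pd.read_csv(cohort)
    validate_cohort_schema(cohort)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = sorted(cohort["group"].dropna().unique())
    tables: dict[str, pd.DataFrame] = {}
    notes: list[str] = []

    if len(groups) >= 2:
        frames = []
        for outcome in (*_PCD_OUTCOMES, "rnfl_global_um"):
            gc = cstats.compare_groups(cohort, outcome,
                                       bonferroni_family=config.bonferroni_family)
            t = gc.contrasts.copy()
            t.insert(0, "outcome", outcome)
            t["model"] = gc.model
            frames.append(t)
        tables["group_comparisons"] = pd.concat(frames, ignore_index=True)
    else:
        notes.append(f"group comparison skipped: only one group present ({groups})")

    frames = []
    for g in groups:
        t = cstats.sector_contrasts(cohort, g)
        t.insert(0, "group", g)
        frames.append(t)
    tables["sector_contrasts"] = pd.concat(frames, ignore_index=True)

    pools = {name: cohort[cohort["group"].isin(members)]
             for name, members in _POOLS.items()
             if all(m in groups for m in members)}
    if not pools:
        pools = {"all": cohort}
    reg_rows, diff_rows = [], []
    for pool_name, sub in pools.items():
        for sector in SECTORS:
            short = {"superior": "sup", "nasal": "nas", "inferior": "inf", "temporal": "temp"}[sector]
            fit = cstats.univariate_fit(sub, f"pcd_{short}_pct", f"rnfl_{short}_um")
            reg_rows.append({"pool": pool_name, "y": f"pcd_{short}_pct", "x": f"rnfl_{short}_um",
                             "slope": fit.slope, "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                             "r": fit.r, "r2": fit.r2, "p": fit.p, "n": fit.n})
        fit = cstats.univariate_fit(sub, "pcd_whole_pct", "md_db")
        reg_rows.append({"pool": pool_name, "y": "pcd_whole_pct", "x": "md_db",
                         "slope": fit.slope, "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                         "r": fit.r, "r2": fit.r2, "p": fit.p, "n": fit.n})
        for a, b in itertools.combinations(SECTORS, 2):
            cc = cstats.sector_correlation_difference(sub, a, b)
            diff_rows.append({"pool": pool_name, "sector_a": a, "sector_b": b,
                              "r_a": cc.r1, "r_b": cc.r2, "difference": cc.difference,
                              "z": cc.z, "p": cc.p, "n": cc.n})
    tables["regressions"] = pd.DataFrame(reg_rows)
    tables["correlation_differences"] = pd.DataFrame(diff_rows)

    chash = config.config_hash()
    for name, t in tables.items():
        t = t.copy()
        t.insert(0, "config_hash", chash)
        t.to_csv(out_dir / f"{name}.csv", index=False)
        tables[name] = t
    report = [f"pcdquant analysis report (config {chash})",
              f"groups: {groups}; eyes: {len(cohort)}; subjects: {cohort['subject_id'].nunique()}",
              *notes, ""]
    for name, t in tables.items():
        report.append(f"== {name} ==")
        report.append(t.round(4).to_string(index=False))
        report.append("")
    (out_dir / "report.txt").write_text("\n".join(report))
    return tables
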