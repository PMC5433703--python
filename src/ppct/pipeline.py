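"""End-to-end study orchestration.

`run_study` executes the whole design on synthetic or loaded data:
eligibility screening, a seeded split of the controls into teaching and
validating halves, zone delineation on the teaching mean map (zones are
frozen there and never see validating or case grids), regional partitions,
the case-control comparison table, the zone-wise percent-difference block,
and severity correlations.  Results are returned as a `StudyReport` and
written as delimited tables plus a JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .geometry import GridGeometry, Laterality, build_geometry, select_onh_mask
from .grids import ThicknessGrid, read_grid, write_grid
from .regional import (
    group_regional_summary,
    quadrant_partition,
    sector_partition,
    total_partition,
)
from .simulate import CohortSpec, PatternParams, simulate_study
from .stats import (
    SubjectRecord,
    apply_eligibility,
    compare_groups,
    percent_difference,
    severity_correlations,
)
from .zones import (
    ZONE_LABELS,
    ZoneBinSpec,
    ZoneMap,
    cube_bin_counts,
    delineate_zones,
    group_zone_summary,
    mean_thickness_map,
)

log = logging.getLogger("ppct")

__all__ = [
    "RunConfig",
    "StudyReport",
    "split_controls",
    "run_study",
    "records_to_frame",
    "frame_to_records",
    "write_zone_map",
]


@dataclass
class RunConfig:
    """Configuration of a full study run; serialisable to/from YAML."""

    geometry: GridGeometry = field(default_factory=GridGeometry)
    bins: ZoneBinSpec = field(default_factory=ZoneBinSpec)
    params: PatternParams = field(default_factory=PatternParams)
    n_per_group: int = 40
    seed: int = 0
    split_seed: Optional[int] = None  # defaults to seed
    alpha: float = 0.05
    bonferroni_m: int = 10
    pooled_t: bool = True
    laterality: Laterality = "OD"
    outdir: Optional[str] = None
    input_dir: Optional[str] = None   # load grids+manifest instead of simulating

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "geometry" in kwargs:
            kwargs["geometry"] = GridGeometry(**kwargs["geometry"])
        if "bins" in kwargs:
            b = kwargs["bins"]
            kwargs["bins"] = ZoneBinSpec(tuple(b.get("edges", (105, 140, 175))),
                                         b.get("reporting_floor", 70.0))
        if "params" in kwargs:
            kwargs["params"] = PatternParams(**kwargs["params"])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["bins"] = {"edges": list(self.bins.edges),
                       "reporting_floor": self.bins.reporting_floor}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class StudyReport:
    """All study outputs plus provenance."""

    teaching_zone_summary: Dict[int, Tuple[float, float, int]]
    teaching_zone_counts: Dict[int, int]
    teaching_bin_counts: Tuple[int, int, int, int, int]
    zonemap: ZoneMap
    comparison: pd.DataFrame
    percent_differences: pd.DataFrame
    correlations: pd.DataFrame
    split_balance: pd.DataFrame
    excluded: List[Tuple[str, List[str]]]
    seed: int
    config: RunConfig


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Cohort manifest as a DataFrame, one SubjectRecord per row."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def frame_to_records(frame: pd.DataFrame) -> List[SubjectRecord]:
    records = []
    for row in frame.to_dict(orient="records"):
        for k in ("updrs", "hoehn_yahr", "duration"):
            if k in row and pd.isna(row[k]):
                row[k] = None
        records.append(SubjectRecord(**row))
    return records


def split_controls(
    records: Sequence[SubjectRecord],
    grids: Sequence[ThicknessGrid],
    seed: int,
) -> Tuple[Tuple[List[ThicknessGrid], List[SubjectRecord]],
           Tuple[List[ThicknessGrid], List[SubjectRecord]],
           pd.DataFrame]:
    """Randomly split controls into disjoint teaching/validating halves.

    Reproducible from ``seed``; odd cohorts put the extra subject in the
    teaching half.  Also returns an age/sex balance report for the halves.
    """
    if len(records) != len(grids):
        raise ValueError("records and grids must align")
    n = len(records)
    if n < 4:
        raise ValueError("need at least 4 controls to split")
    order = np.random.default_rng(seed).permutation(n)
    half = (n + 1) // 2
    idx_teach, idx_val = order[:half], order[half:]

    def take(idx, role):
        recs = [dataclasses.replace(records[i], cohort_role=role) for i in idx]
        return [grids[i] for i in idx], recs

    teaching, validating = take(idx_teach, "teaching"), take(idx_val, "validating")
    balance = pd.DataFrame(
        [
            {
                "half": name,
                "n": len(recs),
                "age_mean": float(np.mean([r.age for r in recs])),
                "age_sd": float(np.std([r.age for r in recs], ddof=1)),
                "n_male": sum(r.sex == "M" for r in recs),
                "n_female": sum(r.sex == "F" for r in recs),
            }
            for name, (_, recs) in (("teaching", teaching), ("validating", validating))
        ]
    )
    return teaching, validating, balance


def _load_inputs(config: RunConfig) -> dict:
    """Load grids + manifest from ``config.input_dir`` (documented format)."""
    d = Path(config.input_dir)
    manifest = pd.read_csv(d / "manifest.csv")
    records = frame_to_records(manifest)
    grids = {p.stem: read_grid(p, config.geometry) for p in sorted(d.glob("*.tsv"))}
    out = {"control_grids": [], "control_records": [],
           "case_grids": [], "case_records": []}
    for r in records:
        g = grids[f"{r.id}_{config.laterality}"]
        side = "case" if r.group == "PD" else "control"
        out[f"{side}_grids"].append(g)
        out[f"{side}_records"].append(r)
    return out


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full pipeline; see module docstring for the stages."""
    geometry = config.geometry
    mask = select_onh_mask(geometry)

    if config.input_dir:
        log.info("loading cohorts from %s", config.input_dir)
        data = _load_inputs(config)
    else:
        log.info("simulating cohorts (seed=%d, n=%d/group)", config.seed,
                 config.n_per_group)
        data = simulate_study(config.seed, config.n_per_group, config.params,
                              geometry)

    # eligibility screening
    excluded: List[Tuple[str, List[str]]] = []
    for side in ("control", "case"):
        keep_g, keep_r = [], []
        for g, r in zip(data[f"{side}_grids"], data[f"{side}_records"]):
            res = apply_eligibility(r)
            if res.eligible:
                keep_g.append(g)
                keep_r.append(r)
            else:
                excluded.append((r.id, res.reasons))
        data[f"{side}_grids"], data[f"{side}_records"] = keep_g, keep_r
    log.info("eligibility: %d excluded", len(excluded))

    # teaching / validating split of the controls
    split_seed = config.seed if config.split_seed is None else config.split_seed
    (teach_g, teach_r), (val_g, val_r), balance = split_controls(
        data["control_records"], data["control_grids"], split_seed
    )
    log.info("split: %d teaching / %d validating controls", len(teach_g), len(val_g))

    # zones frozen on the teaching cohort only
    teach_map = mean_thickness_map(teach_g)
    zonemap = delineate_zones(teach_map, config.bins, mask)
    teaching_summary = group_zone_summary(teach_g, zonemap)
    teaching_bins = cube_bin_counts(teach_map, config.bins, mask)
    log.info("zones: cube counts %s", zonemap.zone_cube_counts)

    partitions = [
        total_partition(geometry, mask, config.laterality),
        quadrant_partition(geometry, mask, config.laterality),
        sector_partition(geometry, mask, config.laterality),
    ]
    comparison = compare_groups(
        data["case_grids"], data["case_records"], val_g, val_r,
        zonemap, partitions, geometry, mask, config.bins,
        alpha=config.alpha, bonferroni_m=config.bonferroni_m,
        pooled=config.pooled_t,
    )
    log.info("comparison: %d rows", len(comparison))

    zone_rows = comparison[comparison.block == "zone"].set_index("variable")
    pct = [
        {
            "variable": v,
            "case_mean": zone_rows.loc[v, "case_mean"],
            "control_mean": zone_rows.loc[v, "control_mean"],
            "percent_increase": percent_difference(
                zone_rows.loc[v, "case_mean"], zone_rows.loc[v, "control_mean"]
            ),
        }
        for v in [f"zone_{z}_thickness" for z in ZONE_LABELS] + ["total_thickness"]
    ]
    percent_differences = pd.DataFrame(pct)

    correlations = severity_correlations(
        data["case_grids"], data["case_records"], zonemap, mask
    )

    report = StudyReport(
        teaching_zone_summary=teaching_summary,
        teaching_zone_counts=zonemap.zone_cube_counts,
        teaching_bin_counts=teaching_bins,
        zonemap=zonemap,
        comparison=comparison,
        percent_differences=percent_differences,
        correlations=correlations,
        split_balance=balance,
        excluded=excluded,
        seed=config.seed,
        config=config,
    )
    if config.outdir:
        write_report(report, config.outdir)
    return report


def write_zone_map(zonemap: ZoneMap, path: str | Path) -> None:
    """Export the zone map in the grid layout (ONH cells carry label 1)."""
    np.savetxt(path, zonemap.assignment, fmt="%d", delimiter="\t")


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Write all report tables and a JSON summary under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)
    report.percent_differences.to_csv(
        out / "percent_differences.tsv", sep="\t", index=False
    )
    report.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    report.split_balance.to_csv(out / "split_balance.tsv", sep="\t", index=False)
    write_zone_map(report.zonemap, out / "zone_map.tsv")
    teaching = pd.DataFrame(
        [
            {"zone": z, "mean_um": m, "sd_um": s, "n": n,
             "cube_count": report.teaching_zone_counts[z]}
            for z, (m, s, n) in report.teaching_zone_summary.items()
        ]
    )
    teaching.to_csv(out / "teaching_zone_summary.tsv", sep="\t", index=False)
    summary = {
        "seed": report.seed,
        "teaching_zone_counts": report.teaching_zone_counts,
        "teaching_bin_counts": list(report.teaching_bin_counts),
        "n_excluded": len(report.excluded),
        "excluded": [{"id": i, "reasons": r} for i, r in report.excluded],
        "percent_differences": report.percent_differences.to_dict("records"),
        "n_comparison_rows": int(len(report.comparison)),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
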