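"""Eligibility screening and case-control statistics.

The comparison design: clinical covariates and per-subject zone/region
thickness means are compared between Parkinson's disease (PD) eyes and
healthy-control eyes with a pooled-variance Student t-test; categorical
variables (sex, cube-bin membership) use Pearson chi-square without
continuity correction; normality is screened with a one-sample
Kolmogorov-Smirnov test against a normal with estimated parameters; severity
correlations use Pearson's r.  Bonferroni correction is applied to the 10
regional comparisons (4 quadrants + 6 sectors) at alpha/10 = 0.005.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import GridGeometry, ONHMask
from .grids import ThicknessGrid
from .regional import (
    RegionPartition,
    group_regional_summary,
    regional_mean_thickness,
    regional_volume,
)
from .zones import (
    ZONE_LABELS,
    ZoneBinSpec,
    ZoneMap,
    cube_bin_counts,
    group_zone_summary,
    mean_thickness_map,
    subject_zone_means,
)

__all__ = [
    "SubjectRecord",
    "EligibilityResult",
    "apply_eligibility",
    "two_sample_t",
    "chi_square_counts",
    "ks_normality",
    "pearson_r",
    "bonferroni_alpha",
    "percent_difference",
    "compare_groups",
    "severity_correlations",
]

# exclusion thresholds from the study design
SNELLEN_VA_MIN = 0.1          # exclude if Snellen acuity strictly below
IOP_MAX_MMHG = 20.0           # exclude if strictly above
SPHERICAL_EQUIVALENT_MAX_D = 5.0
ASTIGMATISM_MAX_D = 3.0

REGIONAL_BONFERRONI_M = 10    # 4 quadrants + 6 sectors


@dataclass
class SubjectRecord:
    """Clinical covariates for one subject (one eye)."""

    id: str
    group: Literal["PD", "control"]
    cohort_role: Literal["teaching", "validating", "case"]
    age: float
    sex: Literal["M", "F"]
    spherical_equivalent: float     # diopters
    astigmatism: float              # diopters
    bcva: float                     # logMAR
    iop: float                      # mmHg
    disc_area: float                # mm^2
    updrs: Optional[float] = None   # PD only
    hoehn_yahr: Optional[float] = None
    duration: Optional[float] = None
    treatment_category: str = "none"

    def __post_init__(self) -> None:
        if self.group == "control":
            for fname in ("updrs", "hoehn_yahr", "duration"):
                if getattr(self, fname) is not None:
                    raise ValueError(f"{self.id}: control with severity field {fname}")
        if self.hoehn_yahr is not None and not (0 <= self.hoehn_yahr <= 5):
            raise ValueError(f"{self.id}: Hoehn-Yahr {self.hoehn_yahr} outside [0, 5]")
        if self.iop is not None and self.iop <= 0:
            raise ValueError(f"{self.id}: non-positive IOP")


@dataclass
class EligibilityResult:
    eligible: bool
    reasons: List[str] = field(default_factory=list)


def apply_eligibility(record: SubjectRecord) -> EligibilityResult:
    """Apply the ocular exclusion criteria to one subject.

    Excluded if Snellen visual acuity < 0.1 (i.e. BCVA worse than 1.0
    logMAR), IOP > 20 mmHg, |spherical equivalent| > 5 D, or astigmatism
    > 3 D.  Boundary values are all eligible.  Reasons accumulate.
    """
    for fname in ("bcva", "iop", "spherical_equivalent", "astigmatism"):
        if getattr(record, fname) is None:
            raise ValueError(f"{record.id}: missing required field {fname!r}")
    reasons = []
    snellen = 10.0 ** (-record.bcva)
    if snellen < SNELLEN_VA_MIN - 1e-12:
        reasons.append("visual acuity")
    if record.iop > IOP_MAX_MMHG:
        reasons.append("IOP")
    if abs(record.spherical_equivalent) > SPHERICAL_EQUIVALENT_MAX_D:
        reasons.append("refraction")
    if record.astigmatism > ASTIGMATISM_MAX_D:
        reasons.append("astigmatism")
    return EligibilityResult(not reasons, reasons)


def two_sample_t(
    x: Sequence[float], y: Sequence[float], pooled: bool = True
) -> Tuple[float, float, float]:
    """Two-sample t-test; pooled-variance Student's t by default.

    Returns ``(t, df, p)`` with a two-tailed p.  ``pooled=False`` gives the
    Welch unequal-variance variant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


def chi_square_counts(table: np.ndarray) -> Tuple[float, int, float]:
    """Pearson chi-square on a contingency table, no continuity correction.

    Returns ``(chi2, df, p)``.  Raises on a zero row or column marginal.
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


def ks_normality(x: Sequence[float]) -> Tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test against N(mean, sd) of the sample.

    Parameters are estimated from the data, so the returned p-value is
    approximate (anti-conservative); it is intended as a screening statistic
    only.  Raises on n < 5 or a degenerate (zero-variance) sample.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 5:
        raise ValueError("KS normality screening needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample (zero variance)")
    d, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return float(d), float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson product-moment correlation with two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a sample")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison significance level alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def percent_difference(case_mean: float, control_mean: float) -> float:
    """Percent difference of cases relative to controls: 100 (c - k) / k."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (case_mean - control_mean) / control_mean


# ---------------------------------------------------------------------------
# cohort-level comparison table


def _row(
    variable: str,
    block: str,
    a: Tuple[float, float, int],
    b: Tuple[float, float, int],
    test: str,
    stat: float,
    p: float,
    alpha: float,
    bonf_alpha: Optional[float],
) -> dict:
    sig_raw = bool(p < alpha)
    sig_bonf = bool(p < bonf_alpha) if bonf_alpha is not None else None
    return {
        "variable": variable,
        "block": block,
        "case_mean": a[0],
        "case_sd": a[1],
        "case_n": a[2],
        "control_mean": b[0],
        "control_sd": b[1],
        "control_n": b[2],
        "test": test,
        "statistic": stat,
        "p": p,
        "significant_raw": sig_raw,
        "significant_bonferroni": sig_bonf,
    }


def _mean_sd_n(x: Sequence[float]) -> Tuple[float, float, int]:
    arr = np.asarray(x, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"), len(arr)


_COVARIATE_FIELDS = ("age", "spherical_equivalent", "bcva", "iop", "disc_area")


def compare_groups(
    case_grids: Sequence[ThicknessGrid],
    case_records: Sequence[SubjectRecord],
    control_grids: Sequence[ThicknessGrid],
    control_records: Sequence[SubjectRecord],
    zonemap: ZoneMap,
    partitions: Sequence[RegionPartition],
    geometry: GridGeometry,
    mask: ONHMask,
    bins: ZoneBinSpec = ZoneBinSpec(),
    alpha: float = 0.05,
    bonferroni_m: int = REGIONAL_BONFERRONI_M,
    pooled: bool = True,
) -> pd.DataFrame:
    """Full case-control comparison table.

    One row per variable: clinical covariates (t-test, sex by chi-square),
    per-zone and total thickness, regional thicknesses and volumes for each
    partition (Bonferroni-corrected at ``alpha / bonferroni_m``), and
    cube-bin counts of the group mean maps (per-bin 2x2 chi-square plus an
    omnibus test over all bins).  The zone map must come from an independent
    teaching cohort; case and control ids must not overlap.
    """
    case_ids = {r.id for r in case_records}
    control_ids = {r.id for r in control_records}
    if case_ids & control_ids:
        raise ValueError(f"overlapping subject ids: {sorted(case_ids & control_ids)}")

    bonf = bonferroni_alpha(alpha, bonferroni_m)
    rows: List[dict] = []

    # clinical covariates
    for fname in _COVARIATE_FIELDS:
        xa = [getattr(r, fname) for r in case_records]
        xb = [getattr(r, fname) for r in control_records]
        t, _, p = two_sample_t(xa, xb, pooled=pooled)
        rows.append(
            _row(fname, "covariate", _mean_sd_n(xa), _mean_sd_n(xb),
                 "student_t", t, p, alpha, None)
        )
    sex_table = np.array(
        [
            [sum(r.sex == "M" for r in case_records), sum(r.sex == "F" for r in case_records)],
            [sum(r.sex == "M" for r in control_records), sum(r.sex == "F" for r in control_records)],
        ]
    )
    chi2, _, p = chi_square_counts(sex_table)
    rows.append(
        _row("sex", "covariate",
             (float(sex_table[0, 0]), float(sex_table[0, 1]), int(sex_table[0].sum())),
             (float(sex_table[1, 0]), float(sex_table[1, 1]), int(sex_table[1].sum())),
             "chi_square", chi2, p, alpha, None)
    )

    # zone thickness (per-subject zone means), plus the overall mean
    case_zone = {z: [] for z in ZONE_LABELS}
    control_zone = {z: [] for z in ZONE_LABELS}
    case_total, control_total = [], []
    ana = mask.analyzed
    for grids, zdict, tot in (
        (case_grids, case_zone, case_total),
        (control_grids, control_zone, control_total),
    ):
        for g in grids:
            zm = subject_zone_means(g, zonemap)
            for z in ZONE_LABELS:
                zdict[z].append(zm[z])
            tot.append(float(g.values[ana].mean()))
    for z in ZONE_LABELS:
        t, _, p = two_sample_t(case_zone[z], control_zone[z], pooled=pooled)
        rows.append(
            _row(f"zone_{z}_thickness", "zone",
                 _mean_sd_n(case_zone[z]), _mean_sd_n(control_zone[z]),
                 "student_t", t, p, alpha, None)
        )
    t, _, p = two_sample_t(case_total, control_total, pooled=pooled)
    rows.append(
        _row("total_thickness", "zone", _mean_sd_n(case_total),
             _mean_sd_n(control_total), "student_t", t, p, alpha, None)
    )

    # regional thickness and volume; Bonferroni over the 10 regional tests
    for part in partitions:
        for label in part.labels:
            xa = [regional_mean_thickness(g, part)[label] for g in case_grids]
            xb = [regional_mean_thickness(g, part)[label] for g in control_grids]
            t, _, p = two_sample_t(xa, xb, pooled=pooled)
            bonf_level = bonf if part.kind in ("quadrant", "sector") else None
            rows.append(
                _row(f"{part.kind}_{label}_thickness", f"regional_{part.kind}",
                     _mean_sd_n(xa), _mean_sd_n(xb), "student_t", t, p, alpha,
                     bonf_level)
            )
            va = [regional_volume(v, geometry, part.n_regions) for v in xa]
            vb = [regional_volume(v, geometry, part.n_regions) for v in xb]
            tv, _, pv = two_sample_t(va, vb, pooled=pooled)
            rows.append(
                _row(f"{part.kind}_{label}_volume", f"regional_{part.kind}",
                     _mean_sd_n(va), _mean_sd_n(vb), "student_t", tv, pv, alpha,
                     bonf_level)
            )

    # cube-bin counts on the group mean maps
    case_counts = cube_bin_counts(mean_thickness_map(case_grids), bins, mask)
    control_counts = cube_bin_counts(mean_thickness_map(control_grids), bins, mask)
    bin_names = ("below_floor", "floor_bin", "zone3_bin", "zone4_bin", "zone5_bin")
    total = int(np.sum(case_counts))
    for name, ca, co in zip(bin_names, case_counts, control_counts):
        if ca + co == 0:
            continue  # bin empty in both groups; no comparison possible
        tab = np.array([[ca, total - ca], [co, total - co]])
        chi2, _, p = chi_square_counts(tab)
        rows.append(
            _row(f"cube_count_{name}", "cube_bins",
                 (float(ca), float("nan"), total), (float(co), float("nan"), total),
                 "chi_square_2x2", chi2, p, alpha, None)
        )
    nz = [(ca, co) for ca, co in zip(case_counts, control_counts) if ca + co > 0]
    chi2, _, p = chi_square_counts(np.array(nz).T)
    rows.append(
        _row("cube_count_distribution", "cube_bins",
             (float("nan"), float("nan"), total), (float("nan"), float("nan"), total),
             "chi_square_omnibus", chi2, p, alpha, None)
    )

    return pd.DataFrame(rows)


def severity_correlations(
    case_grids: Sequence[ThicknessGrid],
    case_records: Sequence[SubjectRecord],
    zonemap: ZoneMap,
    mask: ONHMask,
) -> pd.DataFrame:
    """Pearson correlation of zone/total thickness with UPDRS and Hoehn-Yahr.

    Uses only case subjects carrying the severity score.  Returns one row
    per (scale, zone) with r and its two-tailed p.
    """
    ana = mask.analyzed
    rows = []
    for scale in ("updrs", "hoehn_yahr"):
        scores, zmeans, totals = [], [], []
        for g, r in zip(case_grids, case_records):
            s = getattr(r, scale)
            if s is None:
                continue
            scores.append(s)
            zmeans.append(subject_zone_means(g, zonemap))
            totals.append(float(g.values[ana].mean()))
        for z in ZONE_LABELS:
            r_, p = pearson_r([zm[z] for zm in zmeans], scores)
            rows.append({"scale": scale, "variable": f"zone_{z}_thickness",
                         "r": r_, "p": p, "n": len(scores)})
        r_, p = pearson_r(totals, scores)
        rows.append({"scale": scale, "variable": "total_thickness",
                     "r": r_, "p": p, "n": len(scores)})
    return pd.DataFrame(rows)
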