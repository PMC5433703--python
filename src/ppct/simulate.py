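"""Synthetic cohorts of peripapillary choroidal thickness grids.

The generator emulates the topography the normative maps show: the choroid
thinnest just outside the optic nerve head and inferiorly, thickening with
distance from the nerve head and toward the superotemporal side.  Each
analysed cube of subject *i* gets

    t = base + slope * (r - r_rim) + amp * cos(angle - peak)
        + b_i + offset * [PD] + coupling * (UPDRS_i - 25.1) * [PD] + e,

with r the cube-centre radius (mm), r_rim the smallest analysed radius,
b_i ~ N(0, subject_sd) a shared subject level, e ~ N(0, cube_sd) independent
cube noise, and the result clipped at a physiological floor.  The default
pattern parameters are calibrated so a 40-subject normative cohort
reproduces the published teaching-cohort zone cube counts (about
120/248/181/31) and zone means (about 95/122/157/187 um), and the constant
PD offset makes zone-wise percent increases fall with distance from the
nerve head (about 33% in zone 2 down to 16% in zone 5).

A cohort is drawn from a single seeded stream, subject by subject, with a
fixed per-subject draw order (covariates, severity scores for PD, subject
level, full-grid cube noise) so that appending subjects never perturbs
earlier subjects' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import truncnorm

from .geometry import (
    DEFAULT_GEOMETRY,
    GridGeometry,
    Laterality,
    ONHMask,
    polar_grid,
    select_onh_mask,
)
from .grids import ThicknessGrid
from .stats import SubjectRecord

__all__ = [
    "PatternParams",
    "CohortSpec",
    "pattern_surface",
    "simulate_subject",
    "simulate_cohort",
    "simulate_study",
]


@dataclass(frozen=True)
class PatternParams:
    """Parameters of the synthetic thickness surface (all in um unless noted).

    ``base`` is the thickness at the ONH rim on the pattern's neutral axis;
    ``radial_slope`` (um/mm) the thickening rate with distance from the rim;
    ``angular_amplitude`` and ``peak_angle`` (deg, anatomical) shape the
    superotemporal bulge; ``subject_sd`` the between-subject level spread;
    ``cube_sd`` the within-subject cube noise; ``group_offset`` the additive
    PD thickening; ``severity_coupling`` (um per UPDRS point) an optional
    severity effect, 0 by default; ``floor`` the clipping minimum.
    """

    base: float = 85.0
    radial_slope: float = 42.0
    angular_amplitude: float = 18.0
    peak_angle: float = 120.0
    subject_sd: float = 12.0
    cube_sd: float = 8.0
    group_offset: float = 30.0
    severity_coupling: float = 0.0
    floor: float = 40.0

    def __post_init__(self) -> None:
        if min(self.base, self.subject_sd, self.cube_sd, self.floor) < 0:
            raise ValueError("base, SDs and floor must be non-negative")
        if not 0 <= self.peak_angle < 360:
            raise ValueError("peak_angle must be in [0, 360)")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, seed and covariate distributions.

    Covariate defaults follow the study demographics: age 69 +/- 7 years,
    sex 26:14 men:women per 40 subjects, and for PD subjects UPDRS
    ~ N(25.1, 5.4) truncated positive, Hoehn-Yahr ~ N(2.7, 0.8) truncated to
    [0, 5], disease duration ~ N(6.7, 2.3) years truncated positive.
    """

    n_per_group: int = 40
    seed: int = 0
    age_mean: float = 69.0
    age_sd: float = 7.0
    male_fraction: float = 26 / 40
    updrs_mean: float = 25.1
    updrs_sd: float = 5.4
    hoehn_yahr_mean: float = 2.7
    hoehn_yahr_sd: float = 0.8
    duration_mean: float = 6.7
    duration_sd: float = 2.3

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


def pattern_surface(
    params: PatternParams = PatternParams(),
    geometry: GridGeometry = DEFAULT_GEOMETRY,
    laterality: Laterality = "OD",
    mask: Optional[ONHMask] = None,
) -> np.ndarray:
    """Noiseless control-subject thickness surface; NaN at ONH cells."""
    if mask is None:
        mask = select_onh_mask(geometry)
    radius, angle = polar_grid(geometry, laterality)
    rim = radius[mask.analyzed].min()
    surface = (
        params.base
        + params.radial_slope * (radius - rim)
        + params.angular_amplitude
        * np.cos(np.radians(angle - params.peak_angle))
    )
    surface = np.clip(surface, params.floor, None)
    surface[mask.array] = np.nan
    return surface


def _trunc_draw(rng, mean, sd, lo=-np.inf, hi=np.inf) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def simulate_subject(
    params: PatternParams,
    record: SubjectRecord,
    rng: np.random.Generator,
    geometry: GridGeometry = DEFAULT_GEOMETRY,
    laterality: Laterality = "OD",
    mask: Optional[ONHMask] = None,
) -> ThicknessGrid:
    """Draw one subject's grid: pattern + subject level + cube noise.

    Consumes exactly one subject-level draw and one full-grid noise draw from
    ``rng`` regardless of the mask, so draw order is stable.  PD subjects
    receive the additive group offset and, if coupling is nonzero, a
    severity term proportional to (UPDRS - 25.1).
    """
    if mask is None:
        mask = select_onh_mask(geometry)
    surface = pattern_surface(params, geometry, laterality, mask)
    level = rng.normal(0.0, params.subject_sd) if params.subject_sd > 0 else 0.0
    noise = (
        rng.normal(0.0, params.cube_sd, size=(geometry.n_rows, geometry.n_cols))
        if params.cube_sd > 0
        else np.zeros((geometry.n_rows, geometry.n_cols))
    )
    values = surface + level + noise
    if record.group == "PD":
        values = values + params.group_offset
        if params.severity_coupling != 0 and record.updrs is not None:
            values = values + params.severity_coupling * (record.updrs - 25.1)
    values = np.clip(values, params.floor, None)
    values[mask.array] = np.nan
    return ThicknessGrid(record.id, laterality, values, geometry)


def _draw_record(
    rng: np.random.Generator,
    spec: CohortSpec,
    group: Literal["PD", "control"],
    cohort_role: str,
    idx: int,
) -> SubjectRecord:
    age = _trunc_draw(rng, spec.age_mean, spec.age_sd, lo=40.0, hi=95.0)
    sex = "M" if rng.random() < spec.male_fraction else "F"
    se = _trunc_draw(rng, 0.13, 1.8, lo=-5.0, hi=5.0)
    astig = _trunc_draw(rng, 0.6, 0.6, lo=0.0, hi=3.0)
    bcva_mean = 0.11 if group == "PD" else 0.03
    bcva = _trunc_draw(rng, bcva_mean, 0.16, lo=-0.2, hi=1.0)
    iop = _trunc_draw(rng, 16.3, 2.4, lo=8.0, hi=20.0)
    disc = _trunc_draw(rng, 1.9, 0.37, lo=0.8, hi=3.5)
    updrs = hy = dur = None
    treatment = "none"
    if group == "PD":
        updrs = _trunc_draw(rng, spec.updrs_mean, spec.updrs_sd, lo=0.0)
        hy = _trunc_draw(rng, spec.hoehn_yahr_mean, spec.hoehn_yahr_sd, lo=0.0, hi=5.0)
        dur = _trunc_draw(rng, spec.duration_mean, spec.duration_sd, lo=0.0)
        treatment = "dopamine-enhancing"
    prefix = "pd" if group == "PD" else {"teaching": "tc", "validating": "vc"}.get(
        cohort_role, "ct"
    )
    return SubjectRecord(
        id=f"{prefix}{idx:03d}",
        group=group,
        cohort_role=cohort_role,  # type: ignore[arg-type]
        age=age,
        sex=sex,  # type: ignore[arg-type]
        spherical_equivalent=se,
        astigmatism=astig,
        bcva=bcva,
        iop=iop,
        disc_area=disc,
        updrs=updrs,
        hoehn_yahr=hy,
        duration=dur,
        treatment_category=treatment,
    )


def simulate_cohort(
    spec: CohortSpec,
    params: PatternParams = PatternParams(),
    group: Literal["PD", "control"] = "control",
    cohort_role: str = "teaching",
    geometry: GridGeometry = DEFAULT_GEOMETRY,
    laterality: Laterality = "OD",
    include_covariates: bool = True,
) -> Tuple[List[ThicknessGrid], List[SubjectRecord]]:
    """Simulate one cohort of grids and subject records.

    Reproducible from ``spec.seed``; a single stream is consumed subject by
    subject, so truncating or extending ``n_per_group`` leaves earlier
    subjects unchanged.  ``include_covariates=False`` skips the clinical
    covariate draws (records carry placeholder covariates) for experiments
    that only touch thickness; the grid draws themselves are unchanged in
    structure.
    """
    rng = np.random.default_rng(spec.seed)
    mask = select_onh_mask(geometry)
    grids, records = [], []
    for i in range(spec.n_per_group):
        if include_covariates:
            rec = _draw_record(rng, spec, group, cohort_role, i)
        else:
            rec = SubjectRecord(
                id=f"{'pd' if group == 'PD' else 'c'}{i:03d}",
                group=group,
                cohort_role=cohort_role,  # type: ignore[arg-type]
                age=69.0, sex="M", spherical_equivalent=0.0, astigmatism=0.0,
                bcva=0.0, iop=16.0, disc_area=1.9,
                updrs=25.1 if group == "PD" else None,
                hoehn_yahr=2.7 if group == "PD" else None,
                duration=6.7 if group == "PD" else None,
            )
        grids.append(
            simulate_subject(params, rec, rng, geometry, laterality, mask)
        )
        records.append(rec)
    return grids, records


def simulate_study(
    seed: int = 0,
    n_per_group: int = 40,
    params: PatternParams = PatternParams(),
    geometry: GridGeometry = DEFAULT_GEOMETRY,
    include_covariates: bool = True,
) -> dict:
    """Simulate the full study layout: 2 x n controls plus n PD cases.

    Controls are drawn as one 2n cohort (later split into teaching and
    validating halves); cases as a separate PD cohort.  Sub-seeds are
    derived deterministically from ``seed``.
    """
    control_spec = CohortSpec(n_per_group=2 * n_per_group, seed=seed)
    case_spec = CohortSpec(n_per_group=n_per_group, seed=seed + 1_000_003)
    control_grids, control_records = simulate_cohort(
        control_spec, params, "control", "teaching", geometry,
        include_covariates=include_covariates,
    )
    case_grids, case_records = simulate_cohort(
        case_spec, params, "PD", "case", geometry,
        include_covariates=include_covariates,
    )
    return {
        "control_grids": control_grids,
        "control_records": control_records,
        "case_grids": case_grids,
        "case_records": case_records,
        "params": params,
        "geometry": geometry,
        "seed": seed,
    }
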