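"""Replicate-level simulation experiments.

These functions characterise the statistical behaviour of the pipeline under
the generator's default conditions: type-I error of the zone-2 comparison
under a null (zero-offset) generator, recovery of the simulated PD
thickening, calibration of the teaching cohort against the published
normative zone table, and uniformity of severity-correlation p-values when
no severity effect is simulated.  They are used by the acceptance checks and
are part of the public API for reproducing those numbers.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Tuple

import numpy as np
from scipy import stats as sps

from .geometry import DEFAULT_GEOMETRY, GridGeometry, select_onh_mask
from .simulate import CohortSpec, PatternParams, simulate_cohort
from .stats import pearson_r, two_sample_t
from .zones import ZONE_LABELS, ZoneBinSpec, delineate_zones, mean_thickness_map

__all__ = [
    "default_zone_map",
    "teaching_calibration",
    "null_rejection_rate",
    "effect_recovery",
    "severity_p_uniformity",
]


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate cohort seeds derived from one master seed.

    Drawn from a seeded stream (rather than consecutive integers) so that
    different master seeds yield essentially disjoint replicate sets.
    """
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def default_zone_map(
    seed: int = 0,
    n_subjects: int = 40,
    params: PatternParams = PatternParams(),
    geometry: GridGeometry = DEFAULT_GEOMETRY,
):
    """Zone map frozen from a default synthetic teaching cohort."""
    grids, _ = simulate_cohort(
        CohortSpec(n_per_group=n_subjects, seed=seed), params,
        include_covariates=False,
    )
    mask = select_onh_mask(geometry)
    return delineate_zones(mean_thickness_map(grids), ZoneBinSpec(), mask), mask


def teaching_calibration(
    seed: int = 0,
    n_subjects: int = 40,
    params: PatternParams = PatternParams(),
) -> Dict[str, Dict[int, float]]:
    """Zone cube counts and mean-map zone means of a teaching cohort."""
    grids, _ = simulate_cohort(
        CohortSpec(n_per_group=n_subjects, seed=seed), params,
        include_covariates=False,
    )
    mask = select_onh_mask(grids[0].geometry)
    mm = mean_thickness_map(grids)
    zm = delineate_zones(mm, ZoneBinSpec(), mask)
    means = {
        z: float(mm.values[zm.zone_mask(z)].mean()) for z in ZONE_LABELS
    }
    return {"counts": zm.zone_cube_counts, "means": means}


def _zone_subject_means(grids, zonemap, zone) -> np.ndarray:
    m = zonemap.zone_mask(zone)
    return np.array([g.values[m].mean() for g in grids])


def null_rejection_rate(
    n_reps: int = 1000,
    seed: int = 0,
    n_per_group: int = 40,
    zone: int = 2,
    alpha: float = 0.05,
    params: PatternParams = PatternParams(),
) -> float:
    """Fraction of zero-offset replicates where the zone t-test rejects.

    Zones are frozen once from a default teaching cohort; each replicate
    then simulates two independent control-like cohorts (group offset 0) and
    runs the pooled t-test on their per-subject zone means.  Under the null
    the rate should sit near ``alpha``.
    """
    zonemap, _ = default_zone_map(seed=seed, params=params)
    null_params = dataclasses.replace(params, group_offset=0.0)
    rejections = 0
    rep_seeds = _replicate_seeds(seed + 10_000, 2 * n_reps)
    for rep in range(n_reps):
        ga, _ = simulate_cohort(
            CohortSpec(n_per_group=n_per_group, seed=rep_seeds[2 * rep]),
            null_params, group="control", include_covariates=False,
        )
        gb, _ = simulate_cohort(
            CohortSpec(n_per_group=n_per_group, seed=rep_seeds[2 * rep + 1]),
            null_params, group="PD", include_covariates=False,
        )
        _, _, p = two_sample_t(
            _zone_subject_means(ga, zonemap, zone),
            _zone_subject_means(gb, zonemap, zone),
        )
        rejections += p < alpha
    return rejections / n_reps


def effect_recovery(
    n_reps: int = 30,
    seed: int = 0,
    n_per_group: int = 40,
    alpha: float = 0.05,
    params: PatternParams = PatternParams(),
) -> Dict[str, float]:
    """Recovery of the simulated PD thickening across replicates.

    Returns the mean estimated total-thickness group difference, its
    standard error across replicates, the true offset, the absolute
    z-discrepancy |estimate - truth| / SE, and the fraction of replicates in
    which all four zone comparisons reject at ``alpha``.
    """
    zonemap, mask = default_zone_map(seed=seed, params=params)
    ana = mask.analyzed
    diffs, all_sig = [], 0
    rep_seeds = _replicate_seeds(seed + 50_000, 2 * n_reps)
    for rep in range(n_reps):
        gc, _ = simulate_cohort(
            CohortSpec(n_per_group=n_per_group, seed=rep_seeds[2 * rep]),
            params, group="control", include_covariates=False,
        )
        gp, _ = simulate_cohort(
            CohortSpec(n_per_group=n_per_group, seed=rep_seeds[2 * rep + 1]),
            params, group="PD", include_covariates=False,
        )
        tc = np.array([g.values[ana].mean() for g in gc])
        tp = np.array([g.values[ana].mean() for g in gp])
        diffs.append(tp.mean() - tc.mean())
        sig = all(
            two_sample_t(
                _zone_subject_means(gp, zonemap, z),
                _zone_subject_means(gc, zonemap, z),
            )[2]
            < alpha
            for z in ZONE_LABELS
        )
        all_sig += sig
    diffs = np.asarray(diffs)
    se = diffs.std(ddof=1) / np.sqrt(len(diffs))
    return {
        "mean_estimated_offset": float(diffs.mean()),
        "se": float(se),
        "true_offset": params.group_offset,
        "z_discrepancy": float(abs(diffs.mean() - params.group_offset) / se),
        "all_zones_significant_fraction": all_sig / n_reps,
    }


def severity_p_uniformity(
    n_reps: int = 200,
    seed: int = 0,
    n_per_group: int = 40,
    params: PatternParams = PatternParams(),
) -> Dict[str, float]:
    """Distribution of severity-correlation p-values with zero coupling.

    Simulates PD cohorts with ``severity_coupling = 0``, correlates total
    thickness with UPDRS in each, and tests the resulting p-values for
    uniformity on [0, 1] (Kolmogorov-Smirnov).  A large KS p indicates the
    null behaves as it should — thickness carries no severity signal.
    """
    null_params = dataclasses.replace(params, severity_coupling=0.0)
    mask = select_onh_mask(DEFAULT_GEOMETRY)
    ana = mask.analyzed
    pvals = []
    rep_seeds = _replicate_seeds(seed + 90_000, n_reps)
    for rep in range(n_reps):
        grids, records = simulate_cohort(
            CohortSpec(n_per_group=n_per_group, seed=rep_seeds[rep]),
            null_params, group="PD", cohort_role="case",
        )
        totals = [g.values[ana].mean() for g in grids]
        scores = [r.updrs for r in records]
        _, p = pearson_r(totals, scores)
        pvals.append(p)
    d, ks_p = sps.kstest(pvals, "uniform")
    return {"ks_statistic": float(d), "ks_pvalue": float(ks_p),
            "mean_p": float(np.mean(pvals)), "n_reps": n_reps}
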