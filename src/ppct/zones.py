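"""Concentric choroidal zone delineation from a teaching cohort.

Zones are defined on the cube-wise mean thickness map of a normative
("teaching") cohort and then frozen: zone 2 collects cubes with mean
thickness below 105 um, zone 3 the range [105, 140) um, zone 4 [140, 175) um
and zone 5 everything at or above 175 um.  Zone 1 is the optic nerve head
itself and is never measured.  Because the choroid thins toward the nerve
head, the zones come out roughly concentric.

Zone statistics treat the subject as the statistical unit: a subject's zone
mean is the average of their cube values inside the zone, and group summaries
are mean +/- sample SD of those per-subject means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .geometry import DEFAULT_GEOMETRY, GridGeometry, ONHMask
from .grids import ThicknessGrid

__all__ = [
    "ZoneBinSpec",
    "MeanMap",
    "ZoneMap",
    "mean_thickness_map",
    "delineate_zones",
    "subject_zone_means",
    "group_zone_summary",
    "cube_bin_counts",
]

ZONE_LABELS = (2, 3, 4, 5)
ONH_ZONE_LABEL = 1  # the nerve head itself; exported but never analysed


@dataclass(frozen=True)
class ZoneBinSpec:
    """Thickness thresholds (um) separating zones 2|3, 3|4 and 4|5.

    Intervals are half-open on the right: (-inf, e1) -> zone 2, [e1, e2) ->
    zone 3, [e2, e3) -> zone 4, [e3, inf) -> zone 5.  ``reporting_floor`` is
    the lower bound of the thinnest *reported* cube bin (the count tables
    start at 70 um); it does not affect zone assignment.
    """

    edges: Tuple[float, float, float] = (105.0, 140.0, 175.0)
    reporting_floor: float = 70.0

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError(f"edges must be strictly increasing: {self.edges}")
        if not self.reporting_floor < self.edges[0]:
            raise ValueError("reporting_floor must lie below the first edge")


@dataclass
class MeanMap:
    """Cube-wise mean thickness (um) over a cohort; NaN at ONH cells."""

    values: np.ndarray
    n_subjects: int
    geometry: GridGeometry = field(default=DEFAULT_GEOMETRY)


@dataclass
class ZoneMap:
    """Zone assignment of every cube: 1 at the ONH, 2-5 elsewhere."""

    assignment: np.ndarray  # int array, shape (n_rows, n_cols)
    geometry: GridGeometry = field(default=DEFAULT_GEOMETRY)

    @property
    def zone_cube_counts(self) -> Dict[int, int]:
        return {z: int((self.assignment == z).sum()) for z in ZONE_LABELS}

    def zone_mask(self, zone: int) -> np.ndarray:
        return self.assignment == zone


def _check_cohort(cohort: Sequence[ThicknessGrid], allow_mirroring: bool) -> List[ThicknessGrid]:
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    geom = cohort[0].geometry
    lat = cohort[0].laterality
    out = []
    for g in cohort:
        if g.geometry != geom:
            raise ValueError("mixed geometries in cohort")
        if g.laterality != lat:
            if not allow_mirroring:
                raise ValueError(
                    "mixed laterality in cohort (pass allow_mirroring=True "
                    "to mirror OS grids onto OD)"
                )
            g = g.mirrored()
        out.append(g)
    return out


def mean_thickness_map(
    cohort: Sequence[ThicknessGrid], allow_mirroring: bool = False
) -> MeanMap:
    """Cube-wise arithmetic mean over subjects at each cell.

    All grids must share geometry and laterality; with
    ``allow_mirroring=True`` grids of the minority laterality are mirrored
    onto the first grid's side before averaging.
    """
    grids = _check_cohort(cohort, allow_mirroring)
    stacked = np.stack([g.values for g in grids])
    return MeanMap(stacked.mean(axis=0), len(grids), grids[0].geometry)


def delineate_zones(
    mean_map: MeanMap, bins: ZoneBinSpec = ZoneBinSpec(), mask: ONHMask | None = None
) -> ZoneMap:
    """Assign every analysed cube to zone 2-5 by its mean thickness.

    Thresholds are compared in um with no rounding: 104.9 um falls in zone 2,
    105.0 in zone 3, 175.0 in zone 5.
    """
    from .geometry import select_onh_mask

    if mask is None:
        mask = select_onh_mask(mean_map.geometry)
    vals = mean_map.values
    ana = mask.analyzed
    if not np.all(np.isfinite(vals[ana])):
        raise ValueError("mean map undefined at analysed cells")
    # digitize: (-inf,e1)->0, [e1,e2)->1, ... ; zone label = 2 + bin index
    assignment = np.full(vals.shape, ONH_ZONE_LABEL, dtype=int)
    assignment[ana] = 2 + np.digitize(vals[ana], bins.edges, right=False)
    return ZoneMap(assignment, mean_map.geometry)


def subject_zone_means(grid: ThicknessGrid, zonemap: ZoneMap) -> Dict[int, float]:
    """Mean of a subject's cube values within each zone.

    Zones with no cubes report NaN.
    """
    out: Dict[int, float] = {}
    for z in ZONE_LABELS:
        m = zonemap.zone_mask(z)
        out[z] = float(grid.values[m].mean()) if m.any() else float("nan")
    return out


def group_zone_summary(
    cohort: Sequence[ThicknessGrid], zonemap: ZoneMap
) -> Dict[int, Tuple[float, float, int]]:
    """Per-zone (mean, sample SD, n) of per-subject zone means.

    SD uses the n-1 denominator and is NaN for n < 2.
    """
    per_subject = {z: [] for z in ZONE_LABELS}
    for g in cohort:
        zm = subject_zone_means(g, zonemap)
        for z in ZONE_LABELS:
            per_subject[z].append(zm[z])
    out = {}
    for z, vals in per_subject.items():
        arr = np.asarray(vals, dtype=float)
        n = len(arr)
        sd = float(arr.std(ddof=1)) if n >= 2 else float("nan")
        out[z] = (float(arr.mean()), sd, n)
    return out


def cube_bin_counts(
    mean_map: MeanMap, bins: ZoneBinSpec = ZoneBinSpec(), mask: ONHMask | None = None
) -> Tuple[int, int, int, int, int]:
    """Cube counts in the reported thickness bins.

    Returns ``(below_floor, floor..e1, e1..e2, e2..e3, >= e3)`` over the
    analysed cubes; the five counts sum to the analysed-cube count.  The
    below-floor bin (< 70 um by default) is kept separate because published
    count tables start at the reporting floor.
    """
    from .geometry import select_onh_mask

    if mask is None:
        mask = select_onh_mask(mean_map.geometry)
    vals = mean_map.values[mask.analyzed]
    if not np.all(np.isfinite(vals)):
        raise ValueError("mean map undefined at analysed cells")
    edges = [bins.reporting_floor, *bins.edges]
    counts = np.histogram(vals, bins=[-np.inf, *edges, np.inf])[0]
    return tuple(int(c) for c in counts)  # type: ignore[return-value]
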