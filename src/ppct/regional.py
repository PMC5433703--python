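"""Quadrant/sector partitions and thickness-to-volume conversion.

The device reports regional choroidal thickness for 4 quadrants and 6
sectors around the optic nerve head.  Cubes are assigned by the anatomical
angle of their centre; the published boundaries are not documented, so this
module uses equal-angle wedges (90 deg quadrants, 60 deg sectors) centred on
the anatomical axes.

Volume converts a regional mean thickness to mm^3 over the *effective*
imaging area — total grid area minus ONH area, 23.52 mm^2 by default — with
each of n equal regions carrying 1/n of that area.  This equal-area rule
reproduces the published (thickness, volume) pairs to two decimals; a
cube-count-weighted alternative is available but non-default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .geometry import GridGeometry, Laterality, ONHMask, polar_grid
from .grids import ThicknessGrid

__all__ = [
    "QUADRANT_LABELS",
    "SECTOR_LABELS",
    "RegionPartition",
    "quadrant_partition",
    "sector_partition",
    "total_partition",
    "regional_mean_thickness",
    "group_regional_summary",
    "regional_volume",
    "cube_count_volume",
]

QUADRANT_LABELS = ("Superior", "Nasal", "Inferior", "Temporal")
SECTOR_LABELS = (
    "Superotemporal",
    "Superonasal",
    "Nasal",
    "Inferonasal",
    "Inferotemporal",
    "Temporal",
)

# [start, end) wedges in anatomical degrees; Temporal wraps through 0
_QUADRANT_WEDGES = {
    "Superior": (45.0, 135.0),
    "Nasal": (135.0, 225.0),
    "Inferior": (225.0, 315.0),
    "Temporal": (315.0, 45.0),
}
_SECTOR_WEDGES = {
    "Temporal": (330.0, 30.0),
    "Superotemporal": (30.0, 90.0),
    "Superonasal": (90.0, 150.0),
    "Nasal": (150.0, 210.0),
    "Inferonasal": (210.0, 270.0),
    "Inferotemporal": (270.0, 330.0),
}


@dataclass
class RegionPartition:
    """Assignment of analysed cubes to named angular regions.

    ``assignment`` maps each label to a boolean (n_rows, n_cols) cube mask;
    the masks are disjoint and together cover exactly the analysed cubes.
    """

    kind: str  # "total" | "quadrant" | "sector"
    labels: Tuple[str, ...]
    assignment: Dict[str, np.ndarray]
    laterality: Laterality

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def region_of(self, row: int, col: int) -> str:
        """Region label of the 1-based (row, col) cube; raises if masked."""
        for label in self.labels:
            if self.assignment[label][row - 1, col - 1]:
                return label
        raise KeyError(f"cube ({row}, {col}) is not an analysed cube")


def _in_wedge(angle: np.ndarray, start: float, end: float) -> np.ndarray:
    if start < end:
        return (angle >= start) & (angle < end)
    return (angle >= start) | (angle < end)  # wraps through 0


def _wedge_partition(
    kind: str,
    wedges: Dict[str, Tuple[float, float]],
    labels: Tuple[str, ...],
    geometry: GridGeometry,
    mask: ONHMask,
    laterality: Laterality,
) -> RegionPartition:
    # Assign on OD angles; OS is the exact horizontal mirror of the OD
    # partition, so boundary cubes (exactly on a wedge edge) land in
    # mirror-consistent regions for the two eyes.
    _, angle = polar_grid(geometry, "OD")
    ana = mask.analyzed
    assignment = {lab: _in_wedge(angle, *wedges[lab]) & ana for lab in labels}
    if laterality == "OS":
        assignment = {lab: m[:, ::-1].copy() for lab, m in assignment.items()}
    return RegionPartition(kind, labels, assignment, laterality)


def quadrant_partition(
    geometry: GridGeometry, mask: ONHMask, laterality: Laterality = "OD"
) -> RegionPartition:
    """Four 90-deg quadrants: Superior [45,135), Nasal [135,225),
    Inferior [225,315), Temporal [315,45)."""
    return _wedge_partition(
        "quadrant", _QUADRANT_WEDGES, QUADRANT_LABELS, geometry, mask, laterality
    )


def sector_partition(
    geometry: GridGeometry, mask: ONHMask, laterality: Laterality = "OD"
) -> RegionPartition:
    """Six 60-deg sectors with Temporal centred on 0 deg."""
    return _wedge_partition(
        "sector", _SECTOR_WEDGES, SECTOR_LABELS, geometry, mask, laterality
    )


def total_partition(
    geometry: GridGeometry, mask: ONHMask, laterality: Laterality = "OD"
) -> RegionPartition:
    """Single region covering all analysed cubes."""
    return RegionPartition(
        "total", ("Total",), {"Total": mask.analyzed.copy()}, laterality
    )


def regional_mean_thickness(
    grid: ThicknessGrid, partition: RegionPartition
) -> Dict[str, float]:
    """Arithmetic mean of the subject's cube values per region (um).

    Empty regions report NaN.
    """
    out = {}
    for label in partition.labels:
        m = partition.assignment[label]
        out[label] = float(grid.values[m].mean()) if m.any() else float("nan")
    return out


def group_regional_summary(
    cohort: Sequence[ThicknessGrid], partition: RegionPartition
) -> Dict[str, Tuple[float, float, int]]:
    """Per-region (mean, sample SD, n) of per-subject regional means."""
    per_subject = {lab: [] for lab in partition.labels}
    for g in cohort:
        rm = regional_mean_thickness(g, partition)
        for lab in partition.labels:
            per_subject[lab].append(rm[lab])
    out = {}
    for lab, vals in per_subject.items():
        arr = np.asarray(vals, dtype=float)
        n = len(arr)
        sd = float(arr.std(ddof=1)) if n >= 2 else float("nan")
        out[lab] = (float(arr.mean()), sd, n)
    return out


def regional_volume(
    mean_thickness_um: float, geometry: GridGeometry, n_regions: int
) -> float:
    """Choroidal volume (mm^3) of one of ``n_regions`` equal-area regions.

    volume = thickness[mm] x effective_area / n_regions, with effective area
    the total grid area minus the ONH area.  ``n_regions`` is 1 (total),
    4 (quadrants) or 6 (sectors).
    """
    if n_regions not in (1, 4, 6):
        raise ValueError(f"n_regions must be 1, 4 or 6, got {n_regions}")
    if mean_thickness_um < 0:
        raise ValueError("mean thickness must be >= 0")
    return (mean_thickness_um / 1000.0) * geometry.effective_area / n_regions


def cube_count_volume(
    mean_thickness_um: float, geometry: GridGeometry, n_cubes: int
) -> float:
    """Alternative volume: thickness[mm] x (cube count x cube area).

    Uses the region's actual cube footprint instead of an equal share of the
    effective area; provided for sensitivity analyses, not the default.
    """
    if n_cubes < 0:
        raise ValueError("cube count must be >= 0")
    return (mean_thickness_um / 1000.0) * n_cubes * geometry.cube_area
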