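"""Physical layout of the peripapillary cube-grid.

The swept-source OCT device lays a 26x26 grid of 200 um x 200 um cubes over a
6.0x6.0 mm optic-disc scan.  The 88 cubes nearest the grid centre fall on the
optic nerve head (ONH) and carry no choroidal thickness; the remaining 588
cubes are the analysed peripapillary area.  This module owns that bookkeeping:
grid dimensions, cube/ONH/effective areas, the ONH mask, and the polar
coordinates (radius in mm, anatomical angle in degrees) of every cube centre.

Angles follow the anatomical convention: superior = 90 deg, inferior = 270,
temporal = 0, nasal = 180.  For a right eye (OD) temporal points toward
decreasing column index; a left eye (OS) is the horizontal mirror.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Literal, Tuple

import numpy as np

Laterality = Literal["OD", "OS"]

__all__ = [
    "GridGeometry",
    "ONHMask",
    "build_geometry",
    "select_onh_mask",
    "cube_polar",
    "polar_grid",
    "DEFAULT_GEOMETRY",
]


class InvalidConfigurationError(ValueError):
    """Raised when grid dimensions or mask count are inconsistent."""


@dataclass(frozen=True)
class GridGeometry:
    """Cube-grid dimensions and derived areas.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (26 x 26 for the device configuration).
    cube_edge
        Cube edge length in mm (0.2 mm = 200 um).
    onh_cube_count
        Number of central cubes masked out as optic nerve head.
    """

    n_rows: int = 26
    n_cols: int = 26
    cube_edge: float = 0.2
    onh_cube_count: int = 88

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0 or self.cube_edge <= 0:
            raise InvalidConfigurationError(
                f"grid dimensions must be positive, got "
                f"{self.n_rows}x{self.n_cols}, edge {self.cube_edge}"
            )
        if self.onh_cube_count < 0 or self.onh_cube_count >= self.n_rows * self.n_cols:
            raise InvalidConfigurationError(
                f"onh_cube_count {self.onh_cube_count} must be in "
                f"[0, {self.n_rows * self.n_cols})"
            )

    @property
    def n_cubes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_analyzed(self) -> int:
        return self.n_cubes - self.onh_cube_count

    @property
    def cube_area(self) -> float:
        """Area of one cube in mm^2."""
        return self.cube_edge**2

    @property
    def total_area(self) -> float:
        """Total grid area in mm^2 (27.04 for the default grid)."""
        return self.n_cubes * self.cube_area

    @property
    def onh_area(self) -> float:
        """Masked optic-nerve-head area in mm^2 (3.52 by default)."""
        return self.onh_cube_count * self.cube_area

    @property
    def effective_area(self) -> float:
        """Analysed peripapillary area in mm^2: total minus ONH."""
        return self.total_area - self.onh_area

    def cube_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """(x, y) cube-centre coordinates in mm, display frame.

        x grows with column index (rightward on the device display),
        y grows *upward*; the origin is the grid centroid.
        """
        rows, cols = np.meshgrid(
            np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij"
        )
        x = (cols + 0.5) * self.cube_edge - self.n_cols * self.cube_edge / 2
        y = self.n_rows * self.cube_edge / 2 - (rows + 0.5) * self.cube_edge
        return x, y


DEFAULT_GEOMETRY = GridGeometry()


def build_geometry(
    n_rows: int = 26,
    n_cols: int = 26,
    cube_edge: float = 0.2,
    onh_cube_count: int = 88,
) -> GridGeometry:
    """Construct a validated :class:`GridGeometry`; defaults match the device."""
    return GridGeometry(n_rows, n_cols, cube_edge, onh_cube_count)


@dataclass(frozen=True)
class ONHMask:
    """Set of masked optic-nerve-head cubes.

    ``array`` is a boolean (n_rows, n_cols) map, True at masked cells.
    ``cells`` exposes the 1-based (row, col) indices matching the device
    display convention.
    """

    array: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "array", np.asarray(self.array, dtype=bool))
        self.array.setflags(write=False)

    @property
    def count(self) -> int:
        return int(self.array.sum())

    @property
    def cells(self) -> FrozenSet[Tuple[int, int]]:
        rr, cc = np.nonzero(self.array)
        return frozenset(zip((rr + 1).tolist(), (cc + 1).tolist()))

    @property
    def analyzed(self) -> np.ndarray:
        """Boolean map of analysed (non-ONH) cubes."""
        return ~self.array


def _centroid_distances(geometry: GridGeometry) -> np.ndarray:
    x, y = geometry.cube_centers()
    return np.hypot(x, y)


def select_onh_mask(geometry: GridGeometry) -> ONHMask:
    """Mask the ``onh_cube_count`` cubes nearest the grid centroid.

    Selection is by ascending Euclidean distance from cube centre to the
    centroid; ties are broken in row-major order, so the result is
    deterministic.  For the default grid this yields an approximately
    circular 88-cube mask (radius about 5.3 cube widths).
    """
    dist = _centroid_distances(geometry)
    order = np.argsort(dist.ravel(), kind="stable")  # row-major tie-break
    mask = np.zeros(geometry.n_cubes, dtype=bool)
    mask[order[: geometry.onh_cube_count]] = True
    return ONHMask(mask.reshape(geometry.n_rows, geometry.n_cols))


def polar_grid(
    geometry: GridGeometry, laterality: Laterality = "OD"
) -> Tuple[np.ndarray, np.ndarray]:
    """Radius (mm) and anatomical angle (deg) of every cube centre.

    Returns two (n_rows, n_cols) arrays.  The angle convention is superior =
    90, inferior = 270, temporal = 0, nasal = 180.  For OD temporal points
    toward decreasing column index; OS is mirrored horizontally so that
    ``angle_OS = (180 - angle_OD) mod 360``.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError(f"laterality must be 'OD' or 'OS', got {laterality!r}")
    x, y = geometry.cube_centers()
    radius = np.hypot(x, y)
    # temporal axis: -x for OD (leftward on display), +x for OS
    x_anat = -x if laterality == "OD" else x
    angle = np.degrees(np.arctan2(y, x_anat)) % 360.0
    return radius, angle


def cube_polar(
    geometry: GridGeometry,
    row: int,
    col: int,
    laterality: Laterality = "OD",
) -> Tuple[float, float]:
    """Polar coordinates of a single cube addressed by 1-based (row, col).

    Row/column indices are 1-based, matching the device display ("row number
    9 and file number 9").  Returns ``(radius_mm, angle_deg)``.
    """
    if not (1 <= row <= geometry.n_rows) or not (1 <= col <= geometry.n_cols):
        raise IndexError(
            f"cube ({row}, {col}) outside 1..{geometry.n_rows} x 1..{geometry.n_cols}"
        )
    radius, angle = polar_grid(geometry, laterality)
    return float(radius[row - 1, col - 1]), float(angle[row - 1, col - 1])
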