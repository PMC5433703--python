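"""Per-subject thickness grids and their delimited-text file format.

A :class:`ThicknessGrid` holds one eye's 26x26 choroidal thickness map in um,
with NaN at the masked optic-nerve-head cells.  Grids are stored on disk as
plain tab-delimited text, 26 rows x 26 columns, masked cells written as
``NA``; the filename carries the subject id and laterality
(``<subject_id>_<OD|OS>.tsv``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List

import numpy as np

from .geometry import DEFAULT_GEOMETRY, GridGeometry, Laterality, ONHMask

__all__ = ["ThicknessGrid", "read_grid", "write_grid", "read_cohort_grids"]

# soft plausibility bounds for choroidal thickness in um
PLAUSIBLE_MIN_UM = 20.0
PLAUSIBLE_MAX_UM = 600.0


@dataclass
class ThicknessGrid:
    """One subject's choroidal thickness map.

    ``values`` is an (n_rows, n_cols) float array in um; masked (ONH) cells
    are NaN, analysed cells are finite and positive.
    """

    subject_id: str
    laterality: Laterality
    values: np.ndarray
    geometry: GridGeometry = field(default=DEFAULT_GEOMETRY)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_rows, self.geometry.n_cols)
        if self.values.shape != expected:
            raise ValueError(
                f"grid shape {self.values.shape} != geometry {expected}"
            )

    def validate(self, mask: ONHMask) -> None:
        """Check mask agreement and value plausibility.

        Raises on structural problems (non-finite or non-positive analysed
        cells, finite masked cells); values outside the 20-600 um plausibility
        band only warn.
        """
        vals = self.values
        ana = mask.analyzed
        if not np.all(np.isfinite(vals[ana])):
            raise ValueError(f"{self.subject_id}: non-finite analysed cells")
        if np.any(vals[ana] <= 0):
            raise ValueError(f"{self.subject_id}: non-positive thickness values")
        if np.any(np.isfinite(vals[mask.array])):
            raise ValueError(f"{self.subject_id}: masked cells carry values")
        out = (vals[ana] < PLAUSIBLE_MIN_UM) | (vals[ana] > PLAUSIBLE_MAX_UM)
        if out.any():
            warnings.warn(
                f"{self.subject_id}: {int(out.sum())} cells outside "
                f"[{PLAUSIBLE_MIN_UM:.0f}, {PLAUSIBLE_MAX_UM:.0f}] um",
                stacklevel=2,
            )

    def mirrored(self) -> "ThicknessGrid":
        """Horizontal mirror, flipping laterality (OD <-> OS)."""
        flipped: Laterality = "OS" if self.laterality == "OD" else "OD"
        return ThicknessGrid(
            self.subject_id, flipped, self.values[:, ::-1].copy(), self.geometry
        )


def write_grid(grid: ThicknessGrid, directory: str | Path) -> Path:
    """Write a grid as tab-delimited text; returns the file path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{grid.subject_id}_{grid.laterality}.tsv"
    with open(path, "w") as fh:
        for row in grid.values:
            fh.write(
                "\t".join("NA" if not np.isfinite(v) else f"{v:.2f}" for v in row)
            )
            fh.write("\n")
    return path


def read_grid(
    path: str | Path, geometry: GridGeometry = DEFAULT_GEOMETRY
) -> ThicknessGrid:
    """Read a tab-delimited grid file written by :func:`write_grid`.

    The filename stem must end in ``_OD`` or ``_OS``.
    """
    path = Path(path)
    stem = path.stem
    if stem.endswith("_OD") or stem.endswith("_OS"):
        subject_id, laterality = stem[:-3], stem[-2:]
    else:
        raise ValueError(f"cannot parse laterality from filename {path.name!r}")
    values = np.genfromtxt(path, delimiter="\t", missing_values="NA")
    return ThicknessGrid(subject_id, laterality, values, geometry)  # type: ignore[arg-type]


def read_cohort_grids(
    paths: Iterable[str | Path], geometry: GridGeometry = DEFAULT_GEOMETRY
) -> List[ThicknessGrid]:
    return [read_grid(p, geometry) for p in sorted(Path(p) for p in paths)]
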