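"""I/O and validation for SUV volumes, VOI masks, and lesion index tables.

Volumes and masks travel as NIfTI-1 images (via :mod:`nibabel`); lesion
tables as UTF-8 CSV with a fixed column order. All volumes of one patient
are assumed to live on a single grid — world coordinates are
``origin + index * spacing`` with 0-based voxel indices, and no registration
step is applied between timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DimensionalityError, GeometryMismatchError, ValidationError

COMPARTMENTS = ("prostate", "node", "bone")
TIMEPOINTS = ("pre", "post")

#: Fixed column order of a lesion table CSV.
LESION_TABLE_COLUMNS = (
    "patient_id",
    "timepoint",
    "compartment",
    "lesion_id",
    "suvmax",
    "suvmean",
    "psma_tv_cm3",
    "psma_tl",
)


@dataclass
class SUVVolume:
    """A 3-D grid of body-weight-normalized SUV values with voxel geometry.

    Parameters
    ----------
    grid
        3-D float array of SUV (dimensionless, finite, >= 0).
    spacing
        Per-axis voxel size in mm, all components > 0.
    origin
        World offset of voxel (0, 0, 0) in mm.
    patient_id, timepoint
        Scan identity; ``timepoint`` is ``"pre"`` or ``"post"``.
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    patient_id: str = ""
    timepoint: str = "pre"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise DimensionalityError(
                f"SUV volume must have exactly 3 axes, got {self.grid.ndim}"
            )
        bad = np.count_nonzero(~np.isfinite(self.grid) | (self.grid < 0))
        if bad:
            raise ValidationError(
                f"SUV volume contains {bad} negative or non-finite voxel(s)"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive components, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (product of the mm spacings / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class VOIMask:
    """A boolean volume of interest restricting lesion search to one compartment."""

    grid: np.ndarray
    compartment: str
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3:
            raise DimensionalityError(
                f"VOI mask must have exactly 3 axes, got {self.grid.ndim}"
            )
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)


def check_aligned(volume: SUVVolume, mask: VOIMask) -> None:
    """Raise :class:`GeometryMismatchError` unless mask and volume share a grid."""
    if mask.grid.shape != volume.grid.shape:
        raise GeometryMismatchError(
            f"mask shape {mask.grid.shape} != volume shape {volume.grid.shape}"
        )


def check_disjoint(masks: Sequence[VOIMask]) -> None:
    """Compartment masks of one scan must not overlap."""
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            n = np.count_nonzero(masks[i].grid & masks[j].grid)
            if n:
                raise ValidationError(
                    f"masks {masks[i].compartment!r} and {masks[j].compartment!r} "
                    f"overlap in {n} voxel(s)"
                )


# ---------------------------------------------------------------------------
# NIfTI round-trip


def read_volume(path: str | Path, patient_id: str = "", timepoint: str = "pre") -> SUVVolume:
    """Read a 3-D NIfTI image as an :class:`SUVVolume`.

    Spacing is taken from the header zooms; values pass through unchanged.
    Non-3-D images raise :class:`DimensionalityError`; negative or NaN voxels
    raise :class:`ValidationError` with the offending count.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3-D image, got {data.ndim} axes")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in np.asarray(img.affine)[:3, 3])
    return SUVVolume(data, spacing, origin, patient_id=patient_id, timepoint=timepoint)


def write_volume(volume: SUVVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(volume.grid.astype(np.float64), volume.affine), str(path))
    return path


def read_mask(path: str | Path, compartment: str) -> VOIMask:
    """Read a NIfTI mask (any nonzero voxel is inside the VOI)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3-D mask, got {data.ndim} axes")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in np.asarray(img.affine)[:3, 3])
    return VOIMask(data != 0, compartment, spacing, origin)


def write_mask(mask: VOIMask, path: str | Path) -> Path:
    path = Path(path)
    aff = np.diag(list(mask.spacing) + [1.0])
    aff[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), aff), str(path))
    return path


# ---------------------------------------------------------------------------
# Lesion tables


def validate_lesion_table(table: pd.DataFrame, rtol: float = 1e-9) -> None:
    """Check the lesion-table invariants, naming the first offending row.

    Invariants: ``psma_tv_cm3 > 0``, ``suvmean <= suvmax``, and
    ``psma_tl == suvmean * psma_tv_cm3`` within floating tolerance.
    """
    missing = [c for c in LESION_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"lesion table missing columns: {missing}")
    for idx, row in table.iterrows():
        if not row["psma_tv_cm3"] > 0:
            raise ValidationError(f"row {idx}: psma_tv_cm3 must be > 0")
        if row["suvmean"] > row["suvmax"] * (1 + rtol):
            raise ValidationError(f"row {idx}: suvmean exceeds suvmax")
        expected = row["suvmean"] * row["psma_tv_cm3"]
        if not np.isclose(row["psma_tl"], expected, rtol=1e-6, atol=1e-12):
            raise ValidationError(
                f"row {idx}: psma_tl {row['psma_tl']} != suvmean*psma_tv {expected}"
            )


def write_lesion_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated lesion table as CSV in the fixed column order."""
    validate_lesion_table(table)
    path = Path(path)
    table.loc[:, list(LESION_TABLE_COLUMNS)].to_csv(path, index=False)
    return path


def read_lesion_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        dtype={"patient_id": str, "timepoint": str, "compartment": str, "lesion_id": int},
    )
    if len(table):
        validate_lesion_table(table)
    return table


def lesion_table_from_rows(rows: Iterable[dict]) -> pd.DataFrame:
    """Build an (empty-safe) lesion table DataFrame with the canonical columns."""
    table = pd.DataFrame(list(rows), columns=list(LESION_TABLE_COLUMNS))
    return table
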