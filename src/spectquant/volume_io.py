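"""Reading and writing uptake volumes, label masks and acquisition metadata.

Volumes and masks are stored as NIfTI (``.nii`` / ``.nii.gz``); acquisition
metadata is a flat JSON object.  All quantification downstream happens in the
voxel space of the loaded grid, so orientation codes are informational only.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: Default Tc-99m physical half-life in hours.
TC99M_HALF_LIFE_H = 6.0067

#: Canonical base-region names.
LV_LATERAL = "LV_LATERAL"
IVS = "IVS"
APEX = "APEX"
RV_FREE_WALL = "RV_FREE_WALL"
STERNUM = "STERNUM"

BASE_REGIONS = (LV_LATERAL, IVS, APEX, RV_FREE_WALL)

#: Default integer labelling used when no explicit label map is given.
DEFAULT_LABEL_MAP: dict[str, int] = {
    LV_LATERAL: 1,
    IVS: 2,
    APEX: 3,
    RV_FREE_WALL: 4,
    STERNUM: 5,
}


class GeometryError(ValueError):
    """Raised when grids that must share geometry do not."""


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D scalar uptake grid with voxel geometry.

    Parameters
    ----------
    values
        Non-negative 3-D array of uptake (arbitrary concentration units).
    spacing_mm
        Per-axis voxel edge lengths in millimetres, all > 0.
    origin_mm
        World position of the first voxel (informational).
    axis_codes
        Anatomical orientation labels (informational).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got {values.ndim}-D")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        if np.any(values < 0):
            raise ValueError(
                "volume contains negative values; clip on ingestion first"
            )
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (mm^3 / 1000)."""
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass(frozen=True)
class AcquisitionMeta:
    """Injected dose, timing and body weight driving decay correction and SUV."""

    injected_activity_MBq: float
    injection_time: datetime
    acquisition_time: datetime
    body_weight_kg: float
    half_life_h: float = TC99M_HALF_LIFE_H

    def __post_init__(self) -> None:
        if self.injected_activity_MBq <= 0:
            raise ValueError("injected_activity_MBq must be > 0")
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be > 0")
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be > 0")
        if self.acquisition_time < self.injection_time:
            raise ValueError("acquisition_time precedes injection_time")

    @property
    def uptake_delay_h(self) -> float:
        """Time from injection to acquisition in hours."""
        return (self.acquisition_time - self.injection_time).total_seconds() / 3600.0


@dataclass(frozen=True)
class RegionMaskSet:
    """Named integer label masks congruent with a companion :class:`VoxelVolume`.

    Labels are disjoint by construction (one integer per voxel, 0 = background).
    """

    label_grid: np.ndarray
    label_map: Mapping[str, int]
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.label_grid)
        if grid.ndim != 3:
            raise ValueError(f"expected a 3-D label grid, got {grid.ndim}-D")
        if not np.issubdtype(grid.dtype, np.integer):
            rounded = np.rint(grid)
            if not np.allclose(grid, rounded):
                raise ValueError("label grid is not integer-valued")
            grid = rounded.astype(np.int32)
        spacing = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in spacing):
            raise ValueError("mask spacing must be positive")
        object.__setattr__(self, "label_grid", grid)
        object.__setattr__(self, "label_map", dict(self.label_map))
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_grid.shape  # type: ignore[return-value]

    def region_names(self) -> list[str]:
        return list(self.label_map)

    def mask(self, name: str) -> np.ndarray:
        """Boolean voxel set for a named region."""
        if name not in self.label_map:
            raise KeyError(f"unknown region {name!r}; known: {sorted(self.label_map)}")
        return self.label_grid == self.label_map[name]

    def empty_regions(self) -> list[str]:
        present = set(np.unique(self.label_grid).tolist())
        return [n for n, lab in self.label_map.items() if lab not in present]

    def check_congruent(self, volume: VoxelVolume, atol_mm: float = 1e-6) -> None:
        """Raise :class:`GeometryError` unless shape and spacing match *volume*."""
        if self.shape != volume.shape:
            raise GeometryError(
                f"mask shape {self.shape} != volume shape {volume.shape}"
            )
        if not np.allclose(self.spacing_mm, volume.spacing_mm, atol=atol_mm):
            raise GeometryError(
                f"mask spacing {self.spacing_mm} != volume spacing {volume.spacing_mm}"
            )


def _affine(spacing_mm, origin_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing_mm)
    aff[:3, 3] = origin_mm
    return aff


def _load_nifti(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return data, zooms, origin


def read_volume(path: str | Path) -> VoxelVolume:
    """Read an uptake volume from a NIfTI file.

    Negative voxels (reconstruction artefacts) are clipped to zero; the number
    of clipped voxels is logged.
    """
    data, zooms, origin = _load_nifti(path)
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite values")
    n_negative = int(np.sum(data < 0))
    if n_negative:
        logger.info("clipped %d negative voxels to 0 in %s", n_negative, path)
        data = np.clip(data, 0.0, None)
    return VoxelVolume(values=data, spacing_mm=zooms, origin_mm=origin)


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(
        volume.values.astype(np.float64), _affine(volume.spacing_mm, volume.origin_mm)
    )
    nib.save(img, str(path))


def read_mask_set(
    path: str | Path,
    label_map: Mapping[str, int] | None = None,
    companion: VoxelVolume | None = None,
) -> RegionMaskSet:
    """Read an integer label mask from NIfTI.

    Warns (listing names) when a mapped label is absent from the grid; raises
    :class:`GeometryError` when *companion* is given and geometry differs.
    """
    data, zooms, origin = _load_nifti(path)
    masks = RegionMaskSet(
        label_grid=data,
        label_map=dict(label_map) if label_map is not None else dict(DEFAULT_LABEL_MAP),
        spacing_mm=zooms,
        origin_mm=origin,
    )
    if companion is not None:
        masks.check_congruent(companion)
    empty = masks.empty_regions()
    if empty:
        warnings.warn(
            f"label map names with no voxels in {path}: {empty}", stacklevel=2
        )
    return masks


def write_mask_set(masks: RegionMaskSet, path: str | Path) -> None:
    img = nib.Nifti1Image(
        masks.label_grid.astype(np.int16), _affine(masks.spacing_mm, masks.origin_mm)
    )
    nib.save(img, str(path))


_REQUIRED_META = (
    "injected_activity_MBq",
    "injection_time",
    "acquisition_time",
    "body_weight_kg",
)


def read_meta(path: str | Path) -> AcquisitionMeta:
    """Parse acquisition metadata from a flat JSON file.

    Required keys: ``injected_activity_MBq``, ``injection_time``,
    ``acquisition_time`` (ISO-8601), ``body_weight_kg``.  ``half_life_h``
    defaults to the Tc-99m value when absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    raw = json.loads(path.read_text())
    missing = [k for k in _REQUIRED_META if k not in raw]
    if missing:
        raise ValueError(f"{path}: missing required metadata field(s): {missing}")
    return AcquisitionMeta(
        injected_activity_MBq=float(raw["injected_activity_MBq"]),
        injection_time=datetime.fromisoformat(raw["injection_time"]),
        acquisition_time=datetime.fromisoformat(raw["acquisition_time"]),
        body_weight_kg=float(raw["body_weight_kg"]),
        half_life_h=float(raw.get("half_life_h", TC99M_HALF_LIFE_H)),
    )


def write_meta(meta: AcquisitionMeta, path: str | Path) -> None:
    payload = {
        "injected_activity_MBq": meta.injected_activity_MBq,
        "injection_time": meta.injection_time.isoformat(),
        "acquisition_time": meta.acquisition_time.isoformat(),
        "body_weight_kg": meta.body_weight_kg,
        "half_life_h": meta.half_life_h,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
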