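"""Region scheme: base VOIs, merged VOIs, and the sternum spill-over exclusion.

The four base regions come from a simplified 16-segment short-axis model.
``LV`` merges the three left-sided walls; ``VENTRICLES`` adds the RV free
wall.  The RV free wall may additionally be trimmed where it lies within a
configurable distance of the sternum, which is hot on bone-avid tracers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import APEX, IVS, LV_LATERAL, RV_FREE_WALL, RegionMaskSet

LV = "LV"
VENTRICLES = "VENTRICLES"

LV_MEMBERS = (LV_LATERAL, IVS, APEX)
VENTRICLES_MEMBERS = (LV_LATERAL, IVS, APEX, RV_FREE_WALL)

#: Default width of the sternum exclusion border (≈ one system FWHM).
DEFAULT_STERNUM_MARGIN_MM = 10.0


@dataclass(frozen=True)
class MergedRegion:
    """A named union of base regions; only LV and VENTRICLES are valid."""

    name: str
    members: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        expected = {LV: LV_MEMBERS, VENTRICLES: VENTRICLES_MEMBERS}
        if self.name not in expected:
            raise ValueError(f"merged region must be LV or VENTRICLES, got {self.name!r}")
        members = tuple(self.members) if self.members else expected[self.name]
        if set(members) != set(expected[self.name]):
            raise ValueError(
                f"{self.name} members must be exactly {set(expected[self.name])}, "
                f"got {set(members)}"
            )
        object.__setattr__(self, "members", members)


MERGED_LV = MergedRegion(LV)
MERGED_VENTRICLES = MergedRegion(VENTRICLES)


def merge_regions(masks: RegionMaskSet, target: MergedRegion) -> np.ndarray:
    """Union of the member voxel sets of *target* as a boolean grid.

    Base labels are disjoint, so the union size is the sum of member sizes.
    Raises if any member region is empty or unmapped.
    """
    union = np.zeros(masks.shape, dtype=bool)
    for name in target.members:
        member = masks.mask(name)
        if not member.any():
            raise ValueError(f"member region {name} is empty; cannot merge into {target.name}")
        union |= member
    return union


def exclude_sternum_spillover(
    rv_mask: np.ndarray,
    sternum_mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
    margin_mm: float = DEFAULT_STERNUM_MARGIN_MM,
) -> np.ndarray:
    """Remove RV voxels within ``margin_mm`` (Euclidean) of the sternum.

    Distance is measured between voxel centres on the anisotropic grid.  With
    ``margin_mm == 0`` only voxels overlapping the sternum are removed.  The
    result is always a subset of *rv_mask* and shrinks monotonically as the
    margin grows.
    """
    rv_mask = np.asarray(rv_mask, dtype=bool)
    sternum_mask = np.asarray(sternum_mask, dtype=bool)
    if rv_mask.shape != sternum_mask.shape:
        raise ValueError(
            f"mask shapes differ: {rv_mask.shape} vs {sternum_mask.shape}"
        )
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if not sternum_mask.any():
        return rv_mask.copy()
    dist = ndimage.distance_transform_edt(~sternum_mask, sampling=spacing_mm)
    return rv_mask & (dist > margin_mm)
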