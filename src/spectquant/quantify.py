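"""Measurement core: decay correction, SUV, isocontour segmentation, burden.

Uptake is expressed as a standardized uptake value (SUV): the decay-corrected
tissue concentration divided by injected activity per kilogram body weight.
No camera/well-counter cross-calibration is applied, so SUVs carry an unknown
but consistent scale factor; all derived quantities inherit it.

Per anatomical VOI, voxels at or above a fraction (default 42 %) of that
VOI's maximum define the segmentation volume.  Mean and max uptake are taken
over the segmented set, and the compound burden score is

    burden = mean_uptake_over_segmented_set * segmented_volume_ml
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import voi_model
from .volume_io import (
    APEX,
    BASE_REGIONS,
    IVS,
    LV_LATERAL,
    RV_FREE_WALL,
    STERNUM,
    AcquisitionMeta,
    RegionMaskSet,
    VoxelVolume,
)

DEFAULT_FRACTION = 0.42

#: Region order of the standard per-study output table.
REPORT_REGIONS = (
    LV_LATERAL,
    IVS,
    APEX,
    RV_FREE_WALL,
    voi_model.LV,
    voi_model.VENTRICLES,
)

METRIC_COLUMNS = (
    "region",
    "dpd_mean",
    "dpd_max",
    "v42_ml",
    "dpd_load",
    "n_voxels_anatomical",
    "n_voxels_thresholded",
)


@dataclass(frozen=True)
class UptakeMetrics:
    """Per-region quantification row: mean/max SUV, segmented volume, burden."""

    region: str
    dpd_mean: float
    dpd_max: float
    v42_ml: float
    dpd_load: float
    n_voxels_anatomical: int
    n_voxels_thresholded: int

    def __post_init__(self) -> None:
        if self.n_voxels_thresholded > self.n_voxels_anatomical:
            raise ValueError("thresholded voxel count exceeds anatomical count")
        if self.dpd_mean < 0 or self.dpd_max < self.dpd_mean - 1e-12:
            raise ValueError("require dpd_max >= dpd_mean >= 0")


@dataclass(frozen=True)
class SparingResult:
    """An apical-sparing ratio; the flag is defined for the echo variant only."""

    ratio: float
    sparing_flag: bool | None = None


def decay_correct(value: float | np.ndarray, meta: AcquisitionMeta) -> float | np.ndarray:
    """Correct measured uptake back to injection time.

    Multiplies by ``2 ** (delay / half_life)`` where delay is the
    injection-to-acquisition interval in hours.
    """
    return value * 2.0 ** (meta.uptake_delay_h / meta.half_life_h)


def suv(concentration: float | np.ndarray, meta: AcquisitionMeta) -> float | np.ndarray:
    """Normalise a decay-corrected concentration by injected dose per kg."""
    return concentration / (meta.injected_activity_MBq / meta.body_weight_kg)


def suv_factor(meta: AcquisitionMeta) -> float:
    """Combined decay-correction and SUV scale applied to raw voxel values."""
    return float(decay_correct(suv(1.0, meta), meta))


def segment_isocontour(
    volume: VoxelVolume,
    voi: np.ndarray,
    fraction: float = DEFAULT_FRACTION,
) -> np.ndarray:
    """Voxels of *voi* at or above ``fraction`` of the VOI maximum.

    The maximum is taken per-VOI, and the comparison is inclusive, so the
    maximum voxel is always retained and the result is never empty.  An
    all-zero VOI is degenerate (threshold 0): the full VOI is returned with a
    warning.
    """
    voi = np.asarray(voi, dtype=bool)
    if voi.shape != volume.shape:
        raise ValueError(f"VOI shape {voi.shape} != volume shape {volume.shape}")
    if not voi.any():
        raise ValueError("VOI is empty")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    vmax = float(volume.values[voi].max())
    if vmax == 0.0:
        warnings.warn(
            "VOI maximum is 0; isocontour threshold is degenerate, returning full VOI",
            stacklevel=2,
        )
        return voi.copy()
    return voi & (volume.values >= fraction * vmax)


def region_metrics(
    volume: VoxelVolume,
    voi: np.ndarray,
    meta: AcquisitionMeta,
    fraction: float = DEFAULT_FRACTION,
    region: str = "",
) -> UptakeMetrics:
    """Quantify one VOI: isocontour-segment, then mean/max SUV, volume, burden.

    *volume* holds raw concentrations; decay correction and SUV normalisation
    are applied internally (both are scalar multiplications, so their order is
    immaterial and does not affect the segmented set).
    """
    segmented = segment_isocontour(volume, voi, fraction)
    factor = suv_factor(meta)
    vals = volume.values[segmented]
    # exactly-rounded sum (order independent), scaled after reduction: keeps
    # results bit-reproducible across voxel orderings and exact on uniform VOIs
    dpd_mean = math.fsum(vals) / vals.size * factor
    dpd_max = float(vals.max()) * factor
    n_thr = int(segmented.sum())
    v42_ml = n_thr * volume.voxel_volume_ml
    return UptakeMetrics(
        region=region,
        dpd_mean=dpd_mean,
        dpd_max=dpd_max,
        v42_ml=v42_ml,
        dpd_load=dpd_mean * v42_ml,
        n_voxels_anatomical=int(np.asarray(voi, dtype=bool).sum()),
        n_voxels_thresholded=n_thr,
    )


def apical_sparing_dpd(
    apex_mean: float, ivs_mean: float, lateral_mean: float
) -> SparingResult:
    """Uptake-based apical sparing: apex / mean(septum, lateral wall).

    No cut-off flag is defined for the uptake variant.
    """
    denom = (ivs_mean + lateral_mean) / 2.0
    if denom <= 0:
        raise ValueError(f"denominator (IVS+lateral)/2 must be > 0, got {denom}")
    if apex_mean < 0:
        raise ValueError("apex uptake must be >= 0")
    return SparingResult(ratio=apex_mean / denom, sparing_flag=None)


def apical_sparing_echo(
    apical_avg: float, basal_avg: float, mid_avg: float
) -> SparingResult:
    """Strain-based apical sparing: apical / (basal + mid), flag at ratio > 1.

    Strains are signed (longitudinal strain is negative); the ratio of two
    negative quantities is positive.  The flag uses a strict > 1 cut-off.
    """
    denom = basal_avg + mid_avg
    if denom == 0:
        raise ValueError("basal + mid strain sum is zero")
    ratio = apical_avg / denom
    return SparingResult(ratio=ratio, sparing_flag=bool(ratio > 1.0))


def quantify_study(
    volume: VoxelVolume,
    masks: RegionMaskSet,
    meta: AcquisitionMeta,
    fraction: float = DEFAULT_FRACTION,
    sternum_margin_mm: float = voi_model.DEFAULT_STERNUM_MARGIN_MM,
) -> pd.DataFrame:
    """Quantify all six report regions of one study into a table.

    The RV free wall is trimmed by the sternum exclusion border when a
    non-empty sternum mask is present.  Merged regions are thresholded as a
    whole (a single per-VOI maximum governs each).
    """
    masks.check_congruent(volume)
    vois: dict[str, np.ndarray] = {}
    for name in (LV_LATERAL, IVS, APEX):
        vois[name] = masks.mask(name)
    rv = masks.mask(RV_FREE_WALL)
    if STERNUM in masks.label_map:
        sternum = masks.mask(STERNUM)
        rv = voi_model.exclude_sternum_spillover(
            rv, sternum, masks.spacing_mm, sternum_margin_mm
        )
    vois[RV_FREE_WALL] = rv
    lv = vois[LV_LATERAL] | vois[IVS] | vois[APEX]
    vois[voi_model.LV] = lv
    vois[voi_model.VENTRICLES] = lv | rv

    rows = []
    for name in REPORT_REGIONS:
        m = region_metrics(volume, vois[name], meta, fraction, region=name)
        rows.append({c: getattr(m, c) for c in METRIC_COLUMNS})
    return pd.DataFrame(rows, columns=list(METRIC_COLUMNS))
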