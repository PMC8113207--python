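from datetime import datetime, timedelta

import numpy as np
import pytest

from spectquant import AcquisitionMeta, VoxelVolume

T0 = datetime(2020, 1, 1, 9, 0, 0)


def make_meta(
    dose=740.0, weight=74.6, delay_h=3.0, half_life_h=6.0067
) -> AcquisitionMeta:
    return AcquisitionMeta(
        injected_activity_MBq=dose,
        injection_time=T0,
        acquisition_time=T0 + timedelta(hours=delay_h),
        body_weight_kg=weight,
        half_life_h=half_life_h,
    )


@pytest.fixture
def meta_3h() -> AcquisitionMeta:
    """Published-protocol-style metadata: 740 MBq, 3 h delay, 74.6 kg."""
    return make_meta()


@pytest.fixture
def meta_identity() -> AcquisitionMeta:
    """Metadata under which raw values pass through unchanged (delay 0, dose == weight)."""
    return make_meta(dose=70.0, weight=70.0, delay_h=0.0)


def make_volume(values, spacing=(4.42, 4.42, 4.42)) -> VoxelVolume:
    return VoxelVolume(values=np.asarray(values, dtype=float), spacing_mm=spacing)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
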