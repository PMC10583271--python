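import numpy as np
import pytest

from nusbench import (
    AcquisitionScheme,
    ChallengeConfig,
    DimensionProcessing,
    DimensionSpec,
    PeakTable,
    SyntheticPeak,
)


@pytest.fixture
def acq2d() -> AcquisitionScheme:
    """2D experiment: 64-point 1H direct, 64-point 15N indirect."""
    return AcquisitionScheme(dims=(
        DimensionSpec(64, 6400.0, 600.0, 8.0, "1H"),
        DimensionSpec(64, 1600.0, 60.0, 118.0, "15N"),
    ))


@pytest.fixture
def acq3d() -> AcquisitionScheme:
    """Small 3D HNCA-style experiment."""
    return AcquisitionScheme(dims=(
        DimensionSpec(32, 6400.0, 600.0, 8.0, "1H"),
        DimensionSpec(16, 1600.0, 60.0, 118.0, "15N"),
        DimensionSpec(20, 4000.0, 150.0, 55.0, "13C"),
    ))


def plain_processing(acq: AcquisitionScheme) -> tuple[DimensionProcessing, ...]:
    """No apodization, no zero fill, no first-point scaling: pure DFT."""
    return tuple(
        DimensionProcessing(apod_power=0, zero_fill=0, first_point_scale=1.0)
        for _ in acq.dims
    )


@pytest.fixture
def config2d_plain(acq2d) -> ChallengeConfig:
    return ChallengeConfig(experiment="toy2d", acq=acq2d, processing=plain_processing(acq2d))


@pytest.fixture
def config3d_plain(acq3d) -> ChallengeConfig:
    return ChallengeConfig(experiment="toy3d", acq=acq3d, processing=plain_processing(acq3d))


def single_peak_table(acq: AcquisitionScheme, freq_hz, decay_hz=None,
                      amplitude: float = 1.0) -> PeakTable:
    nd = acq.ndim
    decay = tuple(decay_hz) if decay_hz is not None else (0.0,) * nd
    peak = SyntheticPeak(
        amplitude=amplitude,
        freq_hz=tuple(freq_hz),
        decay_hz=decay,
        phase_deg=(0.0,) * nd,
        couplings_hz=((),) * nd,
    )
    return PeakTable(peaks=[peak])
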