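"""Spectral processing (DFT chain) and IST reconstruction of NUS data.

Processing chain per dimension: first-point scaling, cosine-power
apodization, zero filling, discrete Fourier transform, phase correction.
Hypercomplex components are combined per the States convention: each
dimension's quadrature pair forms a complex interferogram, is transformed,
and only the real part is carried into the next dimension.  Spectral axes
are ordered high-to-low frequency.

Iterative soft thresholding (IST) operates per direct-frequency plane on
the indirect grid.  The hypercomplex indirect components are mapped to an
equivalent set of complex grids (a bijection: R+iI for one indirect
dimension; the P/N-type pair for two).  Each iteration transforms the grid
estimate to the frequency domain, soft-thresholds at a decreasing fraction
of the current maximum, transforms back, and restores the measured values
at scheduled indels.  The two exit variants differ in the last step taken:
``data_replacement`` exits after the restore (the reconstruction then
matches the measured NUS data exactly at every scheduled indel), while
``post_threshold`` exits after the thresholding step.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_model import (
    AcquisitionScheme,
    AxisCalibration,
    ChallengeConfig,
    ConfigError,
    DimensionError,
    DimensionProcessing,
    NusbenchError,
    Spectrum,
    TimeDomainData,
    read_spectrum,
)
from .sampling import NUSData, SampleSchedule

__all__ = [
    "IstParams",
    "IstResult",
    "SizeCheck",
    "ScriptError",
    "ValidationError",
    "NumericError",
    "ParameterError",
    "process_dft",
    "reconstruct_ist",
    "run_external_reconstruction",
    "check_spectrum_size",
    "next_power_of_two",
]

MAX_ZERO_FILLS = 3  # contest size rule: next Fourier number and 3 zero fills


class ScriptError(NusbenchError):
    """An external reconstruction script failed."""


class ValidationError(NusbenchError):
    """An external reconstruction produced an invalid spectrum."""


class NumericError(NusbenchError):
    """Non-finite values encountered where finite data are required."""


class ParameterError(NusbenchError):
    """An algorithm parameter is out of its valid range."""


# ---------------------------------------------------------------------------
# Per-dimension processing primitives
# ---------------------------------------------------------------------------

def _apodize(x: np.ndarray, axis: int, n_signal: int, proc: DimensionProcessing) -> np.ndarray:
    """First-point scaling and cosine-power window along one axis."""
    w = np.ones(n_signal)
    if proc.apod_power > 0 and n_signal > 1:
        k = np.arange(n_signal)
        w = np.cos(np.pi * k / (2.0 * (n_signal - 1))) ** proc.apod_power
    w[0] *= proc.first_point_scale
    shape = [1] * x.ndim
    shape[axis] = n_signal
    return x * w.reshape(shape)


def _transform(x: np.ndarray, axis: int, n_signal: int, proc: DimensionProcessing
               ) -> tuple[np.ndarray, int]:
    """Zero fill, FFT, shift to high-to-low frequency order, phase."""
    n_fft = n_signal * (2 ** proc.zero_fill)
    pad = [(0, 0)] * x.ndim
    pad[axis] = (0, n_fft - x.shape[axis])
    x = np.pad(x, pad)
    spec = np.fft.fftshift(np.fft.fft(x, axis=axis), axes=axis)
    spec = np.flip(spec, axis=axis)
    if proc.p0_deg or proc.p1_deg:
        b = np.arange(n_fft) / max(n_fft - 1, 1)
        phase = np.exp(1j * np.deg2rad(proc.p0_deg + proc.p1_deg * b))
        shape = [1] * spec.ndim
        shape[axis] = n_fft
        spec = spec * phase.reshape(shape)
    return spec, n_fft


def _axis_calibration(dim, n_fft: int, label_from_dim: bool = True) -> AxisCalibration:
    df = dim.sw_hz / n_fft
    first = (n_fft - 1 - n_fft // 2) * df
    return AxisCalibration(size=n_fft, first_point_hz=first, hz_per_point=df,
                           obs_mhz=dim.obs_mhz, carrier_ppm=dim.carrier_ppm,
                           label=dim.label)


def _roi_slice(axis_cal: AxisCalibration, roi_ppm: tuple[float, float] | None
               ) -> tuple[slice, AxisCalibration]:
    if roi_ppm is None:
        return slice(None), axis_cal
    lo, hi = sorted(roi_ppm)
    ppm = np.asarray(axis_cal.ppm(np.arange(axis_cal.size)))
    inside = np.nonzero((ppm >= lo) & (ppm <= hi))[0]
    if inside.size == 0:
        raise ConfigError(f"direct ROI {roi_ppm} selects no points")
    start, stop = int(inside[0]), int(inside[-1]) + 1
    new_cal = AxisCalibration(
        size=stop - start,
        first_point_hz=float(axis_cal.hz(start)),
        hz_per_point=axis_cal.hz_per_point,
        obs_mhz=axis_cal.obs_mhz,
        carrier_ppm=axis_cal.carrier_ppm,
        label=axis_cal.label,
    )
    return slice(start, stop), new_cal


# ---------------------------------------------------------------------------
# Hypercomplex bookkeeping
# ---------------------------------------------------------------------------

def _indirect_dim_indices(acq: AcquisitionScheme) -> list[int]:
    return [i for i in range(acq.ndim) if i != acq.direct_dim]


def _compact_components(values: np.ndarray, acq: AcquisitionScheme) -> np.ndarray:
    """Complex direct-dimension FIDs per indirect quadrature state.

    Input: (2^D, direct, ...).  Output: complex (2^Dind, direct, ...) where
    compact bit j corresponds to the j-th indirect dimension.
    """
    ind = _indirect_dim_indices(acq)
    direct_bit = 1 << acq.direct_dim
    n_ind = len(ind)
    out = np.empty((2 ** n_ind,) + values.shape[1:], dtype=np.complex128)
    for m in range(2 ** n_ind):
        full = sum(((m >> j) & 1) << ind[j] for j in range(n_ind))
        out[m] = values[full] + 1j * values[full | direct_bit]
    return out


def _states_indirect(planes: np.ndarray, acq: AcquisitionScheme, config: ChallengeConfig
                     ) -> tuple[np.ndarray, list[AxisCalibration]]:
    """States processing of all indirect dimensions.

    ``planes``: real array (2^Dind, direct_points, ind_1, ind_2, ...) after
    direct-dimension processing.  Returns the final real spectrum
    (direct, F_ind1, ...) and indirect axis calibrations.
    """
    ind = _indirect_dim_indices(acq)
    axes_cal: list[AxisCalibration] = []
    current = planes
    n_ind = len(ind)
    for j, dim_i in enumerate(ind):
        dim = acq.dims[dim_i]
        proc = config.processing[dim_i]
        axis = 2 + j  # component axis 0, direct axis 1
        # compact bit 0 is consumed each round: even component indices are
        # the cosine (R) half for this dimension, odd the sine (I) half.
        re = current[0::2]
        im = current[1::2]
        cplx = _apodize(re + 1j * im, axis, dim.n_points, proc)
        spec, n_fft = _transform(cplx, axis, dim.n_points, proc)
        axes_cal.append(_axis_calibration(dim, n_fft))
        current = spec.real
    return current[0], axes_cal


def process_dft(fid: TimeDomainData, config: ChallengeConfig) -> Spectrum:
    """Fourier-process full-grid time-domain data into a real spectrum."""
    acq = fid.acq
    if config.acq.to_dict() != acq.to_dict():
        raise ConfigError("config acquisition scheme does not match the data")
    gd = acq.group_delay_points
    cplx = _compact_components(fid.values, acq)[:, gd:]
    direct_spec, direct_cal, roi = _process_direct(cplx, acq, config)
    values, ind_cal = _states_indirect(direct_spec, acq, config)
    provenance = {
        "direct_size_pre_roi": direct_cal[0],
        "processing": "dft",
    }
    return Spectrum(values=values, axes=(direct_cal[1], *ind_cal), provenance=provenance)


def _process_direct(cplx: np.ndarray, acq: AcquisitionScheme, config: ChallengeConfig
                    ) -> tuple[np.ndarray, tuple[int, AxisCalibration], slice]:
    """Direct-dimension chain on compact complex FIDs; returns real planes."""
    dim = acq.direct
    proc = config.processing[acq.direct_dim]
    x = _apodize(cplx, 1, dim.n_points, proc)
    spec, n_fft = _transform(x, 1, dim.n_points, proc)
    cal = _axis_calibration(dim, n_fft)
    roi, cal_roi = _roi_slice(cal, config.direct_roi_ppm)
    return spec.real[:, roi], (n_fft, cal_roi), roi


# ---------------------------------------------------------------------------
# Hypercomplex <-> complex grids (bijective, per direct-frequency plane)
# ---------------------------------------------------------------------------

def _to_complex_grids(x: np.ndarray, n_ind: int) -> np.ndarray:
    """Real (2^Dind, ...) -> complex (2^(Dind-1), ...) without information loss."""
    if n_ind == 1:
        return (x[0] + 1j * x[1])[None]
    if n_ind == 2:
        rr, ir, ri, ii = x[0], x[1], x[2], x[3]
        z1 = (rr - ii) + 1j * (ir + ri)
        z2 = (rr + ii) + 1j * (ir - ri)
        return np.stack([z1, z2])
    raise DimensionError(f"IST supports 1 or 2 indirect dimensions, got {n_ind}")


def _from_complex_grids(z: np.ndarray, n_ind: int) -> np.ndarray:
    if n_ind == 1:
        return np.stack([z[0].real, z[0].imag])
    rr = (z[0].real + z[1].real) / 2.0
    ii = (z[1].real - z[0].real) / 2.0
    ir = (z[0].imag + z[1].imag) / 2.0
    ri = (z[0].imag - z[1].imag) / 2.0
    return np.stack([rr, ir, ri, ii])


# ---------------------------------------------------------------------------
# IST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IstParams:
    """IST controls: iteration budget, threshold schedule, exit variant.

    The threshold at iteration i is ``f_i * max|F|`` with ``f_i`` decaying
    geometrically from ``threshold_start`` to ``threshold_floor`` over the
    budget and ``max|F|`` the current per-plane frequency-domain maximum.
    """

    iterations: int = 200
    threshold_start: float = 0.99
    threshold_floor: float = 0.01
    exit_mode: str = "data_replacement"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ParameterError("iterations must be >= 1")
        if self.exit_mode not in ("data_replacement", "post_threshold"):
            raise ParameterError(f"unknown exit_mode {self.exit_mode!r}")
        if not (0.0 <= self.threshold_floor <= self.threshold_start <= 1.0):
            raise ParameterError("need 0 <= threshold_floor <= threshold_start <= 1")

    def fractions(self) -> np.ndarray:
        n = self.iterations
        if self.threshold_start == 0.0:
            return np.zeros(n)
        floor = max(self.threshold_floor, 1e-12)
        if n == 1:
            return np.array([self.threshold_start])
        return self.threshold_start * (floor / self.threshold_start) ** (np.arange(n) / (n - 1))


@dataclass
class IstResult:
    """IST output: the processed spectrum plus the raw reconstruction.

    ``freq_grids``/``time_grids`` are the complex indirect-grid arrays the
    iteration worked on, shaped (n_grids, direct_points, *indirect_grid);
    ``measured`` holds the measured complex values in schedule order.
    """

    spectrum: Spectrum
    freq_grids: np.ndarray
    time_grids: np.ndarray
    measured: np.ndarray
    schedule: SampleSchedule


def _soft_threshold(f: np.ndarray, tau: np.ndarray) -> np.ndarray:
    mag = np.abs(f)
    scale = np.maximum(0.0, 1.0 - tau / np.maximum(mag, 1e-300))
    return f * scale


def reconstruct_ist(nus: NUSData, schedule: SampleSchedule | None = None,
                    config: ChallengeConfig | None = None,
                    params: IstParams = IstParams()) -> IstResult:
    """Reconstruct a spectrum from NUS data by iterative soft thresholding."""
    if config is None:
        raise ConfigError("reconstruct_ist requires a ChallengeConfig")
    schedule = nus.schedule if schedule is None else schedule
    if not np.all(np.isfinite(nus.values)):
        raise NumericError("NUS data contain non-finite values")
    acq = nus.acq
    n_ind = acq.ndim - 1
    grid = acq.indirect_grid

    gd = acq.group_delay_points
    cplx = _compact_components(nus.values, acq)[:, gd:]
    planes, (direct_pre_roi, direct_cal), _ = _process_direct(cplx, acq, config)
    # planes: real (2^Dind, direct_roi, n_indels)
    measured = _to_complex_grids(planes, n_ind)  # (n_grids, direct_roi, n_indels)

    idx = schedule.index_arrays()
    restore_index = (slice(None), slice(None)) + idx
    grid_axes = tuple(range(2, 2 + n_ind))

    z = np.zeros(measured.shape[:2] + grid, dtype=np.complex128)
    z[restore_index] = measured
    fractions = params.fractions()
    f_thresh = np.fft.fftn(z, axes=grid_axes)
    for frac in fractions:
        f = np.fft.fftn(z, axes=grid_axes)
        current_max = np.abs(f).max(axis=grid_axes, keepdims=True)
        f_thresh = _soft_threshold(f, frac * current_max)
        z = np.fft.ifftn(f_thresh, axes=grid_axes)
        z[restore_index] = measured

    if params.exit_mode == "data_replacement":
        time_grids = z
        freq_grids = np.fft.fftn(z, axes=grid_axes)
    else:  # post_threshold: exit after the thresholding step
        freq_grids = f_thresh
        time_grids = np.fft.ifftn(freq_grids, axes=grid_axes)

    hyper = _from_complex_grids(time_grids, n_ind)  # (2^Dind, direct_roi, *grid)
    values, ind_cal = _states_indirect(hyper, acq, config)
    spectrum = Spectrum(
        values=values,
        axes=(direct_cal, *ind_cal),
        provenance={
            "direct_size_pre_roi": direct_pre_roi,
            "processing": f"ist:{params.exit_mode}",
            "iterations": params.iterations,
        },
    )
    return IstResult(spectrum=spectrum, freq_grids=freq_grids,
                     time_grids=time_grids, measured=measured, schedule=schedule)


# ---------------------------------------------------------------------------
# Contest size rule
# ---------------------------------------------------------------------------

def next_power_of_two(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


@dataclass(frozen=True)
class SizeCheck:
    passed: bool
    sizes: tuple[int, ...]
    limits: tuple[int, ...]


def check_spectrum_size(spectrum: Spectrum, acq: AcquisitionScheme) -> SizeCheck:
    """Enforce the contest rule: each spectral dimension may not exceed the
    next power of two of its acquisition size times 2**3 (three zero fills).

    The direct dimension is measured before region-of-interest extraction
    (its pre-ROI size is read from the spectrum provenance when present).
    The boundary is inclusive: a size exactly at the limit passes.
    """
    order = [acq.direct_dim] + _indirect_dim_indices(acq)
    sizes = list(spectrum.shape)
    pre_roi = spectrum.provenance.get("direct_size_pre_roi")
    if pre_roi is not None:
        sizes[0] = int(pre_roi)
    limits = tuple(next_power_of_two(acq.dims[i].n_points) * 2 ** MAX_ZERO_FILLS
                   for i in order)
    if len(sizes) != len(limits):
        raise DimensionError("spectrum rank does not match acquisition rank")
    return SizeCheck(
        passed=all(s <= l for s, l in zip(sizes, limits)),
        sizes=tuple(sizes),
        limits=limits,
    )


# ---------------------------------------------------------------------------
# External reconstruction scripts
# ---------------------------------------------------------------------------

def run_external_reconstruction(script, nus_file, schedule_file, config_file,
                                workdir, acq: AcquisitionScheme,
                                timeout: float | None = None) -> Spectrum:
    """Run a contestant script and load its spectrum.

    Contract: the script is invoked as
    ``<script> <nus_file> <schedule_file> <config_file> <output_spectrum>``
    inside ``workdir``; stdout/stderr are captured to ``workdir/script.log``.
    A nonzero exit raises :class:`ScriptError`; a missing output or one
    violating the size rule raises :class:`ValidationError`.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    out_path = workdir / "spectrum.nusb"
    cmd = [str(script), str(nus_file), str(schedule_file), str(config_file), str(out_path)]
    result = subprocess.run(cmd, cwd=workdir, capture_output=True, text=True,
                            timeout=timeout)
    (workdir / "script.log").write_text(
        f"$ {' '.join(cmd)}\n--- stdout ---\n{result.stdout}\n--- stderr ---\n{result.stderr}\n"
    )
    if result.returncode != 0:
        raise ScriptError(
            f"{script} exited {result.returncode}; log at {workdir / 'script.log'}"
        )
    if not out_path.exists():
        raise ValidationError(f"{script} produced no output spectrum at {out_path}")
    spectrum = read_spectrum(out_path)
    check = check_spectrum_size(spectrum, acq)
    if not check.passed:
        raise ValidationError(
            f"spectrum size {check.sizes} exceeds limits {check.limits}"
        )
    return spectrum
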