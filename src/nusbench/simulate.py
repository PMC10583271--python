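"""Synthetic time-domain simulation and injection into reference data.

A synthetic peak contributes a separable product over dimensions.  Along
dimension ``d`` at 0-based grid index ``k`` (evolution time ``t = k/sw``)
the two quadrature factors are::

    R: env(t) * cos(2*pi*nu*t + phi)
    I: env(t) * sin(2*pi*nu*t + phi)

with ``env(t) = exp(-pi * decay_hz * t) * prod_J cos(pi * J * t)``.  The
hypercomplex component with bitmask ``c`` takes the R or I factor per
dimension according to its bits, and the peak amplitude multiplies the whole
product.  Contributions sum over peaks, so simulation is linear in the table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import (
    AcquisitionScheme,
    ConfigError,
    DimensionError,
    PeakTable,
    SyntheticPeak,
    TimeDomainData,
)

__all__ = ["SolventSpec", "simulate_fid", "add_solvent", "inject", "make_synthetic_reference"]


@dataclass(frozen=True)
class SolventSpec:
    """Synthetic solvent signal of fixed width with per-vector random draws.

    One decaying signal is added to every 1D direct-dimension vector; its
    amplitude, phase, and frequency are drawn uniformly within the stated
    bounds, independently per vector.
    """

    width_hz: float
    amp_bounds: tuple[float, float]
    phase_bounds_deg: tuple[float, float] = (0.0, 0.0)
    freq_bounds_hz: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.width_hz <= 0:
            raise ConfigError("solvent width_hz must be > 0")
        for name in ("amp_bounds", "phase_bounds_deg", "freq_bounds_hz"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"solvent {name} must be ordered (low <= high)")


def _direct_times(acq: AcquisitionScheme) -> tuple[np.ndarray, np.ndarray]:
    """Evolution times along the direct axis and a validity mask.

    Group-delay placeholder points occupy indices < group_delay_points and
    carry no signal (zero); time is measured from the first real point.
    """
    gd = acq.group_delay_points
    k = np.arange(acq.n_direct_total)
    t = (k - gd) / acq.direct.sw_hz
    valid = k >= gd
    return t, valid


def _dim_factors(peak: SyntheticPeak, d: int, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(cosine, sine) quadrature vectors of one peak along one dimension."""
    env = np.exp(-np.pi * peak.decay_hz[d] * t)
    for j in peak.couplings_hz[d]:
        env = env * np.cos(np.pi * j * t)
    arg = 2.0 * np.pi * peak.freq_hz[d] * t + np.deg2rad(peak.phase_deg[d])
    return env * np.cos(arg), env * np.sin(arg)


def simulate_fid(table: PeakTable, acq: AcquisitionScheme) -> TimeDomainData:
    """Simulate hypercomplex time-domain data for a synthetic peak table."""
    if table.peaks and table.ndim != acq.ndim:
        raise DimensionError(
            f"peak table is {table.ndim}-D but acquisition is {acq.ndim}-D"
        )
    shape = (acq.n_components, acq.n_direct_total) + acq.indirect_grid
    values = np.zeros(shape, dtype=np.float64)

    t_direct, valid = _direct_times(acq)
    indirect_idx = [i for i in range(acq.ndim) if i != acq.direct_dim]

    for peak in table.peaks:
        # factors[j] = (cos_vec, sin_vec) for dimension slot j of the array
        # layout (slot 0 = direct axis, then indirect axes in order).
        cd, sd = _dim_factors(peak, acq.direct_dim, t_direct)
        cd, sd = np.where(valid, cd, 0.0), np.where(valid, sd, 0.0)
        factors = [(cd, sd)]
        for dim_i in indirect_idx:
            t = acq.dims[dim_i].times()
            factors.append(_dim_factors(peak, dim_i, t))

        for c in range(acq.n_components):
            # bit j of the component selects sine along dimension j, where
            # dimension order is (direct, indirect...) matching array axes.
            contrib = np.float64(peak.amplitude)
            for slot, (cos_v, sin_v) in enumerate(factors):
                vec = sin_v if (c >> _bit_for_slot(slot, acq)) & 1 else cos_v
                contrib = np.multiply.outer(contrib, vec)
            values[c] += contrib
    return TimeDomainData(values=values, acq=acq)


def _bit_for_slot(slot: int, acq: AcquisitionScheme) -> int:
    """Component bit index for array-axis slot (0=direct, then indirect)."""
    if slot == 0:
        return acq.direct_dim
    indirect = [i for i in range(acq.ndim) if i != acq.direct_dim]
    return indirect[slot - 1]


def add_solvent(fid: TimeDomainData, spec: SolventSpec, seed: int) -> TimeDomainData:
    """Add one random decaying signal to every direct-dimension vector.

    Each complex FID (one per indirect quadrature state and indirect grid
    point) receives a signal of fixed linewidth ``spec.width_hz`` whose
    amplitude, phase, and frequency are drawn uniformly within bounds from a
    generator seeded by ``seed``; the result is deterministic given the seed.
    """
    acq = fid.acq
    rng = np.random.default_rng(seed)
    out = fid.values.copy()
    t, valid = _direct_times(acq)
    env = np.where(valid, np.exp(-np.pi * spec.width_hz * np.where(valid, t, 0.0)), 0.0)

    direct_bit = acq.direct_dim
    n_comp = acq.n_components
    # Components with direct bit clear are the R half; pairing c -> c|direct
    # gives the matching I component of the same FID.
    r_components = [c for c in range(n_comp) if not (c >> direct_bit) & 1]
    grid_shape = acq.indirect_grid

    for c_r in r_components:
        c_i = c_r | (1 << direct_bit)
        for flat in range(int(np.prod(grid_shape)) if grid_shape else 1):
            idx = np.unravel_index(flat, grid_shape) if grid_shape else ()
            amp = rng.uniform(*spec.amp_bounds)
            phase = np.deg2rad(rng.uniform(*spec.phase_bounds_deg))
            freq = rng.uniform(*spec.freq_bounds_hz)
            if amp == 0.0:
                continue
            arg = 2.0 * np.pi * freq * t + phase
            out[(c_r, slice(None)) + idx] += amp * env * np.cos(arg)
            out[(c_i, slice(None)) + idx] += amp * env * np.sin(arg)
    return TimeDomainData(values=out, acq=acq)


def inject(reference: TimeDomainData, synthetic: TimeDomainData) -> TimeDomainData:
    """Element-wise sum of synthetic signals into reference time-domain data."""
    if reference.acq != synthetic.acq:
        raise DimensionError("reference and synthetic acquisition schemes differ")
    if reference.values.shape != synthetic.values.shape:
        raise DimensionError(
            f"shape mismatch {reference.values.shape} vs {synthetic.values.shape}"
        )
    return TimeDomainData(values=reference.values + synthetic.values, acq=reference.acq)


def make_synthetic_reference(
    acq: AcquisitionScheme,
    n_peaks: int,
    seed: int,
    amp_range: tuple[float, float] = (0.5, 2.0),
    decay_range_hz: tuple[float, float] = (10.0, 40.0),
    noise_sigma: float = 0.05,
) -> tuple[TimeDomainData, PeakTable]:
    """Generate a stand-in reference experiment: random peaks plus noise.

    Emulates a uniformly sampled measured data set for self-contained runs:
    ``n_peaks`` random signals on the grid with Gaussian thermal noise of
    standard deviation ``noise_sigma`` on every hypercomplex point.
    """
    rng = np.random.default_rng(seed)
    peaks = []
    for _ in range(n_peaks):
        freq = tuple(rng.uniform(-0.4, 0.4) * d.sw_hz for d in acq.dims)
        decay = tuple(rng.uniform(*decay_range_hz) for _ in acq.dims)
        peaks.append(SyntheticPeak(
            amplitude=float(rng.uniform(*amp_range)),
            freq_hz=freq,
            decay_hz=decay,
            phase_deg=tuple(0.0 for _ in acq.dims),
            couplings_hz=tuple(() for _ in acq.dims),
        ))
    table = PeakTable(peaks=peaks)
    fid = simulate_fid(table, acq)
    noisy = fid.values + rng.normal(0.0, noise_sigma, size=fid.values.shape)
    return TimeDomainData(values=noisy, acq=acq), table
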