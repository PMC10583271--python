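"""Spectrum characterization: noise, peak detection, empty-region mask.

Peak detection finds strict local maxima over face-adjacent neighbors and
refines each by a separable per-axis parabolic fit through the maximum and
its two neighbors; results are sorted by interpolated height and truncated.

The empty-region mask marks points whose axis-aligned neighborhood of
half-width ceil(2 x median linewidth) per dimension contains no substantial
signal: neighborhood rms < 1.15 x noise and neighborhood max <= 5.0 x noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_model import RangeError, Spectrum

__all__ = [
    "PickedPeak",
    "EmptyMask",
    "estimate_noise",
    "detect_peaks",
    "build_empty_mask",
    "project_mask",
    "median_linewidths_hz",
]

RMS_FACTOR = 1.15   # neighborhood rms must stay below this multiple of noise
MAX_FACTOR = 5.0    # no neighborhood point may exceed this multiple of noise


@dataclass(frozen=True)
class PickedPeak:
    """A detected local maximum with parabolic refinement.

    ``position`` is the fractional grid coordinate per axis; ``position_hz``
    the corresponding Hz offsets from the carrier.  ``linewidth_hz`` entries
    are NaN where the curvature did not allow an estimate (edge maxima).
    """

    position: tuple[float, ...]
    position_hz: tuple[float, ...]
    height: float
    linewidth_hz: tuple[float, ...]


@dataclass
class EmptyMask:
    """Boolean signal-free map of a spectrum (True = empty neighborhood)."""

    values: np.ndarray
    neighborhood_halfwidths: tuple[int, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)


def estimate_noise(spectrum: Spectrum) -> float:
    """Robust noise sigma: 1.4826 x median absolute deviation about the median."""
    x = spectrum.values.ravel()
    if x.size == 0:
        raise RangeError("cannot estimate noise of an empty spectrum")
    mad = np.median(np.abs(x - np.median(x)))
    sigma = 1.4826 * mad
    if sigma == 0.0:
        warnings.warn("spectrum has no intensity variation; noise estimate is 0")
    return float(sigma)


def _strict_local_maxima(values: np.ndarray) -> np.ndarray:
    """Boolean map of points strictly greater than all face neighbors."""
    is_max = np.ones(values.shape, dtype=bool)
    for axis in range(values.ndim):
        lo = [slice(None)] * values.ndim
        hi = [slice(None)] * values.ndim
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        greater_next = np.ones(values.shape, dtype=bool)
        greater_prev = np.ones(values.shape, dtype=bool)
        greater_next[tuple(lo)] = values[tuple(lo)] > values[tuple(hi)]
        greater_prev[tuple(hi)] = values[tuple(hi)] > values[tuple(lo)]
        is_max &= greater_next & greater_prev
    return is_max


def _parabolic_refine(values: np.ndarray, peak_idx: tuple[int, ...]
                      ) -> tuple[list[float], float, list[float]]:
    """Per-axis 3-point parabola through the maximum.

    Returns (fractional offsets per axis, interpolated height, FWHM in
    points per axis; NaN where inestimable).  The height combines the
    per-axis vertex gains additively, exact for a separable quadratic bump.
    """
    offsets: list[float] = []
    widths: list[float] = []
    f0 = float(values[peak_idx])
    height = f0
    for axis in range(values.ndim):
        k = peak_idx[axis]
        if k == 0 or k == values.shape[axis] - 1:
            offsets.append(0.0)
            widths.append(float("nan"))
            continue
        idx_m = list(peak_idx); idx_m[axis] = k - 1
        idx_p = list(peak_idx); idx_p[axis] = k + 1
        fm, fp = float(values[tuple(idx_m)]), float(values[tuple(idx_p)])
        denom = fm - 2.0 * f0 + fp
        if denom >= 0.0:  # no concave curvature: keep the grid point
            offsets.append(0.0)
            widths.append(float("nan"))
            continue
        d = 0.5 * (fm - fp) / denom
        offsets.append(d)
        gain = -0.25 * (fm - fp) * d
        height += gain
        # FWHM of the fitted parabola relative to zero baseline
        a = 0.5 * denom
        h_axis = f0 + gain
        widths.append(2.0 * np.sqrt(max(h_axis, 0.0) / (-2.0 * a)) if h_axis > 0 else float("nan"))
    return offsets, height, widths


def detect_peaks(spectrum: Spectrum, threshold: float, max_peaks: int) -> list[PickedPeak]:
    """Detect, refine, and truncate the most intense local maxima.

    Local maxima strictly greater than all face-adjacent neighbors and above
    ``threshold`` are refined by per-axis parabolic interpolation, sorted by
    interpolated height descending, and truncated to ``max_peaks``.
    """
    if threshold < 0:
        raise RangeError("threshold must be >= 0")
    if max_peaks < 0:
        raise RangeError("max_peaks must be >= 0")
    values = spectrum.values
    mask = _strict_local_maxima(values) & (values > threshold)
    coords = np.argwhere(mask)
    peaks: list[PickedPeak] = []
    for idx in coords:
        idx_t = tuple(int(i) for i in idx)
        offsets, height, widths_pts = _parabolic_refine(values, idx_t)
        position = tuple(k + d for k, d in zip(idx_t, offsets))
        position_hz = tuple(float(ax.hz(p)) for ax, p in zip(spectrum.axes, position))
        linewidth_hz = tuple(
            w * abs(ax.hz_per_point) if np.isfinite(w) else float("nan")
            for w, ax in zip(widths_pts, spectrum.axes)
        )
        peaks.append(PickedPeak(position=position, position_hz=position_hz,
                                height=height, linewidth_hz=linewidth_hz))
    peaks.sort(key=lambda p: p.height, reverse=True)
    return peaks[:max_peaks]


def median_linewidths_hz(peaks: list[PickedPeak]) -> tuple[float, ...]:
    """Per-dimension median linewidth over detected peaks (NaNs ignored)."""
    if not peaks:
        raise RangeError("no peaks to take median linewidths over")
    ndim = len(peaks[0].linewidth_hz)
    medians = []
    for d in range(ndim):
        vals = np.array([p.linewidth_hz[d] for p in peaks])
        vals = vals[np.isfinite(vals)]
        medians.append(float(np.median(vals)) if vals.size else float("nan"))
    return tuple(medians)


def _box_sum(x: np.ndarray, halfwidths: tuple[int, ...]) -> np.ndarray:
    """Sum over axis-aligned boxes truncated at the edges (cumsum sweep)."""
    out = x.astype(np.float64)
    for axis, h in enumerate(halfwidths):
        if h == 0:
            continue
        c = np.cumsum(out, axis=axis)
        n = out.shape[axis]
        hi = np.minimum(np.arange(n) + h, n - 1)
        lo = np.arange(n) - h - 1
        upper = np.take(c, hi, axis=axis)
        lower = np.where(
            (lo >= 0).reshape([-1 if a == axis else 1 for a in range(out.ndim)]),
            np.take(c, np.maximum(lo, 0), axis=axis),
            0.0,
        )
        out = upper - lower
    return out


def build_empty_mask(spectrum: Spectrum, median_linewidths: tuple[float, ...],
                     sigma: float) -> EmptyMask:
    """Mark points whose +/-2-linewidth neighborhood is signal-free."""
    if sigma <= 0:
        raise RangeError("sigma must be > 0")
    if any(lw <= 0 or not np.isfinite(lw) for lw in median_linewidths):
        raise RangeError("median linewidths must be positive and finite")
    values = spectrum.values
    halfwidths = tuple(
        int(np.ceil(2.0 * lw / abs(ax.hz_per_point)))
        for lw, ax in zip(median_linewidths, spectrum.axes)
    )
    if any(2 * h + 1 > n for h, n in zip(halfwidths, values.shape)):
        warnings.warn("neighborhood exceeds spectrum extent; mask set to all zeros")
        return EmptyMask(values=np.zeros(values.shape, dtype=bool),
                         neighborhood_halfwidths=halfwidths)
    sq_sum = _box_sum(values ** 2, halfwidths)
    counts = _box_sum(np.ones_like(values), halfwidths)
    rms = np.sqrt(sq_sum / counts)
    local_max = ndimage.maximum_filter(
        values, size=tuple(2 * h + 1 for h in halfwidths), mode="constant", cval=-np.inf
    )
    mask = (rms < RMS_FACTOR * sigma) & (local_max <= MAX_FACTOR * sigma)
    return EmptyMask(values=mask, neighborhood_halfwidths=halfwidths)


def project_mask(mask: EmptyMask, drop_axis: int) -> np.ndarray:
    """AND-project a 3D mask along one axis.

    A projected position is empty only if it is empty at every position
    along the dropped axis (no substantial signal anywhere in 3D).
    """
    if mask.values.ndim != 3:
        raise RangeError("project_mask requires a 3D mask")
    if not (0 <= drop_axis < 3):
        raise RangeError(f"drop_axis {drop_axis} invalid for a 3D mask")
    return np.all(mask.values, axis=drop_axis)
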