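"""Program-driven synthetic peak-table generation.

Peaks are placed relative to existing spectral content: a short
keyword=value "program" states how many strips to emit and where the
strip-defining plane coordinates (x = direct, y = first indirect) and the
remaining-dimension coordinate (z) are drawn:

* ``novel``    -- uniformly from positions whose projected empty mask is set
                  (no substantial signal anywhere along the dropped axis);
* ``existing`` -- from coordinates of detected peaks;
* ``offset``   -- an existing coordinate displaced by a stated ppm offset.

Each strip carries ``npeaks`` peaks (two for HNCA-style experiments)
sharing the x,y coordinates; ``pairsep`` separates the pair along z by the
requested ppm.  Every emitted peak receives random linewidth and phase
perturbations and, optionally, random unresolved couplings per dimension.

Program grammar (comma-separated ``keyword=value`` tokens)::

    count=N  xy=novel|existing|offset  z=novel|existing|offset
    xoff=PPM yoff=PPM zoff=PPM  pairsep=PPM
    amp=A | amp=LO:HI  lw=HZ[;HZ;...]  lwpert=FRAC  phasepert=DEG
    ncoup=N  jband=LO:HI  npeaks=N

Unknown keywords are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    AcquisitionScheme,
    AxisCalibration,
    NusbenchError,
    PeakTable,
    RangeError,
    SyntheticPeak,
)
from .characterize import EmptyMask, PickedPeak, project_mask

__all__ = [
    "ProgramSpec",
    "ParseError",
    "PlacementError",
    "parse_program",
    "gen_sim_tab",
    "CANONICAL_PROGRAMS",
]


class ParseError(NusbenchError):
    """A program token could not be parsed."""


class PlacementError(NusbenchError):
    """No empty positions remain for novel placement."""


_MODES = ("novel", "existing", "offset")


@dataclass(frozen=True)
class ProgramSpec:
    """Parsed peak-placement program (defaults suit HNCA-style 3D data)."""

    count: int = 1
    xy_mode: str = "novel"
    z_mode: str = "existing"
    offsets_ppm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # x, y, z
    pair_separation_ppm: float | None = None
    amplitude: tuple[float, float] = (1.0, 1.0)  # uniform range; equal = fixed
    linewidths_hz: tuple[float, ...] = (20.0, 15.0, 25.0)
    linewidth_perturb_frac: float = 0.2
    phase_perturb_deg: float = 5.0
    n_couplings: int = 0
    coupling_band_hz: tuple[float, float] = (3.0, 12.0)
    peaks_per_strip: int = 2

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ParseError(f"count must be >= 0, got {self.count}")
        if self.xy_mode not in _MODES or self.z_mode not in _MODES:
            raise ParseError(f"modes must be one of {_MODES}")
        if self.peaks_per_strip < 1:
            raise ParseError("npeaks must be >= 1")


def _parse_range(text: str, key: str) -> tuple[float, float]:
    try:
        if ":" in text:
            lo, hi = (float(x) for x in text.split(":"))
        else:
            lo = hi = float(text)
    except ValueError as e:
        raise ParseError(f"cannot parse {key}={text!r}") from e
    if lo > hi:
        raise ParseError(f"{key} range must be ordered, got {text!r}")
    return (lo, hi)


def parse_program(text: str) -> ProgramSpec:
    """Parse a keyword=value program string into a :class:`ProgramSpec`."""
    kwargs: dict = {}
    offsets = [0.0, 0.0, 0.0]
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        if "=" not in token:
            raise ParseError(f"malformed token {token!r} (expected keyword=value)")
        key, _, value = token.partition("=")
        key, value = key.strip(), value.strip()
        try:
            if key == "count":
                kwargs["count"] = int(value)
            elif key == "xy":
                kwargs["xy_mode"] = value
            elif key == "z":
                kwargs["z_mode"] = value
            elif key in ("xoff", "yoff", "zoff"):
                offsets["xyz".index(key[0])] = float(value)
            elif key == "pairsep":
                kwargs["pair_separation_ppm"] = float(value)
            elif key == "amp":
                kwargs["amplitude"] = _parse_range(value, "amp")
            elif key == "lw":
                kwargs["linewidths_hz"] = tuple(float(x) for x in value.split(";"))
            elif key == "lwpert":
                kwargs["linewidth_perturb_frac"] = float(value)
            elif key == "phasepert":
                kwargs["phase_perturb_deg"] = float(value)
            elif key == "ncoup":
                kwargs["n_couplings"] = int(value)
            elif key == "jband":
                kwargs["coupling_band_hz"] = _parse_range(value, "jband")
            elif key == "npeaks":
                kwargs["peaks_per_strip"] = int(value)
            else:
                raise ParseError(f"unknown keyword {key!r} in token {token!r}")
        except ValueError as e:
            raise ParseError(f"malformed token {token!r}: {e}") from e
    return ProgramSpec(offsets_ppm=tuple(offsets), **kwargs)


# Canonical evaluation designs: strong closely spaced pairs probe
# resolution, strong isolated peaks probe frequency accuracy, and
# variable-intensity isolated peaks probe sensitivity.
CANONICAL_PROGRAMS: dict[str, str] = {
    "resolution": "count=2,xy=novel,z=existing,pairsep=0.9,amp=5.0",
    "accuracy": "count=2,xy=novel,z=novel,amp=5.0",
    "sensitivity": "count=2,xy=novel,z=novel,amp=0.2:2.0",
    "offset_y": "count=2,xy=offset,yoff=0.5,z=existing,amp=5.0",
    "classic": "count=2,xy=novel,z=existing,amp=5.0",
}


def _draw_perturbed_linewidths(rng, spec: ProgramSpec, ndim: int) -> tuple[float, ...]:
    base = spec.linewidths_hz
    if len(base) < ndim:
        base = tuple(base) + (base[-1],) * (ndim - len(base))
    f = spec.linewidth_perturb_frac
    return tuple(lw * (1.0 + rng.uniform(-f, f)) for lw in base[:ndim])


def gen_sim_tab(
    programs,
    detected: list[PickedPeak],
    mask: EmptyMask,
    acq: AcquisitionScheme,
    seed: int,
    axes: tuple[AxisCalibration, ...] | None = None,
    strip_axes: tuple[int, int] = (0, 1),
    z_axis: int = 2,
) -> PeakTable:
    """Generate a synthetic peak table from placement programs.

    ``detected`` and ``mask`` must derive from the same (reference)
    spectrum, whose axis calibrations are passed via ``axes``; ``seed``
    fixes all randomness.  ``strip_axes`` name the two spectrum axes whose
    coordinates define a strip; ``z_axis`` is the remaining axis.
    """
    if isinstance(programs, (str, ProgramSpec)):
        programs = [programs]
    specs = [parse_program(p) if isinstance(p, str) else p for p in programs]
    if axes is None:
        raise RangeError("gen_sim_tab requires the reference spectrum axes")
    if mask.values.ndim != 3:
        raise RangeError("gen_sim_tab requires a 3D mask")
    rng = np.random.default_rng(seed)
    ax_x, ax_y = strip_axes
    cal_x, cal_y, cal_z = axes[ax_x], axes[ax_y], axes[z_axis]

    projected = project_mask(mask, drop_axis=z_axis)  # empty anywhere along z
    empty_xy = np.argwhere(projected)

    det_xy = [(p.position[ax_x], p.position[ax_y]) for p in detected]
    det_z = [p.position[z_axis] for p in detected]
    det_z_hz = [p.position_hz[z_axis] for p in detected]
    n_z = mask.values.shape[z_axis]

    peaks: list[SyntheticPeak] = []
    strip_ids: list[int] = []
    strip = 0
    # spectrum-axis -> acquisition-dimension mapping: spectrum axis 0 is the
    # direct dimension, the rest follow the indirect order.
    spec_to_acq = [acq.direct_dim] + [i for i in range(acq.ndim) if i != acq.direct_dim]

    for spec in specs:
        for _ in range(spec.count):
            if spec.xy_mode == "novel":
                if len(empty_xy) == 0:
                    raise PlacementError("no empty positions available for xy=novel")
                bx, by = empty_xy[rng.integers(len(empty_xy))]
                x_hz, y_hz = float(cal_x.hz(bx)), float(cal_y.hz(by))
            else:
                if not detected:
                    raise PlacementError("no detected peaks for xy=existing/offset")
                px, py = det_xy[rng.integers(len(det_xy))]
                x_hz, y_hz = float(cal_x.hz(px)), float(cal_y.hz(py))
                if spec.xy_mode == "offset":
                    x_hz += spec.offsets_ppm[0] * cal_x.obs_mhz
                    y_hz += spec.offsets_ppm[1] * cal_y.obs_mhz

            def draw_z() -> float:
                if spec.z_mode == "novel":
                    return float(cal_z.hz(rng.integers(n_z)))
                if not detected:
                    raise PlacementError("no detected peaks for z=existing/offset")
                z = float(det_z_hz[rng.integers(len(det_z_hz))])
                if spec.z_mode == "offset":
                    z += spec.offsets_ppm[2] * cal_z.obs_mhz
                return z

            # with a pair separation the strip shares one base z coordinate
            z_base = draw_z() if spec.pair_separation_ppm is not None else None

            for p in range(spec.peaks_per_strip):
                if z_base is not None:
                    sep_hz = (spec.pair_separation_ppm or 0.0) * cal_z.obs_mhz
                    z_hz = z_base + (p - (spec.peaks_per_strip - 1) / 2.0) * sep_hz
                else:
                    z_hz = draw_z()

                amp = float(rng.uniform(*spec.amplitude))
                lw = _draw_perturbed_linewidths(rng, spec, acq.ndim)
                phases = tuple(
                    float(rng.uniform(-spec.phase_perturb_deg, spec.phase_perturb_deg))
                    for _ in range(acq.ndim)
                )
                couplings = tuple(
                    tuple(float(rng.uniform(*spec.coupling_band_hz))
                          for _ in range(spec.n_couplings))
                    for _ in range(acq.ndim)
                )
                # positions by acquisition dimension: x is the direct
                # dimension, y/z the indirect axes in spectrum order.
                freq_by_axis = {strip_axes[0]: x_hz, strip_axes[1]: y_hz, z_axis: z_hz}
                freq = [0.0] * acq.ndim
                lw_by_dim = [0.0] * acq.ndim
                for spectrum_axis, hz in freq_by_axis.items():
                    freq[spec_to_acq[spectrum_axis]] = hz
                for spectrum_axis in range(3):
                    lw_by_dim[spec_to_acq[spectrum_axis]] = lw[spectrum_axis]
                peaks.append(SyntheticPeak(
                    amplitude=amp,
                    freq_hz=tuple(freq),
                    decay_hz=tuple(lw_by_dim),
                    phase_deg=phases,
                    couplings_hz=couplings,
                ))
                strip_ids.append(strip)
            strip += 1
    return PeakTable(peaks=peaks, strip_ids=strip_ids)
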