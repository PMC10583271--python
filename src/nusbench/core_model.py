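"""Shared domain types, file formats, and unit conversions.

Conventions used throughout the package
---------------------------------------
* Grid indices are 0-based.  Evolution time along a dimension with spectral
  width ``sw`` at index ``k`` is ``t = k / sw``; the first indel sits at
  all-zero evolution times.
* Frequencies are stored as signed Hz offsets from the carrier.
* Hypercomplex data carry ``2**D`` real components for ``D`` dimensions.
  Component ``c`` is a bitmask: bit ``j`` set means the sine-modulated
  (imaginary) quadrature of ``dims[j]``.  For a 3D experiment this yields
  8 real components, i.e. 4 complex FIDs per indel.
* Processed spectral axes run from high to low frequency (increasing index
  = decreasing ppm, the standard NMR display direction).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NusbenchError",
    "FormatError",
    "DimensionError",
    "RangeError",
    "DuplicationError",
    "SchemaError",
    "ConfigError",
    "DimensionSpec",
    "AcquisitionScheme",
    "SyntheticPeak",
    "PeakTable",
    "TimeDomainData",
    "AxisCalibration",
    "Spectrum",
    "ChallengeConfig",
    "DimensionProcessing",
    "hz_to_ppm",
    "ppm_to_hz",
    "timedomain_io",
    "read_timedomain",
    "write_timedomain",
    "schedule_io",
    "read_schedule",
    "write_schedule",
    "peak_table_io",
    "read_peak_table",
    "write_peak_table",
    "read_challenge_config",
    "write_challenge_config",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class NusbenchError(Exception):
    """Base class for all package errors."""


class FormatError(NusbenchError):
    """A file header or record is malformed."""


class DimensionError(NusbenchError):
    """Array shapes, component counts, or dimensionalities disagree."""


class RangeError(NusbenchError):
    """An index or value lies outside its valid range."""


class DuplicationError(NusbenchError):
    """A schedule contains a repeated indel."""


class SchemaError(NusbenchError):
    """A tabular file is missing a required column."""


class ConfigError(NusbenchError):
    """A configuration value is invalid or inconsistent."""


# ---------------------------------------------------------------------------
# Dimensions and acquisition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimensionSpec:
    """One spectral dimension of an experiment.

    Parameters
    ----------
    n_points
        Complex-point count (Nyquist grid size along this axis).
    sw_hz
        Spectral width in Hz; the evolution-time increment is ``1/sw_hz``.
    obs_mhz
        Observe frequency in MHz, used for Hz<->ppm conversion.
    carrier_ppm
        Carrier position in ppm.
    label
        Nucleus tag, e.g. ``"15N"``.
    """

    n_points: int
    sw_hz: float
    obs_mhz: float
    carrier_ppm: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ConfigError(f"n_points must be >= 1, got {self.n_points}")
        if self.sw_hz <= 0:
            raise ConfigError(f"sw_hz must be > 0, got {self.sw_hz}")
        if self.obs_mhz <= 0:
            raise ConfigError(f"obs_mhz must be > 0, got {self.obs_mhz}")

    def times(self, n: int | None = None) -> np.ndarray:
        """Evolution times t = k / sw for k = 0..n-1."""
        n = self.n_points if n is None else n
        return np.arange(n) / self.sw_hz


@dataclass(frozen=True)
class AcquisitionScheme:
    """Full acquisition geometry: one direct dimension plus indirect grid.

    ``group_delay_points`` is the count of "negative time" points prepended
    to every direct-dimension vector (digital-oversampling placeholder).
    """

    dims: tuple[DimensionSpec, ...]
    direct_dim: int = 0
    group_delay_points: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(self.dims))
        if not (0 <= self.direct_dim < len(self.dims)):
            raise ConfigError(
                f"direct_dim {self.direct_dim} outside dims of length {len(self.dims)}"
            )
        if self.group_delay_points < 0:
            raise ConfigError("group_delay_points must be nonnegative")

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def n_components(self) -> int:
        return 2 ** self.ndim

    @property
    def indirect_dims(self) -> tuple[DimensionSpec, ...]:
        return tuple(d for i, d in enumerate(self.dims) if i != self.direct_dim)

    @property
    def indirect_grid(self) -> tuple[int, ...]:
        return tuple(d.n_points for d in self.indirect_dims)

    @property
    def direct(self) -> DimensionSpec:
        return self.dims[self.direct_dim]

    @property
    def n_direct_total(self) -> int:
        """Direct-dimension points including group-delay placeholders."""
        return self.direct.n_points + self.group_delay_points

    @property
    def n_fids_per_indel(self) -> int:
        """Complex FIDs recorded at each indel under full component sampling."""
        return 2 ** (self.ndim - 1)

    def component_label(self, c: int) -> str:
        """Quadrature label, one R/I letter per dimension in dims order."""
        return "".join("I" if (c >> j) & 1 else "R" for j in range(self.ndim))

    def to_dict(self) -> dict:
        return {
            "dims": [asdict(d) for d in self.dims],
            "direct_dim": self.direct_dim,
            "group_delay_points": self.group_delay_points,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionScheme":
        try:
            dims = tuple(DimensionSpec(**x) for x in d["dims"])
            return cls(dims=dims, direct_dim=d["direct_dim"],
                       group_delay_points=d.get("group_delay_points", 0))
        except KeyError as e:  # pragma: no cover - defensive
            raise FormatError(f"acquisition scheme missing field {e}") from e


# ---------------------------------------------------------------------------
# Synthetic peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticPeak:
    """Ground-truth signal: one amplitude, per-dimension frequency/decay/phase.

    ``decay_hz`` is the Lorentzian full width at half maximum; the time
    envelope is ``exp(-pi * decay_hz * t)`` (0 means constant-time, no decay).
    ``couplings_hz`` are cosine modulations ``cos(pi * J * t)``; each coupling
    splits the peak into a doublet separated by J Hz.
    """

    amplitude: float
    freq_hz: tuple[float, ...]
    decay_hz: tuple[float, ...]
    phase_deg: tuple[float, ...]
    couplings_hz: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        nd = len(self.freq_hz)
        object.__setattr__(self, "freq_hz", tuple(float(x) for x in self.freq_hz))
        object.__setattr__(self, "decay_hz", tuple(float(x) for x in self.decay_hz))
        object.__setattr__(self, "phase_deg", tuple(float(x) for x in self.phase_deg))
        object.__setattr__(
            self, "couplings_hz",
            tuple(tuple(float(j) for j in js) for js in self.couplings_hz),
        )
        if not (len(self.decay_hz) == len(self.phase_deg) == len(self.couplings_hz) == nd):
            raise DimensionError("per-dimension parameter lists have unequal lengths")
        if any(d < 0 for d in self.decay_hz):
            raise ConfigError("decay_hz must be >= 0")
        if not np.isfinite(self.amplitude):
            raise ConfigError("amplitude must be finite")

    @property
    def ndim(self) -> int:
        return len(self.freq_hz)


@dataclass
class PeakTable:
    """Ordered collection of synthetic peaks with strip grouping.

    Peaks sharing a ``strip_id`` lie at the same coordinates in the
    strip-defining dimensions (e.g. the 1H,15N plane of an HNCA).
    """

    peaks: list[SyntheticPeak] = field(default_factory=list)
    strip_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.strip_ids:
            self.strip_ids = list(range(len(self.peaks)))
        if len(self.strip_ids) != len(self.peaks):
            raise DimensionError("strip_ids length must equal number of peaks")

    def __len__(self) -> int:
        return len(self.peaks)

    def __add__(self, other: "PeakTable") -> "PeakTable":
        shift = (max(self.strip_ids) + 1) if self.strip_ids else 0
        return PeakTable(
            peaks=self.peaks + other.peaks,
            strip_ids=self.strip_ids + [s + shift for s in other.strip_ids],
        )

    @property
    def ndim(self) -> int:
        return self.peaks[0].ndim if self.peaks else 0

    def positions_hz(self) -> np.ndarray:
        """(n_peaks, ndim) array of frequencies (Hz offsets from carrier)."""
        if not self.peaks:
            return np.empty((0, 0))
        return np.array([p.freq_hz for p in self.peaks], dtype=float)

    def amplitudes(self) -> np.ndarray:
        return np.array([p.amplitude for p in self.peaks], dtype=float)


# ---------------------------------------------------------------------------
# Time-domain container
# ---------------------------------------------------------------------------

@dataclass
class TimeDomainData:
    """Hypercomplex FID array: [component, direct_point, indirect indices...].

    Components enumerate the 2**D quadrature states (see module docstring);
    for 3D data this corresponds to 4 complex FIDs per indel.
    """

    values: np.ndarray
    acq: AcquisitionScheme

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.acq.n_components, self.acq.n_direct_total) + self.acq.indirect_grid
        if self.values.shape != expected:
            raise DimensionError(
                f"array shape {self.values.shape} does not match acquisition "
                f"(expected {expected}: 2^D components x direct x indirect grid)"
            )

    @property
    def components(self) -> list[str]:
        return [self.acq.component_label(c) for c in range(self.acq.n_components)]

    @property
    def n_fids_per_indel(self) -> int:
        return self.acq.n_fids_per_indel

    def copy(self) -> "TimeDomainData":
        return TimeDomainData(values=self.values.copy(), acq=self.acq)


# ---------------------------------------------------------------------------
# Spectrum container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxisCalibration:
    """Frequency calibration of one processed spectral axis.

    ``first_point_hz`` is the signed Hz offset from the carrier at index 0;
    successive points decrease by ``hz_per_point`` (high-to-low frequency
    ordering), so ``hz(b) = first_point_hz - b * hz_per_point``.
    """

    size: int
    first_point_hz: float
    hz_per_point: float
    obs_mhz: float
    carrier_ppm: float = 0.0
    label: str = ""

    def hz(self, b: np.ndarray | float) -> np.ndarray | float:
        return self.first_point_hz - np.asarray(b, dtype=float) * self.hz_per_point

    def ppm(self, b: np.ndarray | float) -> np.ndarray | float:
        return self.carrier_ppm + self.hz(b) / self.obs_mhz

    @property
    def ppm_per_point(self) -> float:
        return -self.hz_per_point / self.obs_mhz

    def bin_of_hz(self, hz: float) -> float:
        """Fractional index of a frequency offset (Hz) on this axis."""
        return (self.first_point_hz - hz) / self.hz_per_point


@dataclass
class Spectrum:
    """Processed real intensity array with per-axis frequency calibration."""

    values: np.ndarray
    axes: tuple[AxisCalibration, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.axes = tuple(self.axes)
        if self.values.ndim != len(self.axes):
            raise DimensionError(
                f"{self.values.ndim}-D array with {len(self.axes)} axis calibrations"
            )
        for ax, n in zip(self.axes, self.values.shape):
            if ax.size != n:
                raise DimensionError(f"axis size {ax.size} != array extent {n}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def position_hz(self, coord: Sequence[float]) -> tuple[float, ...]:
        """Convert a (fractional) grid coordinate to per-axis Hz offsets."""
        return tuple(ax.hz(c) for ax, c in zip(self.axes, coord))


# ---------------------------------------------------------------------------
# Challenge configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimensionProcessing:
    """Processing parameters for one dimension of the DFT chain.

    ``apod_power`` of 0 disables apodization; otherwise a cosine-power
    window ``cos(pi*k / (2*(n-1)))**apod_power`` is applied.  ``zero_fill``
    counts doublings of the time-domain length before the transform.
    """

    apod_power: int = 2
    zero_fill: int = 1
    p0_deg: float = 0.0
    p1_deg: float = 0.0
    first_point_scale: float = 0.5


@dataclass
class ChallengeConfig:
    """Per-challenge metadata: acquisition geometry, processing, direct ROI."""

    experiment: str
    acq: AcquisitionScheme
    direct_roi_ppm: tuple[float, float] | None = None
    processing: tuple[DimensionProcessing, ...] = ()

    def __post_init__(self) -> None:
        if not self.processing:
            self.processing = tuple(DimensionProcessing() for _ in self.acq.dims)
        if len(self.processing) != self.acq.ndim:
            raise ConfigError("one DimensionProcessing required per dimension")
        if self.direct_roi_ppm is not None:
            lo, hi = sorted(self.direct_roi_ppm)
            d = self.acq.direct
            half_ppm = d.sw_hz / 2.0 / d.obs_mhz
            if hi > d.carrier_ppm + half_ppm or lo < d.carrier_ppm - half_ppm:
                raise ConfigError(
                    f"direct ROI {self.direct_roi_ppm} outside spectral range of "
                    f"{d.carrier_ppm:+.3f} +/- {half_ppm:.3f} ppm"
                )
            self.direct_roi_ppm = (lo, hi)


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

def hz_to_ppm(value_hz: float | np.ndarray, dim: DimensionSpec | AxisCalibration) -> float | np.ndarray:
    """Offset-relative Hz -> ppm: ppm = Hz / obs_mhz."""
    if dim.obs_mhz <= 0:
        raise ConfigError("obs_mhz must be > 0")
    return np.asarray(value_hz, dtype=float) / dim.obs_mhz if isinstance(value_hz, np.ndarray) else value_hz / dim.obs_mhz


def ppm_to_hz(value_ppm: float | np.ndarray, dim: DimensionSpec | AxisCalibration) -> float | np.ndarray:
    """Offset-relative ppm -> Hz: Hz = ppm * obs_mhz."""
    if dim.obs_mhz <= 0:
        raise ConfigError("obs_mhz must be > 0")
    return np.asarray(value_ppm, dtype=float) * dim.obs_mhz if isinstance(value_ppm, np.ndarray) else value_ppm * dim.obs_mhz


# ---------------------------------------------------------------------------
# Portable array container (FIDs and spectra)
#
# Single file: 8-byte magic, little-endian uint64 header length, UTF-8 JSON
# header, then the raw C-order float64 array bytes.  Round trips are
# bit-exact.
# ---------------------------------------------------------------------------

_MAGIC = b"NUSBENC1"


def _write_container(path, kind: str, array: np.ndarray, meta: dict) -> None:
    array = np.ascontiguousarray(array, dtype=np.float64)
    header = {"kind": kind, "shape": list(array.shape), "dtype": "float64", **meta}
    blob = json.dumps(header).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        fh.write(array.tobytes(order="C"))


def _read_container(path, expect_kind: str | None = None) -> tuple[dict, np.ndarray]:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != _MAGIC:
            raise FormatError(f"{path}: bad magic {magic!r} (field 'magic')")
        (hlen,) = struct.unpack("<Q", fh.read(8))
        try:
            header = json.loads(fh.read(hlen).decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as e:
            raise FormatError(f"{path}: unreadable JSON header (field 'header'): {e}") from e
        for key in ("kind", "shape", "dtype"):
            if key not in header:
                raise FormatError(f"{path}: header missing field '{key}'")
        if header["dtype"] != "float64":
            raise FormatError(f"{path}: unsupported dtype (field 'dtype'): {header['dtype']}")
        if expect_kind is not None and header["kind"] != expect_kind:
            raise FormatError(
                f"{path}: header field 'kind' is {header['kind']!r}, expected {expect_kind!r}"
            )
        shape = tuple(int(x) for x in header["shape"])
        n = int(np.prod(shape)) if shape else 1
        raw = fh.read(n * 8)
        if len(raw) != n * 8:
            raise FormatError(
                f"{path}: payload truncated (field 'shape'): expected {n} float64 values"
            )
        array = np.frombuffer(raw, dtype=np.float64).reshape(shape)
    return header, array


def write_timedomain(path, data: TimeDomainData) -> None:
    _write_container(path, "fid", data.values, {"acq": data.acq.to_dict()})


def read_timedomain(path) -> TimeDomainData:
    header, array = _read_container(path, expect_kind="fid")
    if "acq" not in header:
        raise FormatError(f"{path}: header missing field 'acq'")
    acq = AcquisitionScheme.from_dict(header["acq"])
    if array.shape[0] != acq.n_components:
        raise DimensionError(
            f"{path}: {array.shape[0]} components for {acq.ndim}-D data "
            f"(expected 2^D = {acq.n_components})"
        )
    return TimeDomainData(values=array, acq=acq)


def write_spectrum(path, spectrum: Spectrum) -> None:
    _write_container(
        path, "spectrum", spectrum.values,
        {"axes": [asdict(a) for a in spectrum.axes], "provenance": spectrum.provenance},
    )


def read_spectrum(path) -> Spectrum:
    header, array = _read_container(path, expect_kind="spectrum")
    if "axes" not in header:
        raise FormatError(f"{path}: header missing field 'axes'")
    axes = tuple(AxisCalibration(**a) for a in header["axes"])
    return Spectrum(values=array, axes=axes, provenance=header.get("provenance", {}))


def timedomain_io(path, mode: str, data: TimeDomainData | None = None) -> TimeDomainData | None:
    """Read or write the portable time-domain container."""
    if mode == "read":
        return read_timedomain(path)
    if mode == "write":
        if data is None:
            raise ConfigError("mode='write' requires data")
        write_timedomain(path, data)
        return None
    raise ConfigError(f"mode must be 'read' or 'write', got {mode!r}")


# ---------------------------------------------------------------------------
# Schedule text format
#
# One indel per line, whitespace-separated 0-based indices, one column per
# indirect dimension.  '#' comment lines carry key: value metadata.
# ---------------------------------------------------------------------------

def write_schedule(path, schedule) -> None:
    lines = []
    for key, value in schedule.metadata.items():
        lines.append(f"# {key}: {value}")
    lines.append(f"# grid: {' '.join(str(n) for n in schedule.grid)}")
    for indel in schedule.indels:
        lines.append(" ".join(str(int(i)) for i in indel))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_schedule(path):
    from .sampling import SampleSchedule  # local import: avoid cycle

    metadata: dict[str, str] = {}
    indels: list[tuple[int, ...]] = []
    grid: tuple[int, ...] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    key, value = key.strip(), value.strip()
                    if key == "grid":
                        grid = tuple(int(x) for x in value.split())
                    else:
                        metadata[key] = value
                continue
            try:
                indel = tuple(int(tok) for tok in line.split())
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: non-integer index in {line!r}") from e
            indels.append(indel)
    if grid is None:
        raise FormatError(f"{path}: missing '# grid:' metadata line")
    ncols = {len(i) for i in indels}
    if ncols and ncols != {len(grid)}:
        raise DimensionError(f"{path}: indel columns {ncols} != grid rank {len(grid)}")
    for indel in indels:
        for axis, (idx, n) in enumerate(zip(indel, grid)):
            if not (0 <= idx < n):
                raise RangeError(
                    f"{path}: index {idx} outside grid axis {axis} (max {n - 1})"
                )
    seen = set()
    for indel in indels:
        if indel in seen:
            raise DuplicationError(f"{path}: duplicate indel {indel}")
        seen.add(indel)
    return SampleSchedule(indels=indels, grid=grid, metadata=metadata)


def schedule_io(path, mode: str, schedule=None):
    if mode == "read":
        return read_schedule(path)
    if mode == "write":
        if schedule is None:
            raise ConfigError("mode='write' requires a schedule")
        write_schedule(path, schedule)
        return None
    raise ConfigError(f"mode must be 'read' or 'write', got {mode!r}")


# ---------------------------------------------------------------------------
# Peak-table tab-text format
# ---------------------------------------------------------------------------

def _peak_columns(ndim: int) -> list[str]:
    cols = ["strip_id", "amplitude"]
    for d in range(ndim):
        cols += [f"freq_hz_{d}", f"decay_hz_{d}", f"phase_deg_{d}", f"couplings_hz_{d}"]
    return cols


def write_peak_table(path, table: PeakTable) -> None:
    ndim = table.ndim
    rows = []
    for strip, peak in zip(table.strip_ids, table.peaks):
        row: dict = {"strip_id": strip, "amplitude": repr(peak.amplitude)}
        for d in range(ndim):
            row[f"freq_hz_{d}"] = repr(peak.freq_hz[d])
            row[f"decay_hz_{d}"] = repr(peak.decay_hz[d])
            row[f"phase_deg_{d}"] = repr(peak.phase_deg[d])
            row[f"couplings_hz_{d}"] = ",".join(repr(j) for j in peak.couplings_hz[d]) or "-"
        rows.append(row)
    df = pd.DataFrame(rows, columns=_peak_columns(ndim) if ndim else ["strip_id", "amplitude"])
    df.to_csv(path, sep="\t", index=False)


def read_peak_table(path) -> PeakTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "amplitude" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'amplitude'")
    ndim = 0
    while f"freq_hz_{ndim}" in df.columns:
        for name in (f"decay_hz_{ndim}", f"phase_deg_{ndim}", f"couplings_hz_{ndim}"):
            if name not in df.columns:
                raise SchemaError(f"{path}: missing required column '{name}'")
        ndim += 1
    if len(df) and ndim == 0:
        raise SchemaError(f"{path}: missing required column 'freq_hz_0'")
    peaks, strips = [], []
    for _, row in df.iterrows():
        couplings = []
        for d in range(ndim):
            cell = str(row[f"couplings_hz_{d}"])
            couplings.append(
                tuple(float(x) for x in cell.split(",")) if cell not in ("-", "nan", "") else ()
            )
        peaks.append(SyntheticPeak(
            amplitude=float(row["amplitude"]),
            freq_hz=tuple(float(row[f"freq_hz_{d}"]) for d in range(ndim)),
            decay_hz=tuple(float(row[f"decay_hz_{d}"]) for d in range(ndim)),
            phase_deg=tuple(float(row[f"phase_deg_{d}"]) for d in range(ndim)),
            couplings_hz=tuple(couplings),
        ))
        strips.append(int(row["strip_id"]) if "strip_id" in df.columns else len(strips))
    return PeakTable(peaks=peaks, strip_ids=strips)


def peak_table_io(path, mode: str, table: PeakTable | None = None) -> PeakTable | None:
    if mode == "read":
        return read_peak_table(path)
    if mode == "write":
        if table is None:
            raise ConfigError("mode='write' requires a table")
        write_peak_table(path, table)
        return None
    raise ConfigError(f"mode must be 'read' or 'write', got {mode!r}")


# ---------------------------------------------------------------------------
# Challenge configuration file (JSON key-value document)
# ---------------------------------------------------------------------------

def write_challenge_config(path, config: ChallengeConfig) -> None:
    doc = {
        "experiment": config.experiment,
        "acq": config.acq.to_dict(),
        "direct_roi_ppm": list(config.direct_roi_ppm) if config.direct_roi_ppm else None,
        "processing": [asdict(p) for p in config.processing],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_challenge_config(path) -> ChallengeConfig:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise FormatError(f"{path}: invalid JSON: {e}") from e
    for key in ("experiment", "acq"):
        if key not in doc:
            raise FormatError(f"{path}: missing field '{key}'")
    roi = doc.get("direct_roi_ppm")
    return ChallengeConfig(
        experiment=doc["experiment"],
        acq=AcquisitionScheme.from_dict(doc["acq"]),
        direct_roi_ppm=tuple(roi) if roi else None,
        processing=tuple(DimensionProcessing(**p) for p in doc.get("processing", [])),
    )
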