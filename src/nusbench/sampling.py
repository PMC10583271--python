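"""Exponentially biased sample-schedule generation and NUS subsampling.

The sampling weight of indel ``(k_1, ..., k_D)`` on the indirect Nyquist
grid is separable per dimension::

    w = prod_d exp(-pi * R_d * k_d / sw_d)

with ``R_d`` the expected signal decay rate (Hz) along dimension ``d``; a
zero decay rate yields uniform weighting along that dimension (the
constant-time case).  The first indel (all-zero evolution times, largest
signal) and the last indel (defining the grid extent) are always forced
into the schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    AcquisitionScheme,
    ConfigError,
    DimensionError,
    DuplicationError,
    RangeError,
    TimeDomainData,
)

__all__ = [
    "SampleSchedule",
    "NUSData",
    "gen_schedule",
    "coverage",
    "subsample",
    "expand_to_grid",
    "write_nus",
    "read_nus",
]


@dataclass
class SampleSchedule:
    """Ordered list of indels (0-based index tuples on the indirect grid)."""

    indels: list[tuple[int, ...]]
    grid: tuple[int, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indels = [tuple(int(i) for i in x) for x in self.indels]
        self.grid = tuple(int(n) for n in self.grid)
        seen = set()
        for indel in self.indels:
            if len(indel) != len(self.grid):
                raise DimensionError(
                    f"indel {indel} has {len(indel)} indices for a "
                    f"{len(self.grid)}-D grid"
                )
            for axis, (idx, n) in enumerate(zip(indel, self.grid)):
                if not (0 <= idx < n):
                    raise RangeError(f"index {idx} outside grid axis {axis} (max {n - 1})")
            if indel in seen:
                raise DuplicationError(f"duplicate indel {indel}")
            seen.add(indel)

    def __len__(self) -> int:
        return len(self.indels)

    @property
    def grid_volume(self) -> int:
        return int(np.prod(self.grid))

    def index_arrays(self) -> tuple[np.ndarray, ...]:
        """Per-axis integer index arrays, suitable for fancy indexing."""
        arr = np.asarray(self.indels, dtype=np.intp).reshape(len(self.indels), len(self.grid))
        return tuple(arr[:, a] for a in range(len(self.grid)))


def _indel_weights(grid: tuple[int, ...], decay_rates_hz, sw_hz) -> np.ndarray:
    """Separable exponential bias over the full grid, flattened C-order."""
    w = np.ones(1)
    for n, r, sw in zip(grid, decay_rates_hz, sw_hz):
        if r < 0:
            raise ConfigError("decay rates must be >= 0")
        if sw <= 0:
            raise ConfigError("spectral widths must be > 0")
        wd = np.exp(-np.pi * r * np.arange(n) / sw)
        w = np.multiply.outer(w, wd)
    return w.reshape(-1)


def gen_schedule(
    grid: tuple[int, ...],
    n_indels: int,
    decay_rates_hz,
    sw_hz,
    seed: int,
    command: str | None = None,
) -> SampleSchedule:
    """Draw an exponentially biased schedule of ``n_indels`` indels.

    The first and last indels are forced; the remaining ``n_indels - 2``
    are drawn without replacement with the separable exponential weights
    (weighted reservoir sampling via exponential keys, equivalent in
    distribution to sequential renormalized draws).  Deterministic given
    ``seed``.
    """
    grid = tuple(int(n) for n in grid)
    volume = int(np.prod(grid))
    if not (2 <= n_indels <= volume):
        raise ConfigError(
            f"n_indels must lie in [2, grid volume {volume}], got {n_indels}"
        )
    rng = np.random.default_rng(seed)
    first_flat = 0
    last_flat = volume - 1
    if n_indels == volume:
        chosen = np.arange(volume)
    else:
        weights = _indel_weights(grid, decay_rates_hz, sw_hz)
        pool = np.ones(volume, dtype=bool)
        pool[[first_flat, last_flat]] = False
        candidates = np.nonzero(pool)[0]
        # Efraimidis-Spirtes keys: the n largest u**(1/w) are a weighted
        # sample without replacement.
        keys = np.log(rng.random(candidates.size)) / weights[candidates]
        take = candidates[np.argsort(keys)[::-1][: n_indels - 2]]
        chosen = np.concatenate(([first_flat, last_flat], take))
    chosen.sort()
    indels = [tuple(int(i) for i in np.unravel_index(f, grid)) for f in chosen]
    metadata = {
        "seed": str(seed),
        "decay_rates_hz": " ".join(str(float(r)) for r in decay_rates_hz),
        "sw_hz": " ".join(str(float(s)) for s in sw_hz),
        "forced_first": "1",
        "forced_last": "1",
    }
    if command:
        metadata["command"] = command
    return SampleSchedule(indels=indels, grid=grid, metadata=metadata)


def coverage(schedule: SampleSchedule, decimals: int = 1) -> float:
    """Percentage of the Nyquist grid sampled, rounded for display."""
    return round(100.0 * len(schedule) / schedule.grid_volume, decimals)


@dataclass
class NUSData:
    """Time-domain data restricted to scheduled indels, in schedule order.

    ``values`` has shape (2^D components, direct points, n_indels): all
    hypercomplex components are kept at every indel (full component
    sampling).
    """

    values: np.ndarray
    schedule: SampleSchedule
    acq: AcquisitionScheme

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = (self.acq.n_components, self.acq.n_direct_total, len(self.schedule))
        if self.values.shape != expected:
            raise DimensionError(
                f"NUS array shape {self.values.shape}, expected {expected}"
            )

    @property
    def n_fids_per_indel(self) -> int:
        return self.acq.n_fids_per_indel


def subsample(fid: TimeDomainData, schedule: SampleSchedule) -> NUSData:
    """Restrict full-grid time-domain data to the scheduled indels."""
    if schedule.grid != fid.acq.indirect_grid:
        raise DimensionError(
            f"schedule grid {schedule.grid} != data indirect grid {fid.acq.indirect_grid}"
        )
    idx = schedule.index_arrays()
    values = fid.values[(slice(None), slice(None)) + idx]
    return NUSData(values=values, schedule=schedule, acq=fid.acq)


def expand_to_grid(nus: NUSData, schedule: SampleSchedule | None = None
                   ) -> tuple[TimeDomainData, np.ndarray]:
    """Embed NUS data on the full grid, zeros at unscheduled indels.

    Returns the zero-filled :class:`TimeDomainData` and a boolean sampling
    indicator over the indirect grid.
    """
    schedule = nus.schedule if schedule is None else schedule
    if len(schedule) != nus.values.shape[-1]:
        raise DimensionError("schedule length does not match NUS data")
    acq = nus.acq
    full = np.zeros((acq.n_components, acq.n_direct_total) + acq.indirect_grid)
    idx = schedule.index_arrays()
    full[(slice(None), slice(None)) + idx] = nus.values
    sampled = np.zeros(acq.indirect_grid, dtype=bool)
    sampled[idx] = True
    return TimeDomainData(values=full, acq=acq), sampled


def write_nus(path, nus: NUSData) -> None:
    """Write NUS data to the portable container (indels kept in the header)."""
    from .core_model import _write_container

    _write_container(path, "nus", nus.values, {
        "acq": nus.acq.to_dict(),
        "grid": list(nus.schedule.grid),
        "indels": [list(i) for i in nus.schedule.indels],
        "schedule_metadata": nus.schedule.metadata,
    })


def read_nus(path) -> NUSData:
    from .core_model import FormatError, _read_container

    header, array = _read_container(path, expect_kind="nus")
    for key in ("acq", "grid", "indels"):
        if key not in header:
            raise FormatError(f"{path}: header missing field '{key}'")
    acq = AcquisitionScheme.from_dict(header["acq"])
    schedule = SampleSchedule(
        indels=[tuple(i) for i in header["indels"]],
        grid=tuple(header["grid"]),
        metadata=header.get("schedule_metadata", {}),
    )
    return NUSData(values=array, schedule=schedule, acq=acq)
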