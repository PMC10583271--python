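"""Peak matching and the five recovery metrics, normalized to [0, 1].

All metrics compare the injected (ground-truth) peak list against the peaks
recovered from a reconstruction:

* M1 frequency accuracy: a symmetric Hausdorff distance over peak positions
  with every point-to-set distance capped at ``d_max``; the score is
  ``1 - H/d_max`` so identical sets score 1.
* M2/M5 intensity linearity: Pearson correlation between injected
  amplitudes and recovered heights, with unmatched injected peaks entering
  at recovered height 0 and negative correlations clamped to 0.  M5 is the
  same quantity computed by an alternative route in the original platform;
  one implementation serves both identifiers here.
* M3 true positive rate: fraction of injected peaks recovered.
* M4 false positive rate: fraction of recovered peaks matching neither an
  injected nor a known reference peak.  For ranking, M4 is oriented as
  1 - FPR so that larger is better for every metric.

Distances are computed in Hz across all spectral dimensions by default; a
ppm-based distance is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import NusbenchError, RangeError

__all__ = [
    "Matching",
    "MetricScore",
    "match_peaks",
    "metric_m1_frequency_accuracy",
    "metric_linearity",
    "metric_m3_tpr",
    "metric_m4_fpr",
    "capped_hausdorff",
]

METRIC_IDS = ("M1", "M2", "M3", "M4", "M5")


@dataclass(frozen=True)
class MetricScore:
    """A single normalized metric value with evaluation context."""

    metric_id: str
    value: float
    not_applicable: bool = False
    degenerate: bool = False
    context: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric_id not in METRIC_IDS:
            raise RangeError(f"unknown metric id {self.metric_id!r}")
        if not self.not_applicable and not (0.0 <= self.value <= 1.0):
            raise RangeError(f"metric value {self.value} outside [0, 1]")


@dataclass
class Matching:
    """One-to-one assignment between injected and recovered peaks."""

    pairs: list[tuple[int, int, float]]  # (injected idx, recovered idx, distance)
    unmatched_injected: list[int]
    unmatched_recovered: list[int]
    tolerance_hz: tuple[float, ...]

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def _as_positions(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 0)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    return arr


def match_peaks(injected, recovered, tolerance_hz) -> Matching:
    """Greedy nearest-first one-to-one assignment within a tolerance box.

    Candidate pairs lie within the per-dimension tolerance box; they are
    sorted by tolerance-scaled Euclidean distance and accepted when both
    indices are still unused.
    """
    inj = _as_positions(injected)
    rec = _as_positions(recovered)
    tol = np.asarray(tolerance_hz, dtype=float).reshape(-1)
    if np.any(tol <= 0):
        raise RangeError("tolerance must be > 0 per dimension")
    if inj.size == 0 or rec.size == 0:
        return Matching(pairs=[], unmatched_injected=list(range(len(inj))),
                        unmatched_recovered=list(range(len(rec))),
                        tolerance_hz=tuple(tol))
    if inj.shape[1] != rec.shape[1]:
        raise RangeError("injected and recovered dimensionalities differ")
    diff = inj[:, None, :] - rec[None, :, :]
    inside = np.all(np.abs(diff) <= tol, axis=2)
    dist = np.sqrt(np.sum((diff / tol) ** 2, axis=2))
    candidates = sorted(
        ((dist[i, j], i, j) for i, j in np.argwhere(inside)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, i, j in candidates:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        hz_dist = float(np.sqrt(np.sum((inj[i] - rec[j]) ** 2)))
        pairs.append((int(i), int(j), hz_dist))
    return Matching(
        pairs=pairs,
        unmatched_injected=[i for i in range(len(inj)) if i not in used_i],
        unmatched_recovered=[j for j in range(len(rec)) if j not in used_j],
        tolerance_hz=tuple(tol),
    )


def capped_hausdorff(a: np.ndarray, b: np.ndarray, d_max: float,
                     scale: np.ndarray | None = None) -> float:
    """Symmetric Hausdorff distance with per-point distances capped at d_max.

    The directed distance from an empty set is 0; the distance *to* an empty
    set is the cap, so one empty and one populated set give H = d_max.
    """
    a = _as_positions(a)
    b = _as_positions(b)
    if len(a) == 0 and len(b) == 0:
        raise RangeError("Hausdorff distance undefined for two empty sets")

    def directed(p: np.ndarray, q: np.ndarray) -> float:
        if len(p) == 0:
            return 0.0
        if len(q) == 0:
            return d_max
        pp, qq = p, q
        if scale is not None:
            pp, qq = p / scale, q / scale
        d = np.sqrt(np.sum((pp[:, None, :] - qq[None, :, :]) ** 2, axis=2))
        return float(np.max(np.minimum(d.min(axis=1), d_max)))

    return max(directed(a, b), directed(b, a))


def metric_m1_frequency_accuracy(injected, recovered, d_max: float,
                                 obs_mhz=None, context: dict | None = None
                                 ) -> MetricScore:
    """Frequency accuracy: 1 - H/d_max with H the capped symmetric Hausdorff.

    Positions and ``d_max`` are in Hz; passing per-dimension ``obs_mhz``
    switches the distance space to ppm (divides each coordinate and leaves
    ``d_max`` to be interpreted in ppm).
    """
    if d_max <= 0:
        raise RangeError("d_max must be > 0")
    inj = _as_positions(injected)
    rec = _as_positions(recovered)
    if len(inj) == 0 and len(rec) == 0:
        return MetricScore("M1", 0.0, not_applicable=True, context=context or {})
    scale = None
    if obs_mhz is not None:
        scale = np.asarray(obs_mhz, dtype=float).reshape(1, -1)
    h = capped_hausdorff(inj, rec, d_max, scale=scale)
    return MetricScore("M1", 1.0 - h / d_max, context=context or {})


def metric_linearity(matching: Matching, injected_amplitudes, recovered_heights,
                     metric_id: str = "M2", context: dict | None = None) -> MetricScore:
    """Intensity linearity: clamped Pearson correlation of injected vs recovered.

    Every injected peak contributes one point; unmatched injected peaks
    enter with recovered height 0.
    """
    if metric_id not in ("M2", "M5"):
        raise RangeError("linearity metric id must be M2 or M5")
    amps = np.asarray(injected_amplitudes, dtype=float)
    heights = np.asarray(recovered_heights, dtype=float)
    if amps.size < 2:
        raise RangeError("linearity requires at least 2 injected peaks")
    y = np.zeros(amps.size)
    for i, j, _ in matching.pairs:
        y[i] = heights[j]
    if np.std(amps) == 0.0 or np.std(y) == 0.0:
        return MetricScore(metric_id, 0.0, degenerate=True, context=context or {})
    r = float(np.corrcoef(amps, y)[0, 1])
    return MetricScore(metric_id, max(r, 0.0), context=context or {})


def metric_m3_tpr(matching: Matching, n_injected: int,
                  context: dict | None = None) -> MetricScore:
    """True positive rate: matched injected count / injected count."""
    if n_injected < 1:
        raise RangeError("n_injected must be >= 1")
    return MetricScore("M3", matching.n_matched / n_injected, context=context or {})


def metric_m4_fpr(matching: Matching, n_recovered: int,
                  reference_matching: Matching | None = None,
                  context: dict | None = None) -> MetricScore:
    """False positive rate: recovered peaks matching nothing / recovered count.

    A recovered peak is false iff it matches neither an injected peak nor,
    when a reference matching is supplied, an empirical reference peak.
    """
    if n_recovered == 0:
        return MetricScore("M4", 0.0, not_applicable=True, context=context or {})
    if n_recovered < 0:
        raise RangeError("n_recovered must be >= 0")
    matched = {j for _, j, _ in matching.pairs}
    if reference_matching is not None:
        matched |= {j for _, j, _ in reference_matching.pairs}
    false_count = sum(1 for j in range(n_recovered) if j not in matched)
    return MetricScore("M4", false_count / n_recovered, context=context or {})
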