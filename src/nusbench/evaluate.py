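"""Workflow orchestration, JSON evaluation records, and percentile ranking.

Every reconstruction evaluation produces one JSON record (the single source
of truth for reporting) holding the identifiers that define it, per-task
compute durations, and the metric scores.  Rank lists are recomputed from
raw scores on every call: one list per (metric, experiment, synthetic
table, schedule) column, contestants sorted by oriented score descending,
ranks converted to percentiles so results are independent of the number of
contestants.  Challenge aggregation averages percentiles over the selected
columns, counting only the columns a contestant participated in.
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    ChallengeConfig,
    ConfigError,
    NusbenchError,
    PeakTable,
    Spectrum,
    TimeDomainData,
    read_challenge_config,
    read_peak_table,
    read_schedule,
    read_timedomain,
    write_peak_table,
    write_schedule,
    write_timedomain,
)
from .characterize import (
    build_empty_mask,
    detect_peaks,
    estimate_noise,
    median_linewidths_hz,
)
from .metrics import (
    Matching,
    MetricScore,
    match_peaks,
    metric_linearity,
    metric_m1_frequency_accuracy,
    metric_m3_tpr,
    metric_m4_fpr,
)
from .peakgen import gen_sim_tab
from .reconstruct import (
    IstParams,
    check_spectrum_size,
    process_dft,
    reconstruct_ist,
    run_external_reconstruction,
)
from .sampling import coverage, expand_to_grid, gen_schedule, subsample
from .simulate import SolventSpec, add_solvent, inject, make_synthetic_reference, simulate_fid

__all__ = [
    "EvaluationRecord",
    "RankTable",
    "evaluate_reconstruction",
    "rank_lists",
    "aggregate_challenge",
    "run_workflow",
    "project_status",
    "injected_positions_spectrum_order",
]

RECOVERED_PEAK_LIMIT = 1500  # recovered tables are truncated to this many peaks


@dataclass
class EvaluationRecord:
    """Scores and metadata for one reconstruction."""

    experiment: str
    table_id: str
    schedule_id: str
    contestant: str
    coverage_percent: float | None = None
    disqualified: bool = False
    durations_s: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)   # metric id -> score document
    artifacts: dict = field(default_factory=dict)

    def add_score(self, score: MetricScore) -> None:
        self.scores[score.metric_id] = {
            "value": score.value,
            "not_applicable": score.not_applicable,
            "degenerate": score.degenerate,
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "EvaluationRecord":
        return cls(**json.loads(text))

    @classmethod
    def read(cls, path) -> "EvaluationRecord":
        return cls.from_json(Path(path).read_text())

    def oriented_score(self, metric_id: str) -> float | None:
        """Higher-is-better score for ranking (M4 is reported as 1 - FPR)."""
        doc = self.scores.get(metric_id)
        if doc is None or doc.get("not_applicable"):
            return None
        return 1.0 - doc["value"] if metric_id == "M4" else doc["value"]


def injected_positions_spectrum_order(table: PeakTable, config: ChallengeConfig) -> np.ndarray:
    """Injected frequencies (Hz) reordered to spectrum-axis order."""
    acq = config.acq
    order = [acq.direct_dim] + [i for i in range(acq.ndim) if i != acq.direct_dim]
    pos = table.positions_hz()
    return pos[:, order] if pos.size else pos.reshape(0, acq.ndim)


def evaluate_reconstruction(
    spectrum: Spectrum,
    injected: PeakTable,
    config: ChallengeConfig,
    *,
    contestant: str = "unknown",
    table_id: str = "table",
    schedule_id: str = "schedule",
    coverage_percent: float | None = None,
    detection_threshold_sigmas: float = 3.0,
    max_peaks: int = RECOVERED_PEAK_LIMIT,
    tolerance_hz=None,
    d_max_hz: float | None = None,
    reference_peaks=None,
    out_dir=None,
) -> EvaluationRecord:
    """Score one reconstruction against the injected ground truth.

    Detection uses a low threshold (``detection_threshold_sigmas`` times the
    spectrum noise) and truncates to the ``max_peaks`` most intense peaks.
    Matching tolerance defaults to the per-dimension median injected
    linewidth; the M1 cap ``d_max`` defaults to twice the largest injected
    linewidth.  A spectrum violating the size rule yields a disqualified
    record with no scores.
    """
    record = EvaluationRecord(
        experiment=config.experiment, table_id=table_id,
        schedule_id=schedule_id, contestant=contestant,
        coverage_percent=coverage_percent,
    )
    check = check_spectrum_size(spectrum, config.acq)
    if not check.passed:
        record.disqualified = True
        record.artifacts["size_check"] = {"sizes": list(check.sizes),
                                          "limits": list(check.limits)}
        if out_dir is not None:
            record.write(Path(out_dir) / "record.json")
        return record

    acq = config.acq
    order = [acq.direct_dim] + [i for i in range(acq.ndim) if i != acq.direct_dim]
    lw = np.array([[p.decay_hz[i] for i in order] for p in injected.peaks], dtype=float)
    if tolerance_hz is None:
        tolerance_hz = np.median(lw, axis=0) if len(lw) else np.ones(acq.ndim)
        tolerance_hz = np.where(tolerance_hz > 0, tolerance_hz, 1.0)
    if d_max_hz is None:
        d_max_hz = 2.0 * float(lw.max()) if lw.size and lw.max() > 0 else 1.0

    t0 = time.perf_counter()
    sigma = estimate_noise(spectrum)
    threshold = detection_threshold_sigmas * sigma
    recovered = detect_peaks(spectrum, threshold=threshold, max_peaks=max_peaks)
    record.durations_s["peak_picking"] = time.perf_counter() - t0

    inj_pos = injected_positions_spectrum_order(injected, config)
    rec_pos = np.array([p.position_hz for p in recovered]).reshape(len(recovered), -1)

    t0 = time.perf_counter()
    matching = match_peaks(inj_pos, rec_pos, tolerance_hz)
    record.add_score(metric_m1_frequency_accuracy(inj_pos, rec_pos, d_max=d_max_hz))
    heights = np.array([p.height for p in recovered])
    if len(injected) >= 2:
        lin = metric_linearity(matching, injected.amplitudes(), heights, metric_id="M2")
        record.add_score(lin)
        record.add_score(MetricScore("M5", lin.value, not_applicable=lin.not_applicable,
                                     degenerate=lin.degenerate))
    if len(injected) >= 1:
        record.add_score(metric_m3_tpr(matching, n_injected=len(injected)))
    ref_matching = None
    if reference_peaks is not None and len(recovered):
        ref_matching = match_peaks(np.asarray(reference_peaks), rec_pos, tolerance_hz)
    record.add_score(metric_m4_fpr(matching, n_recovered=len(recovered),
                                   reference_matching=ref_matching))
    record.durations_s["metrics"] = time.perf_counter() - t0
    record.artifacts["n_recovered"] = len(recovered)
    record.artifacts["n_matched"] = matching.n_matched
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        record.write(out_dir / "record.json")
    return record


# ---------------------------------------------------------------------------
# Rank lists and challenge aggregation
# ---------------------------------------------------------------------------

@dataclass
class RankTable:
    """Per-(metric, dataset) rank lists with percentiles.

    ``columns`` maps (metric_id, experiment, table_id, schedule_id) to a
    list of row dicts with contestant, raw and oriented scores, rank
    (1 = best), and percentile in [0, 100].
    """

    columns: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (metric, experiment, table, schedule), entries in sorted(self.columns.items()):
            for e in entries:
                rows.append({"metric": metric, "experiment": experiment,
                             "table": table, "schedule": schedule, **e})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _percentiles_from_scores(scores: list[float]) -> tuple[list[int], list[float]]:
    """Ranks (1 = best) and percentiles 100*(n-rank)/(n-1), ties averaged."""
    n = len(scores)
    order = np.argsort([-s for s in scores], kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    base = (np.full(n, 100.0) if n == 1
            else 100.0 * (n - ranks.astype(float)) / (n - 1))
    percentiles = base.copy()
    for s in set(scores):
        tied = [i for i in range(n) if scores[i] == s]
        if len(tied) > 1:
            mean_p = float(np.mean(base[tied]))
            for i in tied:
                percentiles[i] = mean_p
            min_rank = min(int(ranks[i]) for i in tied)
            for i in tied:
                ranks[i] = min_rank
    return [int(r) for r in ranks], [float(p) for p in percentiles]


def rank_lists(records: list[EvaluationRecord],
               metrics=("M1", "M2", "M3", "M4", "M5")) -> RankTable:
    """Build rank lists per metric per (experiment, table, schedule)."""
    table = RankTable()
    datasets = sorted({(r.experiment, r.table_id, r.schedule_id) for r in records})
    for metric in metrics:
        for ds in datasets:
            entries = []
            for r in records:
                if (r.experiment, r.table_id, r.schedule_id) != ds or r.disqualified:
                    continue
                oriented = r.oriented_score(metric)
                if oriented is None:
                    continue
                raw = r.scores[metric]["value"]
                entries.append({"contestant": r.contestant, "raw_score": raw,
                                "oriented_score": oriented})
            if not entries:
                continue
            ranks, pcts = _percentiles_from_scores([e["oriented_score"] for e in entries])
            for e, rank, pct in zip(entries, ranks, pcts):
                e["rank"] = rank
                e["percentile"] = pct
            entries.sort(key=lambda e: (-e["oriented_score"], e["contestant"]))
            table.columns[(metric,) + ds] = entries
    return table


def aggregate_challenge(rank: RankTable, challenge: dict) -> list[tuple[str, float]]:
    """Average percentiles over the challenge's parameter combinations.

    ``challenge`` selects columns by metric / experiment / table / schedule
    id lists (a missing key selects everything).  Contestants are averaged
    only over columns in which they participated; the result is sorted by
    mean percentile descending.
    """
    def selected(values, key):
        allowed = challenge.get(key)
        return True if allowed is None else values in set(allowed)

    totals: dict[str, list[float]] = {}
    any_column = False
    for (metric, experiment, table, schedule), entries in rank.columns.items():
        if not (selected(metric, "metrics") and selected(experiment, "experiments")
                and selected(table, "tables") and selected(schedule, "schedules")):
            continue
        any_column = True
        for e in entries:
            totals.setdefault(e["contestant"], []).append(e["percentile"])
    if not any_column:
        raise ConfigError("challenge parameters select no rank-list columns")
    result = [(c, float(np.mean(p))) for c, p in totals.items()]
    result.sort(key=lambda t: (-t[1], t[0]))
    return result


# ---------------------------------------------------------------------------
# Project workflow
# ---------------------------------------------------------------------------

def _load_plan(plan) -> dict:
    if isinstance(plan, (str, Path)):
        return json.loads(Path(plan).read_text())
    return dict(plan)


def _reference_for(exp: dict, project: Path):
    """Reference FID + config for one experiment entry of the plan."""
    if isinstance(exp.get("config"), (str,)):
        config = read_challenge_config(project / exp["config"])
    else:
        raise ConfigError(f"experiment {exp.get('id')}: 'config' path required")
    if "reference_fid" in exp:
        fid = read_timedomain(project / exp["reference_fid"])
    elif "synthetic_reference" in exp:
        params = exp["synthetic_reference"]
        fid, _ = make_synthetic_reference(
            config.acq,
            n_peaks=int(params.get("n_peaks", 8)),
            seed=int(params.get("seed", 0)),
            noise_sigma=float(params.get("noise_sigma", 0.05)),
        )
    else:
        raise ConfigError(
            f"experiment {exp.get('id')}: needs 'reference_fid' or 'synthetic_reference'"
        )
    return fid, config


def _table_for(entry: dict, project: Path, reference_spectrum, config, seed_base: int) -> PeakTable:
    if "path" in entry:
        return read_peak_table(project / entry["path"])
    noise = estimate_noise(reference_spectrum)
    detected = detect_peaks(reference_spectrum, threshold=5.0 * noise,
                            max_peaks=int(entry.get("n_reference_peaks", 256)))
    med_lw = median_linewidths_hz(detected)
    med_lw = tuple(m if np.isfinite(m) and m > 0 else 2 * abs(ax.hz_per_point)
                   for m, ax in zip(med_lw, reference_spectrum.axes))
    mask = build_empty_mask(reference_spectrum, med_lw, sigma=noise)
    return gen_sim_tab(entry["programs"], detected, mask, config.acq,
                       seed=int(entry.get("seed", seed_base)),
                       axes=reference_spectrum.axes)


def _schedule_for(entry: dict, project: Path, config):
    if "path" in entry:
        return read_schedule(project / entry["path"])
    acq = config.acq
    return gen_schedule(
        grid=acq.indirect_grid,
        n_indels=int(entry["n_indels"]),
        decay_rates_hz=entry.get("decay_rates_hz", [0.0] * (acq.ndim - 1)),
        sw_hz=[d.sw_hz for d in acq.indirect_dims],
        seed=int(entry.get("seed", 0)),
    )


def _reconstruct_for(script: dict, nus, config, rundir: Path) -> Spectrum:
    builtin = script.get("builtin")
    if builtin == "ist":
        params = IstParams(**script.get("params", {}))
        return reconstruct_ist(nus, config=config, params=params).spectrum
    if builtin == "dft":
        full, _ = expand_to_grid(nus)
        return process_dft(full, config)
    if "path" in script:
        from .core_model import write_challenge_config
        from .sampling import write_nus
        nus_file = rundir / "nus.nusb"
        sched_file = rundir / "schedule.txt"
        cfg_file = rundir / "config.json"
        rundir.mkdir(parents=True, exist_ok=True)
        write_nus(nus_file, nus)
        write_schedule(sched_file, nus.schedule)
        write_challenge_config(cfg_file, config)
        return run_external_reconstruction(script["path"], nus_file, sched_file,
                                           cfg_file, rundir, config.acq)
    raise ConfigError(f"script {script.get('id')}: needs 'builtin' or 'path'")


def run_workflow(project, plan, force: bool = False) -> list[EvaluationRecord]:
    """Execute the full evaluation workflow over a project directory.

    For every (experiment, table, schedule, script) combination the chain
    simulate -> inject -> subsample -> reconstruct -> evaluate is run and a
    JSON record written under ``runs/``.  Completed combinations (existing
    record.json) are skipped unless ``force``; a failing combination writes
    an error file and does not abort its siblings.
    """
    project = Path(project)
    plan = _load_plan(plan)
    records: list[EvaluationRecord] = []
    runs_dir = project / "runs"
    runs_dir.mkdir(parents=True, exist_ok=True)

    for exp in plan["experiments"]:
        reference, config = _reference_for(exp, project)
        ref_spectrum = process_dft(reference, config)
        ref_noise = estimate_noise(ref_spectrum)
        ref_detected = detect_peaks(ref_spectrum, threshold=5.0 * ref_noise, max_peaks=256)
        ref_positions = (np.array([p.position_hz for p in ref_detected])
                         if ref_detected else None)
        for tab in plan["tables"]:
            table = _table_for(tab, project, ref_spectrum, config,
                               seed_base=int(plan.get("seed", 0)))
            synthetic = simulate_fid(table, config.acq)
            if "solvent" in plan:
                synthetic = add_solvent(synthetic, SolventSpec(**plan["solvent"]),
                                        seed=int(plan.get("seed", 0)))
            combined = inject(reference, synthetic)
            for sched_entry in plan["schedules"]:
                schedule = _schedule_for(sched_entry, project, config)
                nus = subsample(combined, schedule)
                for script in plan["scripts"]:
                    rundir = runs_dir / "__".join(
                        (exp["id"], tab["id"], sched_entry["id"], script["id"]))
                    record_path = rundir / "record.json"
                    if record_path.exists() and not force:
                        records.append(EvaluationRecord.read(record_path))
                        continue
                    rundir.mkdir(parents=True, exist_ok=True)
                    try:
                        t0 = time.perf_counter()
                        spectrum = _reconstruct_for(script, nus, config, rundir)
                        recon_s = time.perf_counter() - t0
                        record = evaluate_reconstruction(
                            spectrum, table, config,
                            contestant=script["id"], table_id=tab["id"],
                            schedule_id=sched_entry["id"],
                            coverage_percent=coverage(schedule),
                            reference_peaks=ref_positions,
                            out_dir=rundir,
                        )
                        record.durations_s["reconstruction"] = recon_s
                        record.write(record_path)
                        records.append(record)
                    except NusbenchError as err:
                        (rundir / "error.txt").write_text(
                            f"{type(err).__name__}: {err}\n{traceback.format_exc()}"
                        )
    return records


def project_status(project) -> dict:
    """Report progress of each evaluation task in a project directory."""
    project = Path(project)
    runs = sorted((project / "runs").glob("*")) if (project / "runs").exists() else []
    status = {"complete": [], "failed": [], "pending": []}
    for run in runs:
        if (run / "record.json").exists():
            status["complete"].append(run.name)
        elif (run / "error.txt").exists():
            status["failed"].append(run.name)
        else:
            status["pending"].append(run.name)
    return status
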