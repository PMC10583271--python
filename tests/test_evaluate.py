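"""Records, percentile rank lists, challenge aggregation, and the workflow."""

import json

import numpy as np
import pytest

from nusbench import (
    ChallengeConfig,
    EvaluationRecord,
    PeakTable,
    SyntheticPeak,
    aggregate_challenge,
    evaluate_reconstruction,
    inject,
    process_dft,
    project_status,
    rank_lists,
    run_workflow,
    simulate_fid,
    write_challenge_config,
    write_peak_table,
)
from nusbench.evaluate import _percentiles_from_scores
from nusbench.simulate import make_synthetic_reference
from conftest import plain_processing


def record_with(contestant, scores, experiment="e", table="t", schedule="s"):
    r = EvaluationRecord(experiment=experiment, table_id=table,
                         schedule_id=schedule, contestant=contestant)
    for metric, value in scores.items():
        r.scores[metric] = {"value": value, "not_applicable": False,
                            "degenerate": False}
    return r


class TestPercentiles:
    def test_three_distinct_scores(self):
        ranks, pcts = _percentiles_from_scores([0.9, 0.5, 0.1])
        assert ranks == [1, 2, 3]
        assert pcts == [100.0, 50.0, 0.0]

    def test_two_way_tie_at_top(self):
        ranks, pcts = _percentiles_from_scores([0.9, 0.9, 0.1])
        assert pcts == [75.0, 75.0, 0.0]
        assert ranks[:2] == [1, 1]

    def test_single_contestant_is_100(self):
        assert _percentiles_from_scores([0.42])[1] == [100.0]

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(1, 9))
            scores = list(np.round(rng.uniform(size=n), 2))
            _, pcts = _percentiles_from_scores(scores)
            # brute-force oracle: per contestant, mean percentile over all
            # positions its tied group occupies in the descending sort
            order = sorted(range(n), key=lambda i: -scores[i])
            base = [100.0] * n if n == 1 else \
                [100.0 * (n - (r + 1)) / (n - 1) for r in range(n)]
            expected = [0.0] * n
            for i in range(n):
                positions = [r for r, j in enumerate(order)
                             if scores[j] == scores[i]]
                expected[i] = float(np.mean([base[r] for r in positions]))
            assert pcts == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self):
        scores = [0.1, 0.7, 0.4, 0.7]
        _, p1 = _percentiles_from_scores(scores)
        _, p2 = _percentiles_from_scores([np.exp(5 * s) for s in scores])
        assert p1 == pytest.approx(p2)


class TestRankLists:
    def test_m4_oriented_as_one_minus_fpr(self):
        records = [record_with("a", {"M4": 0.1}), record_with("b", {"M4": 0.7})]
        table = rank_lists(records, metrics=("M4",))
        col = table.columns[("M4", "e", "t", "s")]
        assert col[0]["contestant"] == "a"  # lower FPR ranks first
        assert col[0]["percentile"] == 100.0

    def test_missing_submissions_skipped(self):
        records = [record_with("a", {"M1": 0.9}), record_with("b", {})]
        table = rank_lists(records, metrics=("M1",))
        col = table.columns[("M1", "e", "t", "s")]
        assert [e["contestant"] for e in col] == ["a"]
        assert col[0]["percentile"] == 100.0

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        records = [record_with("a", {"M1": 0.9, "M3": 1.0}),
                   record_with("b", {"M1": 0.3, "M3": 0.5})]
        path = tmp_path / "ranks.csv"
        rank_lists(records).to_csv(path)
        df = pd.read_csv(path)
        assert set(df["contestant"]) == {"a", "b"}
        assert set(df["metric"]) == {"M1", "M3"}


class TestAggregation:
    def test_singleton_challenge_equals_rank_list(self):
        records = [record_with("a", {"M1": 0.9}), record_with("b", {"M1": 0.3})]
        table = rank_lists(records, metrics=("M1",))
        result = aggregate_challenge(table, {"metrics": ["M1"]})
        assert result == [("a", 100.0), ("b", 0.0)]

    def test_absent_contestant_column_excluded_from_mean(self):
        records = [
            record_with("a", {"M1": 0.9}, table="t1"),
            record_with("b", {"M1": 0.3}, table="t1"),
            record_with("a", {"M1": 0.5}, table="t2"),  # b skipped t2
        ]
        result = dict(aggregate_challenge(rank_lists(records, metrics=("M1",)), {}))
        assert result["a"] == pytest.approx((100.0 + 100.0) / 2)
        assert result["b"] == pytest.approx(0.0)

    def test_hand_computed_two_by_two(self):
        records = [
            record_with("a", {"M1": 0.9}, table="t1"),
            record_with("b", {"M1": 0.3}, table="t1"),
            record_with("a", {"M1": 0.2}, table="t2"),
            record_with("b", {"M1": 0.8}, table="t2"),
        ]
        result = dict(aggregate_challenge(rank_lists(records, metrics=("M1",)), {}))
        assert result["a"] == pytest.approx(50.0)
        assert result["b"] == pytest.approx(50.0)

    def test_empty_selection_raises(self):
        records = [record_with("a", {"M1": 0.9})]
        with pytest.raises(Exception, match="select"):
            aggregate_challenge(rank_lists(records), {"metrics": ["M3"]})


class TestEvaluateReconstruction:
    def _strong_table(self, acq):
        peaks = [
            SyntheticPeak(5.0, (1000.0, 300.0), (20.0, 15.0), (0.0, 0.0), ((), ())),
            SyntheticPeak(4.0, (-800.0, -500.0), (20.0, 15.0), (0.0, 0.0), ((), ())),
            SyntheticPeak(3.0, (200.0, 600.0), (20.0, 15.0), (0.0, 0.0), ((), ())),
        ]
        return PeakTable(peaks=peaks)

    def test_unsubsampled_injected_data_gives_full_recovery(self, acq2d, config2d_plain):
        reference, _ = make_synthetic_reference(acq2d, 0, seed=1, noise_sigma=0.01)
        table = self._strong_table(acq2d)
        combined = inject(reference, simulate_fid(table, acq2d))
        spectrum = process_dft(combined, config2d_plain)
        record = evaluate_reconstruction(spectrum, table, config2d_plain)
        assert record.scores["M3"]["value"] == 1.0
        assert record.scores["M2"]["value"] > 0.99

    def test_determinism(self, acq2d, config2d_plain):
        reference, _ = make_synthetic_reference(acq2d, 2, seed=1, noise_sigma=0.01)
        table = self._strong_table(acq2d)
        spectrum = process_dft(inject(reference, simulate_fid(table, acq2d)),
                               config2d_plain)
        r1 = evaluate_reconstruction(spectrum, table, config2d_plain)
        r2 = evaluate_reconstruction(spectrum, table, config2d_plain)
        assert r1.scores == r2.scores

    def test_record_json_round_trip(self, tmp_path, acq2d, config2d_plain):
        reference, _ = make_synthetic_reference(acq2d, 1, seed=1, noise_sigma=0.01)
        table = self._strong_table(acq2d)
        spectrum = process_dft(inject(reference, simulate_fid(table, acq2d)),
                               config2d_plain)
        record = evaluate_reconstruction(spectrum, table, config2d_plain,
                                         out_dir=tmp_path)
        back = EvaluationRecord.read(tmp_path / "record.json")
        assert back.scores == record.scores
        assert back.experiment == record.experiment

    def test_oversized_spectrum_disqualified(self, acq2d, config2d_plain):
        from nusbench import AxisCalibration, Spectrum

        axes = (AxisCalibration(1024, 0.0, 1.0, 600.0),
                AxisCalibration(64, 0.0, 1.0, 60.0))
        spectrum = Spectrum(np.zeros((1024, 64)), axes)
        record = evaluate_reconstruction(spectrum, self._strong_table(acq2d),
                                         config2d_plain)
        assert record.disqualified
        assert record.scores == {}


class TestWorkflow:
    def _project(self, tmp_path, acq2d, config2d_plain):
        project = tmp_path / "project"
        project.mkdir()
        write_challenge_config(project / "config.json", config2d_plain)
        t1 = PeakTable(peaks=[
            SyntheticPeak(5.0, (1000.0, 300.0), (20.0, 0.0), (0.0, 0.0), ((), ())),
            SyntheticPeak(4.0, (-800.0, -500.0), (20.0, 0.0), (0.0, 0.0), ((), ())),
        ])
        t2 = PeakTable(peaks=[
            SyntheticPeak(3.0, (200.0, 600.0), (20.0, 0.0), (0.0, 0.0), ((), ())),
            SyntheticPeak(2.0, (-200.0, -100.0), (20.0, 0.0), (0.0, 0.0), ((), ())),
        ])
        write_peak_table(project / "t1.tsv", t1)
        write_peak_table(project / "t2.tsv", t2)
        plan = {
            "experiments": [{"id": "exp", "config": "config.json",
                             "synthetic_reference": {"n_peaks": 2, "seed": 3,
                                                     "noise_sigma": 0.01}}],
            "tables": [{"id": "t1", "path": "t1.tsv"},
                       {"id": "t2", "path": "t2.tsv"}],
            "schedules": [{"id": "low", "n_indels": 24, "seed": 1,
                           "decay_rates_hz": [0.0]},
                          {"id": "high", "n_indels": 48, "seed": 1,
                           "decay_rates_hz": [0.0]}],
            "scripts": [{"id": "ist", "builtin": "ist",
                         "params": {"iterations": 40}}],
        }
        (project / "plan.json").write_text(json.dumps(plan))
        return project

    def test_combinatorics_1x2x2x1_gives_4_records(self, tmp_path, acq2d, config2d_plain):
        project = self._project(tmp_path, acq2d, config2d_plain)
        records = run_workflow(project, project / "plan.json")
        assert len(records) == 4
        assert {(r.table_id, r.schedule_id) for r in records} == {
            ("t1", "low"), ("t1", "high"), ("t2", "low"), ("t2", "high")}
        status = project_status(project)
        assert len(status["complete"]) == 4 and not status["failed"]

    def test_rerun_is_noop_and_resume_completes_missing(self, tmp_path, acq2d,
                                                        config2d_plain):
        project = self._project(tmp_path, acq2d, config2d_plain)
        records = run_workflow(project, project / "plan.json")
        mtimes = {p: p.stat().st_mtime_ns
                  for p in (project / "runs").glob("*/record.json")}
        again = run_workflow(project, project / "plan.json")
        assert len(again) == len(records)
        for p, t in mtimes.items():
            assert p.stat().st_mtime_ns == t  # untouched: no-op rerun
        # simulate an interrupted run: delete one record, resume fills it
        victim = sorted(mtimes)[0]
        victim.unlink()
        resumed = run_workflow(project, project / "plan.json")
        assert len(resumed) == 4
        assert victim.exists()
        # the untouched records were not recomputed
        for p, t in mtimes.items():
            if p != victim:
                assert p.stat().st_mtime_ns == t
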