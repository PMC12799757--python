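"""Leave-one-subject-out folds, error statistics, and experiment runs."""

import numpy as np
import pytest

from hemaspec import (
    ExperimentConfig,
    FeatureDataset,
    PredictionRecord,
    WavelengthGrid,
    exclusion_rerun,
    lopo_folds,
    rmse_days,
    run_experiment,
    window_stats,
)

CFG = ExperimentConfig(n_alphas=25, alpha_min_ratio=1e-3)


def _dataset(n_subjects=3, per_subject=2, p=4, seed=0):
    rng = np.random.default_rng(seed)
    n = n_subjects * per_subject
    return FeatureDataset(
        X=rng.normal(size=(n, p)),
        y=rng.uniform(0, 500, size=n),
        subject=np.repeat([f"S{i}" for i in range(n_subjects)], per_subject),
        sex=np.repeat(["M", "F"] * ((n_subjects + 1) // 2), per_subject)[:n],
        method="divide",
        grid=WavelengthGrid(p, 400, 1000),
    )


def _pred(subject, true_h, pred_h, sex="M"):
    return PredictionRecord(subject, sex, true_h, pred_h, "test")


class TestFolds:
    def test_one_fold_per_subject_with_right_sizes(self):
        folds = lopo_folds(_dataset(3, 2))
        assert len(folds) == 3
        for train, test in folds:
            assert len(train) == 4 and len(test) == 2

    def test_folds_partition_the_dataset(self):
        ds = _dataset(5, 3)
        folds = lopo_folds(ds)
        all_test = np.concatenate([test for _, test in folds])
        assert sorted(all_test) == list(range(ds.n_samples))
        for train, test in folds:
            assert not set(train) & set(test)
            assert not set(ds.subject[train]) & set(ds.subject[test])

    def test_25_subjects_give_25_folds(self):
        assert len(lopo_folds(_dataset(25, 1))) == 25

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            lopo_folds(_dataset(1, 4))


class TestRmse:
    def test_perfect_predictions_give_zero(self):
        assert rmse_days([_pred("S1", 100.0, 100.0)]) == 0.0

    def test_symmetric_24h_errors_give_one_day(self):
        preds = [_pred("S1", 100.0, 124.0), _pred("S2", 100.0, 76.0)]
        assert rmse_days(preds) == pytest.approx(1.0)

    def test_hand_arithmetic_123(self):
        preds = [_pred("S1", 0.0, 24.0), _pred("S1", 0.0, 48.0), _pred("S1", 0.0, 72.0)]
        assert rmse_days(preds) == pytest.approx(np.sqrt(14 / 3))

    def test_matches_bruteforce_recomputation(self, rng):
        preds = [
            _pred(f"S{i % 4}", t, p)
            for i, (t, p) in enumerate(zip(rng.uniform(0, 500, 40), rng.uniform(-50, 600, 40)))
        ]
        import math

        brute = math.sqrt(
            math.fsum(((p.predicted_hours - p.true_hours) / 24) ** 2 for p in preds)
            / len(preds)
        )
        assert rmse_days(preds) == brute

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rmse_days([])


class TestWindowStats:
    def test_single_subject_has_no_sd(self):
        preds = [_pred("S1", 50.0, 74.0), _pred("S1", 60.0, 132.0)]  # errors 1 and 3 d
        stats = window_stats(preds)
        m, sd = stats["up_to_day7"]
        assert m == pytest.approx(2.0)
        assert sd is None

    def test_two_subjects_hand_arithmetic(self):
        preds = [_pred("S1", 50.0, 98.0), _pred("S2", 60.0, 156.0)]  # MADs 2 and 4 d
        m, sd = window_stats(preds)["full"]
        assert m == pytest.approx(3.0)
        assert sd == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_exact_predictions_give_zero_mean_and_sd(self):
        preds = [_pred("S1", 50.0, 50.0), _pred("S2", 400.0, 400.0)]
        for window in ("up_to_day7", "after_day7", "full"):
            m, sd = window_stats(preds)[window]
            assert m == 0.0
            assert sd is None or sd == 0.0

    def test_membership_by_true_age_with_inclusive_day7(self):
        preds = [_pred("S1", 168.0, 100.0), _pred("S2", 168.1, 100.0)]
        stats = window_stats(preds)
        assert [p.subject_id for p in preds if p.true_hours <= 168] == ["S1"]
        assert stats["up_to_day7"][0] == pytest.approx(68 / 24 / 1)
        assert stats["after_day7"][0] == pytest.approx(68.1 / 24)

    def test_empty_window_is_absent_not_zero(self):
        preds = [_pred("S1", 50.0, 60.0)]
        assert "after_day7" not in window_stats(preds)

    def test_m_and_sd_are_across_subjects_not_predictions(self):
        # S1 has many predictions, S2 one: M must weight subjects equally
        preds = [_pred("S1", 50.0, 74.0)] * 5 + [_pred("S2", 50.0, 122.0)]
        m, _ = window_stats(preds)["full"]
        assert m == pytest.approx((1.0 + 3.0) / 2)


class TestRunExperiment:
    def test_report_is_consistent_and_reproducible(self, small_recordings):
        report = run_experiment(small_recordings, "divide", "plain", CFG)
        n_usable = sum(not r.is_pre_injection for r in small_recordings)
        assert len(report.predictions) == n_usable
        assert report.rmse_days == rmse_days(report.predictions)
        recomputed = window_stats(report.predictions)
        assert recomputed == report.window_stats
        # pooled RMSE dominates pooled MAD (Jensen)
        mad = np.mean(
            [abs(p.predicted_hours - p.true_hours) / 24 for p in report.predictions]
        )
        assert report.rmse_days >= mad
        again = run_experiment(small_recordings, "divide", "plain", CFG)
        assert [p.predicted_hours for p in again.predictions] == [
            p.predicted_hours for p in report.predictions
        ]

    def test_every_subject_appears_once_in_mad_map(self, small_recordings):
        report = run_experiment(small_recordings, "divide", "plain", CFG)
        subjects = {r.subject_id for r in small_recordings}
        assert set(report.per_subject_mad_days) == subjects

    @pytest.mark.parametrize("architecture", ["hierarchical", "gender"])
    def test_architectures_produce_full_reports(self, small_recordings, architecture):
        report = run_experiment(small_recordings, "divide", architecture, CFG)
        assert np.isfinite(report.rmse_days)
        assert len(report.predictions) == sum(
            not r.is_pre_injection for r in small_recordings
        )


class TestExclusionRerun:
    def test_excluded_recordings_are_still_predicted(self, small_recordings):
        usable = [r for r in small_recordings if not r.is_pre_injection]
        keys = {(usable[0].subject_id, usable[0].age_hours),
                (usable[-1].subject_id, usable[-1].age_hours)}
        report = exclusion_rerun(small_recordings, keys, "divide", "plain", CFG)
        predicted = {(p.subject_id, p.true_hours) for p in report.predictions}
        assert keys <= predicted
        assert len(report.predictions) == len(usable)

    def test_exclusion_changes_training(self, small_recordings):
        usable = [r for r in small_recordings if not r.is_pre_injection]
        keys = {(r.subject_id, r.age_hours) for r in usable if r.subject_id == "S01"}
        base = run_experiment(small_recordings, "divide", "plain", CFG)
        excl = exclusion_rerun(small_recordings, keys, "divide", "plain", CFG)
        others = [p.predicted_hours for p in excl.predictions if p.subject_id != "S01"]
        base_others = [p.predicted_hours for p in base.predictions if p.subject_id != "S01"]
        assert others != base_others
        # the held-out subject's own fold never contained its recordings anyway
        own = [p.predicted_hours for p in excl.predictions if p.subject_id == "S01"]
        base_own = [p.predicted_hours for p in base.predictions if p.subject_id == "S01"]
        assert own == base_own

    def test_unknown_key_rejected(self, small_recordings):
        with pytest.raises(KeyError):
            exclusion_rerun(small_recordings, {("nobody", 1.0)}, "divide", "plain", CFG)
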