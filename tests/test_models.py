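import numpy as np
import pytest

import neurosteps.models as models
from neurosteps import (
    REGRESSORS,
    SensorAnalysisConfig,
    WindowedDataset,
    aggregate_total,
    build_windowed_dataset,
    full_grid,
    loso_folds,
    loso_subject_predictions,
    run_config_grid,
    scores_to_frame,
    train_and_score,
)
from neurosteps.features import feature_registry


def _toy_dataset(n_subjects=4, windows_per_subject=30, seed=0, window_length=5.0):
    """Features linearly predictive of counts plus noise."""
    rng = np.random.default_rng(seed)
    n = n_subjects * windows_per_subject
    d = len(feature_registry())
    X = rng.normal(0, 1, (n, d))
    y = np.clip(2.0 + 1.5 * X[:, 0] + rng.normal(0, 0.3, n), 0, None)
    subjects = np.repeat([f"S{i}" for i in range(n_subjects)], windows_per_subject)
    starts = np.tile(np.arange(windows_per_subject) * window_length / 2, n_subjects)
    totals = {f"S{i}": int(y[subjects == f"S{i}"].sum() / 2) for i in range(n_subjects)}
    return WindowedDataset(X=X, y=y, subject_ids=subjects.astype(object),
                           window_starts=starts, window_length=window_length,
                           true_totals=totals)


CONFIG = SensorAnalysisConfig("waist", "narrow", 5.0, "GB")


class TestLosoFolds:
    def test_full_loso_holds_out_each_subject_once(self):
        ids = [f"S{i}" for i in range(7)]
        folds = loso_folds(ids, 7, seed=0)
        assert sorted(test for _, test in folds) == sorted(ids)
        for train, test in folds:
            assert test not in train
            assert len(train) == 6

    def test_partial_loso_distinct_and_reproducible(self):
        ids = [f"S{i}" for i in range(7)]
        a = loso_folds(ids, 3, seed=5)
        b = loso_folds(ids, 3, seed=5)
        assert a == b
        assert len({test for _, test in a}) == 3

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError, match="LOSO"):
            loso_folds(["a", "b"], 3)


class TestScoring:
    def test_perfect_predictions_give_zero_rmse(self, monkeypatch):
        ds = _toy_dataset()

        def perfect(Xtr, ytr, Xte, name, seed):
            # look the test rows up in the dataset and return their labels
            idx = [np.flatnonzero((ds.X == row).all(axis=1))[0] for row in Xte]
            return ds.y[idx]

        monkeypatch.setattr(models, "_fit_predict", perfect)
        folds = loso_folds(ds.subjects, 4, seed=0)
        score = train_and_score(ds, CONFIG, folds)
        assert score.rmse_per_s == 0.0
        assert score.rmse_per_s == np.median(score.fold_rmses)

    def test_constant_predictor_matches_closed_form(self, monkeypatch):
        ds = _toy_dataset()
        def constant(Xtr, ytr, Xte, name, seed):
            return np.full(len(Xte), ytr.mean())
        monkeypatch.setattr(models, "_fit_predict", constant)
        folds = loso_folds(ds.subjects, 4, seed=0)
        score = train_and_score(ds, CONFIG, folds)
        expected = []
        for train_ids, test_id in folds:
            tr = np.isin(ds.subject_ids, train_ids)
            te = ds.subject_ids == test_id
            rmse = np.sqrt(np.mean((ds.y[te] - ds.y[tr].mean()) ** 2))
            expected.append(rmse / ds.window_length)
        assert score.rmse_per_s == pytest.approx(np.median(expected))

    def test_rmse_scaling_to_one_second(self):
        # window RMSE of 1.5 steps on 5 s windows is 0.30 steps/s
        assert 1.5 / 5.0 == pytest.approx(0.30)

    def test_unknown_regressor_rejected(self):
        with pytest.raises(ValueError, match="unknown regressor"):
            models.make_regressor("XGB")

    def test_swapping_test_subject_changes_fold_score(self):
        ds = _toy_dataset()
        folds_a = [(["S1", "S2", "S3"], "S0")]
        folds_b = [(["S0", "S2", "S3"], "S1")]
        a = train_and_score(ds, SensorAnalysisConfig("waist", "narrow", 5.0, "kNN"), folds_a)
        b = train_and_score(ds, SensorAnalysisConfig("waist", "narrow", 5.0, "kNN"), folds_b)
        assert a.rmse_per_s != b.rmse_per_s

    def test_noisier_features_never_easier(self):
        # adding i.i.d. feature noise does not decrease held-out RMSE in
        # expectation (averaged over seeds)
        cfg = SensorAnalysisConfig("waist", "narrow", 5.0, "kNN")
        base_scores, noisy_scores = [], []
        for seed in range(5):
            ds = _toy_dataset(seed=seed)
            folds = loso_folds(ds.subjects, 4, seed=seed)
            base_scores.append(train_and_score(ds, cfg, folds).rmse_per_s)
            rng = np.random.default_rng(100 + seed)
            noisy = WindowedDataset(X=ds.X + rng.normal(0, 2.0, ds.X.shape), y=ds.y,
                                    subject_ids=ds.subject_ids,
                                    window_starts=ds.window_starts,
                                    window_length=ds.window_length,
                                    true_totals=ds.true_totals)
            noisy_scores.append(train_and_score(noisy, cfg, folds).rmse_per_s)
        assert np.mean(noisy_scores) >= np.mean(base_scores)


class TestAggregation:
    def test_non_overlapping_sum(self):
        assert aggregate_total([2, 3, 4], overlap_fraction=0.0) == 9

    def test_uniform_overlap(self):
        p, W = 1.8, 40
        total = aggregate_total(np.full(W, p), overlap_fraction=0.5)
        assert total == pytest.approx(p * W / 2, rel=0.03)

    def test_all_zero(self):
        assert aggregate_total(np.zeros(10)) == 0.0

    def test_negative_predictions_clipped(self):
        assert aggregate_total([-1.0, -2.0], overlap_fraction=0.0) == 0.0

    def test_unbiased_for_locally_constant_predictions(self):
        # predictions equal to true window counts of a uniform step train
        # recover the true total
        step_times = np.arange(0.5, 99.5, 1.0)  # 99 steps over 100 s
        starts = np.arange(0.0, 95.1, 2.5)
        counts = [np.sum((step_times >= s) & (step_times < s + 5.0)) for s in starts]
        total = aggregate_total(counts, overlap_fraction=0.5)
        covered = np.sum(step_times < starts[-1] + 5.0)
        assert total == pytest.approx(covered, abs=1.5)


class TestGrid:
    def test_grid_sizes(self):
        assert len(full_grid()) == 7 * 3 * 3 * 5 == 315
        no_short = [c for c in full_grid() if c.window_length != 0.5]
        assert len(no_short) == 7 * 3 * 2 * 5 == 210

    def test_subset_grid_scores_and_determinism(self, small_cohort):
        configs = [
            SensorAnalysisConfig("waist", "narrow", 5.0, "kNN"),
            SensorAnalysisConfig("ankle", "narrow", 5.0, "kNN"),
        ]
        a = run_config_grid(small_cohort, configs, n_folds=3, seed=7)
        b = run_config_grid(small_cohort, configs, n_folds=3, seed=7)
        assert len(a) == 2
        assert [s.rmse_per_s for s in a] == [s.rmse_per_s for s in b]
        frame = scores_to_frame(a)
        assert list(frame.columns) == ["location", "filter_band", "window_length",
                                       "regressor", "rmse_per_s"]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SensorAnalysisConfig("hip", "narrow", 5.0, "GB")
        with pytest.raises(ValueError):
            SensorAnalysisConfig("waist", "narrow", 4.0, "GB")
        with pytest.raises(ValueError):
            SensorAnalysisConfig("waist", "narrow", 5.0, "CNN")


class TestSubjectPredictions:
    def test_loso_totals_on_cohort(self, small_cohort):
        ds = build_windowed_dataset(small_cohort, "waist", "narrow", 5.0)
        preds = loso_subject_predictions(ds, "kNN", seed=0)
        assert {p.subject_id for p in preds} == set(small_cohort.subject_ids)
        for p in preds:
            assert p.predicted_total_steps >= 0
            assert p.true_total_steps == small_cohort.annotations(p.subject_id).n_steps

    def test_dataset_shape(self, small_cohort):
        ds = build_windowed_dataset(small_cohort, "waist", "narrow", 5.0)
        assert ds.X.shape[1] == len(feature_registry())
        assert ds.X.shape[0] == len(ds.y) == len(ds.subject_ids)
        assert np.isfinite(ds.X).all()
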