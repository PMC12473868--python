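"""Window-level step-count regressors over the configuration grid.

A configuration is one cell of sensor location × filter band × window length
× regressor type.  Each cell is scored by leave-one-subject-out (LOSO)
cross-validation: the regressor maps per-window features to the window's true
step count, the held-out subject's window RMSE is divided by the window
length (``steps/s``, making window lengths comparable), and the cell's score
is the *median* across folds.

Regressors use library defaults with a fixed seed — the comparison is about
the sensing and analysis configuration, not hyperparameter tuning.  Feature
standardization statistics come from the training folds only (no leakage).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .features import extract_features, feature_registry
from .io_sync import LOCATIONS, AccelRecording, StepAnnotationSet
from .preprocessing import (
    FILTER_BANDS,
    WINDOW_LENGTHS,
    apply_filter,
    assign_axes,
    make_windows,
    window_slices,
)
from .synthetic import Cohort

REGRESSORS = ("GB", "kNN", "MLP", "RF", "SVR")


@dataclass(frozen=True)
class SensorAnalysisConfig:
    """One grid cell: location, filter band, window length, regressor."""

    location: str
    filter_band: str
    window_length: float
    regressor: str

    def __post_init__(self):
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}")
        if self.filter_band not in FILTER_BANDS:
            raise ValueError(f"unknown filter band {self.filter_band!r}")
        if self.window_length not in WINDOW_LENGTHS:
            raise ValueError(f"window length must be one of {WINDOW_LENGTHS}")
        if self.regressor not in REGRESSORS:
            raise ValueError(f"unknown regressor {self.regressor!r}")

    def label(self) -> str:
        return f"{self.location}/{self.filter_band}/{self.window_length:g}s/{self.regressor}"


@dataclass(frozen=True)
class ConfigScore:
    config: SensorAnalysisConfig
    rmse_per_s: float
    fold_rmses: tuple[float, ...]


@dataclass(frozen=True)
class SubjectPrediction:
    subject_id: str
    predicted_total_steps: float
    true_total_steps: int


@dataclass
class WindowedDataset:
    """Valid windows of one (location, filter, window-length) cell, featureised."""

    X: np.ndarray                  # (n_windows, n_features)
    y: np.ndarray                  # true step counts
    subject_ids: np.ndarray        # per-window subject
    window_starts: np.ndarray      # per-window start time, s
    window_length: float
    true_totals: dict[str, int]    # per-subject annotated step total

    @property
    def subjects(self) -> list[str]:
        seen = dict.fromkeys(self.subject_ids.tolist())
        return list(seen)


def make_regressor(name: str, seed: int = 0):
    """Instantiate one of the five regressor types (library defaults)."""
    if name == "GB":
        return GradientBoostingRegressor(random_state=seed)
    if name == "kNN":
        return KNeighborsRegressor()
    if name == "MLP":
        return MLPRegressor(random_state=seed)
    if name == "RF":
        return RandomForestRegressor(random_state=seed)
    if name == "SVR":
        return SVR()
    raise ValueError(f"unknown regressor {name!r}; expected one of {REGRESSORS}")


def build_windowed_dataset(cohort: Cohort, location: str, filter_band: str,
                           window_length: float) -> WindowedDataset:
    """Preprocess and featureise one cohort for one preprocessing cell.

    Axes are assigned on the raw signal, the band filter is applied, windows
    are labelled against the annotations, and invalid (excluded) windows are
    dropped before feature extraction.
    """
    rows, counts, subjects, starts = [], [], [], []
    true_totals: dict[str, int] = {}
    for sid in cohort.subject_ids:
        rec = cohort.recording(sid, location)
        ann = cohort.annotations(sid)
        true_totals[sid] = ann.n_steps
        axes = assign_axes(rec)
        filtered = apply_filter(rec, filter_band)
        vert = axes.vertical_sign * filtered.accel[:, axes.vertical_index]
        ap = filtered.accel[:, axes.anteroposterior_index]
        windows = make_windows(rec, ann, window_length)
        for w, sl in zip(windows, window_slices(rec, windows)):
            if not w.valid:
                continue
            rows.append(extract_features(vert[sl], ap[sl], rec.sample_rate))
            counts.append(w.true_step_count)
            subjects.append(sid)
            starts.append(w.start)
    return WindowedDataset(
        X=np.array(rows).reshape(len(rows), len(feature_registry())),
        y=np.array(counts, dtype=float),
        subject_ids=np.array(subjects, dtype=object),
        window_starts=np.array(starts, dtype=float),
        window_length=float(window_length),
        true_totals=true_totals,
    )


def loso_folds(subject_ids, n_folds: int, seed: int = 0):
    """Leave-one-subject-out folds.

    Each fold holds out exactly one subject; the held-out subjects are drawn
    without replacement with the given seed.  With ``n_folds`` equal to the
    number of subjects every subject is held out once.
    """
    subject_ids = list(subject_ids)
    if n_folds > len(subject_ids):
        raise ValueError(
            f"cannot make {n_folds} LOSO folds from {len(subject_ids)} subjects"
        )
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    rng = np.random.default_rng(seed)
    held_out = rng.choice(len(subject_ids), size=n_folds, replace=False)
    folds = []
    for i in held_out:
        test_id = subject_ids[int(i)]
        train_ids = [s for s in subject_ids if s != test_id]
        folds.append((train_ids, test_id))
    return folds


def _fit_predict(X_train, y_train, X_test, regressor_name: str, seed: int):
    scaler = StandardScaler().fit(X_train)
    model = make_regressor(regressor_name, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP may hit its iteration cap
        model.fit(scaler.transform(X_train), y_train)
        return model.predict(scaler.transform(X_test))


def train_and_score(dataset: WindowedDataset, config: SensorAnalysisConfig,
                    folds, seed: int = 0) -> ConfigScore:
    """Score one configuration: median across folds of held-out window RMSE
    divided by the window length (steps/s)."""
    fold_rmses = []
    for train_ids, test_id in folds:
        train_mask = np.isin(dataset.subject_ids, train_ids)
        test_mask = dataset.subject_ids == test_id
        if not train_mask.any():
            raise ValueError(f"empty training fold for held-out subject {test_id!r}")
        preds = _fit_predict(dataset.X[train_mask], dataset.y[train_mask],
                             dataset.X[test_mask], config.regressor, seed)
        rmse = float(np.sqrt(np.mean((preds - dataset.y[test_mask]) ** 2)))
        fold_rmses.append(rmse / dataset.window_length)
    return ConfigScore(config=config, rmse_per_s=float(np.median(fold_rmses)),
                       fold_rmses=tuple(fold_rmses))


def aggregate_total(window_predictions, overlap_fraction: float = 0.5) -> float:
    """Turn per-window step predictions into a subject total.

    Predictions are clipped at zero.  With non-overlapping windows the total
    is the plain sum.  With 50 % overlap every instant is covered by two
    windows except the first and last half-windows, so the unbiased total is
    ``0.5 × Σp + 0.25 × (p_first + p_last)``.
    """
    p = np.clip(np.asarray(window_predictions, dtype=float), 0.0, None)
    if p.size == 0:
        return 0.0
    if overlap_fraction == 0:
        return float(p.sum())
    if overlap_fraction != 0.5:
        raise ValueError("only 0 or 0.5 overlap supported")
    return float(0.5 * p.sum() + 0.25 * (p[0] + p[-1]))


def loso_subject_predictions(dataset: WindowedDataset, regressor_name: str = "GB",
                             seed: int = 0) -> list[SubjectPrediction]:
    """Per-subject total-step predictions under full LOSO (one fold per subject)."""
    predictions = []
    subjects = dataset.subjects
    for sid in subjects:
        train_mask = dataset.subject_ids != sid
        test_mask = ~train_mask
        preds = _fit_predict(dataset.X[train_mask], dataset.y[train_mask],
                             dataset.X[test_mask], regressor_name, seed)
        order = np.argsort(dataset.window_starts[test_mask])
        total = aggregate_total(preds[order], overlap_fraction=0.5)
        predictions.append(SubjectPrediction(
            subject_id=sid,
            predicted_total_steps=total,
            true_total_steps=int(dataset.true_totals[sid]),
        ))
    return predictions


def full_grid(locations=LOCATIONS, bands=tuple(FILTER_BANDS),
              window_lengths=WINDOW_LENGTHS, regressors=REGRESSORS):
    """Enumerate the configuration grid (7 × 3 × 3 × 5 = 315 cells in full)."""
    return [
        SensorAnalysisConfig(loc, band, wl, reg)
        for loc in locations
        for band in bands
        for wl in window_lengths
        for reg in regressors
    ]


def run_config_grid(cohort: Cohort, configs, n_folds: int = 3,
                    seed: int = 0) -> list[ConfigScore]:
    """Score every configuration in ``configs`` on one cohort.

    Datasets are cached per preprocessing cell; the held-out subjects for each
    configuration are drawn from a seed derived stably from the master seed
    and the configuration label, so results do not depend on grid order.
    """
    cache: dict[tuple, WindowedDataset] = {}
    scores = []
    for config in configs:
        key = (config.location, config.filter_band, config.window_length)
        if key not in cache:
            cache[key] = build_windowed_dataset(cohort, *key)
        dataset = cache[key]
        fold_seed = (int(seed) * 1_000_003 + zlib.crc32(config.label().encode())) % (2**31)
        folds = loso_folds(cohort.subject_ids, n_folds, seed=fold_seed)
        scores.append(train_and_score(dataset, config, folds, seed=int(seed) % (2**31)))
    return scores


def scores_to_frame(scores) -> pd.DataFrame:
    """Flatten ConfigScores into the table the GLM consumes (bit-stable)."""
    return pd.DataFrame(
        {
            "location": [s.config.location for s in scores],
            "filter_band": [s.config.filter_band for s in scores],
            "window_length": [s.config.window_length for s in scores],
            "regressor": [s.config.regressor for s in scores],
            "rmse_per_s": [s.rmse_per_s for s in scores],
        }
    )
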