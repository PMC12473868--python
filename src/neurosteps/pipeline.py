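"""End-to-end study runner: simulate → grid → GLM → select → compare → report.

A single master seed fans out deterministically to per-stage seeds, so the
whole run — cohort simulation, fold draws, regressor fits — reproduces
bit-identical numeric outputs from the same scenario.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .baselines import cwt_count, tca_count
from .config_glm import (
    WINDOW_NAMES,
    fit_config_glm,
    importance_report,
    residual_fit_test,
    select_optimal_config,
)
from .evaluation import compare_algorithms
from .models import (
    REGRESSORS,
    build_windowed_dataset,
    full_grid,
    loso_subject_predictions,
    run_config_grid,
    scores_to_frame,
)
from .preprocessing import WINDOW_LENGTHS
from .synthetic import SessionSpec, default_cohort_profiles, load_scenario, simulate_cohort

logger = logging.getLogger("neurosteps")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunManifest:
    """What a study run produced, and from what."""

    master_seed: int
    scenario: dict
    outputs: dict[str, str]
    started_utc: str
    finished_utc: str
    version: str = __version__

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _load_config(scenario) -> dict:
    if isinstance(scenario, dict):
        return dict(scenario)
    with open(scenario) as fh:
        return yaml.safe_load(fh)


def run_study(scenario, out_dir, seed: int | None = None) -> RunManifest:
    """Execute the full analysis on a (usually synthetic) scenario.

    ``scenario`` is a YAML path or dict (see :func:`synthetic.load_scenario`
    for the cohort keys; an optional ``grid`` section restricts the factor
    levels, and ``n_folds`` sets the grid LOSO fold count, default 3).
    Emits the effect-size table, the parameter-importance report, the
    selected optimal configuration, the algorithm-comparison tables, and a
    manifest listing every output.  Any stage failure aborts with the stage
    name and cause.
    """
    started = datetime.now(timezone.utc).isoformat()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    cfg = _load_config(scenario)
    if seed is not None:
        cfg["master_seed"] = int(seed)
    master_seed = int(cfg.get("master_seed", 0))
    outputs: dict[str, str] = {}

    try:
        stage = "simulate"
        n_subjects = int(cfg.get("n_subjects", 7))
        spec = SessionSpec(
            duration=float(cfg.get("duration_s", 2100.0)),
            locations=tuple(cfg.get("locations", ("waist",))),
            sample_rate=float(cfg.get("sample_rate", 100.0)),
        )
        profiles = default_cohort_profiles(n_subjects, stage_seed(master_seed, "cohort"))
        logger.info("simulating %d subjects × %.0f s × %d locations (seed %d)",
                    n_subjects, spec.duration, len(spec.locations), master_seed)
        cohort = simulate_cohort(profiles, spec)

        stage = "grid"
        grid_cfg = cfg.get("grid") or {}
        configs = full_grid(
            locations=tuple(grid_cfg.get("locations", spec.locations)),
            bands=tuple(grid_cfg.get("bands", ("wide", "medium", "narrow"))),
            window_lengths=tuple(grid_cfg.get("window_lengths", (2.0, 5.0))),
            regressors=tuple(grid_cfg.get("regressors", REGRESSORS)),
        )
        n_folds = int(cfg.get("n_folds", min(3, n_subjects)))
        logger.info("scoring %d configurations with %d LOSO folds", len(configs), n_folds)
        scores = run_config_grid(cohort, configs, n_folds=n_folds,
                                 seed=stage_seed(master_seed, "grid"))
        scores_df = scores_to_frame(scores)
        scores_path = out_dir / "config_scores.csv"
        scores_df.to_csv(scores_path, index=False)
        outputs["config_scores"] = str(scores_path)

        stage = "glm"
        summary = fit_config_glm(scores)
        ks_stat, ks_p = residual_fit_test(summary)
        logger.info("gamma GLM fitted; KS residual check p = %.4f", ks_p)
        summary_path = out_dir / "glm_summary.csv"
        summary.to_csv(summary_path)
        outputs["glm_summary"] = str(summary_path)
        importance = importance_report(summary)
        importance_path = out_dir / "importance.csv"
        importance.rows.to_csv(importance_path, index=False)
        outputs["importance"] = str(importance_path)
        optimal = select_optimal_config(summary)
        logger.info("selected optimal configuration: %s", optimal.label())
        optimal_path = out_dir / "optimal_config.json"
        with open(optimal_path, "w") as fh:
            json.dump(
                dict(location=optimal.location, filter_band=optimal.filter_band,
                     window_length=optimal.window_length, regressor=optimal.regressor,
                     ks_statistic=ks_stat, ks_p=ks_p), fh, indent=2)
        outputs["optimal_config"] = str(optimal_path)

        stage = "compare"
        dataset = build_windowed_dataset(cohort, optimal.location, optimal.filter_band,
                                         optimal.window_length)
        gb_preds = loso_subject_predictions(dataset, optimal.regressor,
                                            seed=stage_seed(master_seed, "final"))
        true_totals = {p.subject_id: p.true_total_steps for p in gb_preds}
        predictions = {
            optimal.regressor: {p.subject_id: p.predicted_total_steps for p in gb_preds},
            "TCA": {}, "CWT": {},
        }
        for sid in cohort.subject_ids:
            rec = cohort.recording(sid, optimal.location)
            predictions["TCA"][sid] = float(tca_count(rec)[0])
            predictions["CWT"][sid] = float(cwt_count(rec)[0])
        comparison = compare_algorithms(true_totals, predictions)
        logger.info("algorithm comparison: Friedman p = %.4f", comparison.friedman_p)
        cmp_path = out_dir / "comparison_summary.csv"
        comparison.summary.to_csv(cmp_path, index=False)
        outputs["comparison_summary"] = str(cmp_path)
        per_subject_path = out_dir / "comparison_per_subject.csv"
        comparison.per_subject.to_csv(per_subject_path, index=False)
        outputs["comparison_per_subject"] = str(per_subject_path)
        stats_path = out_dir / "comparison_stats.json"
        with open(stats_path, "w") as fh:
            json.dump(dict(
                friedman_statistic=comparison.friedman_statistic,
                friedman_p=comparison.friedman_p,
                shapiro_p=(comparison.normality.shapiro_p
                           if comparison.normality else None),
                normality_decision=(comparison.normality.decision
                                    if comparison.normality else None),
            ), fh, indent=2)
        outputs["comparison_stats"] = str(stats_path)
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"study stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    outputs["log"] = str(log_path)
    manifest = RunManifest(
        master_seed=master_seed,
        scenario=cfg,
        outputs=outputs,
        started_utc=started,
        finished_utc=datetime.now(timezone.utc).isoformat(),
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest
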