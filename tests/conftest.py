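import numpy as np
import pytest

from neurosteps import (
    AccelRecording,
    SessionSpec,
    SubjectProfile,
    default_cohort_profiles,
    simulate_cohort,
    simulate_session,
)
from neurosteps.config_glm import GlmSummary

SAMPLE_RATE = 100.0


def make_sinusoid_recording(freq_hz, duration_s=10.0, amplitude=1.0, gravity=9.80665,
                            location="waist", sample_rate=SAMPLE_RATE, noise_sd=0.0,
                            seed=0):
    """Gravity on z plus a vertical sinusoid — the basic signal oracle."""
    t = np.arange(0.0, duration_s, 1.0 / sample_rate)
    accel = np.zeros((t.size, 3))
    accel[:, 2] = gravity + amplitude * np.sin(2 * np.pi * freq_hz * t)
    if noise_sd > 0:
        accel += np.random.default_rng(seed).normal(0, noise_sd, accel.shape)
    return AccelRecording(subject_id="sine", location=location,
                          sample_rate=sample_rate, time=t, accel=accel)


@pytest.fixture(scope="session")
def clean_bout_session():
    """Noise-free single 10 s bout at 1 step/s — ground-truth recoverable."""
    profile = SubjectProfile(
        subject_id="oracle", mean_cadence=1.0, cadence_jitter_sd=0.0,
        bout_length_range=(10.0, 10.0), shuffle_fraction=0.0,
        asymmetry_factor=1.0, adl_artifact_rate=0.0, seed=11,
        target_step_rate=1.0, noise_scale=0.0,
    )
    spec = SessionSpec(duration=10.0, locations=("ankle", "waist"))
    recordings, annotations = simulate_session(profile, spec)
    return profile, spec, recordings, annotations


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects × 2 min at two locations; realistic noise and artifacts."""
    profiles = default_cohort_profiles(3, master_seed=42)
    spec = SessionSpec(duration=120.0, locations=("waist", "ankle"))
    return simulate_cohort(profiles, spec)


# Published effect-size table used as *input* for reporting arithmetic:
# (parameter, level, exp(beta), ci_low, ci_high, p)
TABLE1_ROWS = [
    ("location", "lower_back", 1.100, 1.002, 1.206, 0.044),
    ("location", "ankle", 1.101, 1.004, 1.208, 0.041),
    ("location", "thigh", 1.195, 1.089, 1.310, 0.0005),
    ("location", "chest", 1.276, 1.164, 1.400, 0.0005),
    ("location", "wrist_l", 1.848, 1.685, 2.027, 0.0005),
    ("location", "wrist_r", 2.002, 1.825, 2.196, 0.0005),
    ("filter_band", "narrow", 0.902, 0.849, 0.958, 0.001),
    ("filter_band", "medium", 0.911, 0.857, 0.968, 0.003),
    ("window_length", "long", 0.772, 0.734, 0.811, 0.0001),
    ("regressor", "RF", 0.989, 0.914, 1.069, 0.776),
    ("regressor", "MLP", 1.063, 0.983, 1.150, 0.125),
    ("regressor", "SVR", 1.089, 1.007, 1.178, 0.032),
    ("regressor", "kNN", 1.128, 1.043, 1.219, 0.003),
]

TABLE1_REFERENCE_RMSE = 0.30


@pytest.fixture(scope="session")
def published_summary():
    return GlmSummary.from_effects(TABLE1_REFERENCE_RMSE, TABLE1_ROWS)


def simulate_gamma_grid(beta, reference_rmse, shape, rng,
                        locations=("waist", "ankle", "thigh", "chest", "lower_back",
                                   "wrist_l", "wrist_r"),
                        bands=("wide", "medium", "narrow"),
                        windows=(2.0, 5.0),
                        regressors=("GB", "kNN", "MLP", "RF", "SVR")):
    """Grid of scores drawn from a gamma GLM with known multiplicative effects.

    ``beta`` maps '<factor>:<level>' → log effect (absent keys default to 0,
    i.e. reference); window levels are named short/medium/long.  Returns a
    DataFrame in the grid-score schema.
    """
    import pandas as pd

    rows = []
    for loc in locations:
        for band in bands:
            for win in windows:
                wname = {0.5: "short", 2.0: "medium", 5.0: "long"}[win]
                for reg in regressors:
                    eta = (np.log(reference_rmse)
                           + beta.get(f"location:{loc}", 0.0)
                           + beta.get(f"filter_band:{band}", 0.0)
                           + beta.get(f"window_length:{wname}", 0.0)
                           + beta.get(f"regressor:{reg}", 0.0))
                    mu = np.exp(eta)
                    rows.append(dict(location=loc, filter_band=band,
                                     window_length=win, regressor=reg,
                                     rmse_per_s=rng.gamma(shape, mu / shape)))
    return pd.DataFrame(rows)
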