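"""Per-window feature vector from the vertical and anteroposterior channels.

Families:

* time domain, per axis — mean, standard deviation, number of peaks, range,
  root-mean-square, interquartile range;
* frequency domain, per axis — spectral energy (DC excluded), dominant
  frequency, magnitude at the dominant frequency, spectral entropy;
* cross-axis — maximum normalized cross-correlation (lag bounded to ±1 s),
  the lag of that maximum, and the first autocorrelation peak height per axis.

The registry (:func:`feature_registry`) is the single source of truth for
feature names and ordering.  Features beyond the canonical examples (range,
RMS, IQR, spectral entropy, autocorrelation peak) are tagged ``extended`` in
:data:`FEATURE_FAMILIES`.

Numerical conventions: peaks are local maxima with prominence ≥ 0.1 × the
window standard deviation and ≥ 0.25 s apart (a 4 steps/s ceiling, above the
3 Hz gait fundamental); spectra are computed on the de-meaned, Hann-tapered
window and the dominant frequency excludes the DC bin.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

_PEAK_MIN_SEPARATION_S = 0.25
_PEAK_PROMINENCE_FRACTION = 0.1
_XCORR_MAX_LAG_S = 1.0

_AXES = ("v", "ap")
_TIME_FEATURES = ("mean", "std", "n_peaks", "range", "rms", "iqr")
_FREQ_FEATURES = ("spec_energy", "dom_freq", "dom_mag", "spec_entropy")
_CROSS_FEATURES = ("xcorr_max", "xcorr_lag", "autocorr_peak_v", "autocorr_peak_ap")

#: feature name → family tag ("core" for the canonical examples, "extended"
#: for the additions standing in for the full published feature list).
FEATURE_FAMILIES: dict[str, str] = {}


def feature_registry() -> list[str]:
    """Ordered, stable list of feature names (= dataset column order)."""
    names = []
    for axis in _AXES:
        for f in _TIME_FEATURES:
            names.append(f"{axis}_{f}")
        for f in _FREQ_FEATURES:
            names.append(f"{axis}_{f}")
    names.extend(_CROSS_FEATURES)
    return names


def _init_families():
    extended = {"range", "rms", "iqr", "spec_entropy"}
    for name in feature_registry():
        base = name.split("_", 1)[1] if name.startswith(("v_", "ap_")) else name
        if base in extended or name.startswith("autocorr_peak"):
            FEATURE_FAMILIES[name] = "extended"
        else:
            FEATURE_FAMILIES[name] = "core"


_init_families()


def _count_peaks(x: np.ndarray, sample_rate: float) -> int:
    sd = x.std()
    if sd == 0:
        return 0
    distance = max(1, int(round(_PEAK_MIN_SEPARATION_S * sample_rate)))
    peaks, _ = sps.find_peaks(x, prominence=_PEAK_PROMINENCE_FRACTION * sd,
                              distance=distance)
    return int(peaks.size)


def _spectral(x: np.ndarray, sample_rate: float):
    n = x.size
    tapered = (x - x.mean()) * np.hanning(n)
    spec = np.fft.rfft(tapered)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    power_nodc = power[1:]
    total = power_nodc.sum()
    energy = float(total / n)
    if total <= 0:
        return energy, 0.0, 0.0, 0.0
    k = int(np.argmax(power_nodc)) + 1
    dom_freq = float(freqs[k])
    dom_mag = float(np.abs(spec[k]))
    p = power_nodc / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(p.size)) if p.size > 1 else 0.0
    return energy, dom_freq, dom_mag, entropy


def _axis_features(x: np.ndarray, sample_rate: float) -> list[float]:
    q75, q25 = np.percentile(x, [75, 25])
    energy, dom_freq, dom_mag, entropy = _spectral(x, sample_rate)
    return [
        float(x.mean()),
        float(x.std()),
        float(_count_peaks(x, sample_rate)),
        float(x.max() - x.min()),
        float(np.sqrt(np.mean(x**2))),
        float(q75 - q25),
        energy,
        dom_freq,
        dom_mag,
        entropy,
    ]


def _normalized_xcorr(x: np.ndarray, y: np.ndarray, sample_rate: float):
    """Max normalized cross-correlation and its lag (s), search bounded ±1 s."""
    n = x.size
    x0 = x - x.mean()
    y0 = y - y.mean()
    denom = np.sqrt((x0**2).sum() * (y0**2).sum())
    if denom == 0:
        return 0.0, 0.0
    full = np.correlate(x0, y0, mode="full") / denom
    max_lag = min(n - 1, int(round(_XCORR_MAX_LAG_S * sample_rate)))
    lags = np.arange(-max_lag, max_lag + 1)
    window = full[(n - 1) - max_lag : (n - 1) + max_lag + 1]
    k = int(np.argmax(window))
    return float(window[k]), float(lags[k] / sample_rate)


def _first_autocorr_peak(x: np.ndarray, sample_rate: float) -> float:
    x0 = x - x.mean()
    denom = (x0**2).sum()
    if denom == 0:
        return 0.0
    ac = np.correlate(x0, x0, mode="full")[x0.size - 1 :] / denom
    peaks, props = sps.find_peaks(ac[1:], prominence=0.01)
    if peaks.size == 0:
        return 0.0
    return float(ac[1:][peaks[0]])


def extract_features(vertical: np.ndarray, anteroposterior: np.ndarray,
                     sample_rate: float) -> np.ndarray:
    """Compute the full feature vector for one window (order per registry).

    Raises on NaN input — labels and features are never silently imputed.
    """
    v = np.asarray(vertical, dtype=float)
    ap = np.asarray(anteroposterior, dtype=float)
    if v.size < 2 or ap.size < 2:
        raise ValueError("window must contain at least 2 samples")
    if v.shape != ap.shape:
        raise ValueError("axis channels must have equal length")
    if np.isnan(v).any() or np.isnan(ap).any():
        raise ValueError("NaN in window signal")
    values = _axis_features(v, sample_rate) + _axis_features(ap, sample_rate)
    xc_max, xc_lag = _normalized_xcorr(v, ap, sample_rate)
    values += [xc_max, xc_lag,
               _first_autocorr_peak(v, sample_rate),
               _first_autocorr_peak(ap, sample_rate)]
    return np.array(values, dtype=float)


def export_feature_matrix(matrix: np.ndarray, subject_ids, true_counts, path) -> None:
    """Write valid-window features as delimited text (registry columns +
    subject_id + true_step_count)."""
    import pandas as pd

    df = pd.DataFrame(matrix, columns=feature_registry())
    df["subject_id"] = list(subject_ids)
    df["true_step_count"] = list(true_counts)
    df.to_csv(path, index=False)
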