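"""Axis determination, band filtering, windowing and window labelling.

The processing chain is orientation-agnostic: the vertical axis is the
channel with the highest mean acceleration (gravity-dominant, sign-corrected)
and the anteroposterior axis is the remaining channel most correlated with
it.  Axes are assigned on the *unfiltered* signal — band-pass filtering would
remove the gravity cue the rule depends on — and filtering is applied
afterwards.

Three fixed 5th-order Butterworth bands (zero-phase, forward–backward):
wide (low-pass 15 Hz), medium (band-pass 0.2–5 Hz), narrow (band-pass
0.5–3 Hz).  Windows slide with 50 % overlap at lengths 0.5, 2 and 5 s; a
window's label is the number of annotated steps in its half-open interval
[start, end), and any window touching an excluded interval is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io_sync import AccelRecording, StepAnnotationSet


@dataclass(frozen=True)
class FilterBand:
    """One Butterworth band (order 5, zero phase)."""

    name: str
    kind: str  # "lowpass" | "bandpass"
    low_cut: float | None
    high_cut: float
    order: int = 5


#: The three a-priori analysis bands.
FILTER_BANDS = {
    "wide": FilterBand("wide", "lowpass", None, 15.0),
    "medium": FilterBand("medium", "bandpass", 0.2, 5.0),
    "narrow": FilterBand("narrow", "bandpass", 0.5, 3.0),
}

#: Sliding-window lengths in seconds (50 % overlap everywhere).
WINDOW_LENGTHS = (0.5, 2.0, 5.0)
OVERLAP_FRACTION = 0.5


@dataclass(frozen=True)
class AxisAssignment:
    """Data-driven channel roles: vertical index/sign and anteroposterior index."""

    vertical_index: int
    anteroposterior_index: int
    vertical_sign: int

    def __post_init__(self):
        if self.vertical_index == self.anteroposterior_index:
            raise ValueError("vertical and anteroposterior indices must differ")
        if self.vertical_sign not in (-1, 1):
            raise ValueError("vertical_sign must be ±1")


@dataclass(frozen=True)
class LabeledWindow:
    subject_id: str
    start: float
    end: float
    true_step_count: int
    valid: bool


def assign_axes(rec: AccelRecording) -> AxisAssignment:
    """Identify vertical and anteroposterior channels.

    Vertical is the channel with the largest absolute mean (sign chosen so the
    corrected mean is positive); anteroposterior is the remaining channel with
    the strongest absolute Pearson correlation to the vertical channel.  Means
    and correlations are computed over the whole recording: mounting
    orientation is fixed within a session.  If all non-vertical channels have
    zero variance the lowest-index one is chosen deterministically.
    """
    if len(rec) == 0:
        raise ValueError("cannot assign axes on an empty recording")
    means = rec.accel.mean(axis=0)
    v_idx = int(np.argmax(np.abs(means)))
    v_sign = 1 if means[v_idx] >= 0 else -1
    vertical = v_sign * rec.accel[:, v_idx]

    candidates = [i for i in range(3) if i != v_idx]
    v_sd = vertical.std()
    best_idx, best_corr = candidates[0], -1.0
    for i in candidates:
        sd = rec.accel[:, i].std()
        if sd == 0 or v_sd == 0:
            continue
        r = abs(float(np.corrcoef(vertical, rec.accel[:, i])[0, 1]))
        if r > best_corr:
            best_idx, best_corr = i, r
    return AxisAssignment(vertical_index=v_idx, anteroposterior_index=best_idx,
                          vertical_sign=v_sign)


def _design_sos(band: FilterBand, sample_rate: float):
    nyq = sample_rate / 2.0
    if band.high_cut >= nyq:
        raise ValueError(
            f"band {band.name!r} needs sample_rate > {2 * band.high_cut} Hz, got {sample_rate}"
        )
    if band.kind == "lowpass":
        return sps.butter(band.order, band.high_cut, btype="lowpass", fs=sample_rate,
                          output="sos")
    return sps.butter(band.order, [band.low_cut, band.high_cut], btype="bandpass",
                      fs=sample_rate, output="sos")


def apply_filter(rec: AccelRecording, band: FilterBand | str) -> AccelRecording:
    """Filter each channel forward–backward (zero net phase, same length)."""
    if isinstance(band, str):
        band = FILTER_BANDS[band]
    sos = _design_sos(band, rec.sample_rate)
    padlen = 3 * (2 * sos.shape[0] + 1)  # sosfiltfilt default
    if len(rec) <= padlen:
        raise ValueError(
            f"recording of {len(rec)} samples is shorter than the filter warm-up "
            f"length ({padlen + 1} samples)"
        )
    filtered = sps.sosfiltfilt(sos, rec.accel, axis=0)
    return rec.with_accel(filtered)


def window_starts(duration: float, window_length: float) -> np.ndarray:
    """Start times of 50 %-overlap windows fully inside [0, duration]."""
    step = window_length * (1.0 - OVERLAP_FRACTION)
    n = int(np.floor((duration - window_length) / step + 1e-9)) + 1
    if n <= 0:
        return np.array([])
    return np.arange(n) * step


def make_windows(rec: AccelRecording, annotations: StepAnnotationSet,
                 window_length: float) -> list[LabeledWindow]:
    """Segment a recording into labelled 50 %-overlap windows.

    Event counting uses the half-open convention [start, end): a step at an
    exact boundary belongs to the later window, so no step is double-counted
    by adjacent non-overlapping windows.  ``valid`` is False iff the window
    intersects any excluded interval.  A recording shorter than one window
    yields an empty list.
    """
    starts = window_starts(rec.duration, window_length)
    event_times = annotations.event_times
    windows = []
    for s in starts:
        e = s + window_length
        count = int(np.sum((event_times >= s) & (event_times < e)))
        valid = True
        for a, b in annotations.excluded:
            if s < b and a < e:  # [s, e) intersects [a, b]
                valid = False
                break
        windows.append(LabeledWindow(subject_id=rec.subject_id, start=float(s),
                                     end=float(e), true_step_count=count, valid=valid))
    return windows


def window_slices(rec: AccelRecording, windows: list[LabeledWindow]) -> list[slice]:
    """Sample-index slices matching each window's [start, end) interval."""
    fs = rec.sample_rate
    return [slice(int(round(w.start * fs)), int(round(w.end * fs))) for w in windows]
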