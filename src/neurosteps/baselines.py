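"""Able-bodied baseline step counters and the external-counter adapter.

Two baselines are fully specified and implemented here:

* **TCA** (threshold-crossing algorithm): a step is an upward crossing of a
  fixed threshold (default 0.3 m/s²) by the acceleration vector magnitude.
  A 0.3 m/s² threshold is only meaningful on a gravity-referenced magnitude
  (the raw magnitude sits near 9.81 m/s² at rest), so the default mode
  subtracts standard gravity and half-wave rectifies; a band-passed mode is
  also available.  A refractory period (default 0.25 s, i.e. a 4 steps/s
  ceiling above the 3 Hz gait fundamental) suppresses ringing.

* **CWT** (continuous wavelet transform): a Morlet transform of the vertical
  channel; within successive 5 s segments the dominant scale inside the
  0.5–3 Hz gait band is selected — this is how the detector adapts to walking
  speed — and peaks of the coefficient series at that scale are steps.

Pre-trained external counters (SKDH for the lower back, OxWearables for the
wrist) are exposed through a thin adapter that fails loudly when the external
package is absent; they are never silently substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .io_sync import GRAVITY, AccelRecording
from .preprocessing import FILTER_BANDS, apply_filter, assign_axes


class ExternalCounterUnavailable(RuntimeError):
    """The requested pre-trained external counter is not installed."""


@dataclass(frozen=True)
class TcaParams:
    threshold: float = 0.3            # m/s²
    refractory: float = 0.25          # s
    magnitude_mode: str = "gravity_subtracted"  # or "bandpassed"

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if self.magnitude_mode not in ("gravity_subtracted", "bandpassed"):
            raise ValueError(f"unknown magnitude_mode {self.magnitude_mode!r}")


@dataclass(frozen=True)
class CwtParams:
    scale_low_hz: float = 0.5
    scale_high_hz: float = 3.0
    n_scales: int = 12
    segment_length: float = 5.0       # s; scale-adaptation granularity
    peak_prominence_fraction: float = 0.25
    min_peak_height: float = 0.4      # m/s², absolute floor against noise

    def __post_init__(self):
        if not 0 < self.scale_low_hz < self.scale_high_hz:
            raise ValueError("need 0 < scale_low_hz < scale_high_hz")


def tca_count(rec: AccelRecording, params: TcaParams = TcaParams()):
    """Threshold-crossing step count.  Returns (count, event_times).

    A step is a threshold exceedance of the (gravity-referenced, half-wave
    rectified) vector magnitude; exceedances are localised at magnitude peaks
    and detections within the refractory period of a stronger one are
    discarded.  Counting exceedance *peaks* rather than raw upward crossings
    keeps the count monotone non-increasing in the threshold even when noise
    makes the signal hover around it.
    """
    magnitude = np.linalg.norm(rec.accel, axis=1)
    if params.magnitude_mode == "gravity_subtracted":
        signal = np.maximum(magnitude - GRAVITY, 0.0)
    else:
        mag_rec = rec.with_accel(np.column_stack([magnitude, magnitude, magnitude]))
        signal = apply_filter(mag_rec, FILTER_BANDS["narrow"]).accel[:, 0]
    distance = max(1, int(round(params.refractory * rec.sample_rate)))
    peaks, _ = sps.find_peaks(signal, height=params.threshold, distance=distance)
    events = rec.time[peaks]
    return len(events), np.asarray(events, dtype=float)


def _cwt_scales(params: CwtParams, sample_rate: float):
    freqs = np.geomspace(params.scale_low_hz, params.scale_high_hz, params.n_scales)
    if params.scale_high_hz >= sample_rate / 2:
        raise ValueError("scale search range must stay below the Nyquist frequency")
    fc = pywt.central_frequency("morl")
    scales = fc * sample_rate / freqs
    return scales, freqs


def cwt_count(rec: AccelRecording, params: CwtParams = CwtParams()):
    """Morlet-CWT step count on the vertical channel.

    Returns (count, event_times).  Within each 5 s segment the scale with the
    largest mean squared coefficient inside the gait band is taken as
    dominant (speed adaptation); coefficient peaks at that scale, gated by a
    relative prominence and an absolute height floor, are steps.
    """
    scales, _ = _cwt_scales(params, rec.sample_rate)
    if len(rec) < int(np.max(scales)):
        raise ValueError(
            f"recording of {len(rec)} samples is shorter than the largest wavelet "
            f"support ({int(np.max(scales))} samples)"
        )
    axes = assign_axes(rec)
    vertical = axes.vertical_sign * rec.accel[:, axes.vertical_index]
    vertical = vertical - vertical.mean()
    coefs, _ = pywt.cwt(vertical, scales, "morl",
                        sampling_period=1.0 / rec.sample_rate)

    fs = rec.sample_rate
    seg_len = max(1, int(round(params.segment_length * fs)))
    distance = max(1, int(round(0.25 * fs)))
    events: list[float] = []
    for start in range(0, len(rec), seg_len):
        stop = min(start + seg_len, len(rec))
        seg = coefs[:, start:stop]
        dominant = int(np.argmax(np.mean(seg**2, axis=1)))
        series = seg[dominant]
        floor = max(params.min_peak_height,
                    params.peak_prominence_fraction * np.max(np.abs(series), initial=0.0))
        peaks, _ = sps.find_peaks(series, height=floor, prominence=floor,
                                  distance=distance)
        events.extend(rec.time[start + p] for p in peaks)
    events_arr = np.array(sorted(events))
    return len(events_arr), events_arr


def dominant_cwt_scales(rec: AccelRecording, params: CwtParams = CwtParams()):
    """Per-segment dominant frequency (Hz) — exposes the speed adaptation."""
    scales, freqs = _cwt_scales(params, rec.sample_rate)
    axes = assign_axes(rec)
    vertical = axes.vertical_sign * rec.accel[:, axes.vertical_index]
    coefs, _ = pywt.cwt(vertical - vertical.mean(), scales, "morl",
                        sampling_period=1.0 / rec.sample_rate)
    seg_len = max(1, int(round(params.segment_length * rec.sample_rate)))
    out = []
    for start in range(0, len(rec), seg_len):
        seg = coefs[:, start:min(start + seg_len, len(rec))]
        out.append(float(freqs[int(np.argmax(np.mean(seg**2, axis=1)))]))
    return out


# ---------------------------------------------------------------------------
# External pre-trained counters (adapters only; never re-implemented here)
# ---------------------------------------------------------------------------

def skdh_count(rec: AccelRecording):
    """SciKit Digital Health pre-trained counter (lower-back sensor)."""
    try:
        import skdh  # noqa: F401
    except ImportError as exc:
        raise ExternalCounterUnavailable(
            "external counter 'SKDH' not installed (pip install scikit-digital-health)"
        ) from exc
    raise ExternalCounterUnavailable(
        "SKDH adapter requires the pre-trained gait pipeline; configure skdh.gait "
        "and wrap it here"
    )


def oxw_count(rec: AccelRecording):
    """OxWearables pre-trained counter (wrist sensor)."""
    try:
        import stepcount  # noqa: F401
    except ImportError as exc:
        raise ExternalCounterUnavailable(
            "external counter 'OxW' not installed (pip install stepcount)"
        ) from exc
    raise ExternalCounterUnavailable(
        "OxW adapter requires the pre-trained model bundle; configure stepcount "
        "and wrap it here"
    )


def _tca_entry(rec: AccelRecording):
    return tca_count(rec)


def _cwt_entry(rec: AccelRecording):
    return cwt_count(rec)


#: Uniform registry: name → count_steps(recording) -> (total, event_times).
ALGORITHM_REGISTRY = {
    "tca": _tca_entry,
    "cwt": _cwt_entry,
    "skdh": lambda rec: skdh_count(rec),
    "oxw": lambda rec: oxw_count(rec),
}


def list_algorithms() -> list[str]:
    return sorted(ALGORITHM_REGISTRY)


def count_steps(algorithm: str, rec: AccelRecording):
    """Run a registered baseline counter.  Returns (total, event_times)."""
    try:
        fn = ALGORITHM_REGISTRY[algorithm]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; registered: {list_algorithms()}"
        ) from None
    return fn(rec)
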