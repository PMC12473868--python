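"""Recording/annotation data model, text formats, and video–sensor time alignment.

Accelerometer recordings are plain delimited text with a ``time_s,ax,ay,az``
header (units m/s², strictly increasing time).  Step annotations are stored on
the clock they were produced on (the video clock in the study workflow) as
``time_s,event_type`` rows with event_type in {walking, shuffling}, plus a
companion excluded-intervals file ``start_s,end_s``.  The video clock is mapped
onto the sensor clock by the affine interpolation between two tap anchors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

#: The seven analysed sensor locations.
LOCATIONS = ("wrist_l", "wrist_r", "chest", "lower_back", "waist", "thigh", "ankle")

#: Annotated step-event types.  Both count as steps everywhere downstream.
EVENT_TYPES = ("walking", "shuffling")

#: Standard gravity, m/s² (exact).
GRAVITY = 9.80665

#: Accelerometer full-scale range, m/s² (±8 g).
ACCEL_RANGE = 8.0 * GRAVITY


class FormatError(ValueError):
    """A recording or annotation file violated its format contract."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class AccelRecording:
    """One sensor's triaxial time series for one subject.

    Parameters
    ----------
    subject_id : str
    location : str
        One of :data:`LOCATIONS`.
    sample_rate : float
        Nominal sampling frequency, Hz.
    time : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    accel : ndarray, shape (n, 3)
        Acceleration in m/s² for the three sensor axes.
    """

    subject_id: str
    location: str
    sample_rate: float
    time: np.ndarray
    accel: np.ndarray

    def __post_init__(self):
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown location {self.location!r}; expected one of {LOCATIONS}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        time = np.asarray(self.time, dtype=float)
        accel = np.asarray(self.accel, dtype=float)
        if accel.ndim != 2 or accel.shape[1] != 3:
            raise ValueError("accel must have shape (n, 3)")
        if time.shape[0] != accel.shape[0]:
            raise ValueError("time and accel lengths differ")
        if time.size > 1 and np.any(np.diff(time) <= 0):
            bad = int(np.argmax(np.diff(time) <= 0)) + 1
            raise ValueError(f"time must be strictly increasing (violated at sample {bad})")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "accel", accel)

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds (n samples at the nominal rate)."""
        return len(self) / self.sample_rate

    def with_accel(self, accel: np.ndarray) -> "AccelRecording":
        """Copy of this recording with the acceleration channels replaced."""
        return replace(self, accel=np.asarray(accel, dtype=float))


@dataclass(frozen=True)
class StepAnnotationSet:
    """Ground-truth step events plus video-unusable (excluded) intervals.

    ``events`` is a list of ``(time_s, event_type)`` with event_type in
    {walking, shuffling}; both types are steps.  ``excluded`` intervals mark
    stretches where the feet were not visible on video; windows overlapping
    them are discarded downstream.
    """

    events: tuple[tuple[float, str], ...]
    excluded: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        events = tuple((float(t), str(k)) for t, k in self.events)
        for t, kind in events:
            if kind not in EVENT_TYPES:
                raise ValueError(f"unknown event type {kind!r}; expected one of {EVENT_TYPES}")
        times = [t for t, _ in events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        excluded = tuple((float(a), float(b)) for a, b in self.excluded)
        for a, b in excluded:
            if not a < b:
                raise ValueError(f"excluded interval ({a}, {b}) must have start < end")
        for (a0, b0), (a1, b1) in zip(excluded, excluded[1:]):
            if a1 < b0:
                raise ValueError("excluded intervals must be non-overlapping and sorted")
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "excluded", excluded)

    @property
    def event_times(self) -> np.ndarray:
        return np.array([t for t, _ in self.events], dtype=float)

    @property
    def n_steps(self) -> int:
        return len(self.events)

    def shifted(self, mapper) -> "StepAnnotationSet":
        """Apply a time map (e.g. video→sensor) to events and intervals."""
        events = tuple((float(mapper(t)), k) for t, k in self.events)
        excluded = tuple((float(mapper(a)), float(mapper(b))) for a, b in self.excluded)
        return StepAnnotationSet(events=events, excluded=excluded)


@dataclass(frozen=True)
class SyncAnchors:
    """Two tap anchors tying the video clock to the sensor clock."""

    video_start: float
    video_end: float
    sensor_start: float
    sensor_end: float

    def __post_init__(self):
        if not self.video_end > self.video_start:
            raise ValueError("video_end must exceed video_start")
        if not self.sensor_end > self.sensor_start:
            raise ValueError("sensor_end must exceed sensor_start")


def map_video_time(anchors: SyncAnchors, t_video):
    """Map video-clock time(s) to sensor-clock time(s).

    The map is the affine interpolation sending ``video_start → sensor_start``
    and ``video_end → sensor_end``, applied to annotation event times so that
    video-labelled steps line up with the sensor timeline.
    """
    slope = (anchors.sensor_end - anchors.sensor_start) / (anchors.video_end - anchors.video_start)
    return anchors.sensor_start + slope * (np.asarray(t_video, dtype=float) - anchors.video_start)


def sync_annotations(annotations: StepAnnotationSet, anchors: SyncAnchors) -> StepAnnotationSet:
    """Convert a video-clock annotation set onto the sensor clock."""
    return annotations.shifted(lambda t: map_video_time(anchors, t))


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------

_REC_HEADER = "time_s,ax,ay,az"
_EVT_HEADER = "time_s,event_type"
_EXC_HEADER = "start_s,end_s"


def write_recording(rec: AccelRecording, path) -> None:
    """Write a recording as ``time_s,ax,ay,az`` delimited text (m/s²)."""
    data = np.column_stack([rec.time, rec.accel])
    with open(path, "w") as fh:
        fh.write(_REC_HEADER + "\n")
        np.savetxt(fh, data, fmt="%.6f", delimiter=",")


def read_recording(path, subject_id: str, location: str, sample_rate: float = 100.0) -> AccelRecording:
    """Read a ``time_s,ax,ay,az`` file into a validated :class:`AccelRecording`.

    Raises :class:`FormatError` naming the offending line for a wrong column
    count, an unparseable number, or time going backwards.
    """
    times: list[float] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != _REC_HEADER:
            raise FormatError(f"expected header {_REC_HEADER!r}, got {header!r}", line=1)
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise FormatError(f"expected 4 columns, got {len(parts)}", line=lineno)
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise FormatError(f"unparseable number: {exc}", line=lineno) from None
            if times and vals[0] <= times[-1]:
                raise FormatError(
                    f"time {vals[0]} not greater than previous {times[-1]}", line=lineno
                )
            times.append(vals[0])
            rows.append(vals[1:])
    return AccelRecording(
        subject_id=subject_id,
        location=location,
        sample_rate=sample_rate,
        time=np.array(times),
        accel=np.array(rows).reshape(len(rows), 3),
    )


def write_annotations(annotations: StepAnnotationSet, events_path, excluded_path=None) -> None:
    """Write events (and optionally excluded intervals) as delimited text."""
    with open(events_path, "w") as fh:
        fh.write(_EVT_HEADER + "\n")
        for t, kind in annotations.events:
            fh.write(f"{t:.6f},{kind}\n")
    if excluded_path is not None:
        with open(excluded_path, "w") as fh:
            fh.write(_EXC_HEADER + "\n")
            for a, b in annotations.excluded:
                fh.write(f"{a:.6f},{b:.6f}\n")


def read_annotations(events_path, excluded_path=None) -> StepAnnotationSet:
    """Read event and excluded-interval files into a :class:`StepAnnotationSet`.

    Events with a type outside {walking, shuffling} are rejected with a
    :class:`FormatError`, not silently dropped.
    """
    events: list[tuple[float, str]] = []
    with open(events_path) as fh:
        header = fh.readline().strip()
        if header != _EVT_HEADER:
            raise FormatError(f"expected header {_EVT_HEADER!r}, got {header!r}", line=1)
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"expected 2 columns, got {len(parts)}", line=lineno)
            try:
                t = float(parts[0])
            except ValueError as exc:
                raise FormatError(f"unparseable time: {exc}", line=lineno) from None
            if parts[1] not in EVENT_TYPES:
                raise FormatError(f"unknown event type {parts[1]!r}", line=lineno)
            events.append((t, parts[1]))
    excluded: list[tuple[float, float]] = []
    if excluded_path is not None and Path(excluded_path).exists():
        with open(excluded_path) as fh:
            header = fh.readline().strip()
            if header != _EXC_HEADER:
                raise FormatError(f"expected header {_EXC_HEADER!r}, got {header!r}", line=1)
            for lineno, line in enumerate(fh, start=2):
                line = line.strip()
                if not line:
                    continue
                parts = line.split(",")
                if len(parts) != 2:
                    raise FormatError(f"expected 2 columns, got {len(parts)}", line=lineno)
                try:
                    excluded.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise FormatError(f"unparseable number: {exc}", line=lineno) from None
    return StepAnnotationSet(events=tuple(events), excluded=tuple(excluded))
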