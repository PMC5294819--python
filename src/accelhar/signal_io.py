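"""Reading, validating and segmenting waist-worn accelerometer recordings.

Raw recordings are CSV files with header ``time,x,y,z`` — time in seconds
from recording start, axes in g.  Label files are CSV with header
``start,end,activity`` on the same clock.  Recordings are segmented into
fixed-length non-overlapping clips (10 s at 100 Hz by default), the unit
of classification; windows never straddle a label boundary and trailing
partial windows are dropped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Fixed activity vocabulary, in the canonical reporting order.
ACTIVITIES: tuple[str, ...] = ("lie", "stand", "sit", "wheel", "walk", "stairs")

#: Accelerometer dynamic range in g; samples outside are physically impossible.
DYNAMIC_RANGE_G = 8.0

CONTEXTS = ("lab", "home")


class FormatError(ValueError):
    """Raised when an input file violates the documented CSV contract."""


@dataclass
class AccelRecording:
    """A validated tri-axial recording for one subject in one context.

    ``data`` is a 3 x N array (rows x, y, z) in g; ``time`` is the matching
    N-vector of strictly increasing timestamps in seconds.
    """

    subject_id: str
    context: str
    sample_rate_hz: float
    time: np.ndarray
    data: np.ndarray
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        self.time = np.asarray(self.time, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (3, self.time.size):
            raise ValueError("data must be 3 x len(time)")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            bad = int(np.flatnonzero(np.diff(self.time) <= 0)[0]) + 1
            raise FormatError(f"timestamps not strictly increasing at row {bad}")

    @property
    def n_samples(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class LabelInterval:
    """A half-open labelled time interval [start, end) in seconds."""

    start: float
    end: float
    activity: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start must precede end: {self}")
        if self.activity not in ACTIVITIES:
            raise ValueError(
                f"unknown activity {self.activity!r}; expected one of {ACTIVITIES}"
            )


@dataclass
class Clip:
    """One fixed-length labelled window of tri-axial acceleration (3 x N, g)."""

    subject_id: str
    context: str
    activity: str
    start: float
    data: np.ndarray
    sample_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 3:
            raise ValueError("clip data must be a 3 x N array")
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def read_recording(
    path: str | os.PathLike,
    subject_id: str,
    context: str,
    sample_rate_hz: float = 100.0,
) -> AccelRecording:
    """Read a raw CSV recording, dropping physically impossible rows.

    Rows with any axis outside the sensor's +/-8 g dynamic range are
    rejected; their count is reported on the returned recording.  Missing
    columns or non-monotone timestamps raise :class:`FormatError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("time", "x", "y", "z") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    axes = df[["x", "y", "z"]].to_numpy(dtype=float)
    keep = np.all(np.abs(axes) <= DYNAMIC_RANGE_G, axis=1)
    n_rejected = int((~keep).sum())
    time = df["time"].to_numpy(dtype=float)[keep]
    if time.size > 1 and not np.all(np.diff(time) > 0):
        bad = int(np.flatnonzero(np.diff(time) <= 0)[0]) + 1
        raise FormatError(f"{path}: timestamps not strictly increasing at row {bad}")
    return AccelRecording(
        subject_id=subject_id,
        context=context,
        sample_rate_hz=sample_rate_hz,
        time=time,
        data=axes[keep].T,
        n_rejected=n_rejected,
    )


def write_recording(recording: AccelRecording, path: str | os.PathLike) -> None:
    """Write a recording back to the raw CSV format (6 decimal places)."""
    df = pd.DataFrame(
        {
            "time": recording.time,
            "x": recording.data[0],
            "y": recording.data[1],
            "z": recording.data[2],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_labels(path: str | os.PathLike) -> list[LabelInterval]:
    """Read a label-interval CSV (header ``start,end,activity``)."""
    df = pd.read_csv(path)
    missing = [c for c in ("start", "end", "activity") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return [
        LabelInterval(float(r.start), float(r.end), str(r.activity))
        for r in df.itertuples(index=False)
    ]


def write_labels(labels: Iterable[LabelInterval], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(iv.start, iv.end, iv.activity) for iv in labels],
        columns=["start", "end", "activity"],
    )
    df.to_csv(path, index=False, float_format="%.6f")


def _check_non_overlapping(labels: Sequence[LabelInterval]) -> list[LabelInterval]:
    ordered = sorted(labels, key=lambda iv: iv.start)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start < prev.end:
            raise ValueError(
                f"overlapping label intervals: {prev} and {cur}"
            )
    return ordered


def segment_clips(
    recording: AccelRecording,
    labels: Sequence[LabelInterval],
    clip_seconds: float = 10.0,
) -> list[Clip]:
    """Cut a recording into fixed-length labelled clips.

    Within each label interval, consecutive non-overlapping half-open
    windows ``[s, s + clip_seconds)`` are emitted starting at the interval
    start; the trailing partial window is dropped and windows never
    straddle two intervals.  The result is independent of the ordering of
    ``labels`` and is returned in temporal order.
    """
    if clip_seconds <= 0:
        raise ValueError("clip_seconds must be positive")
    n_per_clip = recording.sample_rate_hz * clip_seconds
    if abs(n_per_clip - round(n_per_clip)) > 1e-9:
        raise ValueError("sample_rate_hz * clip_seconds must be an integer")
    n_per_clip = int(round(n_per_clip))

    ordered = _check_non_overlapping(labels)
    clips: list[Clip] = []
    for interval in ordered:
        w_start = interval.start
        while w_start + clip_seconds <= interval.end + 1e-9:
            lo = int(np.searchsorted(recording.time, w_start - 1e-9, side="left"))
            hi = lo + n_per_clip
            if hi > recording.n_samples:
                break
            window_t = recording.time[lo:hi]
            if window_t[-1] >= w_start + clip_seconds - 1e-9:
                break  # gap in the recording: fewer true samples than expected
            clips.append(
                Clip(
                    subject_id=recording.subject_id,
                    context=recording.context,
                    activity=interval.activity,
                    start=w_start,
                    data=recording.data[:, lo:hi].copy(),
                    sample_rate_hz=recording.sample_rate_hz,
                )
            )
            w_start += clip_seconds
    clips.sort(key=lambda c: c.start)
    return clips


def write_clip_store(clips: Sequence[Clip], directory: str | os.PathLike) -> str:
    """Write per-clip CSVs plus a manifest; returns the manifest path.

    Manifest columns: ``subject,context,activity,start,file``.  Writers are
    bit-stable given identical inputs.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for i, clip in enumerate(clips):
        fname = f"clip_{i:05d}.csv"
        t = clip.start + np.arange(clip.n_samples) / clip.sample_rate_hz
        pd.DataFrame(
            {"time": t, "x": clip.data[0], "y": clip.data[1], "z": clip.data[2]}
        ).to_csv(os.path.join(directory, fname), index=False, float_format="%.6f")
        rows.append((clip.subject_id, clip.context, clip.activity, clip.start, fname))
    manifest = os.path.join(directory, "manifest.csv")
    pd.DataFrame(
        rows, columns=["subject", "context", "activity", "start", "file"]
    ).to_csv(manifest, index=False, float_format="%.6f")
    return manifest


def read_clip_store(directory: str | os.PathLike, sample_rate_hz: float = 100.0) -> list[Clip]:
    """Read back a clip store written by :func:`write_clip_store`."""
    directory = os.fspath(directory)
    manifest = pd.read_csv(os.path.join(directory, "manifest.csv"))
    clips = []
    for r in manifest.itertuples(index=False):
        df = pd.read_csv(os.path.join(directory, r.file))
        clips.append(
            Clip(
                subject_id=str(r.subject),
                context=str(r.context),
                activity=str(r.activity),
                start=float(r.start),
                data=df[["x", "y", "z"]].to_numpy().T,
                sample_rate_hz=sample_rate_hz,
            )
        )
    return clips
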