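"""The 178-value time-series feature bank computed on each 10-s clip.

Feature groups (counts): per-axis mean and absolute value of the mean (6);
per-axis SD, skew, kurtosis (9); SD/skew/kurtosis of the magnitude signal
|a(t)| and of the three instantaneous cross-product signals xy, xz, yz
(12); per-axis RMS (3); per-axis RMS of the boxcar-smoothed signal, 5- and
10-point kernels (6); per-axis min, max, abs min, abs max (12); per-axis
z-score histogram counts, 9 unit-width bins centred on -4..+4 (27); DFT
magnitudes, first 32 coefficients per axis, DC included (96); overall mean
acceleration magnitude (1); cross-product means xy, xz, yz (3); absolute
values of the cross-product means (3).

Conventions: population (1/N) moment normalisation throughout; kurtosis is
excess kurtosis (Gaussian -> 0); a zero-variance axis has skew and
kurtosis 0 by convention and all its histogram mass in the centre bin;
z-scores beyond +/-4.5 are clipped into the end bins so per-axis histogram
counts always sum to the sample count.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .signal_io import Clip

AXES = ("x", "y", "z")
_DERIVED_SIGNALS = ("mag", "xy", "xz", "yz")
N_FOURIER_PER_AXIS = 32
N_HIST_BINS = 9
N_FEATURES = 178

FOURIER_PREFIX = "fourier_"
HIST_PREFIX = "hist_"


@lru_cache(maxsize=1)
def feature_names() -> tuple[str, ...]:
    """The ordered, stable registry of the 178 feature names."""
    names: list[str] = []
    names += [f"mean_{a}" for a in AXES]
    names += [f"absmean_{a}" for a in AXES]
    for stat in ("std", "skew", "kurt"):
        names += [f"{stat}_{a}" for a in AXES]
    for stat in ("std", "skew", "kurt"):
        names += [f"{stat}_{s}" for s in _DERIVED_SIGNALS]
    names += [f"rms_{a}" for a in AXES]
    names += [f"rms_smooth5_{a}" for a in AXES]
    names += [f"rms_smooth10_{a}" for a in AXES]
    for stat in ("min", "max", "absmin", "absmax"):
        names += [f"{stat}_{a}" for a in AXES]
    for a in AXES:
        names += [f"{HIST_PREFIX}{a}_{b}" for b in range(-4, 5)]
    for a in AXES:
        names += [f"{FOURIER_PREFIX}{a}_{k:02d}" for k in range(N_FOURIER_PER_AXIS)]
    names.append("mean_accel_magnitude")
    names += [f"crossmean_{s}" for s in ("xy", "xz", "yz")]
    names += [f"abs_crossmean_{s}" for s in ("xy", "xz", "yz")]
    assert len(names) == N_FEATURES and len(set(names)) == N_FEATURES
    return tuple(names)


@dataclass
class FeatureVector:
    """The 178 named values for one clip, in registry order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} values, got {self.values.shape}")

    @property
    def names(self) -> tuple[str, ...]:
        return feature_names()

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """mean, population SD, skew, excess kurtosis with the 0-SD convention."""
    m = float(np.mean(x))
    sd = float(np.std(x))
    if sd == 0.0:
        return m, 0.0, 0.0, 0.0
    z = (x - m) / sd
    return m, sd, float(np.mean(z**3)), float(np.mean(z**4) - 3.0)


def _zscore_histogram(x: np.ndarray, m: float, sd: float) -> np.ndarray:
    n = x.size
    counts = np.zeros(N_HIST_BINS, dtype=float)
    if sd == 0.0:
        counts[N_HIST_BINS // 2] = n
        return counts
    z = (x - m) / sd
    idx = np.clip(np.floor(z + 4.5).astype(int), 0, N_HIST_BINS - 1)
    return np.bincount(idx, minlength=N_HIST_BINS).astype(float)


def _smoothed(x: np.ndarray, window: int) -> np.ndarray:
    """Boxcar moving average with reflective edge padding, length-preserving."""
    pad_l = (window - 1) // 2
    pad_r = window // 2
    xp = np.pad(x, (pad_l, pad_r), mode="reflect")
    return np.convolve(xp, np.full(window, 1.0 / window), mode="valid")


def extract_features(clip: Clip) -> FeatureVector:
    """Compute all 178 features for one clip (deterministic, pure)."""
    data = clip.data
    n = data.shape[1]
    if n < N_FOURIER_PER_AXIS:
        raise ValueError(
            f"clip has {n} samples; at least {N_FOURIER_PER_AXIS} are required"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError("clip contains non-finite samples")

    x, y, z = data
    magnitude = np.sqrt(x**2 + y**2 + z**2)
    cross = {"xy": x * y, "xz": x * z, "yz": y * z}

    axis_stats = [_moments(a) for a in data]  # (mean, sd, skew, kurt) per axis

    values: list[float] = []
    values += [s[0] for s in axis_stats]                       # mean
    values += [abs(s[0]) for s in axis_stats]                  # |mean|
    values += [s[1] for s in axis_stats]                       # sd
    values += [s[2] for s in axis_stats]                       # skew
    values += [s[3] for s in axis_stats]                       # kurtosis

    derived = [magnitude, cross["xy"], cross["xz"], cross["yz"]]
    derived_stats = [_moments(d) for d in derived]
    values += [s[1] for s in derived_stats]
    values += [s[2] for s in derived_stats]
    values += [s[3] for s in derived_stats]

    values += [float(np.sqrt(np.mean(a**2))) for a in data]    # rms
    for window in (5, 10):
        values += [float(np.sqrt(np.mean(_smoothed(a, window) ** 2))) for a in data]

    values += [float(np.min(a)) for a in data]
    values += [float(np.max(a)) for a in data]
    values += [float(np.min(np.abs(a))) for a in data]
    values += [float(np.max(np.abs(a))) for a in data]

    for a, s in zip(data, axis_stats):
        values += _zscore_histogram(a, s[0], s[1]).tolist()

    for a in data:
        values += np.abs(np.fft.fft(a)[:N_FOURIER_PER_AXIS]).tolist()

    values.append(float(np.mean(magnitude)))
    cross_means = [float(np.mean(cross[s])) for s in ("xy", "xz", "yz")]
    values += cross_means
    values += [abs(c) for c in cross_means]

    return FeatureVector(np.asarray(values))


@dataclass
class FeatureDataset:
    """An M x 178 design matrix with aligned clip metadata."""

    matrix: np.ndarray
    labels: list[str]
    subject_ids: list[str]
    contexts: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix.shape[0]
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_FEATURES:
            raise ValueError(f"matrix must be M x {N_FEATURES}")
        if not (len(self.labels) == len(self.subject_ids) == len(self.contexts) == m):
            raise ValueError("metadata lengths must match the matrix row count")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return feature_names()

    def subset(self, idx: np.ndarray) -> "FeatureDataset":
        idx = np.asarray(idx)
        return FeatureDataset(
            self.matrix[idx],
            [self.labels[i] for i in idx],
            [self.subject_ids[i] for i in idx],
            [self.contexts[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(feature_names()))
        df["subject"] = self.subject_ids
        df["context"] = self.contexts
        df["activity"] = self.labels
        return df

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "FeatureDataset":
        df = pd.read_csv(path)
        names = list(feature_names())
        missing = [c for c in names + ["subject", "context", "activity"] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing[:5]}...")
        return cls(
            df[names].to_numpy(dtype=float),
            df["activity"].astype(str).tolist(),
            df["subject"].astype(str).tolist(),
            df["context"].astype(str).tolist(),
        )


def build_dataset(clips: Sequence[Clip]) -> FeatureDataset:
    """Row i of the returned matrix is ``extract_features(clips[i])``."""
    if not clips:
        raise ValueError("clip sequence must be nonempty")
    lengths = {c.n_samples for c in clips}
    if len(lengths) != 1:
        raise ValueError(f"heterogeneous clip lengths {sorted(lengths)}")
    matrix = np.vstack([extract_features(c).values for c in clips])
    return FeatureDataset(
        matrix,
        [c.activity for c in clips],
        [c.subject_id for c in clips],
        [c.context for c in clips],
    )
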