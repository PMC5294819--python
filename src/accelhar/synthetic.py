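"""Synthetic tri-axial accelerometer cohorts with a lab-to-home domain shift.

Real recordings of ambulatory incomplete-SCI subjects are not publicly
available, so this module generates labelled cohorts with the statistical
structure the analysis assumes.  Each 10-s clip is the sum of

* a gravity projection along a per-activity device orientation,
* a dominant movement sinusoid along that orientation,
* a broadband activity-specific "movement texture" band — tones on the
  clip's DFT grid with a Gaussian spectral envelope, emulating postural
  sway, step harmonics and movement irregularity,
* periodic sharp impact transients (heel strikes) for gait classes,
* an irregular amplitude-modulated 7-13 Hz tremor band emulating
  impaired movement, and
* white sensor noise, with samples saturating at the +/-8 g range.

The phases of the periodic components form a per-(subject, activity)
movement signature shared between contexts: a person's movement waveform
is a reproducible trait, and on-grid tones repeat with identical phase in
every consecutive window of a continuous recording.  The home context
applies a parametric :class:`ContextShift` — amplitude scaling, per-clip
frequency jitter, extra noise in quadrature, per-clip random
re-orientation of the device and a systematic per-subject placement bias
(self-placed waist strap) — modelling unsupervised, more variable
at-home movement.  The identity shift makes home statistically identical
to lab.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .signal_io import (
    ACTIVITIES,
    DYNAMIC_RANGE_G,
    AccelRecording,
    Clip,
    LabelInterval,
    write_labels,
    write_recording,
)

STATIC_POSTURES = ("lie", "sit", "stand")


class ClippingWarning(UserWarning):
    """More than half of a clip's samples saturated at the sensor range."""


@dataclass(frozen=True)
class ActivityParams:
    """Signal-model parameters for one activity class.

    gravity_axis_weights is the unit direction of gravity in the device
    frame (g); osc_freq_hz/osc_amp_g describe the dominant movement
    sinusoid (freq 0 for static postures); sway_amp_g/sway_peak_hz/
    sway_width_hz shape the broadband activity-specific "movement
    texture" band (postural sway, step impacts and their harmonics)
    realised as on-grid tones with a Gaussian spectral envelope;
    impact_amp_g is the height of the periodic sharp impact transients
    (heel strikes) locked to the dominant movement cycle; tremor_amp_g
    scales the irregular 7-13 Hz band; noise_sd_g is the white-noise SD
    per axis.
    """

    activity: str
    gravity_axis_weights: tuple[float, float, float]
    osc_freq_hz: float
    osc_amp_g: float
    noise_sd_g: float
    tremor_amp_g: float = 0.0
    sway_amp_g: float = 0.0
    sway_peak_hz: float = 0.5
    sway_width_hz: float = 0.5
    impact_amp_g: float = 0.0

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        w = np.asarray(self.gravity_axis_weights, dtype=float)
        if abs(np.linalg.norm(w) - 1.0) > 1e-9:
            raise ValueError("gravity_axis_weights must be a unit vector")
        amps = (
            self.osc_freq_hz,
            self.osc_amp_g,
            self.tremor_amp_g,
            self.noise_sd_g,
            self.sway_amp_g,
            self.sway_peak_hz,
            self.impact_amp_g,
        )
        if min(amps) < 0:
            raise ValueError("frequencies, amplitudes and noise SDs must be >= 0")
        if self.sway_width_hz <= 0:
            raise ValueError("sway_width_hz must be positive")
        if self.activity in STATIC_POSTURES and self.osc_freq_hz != 0:
            raise ValueError(f"static posture {self.activity!r} must have osc_freq_hz = 0")


@dataclass(frozen=True)
class ContextShift:
    """Parametric lab-to-home distribution shift.

    amp_scale, freq_jitter_sd, extra_noise_sd_g and orientation_jitter_deg
    act per home clip; placement_bias_deg is a systematic per-subject
    re-orientation of the device at home (self-placement of the waist
    strap without supervision), drawn once per subject and applied to all
    of that subject's home clips.
    """

    amp_scale: float = 1.0
    freq_jitter_sd: float = 0.0
    extra_noise_sd_g: float = 0.0
    orientation_jitter_deg: float = 0.0
    placement_bias_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.amp_scale <= 0:
            raise ValueError("amp_scale must be positive")
        low = min(
            self.freq_jitter_sd,
            self.extra_noise_sd_g,
            self.orientation_jitter_deg,
            self.placement_bias_deg,
        )
        if low < 0:
            raise ValueError("jitter and noise fields must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.amp_scale == 1.0
            and self.freq_jitter_sd == 0.0
            and self.extra_noise_sd_g == 0.0
            and self.orientation_jitter_deg == 0.0
            and self.placement_bias_deg == 0.0
        )


def default_activity_params() -> dict[str, ActivityParams]:
    """Default per-activity parameters.

    Device frame: x mediolateral, y vertical (up), z anteroposterior.
    Upright activities carry gravity mostly on y with small forward tilts;
    lying puts gravity on z (supine).  Wheeling is a near-sitting
    orientation with a weak slow oscillation, reflecting joystick
    wheelchair use being close to sitting; stairs resemble walking with a
    larger, slower vertical excursion so the two classes are confusable.
    """

    def unit(v: tuple[float, float, float]) -> tuple[float, float, float]:
        a = np.asarray(v, float)
        a = a / np.linalg.norm(a)
        return (float(a[0]), float(a[1]), float(a[2]))

    return {
        "lie": ActivityParams(
            "lie", unit((0.06, 0.12, 0.99)), 0.0, 0.0, 0.002, 0.005,
            sway_amp_g=0.004, sway_peak_hz=0.1, sway_width_hz=0.15,
        ),
        "sit": ActivityParams(
            "sit", unit((0.02, 0.92, 0.39)), 0.0, 0.0, 0.003, 0.010,
            sway_amp_g=0.006, sway_peak_hz=0.2, sway_width_hz=0.20,
        ),
        "stand": ActivityParams(
            "stand", unit((0.00, 0.99, 0.10)), 0.0, 0.0, 0.004, 0.015,
            sway_amp_g=0.012, sway_peak_hz=0.3, sway_width_hz=0.30,
        ),
        "wheel": ActivityParams(
            "wheel", unit((0.05, 0.90, 0.43)), 0.8, 0.05, 0.006, 0.010,
            sway_amp_g=0.030, sway_peak_hz=0.6, sway_width_hz=0.40,
        ),
        "walk": ActivityParams(
            "walk", unit((0.00, 0.98, 0.20)), 1.8, 0.30, 0.010, 0.030,
            sway_amp_g=0.120, sway_peak_hz=1.8, sway_width_hz=0.60,
            impact_amp_g=1.0,
        ),
        "stairs": ActivityParams(
            "stairs", unit((0.05, 0.97, 0.24)), 1.3, 0.40, 0.012, 0.040,
            sway_amp_g=0.150, sway_peak_hz=1.2, sway_width_hz=0.80,
            impact_amp_g=1.2,
        ),
    }


def default_context_shift() -> ContextShift:
    """Default home shift: stronger, noisier, re-oriented movement."""
    return ContextShift(
        amp_scale=1.3,
        freq_jitter_sd=0.008,
        extra_noise_sd_g=0.003,
        orientation_jitter_deg=0.7,
        placement_bias_deg=8.0,
    )


@dataclass
class SyntheticConfig:
    """Full cohort recipe: who, how many clips, and the signal parameters.

    When ``total_clips_lab``/``total_clips_home`` is set it overrides the
    per-(subject, activity) count and the total is spread as evenly as
    possible over (subject, activity) pairs in fixed order, so that stated
    cohort totals (e.g. 1170 lab / 1089 home clips) can be hit exactly.
    """

    n_subjects: int = 13
    clips_per_activity_lab: int = 15
    clips_per_activity_home: int = 14
    sample_rate_hz: float = 100.0
    clip_seconds: float = 10.0
    activity_params: Mapping[str, ActivityParams] = field(default_factory=default_activity_params)
    context_shift: ContextShift = field(default_factory=default_context_shift)
    subject_sd: float = 0.15
    seed: int = 0
    total_clips_lab: int | None = None
    total_clips_home: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.clips_per_activity_lab <= 0 or self.clips_per_activity_home <= 0:
            raise ValueError("clip counts must be positive")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        n = self.sample_rate_hz * self.clip_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_rate_hz * clip_seconds must be an integer")
        if sorted(self.activity_params) != sorted(ACTIVITIES):
            raise ValueError("activity_params must contain each of the six activities exactly once")
        for name, p in self.activity_params.items():
            if p.activity != name:
                raise ValueError(f"activity_params[{name!r}] describes {p.activity!r}")


def default_config(seed: int = 0) -> SyntheticConfig:
    """The study-scale cohort: 13 subjects, 1170 lab and 1089 home clips."""
    return SyntheticConfig(
        n_subjects=13,
        clips_per_activity_lab=15,
        clips_per_activity_home=14,
        total_clips_home=1089,
        seed=seed,
    )


@dataclass
class Cohort:
    """Generated labelled clips, split by recording context."""

    lab: list[Clip]
    home: list[Clip]

    @property
    def all_clips(self) -> list[Clip]:
        return self.lab + self.home


#: number of texture tones = one per DFT-grid frequency below the spectral
#: feature block's upper edge
_N_TONES = 31

#: per-clip SD of the texture amplitude factor and tone phase drift (rad),
#: modelling imperfect cycle-to-cycle repeatability of impaired movement
_TEXTURE_AMP_JITTER = 0.015
_TEXTURE_PHASE_DRIFT = 0.012


@dataclass(frozen=True)
class _MovementSignature:
    """Random draws shared by all clips of one (subject, activity) pair.

    A person's movement waveform is a reproducible trait: the same subject
    performing the same activity produces the same cycle shape in the lab
    and at home, and on-grid tones repeat with identical phase in every
    consecutive 10-s window of a continuous recording.  Only sensor noise,
    small cycle-to-cycle irregularity and the home-context per-clip
    jitters vary between clips sharing a signature.
    """

    osc_phase: float
    texture_phases: np.ndarray
    tremor_freq_hz: float
    tremor_phases: tuple[float, float]
    tremor_direction: np.ndarray


def _tone_directions(g_dir: np.ndarray, n_tones: int) -> np.ndarray:
    """Deterministic unit directions, one per texture tone.

    Tones fan out on a cone about the gravity axis at golden-angle
    azimuths, so the texture excites all three device axes with
    orientation-determined weights.
    """
    p1 = np.cross(g_dir, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(p1) < 1e-6:
        p1 = np.cross(g_dir, np.array([0.0, 1.0, 0.0]))
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(g_dir, p1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    az = golden * np.arange(n_tones)
    out = (
        g_dir[None, :]
        + 0.8 * np.cos(az)[:, None] * p1[None, :]
        + 0.8 * np.sin(az)[:, None] * p2[None, :]
    )
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _draw_placement(bias_deg: float, rng: np.random.Generator) -> Rotation:
    """Random systematic device re-orientation: angle ~ N(0, bias_deg)
    about a uniformly random axis."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, bias_deg))
    return Rotation.from_rotvec(angle * axis)


def _draw_signature(rng: np.random.Generator) -> _MovementSignature:
    direction = rng.normal(size=3)
    direction = direction / np.linalg.norm(direction)
    return _MovementSignature(
        osc_phase=float(rng.uniform(0.0, 2.0 * np.pi)),
        texture_phases=rng.uniform(0.0, 2.0 * np.pi, size=_N_TONES),
        tremor_freq_hz=float(rng.uniform(7.0, 13.0)),
        tremor_phases=tuple(rng.uniform(0.0, 2.0 * np.pi, size=2)),
        tremor_direction=direction,
    )


def _clip_from_signature(
    params: ActivityParams,
    state: _MovementSignature,
    shift: ContextShift | None,
    subject_scale: float,
    rate: float,
    seconds: float,
    rng: np.random.Generator,
    subject_id: str,
    start: float,
    placement: Rotation | None = None,
) -> Clip:
    """One clip sharing a movement signature.  Per-clip draw order is
    fixed: home orientation jitter, home frequency jitter, texture
    amplitude factor, texture phase drift, tremor phase drift, noise.
    ``placement`` is the subject's systematic home device re-orientation
    (drawn at cohort level, not here)."""
    if subject_scale <= 0:
        raise ValueError("subject_scale must be positive")
    n = rate * seconds
    if abs(n - round(n)) > 1e-9:
        raise ValueError("rate * seconds must be an integer sample count")
    n = int(round(n))
    t = np.arange(n) / rate

    g_dir = np.asarray(params.gravity_axis_weights, dtype=float)
    freq = params.osc_freq_hz
    amp = params.osc_amp_g * subject_scale
    sway_amp = params.sway_amp_g * subject_scale
    noise_sd = params.noise_sd_g
    freq_delta = 0.0

    if shift is not None:
        if placement is not None:
            g_dir = placement.apply(g_dir)
        if shift.orientation_jitter_deg > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.normal(0.0, shift.orientation_jitter_deg))
            g_dir = Rotation.from_rotvec(angle * axis).apply(g_dir)
        if shift.freq_jitter_sd > 0:
            freq_delta = float(rng.normal(0.0, shift.freq_jitter_sd))
            if freq > 0:
                freq = max(0.0, freq + freq_delta)
        amp *= shift.amp_scale
        sway_amp *= shift.amp_scale
        noise_sd = float(np.hypot(noise_sd, shift.extra_noise_sd_g))

    data = np.outer(g_dir, np.ones(n))
    if freq > 0 and amp > 0:
        data += amp * np.outer(
            g_dir, np.sin(2.0 * np.pi * freq * t + state.osc_phase)
        )
    if params.impact_amp_g > 0 and freq > 0:
        # sharp impact transients (heel strikes) locked to the movement
        # cycle: 12-ms Gaussian pulses along the gravity axis.  They give
        # gait classes their deterministic heavy-tailed sample
        # distribution (high-kurtosis, populated extreme z-score bins)
        offset = state.osc_phase / (2.0 * np.pi) / freq
        times = offset + np.arange(int(np.ceil(seconds * freq)) + 1) / freq
        times = times[times < seconds]
        pulse_width = 0.012
        imp = np.zeros(n)
        for tm in times:
            imp += np.exp(-0.5 * ((t - tm) / pulse_width) ** 2)
        data += (params.impact_amp_g * subject_scale
                 * (shift.amp_scale if shift is not None else 1.0)
                 ) * np.outer(g_dir, imp)
    if sway_amp > 0:
        # broadband movement texture: tones on the clip's DFT grid with a
        # Gaussian spectral envelope, each along a deterministic per-tone
        # direction on a cone about the device's gravity axis, so every
        # axis's spectral magnitudes are activity-determined rather than
        # noise-determined
        n_tones = min(_N_TONES, n // 2 - 1) if n >= 6 else 0
        grid = np.arange(1, n_tones + 1) / seconds
        amp_factor = max(0.1, 1.0 + _TEXTURE_AMP_JITTER * rng.standard_normal())
        envelope = sway_amp * amp_factor * np.exp(
            -0.5 * ((grid - params.sway_peak_hz) / params.sway_width_hz) ** 2
        )
        drift = _TEXTURE_PHASE_DRIFT * rng.standard_normal(n_tones)
        phases = state.texture_phases[:n_tones] + drift
        arg = 2.0 * np.pi * np.outer(grid + freq_delta, t) + phases[:, None]
        tones = envelope[:, None] * np.sin(arg)
        directions = _tone_directions(g_dir, n_tones)
        data += directions.T @ tones
    if params.tremor_amp_g > 0:
        # irregular high-frequency band: amplitude-modulated 7-13 Hz tone
        # along a bout-stable random direction, emulating spasticity/tremor
        ph1 = state.tremor_phases[0] + 0.2 * rng.standard_normal()
        ph2 = state.tremor_phases[1] + 0.2 * rng.standard_normal()
        envelope = 1.0 + 0.5 * np.sin(2.0 * np.pi * 0.5 * t + ph2)
        tremor = params.tremor_amp_g * subject_scale * envelope * np.sin(
            2.0 * np.pi * state.tremor_freq_hz * t + ph1
        )
        data += np.outer(state.tremor_direction, tremor)
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=(3, n))

    clipped = np.any(np.abs(data) > DYNAMIC_RANGE_G, axis=0)
    if clipped.mean() > 0.5:
        warnings.warn(
            "more than 50% of samples saturate at +/-8 g; the clip's structure is destroyed",
            ClippingWarning,
            stacklevel=2,
        )
    np.clip(data, -DYNAMIC_RANGE_G, DYNAMIC_RANGE_G, out=data)

    return Clip(
        subject_id=subject_id,
        context="home" if shift is not None else "lab",
        activity=params.activity,
        start=start,
        data=data,
        sample_rate_hz=rate,
    )


def generate_clip(
    params: ActivityParams,
    shift: ContextShift | None,
    subject_scale: float,
    rate: float,
    seconds: float,
    rng: np.random.Generator,
    subject_id: str = "s01",
    start: float = 0.0,
) -> Clip:
    """Generate one standalone clip; context is "home" when a shift is given.

    A fresh movement signature (cycle phases, tremor band) is drawn
    first, then — for a shifted clip — the subject's home placement bias,
    then the clip itself; all randomness comes from ``rng``, so identical
    seeds give bit-identical clips.
    """
    state = _draw_signature(rng)
    placement = None
    if shift is not None and shift.placement_bias_deg > 0:
        placement = _draw_placement(shift.placement_bias_deg, rng)
    return _clip_from_signature(
        params, state, shift, subject_scale, rate, seconds, rng, subject_id, start,
        placement=placement,
    )


def _allocate_counts(total: int | None, per_pair: int, n_subjects: int) -> np.ndarray:
    """Clip counts per (subject, activity) pair, subjects outer, fixed order."""
    n_pairs = n_subjects * len(ACTIVITIES)
    if total is None:
        return np.full(n_pairs, per_pair, dtype=int)
    if total < n_pairs:
        raise ValueError(f"total {total} too small for {n_pairs} (subject, activity) pairs")
    counts = np.full(n_pairs, total // n_pairs, dtype=int)
    counts[: total % n_pairs] += 1
    return counts


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate the full two-context cohort deterministically from the seed.

    Each (subject, activity) pair gets one movement signature shared by
    that subject's lab and home clips, so the lab-to-home difference is
    exactly what :class:`ContextShift` injects.
    """
    rng = np.random.default_rng(config.seed)
    scales = np.exp(rng.normal(0.0, config.subject_sd, size=config.n_subjects))
    signatures = {
        (s, activity): _draw_signature(rng)
        for s in range(config.n_subjects)
        for activity in ACTIVITIES
    }
    placements: dict[int, Rotation] = {}
    if config.context_shift.placement_bias_deg > 0:
        placements = {
            s: _draw_placement(config.context_shift.placement_bias_deg, rng)
            for s in range(config.n_subjects)
        }

    lab_counts = _allocate_counts(
        config.total_clips_lab, config.clips_per_activity_lab, config.n_subjects
    )
    home_counts = _allocate_counts(
        config.total_clips_home, config.clips_per_activity_home, config.n_subjects
    )

    cohort = Cohort(lab=[], home=[])
    for context, counts, clips in (
        ("lab", lab_counts, cohort.lab),
        ("home", home_counts, cohort.home),
    ):
        shift = config.context_shift if context == "home" else None
        pair = 0
        for s in range(config.n_subjects):
            subject_id = f"s{s + 1:02d}"
            t_cursor = 0.0
            for activity in ACTIVITIES:
                params = config.activity_params[activity]
                signature = signatures[(s, activity)]
                for _ in range(int(counts[pair])):
                    clips.append(
                        _clip_from_signature(
                            params,
                            signature,
                            shift,
                            float(scales[s]),
                            config.sample_rate_hz,
                            config.clip_seconds,
                            rng,
                            subject_id=subject_id,
                            start=t_cursor,
                            placement=placements.get(s) if context == "home" else None,
                        )
                    )
                    t_cursor += config.clip_seconds
                pair += 1
    return cohort


def write_cohort(cohort: Cohort, directory: str | os.PathLike) -> str:
    """Write a cohort as raw recordings + label files + a recordings manifest.

    One continuous recording per (subject, context) is assembled by
    concatenating that subject's clips on a contiguous time base, with one
    label interval per clip, so downstream modules cannot distinguish a
    synthetic cohort from a real one.  Returns the manifest path.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    rows = []
    for context, clips in (("lab", cohort.lab), ("home", cohort.home)):
        by_subject: dict[str, list[Clip]] = {}
        for clip in clips:
            by_subject.setdefault(clip.subject_id, []).append(clip)
        for subject_id in sorted(by_subject):
            sclips = sorted(by_subject[subject_id], key=lambda c: c.start)
            rate = sclips[0].sample_rate_hz
            data = np.concatenate([c.data for c in sclips], axis=1)
            time = np.arange(data.shape[1]) / rate
            rec = AccelRecording(subject_id, context, rate, time, data)
            labels = []
            cursor = 0.0
            for c in sclips:
                dur = c.n_samples / rate
                labels.append(LabelInterval(cursor, cursor + dur, c.activity))
                cursor += dur
            rec_file = f"{subject_id}_{context}.csv"
            lab_file = f"{subject_id}_{context}_labels.csv"
            write_recording(rec, os.path.join(directory, rec_file))
            write_labels(labels, os.path.join(directory, lab_file))
            rows.append((subject_id, context, rec_file, lab_file))
    manifest = os.path.join(directory, "recordings.csv")
    import pandas as pd

    pd.DataFrame(
        rows, columns=["subject", "context", "recording", "labels"]
    ).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# config (de)serialization: key-value text with nested sections


def config_to_yaml(config: SyntheticConfig, path: str | os.PathLike) -> None:
    doc = {
        "n_subjects": config.n_subjects,
        "clips_per_activity_lab": config.clips_per_activity_lab,
        "clips_per_activity_home": config.clips_per_activity_home,
        "sample_rate_hz": config.sample_rate_hz,
        "clip_seconds": config.clip_seconds,
        "subject_sd": config.subject_sd,
        "seed": config.seed,
        "total_clips_lab": config.total_clips_lab,
        "total_clips_home": config.total_clips_home,
        "context_shift": {
            "amp_scale": config.context_shift.amp_scale,
            "freq_jitter_sd": config.context_shift.freq_jitter_sd,
            "extra_noise_sd_g": config.context_shift.extra_noise_sd_g,
            "orientation_jitter_deg": config.context_shift.orientation_jitter_deg,
            "placement_bias_deg": config.context_shift.placement_bias_deg,
        },
        "activity_params": {
            name: {
                "gravity_axis_weights": list(p.gravity_axis_weights),
                "osc_freq_hz": p.osc_freq_hz,
                "osc_amp_g": p.osc_amp_g,
                "noise_sd_g": p.noise_sd_g,
                "tremor_amp_g": p.tremor_amp_g,
                "sway_amp_g": p.sway_amp_g,
                "sway_peak_hz": p.sway_peak_hz,
                "sway_width_hz": p.sway_width_hz,
                "impact_amp_g": p.impact_amp_g,
            }
            for name, p in config.activity_params.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def config_from_yaml(path: str | os.PathLike) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig`; omitted keys keep their defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in (
        "n_subjects",
        "clips_per_activity_lab",
        "clips_per_activity_home",
        "sample_rate_hz",
        "clip_seconds",
        "subject_sd",
        "seed",
        "total_clips_lab",
        "total_clips_home",
    ):
        if key in doc:
            kwargs[key] = doc[key]
    if "context_shift" in doc:
        kwargs["context_shift"] = ContextShift(**doc["context_shift"])
    if "activity_params" in doc:
        defaults = default_activity_params()
        params = {}
        for name, sub in doc["activity_params"].items():
            sub = dict(sub)
            if "gravity_axis_weights" in sub:
                sub["gravity_axis_weights"] = tuple(sub["gravity_axis_weights"])
            params[name] = replace(defaults[name], **sub)
        for name in ACTIVITIES:
            params.setdefault(name, defaults[name])
        kwargs["activity_params"] = params
    return SyntheticConfig(**kwargs)
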