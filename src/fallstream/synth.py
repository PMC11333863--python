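"""Synthetic wearable-IMU trial generator.

Produces labeled tri-axial accelerometer + gyroscope trials with the
statistical structure a body-worn fall detector relies on, so the whole
pipeline is exercisable without downloading any public dataset.

A fall trial follows the canonical four-phase structure:

* **prefall** — ordinary movement: gravity (1 g) plus a small gait
  oscillation;
* **falling** — loss of support: acceleration magnitude decays below 1 g
  (approaching free fall) while the gyroscope records a rotation burst;
* **impact** — a short high-g spike, the global magnitude maximum;
* **postfall** — lying still: magnitude back to ~1 g but along a rotated
  gravity axis, gyroscope near zero.

ADL trials cover rest, periodic gait (walking/jogging) and "fall-like"
transients (sitting down, bending down) that reach elevated magnitudes
without the free-fall dip or the sustained postural change of a true fall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .types import ADL, FALL, RawRecording

ADL_KINDS = ("rest", "walking", "jogging", "sit_down", "bend_down")

_G_AXIS = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class FallProfile:
    """Shape parameters of one synthetic fall.

    Durations are seconds; the postfall phase fills whatever remains of the
    trial. ``impact_peak`` is the acceleration-magnitude maximum in g;
    ``gyro_burst_peak`` the rotation-rate maximum in deg/s.
    """

    prefall_duration: float = 4.0
    falling_duration: float = 0.4
    impact_peak: float = 4.0
    impact_duration: float = 0.1
    postfall_orientation_change: float = 90.0
    gyro_burst_peak: float = 200.0
    noise_sd: float = 0.02
    prefall_gait_amplitude: float = 0.3  # g, oscillation around 1 g
    prefall_gait_frequency: float = 2.0  # Hz

    def __post_init__(self) -> None:
        if min(self.prefall_duration, self.falling_duration, self.impact_duration) <= 0:
            raise ValueError("all phase durations must be positive")
        if self.impact_peak <= 1.0:
            raise ValueError("impact_peak must exceed 1 g")
        if self.gyro_burst_peak <= 0:
            raise ValueError("gyro_burst_peak must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class AdlProfile:
    """Shape parameters of one synthetic activity of daily living."""

    activity_kind: str = "walking"
    gait_frequency: float = 2.0  # Hz, used by walking/jogging
    gait_amplitude: float = 0.3  # g
    transient_peak: float = 2.0  # g, used by sit_down/bend_down
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.activity_kind not in ADL_KINDS:
            raise ValueError(
                f"unknown activity_kind {self.activity_kind!r}; expected one of {ADL_KINDS}"
            )
        if not (0 < self.gait_frequency <= 5):
            raise ValueError("gait_frequency must be in (0, 5] Hz")
        if self.gait_amplitude < 0 or self.transient_peak < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be nonnegative")


@dataclass
class SyntheticCohort:
    """A reproducible multi-subject collection of labeled trials."""

    subjects: List[str]
    trials: List[Tuple[RawRecording, str, str]]  # (recording, label, subject_id)
    seed: int = 0

    def __post_init__(self) -> None:
        known = set(self.subjects)
        for _, label, sid in self.trials:
            if label not in (FALL, ADL):
                raise ValueError(f"trial label must be {FALL!r}/{ADL!r}, got {label!r}")
            if sid not in known:
                raise ValueError(f"trial subject {sid!r} not in cohort subjects")

    @property
    def n_falls(self) -> int:
        return sum(1 for _, label, _ in self.trials if label == FALL)


def _check_args(fs: float, duration: float) -> int:
    if fs <= 0:
        raise ValueError("fs must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    return int(round(duration * fs))


def _rotation_axis_angle(rng: np.random.Generator, angle_deg: float) -> np.ndarray:
    """Unit vector at ``angle_deg`` from the resting gravity axis."""
    theta = math.radians(angle_deg)
    phi = rng.uniform(0, 2 * math.pi)
    return np.array(
        [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi), math.cos(theta)]
    )


def generate_fall(
    profile: FallProfile, fs: float, duration: float, rng: np.random.Generator
) -> RawRecording:
    """Synthesize one four-phase fall trial of ``round(duration * fs)`` samples.

    The acceleration magnitude is ~1 g during prefall, dips toward 0.2 g
    while falling, reaches its unique global maximum (= ``impact_peak`` in
    the noiseless case) during impact, and settles at 1 g on a gravity axis
    rotated by ``postfall_orientation_change`` degrees. The gyroscope
    carries a Gaussian rotation burst time-locked to the falling phase.
    """
    n = _check_args(fs, duration)
    t = np.arange(n) / fs

    t_fall = profile.prefall_duration
    t_imp = t_fall + profile.falling_duration
    t_post = t_imp + profile.impact_duration
    if t_post >= duration:
        raise ValueError("phase durations exceed trial duration; no postfall phase left")

    mag = np.empty(n)
    pre = t < t_fall
    falling = (t >= t_fall) & (t < t_imp)
    impact = (t >= t_imp) & (t < t_post)
    post = t >= t_post

    mag[pre] = 1.0 + profile.prefall_gait_amplitude * np.sin(
        2 * math.pi * profile.prefall_gait_frequency * t[pre]
    )
    # exponential decay toward 0.2 g (partial free fall)
    tau = profile.falling_duration / 3.0
    mag[falling] = 0.2 + 0.8 * np.exp(-(t[falling] - t_fall) / tau)
    # half-sine spike whose maximum equals impact_peak exactly
    mag[impact] = 0.2 + (profile.impact_peak - 0.2) * np.sin(
        math.pi * (t[impact] - t_imp) / profile.impact_duration
    )
    mag[post] = 1.0

    # orientation: resting axis before impact, rotated axis after
    post_axis = _rotation_axis_angle(rng, profile.postfall_orientation_change)
    axis = np.where(post[:, None], post_axis[None, :], _G_AXIS[None, :])
    acc = mag[:, None] * axis
    if profile.noise_sd > 0:
        acc = acc + rng.normal(0.0, profile.noise_sd, size=acc.shape)

    # gyroscope: Gaussian burst centered on the falling phase, spread over
    # falling+impact, split across axes by a random unit vector
    center = 0.5 * (t_fall + t_post)
    width = 0.5 * (profile.falling_duration + profile.impact_duration)
    burst = profile.gyro_burst_peak * np.exp(-0.5 * ((t - center) / (width / 2)) ** 2)
    gaxis = rng.normal(size=3)
    gaxis /= np.linalg.norm(gaxis)
    gyro = burst[:, None] * gaxis[None, :]
    gyro_noise_sd = profile.noise_sd * 50.0  # deg/s noise floor tied to acc noise
    if gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, gyro_noise_sd, size=gyro.shape)

    return RawRecording(
        acc=acc,
        gyro=gyro,
        fs_acc=fs,
        fs_gyro=fs,
        subject_id="synthetic",
        activity_code="F_SYN",
        is_fall=True,
    )


def generate_adl(
    profile: AdlProfile, fs: float, duration: float, rng: np.random.Generator
) -> RawRecording:
    """Synthesize one ADL trial (rest, gait, or a fall-like transient)."""
    n = _check_args(fs, duration)
    t = np.arange(n) / fs
    kind = profile.activity_kind

    if kind == "rest":
        mag = np.ones(n)
        gyro_base = np.zeros((n, 3))
    elif kind in ("walking", "jogging"):
        f = profile.gait_frequency
        amp = profile.gait_amplitude
        mag = 1.0 + amp * np.sin(2 * math.pi * f * t)
        # mild limb rotation at the gait frequency, phase-shifted per axis
        gyro_base = np.stack(
            [20.0 * amp * np.sin(2 * math.pi * f * t + ph) for ph in (0.0, 2.1, 4.2)],
            axis=1,
        )
    elif kind in ("sit_down", "bend_down"):
        mag = np.ones(n)
        gyro_base = np.zeros((n, 3))
        peak = max(profile.transient_peak, 1.0)
        width = 0.5  # seconds
        start = rng.uniform(0.2 * duration, 0.6 * duration)
        sel = (t >= start) & (t < start + width)
        mag[sel] = 1.0 + (peak - 1.0) * np.sin(math.pi * (t[sel] - start) / width)
        # transient rotation during the movement, returning to zero after
        gyro_base[sel, 0] = 60.0 * np.sin(math.pi * (t[sel] - start) / width)
    else:  # pragma: no cover - guarded by AdlProfile validation
        raise ValueError(f"unknown activity_kind {kind!r}")

    acc = mag[:, None] * _G_AXIS[None, :]
    if profile.noise_sd > 0:
        acc = acc + rng.normal(0.0, profile.noise_sd, size=acc.shape)
    gyro = gyro_base
    gyro_noise_sd = profile.noise_sd * 50.0
    if gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, gyro_noise_sd, size=gyro.shape)

    return RawRecording(
        acc=acc,
        gyro=gyro,
        fs_acc=fs,
        fs_gyro=fs,
        subject_id="synthetic",
        activity_code=f"D_{kind.upper()}",
        is_fall=False,
    )


@dataclass(frozen=True)
class CohortRanges:
    """Per-subject parameter ranges the cohort generator draws from."""

    impact_peak: Tuple[float, float] = (3.0, 6.0)
    gait_frequency: Tuple[float, float] = (1.5, 2.5)
    gait_amplitude: Tuple[float, float] = (0.2, 0.4)
    transient_peak: Tuple[float, float] = (1.5, 2.5)
    gyro_burst_peak: Tuple[float, float] = (150.0, 300.0)
    noise_sd: Tuple[float, float] = (0.01, 0.05)


def generate_cohort(
    n_subjects: int,
    falls_per_subject: int,
    adls_per_subject: int,
    fs: float = 50.0,
    seed: int = 0,
    duration: float = 12.0,
    ranges: CohortRanges = CohortRanges(),
) -> SyntheticCohort:
    """Generate a deterministic multi-subject cohort of labeled trials.

    Each subject gets its own parameter draw (impact peak, gait frequency,
    noise level, ...) from ``ranges`` so subjects differ systematically —
    the structure a subject-wise split is meant to respect. ADL kinds cycle
    through rest / walking / jogging / sit_down / bend_down.
    """
    if n_subjects <= 0 or falls_per_subject <= 0 or adls_per_subject <= 0:
        raise ValueError("all counts must be positive")
    root = np.random.default_rng(seed)
    subject_seeds = root.integers(0, 2**31 - 1, size=n_subjects)

    subjects = [f"S{i + 1:02d}" for i in range(n_subjects)]
    trials: List[Tuple[RawRecording, str, str]] = []
    for sid, s_seed in zip(subjects, subject_seeds):
        rng = np.random.default_rng(int(s_seed))
        u = lambda lo_hi: float(rng.uniform(*lo_hi))  # noqa: E731
        noise = u(ranges.noise_sd)
        fall_profile = FallProfile(
            impact_peak=u(ranges.impact_peak),
            gyro_burst_peak=u(ranges.gyro_burst_peak),
            noise_sd=noise,
            prefall_gait_frequency=u(ranges.gait_frequency),
        )
        adl_base = AdlProfile(
            gait_frequency=u(ranges.gait_frequency),
            gait_amplitude=u(ranges.gait_amplitude),
            transient_peak=u(ranges.transient_peak),
            noise_sd=noise,
        )
        for k in range(falls_per_subject):
            rec = generate_fall(fall_profile, fs, duration, rng)
            rec.subject_id = sid
            rec.activity_code = f"F{k + 1:02d}"
            trials.append((rec, FALL, sid))
        for k in range(adls_per_subject):
            kind = ADL_KINDS[k % len(ADL_KINDS)]
            rec = generate_adl(replace(adl_base, activity_kind=kind), fs, duration, rng)
            rec.subject_id = sid
            rec.activity_code = f"D{k + 1:02d}"
            trials.append((rec, ADL, sid))
    return SyntheticCohort(subjects=subjects, trials=trials, seed=seed)


def generate_stream(
    fs: float,
    duration: float,
    seed: int,
    fall_at: float | None = None,
    fall_profile: FallProfile | None = None,
    background: AdlProfile | None = None,
) -> RawRecording:
    """A continuous monitoring stream: background activity, optionally with
    one embedded fall whose impact lands near ``fall_at`` seconds.

    Used to exercise the sliding-window detector the way an on-watch
    deployment would see data.
    """
    rng = np.random.default_rng(seed)
    background = background or AdlProfile(activity_kind="rest", noise_sd=0.02)
    if fall_at is None:
        return replace_meta(generate_adl(background, fs, duration, rng), "stream", False)
    fall_profile = fall_profile or FallProfile()
    fall_len = 8.0
    if not (0 < fall_at - fall_profile.prefall_duration
            and fall_at + (fall_len - fall_profile.prefall_duration) < duration):
        raise ValueError("fall_at leaves no room for the fall inside the stream")
    base = generate_adl(background, fs, duration, rng)
    fall = generate_fall(fall_profile, fs, fall_len, rng)
    start = int(round((fall_at - fall_profile.prefall_duration) * fs))
    n = fall.acc.shape[0]
    acc = base.acc.copy()
    gyro = base.gyro.copy()
    acc[start : start + n] = fall.acc
    gyro[start : start + n] = fall.gyro
    rec = RawRecording(
        acc=acc, gyro=gyro, fs_acc=fs, fs_gyro=fs, subject_id="stream",
        activity_code="STREAM_FALL", is_fall=True,
    )
    return rec


def replace_meta(rec: RawRecording, subject_id: str, is_fall: bool) -> RawRecording:
    rec.subject_id = subject_id
    rec.is_fall = is_fall
    return rec


def write_cohort_sisfall(cohort: SyntheticCohort, directory: str | Path) -> List[Path]:
    """Write every trial in the SisFall plain-text dialect (one file each).

    File names follow the ``<activity>_<subject>_R<trial>.txt`` pattern the
    SisFall reader parses, so synthetic cohorts round-trip through the real
    ingestion path.
    """
    from .datasets import write_sisfall_trial

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    counters: dict = {}
    for rec, label, sid in cohort.trials:
        key = (sid, rec.activity_code)
        counters[key] = counters.get(key, 0) + 1
        name = f"{rec.activity_code}_{sid}_R{counters[key]:02d}.txt"
        path = directory / name
        write_sisfall_trial(rec, path)
        paths.append(path)
    return paths
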