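"""Core data containers shared across the pipeline.

Conventions
-----------
* Time-series arrays are time-major: shape ``(n_samples, 3)`` for tri-axial
  sensors. Accelerometer values are in units of g (1 g = 9.81 m/s^2,
  gravity included, so a device at rest reads magnitude ~1 g); gyroscope
  values are in deg/s.
* The positive class throughout is "fall"; everything else is an activity
  of daily living (ADL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Optional, Tuple

import numpy as np

FALL = "fall"
ADL = "adl"


@dataclass
class RawRecording:
    """One trial as recorded: tri-axial accelerometer + gyroscope.

    The two sensors may run at different native rates (e.g. a smartphone
    accelerometer at ~87 Hz and gyroscope at ~100 Hz), so each carries its
    own sampling rate and, optionally, explicit timestamps in seconds.
    """

    acc: np.ndarray  # (n_a, 3), g
    gyro: np.ndarray  # (n_g, 3), deg/s
    fs_acc: float
    fs_gyro: float
    subject_id: str
    activity_code: str = ""
    is_fall: bool = False
    acc_times: Optional[np.ndarray] = None  # seconds, shape (n_a,)
    gyro_times: Optional[np.ndarray] = None  # seconds, shape (n_g,)

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError(f"acc must be (n, 3), got {self.acc.shape}")
        if self.gyro.ndim != 2 or self.gyro.shape[1] != 3:
            raise ValueError(f"gyro must be (n, 3), got {self.gyro.shape}")
        if self.acc.shape[0] == 0 or self.gyro.shape[0] == 0:
            raise ValueError("empty recording")
        if self.fs_acc <= 0 or self.fs_gyro <= 0:
            raise ValueError("sampling rates must be positive")
        if not (np.isfinite(self.acc).all() and np.isfinite(self.gyro).all()):
            raise ValueError("recording contains NaN or Inf")

    @property
    def duration(self) -> float:
        """Trial duration in seconds (accelerometer stream)."""
        return self.acc.shape[0] / self.fs_acc

    def acc_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.acc, axis=1)

    def gyro_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.gyro, axis=1)


@dataclass
class SensorSegment:
    """A fixed-length window at a common rate, ready for the classifier.

    ``LoS`` (length of segment) = ``window_s * fs`` samples per channel;
    600 for a 12 s window at 50 Hz, 400 for 8 s.
    """

    acc: np.ndarray  # (LoS, 3), g
    gyro: np.ndarray  # (LoS, 3), deg/s
    fs: float
    label: str  # FALL or ADL
    subject_id: str

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.acc.shape != self.gyro.shape:
            raise ValueError(
                f"acc and gyro must share shape, got {self.acc.shape} vs {self.gyro.shape}"
            )
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError(f"segment channels must be (LoS, 3), got {self.acc.shape}")
        if self.label not in (FALL, ADL):
            raise ValueError(f"label must be {FALL!r} or {ADL!r}, got {self.label!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def los(self) -> int:
        """Number of samples per channel."""
        return self.acc.shape[0]

    @property
    def is_fall(self) -> bool:
        return self.label == FALL


@dataclass(frozen=True)
class SplitSpec:
    """A subject-wise train/test partition: no participant appears on both sides."""

    train_subjects: Tuple[str, ...]
    test_subjects: Tuple[str, ...]
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_subjects) & set(self.test_subjects)
        if overlap:
            raise ValueError(f"subjects in both train and test: {sorted(overlap)}")


@dataclass(frozen=True)
class Confusion:
    """Binary confusion counts with fall as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class EvalReport:
    """Detection metrics in percent (0..100), plus the underlying confusion.

    ``undefined`` names metrics whose denominator was zero; they are
    reported as 0.0 and flagged rather than raising.
    """

    accuracy: float
    recall: float
    precision: float
    specificity: float
    f1: float
    confusion: Confusion
    undefined: FrozenSet[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "specificity": self.specificity,
            "f1": self.f1,
            "confusion": {
                "tp": self.confusion.tp,
                "fn": self.confusion.fn,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
            },
            "undefined": sorted(self.undefined),
        }
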