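"""Signal conditioning and windowing.

Pipeline order is fixed: physical-unit conversion (done by the readers) ->
zero-phase low-pass at the native rate -> resample to the common rate
(50 Hz by default) -> fixed-length windowing -> subject-wise splitting.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence

import numpy as np
from scipy import signal as sps

from .types import ADL, FALL, RawRecording, SensorSegment, SplitSpec

logger = logging.getLogger(__name__)

TARGET_FS = 50.0
CUTOFF_HZ = 20.0


def lowpass_filter(x: np.ndarray, fs: float, cutoff: float = CUTOFF_HZ, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the first axis.

    Applied forward and backward (filtfilt) so the filter adds no group
    delay — impact spikes keep their timing. Requires ``fs > 2 * cutoff``.
    """
    x = np.asarray(x, dtype=float)
    if fs <= 2 * cutoff:
        raise ValueError(f"fs={fs} must exceed twice the cutoff ({cutoff} Hz)")
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


def resample_to(
    x: np.ndarray,
    fs_in: float,
    fs_out: float = TARGET_FS,
    timestamps: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Resample along the first axis to ``fs_out``.

    Integer decimation when ``fs_in / fs_out`` is integral (the signal is
    assumed already band-limited by :func:`lowpass_filter`), linear
    interpolation onto a uniform grid otherwise (e.g. 87 -> 50 Hz). Output
    length is ``round(n * fs_out / fs_in)``. If ``timestamps`` (seconds)
    are given they define the input grid instead of ``arange(n)/fs_in``.
    """
    x = np.asarray(x, dtype=float)
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    n = x.shape[0]
    if fs_in == fs_out and timestamps is None:
        return x.copy()
    ratio = fs_in / fs_out
    if timestamps is None and abs(ratio - round(ratio)) < 1e-9:
        n_out = int(round(n * fs_out / fs_in))
        return x[:: int(round(ratio))][:n_out].copy()
    t_in = np.asarray(timestamps) if timestamps is not None else np.arange(n) / fs_in
    n_out = int(round(n * fs_out / fs_in))
    t_out = np.arange(n_out) / fs_out + t_in[0]
    if x.ndim == 1:
        return np.interp(t_out, t_in, x)
    return np.stack([np.interp(t_out, t_in, x[:, j]) for j in range(x.shape[1])], axis=1)


def preprocess_recording(
    rec: RawRecording,
    target_fs: float = TARGET_FS,
    cutoff: float = CUTOFF_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Filter and resample both sensor streams onto one uniform grid.

    When the streams have different native rates/timestamps they are
    interpolated onto a shared ``target_fs`` grid and truncated to their
    common length, so the stacked channels are sample-aligned.
    """
    acc = lowpass_filter(rec.acc, rec.fs_acc, cutoff)
    gyro = lowpass_filter(rec.gyro, rec.fs_gyro, cutoff)
    acc = resample_to(acc, rec.fs_acc, target_fs, rec.acc_times)
    gyro = resample_to(gyro, rec.fs_gyro, target_fs, rec.gyro_times)
    n = min(acc.shape[0], gyro.shape[0])
    return acc[:n], gyro[:n]


def make_segments(
    rec: RawRecording,
    window_s: float = 12.0,
    fs: float = TARGET_FS,
    cutoff: float = CUTOFF_HZ,
) -> List[SensorSegment]:
    """Window one recording into fixed-length segments of ``window_s * fs`` samples.

    Fall trials yield a single segment centered on the global
    acceleration-magnitude peak (the impact), with the window start clamped
    into bounds; ADL trials are tiled with consecutive non-overlapping
    windows. Recordings shorter than one window are skipped with a logged
    warning so batch ingestion proceeds.
    """
    los = int(round(window_s * fs))
    acc, gyro = preprocess_recording(rec, fs, cutoff)
    n = acc.shape[0]
    if n < los:
        logger.warning(
            "recording %s/%s too short for a %gs window (%d < %d samples); skipped",
            rec.subject_id, rec.activity_code, window_s, n, los,
        )
        return []
    label = FALL if rec.is_fall else ADL
    segments: List[SensorSegment] = []
    if rec.is_fall:
        peak = int(np.argmax(np.linalg.norm(acc, axis=1)))
        start = min(max(peak - los // 2, 0), n - los)
        segments.append(
            SensorSegment(acc[start : start + los], gyro[start : start + los], fs, label, rec.subject_id)
        )
    else:
        for start in range(0, n - los + 1, los):
            segments.append(
                SensorSegment(acc[start : start + los], gyro[start : start + los], fs, label, rec.subject_id)
            )
    return segments


def segment_cohort(trials, window_s: float = 12.0, fs: float = TARGET_FS) -> List[SensorSegment]:
    """Apply :func:`make_segments` across ``(recording, label, subject)`` trials."""
    out: List[SensorSegment] = []
    for rec, _label, _sid in trials:
        out.extend(make_segments(rec, window_s, fs))
    return out


def subject_split(subject_ids: Sequence[str], ratio: float = 0.8, seed: int = 0) -> SplitSpec:
    """Partition participants into train/test groups at ``ratio`` by subject.

    ``round(ratio * n)`` subjects go to training; the shuffle is
    deterministic given ``seed``. No subject ever contributes segments to
    both sides.
    """
    subjects = list(dict.fromkeys(subject_ids))  # preserve order, dedupe
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for a subject-wise split")
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_train = int(round(ratio * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    train = tuple(subjects[i] for i in sorted(order[:n_train]))
    test = tuple(subjects[i] for i in sorted(order[n_train:]))
    return SplitSpec(train_subjects=train, test_subjects=test, ratio=ratio, seed=seed)


def subject_folds(subject_ids: Sequence[str], k: int, seed: int = 0) -> List[List[str]]:
    """Shuffle subjects and split them into ``k`` near-equal disjoint folds."""
    subjects = list(dict.fromkeys(subject_ids))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds number of subjects ({len(subjects)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    return [[subjects[i] for i in chunk] for chunk in np.array_split(order, k)]


def filter_segments(segments: Sequence[SensorSegment], subjects: Sequence[str]) -> List[SensorSegment]:
    wanted = set(subjects)
    return [s for s in segments if s.subject_id in wanted]
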