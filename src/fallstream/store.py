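"""HDF5 caches for cohorts and preprocessed segment sets."""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import h5py
import numpy as np

from .synth import SyntheticCohort
from .types import ADL, FALL, RawRecording, SensorSegment


def save_segments(segments: Sequence[SensorSegment], path: str | Path) -> Path:
    """Segment cache layout: datasets ``acc`` (n, LoS, 3), ``gyro``,
    ``label`` (1 = fall), ``subject`` (strings); attrs ``fs``."""
    if not segments:
        raise ValueError("no segments to save")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("acc", data=np.stack([s.acc for s in segments]))
        f.create_dataset("gyro", data=np.stack([s.gyro for s in segments]))
        f.create_dataset("label", data=np.array([int(s.is_fall) for s in segments]))
        f.create_dataset(
            "subject",
            data=np.array([s.subject_id for s in segments], dtype=h5py.string_dtype()),
        )
        f.attrs["fs"] = segments[0].fs
    return path


def load_segments(path: str | Path) -> List[SensorSegment]:
    with h5py.File(path, "r") as f:
        acc = f["acc"][:]
        gyro = f["gyro"][:]
        labels = f["label"][:]
        subjects = [s.decode() if isinstance(s, bytes) else str(s) for s in f["subject"][:]]
        fs = float(f.attrs["fs"])
    return [
        SensorSegment(a, g, fs, FALL if y else ADL, sid)
        for a, g, y, sid in zip(acc, gyro, labels, subjects)
    ]


def save_cohort(cohort: SyntheticCohort, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = cohort.seed
        f.attrs["subjects"] = np.array(cohort.subjects, dtype=h5py.string_dtype())
        for i, (rec, label, sid) in enumerate(cohort.trials):
            g = f.create_group(f"trials/{i:05d}")
            g.create_dataset("acc", data=rec.acc)
            g.create_dataset("gyro", data=rec.gyro)
            g.attrs.update(
                {
                    "fs_acc": rec.fs_acc,
                    "fs_gyro": rec.fs_gyro,
                    "subject_id": sid,
                    "activity_code": rec.activity_code,
                    "label": label,
                }
            )
    return path


def load_cohort(path: str | Path) -> SyntheticCohort:
    trials = []
    with h5py.File(path, "r") as f:
        subjects = [s.decode() if isinstance(s, bytes) else str(s) for s in f.attrs["subjects"]]
        seed = int(f.attrs["seed"])
        for key in sorted(f["trials"]):
            g = f[f"trials/{key}"]
            label = str(g.attrs["label"])
            rec = RawRecording(
                acc=g["acc"][:],
                gyro=g["gyro"][:],
                fs_acc=float(g.attrs["fs_acc"]),
                fs_gyro=float(g.attrs["fs_gyro"]),
                subject_id=str(g.attrs["subject_id"]),
                activity_code=str(g.attrs["activity_code"]),
                is_fall=label == FALL,
            )
            trials.append((rec, label, rec.subject_id))
    return SyntheticCohort(subjects=subjects, trials=trials, seed=seed)
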