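"""Readers and writers for the SisFall and MobiFall plain-text dialects.

SisFall trials are single files of comma-separated integer ADC counts, one
row per 200 Hz sample, nine columns (first accelerometer xyz, gyroscope
xyz, second accelerometer xyz), each row terminated by a semicolon. Only
the first accelerometer and the gyroscope are used. Conversion to physical
units is linear:

    value = counts * (2 * range) / 2**resolution_bits

with dataset defaults +/-16 g at 13 bits for the accelerometer and
+/-2000 deg/s at 16 bits for the gyroscope. Subject and activity are
parsed from the ``<activity>_<subject>_R<trial>.txt`` filename; activity
codes starting with ``F`` are falls.

MobiFall trials ship one file per sensor: ``#``-prefixed header lines,
then ``timestamp,x,y,z`` rows with nanosecond timestamps, acceleration in
m/s^2 (~87 Hz) and angular velocity in rad/s (~100 Hz). The orientation
sensor is ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .types import RawRecording

SISFALL_FS = 200.0


@dataclass(frozen=True)
class SisFallScale:
    """Linear ADC-count -> physical-unit conversion for one SisFall device."""

    acc_range_g: float = 16.0
    acc_bits: int = 13
    gyro_range_dps: float = 2000.0
    gyro_bits: int = 16

    @property
    def acc_factor(self) -> float:
        return 2.0 * self.acc_range_g / 2.0**self.acc_bits

    @property
    def gyro_factor(self) -> float:
        return 2.0 * self.gyro_range_dps / 2.0**self.gyro_bits


_SISFALL_NAME = re.compile(r"^(?P<act>[A-Za-z]\d+)_(?P<subj>[A-Za-z]+\d+)_R\d+", re.ASCII)


def _parse_sisfall_name(path: Path) -> Tuple[str, str, bool]:
    m = _SISFALL_NAME.match(path.stem)
    if not m:
        return "", path.stem, False
    act = m.group("act").upper()
    return act, m.group("subj"), act.startswith("F")


def read_sisfall_trial(
    path: str | Path,
    scale: SisFallScale = SisFallScale(),
    fs: float = SISFALL_FS,
) -> RawRecording:
    """Read one SisFall trial file into physical units (g, deg/s)."""
    path = Path(path)
    acc_rows = []
    gyro_rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip().rstrip(";").rstrip(",")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 9:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 9 comma-separated values, got {len(parts)}"
                )
            try:
                vals = [int(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: non-integer value ({exc})") from None
            acc_rows.append(vals[0:3])
            gyro_rows.append(vals[3:6])
    if not acc_rows:
        raise ValueError(f"{path.name}: no data rows")
    acc = np.asarray(acc_rows, dtype=float) * scale.acc_factor
    gyro = np.asarray(gyro_rows, dtype=float) * scale.gyro_factor
    activity, subject, is_fall = _parse_sisfall_name(path)
    return RawRecording(
        acc=acc, gyro=gyro, fs_acc=fs, fs_gyro=fs,
        subject_id=subject, activity_code=activity, is_fall=is_fall,
    )


def write_sisfall_trial(
    rec: RawRecording, path: str | Path, scale: SisFallScale = SisFallScale()
) -> Path:
    """Write a recording in the SisFall dialect (quantizing to ADC counts).

    The second accelerometer's columns are filled with a re-quantized copy
    of the first so files keep the 9-column layout.
    """
    path = Path(path)
    acc_counts = np.rint(rec.acc / scale.acc_factor).astype(int)
    gyro_counts = np.rint(rec.gyro / scale.gyro_factor).astype(int)
    n = min(len(acc_counts), len(gyro_counts))
    with open(path, "w") as fh:
        for i in range(n):
            row = list(acc_counts[i]) + list(gyro_counts[i]) + list(acc_counts[i])
            fh.write(",".join(str(v) for v in row) + ";\n")
    return path


MOBIFALL_ACC_MS2_PER_G = 9.80665
MOBIFALL_GYRO_RAD = True  # gyroscope rows are rad/s


def _read_mobifall_file(path: Path) -> Tuple[np.ndarray, np.ndarray]:
    """Return (timestamps_s, values (n,3)) from one MobiFall sensor file."""
    times = []
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise ValueError(
                    f"{path.name}:{lineno}: expected timestamp,x,y,z; got {len(parts)} fields"
                )
            try:
                times.append(float(parts[0]))
                rows.append([float(p) for p in parts[1:]])
            except ValueError as exc:
                raise ValueError(f"{path.name}:{lineno}: bad number ({exc})") from None
    if not rows:
        raise ValueError(f"{path.name}: no data rows (header only?)")
    t = np.asarray(times)
    t = (t - t[0]) * 1e-9  # nanoseconds -> seconds from stream start
    return t, np.asarray(rows, dtype=float)


_MOBIFALL_NAME = re.compile(r"(?P<act>[A-Z]{3})_(?P<subj>sub\d+)", re.IGNORECASE)
# MobiFall fall activity codes (FOL/FKL/SDL/BSC); everything else is an ADL
MOBIFALL_FALL_CODES = {"FOL", "FKL", "SDL", "BSC"}


def read_mobifall_trial(
    acc_path: str | Path,
    gyro_path: Optional[str | Path] = None,
) -> RawRecording:
    """Read one MobiFall trial (accelerometer file + matching gyroscope file).

    If ``gyro_path`` is omitted it is derived from ``acc_path`` by the
    dataset's ``acc``/``gyro`` filename convention. Each stream keeps its
    native timestamps; no resampling happens here.
    """
    acc_path = Path(acc_path)
    if gyro_path is None:
        candidate = acc_path.with_name(acc_path.name.replace("acc", "gyro"))
        if candidate == acc_path or not candidate.exists():
            raise FileNotFoundError(
                f"cannot derive gyroscope file for {acc_path.name}; pass gyro_path"
            )
        gyro_path = candidate
    gyro_path = Path(gyro_path)

    t_acc, acc_ms2 = _read_mobifall_file(acc_path)
    t_gyro, gyro_rad = _read_mobifall_file(gyro_path)
    acc = acc_ms2 / MOBIFALL_ACC_MS2_PER_G
    gyro = np.degrees(gyro_rad)

    def _rate(t: np.ndarray, default: float) -> float:
        if len(t) < 2 or t[-1] <= t[0]:
            return default
        return (len(t) - 1) / (t[-1] - t[0])

    m = _MOBIFALL_NAME.search(acc_path.stem)
    act = m.group("act").upper() if m else ""
    subj = m.group("subj") if m else acc_path.stem
    return RawRecording(
        acc=acc,
        gyro=gyro,
        fs_acc=_rate(t_acc, 87.0),
        fs_gyro=_rate(t_gyro, 100.0),
        subject_id=subj,
        activity_code=act,
        is_fall=act in MOBIFALL_FALL_CODES,
        acc_times=t_acc,
        gyro_times=t_gyro,
    )


def write_mobifall_trial(
    rec: RawRecording, acc_path: str | Path, gyro_path: str | Path
) -> Tuple[Path, Path]:
    """Write a recording as a MobiFall-dialect acc/gyro file pair."""
    acc_path, gyro_path = Path(acc_path), Path(gyro_path)
    t_acc = rec.acc_times if rec.acc_times is not None else np.arange(len(rec.acc)) / rec.fs_acc
    t_gyro = (
        rec.gyro_times if rec.gyro_times is not None else np.arange(len(rec.gyro)) / rec.fs_gyro
    )
    with open(acc_path, "w") as fh:
        fh.write("#MobiFall (synthetic) accelerometer, m/s2\n#timestamp,x,y,z\n")
        for t, row in zip(t_acc, rec.acc * MOBIFALL_ACC_MS2_PER_G):
            fh.write(f"{int(round(t * 1e9))},{row[0]:.6f},{row[1]:.6f},{row[2]:.6f}\n")
    with open(gyro_path, "w") as fh:
        fh.write("#MobiFall (synthetic) gyroscope, rad/s\n#timestamp,x,y,z\n")
        for t, row in zip(t_gyro, np.radians(rec.gyro)):
            fh.write(f"{int(round(t * 1e9))},{row[0]:.8f},{row[1]:.8f},{row[2]:.8f}\n")
    return acc_path, gyro_path
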