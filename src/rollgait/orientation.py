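"""Sensor orientation streams and roll-angle extraction.

A body-worn orientation sensor reports a unit quaternion per sample. The
joint model downstream uses only the sensor's rotation about its
longitudinal ("roll") axis: with the sensors mounted so their long axes are
parallel and aligned with the limb segments, sagittal-plane segment
rotation appears as roll. Extracting roll as the final rotation of an
intrinsic Euler sequence ending in the x axis makes the result independent
of the heading (yaw) component, so magnetometer disturbances never reach
the joint angles.

Angles are degrees everywhere in the public interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import GimbalLockWarning, InvalidInputError

#: Sensor labels used throughout the three-sensor model.
SENSOR_IDS = ("sacrum", "thigh", "shank")

#: Intrinsic Euler sequences whose third rotation is about the sensor x
#: (longitudinal) axis, i.e. whose third angle is "roll" in our sense.
VALID_CONVENTIONS = ("ZYX", "YZX")

DEFAULT_CONVENTION = "ZYX"

_UNIT_NORM_TOL = 1e-6
# Guard for |sin(pitch)| -> 1 (pitch numerically at +/-90 deg).
_GIMBAL_TOL = 1e-9


def _as_quat_array(q) -> np.ndarray:
    """Validate and return quaternions as an (..., 4) float array (w, x, y, z)."""
    arr = np.asarray(q, dtype=float)
    if arr.shape == (4,) or (arr.ndim == 2 and arr.shape[1] == 4):
        pass
    else:
        raise InvalidInputError(
            f"quaternions must have shape (4,) or (N, 4); got {arr.shape}"
        )
    norm = np.linalg.norm(arr, axis=-1)
    dev = np.abs(norm - 1.0)
    if np.any(dev > _UNIT_NORM_TOL):
        worst = float(norm.flat[np.argmax(dev)] if arr.ndim == 2 else norm)
        raise InvalidInputError(
            f"quaternion is not unit-norm: |q| = {worst!r} "
            f"(tolerance {_UNIT_NORM_TOL})"
        )
    return arr


def roll_from_quaternion(q, convention: str = DEFAULT_CONVENTION):
    """Rotation about the sensor's longitudinal (x) axis, in degrees.

    Parameters
    ----------
    q
        A unit quaternion ``(w, x, y, z)`` or an ``(N, 4)`` array of them.
    convention
        Intrinsic Euler sequence; the last rotation must be about x so the
        returned angle is the roll. ``"ZYX"`` (yaw-pitch-roll, the common
        sensor-vendor convention) is the default and is evaluated in closed
        form; other supported sequences go through a rotation-matrix
        decomposition.

    Returns
    -------
    float or ndarray
        Roll in ``(-180, 180]`` degrees. By construction the heading (yaw)
        component of ``q`` does not affect the result away from gimbal
        lock; at gimbal lock (pitch at ±90°) a warning is emitted and the
        stabilized form ``2·atan2(x, w)`` is returned.
    """
    if convention not in VALID_CONVENTIONS:
        raise InvalidInputError(
            f"unsupported Euler convention {convention!r}; "
            f"expected one of {VALID_CONVENTIONS}"
        )
    arr = _as_quat_array(q)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    w, x, y, z = arr.T

    if convention == "ZYX":
        sin_pitch = np.clip(2.0 * (w * y - x * z), -1.0, 1.0)
        gimbal = np.abs(sin_pitch) > 1.0 - _GIMBAL_TOL
        roll = np.degrees(np.arctan2(2.0 * (w * x + y * z),
                                     1.0 - 2.0 * (x * x + y * y)))
        if np.any(gimbal):
            warnings.warn(
                "pitch is numerically at ±90°; roll/yaw are degenerate and "
                "roll is reported with yaw taken as zero",
                GimbalLockWarning,
                stacklevel=2,
            )
            roll = np.where(gimbal, np.degrees(2.0 * np.arctan2(x, w)), roll)
    else:
        # scipy expects (x, y, z, w); uppercase sequence = intrinsic.
        rot = Rotation.from_quat(np.column_stack([x, y, z, w]))
        roll = rot.as_euler(convention, degrees=True)[:, 2]

    roll = np.where(roll <= -180.0, roll + 360.0, roll)
    return float(roll[0]) if scalar else roll


def quaternions_from_roll(roll_deg) -> np.ndarray:
    """Unit quaternions for pure rotations about the x (roll) axis."""
    half = np.radians(np.asarray(roll_deg, dtype=float)) / 2.0
    return np.stack(
        [np.cos(half), np.sin(half), np.zeros_like(half), np.zeros_like(half)],
        axis=-1,
    )


def unwrap_degrees(values) -> np.ndarray:
    """Remove 360° wrap discontinuities from a degree sequence.

    Output differs from the input element-wise by integer multiples of
    360° and has no successive jump exceeding 180° in magnitude.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot unwrap an empty sequence")
    return np.unwrap(arr, period=360.0)


@dataclass
class OrientationSeries:
    """Uniformly sampled orientation stream for one sensor.

    Exactly one of ``quaternions`` (an ``(N, 4)`` array, scalar-first) or
    ``rolls_deg`` (pre-extracted roll angles, degrees) is populated.
    Timestamps are implicit: sample ``i`` is at ``i / rate_hz`` seconds.
    """

    sensor_id: str
    rate_hz: float
    quaternions: np.ndarray | None = None
    rolls_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise InvalidInputError(f"rate_hz must be positive, got {self.rate_hz}")
        if (self.quaternions is None) == (self.rolls_deg is None):
            raise InvalidInputError(
                "exactly one of quaternions and rolls_deg must be populated"
            )
        if self.quaternions is not None:
            self.quaternions = _as_quat_array(self.quaternions)
            if self.quaternions.ndim != 2:
                self.quaternions = self.quaternions.reshape(1, 4)
        else:
            self.rolls_deg = np.asarray(self.rolls_deg, dtype=float)
        if len(self) == 0:
            raise InvalidInputError("orientation series is empty")

    def __len__(self) -> int:
        data = self.quaternions if self.quaternions is not None else self.rolls_deg
        return 0 if data is None else len(data)

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate_hz


@dataclass
class RollSeries:
    """Unwrapped roll-angle stream (degrees) for one sensor."""

    sensor_id: str
    values_deg: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.values_deg = np.asarray(self.values_deg, dtype=float)
        if self.rate_hz <= 0:
            raise InvalidInputError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.values_deg.size == 0:
            raise InvalidInputError("roll series is empty")

    def __len__(self) -> int:
        return len(self.values_deg)


def extract_roll_series(
    series: OrientationSeries, convention: str = DEFAULT_CONVENTION
) -> RollSeries:
    """Per-sample roll extraction followed by unwrapping; length preserved.

    If the series already carries roll angles they are passed through the
    unwrap step only.
    """
    if len(series) == 0:
        raise InvalidInputError("cannot extract roll from an empty series")
    if series.quaternions is not None:
        raw = roll_from_quaternion(series.quaternions, convention=convention)
    else:
        raw = series.rolls_deg
    return RollSeries(
        sensor_id=series.sensor_id,
        values_deg=unwrap_degrees(raw),
        rate_hz=series.rate_hz,
    )


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: header row required, UTF-8. Either
#   time_s, qw, qx, qy, qz        (quaternion form)
#   time_s, roll_deg              (roll form)
# with an optional sensor_id column; one file may hold several sensors.

_QUAT_COLS = ["qw", "qx", "qy", "qz"]


def _infer_rate(time_s: np.ndarray) -> float:
    if len(time_s) < 2:
        raise InvalidInputError("need at least two samples to infer the rate")
    diffs = np.diff(time_s)
    step = diffs.mean()
    if step <= 0 or np.max(np.abs(diffs - step)) > 1e-9 + 1e-9 * step:
        raise InvalidInputError("timestamps are not uniformly increasing")
    return 1.0 / step


def read_orientation_csv(path) -> dict[str, OrientationSeries]:
    """Read one or more orientation streams from a CSV file.

    Returns a mapping from sensor id to series. A file without a
    ``sensor_id`` column yields a single entry keyed ``"sensor"``.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise InvalidInputError(f"{path}: missing required column 'time_s'")
    has_quat = all(c in df.columns for c in _QUAT_COLS)
    has_roll = "roll_deg" in df.columns
    if has_quat == has_roll:
        raise InvalidInputError(
            f"{path}: expected either columns {_QUAT_COLS} or 'roll_deg'"
        )
    groups = (
        df.groupby("sensor_id", sort=True)
        if "sensor_id" in df.columns
        else [("sensor", df)]
    )
    out: dict[str, OrientationSeries] = {}
    for sensor_id, sub in groups:
        rate = _infer_rate(sub["time_s"].to_numpy(dtype=float))
        if has_quat:
            out[str(sensor_id)] = OrientationSeries(
                sensor_id=str(sensor_id),
                rate_hz=rate,
                quaternions=sub[_QUAT_COLS].to_numpy(dtype=float),
            )
        else:
            out[str(sensor_id)] = OrientationSeries(
                sensor_id=str(sensor_id),
                rate_hz=rate,
                rolls_deg=sub["roll_deg"].to_numpy(dtype=float),
            )
    return out


def write_orientation_csv(streams: Mapping[str, OrientationSeries], path) -> None:
    """Write orientation streams to one CSV file with a sensor_id column."""
    frames = []
    for sensor_id in sorted(streams):
        s = streams[sensor_id]
        base = {"sensor_id": sensor_id, "time_s": s.timestamps}
        if s.quaternions is not None:
            for i, col in enumerate(_QUAT_COLS):
                base[col] = s.quaternions[:, i]
        else:
            base["roll_deg"] = s.rolls_deg
        frames.append(pd.DataFrame(base))
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)
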