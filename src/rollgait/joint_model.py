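"""Single-axis-rotation joint model and static-trial zeroing.

With the three sensors (sacrum, thigh, shank) mounted so their
longitudinal axes are parallel, sagittal joint angles reduce to
differences of sensor roll angles:

    knee flexion = thigh roll − shank roll
    hip flexion  = sacrum roll − thigh roll

Constant mounting offsets common to a sensor pair cancel in the
difference; the residual per-joint offset is removed by subtracting the
mean joint angle recorded while the participant stands in the anatomical
position ("zeroing"). Flexion is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidStateError
from .orientation import RollSeries

JOINTS = ("hip", "knee")
SOURCES = ("sensor", "reference", "truth")


@dataclass
class JointAngleSeries:
    """A flexion-angle time series (degrees) for one joint.

    ``source`` tags provenance (sensor-derived, camera-like reference, or
    simulator ground truth); ``zeroed`` records whether the static-trial
    offset has been subtracted.
    """

    joint: str
    source: str
    zeroed: bool
    values_deg: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise InvalidInputError(f"joint must be one of {JOINTS}, got {self.joint!r}")
        if self.source not in SOURCES:
            raise InvalidInputError(
                f"source must be one of {SOURCES}, got {self.source!r}"
            )
        self.values_deg = np.asarray(self.values_deg, dtype=float)
        if self.values_deg.size == 0:
            raise InvalidInputError("joint-angle series is empty")
        if self.rate_hz <= 0:
            raise InvalidInputError(f"rate_hz must be positive, got {self.rate_hz}")

    def __len__(self) -> int:
        return len(self.values_deg)

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate_hz


@dataclass
class CalibrationOffsets:
    """Per-joint mean angles from the standing calibration trial."""

    hip_offset_deg: float
    knee_offset_deg: float
    trial_duration_s: float = 10.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.hip_offset_deg) and np.isfinite(self.knee_offset_deg)):
            raise InvalidInputError("calibration offsets must be finite")

    def for_joint(self, joint: str) -> float:
        return self.hip_offset_deg if joint == "hip" else self.knee_offset_deg


def _check_pair(a: RollSeries, b: RollSeries) -> None:
    if len(a) != len(b):
        raise InvalidInputError(f"length mismatch: {len(a)} vs {len(b)}")
    if abs(a.rate_hz - b.rate_hz) > 1e-9:
        raise InvalidInputError(f"rate mismatch: {a.rate_hz} vs {b.rate_hz} Hz")


def knee_flexion(
    thigh: RollSeries, shank: RollSeries, flip_sign: bool = False
) -> JointAngleSeries:
    """Knee flexion as thigh roll minus shank roll (degrees).

    ``flip_sign`` negates the result for installations whose sensor
    x axes point the other way.
    """
    _check_pair(thigh, shank)
    values = thigh.values_deg - shank.values_deg
    return JointAngleSeries(
        joint="knee",
        source="sensor",
        zeroed=False,
        values_deg=-values if flip_sign else values,
        rate_hz=thigh.rate_hz,
    )


def hip_flexion(
    sacrum: RollSeries, thigh: RollSeries, flip_sign: bool = False
) -> JointAngleSeries:
    """Hip flexion as sacrum roll minus thigh roll (degrees)."""
    _check_pair(sacrum, thigh)
    values = sacrum.values_deg - thigh.values_deg
    return JointAngleSeries(
        joint="hip",
        source="sensor",
        zeroed=False,
        values_deg=-values if flip_sign else values,
        rate_hz=sacrum.rate_hz,
    )


def compute_offsets(
    static_hip: JointAngleSeries,
    static_knee: JointAngleSeries,
    window: tuple[float, float] | None = None,
) -> CalibrationOffsets:
    """Mean joint angles over the standing calibration trial.

    ``window`` optionally restricts the average to a ``(start_s, end_s)``
    sub-interval to exclude postural sway at the trial edges; the default
    uses the full trial.
    """

    def mean_of(series: JointAngleSeries) -> float:
        values = series.values_deg
        if window is not None:
            lo = int(round(window[0] * series.rate_hz))
            hi = int(round(window[1] * series.rate_hz))
            values = values[lo:hi]
            if values.size == 0:
                raise InvalidInputError(
                    f"calibration window {window} selects no samples"
                )
        return float(values.mean())

    return CalibrationOffsets(
        hip_offset_deg=mean_of(static_hip),
        knee_offset_deg=mean_of(static_knee),
        trial_duration_s=len(static_hip) / static_hip.rate_hz,
    )


def apply_zeroing(
    series: JointAngleSeries, offsets: CalibrationOffsets
) -> JointAngleSeries:
    """Subtract the joint's static-trial offset from a series.

    Applies to both sensor-derived and reference series (zeroing the
    reference produces the "corrected" comparison variant). Zeroing an
    already-zeroed series is an error rather than a silent no-op.
    """
    if series.zeroed:
        raise InvalidStateError(f"{series.joint} series is already zeroed")
    return replace(
        series,
        values_deg=series.values_deg - offsets.for_joint(series.joint),
        zeroed=True,
    )


# ---------------------------------------------------------------------------
# CSV I/O — long format: time_s, joint, source, zeroed, angle_deg


def write_joint_angles_csv(series_list, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_s": s.timestamps,
                "joint": s.joint,
                "source": s.source,
                "zeroed": s.zeroed,
                "angle_deg": s.values_deg,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


def read_joint_angles_csv(path) -> list[JointAngleSeries]:
    df = pd.read_csv(path)
    required = {"time_s", "joint", "source", "zeroed", "angle_deg"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (joint, source, zeroed), sub in df.groupby(
        ["joint", "source", "zeroed"], sort=True
    ):
        t = sub["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise InvalidInputError(f"{path}: series {joint}/{source} too short")
        rate = 1.0 / float(np.mean(np.diff(t)))
        out.append(
            JointAngleSeries(
                joint=str(joint),
                source=str(source),
                zeroed=bool(zeroed),
                values_deg=sub["angle_deg"].to_numpy(dtype=float),
                rate_hz=rate,
            )
        )
    return out
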