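"""Synthetic gait sessions for exercising the full pipeline.

No raw motion data ship with the package, so every stage is tested
against a generator that emulates the study conditions: a cohort of
participants, each with a 10-second standing calibration trial and
20-second walking segments at two timepoints (T1 before, T2 after a
treadmill protocol), sampled at 60 Hz.

Ground-truth hip and knee flexion are periodic-with-jitter waveforms
(harmonic sums over the gait cycle, clamped to physiological ranges).
Segment roll streams are solved exactly so the single-axis joint model
recovers the truth, then corrupted per sensor with:

* a constant mounting offset (what the static calibration removes),
* slow linear drift,
* additive white noise,
* a soft-tissue artifact — low-pass-filtered joint excursion scaled by a
  gain — on the muscle-mounted thigh and shank sensors only (the sacrum
  sensor sits over bone), and
* an extra attachment-degradation offset at T2 (tape loosening), applied
  to the thigh sensor by default.

The camera-like reference streams are the truth plus independent small
white noise and an optional constant frame offset; they extend a
configurable lead/trail pad beyond the sensor window so the analysis can
recover a nonzero sensor-vs-reference lag and still overlap the full
window. All randomness derives from one seed via a documented
``default_rng([seed, participant, stream])`` scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal

from .errors import InvalidInputError
from .joint_model import JointAngleSeries, hip_flexion, knee_flexion
from .orientation import (
    SENSOR_IDS,
    OrientationSeries,
    RollSeries,
    quaternions_from_roll,
    write_orientation_csv,
)

DEFAULT_RATE_HZ = 60.0
DEFAULT_WALK_S = 20.0
DEFAULT_CALIBRATION_S = 10.0

#: Physiological clamps for the generated waveforms, degrees.
HIP_RANGE = (-30.0, 60.0)
KNEE_RANGE = (-5.0, 90.0)

_SENSOR_INDEX = {name: i for i, name in enumerate(SENSOR_IDS)}
# Sub-stream codes for the seeding scheme.
_STREAM_PROFILE = 0
_STREAM_TRUTH = 1
_STREAM_SENSOR = 2
_STREAM_REFERENCE = 3
_STREAM_LAG = 4
_SOFT_TISSUE_CUTOFF_HZ = 3.0


# ---------------------------------------------------------------------------
# Protocol arithmetic


def session_schedule(
    n_bouts: int = 4, bout_minutes: float = 8.0, rest_minutes: float = 3.0
) -> list[tuple[str, float]]:
    """Walking/rest schedule of the between-timepoint treadmill protocol.

    Bouts alternate with rests, so ``n_bouts`` walking bouts enclose
    ``n_bouts - 1`` rests (defaults: four 8-minute bouts, 3-minute rests,
    41 minutes total).
    """
    if n_bouts < 1:
        raise InvalidInputError("need at least one bout")
    schedule: list[tuple[str, float]] = []
    for i in range(n_bouts):
        if i > 0:
            schedule.append(("rest", rest_minutes))
        schedule.append(("walk", bout_minutes))
    return schedule


def protocol_total_minutes(
    n_bouts: int = 4, bout_minutes: float = 8.0, rest_minutes: float = 3.0
) -> float:
    """Total duration, in minutes, of the treadmill protocol."""
    return float(
        sum(d for _, d in session_schedule(n_bouts, bout_minutes, rest_minutes))
    )


# ---------------------------------------------------------------------------
# Ground-truth waveforms


@dataclass
class GaitProfile:
    """Periodic sagittal-plane flexion waveforms for one participant.

    Harmonics are ``(amplitude_deg, phase_rad)`` pairs for successive
    multiples of the cycle frequency; the waveform is
    ``baseline + Σ_k A_k · cos(k·phase + φ_k)`` clamped to physiological
    ranges. Defaults give normative-looking shapes: hip swinging ±20°
    about a 10° baseline, knee with a small stance flexion wave and a
    swing peak near 60°.
    """

    cycle_duration_s: float = 1.1
    hip_harmonics: Sequence[tuple[float, float]] = ((20.0, 0.0),)
    hip_baseline_deg: float = 10.0
    knee_harmonics: Sequence[tuple[float, float]] = ((18.0, 2.3), (14.0, -1.4))
    knee_baseline_deg: float = 28.0
    cycle_jitter_cv: float = 0.03
    pelvis_amplitude_deg: float = 2.0

    def __post_init__(self) -> None:
        if self.cycle_duration_s <= 0:
            raise InvalidInputError("cycle_duration_s must be positive")
        if self.cycle_jitter_cv < 0:
            raise InvalidInputError("cycle_jitter_cv must be non-negative")


def _jittered_phase(
    n: int, rate_hz: float, profile: GaitProfile, rng: np.random.Generator
) -> np.ndarray:
    """Cycle phase (radians) at each sample, with per-cycle duration jitter."""
    t = np.arange(n) / rate_hz
    total = t[-1] if n > 1 else 0.0
    durations: list[float] = []
    acc = 0.0
    while acc <= total + profile.cycle_duration_s:
        d = profile.cycle_duration_s * (
            1.0 + profile.cycle_jitter_cv * rng.standard_normal()
        )
        d = max(d, 0.3 * profile.cycle_duration_s)
        durations.append(d)
        acc += d
    bounds = np.concatenate([[0.0], np.cumsum(durations)])
    idx = np.searchsorted(bounds, t, side="right") - 1
    frac = (t - bounds[idx]) / np.asarray(durations)[idx]
    return 2.0 * np.pi * (idx + frac)


def _waveform(
    phase: np.ndarray,
    harmonics: Sequence[tuple[float, float]],
    baseline: float,
    clamp: tuple[float, float],
) -> np.ndarray:
    values = np.full_like(phase, baseline, dtype=float)
    for k, (amp, ph) in enumerate(harmonics, start=1):
        values += amp * np.cos(k * phase + ph)
    return np.clip(values, *clamp)


def _truth_arrays(
    profile: GaitProfile, n: int, rate_hz: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(hip, knee, pelvis) truth arrays over n samples."""
    phase = _jittered_phase(n, rate_hz, profile, rng)
    hip = _waveform(phase, profile.hip_harmonics, profile.hip_baseline_deg, HIP_RANGE)
    knee = _waveform(
        phase, profile.knee_harmonics, profile.knee_baseline_deg, KNEE_RANGE
    )
    pelvis = profile.pelvis_amplitude_deg * np.sin(phase)
    return hip, knee, pelvis


def generate_truth(
    profile: GaitProfile,
    duration_s: float,
    rate_hz: float = DEFAULT_RATE_HZ,
    seed: int = 0,
) -> tuple[JointAngleSeries, JointAngleSeries]:
    """Ground-truth hip and knee flexion series, reproducible given seed."""
    if duration_s <= 0:
        raise InvalidInputError("duration_s must be positive")
    n = int(round(duration_s * rate_hz))
    rng = np.random.default_rng(seed)
    hip, knee, _ = _truth_arrays(profile, n, rate_hz, rng)
    mk = lambda joint, v: JointAngleSeries(
        joint=joint, source="truth", zeroed=False, values_deg=v, rate_hz=rate_hz
    )
    return mk("hip", hip), mk("knee", knee)


def truth_to_segment_rolls(
    truth_hip: JointAngleSeries,
    truth_knee: JointAngleSeries,
    pelvis_motion=0.0,
) -> dict[str, RollSeries]:
    """Solve segment rolls so the joint model returns the truth exactly.

    With hip = sacrum − thigh and knee = thigh − shank:
    sacrum = pelvis motion, thigh = sacrum − hip, shank = thigh − knee.
    """
    if len(truth_hip) != len(truth_knee):
        raise InvalidInputError("truth series must have equal length")
    rate = truth_hip.rate_hz
    pelvis = np.broadcast_to(
        np.asarray(pelvis_motion, dtype=float), (len(truth_hip),)
    ).astype(float)
    sacrum = pelvis
    thigh = sacrum - truth_hip.values_deg
    shank = thigh - truth_knee.values_deg
    return {
        "sacrum": RollSeries("sacrum", sacrum, rate),
        "thigh": RollSeries("thigh", thigh, rate),
        "shank": RollSeries("shank", shank, rate),
    }


# ---------------------------------------------------------------------------
# Sensor corruption


@dataclass
class SensorNoiseModel:
    """Additive corruption applied to the ideal segment roll streams.

    ``static_offset_deg`` may be a scalar (same mounting offset on every
    sensor) or a per-sensor mapping. ``t2_offset_shift_deg`` given as a
    scalar applies to the thigh sensor only — attachment degradation at
    the second timepoint predominantly moves the knee comparison — or as
    a mapping for per-sensor control.
    """

    static_offset_deg: float | Mapping[str, float] = 0.0
    white_sd_deg: float = 0.0
    drift_deg_per_min: float = 0.0
    soft_tissue_gain: float = 0.0
    t2_offset_shift_deg: float | Mapping[str, float] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("white_sd_deg", "drift_deg_per_min", "soft_tissue_gain"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")

    def offset_for(self, sensor: str) -> float:
        if isinstance(self.static_offset_deg, Mapping):
            return float(self.static_offset_deg.get(sensor, 0.0))
        return float(self.static_offset_deg)

    def t2_shift_for(self, sensor: str) -> float:
        if isinstance(self.t2_offset_shift_deg, Mapping):
            return float(self.t2_offset_shift_deg.get(sensor, 0.0))
        return float(self.t2_offset_shift_deg) if sensor == "thigh" else 0.0


def _lowpass(x: np.ndarray, rate_hz: float, cutoff_hz: float) -> np.ndarray:
    if cutoff_hz >= rate_hz / 2 or len(x) < 15:
        return x
    b, a = _signal.butter(2, cutoff_hz / (rate_hz / 2))
    return _signal.filtfilt(b, a, x)


def corrupt(
    rolls: Mapping[str, RollSeries],
    noise: SensorNoiseModel,
    timepoint: str = "T1",
) -> dict[str, OrientationSeries]:
    """Apply the sensor noise model and emit quaternion streams.

    The soft-tissue artifact on the thigh (resp. shank) sensor follows
    the hip (resp. knee) excursion, low-pass filtered, to mimic muscle
    contraction deforming the segment under the mount.
    """
    for sensor in SENSOR_IDS:
        if sensor not in rolls:
            raise InvalidInputError(f"missing roll series for sensor {sensor!r}")
    rate = rolls["sacrum"].rate_hz
    n = len(rolls["sacrum"])
    hip_exc = rolls["sacrum"].values_deg - rolls["thigh"].values_deg
    knee_exc = rolls["thigh"].values_deg - rolls["shank"].values_deg
    excursions = {
        "sacrum": None,
        "thigh": hip_exc - hip_exc.mean(),
        "shank": knee_exc - knee_exc.mean(),
    }
    t_min = np.arange(n) / rate / 60.0
    tp_code = 0 if timepoint == "T1" else 1
    out: dict[str, OrientationSeries] = {}
    for sensor in SENSOR_IDS:
        rng = np.random.default_rng(
            [noise.seed, _SENSOR_INDEX[sensor], _STREAM_SENSOR, tp_code]
        )
        values = rolls[sensor].values_deg.copy()
        values += noise.offset_for(sensor)
        if timepoint == "T2":
            values += noise.t2_shift_for(sensor)
        values += noise.drift_deg_per_min * t_min
        if noise.soft_tissue_gain > 0 and excursions[sensor] is not None:
            values += noise.soft_tissue_gain * _lowpass(
                excursions[sensor], rate, _SOFT_TISSUE_CUTOFF_HZ
            )
        if noise.white_sd_deg > 0:
            values += rng.normal(0.0, noise.white_sd_deg, n)
        out[sensor] = OrientationSeries(
            sensor_id=sensor, rate_hz=rate, quaternions=quaternions_from_roll(values)
        )
    return out


# ---------------------------------------------------------------------------
# Sessions and cohorts


@dataclass
class Calibration:
    """Standing-trial streams shared by a participant's two timepoints."""

    sensor_streams: dict[str, OrientationSeries]
    reference_hip: JointAngleSeries
    reference_knee: JointAngleSeries
    truth_hip: JointAngleSeries
    truth_knee: JointAngleSeries


@dataclass
class SimSession:
    """One synthetic walking segment with everything the pipeline needs."""

    participant_id: str
    timepoint: str
    rate_hz: float
    truth_hip: JointAngleSeries
    truth_knee: JointAngleSeries
    sensor_streams: dict[str, OrientationSeries]
    reference_hip: JointAngleSeries
    reference_knee: JointAngleSeries
    calibration: Calibration
    injected_lag_samples: int
    reference_lead_samples: int
    params: dict = field(default_factory=dict)

    @property
    def expected_xcorr_lag(self) -> int:
        """Lag align_by_xcorr should report for sensor vs (padded) reference."""
        return self.injected_lag_samples - self.reference_lead_samples


@dataclass
class ParticipantRecord:
    participant_id: str
    calibration: Calibration
    sessions: dict[str, SimSession]
    params: dict = field(default_factory=dict)


def _reference_series(
    joint: str,
    truth: np.ndarray,
    rate: float,
    offset: float,
    sd: float,
    rng: np.random.Generator,
) -> JointAngleSeries:
    values = truth + offset
    if sd > 0:
        values = values + rng.normal(0.0, sd, len(truth))
    return JointAngleSeries(
        joint=joint, source="reference", zeroed=False, values_deg=values, rate_hz=rate
    )


def simulate_participant(
    participant_id: str,
    profile: GaitProfile,
    noise: SensorNoiseModel,
    seed: int,
    participant_index: int = 0,
    duration_s: float = DEFAULT_WALK_S,
    calibration_s: float = DEFAULT_CALIBRATION_S,
    rate_hz: float = DEFAULT_RATE_HZ,
    lag_pad_s: float = 2.0,
    max_lag_samples: int = 30,
    reference_sd_deg: float = 0.3,
    reference_offset_deg: Mapping[str, float] | None = None,
    sway_sd_deg: float = 0.5,
) -> ParticipantRecord:
    """Simulate calibration plus T1/T2 walking segments for one participant."""
    n = int(round(duration_s * rate_hz))
    pad = int(round(lag_pad_s * rate_hz))
    if max_lag_samples > pad:
        raise InvalidInputError(
            f"max_lag_samples ({max_lag_samples}) exceeds the reference pad ({pad})"
        )
    ref_off = dict(reference_offset_deg or {"hip": 0.0, "knee": 0.0})

    # Standing calibration: joints at anatomical zero plus slow sway.
    n_cal = int(round(calibration_s * rate_hz))
    rng_cal = np.random.default_rng([seed, participant_index, _STREAM_TRUTH, 9])
    sway = lambda: (
        _lowpass(rng_cal.normal(0.0, sway_sd_deg, n_cal), rate_hz, 1.0)
        if sway_sd_deg > 0
        else np.zeros(n_cal)
    )
    cal_hip = JointAngleSeries("hip", "truth", False, sway(), rate_hz)
    cal_knee = JointAngleSeries("knee", "truth", False, sway(), rate_hz)
    cal_rolls = truth_to_segment_rolls(cal_hip, cal_knee, pelvis_motion=0.0)
    cal_noise = SensorNoiseModel(
        static_offset_deg=noise.static_offset_deg,
        white_sd_deg=noise.white_sd_deg,
        drift_deg_per_min=noise.drift_deg_per_min,
        soft_tissue_gain=0.0,  # standing: no muscle-contraction artifact
        seed=noise.seed + 1,
    )
    rng_ref_cal = np.random.default_rng([seed, participant_index, _STREAM_REFERENCE, 9])
    calibration = Calibration(
        sensor_streams=corrupt(cal_rolls, cal_noise, timepoint="T1"),
        reference_hip=_reference_series(
            "hip", cal_hip.values_deg, rate_hz, ref_off["hip"],
            reference_sd_deg, rng_ref_cal,
        ),
        reference_knee=_reference_series(
            "knee", cal_knee.values_deg, rate_hz, ref_off["knee"],
            reference_sd_deg, rng_ref_cal,
        ),
        truth_hip=cal_hip,
        truth_knee=cal_knee,
    )

    sessions: dict[str, SimSession] = {}
    for tp_code, timepoint in enumerate(("T1", "T2")):
        rng_truth = np.random.default_rng(
            [seed, participant_index, _STREAM_TRUTH, tp_code]
        )
        # Padded truth covers [-pad, n + pad) so both the (possibly
        # lag-shifted) sensor window and the padded reference fit.
        n_padded = n + 2 * pad
        hip_p, knee_p, pelvis_p = _truth_arrays(profile, n_padded, rate_hz, rng_truth)

        rng_lag = np.random.default_rng([seed, participant_index, _STREAM_LAG, tp_code])
        lag = (
            int(rng_lag.integers(-max_lag_samples, max_lag_samples + 1))
            if max_lag_samples > 0
            else 0
        )

        # Sensor window: sample i holds the truth at (i - lag)/rate, i.e.
        # padded index i - lag + pad.
        sl = slice(pad - lag, pad - lag + n)
        truth_hip = JointAngleSeries("hip", "truth", False, hip_p[pad : pad + n], rate_hz)
        truth_knee = JointAngleSeries(
            "knee", "truth", False, knee_p[pad : pad + n], rate_hz
        )
        sensor_hip = JointAngleSeries("hip", "truth", False, hip_p[sl], rate_hz)
        sensor_knee = JointAngleSeries("knee", "truth", False, knee_p[sl], rate_hz)
        rolls = truth_to_segment_rolls(sensor_hip, sensor_knee, pelvis_motion=pelvis_p[sl])
        sensor_streams = corrupt(rolls, noise, timepoint=timepoint)

        rng_ref = np.random.default_rng(
            [seed, participant_index, _STREAM_REFERENCE, tp_code]
        )
        reference_hip = _reference_series(
            "hip", hip_p, rate_hz, ref_off["hip"], reference_sd_deg, rng_ref
        )
        reference_knee = _reference_series(
            "knee", knee_p, rate_hz, ref_off["knee"], reference_sd_deg, rng_ref
        )
        sessions[timepoint] = SimSession(
            participant_id=participant_id,
            timepoint=timepoint,
            rate_hz=rate_hz,
            truth_hip=truth_hip,
            truth_knee=truth_knee,
            sensor_streams=sensor_streams,
            reference_hip=reference_hip,
            reference_knee=reference_knee,
            calibration=calibration,
            injected_lag_samples=lag,
            reference_lead_samples=pad,
            params={"reference_offset_deg": ref_off},
        )
    return ParticipantRecord(
        participant_id=participant_id,
        calibration=calibration,
        sessions=sessions,
        params={
            "profile": asdict(profile),
            "noise": {
                "static_offset_deg": dict(noise.static_offset_deg)
                if isinstance(noise.static_offset_deg, Mapping)
                else noise.static_offset_deg,
                "white_sd_deg": noise.white_sd_deg,
                "drift_deg_per_min": noise.drift_deg_per_min,
                "soft_tissue_gain": noise.soft_tissue_gain,
                "t2_offset_shift_deg": dict(noise.t2_offset_shift_deg)
                if isinstance(noise.t2_offset_shift_deg, Mapping)
                else noise.t2_offset_shift_deg,
                "seed": noise.seed,
            },
            "reference_sd_deg": reference_sd_deg,
            "reference_offset_deg": ref_off,
            "injected_lag_samples": {
                tp: sessions[tp].injected_lag_samples for tp in sessions
            },
            "reference_lead_samples": int(round(lag_pad_s * rate_hz)),
        },
    )


def simulate_cohort(
    n_participants: int = 20,
    duration_s: float = DEFAULT_WALK_S,
    calibration_s: float = DEFAULT_CALIBRATION_S,
    rate_hz: float = DEFAULT_RATE_HZ,
    seed: int = 0,
    noise: bool = True,
    max_lag_samples: int = 30,
    lag_pad_s: float = 2.0,
) -> list[ParticipantRecord]:
    """Simulate a cohort of participants, each with T1 and T2 sessions.

    With ``noise=True`` per-participant gait profiles and noise levels are
    drawn from realistic ranges (mounting offsets ~N(0, 3°), white noise
    0.2–0.5°, drift up to 0.2°/min, soft-tissue gain 2–6% of excursion,
    T2 thigh attachment shift ~N(2.5°, 1°), camera noise 0.3° with
    per-joint frame offsets ~N(0, 1.5°)). With ``noise=False`` every
    corruption is zero and the chain is exactly invertible.
    """
    if n_participants < 1:
        raise InvalidInputError("need at least one participant")
    records = []
    for p in range(n_participants):
        rng = np.random.default_rng([seed, p, _STREAM_PROFILE])
        profile = GaitProfile(
            cycle_duration_s=float(rng.uniform(1.0, 1.25)),
            hip_harmonics=((float(rng.uniform(16.0, 24.0)), 0.0),),
            hip_baseline_deg=float(rng.uniform(6.0, 14.0)),
            knee_harmonics=(
                (float(rng.uniform(15.0, 21.0)), 2.3),
                (float(rng.uniform(11.0, 17.0)), -1.4),
            ),
            knee_baseline_deg=float(rng.uniform(24.0, 32.0)),
        )
        if noise:
            noise_model = SensorNoiseModel(
                static_offset_deg={
                    s: float(rng.normal(0.0, 3.0)) for s in SENSOR_IDS
                },
                white_sd_deg=float(rng.uniform(0.2, 0.5)),
                drift_deg_per_min=float(rng.uniform(0.0, 0.2)),
                soft_tissue_gain=float(rng.uniform(0.02, 0.06)),
                t2_offset_shift_deg=float(rng.normal(2.5, 1.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            reference_sd = 0.3
            reference_offset = {
                "hip": float(rng.normal(0.0, 1.5)),
                "knee": float(rng.normal(0.0, 1.5)),
            }
        else:
            noise_model = SensorNoiseModel(seed=0)
            reference_sd = 0.0
            reference_offset = {"hip": 0.0, "knee": 0.0}
        sway_sd = 0.5 if noise else 0.0
        records.append(
            simulate_participant(
                participant_id=f"P{p + 1:02d}",
                profile=profile,
                noise=noise_model,
                seed=seed,
                participant_index=p,
                duration_s=duration_s,
                calibration_s=calibration_s,
                rate_hz=rate_hz,
                lag_pad_s=lag_pad_s,
                max_lag_samples=max_lag_samples,
                reference_sd_deg=reference_sd,
                reference_offset_deg=reference_offset,
                sway_sd_deg=sway_sd,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Cohort I/O (the CSV dialects the readers consume, plus a manifest)


def write_cohort(
    records: Sequence[ParticipantRecord], outdir, meta: dict | None = None
) -> Path:
    """Write a cohort to disk; returns the manifest path.

    Layout: ``<outdir>/<participant>/calibration/{sensors,reference}.csv``
    and ``<outdir>/<participant>/<timepoint>/{sensors,reference}.csv``,
    plus ``manifest.json`` recording every ground-truth parameter.
    """
    from .joint_model import write_joint_angles_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"meta": meta or {}, "participants": {}}
    for rec in records:
        pdir = outdir / rec.participant_id
        cdir = pdir / "calibration"
        cdir.mkdir(parents=True, exist_ok=True)
        write_orientation_csv(rec.calibration.sensor_streams, cdir / "sensors.csv")
        write_joint_angles_csv(
            [rec.calibration.reference_hip, rec.calibration.reference_knee],
            cdir / "reference.csv",
        )
        for tp, sess in rec.sessions.items():
            tdir = pdir / tp
            tdir.mkdir(parents=True, exist_ok=True)
            write_orientation_csv(sess.sensor_streams, tdir / "sensors.csv")
            write_joint_angles_csv(
                [sess.reference_hip, sess.reference_knee], tdir / "reference.csv"
            )
            write_joint_angles_csv(
                [sess.truth_hip, sess.truth_knee], tdir / "truth.csv"
            )
        manifest["participants"][rec.participant_id] = rec.params
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
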