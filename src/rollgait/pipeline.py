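"""End-to-end analysis: streams -> joint angles -> alignment -> agreement.

Per session: extract sensor rolls, form hip/knee flexion, zero them with
the standing-trial offsets, build the raw and zeroed reference variants,
recover the sensor-vs-reference lag by cross-correlation (on the knee by
default — the larger excursion — and shared across joints), crop to the
aligned overlap, and compute the agreement metrics for every
joint × comparison-variant. Cohort level: across-participant summary,
pooled-sample agreement, and paired T1-vs-T2 tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import (
    METRICS,
    TimepointComparison,
    agreement_row,
    compare_timepoints,
    summarize_cohort,
)
from .config import RunConfig
from .errors import InvalidInputError
from .joint_model import (
    CalibrationOffsets,
    JointAngleSeries,
    apply_zeroing,
    compute_offsets,
    hip_flexion,
    knee_flexion,
    read_joint_angles_csv,
)
from .orientation import SENSOR_IDS, extract_roll_series, read_orientation_csv
from .time_alignment import AlignmentResult, align_by_xcorr, crop_to_overlap

logger = logging.getLogger("rollgait")

VARIANTS = ("raw", "zeroed")  # reference compared un-zeroed vs zeroed


@dataclass
class SessionData:
    """Inputs for one participant-timepoint (simulator sessions duck-type this)."""

    participant_id: str
    timepoint: str
    rate_hz: float
    sensor_streams: dict
    reference_hip: JointAngleSeries
    reference_knee: JointAngleSeries
    calibration: object
    truth_hip: JointAngleSeries | None = None
    truth_knee: JointAngleSeries | None = None


@dataclass
class LoadedRecord:
    participant_id: str
    calibration: object
    sessions: dict


@dataclass
class CalibrationData:
    sensor_streams: dict
    reference_hip: JointAngleSeries
    reference_knee: JointAngleSeries


@dataclass
class SessionAnalysis:
    participant_id: str
    timepoint: str
    alignments: dict[str, AlignmentResult]
    rows: dict[tuple[str, str], dict]          # (joint, variant) -> metrics
    aligned: dict[tuple[str, str], tuple]      # (joint, variant) -> (s, r) arrays
    offsets: CalibrationOffsets
    reference_offsets: CalibrationOffsets


def sensor_joint_angles(
    sensor_streams: Mapping[str, object], config: RunConfig
) -> dict[str, JointAngleSeries]:
    """Unzeroed hip/knee flexion from three orientation streams."""
    missing = [s for s in SENSOR_IDS if s not in sensor_streams]
    if missing:
        raise InvalidInputError(
            f"missing sensor streams {missing}; expected ids {list(SENSOR_IDS)}"
        )
    rolls = {
        s: extract_roll_series(sensor_streams[s], convention=config.euler_convention)
        for s in SENSOR_IDS
    }
    return {
        "hip": hip_flexion(rolls["sacrum"], rolls["thigh"], config.flip_hip_sign),
        "knee": knee_flexion(rolls["thigh"], rolls["shank"], config.flip_knee_sign),
    }


def _calibration_offsets(
    calibration, config: RunConfig
) -> tuple[CalibrationOffsets, CalibrationOffsets]:
    """(sensor offsets, reference offsets) from the standing trial."""
    cal_joints = sensor_joint_angles(calibration.sensor_streams, config)
    sensor_off = compute_offsets(
        cal_joints["hip"], cal_joints["knee"], window=config.calibration_window_s
    )
    ref_off = compute_offsets(
        calibration.reference_hip,
        calibration.reference_knee,
        window=config.calibration_window_s,
    )
    return sensor_off, ref_off


def analyze_session(session, config: RunConfig | None = None) -> SessionAnalysis:
    """Full per-session analysis for one participant-timepoint."""
    config = config or RunConfig()
    joints = sensor_joint_angles(session.sensor_streams, config)
    sensor_off, ref_off = _calibration_offsets(session.calibration, config)
    zeroed = {j: apply_zeroing(joints[j], sensor_off) for j in joints}
    reference = {"hip": session.reference_hip, "knee": session.reference_knee}
    ref_zeroed = {j: apply_zeroing(reference[j], ref_off) for j in reference}

    alignments: dict[str, AlignmentResult] = {}
    if config.alignment_joint == "per_joint":
        for j in ("hip", "knee"):
            alignments[j] = align_by_xcorr(
                zeroed[j], reference[j], max_lag_s=config.max_lag_s
            )
    else:
        shared = align_by_xcorr(
            zeroed[config.alignment_joint],
            reference[config.alignment_joint],
            max_lag_s=config.max_lag_s,
        )
        alignments = {"hip": shared, "knee": shared}
    logger.info(
        "%s/%s: lag %+d samples (r=%.4f)",
        session.participant_id,
        session.timepoint,
        alignments["knee"].lag_samples,
        alignments["knee"].peak_correlation,
    )

    rows: dict[tuple[str, str], dict] = {}
    aligned: dict[tuple[str, str], tuple] = {}
    for j in ("hip", "knee"):
        for variant, ref in (("raw", reference[j]), ("zeroed", ref_zeroed[j])):
            s_c, r_c = crop_to_overlap(zeroed[j], ref, alignments[j])
            rows[(j, variant)] = agreement_row(
                s_c, r_c, predictor=config.regression_predictor
            )
            aligned[(j, variant)] = (s_c.values_deg, r_c.values_deg)
    return SessionAnalysis(
        participant_id=session.participant_id,
        timepoint=session.timepoint,
        alignments=alignments,
        rows=rows,
        aligned=aligned,
        offsets=sensor_off,
        reference_offsets=ref_off,
    )


@dataclass
class CohortResult:
    frame: pd.DataFrame
    analyses: list[SessionAnalysis]
    summary: pd.DataFrame
    pooled: dict
    comparisons: dict[tuple[str, str], list[TimepointComparison]]
    notices: list[str] = field(default_factory=list)


def analyze_cohort(records: Sequence, config: RunConfig | None = None) -> CohortResult:
    """Analyze every session of every participant and aggregate."""
    config = config or RunConfig()
    analyses: list[SessionAnalysis] = []
    rows = []
    pooled_parts: dict[str, list[tuple]] = {}
    timepoints: set[str] = set()
    for rec in records:
        for tp in sorted(rec.sessions):
            timepoints.add(tp)
            a = analyze_session(rec.sessions[tp], config)
            analyses.append(a)
            for (joint, variant), metrics in a.rows.items():
                rows.append(
                    {
                        "participant": a.participant_id,
                        "timepoint": tp,
                        "joint": joint,
                        "variant": variant,
                        **metrics,
                    }
                )
                pooled_parts.setdefault(f"{joint}|{tp}|{variant}", []).append(
                    a.aligned[(joint, variant)]
                )
    frame = pd.DataFrame(rows)

    pooled_series = {
        key: (
            np.concatenate([s for s, _ in parts]),
            np.concatenate([r for _, r in parts]),
        )
        for key, parts in pooled_parts.items()
    }
    cohort = summarize_cohort(
        frame,
        pooled_series if config.pooled else None,
        predictor=config.regression_predictor,
    )

    notices: list[str] = []
    comparisons: dict[tuple[str, str], list[TimepointComparison]] = {}
    if {"T1", "T2"} <= timepoints:
        for joint in ("hip", "knee"):
            for variant in VARIANTS:
                tables = {}
                for tp in ("T1", "T2"):
                    sub = frame[
                        (frame.timepoint == tp)
                        & (frame.joint == joint)
                        & (frame.variant == variant)
                    ]
                    tables[tp] = sub.set_index("participant")[list(METRICS)]
                comparisons[(joint, variant)] = compare_timepoints(
                    tables["T1"], tables["T2"], alpha=config.alpha
                )
    else:
        notices.append(
            "single timepoint present; T1-vs-T2 comparisons omitted"
        )
        logger.info(notices[-1])
    return CohortResult(
        frame=frame,
        analyses=analyses,
        summary=cohort["summary"],
        pooled=cohort["pooled"],
        comparisons=comparisons,
        notices=notices,
    )


# ---------------------------------------------------------------------------
# Report serialization (deterministic: floats fixed to 6 decimals)


def _round(obj):
    if isinstance(obj, float):
        return round(obj, 6)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), 6)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v) for v in obj]
    return obj


def cohort_report(result: CohortResult, config: RunConfig | None = None) -> dict:
    """JSON-serializable report of a cohort analysis."""
    config = config or RunConfig()
    participants: dict = {}
    for a in result.analyses:
        tp_entry = {
            "lag_samples": a.alignments["knee"].lag_samples,
            "lag_seconds": a.alignments["knee"].lag_seconds,
            "peak_correlation": a.alignments["knee"].peak_correlation,
            "overlap_length": a.alignments["knee"].overlap_length,
            "sensor_offsets_deg": {
                "hip": a.offsets.hip_offset_deg,
                "knee": a.offsets.knee_offset_deg,
            },
            "joints": {},
        }
        for (joint, variant), metrics in a.rows.items():
            tp_entry["joints"].setdefault(joint, {})[variant] = metrics
        participants.setdefault(a.participant_id, {})[a.timepoint] = tp_entry

    report = {
        "settings": {
            "rate_hz": config.rate_hz,
            "euler_convention": config.euler_convention,
            "max_lag_s": config.max_lag_s,
            "alpha": config.alpha,
            "regression_predictor": config.regression_predictor,
            "alignment_joint": config.alignment_joint,
        },
        "participants": participants,
        "cohort_summary": result.summary.to_dict(orient="records"),
        "pooled": result.pooled,
        "comparisons": [
            {
                "joint": joint,
                "variant": variant,
                "metric": c.metric,
                "mean_diff": c.mean_diff,
                "sd_diff": c.sd_diff,
                "t_stat": c.t_stat,
                "p_value": c.p_value,
                "significant": c.significant,
                "n": c.n,
            }
            for (joint, variant), comps in sorted(result.comparisons.items())
            for c in comps
        ],
        "notices": result.notices,
    }
    return _round(report)


def write_report(report: dict, path) -> None:
    Path(path).write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=False) + "\n"
    )


# ---------------------------------------------------------------------------
# Loading a cohort from the on-disk layout the simulator writes


def _load_session_dir(pdir: Path, tp: str, participant: str, calibration):
    tdir = pdir / tp
    streams = read_orientation_csv(tdir / "sensors.csv")
    refs = {s.joint: s for s in read_joint_angles_csv(tdir / "reference.csv")}
    truths = {}
    truth_path = tdir / "truth.csv"
    if truth_path.exists():
        truths = {s.joint: s for s in read_joint_angles_csv(truth_path)}
    rate = streams[next(iter(streams))].rate_hz
    return SessionData(
        participant_id=participant,
        timepoint=tp,
        rate_hz=rate,
        sensor_streams=streams,
        reference_hip=refs["hip"],
        reference_knee=refs["knee"],
        calibration=calibration,
        truth_hip=truths.get("hip"),
        truth_knee=truths.get("knee"),
    )


def load_cohort(datadir) -> list[LoadedRecord]:
    """Load a cohort written by :func:`rollgait.synthetic.write_cohort`."""
    datadir = Path(datadir)
    if not datadir.is_dir():
        raise InvalidInputError(f"not a directory: {datadir}")
    records = []
    for pdir in sorted(p for p in datadir.iterdir() if p.is_dir()):
        cdir = pdir / "calibration"
        if not cdir.is_dir():
            continue
        refs = {s.joint: s for s in read_joint_angles_csv(cdir / "reference.csv")}
        calibration = CalibrationData(
            sensor_streams=read_orientation_csv(cdir / "sensors.csv"),
            reference_hip=refs["hip"],
            reference_knee=refs["knee"],
        )
        sessions = {
            tp: _load_session_dir(pdir, tp, pdir.name, calibration)
            for tp in ("T1", "T2")
            if (pdir / tp).is_dir()
        }
        if not sessions:
            raise InvalidInputError(f"{pdir}: no timepoint directories found")
        records.append(
            LoadedRecord(
                participant_id=pdir.name, calibration=calibration, sessions=sessions
            )
        )
    if not records:
        raise InvalidInputError(f"{datadir}: no participant directories found")
    return records
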