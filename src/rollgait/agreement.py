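"""Method-agreement statistics for sensor vs reference joint angles.

The validation battery follows standard method-comparison practice:

* Bland-Altman analysis of the paired differences d_i = sensor_i −
  reference_i: bias Mdif = mean(d), spread Sd = sample standard deviation
  of d, repeatability coefficient RPC = 1.96·Sd, and 95% limits of
  agreement ULA/LLA = Mdif ± RPC.
* Ordinary least squares of the reference on the sensor signal
  (reference = m·sensor + b), with r² the squared Pearson correlation.
  The sensor signal is the predictor so that a slope below one reads as
  the sensor overestimating joint excursion rates.
* MAE and RMSE of the paired differences, in degrees.
* Paired two-tailed t-tests comparing each per-participant metric between
  the two timepoints, at α = 0.05 by default, with no multiple-testing
  correction across metrics.

Metrics are computed per participant / joint / timepoint and then averaged
across participants for the cohort table; pooling all participants'
aligned samples into one Bland-Altman/regression is a separate mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    InvalidInputError,
    ZeroVarianceTTestWarning,
)

#: The nine scalar agreement metrics compared between timepoints.
METRICS = ("m_dif", "rpc", "ula", "lla", "r2", "m", "b", "mae", "rmse")

#: z-quantile fixed by the 95% limits-of-agreement definition.
LOA_Z = 1.96


@dataclass
class BlandAltmanResult:
    m_dif: float   # mean of sensor - reference differences ("bias"), degrees
    sd: float      # sample (n-1) standard deviation of the differences
    rpc: float     # repeatability coefficient, 1.96 * sd
    ula: float     # upper limit of agreement, m_dif + rpc
    lla: float     # lower limit of agreement, m_dif - rpc
    n: int


@dataclass
class RegressionResult:
    r2: float      # coefficient of determination
    m: float       # slope (reference per unit sensor)
    b: float       # intercept, degrees
    n: int


@dataclass
class ErrorMetrics:
    mae: float     # mean absolute difference, degrees
    rmse: float    # root mean square difference, degrees
    n: int


@dataclass
class TimepointComparison:
    metric: str
    mean_diff: float   # T2 - T1, averaged across participants
    sd_diff: float
    t_stat: float
    p_value: float
    significant: bool
    n: int


def _values(x) -> np.ndarray:
    return np.asarray(getattr(x, "values_deg", x), dtype=float)


def _paired(sensor, reference, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    s, r = _values(sensor), _values(reference)
    if len(s) != len(r):
        raise InvalidInputError(f"length mismatch: {len(s)} vs {len(r)}")
    if len(s) < min_n:
        raise InvalidInputError(f"need at least {min_n} paired samples, got {len(s)}")
    return s, r


def bland_altman(sensor, reference) -> BlandAltmanResult:
    """Bias, spread and 95% limits of agreement of sensor − reference."""
    s, r = _paired(sensor, reference, min_n=2)
    d = s - r
    m_dif = float(d.mean())
    sd = float(d.std(ddof=1))
    rpc = LOA_Z * sd
    return BlandAltmanResult(
        m_dif=m_dif, sd=sd, rpc=rpc, ula=m_dif + rpc, lla=m_dif - rpc, n=len(d)
    )


def linear_fit(sensor, reference, predictor: str = "sensor") -> RegressionResult:
    """OLS of one stream on the other; default reference = m·sensor + b."""
    s, r = _paired(sensor, reference, min_n=3)
    x, y = (s, r) if predictor == "sensor" else (r, s)
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("predictor has zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        r2=float(fit.rvalue**2), m=float(fit.slope), b=float(fit.intercept), n=len(x)
    )


def error_metrics(sensor, reference) -> ErrorMetrics:
    """Mean absolute and root-mean-square difference, degrees."""
    s, r = _paired(sensor, reference, min_n=1)
    d = s - r
    return ErrorMetrics(
        mae=float(np.mean(np.abs(d))),
        rmse=float(np.sqrt(np.mean(d**2))),
        n=len(d),
    )


def agreement_row(sensor, reference, predictor: str = "sensor") -> dict[str, float]:
    """All nine metrics for one aligned pair, as a flat mapping."""
    ba = bland_altman(sensor, reference)
    reg = linear_fit(sensor, reference, predictor=predictor)
    err = error_metrics(sensor, reference)
    return {
        "m_dif": ba.m_dif,
        "rpc": ba.rpc,
        "ula": ba.ula,
        "lla": ba.lla,
        "r2": reg.r2,
        "m": reg.m,
        "b": reg.b,
        "mae": err.mae,
        "rmse": err.rmse,
        "n": ba.n,
    }


def paired_ttest(t1: np.ndarray, t2: np.ndarray) -> tuple[float, float]:
    """Two-tailed paired t-test of T2 vs T1 values.

    Zero-variance differences make t undefined; by convention the result
    is then p = 0 when the mean difference is nonzero (a perfectly
    consistent shift) and p = 1 when it is zero, with a warning.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if len(t1) != len(t2) or len(t1) < 2:
        raise InvalidInputError("paired t-test needs two equal-length samples, n >= 2")
    d = t2 - t1
    if d.std(ddof=1) == 0.0:
        warnings.warn(
            "paired differences have zero variance; p-value set by convention",
            ZeroVarianceTTestWarning,
            stacklevel=2,
        )
        if d.mean() == 0.0:
            return 0.0, 1.0
        return float(np.inf * np.sign(d.mean())), 0.0
    res = stats.ttest_rel(t2, t1)
    return float(res.statistic), float(res.pvalue)


def compare_timepoints(
    per_participant_t1: pd.DataFrame,
    per_participant_t2: pd.DataFrame,
    alpha: float = 0.05,
) -> list[TimepointComparison]:
    """Paired t-test for each metric between the two timepoints.

    Inputs are per-participant metric tables indexed by participant id
    with the metric columns of :data:`METRICS`; the participant sets must
    match exactly.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha}")
    ids1 = set(per_participant_t1.index)
    ids2 = set(per_participant_t2.index)
    if ids1 != ids2:
        raise InvalidInputError(
            f"participant mismatch between timepoints: only-T1={sorted(ids1 - ids2)}, "
            f"only-T2={sorted(ids2 - ids1)}"
        )
    order = sorted(ids1)
    t1 = per_participant_t1.loc[order]
    t2 = per_participant_t2.loc[order]
    out = []
    for metric in METRICS:
        if metric not in t1.columns or metric not in t2.columns:
            continue
        v1 = t1[metric].to_numpy(dtype=float)
        v2 = t2[metric].to_numpy(dtype=float)
        d = v2 - v1
        t_stat, p = paired_ttest(v1, v2)
        out.append(
            TimepointComparison(
                metric=metric,
                mean_diff=float(d.mean()),
                sd_diff=float(d.std(ddof=1)),
                t_stat=t_stat,
                p_value=p,
                significant=bool(p < alpha),
                n=len(d),
            )
        )
    return out


def summarize_cohort(
    per_participant: pd.DataFrame,
    pooled_series: Mapping[str, tuple] | None = None,
    predictor: str = "sensor",
) -> dict:
    """Cohort-level summary of per-participant agreement metrics.

    Parameters
    ----------
    per_participant
        Tidy table with columns ``participant, joint, timepoint, variant``
        plus the metric columns; one row per participant/joint/timepoint/
        comparison-variant.
    pooled_series
        Optional mapping from a ``(joint, timepoint, variant)``-style key
        to an (aligned sensor array, reference array) pair; each gets a
        pooled Bland-Altman/regression/error computation over the
        concatenated samples.

    Returns
    -------
    dict with ``"summary"`` (across-participant mean and sd of every
    metric, grouped by joint/timepoint/variant) and ``"pooled"`` (metric
    rows for the concatenated samples, if provided).
    """
    if len(per_participant) == 0:
        raise InvalidInputError("no per-participant rows to summarize")
    metrics = [m for m in METRICS if m in per_participant.columns]
    grouped = per_participant.groupby(["joint", "timepoint", "variant"], sort=True)
    agg = grouped[metrics].agg(["mean", "std"])
    agg.columns = [f"{metric}_{stat}" for metric, stat in agg.columns]
    summary = agg.reset_index()
    summary.insert(3, "n_participants", grouped.size().to_numpy())
    # A single participant has no across-participant spread; report sd 0.
    if summary["n_participants"].max() == 1:
        sd_cols = [c for c in summary.columns if c.endswith("_std")]
        summary[sd_cols] = summary[sd_cols].fillna(0.0)

    pooled = {}
    if pooled_series is not None:
        for key, (s, r) in pooled_series.items():
            pooled[key] = agreement_row(s, r, predictor=predictor)
    return {"summary": summary, "pooled": pooled}


# ---------------------------------------------------------------------------
# Report export


def write_cohort_csv(summary: pd.DataFrame, path) -> None:
    """Flat CSV of across-participant mean ± sd metric columns."""
    summary.to_csv(Path(path), index=False, float_format="%.6f")


def comparisons_frame(
    comparisons: Mapping[tuple, list[TimepointComparison]]
) -> pd.DataFrame:
    """Tidy frame of timepoint comparisons keyed by (joint, variant)."""
    rows = []
    for (joint, variant), comps in sorted(comparisons.items()):
        for c in comps:
            rows.append(
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
            )
    return pd.DataFrame(rows)


def write_comparisons_csv(
    comparisons: Mapping[tuple, list[TimepointComparison]], path
) -> None:
    comparisons_frame(comparisons).to_csv(Path(path), index=False, float_format="%.6f")
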