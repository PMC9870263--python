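"""Time alignment of sensor-derived and reference joint-angle streams.

The two acquisition systems are not hardware-synchronized, so before any
sample-wise comparison the streams are aligned by maximizing the
normalized cross-correlation over a bounded range of integer-sample lags.
Both signals are mean-removed per candidate overlap, so the reported peak
is a Pearson-style coefficient and a constant offset between the systems
cannot bias the lag.

Lag sign convention: a positive lag means the first (sensor) stream lags
the second (reference) stream, i.e. ``a[i] ≈ b[i - lag]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidInputError
from .joint_model import JointAngleSeries

DEFAULT_MAX_LAG_S = 5.0


@dataclass
class AlignmentResult:
    """Outcome of a cross-correlation alignment."""

    lag_samples: int
    lag_seconds: float
    peak_correlation: float
    overlap_length: int


def _values(x) -> np.ndarray:
    return np.asarray(getattr(x, "values_deg", x), dtype=float)


def _overlap_bounds(na: int, nb: int, lag: int) -> tuple[int, int]:
    """Index range [i0, i1) in a such that b index i - lag is valid."""
    return max(0, lag), min(na, nb + lag)


def align_by_xcorr(
    a: JointAngleSeries,
    b: JointAngleSeries,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
) -> AlignmentResult:
    """Integer-sample lag maximizing the Pearson correlation of a vs b.

    Candidate lags span ``[-max_lag, +max_lag]`` samples. Ties in the
    correlation peak resolve to the smallest ``|lag|``, then to the
    negative lag, so degenerate periodic inputs behave deterministically.
    """
    if abs(a.rate_hz - b.rate_hz) > 1e-9:
        raise InvalidInputError(f"rate mismatch: {a.rate_hz} vs {b.rate_hz} Hz")
    rate = a.rate_hz
    max_lag = int(round(max_lag_s * rate))
    xa, xb = _values(a), _values(b)
    if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(xb))):
        raise InvalidInputError("series contain non-finite values")
    if len(xa) <= max_lag or len(xb) <= max_lag:
        raise InvalidInputError(
            f"series must be longer than max_lag ({max_lag} samples); "
            f"got lengths {len(xa)}, {len(xb)}"
        )
    if np.ptp(xa) == 0.0 or np.ptp(xb) == 0.0:
        raise DegenerateInputError(
            "cross-correlation is undefined for all-constant input"
        )

    best_lag: int | None = None
    best_r = -np.inf
    # Tie-break priority order: 0, -1, +1, -2, +2, ...
    order = [0]
    for k in range(1, max_lag + 1):
        order.extend([-k, k])
    for lag in order:
        i0, i1 = _overlap_bounds(len(xa), len(xb), lag)
        if i1 - i0 < 2:
            continue
        sa = xa[i0:i1]
        sb = xb[i0 - lag : i1 - lag]
        da = sa - sa.mean()
        db = sb - sb.mean()
        denom = np.sqrt((da @ da) * (db @ db))
        if denom == 0.0:
            continue
        r = float((da @ db) / denom)
        if r > best_r:
            best_r = r
            best_lag = lag
    if best_lag is None:
        raise DegenerateInputError("no lag produced a usable overlap")
    i0, i1 = _overlap_bounds(len(xa), len(xb), best_lag)
    return AlignmentResult(
        lag_samples=best_lag,
        lag_seconds=best_lag / rate,
        peak_correlation=best_r,
        overlap_length=i1 - i0,
    )


def crop_to_overlap(
    a: JointAngleSeries, b: JointAngleSeries, result: AlignmentResult
) -> tuple[JointAngleSeries, JointAngleSeries]:
    """Crop both series to their aligned overlap.

    Sample ``i`` of each output corresponds to the same physical instant;
    both outputs have length ``result.overlap_length`` (recomputed for the
    actual input lengths).
    """
    lag = result.lag_samples
    if abs(lag) >= min(len(a), len(b)):
        raise InvalidInputError(
            f"|lag| = {abs(lag)} leaves no overlap for lengths "
            f"{len(a)}, {len(b)}"
        )
    i0, i1 = _overlap_bounds(len(a), len(b), lag)
    if i1 <= i0:
        raise InvalidInputError("alignment leaves an empty overlap")
    from dataclasses import replace

    return (
        replace(a, values_deg=a.values_deg[i0:i1]),
        replace(b, values_deg=b.values_deg[i0 - lag : i1 - lag]),
    )
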