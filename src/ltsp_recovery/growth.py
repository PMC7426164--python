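"""Exponential growth-rate estimation from plate-reader OD curves.

The exponential rate of a well is taken as the maximal slope of ln(OD)
versus time over a sliding window of consecutive time points (five by
default), accepting only windows whose ordinary-least-squares fit has
R^2 above a quality threshold (0.99 by default).  Rates are then
expressed as a percentage of a wild-type rate measured on the same
plate, and recovery over serial-dilution cycles is summarised by the
maximal relative rate and the first cycle at which it reaches a
threshold (90% by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ODCurve",
    "GrowthRateEstimate",
    "RecoveryTrajectory",
    "RecoverySummary",
    "InsufficientDataError",
    "UnqualifiedEstimateError",
    "fit_exponential_rate",
    "relative_growth_rate",
    "recovery_summary",
    "read_plate_csv",
    "rates_table",
]


class InsufficientDataError(ValueError):
    """Raised when a curve has too few usable points for a window fit."""


class UnqualifiedEstimateError(ValueError):
    """Raised when a relative rate is requested from a failed fit."""


@dataclass(frozen=True)
class ODCurve:
    """One well's optical-density (600 nm) time series.

    times are minutes, strictly increasing; od values are non-negative.
    """

    sample_id: str
    times: tuple[float, ...]
    od: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        od = tuple(float(x) for x in self.od)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if len(times) != len(od):
            raise ValueError(
                f"{self.sample_id}: {len(times)} times but {len(od)} OD readings"
            )
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.sample_id}: times must be strictly increasing")
        if any(x < 0 for x in od):
            raise ValueError(f"{self.sample_id}: negative OD reading")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GrowthRateEstimate:
    """Result of the windowed max-slope fit.

    ``rate`` is the per-minute slope of ln(OD) vs time for the winning
    window; absent (None) when no window met the R^2 threshold.
    """

    sample_id: str
    qualified: bool
    rate: Optional[float] = None
    window_start_index: Optional[int] = None
    window_r2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.qualified:
            if self.rate is None or self.window_r2 is None:
                raise ValueError("qualified estimate must carry rate and R^2")
            if not 0.0 <= self.window_r2 <= 1.0 + 1e-12:
                raise ValueError(f"R^2 out of range: {self.window_r2}")
        elif self.rate is not None:
            raise ValueError("unqualified estimate must not carry a rate")


@dataclass(frozen=True)
class RecoveryTrajectory:
    """Relative growth rate (% of wild type) across dilution cycles.

    Cycle 0 is the day of sampling, before any dilution into fresh medium.
    """

    sample_id: str
    cycles: tuple[int, ...]
    relative_rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cycles) != len(self.relative_rates):
            raise ValueError("cycles and relative_rates must have equal length")
        if any(b < a for a, b in zip(self.cycles, self.cycles[1:])):
            raise ValueError("cycles must be non-decreasing")


@dataclass(frozen=True)
class RecoverySummary:
    """Maximal relative rate and first cycle reaching the threshold.

    ``first_cycle_at_threshold`` is None when the threshold is never
    reached (printed as N/A in tabular output).
    """

    sample_id: str
    max_relative_rate: float
    first_cycle_at_threshold: Optional[int]


def _ols_loglinear(times: np.ndarray, log_od: np.ndarray) -> tuple[float, float]:
    """Slope and R^2 of OLS of log OD on time.

    R^2 is NaN when log OD has zero variance (flat window): a horizontal
    line is fit perfectly but carries no rate information, so such
    windows never qualify.
    """
    t = times - times.mean()
    y = log_od - log_od.mean()
    ss_tot = float(y @ y)
    if ss_tot == 0.0:
        return 0.0, float("nan")
    slope = float((t @ y) / (t @ t))
    resid = y - slope * t
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return slope, r2


def fit_exponential_rate(
    curve: ODCurve,
    window: int = 5,
    r2_min: float = 0.99,
    od_floor: float = 0.01,
) -> GrowthRateEstimate:
    """Fit the maximal exponential rate over sliding windows.

    Every run of ``window`` consecutive readings with OD above
    ``od_floor`` is fit by OLS of ln(OD) on time; among windows with
    R^2 strictly greater than ``r2_min`` the one with the largest slope
    wins (earliest window on ties).  Readings at or below ``od_floor``
    are treated as blank/noise-dominated and excluded before the log
    transform.

    Raises
    ------
    InsufficientDataError
        If fewer than ``window`` readings are above ``od_floor``.
    """
    if window < 2:
        raise ValueError("window must span at least 2 points")
    times = np.asarray(curve.times, dtype=float)
    od = np.asarray(curve.od, dtype=float)
    usable = od > od_floor
    if int(usable.sum()) < window:
        raise InsufficientDataError(
            f"{curve.sample_id}: only {int(usable.sum())} readings above "
            f"od_floor={od_floor}, need {window}"
        )

    best_slope = -math.inf
    best_start: Optional[int] = None
    best_r2 = float("nan")
    for start in range(len(od) - window + 1):
        seg = slice(start, start + window)
        if not usable[seg].all():
            continue
        if (od[seg] <= 0).any():  # unreachable for od_floor > 0; guards floor<=0
            logger.warning(
                "%s: non-positive OD in window at index %d, skipped",
                curve.sample_id,
                start,
            )
            continue
        slope, r2 = _ols_loglinear(times[seg], np.log(od[seg]))
        if math.isnan(r2) or r2 <= r2_min:
            continue
        if slope > best_slope:
            best_slope = slope
            best_start = start
            best_r2 = r2
    if best_start is None:
        return GrowthRateEstimate(sample_id=curve.sample_id, qualified=False)
    return GrowthRateEstimate(
        sample_id=curve.sample_id,
        qualified=True,
        rate=best_slope,
        window_start_index=best_start,
        window_r2=min(best_r2, 1.0),
    )


def relative_growth_rate(
    sample: GrowthRateEstimate, wildtype: GrowthRateEstimate
) -> float:
    """Sample rate as a percentage of the wild-type rate (62.0 means 62%)."""
    if not sample.qualified:
        raise UnqualifiedEstimateError(f"{sample.sample_id}: no qualified fit")
    if not wildtype.qualified:
        raise UnqualifiedEstimateError(f"{wildtype.sample_id}: no qualified fit")
    assert sample.rate is not None and wildtype.rate is not None
    if wildtype.rate <= 0:
        raise ValueError(f"wild-type rate must be positive, got {wildtype.rate}")
    return 100.0 * sample.rate / wildtype.rate


def recovery_summary(
    trajectory: RecoveryTrajectory, threshold: float = 90.0
) -> RecoverySummary:
    """Maximal relative rate and first cycle at or above ``threshold``."""
    if len(trajectory.cycles) == 0:
        raise ValueError(f"{trajectory.sample_id}: empty trajectory")
    max_rate = max(trajectory.relative_rates)
    first: Optional[int] = None
    for cyc, rate in zip(trajectory.cycles, trajectory.relative_rates):
        if rate >= threshold and (first is None or cyc < first):
            first = cyc
    return RecoverySummary(
        sample_id=trajectory.sample_id,
        max_relative_rate=max_rate,
        first_cycle_at_threshold=first,
    )


def read_plate_csv(path) -> list[ODCurve]:
    """Read a plate-reader CSV: first column ``time_min``, one column per well.

    Header names become sample ids.  Raises on non-monotone times,
    non-numeric cells, or an empty file; OD readings are assumed
    background-corrected.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty plate file") from exc
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one well")
    time_col = frame.columns[0]
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2}"
            )
        frame[col] = coerced
    times = frame[time_col].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        row = int(np.argmax(np.diff(times) <= 0)) + 2
        raise ValueError(f"{path}: time column not strictly increasing at row {row}")
    curves = []
    for col in frame.columns[1:]:
        curves.append(
            ODCurve(sample_id=str(col), times=tuple(times), od=tuple(frame[col]))
        )
    return curves


def rates_table(
    curves: Sequence[ODCurve],
    wildtype_ids: Sequence[str],
    window: int = 5,
    r2_min: float = 0.99,
    od_floor: float = 0.01,
) -> pd.DataFrame:
    """Fit every curve and express rates relative to the mean wild-type rate.

    Columns: sample_id, rate_per_min, window_start_min, r2,
    relative_percent.  Unqualified fits yield NaN in the numeric columns.
    The wild-type reference is the mean of the qualified rates of the
    wells named in ``wildtype_ids``.
    """
    wt_set = set(wildtype_ids)
    missing = wt_set - {c.sample_id for c in curves}
    if missing:
        raise ValueError(f"wild-type wells not on plate: {sorted(missing)}")
    estimates = {
        c.sample_id: fit_exponential_rate(c, window=window, r2_min=r2_min, od_floor=od_floor)
        for c in curves
    }
    wt_rates = [e.rate for sid, e in estimates.items() if sid in wt_set and e.qualified]
    if not wt_rates:
        raise UnqualifiedEstimateError("no wild-type well produced a qualified fit")
    wt_mean = float(np.mean(wt_rates))
    rows = []
    for c in curves:
        e = estimates[c.sample_id]
        rows.append(
            {
                "sample_id": c.sample_id,
                "rate_per_min": e.rate if e.qualified else float("nan"),
                "window_start_min": (
                    c.times[e.window_start_index] if e.qualified else float("nan")
                ),
                "r2": e.window_r2 if e.qualified else float("nan"),
                "relative_percent": (
                    100.0 * e.rate / wt_mean if e.qualified else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
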