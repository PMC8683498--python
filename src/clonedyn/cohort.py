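"""Cohort-level statistics: Kaplan-Meier survival, co-occurrence rates,
PET metabolic-response classification, tumor-volume and growth-rate helpers.

The product-limit estimation is delegated to lifelines; this module fixes the
conventions used throughout the package: the KM median is the smallest
observed event time t with S(t) <= 0.5, and one month is 365.25/12 days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .errors import InputError

DAYS_PER_MONTH = 365.25 / 12.0


def days_to_months(days: float) -> float:
    return days / DAYS_PER_MONTH


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: ``event=True`` means the event (death) was
    observed at ``time``; ``False`` means censored alive at ``time``."""

    patient_id: str
    time: float  # days
    event: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise InputError(f"invalid survival time {self.time!r} for {self.patient_id}")


@dataclass
class KMCurve:
    """Product-limit curve: step function over observed times.

    ``times``/``survival`` contain every distinct observed time (events and
    censorings) in ascending order; ``event_times`` the subset where at least
    one event occurred.  Greenwood/log-log confidence bands are carried along
    but are reported, not validated, downstream.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    event_times: np.ndarray
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )
        if self.ci_lower is not None:
            frame["ci_lower"] = self.ci_lower
            frame["ci_upper"] = self.ci_upper
        return frame


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate (events-first at tied times)."""
    records = list(records)
    if not records:
        raise InputError("no survival records")
    durations = np.array([r.time for r in records], dtype=float)
    observed = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table  # indexed by time, starts at t=0 row
    sf = kmf.survival_function_["KM_estimate"]
    ci = kmf.confidence_interval_
    times = np.asarray(table.index[table.index > 0], dtype=float)
    surv = np.array([float(sf.loc[t]) for t in times])
    at_risk = np.asarray(table.loc[times, "at_risk"], dtype=int)
    event_times = np.asarray(
        [t for t in times if table.loc[t, "observed"] > 0], dtype=float
    )
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=at_risk,
        event_times=event_times,
        ci_lower=np.array([float(ci.loc[t].iloc[0]) for t in times]),
        ci_upper=np.array([float(ci.loc[t].iloc[1]) for t in times]),
    )


def km_median(curve: KMCurve) -> Optional[float]:
    """Smallest event time t with S(t) <= 0.5; ``None`` when S never
    reaches 0.5 (median undefined, a typed outcome rather than an error)."""
    for t in curve.event_times:
        if curve.survival_at(t) <= 0.5 + 1e-12:
            return float(t)
    return None


def cooccurrence_rate(k: int, n: int) -> float:
    """100*k/n rounded half-up to one decimal (cohort proportion in %)."""
    if n < 1:
        raise InputError("denominator must be >= 1")
    if not 0 <= k <= n:
        raise InputError(f"need 0 <= k <= n, got k={k}, n={n}")
    pct = Decimal(100) * Decimal(k) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify_metabolic_response(suv_baseline: float, suv_followup: float) -> str:
    """PERCIST-style call: ``"response"`` iff SUVmax of the hottest lesion
    dropped by at least 30% (inclusive boundary) from baseline."""
    if suv_baseline <= 0:
        raise InputError("baseline SUVmax must be positive")
    if suv_followup < 0:
        raise InputError("follow-up SUVmax must be non-negative")
    reduction = (suv_baseline - suv_followup) / suv_baseline
    return "response" if reduction >= 0.30 - 1e-12 else "non_response"


def tumor_volume(length: float, width: float) -> float:
    """Caliper volume V = 0.5 * length * width^2 (mm^3).

    ``length`` is the longest dimension; swapped inputs are auto-corrected
    with a warning rather than silently producing the wrong ellipsoid.
    """
    if length < 0 or width < 0:
        raise InputError("dimensions must be non-negative")
    if width > length:
        warnings.warn(
            f"width ({width}) > length ({length}); dimensions swapped", stacklevel=2
        )
        length, width = width, length
    return 0.5 * length * width * width


def growth_rate(counts: Iterable[float], days: Optional[Sequence[float]] = None) -> float:
    """OLS slope of day-1-normalized cell counts against day index."""
    counts = np.asarray(list(counts), dtype=float)
    if counts.size < 3:
        raise InputError("need at least 3 time points")
    if counts[0] <= 0:
        raise InputError("day-1 count must be positive for normalization")
    y = counts / counts[0]
    x = np.asarray(days, dtype=float) if days is not None else np.arange(1, counts.size + 1.0)
    if x.size != y.size:
        raise InputError("days and counts length mismatch")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
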