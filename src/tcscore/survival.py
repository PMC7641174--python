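"""Ophthalmopathy-free survival: Kaplan-Meier curves and the log-rank test.

Patients predicted as progressors vs non-progressors are compared on time
(months) from sampling to confirmed ophthalmopathy; records without the
event are right-censored (default horizon 18 months).  Estimation and
testing delegate to lifelines; ties at an event time use the standard
hypergeometric variance, and censoring at an event time is processed
after the event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import DataError

DEFAULT_HORIZON_MONTHS = 18.0


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    group: str  # e.g. "predicted_GO" / "predicted_GH"
    time: float  # months > 0
    event: bool  # ophthalmopathy confirmed

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise DataError(f"follow-up time must be positive and finite, got {self.time}")


def _arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not records:
        raise DataError("no survival records")
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    return t, e


def km_estimate(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival estimate as a step table (time, survival).

    S(0) = 1 and the curve is right-continuous, stepping down at each
    event time.
    """
    t, e = _arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)})


def km_survival_at(km: pd.DataFrame, time: float) -> float:
    """Evaluate a KM step table at a time point (right-continuous)."""
    eligible = km.loc[km["time"] <= time, "survival"]
    return float(eligible.iloc[-1]) if len(eligible) else 1.0


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float


def logrank(group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]) -> LogrankResult:
    """Two-group log-rank test (chi-square with 1 dof)."""
    ta, ea = _arrays(group_a)
    tb, eb = _arrays(group_b)
    if int(ea.sum()) + int(eb.sum()) == 0:
        raise DataError("log-rank test undefined with zero events")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(chi2=float(res.test_statistic), p=float(res.p_value))


def split_by_group(records: Iterable[SurvivalRecord]) -> dict[str, list[SurvivalRecord]]:
    groups: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        groups.setdefault(r.group, []).append(r)
    return groups


def progression_time_summary(times: Sequence[float]) -> dict[str, float]:
    """Median and interquartile range of confirmed progression times."""
    if not len(times):
        raise DataError("no progression times")
    t = np.asarray(times, dtype=float)
    return {
        "median": float(np.median(t)),
        "q1": float(np.percentile(t, 25)),
        "q3": float(np.percentile(t, 75)),
    }


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group": [r.group for r in records],
            "time": [r.time for r in records],
            "event": [r.event for r in records],
        }
    )
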