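"""Median-split stratification, Kaplan-Meier estimation and the log-rank test.

Conventions: for even n the median is the midpoint of the two central order
statistics; samples exactly at the median go to the low stratum. At tied
times, events are processed before censorings (censored-at-t records remain
in the risk set for events at t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int  # 1 = event, 0 = censored
    stratum: str  # "high" / "low"

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValidationError(f"survival time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValidationError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray  # ascending distinct event times
    survival: np.ndarray  # S(t) at each event time, non-increasing
    at_risk: np.ndarray  # risk-set size just before each event time
    n_events: np.ndarray  # events at each time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def stratify_by_median(
    expression: Mapping[str, float] | pd.Series, gene: str | None = None
) -> dict[str, str]:
    """Split samples into high (> median) and low (<= median) strata."""
    series = pd.Series(dict(expression)) if not isinstance(expression, pd.Series) else expression
    if len(series) < 4:
        raise ValidationError("median stratification needs at least 4 samples")
    values = series.to_numpy(dtype=float)
    if np.all(values == values[0]):
        label = f" for {gene}" if gene else ""
        raise ValidationError(f"all expression values identical{label}; stratification is degenerate")
    median = float(np.median(values))
    return {sid: ("high" if v > median else "low") for sid, v in series.items()}


def _to_arrays(records: Sequence[SurvivalRecord]):
    time = np.array([r.time for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=int)
    return time, event


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate."""
    if not records:
        raise ValidationError("no survival records")
    time, event = _to_arrays(records)
    if np.any(time <= 0):
        raise ValidationError("survival times must be positive")
    event_times = np.unique(time[event == 1])
    survival = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    n_events = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_i = int((time >= t).sum())  # censored at t still at risk (events first)
        d_i = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d_i / n_i
        at_risk[i] = n_i
        n_events[i] = d_i
        survival[i] = s
    return KMCurve(event_times=event_times, survival=survival, at_risk=at_risk, n_events=n_events)


def logrank_test(records: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Two-group log-rank test over the record strata.

    Returns (chi-square statistic, p-value) with 1 degree of freedom:
    U = sum over event times of (O1 - E1), V the hypergeometric variances,
    statistic U^2 / V.
    """
    strata = sorted({r.stratum for r in records})
    if len(strata) != 2:
        raise ValidationError(f"log-rank needs exactly 2 strata, got {strata}")
    time, event = _to_arrays(records)
    group = np.array([r.stratum == strata[1] for r in records])
    return logrank_from_arrays(time, event, group)


def logrank_from_arrays(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    if group.all() or (~group).all():
        raise ValidationError("both strata must be non-empty")
    if event.sum() == 0:
        raise ValidationError("log-rank needs at least one event")
    event_times = np.unique(time[event == 1])
    U = 0.0
    V = 0.0
    for t in event_times:
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group).sum())
        dying = (time == t) & (event == 1)
        d = int(dying.sum())
        d1 = int((dying & group).sum())
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        raise ValidationError(
            "log-rank variance is zero (every event time exhausts one stratum's risk set); "
            "the test statistic is undefined"
        )
    statistic = U * U / V
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p
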