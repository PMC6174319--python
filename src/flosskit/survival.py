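"""Left-truncated product-limit estimation, log-rank testing, and RMST.

All estimation runs on the age scale with delayed entry: a record enters the
risk set at its entry age (e.g. its age in the study year) and leaves at its
exit age by death or censoring.  The risk set at age t comprises records with
entry < t <= exit, so deaths are processed before censorings at tied ages and
a death at the entry age itself contributes nothing (such zero-length records
are discarded with a warning).

The log-rank test uses the same truncation-aware risk sets, with the
tie-corrected hypergeometric variance, and refers the statistic to a
chi-square distribution with one degree of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConditioningError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject on the age scale: delayed entry, exit, and event flag."""

    entry_age: float
    exit_age: float
    event: bool
    group_label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.entry_age <= self.exit_age:
            raise ValueError(
                f"require 0 <= entry_age <= exit_age, got "
                f"({self.entry_age}, {self.exit_age})"
            )


@dataclass
class SurvivalCurve:
    """Right-continuous step estimate of survival on the age scale.

    ``ages`` holds the event ages only; the curve is 1 on
    [``start_age``, first event age).
    """

    ages: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    start_age: float
    group_label: str = ""

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=float)
        self.n_event = np.asarray(self.n_event, dtype=float)
        if self.ages.size:
            if np.any(np.diff(self.ages) <= 0):
                raise ValueError("event ages must be strictly increasing")
            if np.any(np.diff(self.survival) > 1e-12):
                raise ValueError("survival must be non-increasing")
            if self.survival.min() < -1e-12 or self.survival.max() > 1 + 1e-12:
                raise ValueError("survival must lie in [0, 1]")

    def evaluate(self, t) -> np.ndarray | float:
        """Step-function value S(t); 1 below the first event age."""
        t_arr = np.asarray(t, dtype=float)
        if self.ages.size == 0:
            out = np.ones_like(t_arr, dtype=float)
        else:
            idx = np.searchsorted(self.ages, t_arr, side="right") - 1
            out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "survival": self.survival,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
            }
        )


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def _as_arrays(
    records: Iterable[SurvivalRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    records = list(records)
    entry = np.array([r.entry_age for r in records], dtype=float)
    exit_ = np.array([r.exit_age for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=bool)
    return entry, exit_, event


def _risk_counts(
    entry: np.ndarray, exit_: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Number at risk (entry < t <= exit) at each time, via sorted counts."""
    se = np.sort(entry)
    sx = np.sort(exit_)
    return np.searchsorted(se, times, side="left") - np.searchsorted(
        sx, times, side="left"
    )


def km_from_arrays(
    entry: np.ndarray,
    exit_: np.ndarray,
    event: np.ndarray,
    group_label: str = "",
) -> SurvivalCurve:
    """Vectorized product-limit estimator with delayed entry."""
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    event = np.asarray(event, dtype=bool)
    if entry.size == 0:
        raise ValueError("no records")
    keep = exit_ > entry
    n_zero = int((~keep).sum())
    if n_zero:
        warnings.warn(
            f"discarding {n_zero} zero-length record(s) (exit == entry)",
            stacklevel=2,
        )
        entry, exit_, event = entry[keep], exit_[keep], event[keep]
        if entry.size == 0:
            raise ValueError("no records with exit_age > entry_age")
    start_age = float(entry.min())
    times, d = np.unique(exit_[event], return_counts=True)
    if times.size == 0:
        return SurvivalCurve(
            np.empty(0), np.empty(0), np.empty(0), np.empty(0), start_age, group_label
        )
    n = _risk_counts(entry, exit_, times)
    # an event at t implies its own record is at risk at t, so n >= 1 here
    surv = np.cumprod(1.0 - d / n)
    return SurvivalCurve(times, surv, n, d, start_age, group_label)


def km_left_truncated(records: Iterable[SurvivalRecord]) -> SurvivalCurve:
    """Product-limit estimate from :class:`SurvivalRecord` objects."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    entry, exit_, event = _as_arrays(records)
    labels = {r.group_label for r in records if r.group_label}
    label = labels.pop() if len(labels) == 1 else ""
    return km_from_arrays(entry, exit_, event, label)


def condition_curve(curve: SurvivalCurve, condition_age: float = 80.0) -> SurvivalCurve:
    """Rescale a curve by S(condition_age) and restrict to later ages."""
    s0 = curve.evaluate(condition_age)
    if s0 <= 0:
        raise ConditioningError(
            f"survival is 0 at conditioning age {condition_age}"
        )
    keep = curve.ages > condition_age
    return SurvivalCurve(
        curve.ages[keep],
        curve.survival[keep] / s0,
        curve.n_risk[keep],
        curve.n_event[keep],
        start_age=float(condition_age),
        group_label=curve.group_label,
    )


def logrank_from_arrays(
    entry_a: np.ndarray,
    exit_a: np.ndarray,
    event_a: np.ndarray,
    entry_b: np.ndarray,
    exit_b: np.ndarray,
    event_b: np.ndarray,
) -> LogRankResult:
    """Two-sample log-rank chi-square with truncation-aware risk sets."""
    entry_a, exit_a = np.asarray(entry_a, float), np.asarray(exit_a, float)
    entry_b, exit_b = np.asarray(entry_b, float), np.asarray(exit_b, float)
    event_a, event_b = np.asarray(event_a, bool), np.asarray(event_b, bool)
    if entry_a.size == 0 or entry_b.size == 0:
        raise ValueError("both groups must be non-empty")
    times = np.unique(np.concatenate([exit_a[event_a], exit_b[event_b]]))
    if times.size == 0:
        warnings.warn("no events in either group; log-rank undefined", stacklevel=2)
        return LogRankResult(0.0, 1, 1.0)
    na = _risk_counts(entry_a, exit_a, times)
    nb = _risk_counts(entry_b, exit_b, times)
    idx_a = np.searchsorted(times, exit_a[event_a])
    idx_b = np.searchsorted(times, exit_b[event_b])
    da = np.bincount(idx_a, minlength=times.size)
    db = np.bincount(idx_b, minlength=times.size)
    n = na + nb
    d = da + db
    ok = n > 0
    n, d, na, nb, da = n[ok], d[ok], na[ok], nb[ok], da[ok]
    expected_a = d * na / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(
            n > 1,
            d * (na / n) * (nb / n) * (n - d) / np.maximum(n - 1, 1),
            0.0,
        )
    observed_minus_expected = float((da - expected_a).sum())
    v = float(var.sum())
    if v <= 0:
        warnings.warn("log-rank variance is 0; returning statistic 0", stacklevel=2)
        return LogRankResult(0.0, 1, 1.0)
    stat = observed_minus_expected**2 / v
    return LogRankResult(stat, 1, float(stats.chi2.sf(stat, df=1)))


def logrank(
    records_a: Iterable[SurvivalRecord], records_b: Iterable[SurvivalRecord]
) -> LogRankResult:
    ea, xa, va = _as_arrays(records_a)
    eb, xb, vb = _as_arrays(records_b)
    return logrank_from_arrays(ea, xa, va, eb, xb, vb)


def rmst(curve: SurvivalCurve, from_age: float, to_age: float) -> float:
    """Restricted mean survival time: area under the step curve on a window.

    Beyond the last observed event the curve is carried forward flat, the
    product-limit convention.
    """
    if not from_age < to_age:
        raise ValueError("require from_age < to_age")
    if from_age < curve.start_age:
        raise ValueError(
            f"window start {from_age} precedes curve support "
            f"(start_age={curve.start_age})"
        )
    inner = curve.ages[(curve.ages > from_age) & (curve.ages < to_age)]
    xs = np.concatenate([[from_age], inner, [to_age]])
    vals = np.asarray(curve.evaluate(xs[:-1]), dtype=float)
    return float(np.sum(vals * np.diff(xs)))
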