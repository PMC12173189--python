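"""Strategy-comparison metrics and natural-history summaries.

Two simulated arms share one population: the unscreened arm diagnoses every
tumor at its natural symptomatic age, the screened arm after overlaying a
policy.  All strategy counts are restricted to detections at ages within the
policy's ``[start_age, end_age]`` window, in both arms; overdiagnosis is the
excess of screened-arm over unscreened-arm in-window diagnoses as a share of
the screened-arm count, ``Q = (N_scr - N_abs) / N_scr``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .screening import (
    DetectionOutcomes,
    ScreeningPolicy,
    MODE_SCREEN,
    MODE_INTERVAL,
    MODE_NONE,
)

__all__ = [
    "StrategyMetrics",
    "SizeDistribution",
    "SummaryStats",
    "overdiagnosis_pct",
    "percent_change",
    "strategy_metrics",
    "size_category_table",
    "doubling_time_days",
    "doubling_time_summary",
    "presence_time_summary",
    "age_summary",
    "summary_stats",
]

SIZE_BIN_LABELS = ("0-9 mm", "10-19 mm", "20-50 mm", ">50 mm")


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    n: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StrategyMetrics:
    n_no_screening: int
    n_screening: int
    pct_change: float
    pct_overdiagnosis: float
    pct_screen_detected: float
    pct_interval: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SizeDistribution:
    """Counts and percentages in the 0-9 / 10-19 / 20-50 / >50 mm bins."""

    counts: tuple
    percentages: tuple
    total: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size_bin": SIZE_BIN_LABELS, "count": self.counts, "pct": self.percentages}
        )


def overdiagnosis_pct(n_scr: int, n_abs: int) -> float:
    """Overdiagnosis ``100 (N_scr - N_abs) / N_scr``."""
    if n_scr <= 0:
        raise ValueError("screened-arm count must be positive")
    return 100.0 * (n_scr - n_abs) / n_scr


def percent_change(n_scr: int, n_abs: int) -> float:
    """Relative change in diagnoses ``100 (N_scr - N_abs) / N_abs``."""
    if n_abs <= 0:
        raise ValueError("unscreened-arm count must be positive")
    return 100.0 * (n_scr - n_abs) / n_abs


def in_window(out: DetectionOutcomes, policy: ScreeningPolicy) -> np.ndarray:
    """Detections at ages within the policy's evaluation window."""
    with np.errstate(invalid="ignore"):
        return (
            (out.mode != MODE_NONE)
            & (out.detection_age >= policy.start_age)
            & (out.detection_age <= policy.end_age)
        )


def strategy_metrics(
    no_screen: DetectionOutcomes,
    screened: DetectionOutcomes,
    policy: ScreeningPolicy,
) -> StrategyMetrics:
    """Table-shaped evaluation of one strategy on one shared population."""
    if no_screen.n != screened.n or not np.array_equal(
        no_screen.individual_id, screened.individual_id
    ):
        raise ValueError("arms must come from the same simulated population")
    win_abs = in_window(no_screen, policy)
    win_scr = in_window(screened, policy)
    n_abs = int(win_abs.sum())
    n_scr = int(win_scr.sum())
    n_screen_det = int((win_scr & (screened.mode == MODE_SCREEN)).sum())
    n_interval = int((win_scr & (screened.mode == MODE_INTERVAL)).sum())
    return StrategyMetrics(
        n_no_screening=n_abs,
        n_screening=n_scr,
        pct_change=percent_change(n_scr, n_abs),
        pct_overdiagnosis=overdiagnosis_pct(n_scr, n_abs),
        pct_screen_detected=100.0 * n_screen_det / n_scr,
        pct_interval=100.0 * n_interval / n_scr,
    )


def size_category_table(diameters) -> SizeDistribution:
    """Tabulate diameters (mm) into [0,10), [10,20), [20,50], (50, inf)."""
    d = np.asarray(diameters, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("no diameters to tabulate")
    if np.any(d < 0):
        raise ValueError("diameters must be nonnegative")
    counts = (
        int((d < 10).sum()),
        int(((d >= 10) & (d < 20)).sum()),
        int(((d >= 20) & (d <= 50)).sum()),
        int((d > 50).sum()),
    )
    total = d.size
    return SizeDistribution(
        counts=counts,
        percentages=tuple(100.0 * c / total for c in counts),
        total=total,
    )


def doubling_time_days(r):
    """Tumor volume doubling time in days, ``365 ln(2) r``."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("inverse growth rate must be positive")
    out = 365.0 * np.log(2.0) * r
    return out if out.ndim else float(out)


def summary_stats(x) -> SummaryStats:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return SummaryStats(
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        n=int(x.size),
    )


def doubling_time_summary(hist, out: DetectionOutcomes, restrict=None) -> dict:
    """Doubling-time summaries stratified by detection mode.

    Returns ``{"screen_detected": SummaryStats, "interval": SummaryStats}``;
    ``restrict`` optionally masks cases (e.g. to the policy window).
    """
    res = {}
    for label, code in (("screen_detected", MODE_SCREEN), ("interval", MODE_INTERVAL)):
        mask = out.mode == code
        if restrict is not None:
            mask &= restrict
        if mask.any():
            res[label] = summary_stats(doubling_time_days(hist.inv_growth_rate[mask]))
    return res


def presence_time_summary(hist, out: DetectionOutcomes, restrict=None) -> SummaryStats:
    """Tumor presence time (onset to symptomatic detectability) of interval cancers."""
    mask = out.mode == MODE_INTERVAL
    if restrict is not None:
        mask &= restrict
    if not mask.any():
        raise ValueError("no interval cancers present")
    return summary_stats(hist.symptomatic_age[mask] - hist.onset_age[mask])


def age_summary(out: DetectionOutcomes, restrict=None) -> SummaryStats:
    """Detection-age summary of one arm (optionally masked to a window)."""
    mask = out.detected
    if restrict is not None:
        mask &= restrict
    return summary_stats(out.detection_age[mask])
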