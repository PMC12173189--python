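"""Screening-policy overlay: schedules, attendance, sensitivity, detection mode.

A policy screens every ``interval`` years from ``start_age`` while scheduled
ages stay within ``end_age``.  At each attended screen the probability of
detecting an existing tumor of diameter d is logistic,
``expit(beta0 + beta1 * d)``, drawn independently per screen.  Walking the
schedule in order, the first successful screen wins; otherwise the tumor
surfaces at its natural symptomatic age.  A symptomatic case that follows at
least one attended, negative screen and precedes the next scheduled screen
(or the program's end, when the last attended screen had no successor) is an
interval cancer; all other symptomatic cases are "other symptomatic".
Screening never delays detection: a screen can only pre-empt the natural
symptomatic age, never move it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .natural_history import NaturalHistory, substream, diameter_from_volume

__all__ = [
    "ScreeningPolicy",
    "SensitivityParams",
    "AttendanceModel",
    "DetectionOutcomes",
    "MODE_NONE",
    "MODE_SCREEN",
    "MODE_INTERVAL",
    "MODE_SYMPTOMATIC",
    "MODE_LABELS",
    "SENSITIVITY_SCENARIOS",
    "screening_schedule",
    "screen_sensitivity",
    "assign_attendance",
    "apply_screening",
    "natural_history_outcomes",
]

MODE_NONE = 0
MODE_SCREEN = 1
MODE_INTERVAL = 2
MODE_SYMPTOMATIC = 3
MODE_LABELS = {
    MODE_NONE: "none",
    MODE_SCREEN: "screen_detected",
    MODE_INTERVAL: "interval",
    MODE_SYMPTOMATIC: "other_symptomatic",
}

#: logistic size-sensitivity parameter pairs (beta0, beta1 per mm).
SENSITIVITY_SCENARIOS = {
    "low": (-5.45, 0.48),
    "moderate": (-5.04, 0.56),
    "high": (-4.67, 0.65),
}


@dataclass(frozen=True)
class ScreeningPolicy:
    start_age: float
    end_age: float
    interval: float

    def __post_init__(self) -> None:
        if not (self.start_age < self.end_age):
            raise ValueError("start_age must be below end_age")
        if not (self.interval > 0):
            raise ValueError("interval must be positive")


@dataclass(frozen=True)
class SensitivityParams:
    """Logistic screening sensitivity: ``P(detect | d) = expit(beta0 + beta1 d)``."""

    beta0: float
    beta1: float
    scenario_label: str = "custom"

    def __post_init__(self) -> None:
        if not (self.beta1 > 0):
            raise ValueError("beta1 must be positive (detection improves with size)")

    @classmethod
    def from_scenario(cls, label: str, perturb_pct: float = 0.0) -> "SensitivityParams":
        """Named scenario, optionally with both parameters perturbed by ±pct/100."""
        try:
            b0, b1 = SENSITIVITY_SCENARIOS[label]
        except KeyError:
            raise ValueError(
                f"unknown sensitivity scenario {label!r}; "
                f"choose from {sorted(SENSITIVITY_SCENARIOS)}"
            ) from None
        f = 1.0 + perturb_pct / 100.0
        return cls(beta0=b0 * f, beta1=b1 * f, scenario_label=label)

    @property
    def half_detection_diameter(self) -> float:
        """Diameter (mm) at which the detection probability is 0.5."""
        return -self.beta0 / self.beta1


@dataclass(frozen=True)
class AttendanceModel:
    """Two-type attendance mixture (or the perfect / none limits).

    Under ``imperfect`` attendance each woman is permanently typed regular
    (probability ``regular_fraction``) or irregular, and then attends each
    scheduled screen independently with probability ``p_regular`` or
    ``p_irregular`` respectively.
    """

    mode: str = "imperfect"
    regular_fraction: float = 0.80
    p_regular: float = 0.90
    p_irregular: float = 0.15

    def __post_init__(self) -> None:
        if self.mode not in ("perfect", "imperfect", "none"):
            raise ValueError(f"unknown attendance mode {self.mode!r}")
        for p in (self.regular_fraction, self.p_regular, self.p_irregular):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class DetectionOutcomes:
    """Per-individual detection result after overlaying one screening policy."""

    individual_id: np.ndarray
    mode: np.ndarray  # int8 codes, see MODE_LABELS
    detection_age: np.ndarray
    detection_diameter: np.ndarray
    n_attended_negative_screens: np.ndarray
    policy: Optional[ScreeningPolicy]
    seed: int

    @property
    def n(self) -> int:
        return self.individual_id.size

    @property
    def detected(self) -> np.ndarray:
        return self.mode != MODE_NONE

    def mode_labels(self) -> np.ndarray:
        return np.array([MODE_LABELS[m] for m in self.mode])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "mode": self.mode_labels(),
                "detection_age": self.detection_age,
                "detection_diameter_mm": self.detection_diameter,
                "n_attended_negative_screens": self.n_attended_negative_screens,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def screening_schedule(p: ScreeningPolicy) -> np.ndarray:
    """Scheduled screen ages: start, start+interval, ... while <= end_age."""
    n_screens = int(np.floor((p.end_age - p.start_age) / p.interval + 1e-9)) + 1
    return p.start_age + p.interval * np.arange(n_screens)


def screen_sensitivity(d, s: SensitivityParams):
    """Probability that a screen detects an existing tumor of diameter ``d`` mm."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be nonnegative")
    out = expit(s.beta0 + s.beta1 * d)
    return out if out.ndim else float(out)


def assign_attendance(
    n: int, am: AttendanceModel, schedule: np.ndarray, rng_type, rng_screens=None
) -> np.ndarray:
    """Boolean (n, n_screens) attendance indicators.

    ``rng_type`` draws the permanent regular/irregular type, ``rng_screens``
    (defaults to ``rng_type``) the per-screen attendance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = len(schedule)
    if am.mode == "perfect":
        return np.ones((n, k), dtype=bool)
    if am.mode == "none":
        return np.zeros((n, k), dtype=bool)
    rng_screens = rng_type if rng_screens is None else rng_screens
    regular = rng_type.random(n) < am.regular_fraction
    p = np.where(regular, am.p_regular, am.p_irregular)
    return rng_screens.random((n, k)) < p[:, None]


def apply_screening(
    hist: NaturalHistory,
    policy: ScreeningPolicy,
    sens: SensitivityParams,
    attendance: AttendanceModel,
    seed: Optional[int] = None,
) -> DetectionOutcomes:
    """Overlay a screening policy on a simulated natural history.

    ``seed`` defaults to the history's master seed, so that every policy
    overlaid on the same history shares attendance-type and sensitivity
    substreams (common random numbers).  At a screen age exactly equal to the
    symptomatic age, symptomatic detection wins.
    """
    seed = hist.seed if seed is None else int(seed)
    sched = screening_schedule(policy)
    n = hist.n
    v0 = hist.v0

    att = assign_attendance(
        n, attendance, sched, substream(seed, "attendance_type"), substream(seed, "attendance")
    )
    u_sens = substream(seed, "sensitivity").random((n, len(sched)))

    onset = hist.onset_age
    U = hist.symptomatic_age
    r = hist.inv_growth_rate
    has = hist.has_onset

    mode = np.zeros(n, dtype=np.int8)
    det_age = np.full(n, np.nan)
    det_diam = np.full(n, np.nan)
    n_neg = np.zeros(n, dtype=np.int32)
    last_neg = np.full(n, np.nan)
    screen_detected = np.zeros(n, dtype=bool)

    for j, x in enumerate(sched):
        attended = att[:, j]
        # a screen before the symptomatic age is negative unless it detects
        undetected = attended & ~screen_detected & (np.isnan(U) | (U > x))
        present = undetected & has & (onset <= x) & (U > x)
        if present.any():
            grow = np.clip((x - onset[present]) / r[present], None, 60.0)
            diam = diameter_from_volume(v0 * np.exp(grow))
            p = screen_sensitivity(diam, sens)
            hit = u_sens[present, j] < p
            idx = np.nonzero(present)[0][hit]
            screen_detected[idx] = True
            mode[idx] = MODE_SCREEN
            det_age[idx] = x
            det_diam[idx] = diam[hit]
        negative = undetected & ~screen_detected
        n_neg[negative] += 1
        last_neg[negative] = x

    # symptomatic detection for everyone a screen did not pre-empt
    sym = has & ~screen_detected & (U <= hist.max_follow_up_age)
    mode[sym] = MODE_SYMPTOMATIC
    det_age[sym] = U[sym]
    det_diam[sym] = hist.symptomatic_diameter[sym]

    # interval cancers: symptomatic after >= 1 attended negative screen and
    # before the next scheduled screen (program end when none remains)
    with np.errstate(invalid="ignore"):
        next_screen = last_neg + policy.interval
        bound = np.where(next_screen <= sched[-1] + 1e-9, next_screen, policy.end_age)
        is_interval = sym & ~np.isnan(last_neg) & (
            (U < bound) | ((next_screen > sched[-1] + 1e-9) & (U <= policy.end_age))
        )
    mode[is_interval] = MODE_INTERVAL

    return DetectionOutcomes(
        individual_id=hist.individual_id.copy(),
        mode=mode,
        detection_age=det_age,
        detection_diameter=det_diam,
        n_attended_negative_screens=n_neg,
        policy=policy,
        seed=seed,
    )


def natural_history_outcomes(hist: NaturalHistory) -> DetectionOutcomes:
    """The unscreened arm: every diagnosis is symptomatic at its natural age."""
    sym = hist.diagnosed
    mode = np.where(sym, MODE_SYMPTOMATIC, MODE_NONE).astype(np.int8)
    return DetectionOutcomes(
        individual_id=hist.individual_id.copy(),
        mode=mode,
        detection_age=np.where(sym, hist.symptomatic_age, np.nan),
        detection_diameter=np.where(sym, hist.symptomatic_diameter, np.nan),
        n_attended_negative_screens=np.zeros(hist.n, dtype=np.int32),
        policy=None,
        seed=hist.seed,
    )
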