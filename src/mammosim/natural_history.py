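"""Tumor onset, growth and symptomatic detection: the no-screening natural history.

The disease model has three coupled sub-models:

* **Onset** — the age at which a tumor reaches the 0.5 mm "onset" diameter is
  governed by a two-stage (Moolgavkar–Venzon–Knudson) clonal-expansion model,
  summarised by three reduced parameters ``A < 0``, ``B > 0`` and ``delta > 0``.
  Onset ages are sampled on a discrete grid of candidate ages and adjusted to
  the target population by an incidence ratio (here 0.48, West Africa vs
  Northern Europe).
* **Growth** — after onset the tumor volume grows exponentially,
  ``V(x) = v0 * exp((x - t) / r)``, where the inverse growth rate ``r`` (years)
  varies between women according to a gamma distribution with shape ``a`` and
  rate ``b``; the tumor volume doubling time is ``ln(2) * r``.
* **Symptomatic detection** — symptoms surface with a hazard proportional to
  the current tumor volume (rate ``eta`` per mm^3 per year), which makes the
  volume at symptomatic detection, in excess of the onset volume, exponential
  with rate ``eta * r`` given ``r``.

All tumors are spherical, so diameter d (mm) and volume v (mm^3) are linked by
``v = pi d^3 / 6``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "OnsetModel",
    "GrowthModel",
    "DetectionModel",
    "CohortSpec",
    "NaturalHistory",
    "onset_survival",
    "onset_hazard",
    "onset_density",
    "mvk_params_from_rates",
    "onset_weights",
    "sample_onset",
    "sample_inverse_growth_rate",
    "tumor_volume_at_age",
    "diameter_from_volume",
    "volume_from_diameter",
    "sample_symptomatic_volume",
    "time_to_symptomatic",
    "simulate_natural_history",
    "substream",
]

#: indices of the named random substreams derived from the master seed.  One
#: stream per stochastic sub-process so that overlaying different screening
#: policies on the same master seed reuses an identical natural history
#: (common random numbers across arms).
STREAMS = {
    "onset": 0,
    "growth": 1,
    "symptomatic": 2,
    "attendance_type": 3,
    "attendance": 4,
    "sensitivity": 5,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named random substream derived from the master ``seed``."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(STREAMS[name],))
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OnsetModel:
    """Reduced two-stage clonal-expansion onset model.

    Parameters
    ----------
    A, B, delta
        Reduced model parameters; ``A < 0``, ``B > 0``, ``delta > 0``.
    age_grid
        Strictly increasing candidate onset ages (years).
    age_scale
        Population incidence adjustment in (0, 1].  With
        ``adjustment="age_scaling"`` a sampled grid age is multiplied by this
        factor; with ``"thinning"`` the per-age onset probabilities are
        multiplied instead and ages are left unchanged.
    no_onset_allowed
        If True (default) the residual probability mass is an explicit
        "never develops a tumor" category.
    """

    A: float = -0.0722
    B: float = 1.18e-3
    delta: float = 0.0952
    age_grid: np.ndarray = field(
        default_factory=lambda: np.arange(38, 93, dtype=float)
    )
    age_scale: float = 0.48
    adjustment: str = "age_scaling"
    no_onset_allowed: bool = True

    def __post_init__(self) -> None:
        if not (self.A < 0):
            raise ValueError(f"A must be negative, got {self.A}")
        if not (self.B > 0):
            raise ValueError(f"B must be positive, got {self.B}")
        if not (self.delta > 0):
            raise ValueError(f"delta must be positive, got {self.delta}")
        if not (0 < self.age_scale <= 1):
            raise ValueError(f"age_scale must be in (0, 1], got {self.age_scale}")
        grid = np.asarray(self.age_grid, dtype=float)
        if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("age_grid must be a non-empty strictly increasing 1-d array")
        object.__setattr__(self, "age_grid", grid)
        if self.adjustment not in ("age_scaling", "thinning"):
            raise ValueError(f"unknown adjustment {self.adjustment!r}")


@dataclass(frozen=True)
class GrowthModel:
    """Gamma law of the inverse growth rate r (shape ``a``, rate ``b``)."""

    a: float = 0.8162
    b: float = 0.8162
    constrain_equal: bool = True

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("gamma parameters must be positive")
        if self.constrain_equal and self.a != self.b:
            raise ValueError("constrain_equal requires a == b")

    @property
    def mean(self) -> float:
        return self.a / self.b


@dataclass(frozen=True)
class DetectionModel:
    """Symptomatic-detection hazard, proportional to tumor volume.

    ``eta`` is the hazard per mm^3 of tumor volume per year; ``d0`` is the
    onset diameter (mm), fixing the onset volume ``v0 = pi d0^3 / 6``.
    ``max_diameter`` optionally truncates the symptomatic-size distribution
    (no truncation by default).
    """

    eta: float = float(np.exp(-9.644))
    d0: float = 0.5
    max_diameter: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.eta > 0):
            raise ValueError("eta must be positive")
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if self.max_diameter is not None and self.max_diameter <= self.d0:
            raise ValueError("max_diameter must exceed the onset diameter")

    @property
    def v0(self) -> float:
        """Tumor volume at onset (mm^3)."""
        return volume_from_diameter(self.d0)


@dataclass(frozen=True)
class CohortSpec:
    """Size and labelling of the simulated multi-cohort population."""

    births_per_cohort: int = 5000
    n_cohorts: int = 35
    first_cohort_year: int = 1985
    max_follow_up_age: float = 100.0

    def __post_init__(self) -> None:
        if self.births_per_cohort <= 0 or self.n_cohorts <= 0:
            raise ValueError("cohort counts must be positive")
        if self.max_follow_up_age <= 0:
            raise ValueError("max_follow_up_age must be positive")

    @property
    def n_individuals(self) -> int:
        return self.births_per_cohort * self.n_cohorts


# ---------------------------------------------------------------------------
# Onset model functions
# ---------------------------------------------------------------------------


def onset_survival(t, m: OnsetModel):
    """Probability that tumor onset has not occurred by age ``t``.

    ``G(t) = [(B - A) e^{B t} / (B e^{(B - A) t} - A)]^delta``.
    """
    t = _check_age(t)
    A, B, d = m.A, m.B, m.delta
    return ((B - A) * np.exp(B * t) / (B * np.exp((B - A) * t) - A)) ** d


def onset_hazard(t, m: OnsetModel):
    """Age-specific onset hazard (per year).

    ``h(t) = delta A B (1 - e^{(B - A) t}) / (B e^{(B - A) t} - A)``;
    nonnegative for A < 0, B > 0.
    """
    t = _check_age(t)
    A, B, d = m.A, m.B, m.delta
    return d * A * B * (1.0 - np.exp((B - A) * t)) / (B * np.exp((B - A) * t) - A)


def onset_density(t, m: OnsetModel):
    """Onset age density ``f(t) = -dG/dt = h(t) G(t)`` (per year)."""
    t = _check_age(t)
    A, B, d = m.A, m.B, m.delta
    e = np.exp((B - A) * t)
    return d * A * B * (B - A) ** d * np.exp(d * B * t) * (1.0 - e) / (B * e - A) ** (d + 1)


def _check_age(t):
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("age must be finite")
    if np.any(t < 0):
        raise ValueError("age must be nonnegative")
    return t if t.ndim else float(t)


def mvk_params_from_rates(alpha: float, nu: float, beta: float, mu: float):
    """Map the four Poisson event rates of the two-stage model to (A, B, delta).

    ``alpha`` cell division, ``nu`` first mutation, ``beta`` cell death,
    ``mu`` second mutation (all >= 0, ``alpha > 0``).  A and B are the two
    roots of ``z^2 - (beta + mu - alpha) z - alpha mu``, assigned so that
    ``A <= 0 <= B``; ``delta = nu / alpha``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if min(nu, beta, mu) < 0:
        raise ValueError("rates must be nonnegative")
    s = beta + mu - alpha
    disc = s * s + 4.0 * alpha * mu
    if disc < 0:  # unreachable for nonnegative rates; guard for generality
        raise ValueError("negative discriminant")
    root = float(np.sqrt(disc))
    A = 0.5 * (s - root)
    B = 0.5 * (s + root)
    return A, B, nu / alpha


def onset_weights(m: OnsetModel):
    """Per-age onset probabilities on the grid and the no-onset mass.

    Returns ``(ages, weights, p_no_onset)``.  Under the thinning adjustment
    the weights are scaled by ``age_scale``; under age scaling they are the
    raw density values (the scaling is applied to the sampled age instead).
    """
    w = onset_density(m.age_grid, m)
    if m.adjustment == "thinning":
        w = w * m.age_scale
    total = float(w.sum())
    if total > 1.0:
        raise ValueError(
            f"onset probabilities sum to {total:.4f} > 1; shrink the grid or parameters"
        )
    return m.age_grid, w, 1.0 - total


def sample_onset(n: int, m: OnsetModel, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` onset ages; NaN marks individuals who never develop a tumor.

    Each grid age ``t`` carries probability mass ``f(t)`` (thinned by
    ``age_scale`` under the thinning adjustment); the residual mass is the
    no-onset category.  Sampled integer ages are jittered uniformly within
    the year so downstream ages are continuous, then multiplied by
    ``age_scale`` under the age-scaling adjustment.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ages, w, p_none = onset_weights(m)
    p = np.append(w, p_none)
    cat = rng.choice(p.size, size=n, p=p)
    out = np.full(n, np.nan)
    has = cat < ages.size
    jittered = ages[cat[has]] + rng.random(int(has.sum()))
    if m.adjustment == "age_scaling":
        jittered = jittered * m.age_scale
    out[has] = jittered
    return out


# ---------------------------------------------------------------------------
# Growth and symptomatic detection
# ---------------------------------------------------------------------------


def sample_inverse_growth_rate(n: int, g: GrowthModel, rng: np.random.Generator) -> np.ndarray:
    """Draw inverse growth rates r from Gamma(shape ``a``, rate ``b``)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.gamma(shape=g.a, scale=1.0 / g.b, size=n)


def tumor_volume_at_age(x, t, r, v0):
    """Latent tumor volume ``v0 exp((x - t)/r)`` at age ``x`` given onset at ``t``."""
    x, t, r = np.asarray(x, float), np.asarray(t, float), np.asarray(r, float)
    if np.any(x < t):
        raise ValueError("age x must be >= onset age t")
    if np.any(r <= 0):
        raise ValueError("inverse growth rate must be positive")
    return v0 * np.exp((x - t) / r)


def diameter_from_volume(v):
    """Diameter (mm) of a sphere of volume ``v`` (mm^3)."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    out = np.cbrt(6.0 * v / np.pi)
    return out if out.ndim else float(out)


def volume_from_diameter(d):
    """Volume (mm^3) of a sphere of diameter ``d`` (mm)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    out = np.pi * d**3 / 6.0
    return out if out.ndim else float(out)


def sample_symptomatic_volume(r, dm: DetectionModel, u):
    """Invert a uniform variate into the volume at symptomatic detection.

    ``V = v0 - ln(1 - u) / (eta r)``: given ``r``, the excess volume
    ``V - v0`` is exponential with rate ``eta r``.
    """
    r = np.asarray(r, dtype=float)
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("u must lie in [0, 1)")
    if np.any(r <= 0):
        raise ValueError("inverse growth rate must be positive")
    out = dm.v0 - np.log1p(-u) / (dm.eta * r)
    return out if out.ndim else float(out)


def time_to_symptomatic(V, r, v0):
    """Years from onset to symptomatic detection: ``r ln(V / v0)``."""
    V = np.asarray(V, dtype=float)
    if np.any(V < v0):
        raise ValueError("symptomatic volume cannot be below the onset volume")
    out = np.asarray(r, dtype=float) * np.log(V / v0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


@dataclass
class NaturalHistory:
    """Array-backed latent disease courses of one simulated population.

    Individuals without onset carry NaN in every disease field.  Ages are in
    years, volumes in mm^3, diameters in mm.
    """

    individual_id: np.ndarray
    cohort_year: np.ndarray
    onset_age: np.ndarray
    inv_growth_rate: np.ndarray
    symptomatic_volume: np.ndarray
    symptomatic_diameter: np.ndarray
    symptomatic_age: np.ndarray
    max_follow_up_age: float
    seed: int
    v0: float = float(np.pi * 0.5**3 / 6.0)

    @property
    def n(self) -> int:
        return self.individual_id.size

    @property
    def has_onset(self) -> np.ndarray:
        return ~np.isnan(self.onset_age)

    @property
    def diagnosed(self) -> np.ndarray:
        """Symptomatic detection occurs within the follow-up horizon."""
        return self.has_onset & (self.symptomatic_age <= self.max_follow_up_age)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "cohort_year": self.cohort_year,
                "onset_age": self.onset_age,
                "inv_growth_rate": self.inv_growth_rate,
                "symptomatic_age": self.symptomatic_age,
                "symptomatic_diameter_mm": self.symptomatic_diameter,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_natural_history(
    spec: CohortSpec,
    onset: OnsetModel,
    growth: GrowthModel,
    det: DetectionModel,
    seed: int,
) -> NaturalHistory:
    """Simulate the latent no-screening disease course of a full population.

    Each of ``spec.n_individuals`` independent women gets an onset age (or
    none); women with onset get an inverse growth rate, a symptomatic volume
    via a fresh uniform variate (truncated at ``det.max_diameter`` when set,
    via the inverse CDF), the corresponding diameter, and a symptomatic age
    ``onset + r ln(V / v0)``.  Reproducible from ``seed``; each sub-process
    consumes its own named substream.
    """
    n = spec.n_individuals
    onset_age = sample_onset(n, onset, substream(seed, "onset"))
    has = ~np.isnan(onset_age)
    m = int(has.sum())

    r = np.full(n, np.nan)
    V = np.full(n, np.nan)
    if m:
        r[has] = sample_inverse_growth_rate(m, growth, substream(seed, "growth"))
        u = substream(seed, "symptomatic").random(m)
        if det.max_diameter is not None:
            vmax = volume_from_diameter(det.max_diameter)
            u = u * -np.expm1(-det.eta * r[has] * (vmax - det.v0))
        V[has] = sample_symptomatic_volume(r[has], det, u)

    d = np.full(n, np.nan)
    U = np.full(n, np.nan)
    if m:
        d[has] = diameter_from_volume(V[has])
        U[has] = onset_age[has] + time_to_symptomatic(V[has], r[has], det.v0)

    cohort = spec.first_cohort_year + np.arange(n) // spec.births_per_cohort
    return NaturalHistory(
        individual_id=np.arange(n, dtype=np.int64),
        cohort_year=cohort.astype(np.int32),
        onset_age=onset_age,
        inv_growth_rate=r,
        symptomatic_volume=V,
        symptomatic_diameter=d,
        symptomatic_age=U,
        max_follow_up_age=spec.max_follow_up_age,
        seed=int(seed),
        v0=det.v0,
    )
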