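"""Clinical-style tumor-size data with the structure the estimation step assumes.

The study's real tumor-size records are not deposited, so this module is the
package's stand-in data source: per case it draws an inverse growth rate from
the gamma law, a symptomatic volume whose excess over the onset volume is
exponential with rate ``eta * r``, and converts to a diameter — i.e. it
samples exactly the Lomax-type marginal the likelihood is built on.  Optional
0.5 mm rounding mimics how histology reports sizes; an optional maximum
diameter truncates the tail.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .estimation import TumorSizeData, fit_mle
from .natural_history import (
    DetectionModel,
    GrowthModel,
    diameter_from_volume,
    sample_inverse_growth_rate,
    sample_symptomatic_volume,
    volume_from_diameter,
)

__all__ = ["GeneratorSpec", "generate_clinical_dataset", "parameter_recovery_experiment"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic clinical dataset.

    Defaults are the fitted values of the reference analysis: 187 cases,
    ``eta = 6.481e-5`` per mm^3-year, ``a = b = 0.8162``, onset diameter
    0.5 mm, no rounding and no maximum size.
    """

    n_cases: int = 187
    eta: float = 6.481e-5
    a: float = 0.8162
    b: float = 0.8162
    d0: float = 0.5
    rounding: Optional[float] = None  # e.g. 0.5 for half-millimetre increments
    max_diameter: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if min(self.eta, self.a, self.b, self.d0) <= 0:
            raise ValueError("model parameters must be positive")
        if self.rounding is not None and self.rounding <= 0:
            raise ValueError("rounding increment must be positive")


def generate_clinical_dataset(spec: GeneratorSpec) -> TumorSizeData:
    """Draw one dataset of symptomatically detected tumor diameters (mm)."""
    rng = np.random.default_rng(spec.seed)
    growth = GrowthModel(a=spec.a, b=spec.b, constrain_equal=spec.a == spec.b)
    det = DetectionModel(eta=spec.eta, d0=spec.d0, max_diameter=spec.max_diameter)
    r = sample_inverse_growth_rate(spec.n_cases, growth, rng)
    u = rng.random(spec.n_cases)
    if spec.max_diameter is not None:
        vmax = volume_from_diameter(spec.max_diameter)
        u = u * -np.expm1(-det.eta * r * (vmax - det.v0))
    d = diameter_from_volume(sample_symptomatic_volume(r, det, u))
    if spec.rounding is not None:
        # nearest increment, floored one increment above the onset diameter so
        # rounded sizes stay inside the likelihood's support
        d = np.round(d / spec.rounding) * spec.rounding
        d = np.maximum(d, np.floor(spec.d0 / spec.rounding + 1.0) * spec.rounding)
    return TumorSizeData(diameters=d)


def parameter_recovery_experiment(
    spec: GeneratorSpec,
    n_replicates: int,
    z_multiplier: float = 1.96,
) -> pd.DataFrame:
    """Generate-and-fit repeatedly; report bias, RMSE and CI coverage.

    Returns one row per parameter (eta, b) with the generating truth, mean
    estimate, bias, RMSE, empirical SD of the estimates, mean asymptotic SE,
    and the fraction of ``z_multiplier`` intervals covering the truth.  Fit
    failures are counted, not fatal.
    """
    if n_replicates < 2:
        raise ValueError("need at least two replicates")
    truth = {"eta": spec.eta, "b": spec.b}
    est = {k: [] for k in truth}
    ses = {k: [] for k in truth}
    cover = {k: [] for k in truth}
    n_failed = 0
    base = np.random.SeedSequence(spec.seed)
    for child in base.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        data = generate_clinical_dataset(
            GeneratorSpec(
                n_cases=spec.n_cases, eta=spec.eta, a=spec.a, b=spec.b, d0=spec.d0,
                rounding=spec.rounding, max_diameter=spec.max_diameter, seed=rep_seed,
            )
        )
        fit = fit_mle(data, constrain_equal=True, z_multiplier=z_multiplier)
        if not fit.converged:
            n_failed += 1
            continue
        values = {"eta": fit.eta_hat, "b": fit.b_hat}
        for k in truth:
            est[k].append(values[k])
            ses[k].append(fit.se.get(k, np.nan))
            lo, hi = fit.ci.get(k, (np.nan, np.nan))
            cover[k].append(lo <= truth[k] <= hi)
    rows = []
    for k, t in truth.items():
        e = np.asarray(est[k])
        rows.append(
            {
                "parameter": k,
                "truth": t,
                "n_fits": e.size,
                "n_failed": n_failed,
                "mean_estimate": e.mean() if e.size else np.nan,
                "bias": e.mean() - t if e.size else np.nan,
                "rmse": float(np.sqrt(np.mean((e - t) ** 2))) if e.size else np.nan,
                "sd_estimate": e.std(ddof=1) if e.size > 1 else np.nan,
                "mean_se": float(np.nanmean(ses[k])) if e.size else np.nan,
                "ci_coverage": float(np.mean(cover[k])) if e.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
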