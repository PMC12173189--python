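import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mammosim import (
    CohortSpec,
    DetectionModel,
    GrowthModel,
    OnsetModel,
    simulate_natural_history,
    natural_history_outcomes,
)

#: master seed for the shared study-size population fixture
MASTER_SEED = 20260921


@pytest.fixture(scope="session")
def default_models():
    return OnsetModel(), GrowthModel(), DetectionModel()


@pytest.fixture(scope="session")
def hist_default(default_models):
    """The study-size population: 5000 births x 35 cohorts, default models."""
    onset, growth, det = default_models
    return simulate_natural_history(CohortSpec(), onset, growth, det, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def no_screen_default(hist_default):
    return natural_history_outcomes(hist_default)


def make_history(onset_age, inv_growth_rate, symptomatic_volume, seed=0, follow_up=100.0):
    """Hand-built NaturalHistory for targeted unit tests."""
    from mammosim.natural_history import NaturalHistory, DetectionModel

    v0 = DetectionModel().v0
    onset_age = np.asarray(onset_age, dtype=float)
    r = np.asarray(inv_growth_rate, dtype=float)
    V = np.asarray(symptomatic_volume, dtype=float)
    n = onset_age.size
    U = onset_age + r * np.log(V / v0)
    return NaturalHistory(
        individual_id=np.arange(n, dtype=np.int64),
        cohort_year=np.full(n, 1985, dtype=np.int32),
        onset_age=onset_age,
        inv_growth_rate=r,
        symptomatic_volume=V,
        symptomatic_diameter=np.cbrt(6 * V / np.pi),
        symptomatic_age=U,
        max_follow_up_age=follow_up,
        seed=seed,
        v0=v0,
    )
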