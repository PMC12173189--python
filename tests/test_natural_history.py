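"""Onset, growth and symptomatic-detection model units and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mammosim import (
    CohortSpec,
    DetectionModel,
    GrowthModel,
    OnsetModel,
    diameter_from_volume,
    mvk_params_from_rates,
    onset_density,
    onset_hazard,
    onset_survival,
    sample_inverse_growth_rate,
    sample_onset,
    sample_symptomatic_volume,
    simulate_natural_history,
    time_to_symptomatic,
    tumor_volume_at_age,
    volume_from_diameter,
)
from mammosim.natural_history import onset_weights


@pytest.fixture(scope="module")
def om():
    return OnsetModel()


class TestOnsetFunctions:
    def test_survival_at_zero_is_one(self, om):
        assert onset_survival(0.0, om) == pytest.approx(1.0, abs=1e-15)

    def test_survival_matches_direct_transcription(self, om):
        # independent one-line transcription of the closed form
        A, B, d, t = om.A, om.B, om.delta, 50.0
        direct = ((B - A) * np.exp(B * t) / (B * np.exp((B - A) * t) - A)) ** d
        assert onset_survival(t, om) == pytest.approx(direct, rel=1e-12)

    def test_survival_nonincreasing(self, om):
        t = np.linspace(0, 92, 500)
        G = onset_survival(t, om)
        assert np.all(np.diff(G) <= 0)
        assert onset_survival(60.0, om) < onset_survival(40.0, om)
        assert np.all((G > 0) & (G <= 1))

    def test_hazard_zero_at_birth_and_nonnegative(self, om):
        assert onset_hazard(0.0, om) == 0.0
        assert np.all(onset_hazard(np.linspace(0, 92, 500), om) >= 0)

    def test_hazard_is_negative_log_derivative_of_survival(self, om):
        h = 1e-5
        for t in (10.0, 30.0, 50.0, 70.0, 90.0):
            num = -(np.log(onset_survival(t + h, om)) - np.log(onset_survival(t - h, om))) / (2 * h)
            assert onset_hazard(t, om) == pytest.approx(num, rel=1e-6)

    def test_density_is_negative_derivative_of_survival(self, om):
        # also validates the (B-A)**delta reading of the density's constant
        h = 1e-5
        for t in np.linspace(0.5, 92, 25):
            num = -(onset_survival(t + h, om) - onset_survival(t - h, om)) / (2 * h)
            assert onset_density(t, om) == pytest.approx(num, rel=1e-6)

    def test_density_equals_hazard_times_survival(self, om):
        t = np.array([10.0, 30.0, 50.0, 70.0, 90.0])
        np.testing.assert_allclose(
            onset_density(t, om), onset_hazard(t, om) * onset_survival(t, om), rtol=1e-9
        )
        assert onset_density(0.0, om) == 0.0

    def test_nonfinite_age_rejected(self, om):
        with pytest.raises(ValueError):
            onset_survival(np.nan, om)
        with pytest.raises(ValueError):
            onset_density(-1.0, om)


class TestMvkParams:
    @pytest.mark.parametrize(
        "rates", [(1.0, 0.1, 0.5, 0.01), (2.0, 0.3, 1.0, 0.2), (0.5, 0.05, 0.9, 1e-4)]
    )
    def test_root_identities(self, rates):
        alpha, nu, beta, mu = rates
        A, B, delta = mvk_params_from_rates(alpha, nu, beta, mu)
        assert A + B == pytest.approx(beta + mu - alpha, rel=1e-12)
        assert A * B == pytest.approx(-alpha * mu, rel=1e-12)
        assert A < 0 < B
        assert delta == pytest.approx(nu / alpha)

    def test_zero_second_mutation_gives_zero_root(self):
        A, B, _ = mvk_params_from_rates(1.0, 0.1, 0.5, 0.0)
        assert min(abs(A), abs(B)) == 0.0

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            mvk_params_from_rates(0.0, 0.1, 0.5, 0.01)
        with pytest.raises(ValueError):
            mvk_params_from_rates(1.0, -0.1, 0.5, 0.01)


class TestOnsetSampling:
    def test_zero_grid_means_disease_free(self):
        m = OnsetModel(age_grid=np.array([0.0]), age_scale=1.0)
        ages = sample_onset(500, m, np.random.default_rng(0))
        assert np.all(np.isnan(ages))

    def test_onset_fraction_matches_weight_sum(self, om):
        _, w, p_none = onset_weights(om)
        p_onset = w.sum()
        n = 200_000
        ages = sample_onset(n, om, np.random.default_rng(1))
        frac = np.mean(~np.isnan(ages))
        se = np.sqrt(p_onset * (1 - p_onset) / n)
        assert abs(frac - p_onset) < 3 * se
        assert p_none == pytest.approx(1 - p_onset)

    def test_age_scaling_support(self, om):
        ages = sample_onset(50_000, om, np.random.default_rng(2))
        ages = ages[~np.isnan(ages)]
        lo, hi = om.age_grid[0] * om.age_scale, (om.age_grid[-1] + 1) * om.age_scale
        assert ages.min() >= lo and ages.max() < hi

    def test_thinning_support_and_rate(self, om):
        m = OnsetModel(adjustment="thinning")
        n = 200_000
        ages = sample_onset(n, m, np.random.default_rng(3))
        frac = np.mean(~np.isnan(ages))
        _, w, _ = onset_weights(om)
        expected = m.age_scale * w.sum()
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / n)
        kept = ages[~np.isnan(ages)]
        assert kept.min() >= m.age_grid[0] and kept.max() < m.age_grid[-1] + 1

    def test_overweight_grid_rejected(self):
        m = OnsetModel(age_grid=np.arange(0, 92.5, 0.1))
        with pytest.raises(ValueError, match="sum"):
            sample_onset(10, m, np.random.default_rng(0))


class TestGrowthAndSize:
    def test_gamma_mean_and_variance(self):
        g = GrowthModel()
        n = 1_000_000
        r = sample_inverse_growth_rate(n, g, np.random.default_rng(4))
        assert np.all(r > 0)
        sd = np.sqrt(g.a) / g.b
        assert abs(r.mean() - 1.0) < 3 * sd / np.sqrt(n)
        assert r.var() == pytest.approx(g.a / g.b**2, rel=0.02)

    def test_volume_growth(self):
        v0 = 0.0654
        assert tumor_volume_at_age(40.0, 40.0, 1.0, v0) == pytest.approx(v0)
        assert tumor_volume_at_age(40 + np.log(2), 40.0, 1.0, v0) == pytest.approx(2 * v0)
        assert tumor_volume_at_age(45.0, 40.0, 1.0, v0) == pytest.approx(0.0654 * np.e**5)
        with pytest.raises(ValueError):
            tumor_volume_at_age(39.0, 40.0, 1.0, v0)

    def test_sphere_values(self):
        assert volume_from_diameter(0.5) == pytest.approx(0.0654, abs=5e-4)
        assert volume_from_diameter(20.0) == pytest.approx(4188.79, abs=0.01)
        with pytest.raises(ValueError):
            diameter_from_volume(0.0)

    @given(st.floats(min_value=1e-3, max_value=1e6))
    def test_sphere_round_trip(self, d):
        assert diameter_from_volume(volume_from_diameter(d)) == pytest.approx(d, rel=1e-12)


class TestSymptomaticDetection:
    def test_quantile_values(self):
        dm = DetectionModel()
        assert sample_symptomatic_volume(1.0, dm, 0.0) == pytest.approx(dm.v0)
        v = sample_symptomatic_volume(2.0, dm, 1 - np.exp(-1.0))
        assert v == pytest.approx(dm.v0 + 1.0 / (dm.eta * 2.0), rel=1e-9)
        with pytest.raises(ValueError):
            sample_symptomatic_volume(1.0, dm, 1.0)

    def test_excess_volume_is_exponential_given_r(self):
        dm = DetectionModel()
        r = 0.7
        u = np.random.default_rng(5).random(100_000)
        excess = sample_symptomatic_volume(r, dm, u) - dm.v0
        ks = stats.kstest(excess, stats.expon(scale=1 / (dm.eta * r)).cdf)
        assert ks.statistic < 1.63 / np.sqrt(excess.size)  # 1% critical value

    def test_time_to_symptomatic(self):
        v0 = DetectionModel().v0
        assert time_to_symptomatic(v0, 1.0, v0) == 0.0
        assert time_to_symptomatic(2 * v0, 2.0, v0) == pytest.approx(2 * np.log(2))
        with pytest.raises(ValueError):
            time_to_symptomatic(0.5 * v0, 1.0, v0)

    def test_composition_inverts_growth(self):
        v0 = DetectionModel().v0
        V = tumor_volume_at_age(47.3, 40.0, 1.7, v0)
        assert time_to_symptomatic(V, 1.7, v0) == pytest.approx(7.3, rel=1e-12)


class TestSimulation:
    def test_determinism(self, default_models):
        onset, growth, det = default_models
        spec = CohortSpec(births_per_cohort=500, n_cohorts=4)
        h1 = simulate_natural_history(spec, onset, growth, det, seed=42)
        h2 = simulate_natural_history(spec, onset, growth, det, seed=42)
        np.testing.assert_array_equal(h1.onset_age, h2.onset_age)
        np.testing.assert_array_equal(h1.symptomatic_age, h2.symptomatic_age)
        h3 = simulate_natural_history(spec, onset, growth, det, seed=43)
        assert not np.array_equal(h1.onset_age, h3.onset_age)

    def test_zero_onset_gives_empty_histories(self, default_models):
        _, growth, det = default_models
        onset = OnsetModel(age_grid=np.array([0.0]), age_scale=1.0)
        h = simulate_natural_history(CohortSpec(200, 2), onset, growth, det, seed=0)
        assert not h.has_onset.any()
        assert np.all(np.isnan(h.symptomatic_age))

    def test_disease_course_invariants(self, hist_default):
        h = hist_default
        has = h.has_onset
        assert np.all(h.symptomatic_age[has] >= h.onset_age[has])
        assert np.all(h.symptomatic_diameter[has] >= 0.5)
        assert np.all(h.symptomatic_volume[has] >= h.v0)
        assert np.all(np.isnan(h.onset_age[~has]))
        # fields after onset_age absent iff onset_age absent
        assert np.all(np.isnan(h.symptomatic_age[~has]))

    def test_max_diameter_truncation(self, default_models):
        onset, growth, _ = default_models
        det = DetectionModel(max_diameter=120.0)
        h = simulate_natural_history(CohortSpec(2000, 10), onset, growth, det, seed=7)
        d = h.symptomatic_diameter[h.has_onset]
        assert d.max() <= 120.0

    def test_csv_export_round_trip(self, default_models, tmp_path):
        import pandas as pd

        onset, growth, det = default_models
        h = simulate_natural_history(CohortSpec(100, 2), onset, growth, det, seed=9)
        path = tmp_path / "hist.csv"
        h.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "individual_id", "cohort_year", "onset_age", "inv_growth_rate",
            "symptomatic_age", "symptomatic_diameter_mm",
        ]
        assert len(df) == h.n
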