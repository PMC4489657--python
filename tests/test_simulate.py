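"""Synthetic-data generators: growth, abundance, chases, Ct tables, scenarios."""

import numpy as np
import pandas as pd
import pytest

import turnoverkit as tk
from turnoverkit.simulate import (
    DEFAULT_GROWTH_RATE,
    GrowthModel,
    KsProfile,
    NoiseSpec,
    generate_abundance_course,
    generate_chase_course,
    generate_growth_curve,
    linear_decline_profile,
    solve_piecewise_abundance,
)


class TestGrowthModel:
    def test_initial_od(self):
        assert GrowthModel().od(0.0) == pytest.approx(0.4, rel=1e-12)

    def test_plateau_asymptote(self):
        model = GrowthModel()
        assert model.od(5000.0) == pytest.approx(1.5, abs=1e-3)
        assert np.all(np.diff(model.od(np.linspace(0, 2000, 200))) > 0)

    def test_default_rate_hits_od1_at_160min(self):
        assert GrowthModel().od(160.0) == pytest.approx(1.0, abs=0.01)
        anchored = GrowthModel.from_anchor(0.4, 1.5, 160.0, 1.0)
        assert anchored.r == pytest.approx(DEFAULT_GROWTH_RATE, rel=1e-12)
        assert anchored.od(160.0) == pytest.approx(1.0, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            GrowthModel(od0=2.0, K=1.5)
        with pytest.raises(ValueError):
            GrowthModel.from_anchor(0.4, 1.5, 160.0, 1.8)

    def test_growth_curve_induces_od_map(self):
        df, od_map = generate_growth_curve(GrowthModel(), np.arange(0.0, 401.0, 50.0))
        assert list(df.columns) == ["time_min", "od600"]
        assert od_map.od_at(160.0) == pytest.approx(1.0, abs=0.01)


class TestNoiseSpec:
    def test_zero_cv_is_identity(self):
        spec = NoiseSpec(cv=0.0, seed=1)
        assert np.all(spec.factors(spec.rng(), 10) == 1.0)

    def test_factors_have_unit_mean_and_requested_cv(self):
        spec = NoiseSpec(cv=0.10, seed=2)
        draws = spec.factors(spec.rng(), 200_000)
        assert draws.mean() == pytest.approx(1.0, abs=1e-3)
        assert draws.std() == pytest.approx(0.10, abs=2e-3)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(cv=-0.1)


class TestKsProfile:
    def test_right_edge_segment_convention(self):
        profile = KsProfile(change_times=[10.0, 20.0], values=[1.0, 0.5])
        assert profile.at(0.0) == 1.0
        assert profile.at(10.0) == 1.0  # value AT the change time is its segment's
        assert profile.at(10.1) == 0.5
        assert profile.at(20.0) == 0.5
        assert profile.at(25.0) == 0.5  # held beyond the last change point

    def test_constant_profile_matches_constant_model(self, schedule_23_20, grid_0_400):
        model = tk.TurnoverModel.at_steady_state(schedule_23_20)
        profile = KsProfile.constant(model.ks, 400.0)
        piecewise = solve_piecewise_abundance(profile, schedule_23_20, 1.0, grid_0_400)
        reference = tk.analytic_trajectory(model, grid_0_400).values
        np.testing.assert_allclose(piecewise, reference, rtol=1e-10)

    def test_profile_value_is_instantaneous_rate_at_sample_times(self, schedule_23_20):
        # the point-wise estimator ks = dP/dt + kd P must exactly invert the
        # generator at profile change times (exact derivative, not the global fit)
        profile = KsProfile(change_times=[100.0, 400.0], values=[0.03, 0.01])
        times = np.array([0.0, 100.0, 400.0])
        p = solve_piecewise_abundance(profile, schedule_23_20, 1.0, times)
        for t, pt in zip(times, p):
            dpdt = profile.at(t) - float(schedule_23_20.rate(t)) * pt
            ks_back = dpdt + float(schedule_23_20.rate(t)) * pt
            assert ks_back == pytest.approx(profile.at(t), rel=1e-12)


class TestLinearDeclineProfile:
    def test_envelope_declines_by_requested_fold(self, schedule_23_20):
        profile, slope = linear_decline_profile(schedule_23_20, 20.0, 400.0)
        kd0 = float(schedule_23_20.rate(0.0))
        kde = float(schedule_23_20.rate(400.0))
        ks0 = slope + kd0 * 1.0
        ks_end = slope + kde * (1.0 + slope * 400.0)
        assert ks_end / ks0 == pytest.approx(1.0 / 20.0, rel=1e-12)

    def test_generated_abundance_is_nearly_linear(self, schedule_23_20, grid_0_400):
        profile, slope = linear_decline_profile(schedule_23_20, 20.0, 400.0)
        p = solve_piecewise_abundance(profile, schedule_23_20, 1.0, grid_0_400)
        np.testing.assert_allclose(p, 1.0 + slope * grid_0_400, atol=0.01)

    def test_profile_is_positive_and_monotone_decreasing(self, schedule_23_20):
        profile, _ = linear_decline_profile(schedule_23_20, 20.0, 400.0)
        assert np.all(profile.values > 0)
        assert np.all(np.diff(profile.values) < 0)


class TestGenerateAbundance:
    def test_zero_noise_reproduces_forward_solution(self, schedule_23_20, grid_0_400):
        model = tk.TurnoverModel.at_steady_state(schedule_23_20)
        series, tidy = generate_abundance_course(model, grid_0_400)
        reference = tk.analytic_trajectory(model, grid_0_400).values
        np.testing.assert_allclose(series.values, reference, rtol=1e-12)
        assert len(tidy) == len(grid_0_400)

    def test_same_seed_bitwise_identical(self, schedule_23_20, grid_0_400):
        model = tk.TurnoverModel.at_steady_state(schedule_23_20)
        a, tidy_a = generate_abundance_course(
            model, grid_0_400, noise=NoiseSpec(cv=0.10, seed=7), n_replicates=3)
        b, tidy_b = generate_abundance_course(
            model, grid_0_400, noise=NoiseSpec(cv=0.10, seed=7), n_replicates=3)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(tidy_a, tidy_b)
        c, _ = generate_abundance_course(
            model, grid_0_400, noise=NoiseSpec(cv=0.10, seed=8), n_replicates=3)
        assert not np.allclose(a.values, c.values)

    def test_replicate_mean_within_clt_bounds(self, schedule_23_20):
        model = tk.TurnoverModel.at_steady_state(schedule_23_20)
        times = np.array([0.0, 200.0, 400.0])
        n = 1000
        series, _ = generate_abundance_course(
            model, times, noise=NoiseSpec(cv=0.10, seed=3), n_replicates=n)
        truth = tk.analytic_trajectory(model, times).values
        # mean of n lognormal factors: se = cv/sqrt(n); allow 4 se
        assert np.all(np.abs(series.values - truth) / truth < 4 * 0.10 / np.sqrt(n))


class TestGenerateChase:
    def test_zero_noise_exact_samples(self):
        course = generate_chase_course(20.0, [0.0, 10.0, 20.0, 30.0])
        np.testing.assert_allclose(
            course.data["intensity"].to_numpy(),
            [1.0, 2 ** -0.5, 0.5, 2 ** -1.5], rtol=1e-12)

    def test_roundtrip_recovers_halflife(self):
        course = generate_chase_course(13.0, np.arange(0.0, 41.0, 10.0))
        assert tk.estimate_halflife(course).halflife == pytest.approx(13.0, rel=1e-9)

    def test_estimator_bias_and_spread_vs_noise(self):
        # estimator spread grows with CV while the median stays near truth
        t = np.arange(0.0, 41.0, 10.0)
        spreads = []
        for cv in (0.05, 0.20):
            ests = [
                tk.estimate_halflife(
                    generate_chase_course(13.0, t, noise=NoiseSpec(cv=cv, seed=i))
                ).halflife
                for i in range(150)
            ]
            assert np.median(ests) == pytest.approx(13.0, rel=0.10)
            spreads.append(np.subtract(*np.percentile(ests, [75, 25])))
        assert spreads[1] > spreads[0]


class TestScenario:
    def test_writes_all_tables_and_truth(self, noisy_scenario):
        _, outdir = noisy_scenario
        for name in ("growth.csv", "abundance.csv", "chase.csv", "ct.csv", "truth.json"):
            assert (outdir / name).exists(), name

    def test_seed_determinism_across_generators(self, tmp_path):
        a = tk.generate_scenario(outdir=tmp_path / "a", seed=42)
        b = tk.generate_scenario(outdir=tmp_path / "b", seed=42)
        pd.testing.assert_frame_equal(a["abundance"].data, b["abundance"].data)
        pd.testing.assert_frame_equal(a["chase"], b["chase"])
        pd.testing.assert_frame_equal(a["ct"].data, b["ct"].data)
        assert (tmp_path / "a" / "abundance.csv").read_bytes() == (
            tmp_path / "b" / "abundance.csv").read_bytes()

    def test_truth_records_generating_parameters(self, noisefree_scenario):
        scen, _ = noisefree_scenario
        truth = scen["truth"]
        assert truth["synthesis"]["fold"] == 20.0
        assert truth["mrna"]["terminal_fraction"] == 0.65
        assert truth["chase_halflives_min"]["exponential"] == 23.0
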