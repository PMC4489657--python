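"""Turnover-model kinetics: rate conversions, schedules, solver and closed form."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import turnoverkit as tk

LN2 = math.log(2.0)


class TestRateHalflifeConversion:
    @pytest.mark.parametrize(
        "halflife, rate", [(23.0, 0.030137), (20.0, 0.034657), (9.1, LN2 / 9.1)]
    )
    def test_definition(self, halflife, rate):
        assert tk.rate_from_halflife(halflife) == pytest.approx(rate, abs=5e-7)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_inverse_pair(self, halflife):
        assert tk.halflife_from_rate(tk.rate_from_halflife(halflife)) == pytest.approx(
            halflife, rel=1e-12
        )

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            tk.rate_from_halflife(bad)
        with pytest.raises(ValueError):
            tk.halflife_from_rate(bad)


class TestDegradationSchedule:
    def test_anchored_schedule_values(self, schedule_23_20):
        assert schedule_23_20.kd0 == pytest.approx(LN2 / 23.0, rel=1e-12)
        assert schedule_23_20.a == pytest.approx((LN2 / 20 - LN2 / 23) / 160, rel=1e-12)
        assert schedule_23_20.a == pytest.approx(2.825e-5, rel=1e-3)

    def test_equal_halflives_give_constant_rate(self):
        sched = tk.build_linear_schedule(23.0, 23.0, 160.0, 400.0)
        assert sched.a == 0.0
        assert float(sched.halflife(321.0)) == pytest.approx(23.0, rel=1e-12)

    def test_bestfit_halflife_hits_anchor_exactly(self, schedule_23_91):
        assert float(schedule_23_91.halflife(160.0)) == pytest.approx(9.1, rel=1e-12)

    def test_rate_crossing_zero_rejected(self):
        # strongly decelerating schedule goes negative before the window ends
        with pytest.raises(ValueError):
            tk.build_linear_schedule(10.0, 1.0e9, 10.0, 400.0)

    def test_negative_acceleration_allowed_if_positive(self):
        sched = tk.build_linear_schedule(20.0, 23.0, 160.0, 400.0)
        assert sched.a < 0
        assert float(sched.rate(400.0)) > 0

    def test_halflife_positive_on_window(self, schedule_23_91):
        t = np.linspace(*schedule_23_91.window, 101)
        assert np.all(schedule_23_91.halflife(t) > 0)


class TestSolveAbundance:
    def test_steady_state_is_flat(self):
        sched = tk.DegradationSchedule(kd0=LN2 / 23, a=0.0)
        model = tk.TurnoverModel.at_steady_state(sched, p0=1.0)
        traj = tk.solve_abundance(model, np.linspace(0, 400, 41))
        assert np.max(np.abs(traj.values - 1.0)) <= 1e-9

    def test_pure_decay_two_halflives(self):
        sched = tk.DegradationSchedule(kd0=LN2 / 23, a=0.0)
        model = tk.TurnoverModel(ks=0.0, schedule=sched, p0=1.0)
        traj = tk.solve_abundance(model, np.array([0.0, 46.0]))
        assert traj.values[-1] == pytest.approx(0.25, rel=1e-6)

    def test_measured_schedule_gives_about_quarter_decrease(self, schedule_23_20):
        model = tk.TurnoverModel.at_steady_state(schedule_23_20)
        traj = tk.solve_abundance(model, np.array([0.0, 400.0]))
        decrease = 100.0 * (1.0 - traj.values[-1] / traj.values[0])
        assert decrease == pytest.approx(26.01, abs=0.1)  # "at most a 25% decrease"

    def test_times_outside_window_rejected(self, schedule_23_20):
        model = tk.TurnoverModel.at_steady_state(schedule_23_20)
        with pytest.raises(ValueError):
            tk.solve_abundance(model, np.array([0.0, 500.0]))


class TestAnalyticAbundance:
    def test_constant_rate_closed_form(self):
        kd, ks, p0, t = 0.05, 0.01, 2.0, 37.0
        sched = tk.DegradationSchedule(kd0=kd, a=0.0)
        model = tk.TurnoverModel(ks=ks, schedule=sched, p0=p0)
        expected = ks / kd + (p0 - ks / kd) * math.exp(-kd * t)
        assert tk.analytic_abundance(model, t) == pytest.approx(expected, rel=1e-12)

    def test_no_synthesis_limit(self, schedule_23_91):
        model = tk.TurnoverModel(ks=0.0, schedule=schedule_23_91, p0=1.5)
        t = 123.0
        expected = 1.5 * math.exp(-(schedule_23_91.kd0 * t + schedule_23_91.a * t**2 / 2))
        assert tk.analytic_abundance(model, t) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_solver_on_random_parameters(self):
        rng = np.random.default_rng(42)
        times = np.linspace(0.0, 400.0, 21)
        worst = 0.0
        for _ in range(100):
            kd0 = rng.uniform(0.005, 0.1)
            sched = tk.DegradationSchedule(
                kd0=kd0, a=rng.uniform(-0.9 * kd0 / 400, 5e-4), window=(0, 400)
            )
            model = tk.TurnoverModel(
                ks=rng.uniform(0, 0.1), schedule=sched, p0=rng.uniform(0.1, 5)
            )
            num = tk.solve_abundance(model, times).values
            ana = tk.analytic_trajectory(model, times).values
            worst = max(worst, float(np.max(np.abs(num - ana) / ana)))
        assert worst <= 1e-6


class TestModelProperties:
    @given(st.floats(min_value=1e-6, max_value=8e-5))
    @settings(max_examples=25, deadline=None)
    def test_faster_acceleration_lowers_abundance_pointwise(self, a):
        base = tk.DegradationSchedule(kd0=LN2 / 23, a=0.0, window=(0, 400))
        accel = tk.DegradationSchedule(kd0=LN2 / 23, a=a, window=(0, 400))
        ks = base.kd0  # steady state of the base schedule
        times = np.linspace(10, 400, 14)
        p_base = tk.analytic_trajectory(tk.TurnoverModel(ks, base), times).values
        p_acc = tk.analytic_trajectory(tk.TurnoverModel(ks, accel), times).values
        assert np.all(p_acc < p_base)

    @given(
        st.floats(min_value=0.0, max_value=0.1),
        st.floats(min_value=0.01, max_value=5.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_positivity(self, ks, p0):
        sched = tk.DegradationSchedule(kd0=LN2 / 23, a=2e-5, window=(0, 400))
        traj = tk.analytic_trajectory(
            tk.TurnoverModel(ks=ks, schedule=sched, p0=p0), np.linspace(0, 400, 17)
        )
        assert np.all(traj.values > 0)


class TestQuasiSteadyState:
    def test_steady_state_value(self):
        sched = tk.DegradationSchedule(kd0=LN2 / 23, a=0.0)
        model = tk.TurnoverModel.at_steady_state(sched, p0=1.0)
        assert tk.qss_abundance(model, 0.0) == pytest.approx(1.0, rel=1e-12)

    def test_measured_schedule_terminal_qss(self, schedule_23_20):
        model = tk.TurnoverModel.at_steady_state(schedule_23_20)
        # kd(0)/kd(400) = 0.727...: the QSS floor the full solution lags above
        assert tk.qss_abundance(model, 400.0) == pytest.approx(8.0 / 11.0, rel=1e-9)

    def test_constant_rate_limit_matches_closed_form(self):
        # with a = 0 the deviation from QSS is exactly the relaxing transient
        kd, ks, p0 = 0.04, 0.02, 1.0
        sched = tk.DegradationSchedule(kd0=kd, a=0.0)
        model = tk.TurnoverModel(ks=ks, schedule=sched, p0=p0)
        for t in (10.0, 50.0, 200.0):
            qss = tk.qss_abundance(model, t)
            full = tk.analytic_abundance(model, t)
            expected = abs(p0 - ks / kd) * math.exp(-kd * t) / (ks / kd)
            assert abs(full - qss) / qss == pytest.approx(expected, rel=1e-9)

    def test_solution_approaches_qss_as_acceleration_shrinks(self, schedule_23_20):
        # at large t the lag behind QSS scales like a * ks / kd^3
        devs = []
        for a in (2e-5, 1e-5, 5e-6):
            sched = tk.DegradationSchedule(kd0=LN2 / 23, a=a, window=(0, 2000))
            model = tk.TurnoverModel.at_steady_state(sched)
            qss = tk.qss_abundance(model, 2000.0)
            devs.append(abs(tk.analytic_abundance(model, 2000.0) - qss) / qss)
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 0.01


class TestTimeOdMap:
    def test_default_anchors(self):
        od_map = tk.TimeOdMap()
        assert od_map.od_at(0.0) == pytest.approx(0.4)
        assert od_map.od_at(160.0) == pytest.approx(1.0)
        assert od_map.od_at(400.0) == pytest.approx(1.5)

    def test_interpolation_is_monotone_and_invertible(self):
        od_map = tk.TimeOdMap()
        t = np.linspace(0, 400, 41)
        od = od_map.od_at(t)
        assert np.all(np.diff(od) > 0)
        np.testing.assert_allclose(od_map.time_at(od), t, atol=1e-9)

    def test_out_of_range_rejected(self):
        od_map = tk.TimeOdMap()
        with pytest.raises(ValueError):
            od_map.od_at(500.0)
        with pytest.raises(ValueError):
            od_map.time_at(0.2)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(ValueError):
            tk.TimeOdMap(times=[0, 100, 50], ods=[0.4, 1.0, 1.5])


def test_trajectory_serialises_with_od(tmp_path):
    sched = tk.DegradationSchedule(kd0=LN2 / 23, a=0.0)
    traj = tk.analytic_trajectory(
        tk.TurnoverModel.at_steady_state(sched), np.array([0.0, 160.0, 400.0])
    )
    df = traj.to_frame(od_map=tk.TimeOdMap())
    assert list(df.columns) == ["time_min", "od600", "abundance"]
    assert df["od600"].tolist() == pytest.approx([0.4, 1.0, 1.5])


def test_steady_state_constructor_pins_ks(schedule_23_20):
    model = tk.TurnoverModel.at_steady_state(schedule_23_20, p0=2.0)
    assert model.ks == pytest.approx(2.0 * schedule_23_20.kd0, rel=1e-15)


class TestModelConfig:
    def test_steady_state_mode_from_mapping(self):
        model = tk.model_from_config({
            "halflife_t0_min": 23.0, "halflife_t1_min": 20.0,
            "t1_min": 160.0, "window_end_min": 400.0,
            "ks_mode": "steady_state", "p0": 1.0,
        })
        assert model.ks == pytest.approx(LN2 / 23.0, rel=1e-12)

    def test_explicit_mode_from_yaml_file(self, tmp_path):
        path = tmp_path / "model.yaml"
        path.write_text(
            "halflife_t0_min: 23\nhalflife_t1_min: 20\nt1_min: 160\n"
            "window_end_min: 400\nks_mode: explicit\nks: 0.01\np0: 2.0\n")
        model = tk.model_from_config(path)
        assert (model.ks, model.p0) == (0.01, 2.0)

    def test_missing_keys_and_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="halflife_t1_min"):
            tk.model_from_config({"halflife_t0_min": 23.0})
        with pytest.raises(ValueError, match="ks_mode"):
            tk.model_from_config({
                "halflife_t0_min": 23.0, "halflife_t1_min": 20.0,
                "t1_min": 160.0, "window_end_min": 400.0, "ks_mode": "wat"})
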