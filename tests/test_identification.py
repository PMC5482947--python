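"""Integral-method identification tests: interpolation, insulin compartments,
hourly closed-form SI solve, and recovery on synthetic truth."""

import numpy as np
import pytest

import sivar
from sivar import (IcingParameters, InputSchedule, ModelInputError, ModelState,
                   PatientRecord, PiecewiseConstant, SITrajectory,
                   InsulinSensitivityModel, fit_si_hour, fit_si_profile,
                   interpolate_bg, ode_rhs, simulate,
                   simulate_insulin_compartments)
from sivar.identification import basal_insulin_state
from sivar.records import G_PER_H_TO_MMOL_PER_MIN, U_PER_H_TO_MU_PER_MIN
from conftest import euler_oracle, steady_state_oracle


def make_record(bg_times, bg_values, insulin_u_h=2.0, feed_g_h=3.0,
                outcome="survivor", therapy_start=0.0):
    return PatientRecord(
        patient_id="T1", outcome=outcome, admission_time=0.0,
        therapy_start=therapy_start, bg_times=bg_times, bg_values=bg_values,
        insulin_times=[0.0], insulin_rates=[insulin_u_h],
        nutrition_times=[0.0], nutrition_rates=[feed_g_h])


def synthetic_record(params, si_traj, hours, bg_step_min=5.0,
                     insulin_u_h=2.0, feed_g_h=3.0, g0=8.0):
    """Forward-simulate the model under a known SI trajectory and package the
    trajectory as a clinical-style record (noise-free BG samples)."""
    I0, Q0 = basal_insulin_state(params, g0)
    sched = InputSchedule(
        u_ex=PiecewiseConstant.constant(insulin_u_h * U_PER_H_TO_MU_PER_MIN),
        P=PiecewiseConstant.constant(feed_g_h * G_PER_H_TO_MMOL_PER_MIN))
    grid = np.arange(0.0, hours * 60.0 + 0.1, bg_step_min)
    out = simulate(ModelState(G=g0, I=I0, Q=Q0), params, si_traj, sched,
                   horizon=hours * 60.0, output_grid=grid,
                   rtol=1e-9, atol=1e-11)
    return make_record(out["time_min"].to_numpy(), out["G"].to_numpy(),
                       insulin_u_h=insulin_u_h, feed_g_h=feed_g_h)


class TestInterpolateBg:
    def test_linear_midpoint(self):
        assert interpolate_bg([0.0, 60.0], [5.0, 7.0], np.array([30.0])) == 6.0

    def test_exact_at_measurement_times(self):
        t = np.array([0.0, 37.0, 90.0])
        v = np.array([5.1, 6.3, 4.9])
        assert np.array_equal(interpolate_bg(t, v, t), v)

    def test_matches_two_point_formula_oracle(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 300, 12))
        v = rng.uniform(4, 10, 12)
        q = rng.uniform(t[0], t[-1], 200)
        got = interpolate_bg(t, v, q)
        # hand-rolled two-point formula
        expected = np.empty_like(q)
        for j, x in enumerate(q):
            i = np.searchsorted(t, x, side="right") - 1
            i = min(i, t.size - 2)
            w = (x - t[i]) / (t[i + 1] - t[i])
            expected[j] = (1 - w) * v[i] + w * v[i + 1]
        assert np.allclose(got, expected, rtol=0, atol=1e-12)

    def test_grid_outside_span_rejected(self):
        with pytest.raises(ModelInputError, match="span"):
            interpolate_bg([0.0, 60.0], [5.0, 6.0], np.array([61.0]))


class TestInsulinCompartments:
    def test_no_source_stays_at_zero(self, params):
        p = params.replace(u_en_active=False)
        rec = make_record([0.0, 120.0], [6.0, 6.0], insulin_u_h=0.0)
        grid = np.arange(0.0, 121.0)
        G = interpolate_bg(rec.bg_times, rec.bg_values, grid)
        I, Q = simulate_insulin_compartments(rec, p, grid, G)
        assert np.all(I == 0.0) and np.all(Q == 0.0)

    def test_terminal_equilibrium_matches_root_oracle(self, params):
        p = params.replace(alpha_I=1e-12, u_en_active=False)
        u_h = 3.0
        rec = make_record([0.0, 2000.0], [6.0, 6.0], insulin_u_h=u_h)
        grid = np.arange(0.0, 2001.0)
        G = interpolate_bg(rec.bg_times, rec.bg_values, grid)
        I, Q = simulate_insulin_compartments(rec, p, grid, G)
        _, I_star, Q_star = steady_state_oracle(
            p, 3e-4, u_h * U_PER_H_TO_MU_PER_MIN, 0.3, guess=(6.0, 60.0, 40.0))
        assert abs(I[-1] - I_star) / I_star < 1e-3
        assert abs(Q[-1] - Q_star) / Q_star < 1e-3

    def test_matches_fine_step_euler_oracle(self, params):
        rec = make_record([0.0, 180.0], [9.0, 6.0], insulin_u_h=4.0)
        grid = np.arange(0.0, 181.0)
        G = interpolate_bg(rec.bg_times, rec.bg_values, grid)
        I, Q = simulate_insulin_compartments(rec, params, grid, G)

        # Euler oracle with glucose clamped to the same interpolant
        I0, Q0 = basal_insulin_state(params, 9.0)
        y_euler = np.array([I0, Q0], float)
        t, dt = 0.0, 0.002
        u_ex = 4.0 * U_PER_H_TO_MU_PER_MIN
        for _ in range(int(180 / dt)):
            g = np.interp(t, grid, G)
            _, dI, dQ = ode_rhs((g, y_euler[0], y_euler[1]), params, 0.0,
                                u_ex, 0.0)
            y_euler = y_euler + dt * np.array([dI, dQ])
            t += dt
        assert abs(I[-1] - y_euler[0]) / y_euler[0] < 1e-4
        assert abs(Q[-1] - y_euler[1]) / y_euler[1] < 1e-4


class TestHourlySolve:
    def test_constant_si_round_trip(self, params):
        si_true = 3.0e-4
        rec = synthetic_record(params, SITrajectory.constant(si_true, 4), hours=4)
        res = InsulinSensitivityModel(rec, params).fit(4)
        assert res.nobs == 4
        assert np.all(np.abs(res.si - si_true) / si_true < 0.005)

    def test_zero_si_generation_clamps(self, params):
        rec = synthetic_record(params, SITrajectory.constant(0.0, 2), hours=2)
        si, flag = fit_si_hour(rec, params, hour=0)
        # integration-level zero: clamped outright, or orders of magnitude
        # below any physiological SI
        assert flag == "clamped" or si <= 1e-7

    def test_no_insulin_exposure_is_unidentifiable(self, params):
        p = params.replace(u_en_active=False)
        rec = make_record(np.arange(0.0, 121.0, 30.0),
                          np.full(5, 6.5), insulin_u_h=0.0)
        si, flag = fit_si_hour(rec, p, hour=0)
        assert si is None and flag == "unidentifiable"

    def test_stepped_daily_profile_recovered(self, params):
        steps = np.concatenate([np.full(24, 2e-4), np.full(24, 4e-4),
                                np.full(24, 3e-4)])
        rec = synthetic_record(params, SITrajectory(steps), hours=72,
                               bg_step_min=5.0)
        res = InsulinSensitivityModel(rec, params).fit(72)
        assert res.nobs == 72
        err = np.abs(res.si - steps[res.hours]) / steps[res.hours]
        assert np.all(err < 0.02)

    def test_matches_shooting_oracle(self, params):
        """Closed-form integral solve vs brute-force scalar minimisation:
        for each hour, the oracle shoots the glucose ODE (driven by the same
        interpolated-G insulin compartments) and minimises the end-of-hour
        mismatch over SI."""
        from scipy.integrate import solve_ivp
        from scipy.optimize import minimize_scalar

        si_traj = SITrajectory([2e-4, 4e-4, 3e-4])
        rec = synthetic_record(params, si_traj, hours=3, bg_step_min=1.0)
        model = InsulinSensitivityModel(rec, params)
        res = model.fit(3)
        grid = np.arange(0.0, 3 * 60.0 + 0.5)
        G = interpolate_bg(rec.bg_times, rec.bg_values, grid)
        I, Q = simulate_insulin_compartments(rec, params, grid, G)
        src = (3.0 * G_PER_H_TO_MMOL_PER_MIN + params.EGP - params.CNS) / params.V_G

        for j, h in enumerate(res.hours):
            t0, t1 = 60.0 * h, 60.0 * (h + 1)
            g0 = np.interp(t0, rec.bg_times, rec.bg_values)
            g1 = np.interp(t1, rec.bg_times, rec.bg_values)

            def end_mismatch(si):
                def rhs(t, y):
                    q = np.interp(t, grid, Q)
                    return [-params.p_G * y[0]
                            - si * y[0] * q / (1 + params.alpha_G * q) + src]

                sol = solve_ivp(rhs, (t0, t1), [g0], rtol=1e-10, atol=1e-12)
                return (sol.y[0, -1] - g1) ** 2

            oracle = minimize_scalar(end_mismatch, bounds=(1e-6, 2e-3),
                                     method="bounded",
                                     options={"xatol": 1e-10}).x
            assert abs(res.si[j] - oracle) / oracle < 1e-3


class TestProfiles:
    def test_short_record_yields_covered_hours_only(self, params):
        rec = synthetic_record(params, SITrajectory.constant(3e-4, 30), hours=30)
        res = fit_si_profile(rec, params, horizon_hours=72)
        assert np.array_equal(res.hours, np.arange(30))

    def test_partial_edge_hours_dropped(self, params):
        rec = synthetic_record(params, SITrajectory.constant(3e-4, 3), hours=3)
        rec = make_record(rec.bg_times[(rec.bg_times >= 25) & (rec.bg_times <= 155)],
                          rec.bg_values[(rec.bg_times >= 25) & (rec.bg_times <= 155)])
        res = fit_si_profile(rec, params, horizon_hours=3)
        assert np.array_equal(res.hours, np.array([1]))  # only [60, 120] covered

    def test_too_few_measurements_rejected(self, params):
        with pytest.raises(ModelInputError, match="fewer than 2"):
            fit_si_profile(make_record([0.0], [6.0]), params)

    def test_deterministic_bit_identical_refit(self, params):
        rec = synthetic_record(params, SITrajectory.constant(3e-4, 4), hours=4,
                               bg_step_min=30.0)
        a = InsulinSensitivityModel(rec, params).fit(4)
        b = InsulinSensitivityModel(rec, params).fit(4)
        assert np.array_equal(a.si, b.si) and np.array_equal(a.hours, b.hours)

    @pytest.mark.parametrize("factor", [1.05, 1.2, 1.5])
    def test_uniform_bg_raise_never_raises_si(self, params, factor):
        rec = synthetic_record(params, SITrajectory.constant(3e-4, 4), hours=4,
                               bg_step_min=15.0)
        base = InsulinSensitivityModel(rec, params).fit(4)
        scaled_rec = make_record(rec.bg_times, rec.bg_values * factor)
        scaled = InsulinSensitivityModel(scaled_rec, params).fit(4)
        assert np.all(scaled.si <= base.si + 1e-15)

    def test_summary_reports_fit(self, params):
        rec = synthetic_record(params, SITrajectory.constant(3e-4, 4), hours=4)
        text = InsulinSensitivityModel(rec, params).fit(4).summary()
        assert "hours fitted:   4" in text and "SI median" in text


class TestCohortRecovery:
    def test_hourly_noise_free_recovery_under_5_percent(self, noise_free_cohort):
        cohort, profiles = noise_free_cohort
        merged = (sivar.profiles_to_frame(profiles)
                  .merge(cohort.truth, on=["patient_id", "hour"]))
        err = np.abs(merged["si"] - merged["true_si"]) / merged["true_si"]
        assert np.median(err) < 0.05

    def test_five_minute_bg_recovery_under_1_percent(self, params):
        from sivar.cohort import CohortConfig, generate_cohort

        cfg = CohortConfig(n_survivors=5, n_nonsurvivors=5, bg_error_sd=0.0,
                           measurement_interval=5.0, horizon_hours=24,
                           los_median_hours=30.0, los_log_sd=0.0,
                           los_min_hours=30.0, seed=20201)
        cohort = generate_cohort(cfg, params=params)
        profiles = [InsulinSensitivityModel(r, params).fit(24)
                    for r in cohort.records]
        merged = (sivar.profiles_to_frame(profiles)
                  .merge(cohort.truth, on=["patient_id", "hour"]))
        err = np.abs(merged["si"] - merged["true_si"]) / merged["true_si"]
        assert np.median(err) < 0.01

    def test_measurement_noise_leaves_median_unbiased(self, headline_cohort):
        from scipy import stats

        cohort, _ = headline_cohort
        profiles = [InsulinSensitivityModel(r).fit(73) for r in cohort.records[:40]]
        merged = (sivar.profiles_to_frame(profiles)
                  .merge(cohort.truth, on=["patient_id", "hour"]))
        err = merged["si"] - merged["true_si"]
        n_pos = int((err > 0).sum())
        p = stats.binomtest(n_pos, int((err != 0).sum())).pvalue
        assert p > 0.01
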