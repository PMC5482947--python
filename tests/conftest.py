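"""Shared fixtures: model constants, oracle helpers, and session-scoped
synthetic cohorts reused by the identification, calibration and pipeline
tests (they are expensive to generate, and every consumer is read-only)."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import fsolve

from sivar import (CohortAnalysis, CohortConfig, IcingParameters,
                   InsulinSensitivityModel, generate_cohort, ode_rhs)

settings.register_profile(
    "suite", settings(deadline=None, derandomize=True, max_examples=25,
                      suppress_health_check=[HealthCheck.too_slow]))
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> IcingParameters:
    return IcingParameters.defaults()


def steady_state_oracle(params: IcingParameters, si: float, u_ex: float,
                        P: float, guess=(6.0, 20.0, 15.0)) -> np.ndarray:
    """Independent root-finding oracle for the model's algebraic steady state."""
    sol, info, ok, msg = fsolve(
        lambda y: ode_rhs(y, params, si, u_ex, P), np.asarray(guess, float),
        full_output=True, xtol=1e-13)
    assert ok == 1, msg
    return sol


def euler_oracle(y0, params, si_of_t, u_ex_of_t, P_of_t, t0, t1, dt=0.005):
    """Fine-step explicit-Euler forward integration (brute-force oracle)."""
    n = int(round((t1 - t0) / dt))
    y = np.asarray(y0, float).copy()
    t = t0
    for _ in range(n):
        d = ode_rhs(y, params, si_of_t(t), u_ex_of_t(t), P_of_t(t))
        y = y + dt * np.asarray(d)
        t += dt
    return y


@pytest.fixture(scope="session")
def noise_free_cohort(params):
    """100 virtual patients, hourly BG, no measurement error: the parameter-
    recovery reference condition."""
    cfg = CohortConfig(n_survivors=50, n_nonsurvivors=50, bg_error_sd=0.0,
                       measurement_interval=60.0, los_median_hours=200.0,
                       los_log_sd=0.0, los_min_hours=100.0, seed=20200)
    cohort = generate_cohort(cfg, params=params)
    profiles = [InsulinSensitivityModel(r, params).fit(73) for r in cohort.records]
    return cohort, profiles


@pytest.fixture(scope="session")
def headline_cohort(params):
    """Study-structure cohort (119 survivors / 26 non-survivors, non-survivor
    SI x1.2, 9.4% BG error) with its full single-cohort analysis."""
    cfg = CohortConfig(seed=20170)
    cohort = generate_cohort(cfg, params=params)
    results = CohortAnalysis(cohort.records, params=params, seed=20170,
                             cohorts=("cohort1",)).fit()
    return cohort, results


@pytest.fixture(scope="session")
def null_calibration(params):
    """Bootstrap/KS calibration sweep under the null (equal groups, shared
    variability): per-seed, per-block %dSI CIs and KS p-values."""
    from sivar.equivalence import bootstrap_median_diff, ks_two_sample
    from sivar.variability import pool_blocks

    rows = []
    for i, seed in enumerate(range(100, 110)):
        cfg = CohortConfig(n_survivors=25, n_nonsurvivors=25,
                           nonsurvivor_si_multiplier=1.0, seed=seed)
        cohort = generate_cohort(cfg, params=params)
        profiles = [InsulinSensitivityModel(r, params).fit(73)
                    for r in cohort.records]
        samples = pool_blocks(profiles, cohort.outcomes, metric="delta_si")
        by = {(s.block, s.group): s for s in samples}
        for b in range(12):
            x, y = by[(b, "survivor")], by[(b, "non-survivor")]
            if x.n < 2 or y.n < 2:
                continue
            rng = np.random.default_rng(np.random.SeedSequence((seed, b)))
            ci = bootstrap_median_diff(x.values, y.values, seed=rng)
            rows.append({"seed": seed, "block": b,
                         "ci95_lo": ci.ci95[0], "ci95_hi": ci.ci95[1],
                         "ci996_lo": ci.ci996[0], "ci996_hi": ci.ci996[1],
                         "ks_p": ks_two_sample(x.values, y.values)})
    return rows
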