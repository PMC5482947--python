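"""Virtual-patient cohort generator for glycaemic-control analyses.

Each virtual patient carries a "true" hourly insulin-sensitivity trajectory
(a geometric random walk on log-SI with hour-to-hour variability that shrinks
over the first 72 h, a deterministic upward drift, a patient-level baseline
spread, and a group-level offset for non-survivors). Blood glucose evolves
under the compartment model in closed loop with a stylized table-like
glycaemic-control protocol that modulates both insulin and feed towards a
4.4-8.0 mmol/L band. Measurements are taken at a fixed interval, corrupted by
multiplicative Gaussian error (truncated at +/-3 SD), and records are cut at
a lognormal length of stay, creating the >=24 h / >=72 h cohort structure.

The generator is an emulation of the statistical structure such cohorts
exhibit, not a fit to any patient data; its defaults are the study-style
conditions used throughout the test-suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .icing import (IcingParameters, InputSchedule, ModelInputError, ModelState,
                    PiecewiseConstant, SITrajectory, simulate)
from .identification import basal_insulin_state
from .records import PatientRecord


@dataclass(frozen=True)
class ControllerConfig:
    """Stylized glycaemic-control protocol parameters."""

    target_lo: float = 4.4        # mmol/L
    target_hi: float = 8.0        # mmol/L
    severe_hypo: float = 3.5      # mmol/L, insulin cut-out
    insulin_cap: float = 6.0      # U/h
    insulin_step: float = 1.0     # U/h quantum
    start_insulin: float = 3.0    # U/h
    feed_base_g_h: float = 4.0    # goal carbohydrate rate (g/h)
    feed_frac_start: float = 0.8
    feed_frac_min: float = 0.3
    feed_step: float = 0.1
    rise_threshold: float = 0.5   # mmol/L change treated as a trend


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of the synthetic cohort, including the seed."""

    n_survivors: int = 119
    n_nonsurvivors: int = 26
    si_level_median: float = 1.5e-4          # survivors, L/mU/min at hour 0
    nonsurvivor_si_multiplier: float = 1.2   # group level offset
    patient_level_sd: float = 0.4            # log-SD of baseline SI between patients
    delta_si_sd_start: float = 0.30          # log-SD of hourly step at h=0
    delta_si_sd_end: float = 0.10            # log-SD of hourly step at h=72
    si_drift_per_day: float = 1.3            # deterministic multiplicative drift
    si_bounds: tuple[float, float] = (1e-6, 5e-3)
    bg_error_sd: float = 9.4                 # percent, multiplicative
    measurement_interval: float = 90.0       # min (~16 BG measures/day)
    horizon_hours: int = 73
    los_median_hours: float = 120.0
    los_log_sd: float = 0.9
    los_min_hours: float = 12.0
    therapy_start_max_min: float = 720.0     # therapy begins within 12 h of admission
    init_bg_median: float = 9.0              # mmol/L at therapy start
    init_bg_log_sd: float = 0.15
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_survivors < 0 or self.n_nonsurvivors < 0:
            raise ModelInputError("group counts must be >= 0")
        if self.nonsurvivor_si_multiplier <= 0 or self.si_level_median <= 0:
            raise ModelInputError("SI level parameters must be > 0")
        for nm in ("patient_level_sd", "delta_si_sd_start", "delta_si_sd_end",
                   "bg_error_sd"):
            if getattr(self, nm) < 0:
                raise ModelInputError(f"{nm} must be >= 0")
        if self.measurement_interval <= 0:
            raise ModelInputError("measurement_interval must be > 0")
        if self.si_bounds[0] <= 0 or self.si_bounds[1] <= self.si_bounds[0]:
            raise ModelInputError("si_bounds must be positive and ordered")

    def replace(self, **changes) -> "CohortConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        ctrl = payload.pop("controller", None)
        cfg = cls(**payload) if ctrl is None else cls(
            controller=ControllerConfig(**ctrl), **payload)
        return cfg


def sample_si_trajectory(config: CohortConfig, group: str,
                         rng: np.random.Generator) -> np.ndarray:
    """True hourly SI for one patient: geometric random walk on log-SI.

    Hourly multiplicative steps with log-SD interpolated from
    ``delta_si_sd_start`` (h=0) to ``delta_si_sd_end`` (h=72), a deterministic
    upward drift of ``si_drift_per_day`` per 24 h, and a lognormal
    patient-level baseline around the group median (scaled by
    ``nonsurvivor_si_multiplier`` for non-survivors).
    """
    H = int(config.horizon_hours)
    level = config.si_level_median
    if group == "non-survivor":
        level = level * config.nonsurvivor_si_multiplier
    elif group != "survivor":
        raise ModelInputError(f"unknown group {group!r}")
    log_si = np.empty(H)
    log_si[0] = np.log(level) + config.patient_level_sd * rng.standard_normal()
    drift = np.log(config.si_drift_per_day) / 24.0
    sds = np.interp(np.arange(1, H), [0.0, 72.0],
                    [config.delta_si_sd_start, config.delta_si_sd_end])
    steps = drift + sds * rng.standard_normal(H - 1)
    log_si[1:] = log_si[0] + np.cumsum(steps)
    return np.clip(np.exp(log_si), config.si_bounds[0], config.si_bounds[1])


def _quantise(x: float, step: float) -> float:
    return round(x / step) * step


def stylized_controller(bg_history: Sequence[float], insulin_u_h: float,
                        feed_frac: float, cfg: ControllerConfig) -> tuple[float, float]:
    """Next-interval (insulin U/h, feed fraction) from measured BG history.

    Deterministic protocol-like rule: insulin rises stepwise with BG above
    the target band and with rising BG inside its upper half, capped;
    feed is cut stepwise under persistent hyperglycaemia and restored when
    control is regained. Outputs are quantised to protocol-like steps.
    """
    if len(bg_history) == 0:
        raise ModelInputError("controller needs at least one BG value")
    bg = float(bg_history[-1])
    prev = float(bg_history[-2]) if len(bg_history) > 1 else bg
    u, f = float(insulin_u_h), float(feed_frac)

    if bg < cfg.severe_hypo:
        u = 0.0
        f = min(1.0, f + 2 * cfg.feed_step)
    elif bg < cfg.target_lo:
        u = max(0.0, u - 2 * cfg.insulin_step)
        f = min(1.0, f + cfg.feed_step)
    elif bg <= cfg.target_hi:
        rising = (bg - prev) > cfg.rise_threshold
        falling = (prev - bg) > cfg.rise_threshold
        if bg > 6.5 and rising:
            u = min(cfg.insulin_cap, u + cfg.insulin_step)
        elif bg < 5.0 and falling:
            u = max(0.0, u - cfg.insulin_step)
        if bg < 7.0:
            f = min(1.0, f + cfg.feed_step)
    else:
        step = 2 * cfg.insulin_step if bg > 10.0 else cfg.insulin_step
        u = min(cfg.insulin_cap, u + step)
        if prev > cfg.target_hi:
            f = max(cfg.feed_frac_min, f - cfg.feed_step)

    u = min(cfg.insulin_cap, max(0.0, _quantise(u, cfg.insulin_step)))
    f = min(1.0, max(cfg.feed_frac_min if bg > cfg.target_hi else 0.0,
                     _quantise(f, cfg.feed_step)))
    return u, f


def _truncated_normal(rng: np.random.Generator, bound: float = 3.0) -> float:
    z = rng.standard_normal()
    while abs(z) > bound:
        z = rng.standard_normal()
    return z


def generate_patient(config: CohortConfig, group: str, rng: np.random.Generator,
                     patient_id: str,
                     params: IcingParameters | None = None
                     ) -> tuple[PatientRecord, np.ndarray]:
    """Closed-loop simulation of one virtual patient.

    Returns the clinical-style record (noisy BG at the measurement interval,
    protocol insulin/feed schedules, lognormal length-of-stay truncation) and
    the true hourly SI trajectory over the covered hours.
    """
    params = params if params is not None else IcingParameters.defaults()
    ctrl = config.controller
    truth = sample_si_trajectory(config, group, rng)
    si_traj = SITrajectory(truth, start_hour=0)

    los_h = max(config.los_min_hours,
                float(rng.lognormal(np.log(config.los_median_hours), config.los_log_sd)))
    horizon_min = min(config.horizon_hours, los_h) * 60.0
    n_intervals = int(np.floor(horizon_min / config.measurement_interval))
    if n_intervals < 1:
        raise ModelInputError("length of stay shorter than one measurement interval")

    therapy_start = float(rng.uniform(0.0, config.therapy_start_max_min))
    G0 = float(np.clip(rng.lognormal(np.log(config.init_bg_median),
                                     config.init_bg_log_sd), 4.0, 15.0))
    I0, Q0 = basal_insulin_state(params, G0)

    err = config.bg_error_sd / 100.0
    meas_times, meas_values = [], []
    ins_times, ins_rates = [], []
    feed_times, feed_rates = [], []

    def measure(t_rel: float, G: float) -> float:
        noisy = G * (1.0 + err * _truncated_normal(rng)) if err > 0 else G
        noisy = max(noisy, 0.1)  # meters never report non-positive BG
        meas_times.append(therapy_start + t_rel)
        meas_values.append(noisy)
        return noisy

    u, f = ctrl.start_insulin, ctrl.feed_frac_start
    state = np.array([G0, I0, Q0])
    t_rel = 0.0
    measure(0.0, G0)
    for k in range(n_intervals):
        u, f = stylized_controller(meas_values, u, f, ctrl)
        ins_times.append(therapy_start + t_rel)
        ins_rates.append(u)
        feed_times.append(therapy_start + t_rel)
        feed_rates.append(f * ctrl.feed_base_g_h)

        schedule = InputSchedule(
            u_ex=PiecewiseConstant.constant(u * 1000.0 / 60.0, start=t_rel),
            P=PiecewiseConstant.constant(f * ctrl.feed_base_g_h * (1000.0 / 180.156) / 60.0,
                                         start=t_rel))
        t_next = t_rel + config.measurement_interval
        traj = simulate(ModelState(G=state[0], I=state[1], Q=state[2], t=t_rel),
                        params, si_traj, schedule,
                        horizon=config.measurement_interval,
                        output_grid=np.array([t_next]))
        state = traj[["G", "I", "Q"]].iloc[-1].to_numpy()
        t_rel = t_next
        measure(t_rel, float(state[0]))

    covered_hours = int(np.floor(t_rel / 60.0))
    record = PatientRecord(
        patient_id=patient_id, outcome=group,
        admission_time=0.0, therapy_start=therapy_start,
        bg_times=np.asarray(meas_times), bg_values=np.asarray(meas_values),
        insulin_times=np.asarray(ins_times), insulin_rates=np.asarray(ins_rates),
        nutrition_times=np.asarray(feed_times), nutrition_rates=np.asarray(feed_rates),
    )
    return record, truth[:max(covered_hours, 1)]


@dataclass
class SyntheticCohort:
    """Generated records plus the ground-truth SI table for recovery tests."""

    records: list[PatientRecord]
    truth: pd.DataFrame          # patient_id, hour, true_si
    config: CohortConfig

    @property
    def outcomes(self) -> dict[str, str]:
        return {r.patient_id: r.outcome for r in self.records}

    def save(self, out_dir: str | Path) -> None:
        from .records import write_records_csv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records_csv(self.records, out / "cohort_data.csv", out / "cohort_meta.csv")
        self.truth.to_csv(out / "cohort_truth.csv", index=False, float_format="%.10g")
        (out / "cohort_config.json").write_text(
            json.dumps(self.config.to_dict(), indent=2, sort_keys=True) + "\n")


def generate_cohort(config: CohortConfig,
                    params: IcingParameters | None = None) -> SyntheticCohort:
    """Generate the configured cohort, reproducibly under ``config.seed``.

    Each patient draws from an independent child of the cohort seed, so the
    cohort is reproducible and insensitive to generation order.
    """
    params = params if params is not None else IcingParameters.defaults()
    n_total = config.n_survivors + config.n_nonsurvivors
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    records, truth_rows = [], []
    specs = ([("survivor", f"S{i + 1:03d}") for i in range(config.n_survivors)]
             + [("non-survivor", f"N{i + 1:03d}") for i in range(config.n_nonsurvivors)])
    for (group, pid), child in zip(specs, children):
        rng = np.random.default_rng(child)
        record, truth = generate_patient(config, group, rng, pid, params=params)
        records.append(record)
        truth_rows.extend((pid, h, si) for h, si in enumerate(truth))
    truth_df = pd.DataFrame(truth_rows, columns=["patient_id", "hour", "true_si"])
    return SyntheticCohort(records=records, truth=truth_df, config=config)
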