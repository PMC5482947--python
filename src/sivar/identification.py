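"""Hourly insulin-sensitivity identification by the integral method.

The insulin compartments (I, Q) of the glucose-insulin model are independent
of SI, so they can be simulated once from the recorded insulin schedule with
endogenous secretion evaluated on interpolated blood glucose. Integrating the
glucose equation over one hour then leaves SI linear, with the closed-form
solution

    SI_h = [ -dG_h - p_G * int(G) + int((P + EGP - CNS)/V_G) ]
           / int( G * Q / (1 + alpha_G * Q) )

where all integrals run over the hour [h, h+1) (therapy-start-anchored,
half-open), dG_h is the change in interpolated G across the hour boundaries,
and the integrals are composite trapezoids on a 1-minute grid.

Negative solutions (possible under measurement noise) are clamped to a small
positive floor and flagged; hours with no effective insulin exposure are
flagged unidentifiable. Hours only partially covered by BG data are dropped,
never extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .icing import IcingParameters, ModelInputError
from .records import PatientRecord

#: default clamp floor for identified SI (L/mU/min)
SI_MIN_DEFAULT = 1e-8

#: absolute threshold on the insulin-exposure integral below which the hour
#: carries no SI information (mmol*min scale of the denominator integral)
DENOMINATOR_EPS = 1e-6

FLAG_OK = "ok"
FLAG_CLAMPED = "clamped"
FLAG_UNIDENTIFIABLE = "unidentifiable"


def interpolate_bg(bg_times: np.ndarray, bg_values: np.ndarray,
                   grid: np.ndarray) -> np.ndarray:
    """Piecewise-linear BG interpolant evaluated on ``grid`` (minutes).

    Exact at measurement times; raises if the grid leaves the measured span.
    """
    t = np.asarray(bg_times, float)
    v = np.asarray(bg_values, float)
    g = np.asarray(grid, float)
    if t.size < 2:
        raise ModelInputError("need >= 2 BG measurements to interpolate")
    if g.size and (g.min() < t[0] - 1e-9 or g.max() > t[-1] + 1e-9):
        raise ModelInputError(
            f"interpolation grid [{g.min():.3f}, {g.max():.3f}] outside "
            f"measured span [{t[0]:.3f}, {t[-1]:.3f}]")
    return np.interp(g, t, v)


def basal_insulin_state(params: IcingParameters, G0: float) -> tuple[float, float]:
    """Steady (I, Q) under endogenous secretion only (no exogenous insulin).

    Used as the identification (and simulation) initial condition: before
    therapy starts the patient is assumed at the secretion-driven equilibrium.
    """
    u0 = (1.0 - params.x_L) * params.u_en(G0) / params.V_I
    if u0 <= 0:
        return 0.0, 0.0

    def q_of_i(I: float) -> float:
        a = params.n_I * params.alpha_G
        b = params.n_I + params.n_C - params.n_I * params.alpha_G * I
        c = -params.n_I * I
        return (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)

    def f(I: float) -> float:
        Q = q_of_i(I)
        return (-params.n_K * I - params.n_L * I / (1.0 + params.alpha_I * I)
                - params.n_I * (I - Q) + u0)

    hi = 1.0
    while f(hi) > 0 and hi < 1e7:
        hi *= 2.0
    I0 = brentq(f, 0.0, hi, xtol=1e-10, rtol=1e-12)
    return float(I0), float(q_of_i(I0))


def simulate_insulin_compartments(record: PatientRecord,
                                  params: IcingParameters,
                                  grid: np.ndarray,
                                  G_interp: np.ndarray,
                                  init: tuple[float, float] | None = None,
                                  substep: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Simulate I(t), Q(t) on ``grid`` (minutes, absolute clock), SI-free.

    The insulin subsystem is driven by the recorded exogenous schedule and by
    endogenous secretion evaluated on the *interpolated* BG, keeping the
    subsequent SI solve linear. Fixed-step RK4 with ``substep``-minute steps.
    """
    grid = np.asarray(grid, float)
    if grid.size < 2:
        raise ModelInputError("grid must have >= 2 points")
    u_ex_sched = record.input_schedule().u_ex
    n_sub = max(1, int(round((grid[1] - grid[0]) / substep)))
    dt = (grid[1] - grid[0]) / n_sub

    # BG at RK4 stage resolution (stages at 0, dt/2, dt within each substep)
    fine_t = np.linspace(grid[0], grid[-1], (grid.size - 1) * n_sub * 2 + 1)
    fine_G = np.interp(fine_t, grid, G_interp)
    u_en_fine = params.u_en(fine_G) if params.u_en_active else np.zeros_like(fine_G)
    en_rate = (1.0 - params.x_L) / params.V_I * u_en_fine
    # exogenous rate constant on each substep; evaluate at substep midpoints
    mid_t = fine_t[1::2]
    u_rate = u_ex_sched.rate_at(np.maximum(mid_t, u_ex_sched.times[0])) / params.V_I

    n_K, n_L, n_I, n_C = params.n_K, params.n_L, params.n_I, params.n_C
    a_I, a_G = params.alpha_I, params.alpha_G
    nk_sign = 1.0 if params.printed_nk_sign else -1.0

    if init is None:
        init = basal_insulin_state(params, float(G_interp[0]))
    I, Q = float(init[0]), float(init[1])
    out_I = np.empty(grid.size)
    out_Q = np.empty(grid.size)
    out_I[0], out_Q[0] = I, Q

    def rhs(I, Q, u_in):
        dI = (nk_sign * n_K * I - n_L * I / (1.0 + a_I * I)
              - n_I * (I - Q) + u_in)
        dQ = n_I * (I - Q) - n_C * Q / (1.0 + a_G * Q)
        return dI, dQ

    k = 0  # index into fine arrays, advances by 2 per substep
    for j in range(grid.size - 1):
        for _ in range(n_sub):
            u0 = u_rate[k // 2] + en_rate[k]
            um = u_rate[k // 2] + en_rate[k + 1]
            u1 = u_rate[k // 2] + en_rate[k + 2]
            k1I, k1Q = rhs(I, Q, u0)
            k2I, k2Q = rhs(I + 0.5 * dt * k1I, Q + 0.5 * dt * k1Q, um)
            k3I, k3Q = rhs(I + 0.5 * dt * k2I, Q + 0.5 * dt * k2Q, um)
            k4I, k4Q = rhs(I + dt * k3I, Q + dt * k3Q, u1)
            I += dt / 6.0 * (k1I + 2 * k2I + 2 * k3I + k4I)
            Q += dt / 6.0 * (k1Q + 2 * k2Q + 2 * k3Q + k4Q)
            k += 2
        I = max(I, 0.0)
        Q = max(Q, 0.0)
        out_I[j + 1], out_Q[j + 1] = I, Q
    return out_I, out_Q


@dataclass
class _FitArrays:
    """Shared per-record precomputation for the hourly solves."""

    hours: np.ndarray            # candidate hour indices with full BG coverage
    grid: np.ndarray             # 1-min grid, absolute minutes
    G: np.ndarray
    I: np.ndarray
    Q: np.ndarray
    cum_G: np.ndarray            # cumulative cell integrals, leading zero
    cum_src: np.ndarray
    cum_den: np.ndarray
    idx_of_hour: dict


class InsulinSensitivityModel:
    """Identifies an hourly SI profile from one patient's record.

    Parameters
    ----------
    record : PatientRecord
        BG/insulin/nutrition time series in clinical units.
    params : IcingParameters, optional
        Model constants; packaged defaults when omitted.
    si_min : float
        Clamp floor for negative identified SI (L/mU/min).
    grid_step : float
        Integration grid spacing in minutes for the hourly integrals.

    ``fit`` returns :class:`SIProfileResults` carrying the hourly estimates,
    validity flags, the %-change series and a summary table.
    """

    def __init__(self, record: PatientRecord, params: IcingParameters | None = None,
                 si_min: float = SI_MIN_DEFAULT, grid_step: float = 1.0):
        self.record = record
        self.params = params if params is not None else IcingParameters.defaults()
        self.si_min = float(si_min)
        self.grid_step = float(grid_step)
        if record.bg_times.size < 2:
            raise ModelInputError(
                f"patient {record.patient_id}: fewer than 2 BG measurements")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, meta: pd.DataFrame,
                       patient_id: str | None = None, **kwargs) -> "InsulinSensitivityModel":
        """Build from long-format data and metadata frames (CSV dialect)."""
        from .records import frames_to_records

        records = frames_to_records(data, meta)
        if patient_id is not None:
            records = [r for r in records if r.patient_id == str(patient_id)]
        if len(records) != 1:
            raise ModelInputError(
                "from_dataframe needs exactly one patient; pass patient_id")
        return cls(records[0], **kwargs)

    # -- internals ----------------------------------------------------------
    def _prepare(self, horizon_hours: int) -> _FitArrays | None:
        rec, p = self.record, self.params
        t0 = rec.therapy_start
        lo_rel = max(0.0, rec.bg_times[0] - t0)
        hi_rel = min(horizon_hours * 60.0, rec.bg_times[-1] - t0)
        first_hour = int(np.ceil(lo_rel / 60.0 - 1e-9))
        last_hour = int(np.floor(hi_rel / 60.0 + 1e-9))  # exclusive upper hour boundary
        if last_hour - first_hour < 1:
            return None
        hours = np.arange(first_hour, last_hour)

        grid = t0 + np.arange(first_hour * 60.0, last_hour * 60.0 + 0.5 * self.grid_step,
                              self.grid_step)
        G = interpolate_bg(rec.bg_times, rec.bg_values, grid)
        I, Q = simulate_insulin_compartments(rec, p, grid, G)

        sched = rec.input_schedule()
        mid = 0.5 * (grid[:-1] + grid[1:])
        P_mid = sched.P.rate_at(np.maximum(mid, sched.P.times[0]))
        dt = np.diff(grid)
        cell_G = 0.5 * (G[:-1] + G[1:]) * dt
        cell_src = (P_mid + p.EGP - p.CNS) / p.V_G * dt
        den_pt = G * Q / (1.0 + p.alpha_G * Q)
        cell_den = 0.5 * (den_pt[:-1] + den_pt[1:]) * dt

        zero = np.zeros(1)
        cum_G = np.concatenate([zero, np.cumsum(cell_G)])
        cum_src = np.concatenate([zero, np.cumsum(cell_src)])
        cum_den = np.concatenate([zero, np.cumsum(cell_den)])
        per_hour = int(round(60.0 / self.grid_step))
        idx_of_hour = {h: (h - first_hour) * per_hour for h in range(first_hour, last_hour + 1)}
        return _FitArrays(hours, grid, G, I, Q, cum_G, cum_src, cum_den, idx_of_hour)

    def _solve_hour(self, arrays: _FitArrays, hour: int) -> tuple[float | None, str]:
        p = self.params
        i0 = arrays.idx_of_hour[hour]
        i1 = arrays.idx_of_hour[hour + 1]
        dG = arrays.G[i1] - arrays.G[i0]
        num = (-dG - p.p_G * (arrays.cum_G[i1] - arrays.cum_G[i0])
               + (arrays.cum_src[i1] - arrays.cum_src[i0]))
        den = arrays.cum_den[i1] - arrays.cum_den[i0]
        if den < DENOMINATOR_EPS:
            return None, FLAG_UNIDENTIFIABLE
        si = num / den
        if si < self.si_min:
            return self.si_min, FLAG_CLAMPED
        return float(si), FLAG_OK

    # -- public API ---------------------------------------------------------
    def fit(self, horizon_hours: int = 72) -> "SIProfileResults":
        """Identify SI for each fully BG-covered hour in [0, horizon_hours)."""
        arrays = self._prepare(int(horizon_hours))
        hours, si, flags = [], [], []
        if arrays is not None:
            for h in arrays.hours:
                value, flag = self._solve_hour(arrays, int(h))
                if value is None:
                    continue  # unidentifiable hours carry no value
                hours.append(int(h))
                si.append(value)
                flags.append(flag)
        return SIProfileResults(
            patient_id=self.record.patient_id,
            hours=np.asarray(hours, int),
            si=np.asarray(si, float),
            flags=np.asarray(flags, object),
            si_min=self.si_min,
            params=self.params,
            model=self,
        )


def fit_si_hour(record: PatientRecord, params: IcingParameters | None = None,
                hour: int = 0, si_min: float = SI_MIN_DEFAULT,
                grid_step: float = 1.0) -> tuple[float | None, str]:
    """Closed-form SI for one hour; ``(None, 'unidentifiable')`` when the
    insulin-exposure integral vanishes."""
    model = InsulinSensitivityModel(record, params, si_min=si_min, grid_step=grid_step)
    arrays = model._prepare(hour + 1)
    if arrays is None or hour not in arrays.hours:
        raise ModelInputError(
            f"patient {record.patient_id}: hour {hour} not fully covered by BG data")
    return model._solve_hour(arrays, hour)


def fit_si_profile(record: PatientRecord, params: IcingParameters | None = None,
                   horizon_hours: int = 72, si_min: float = SI_MIN_DEFAULT,
                   grid_step: float = 1.0) -> "SIProfileResults":
    return InsulinSensitivityModel(record, params, si_min=si_min,
                                   grid_step=grid_step).fit(horizon_hours)


@dataclass
class SIProfileResults:
    """Hourly identified SI trajectory with validity flags.

    ``hours`` are 0-based from therapy start; hours without BG coverage are
    absent, not imputed. ``flags`` per hour: ok | clamped.
    """

    patient_id: str
    hours: np.ndarray
    si: np.ndarray
    flags: np.ndarray
    si_min: float
    params: IcingParameters
    model: InsulinSensitivityModel | None = None

    @property
    def nobs(self) -> int:
        return int(self.hours.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"patient_id": self.patient_id, "hour": self.hours,
                             "si": self.si, "flag": self.flags})

    def delta_si(self) -> pd.DataFrame:
        """Forward hour-to-hour percent change, 100*(SI_{i+1}-SI_i)/SI_i.

        Defined only for consecutive hour pairs where both values exist
        (ok or clamped) and SI_i > 0. ``from_clamped`` marks pairs touching
        a clamped hour, retained but flagged for sensitivity analysis.
        """
        rows = []
        pos = {int(h): j for j, h in enumerate(self.hours)}
        for j, h in enumerate(self.hours):
            nxt = pos.get(int(h) + 1)
            if nxt is None or self.si[j] <= 0:
                continue
            pct = 100.0 * (self.si[nxt] - self.si[j]) / self.si[j]
            clamped = (self.flags[j] == FLAG_CLAMPED) or (self.flags[nxt] == FLAG_CLAMPED)
            rows.append((self.patient_id, int(h), pct, bool(clamped)))
        return pd.DataFrame(rows, columns=["patient_id", "hour", "delta_si_pct",
                                           "from_clamped"])

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Insulin Sensitivity Profile",
            "===========================",
            f"patient:        {self.patient_id}",
            f"hours fitted:   {self.nobs}",
            f"flag counts:    ok={int((self.flags == FLAG_OK).sum())}, "
            f"clamped={int((self.flags == FLAG_CLAMPED).sum())}",
        ]
        if self.nobs:
            q = np.percentile(self.si, [25, 50, 75])
            lines.append(
                f"SI median [IQR]: {q[1]:.3e} [{q[0]:.3e}, {q[2]:.3e}] L/mU/min")
            d = self.delta_si()
            if len(d):
                qd = np.percentile(d["delta_si_pct"], [25, 50, 75])
                lines.append(
                    f"%dSI median [IQR]: {qd[1]:+.1f} [{qd[0]:+.1f}, {qd[2]:+.1f}] %")
        return "\n".join(lines)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def profiles_to_frame(results: Sequence[SIProfileResults]) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(columns=["patient_id", "hour", "si", "flag"])
    return pd.concat([r.to_frame() for r in results], ignore_index=True)
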