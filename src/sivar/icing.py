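"""ICING glucose-insulin compartment model and its forward simulation.

The model tracks blood glucose G (mmol/L), plasma insulin I (mU/L) and
interstitial insulin Q (mU/L) in a critically ill adult:

    dG/dt = -p_G*G - SI*G*Q/(1 + alpha_G*Q) + (P(t) + EGP - CNS)/V_G
    dI/dt = -n_K*I - n_L*I/(1 + alpha_I*I) - n_I*(I - Q)
            + u_ex(t)/V_I + (1 - x_L)*u_en(G)/V_I
    dQ/dt =  n_I*(I - Q) - n_C*Q/(1 + alpha_G*Q)

SI (L/mU/min) is the patient-specific, time-varying insulin sensitivity;
u_ex is the exogenous insulin infusion (mU/min) and P the glucose appearance
from enteral/parenteral carbohydrate (mmol/min), both piecewise constant.
Endogenous secretion u_en(G) is a bounded, non-decreasing function of G.

All times are minutes; hour indices are 0-based half-open [h, h+1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp


class ModelInputError(ValueError):
    """Raised when a model state, parameter or schedule is invalid."""


_RATE_FIELDS = ("p_G", "alpha_G", "alpha_I", "n_K", "n_L", "n_I", "n_C",
                "V_G", "V_I")


@dataclass(frozen=True)
class IcingParameters:
    """Rate/volume constants of the glucose-insulin model.

    Endogenous secretion is a saturating linear function of G:
    ``u_en(G) = clip(u_en_k1*G + u_en_k2, u_en_min, u_en_max)`` (mU/min),
    or identically zero when ``u_en_active`` is False (suppressed secretion,
    e.g. C-peptide-suppressed patients).

    ``printed_nk_sign`` is an audit flag: when True the renal clearance term
    enters dI/dt with a positive sign as printed in some sources; the default
    treats n_K*I as a clearance (loss).
    """

    p_G: float = 0.006          # endogenous glucose clearance (1/min)
    alpha_G: float = 0.0154     # insulin-effect saturation (L/mU)
    alpha_I: float = 0.0017     # hepatic-clearance saturation (L/mU)
    n_K: float = 0.0542         # renal insulin clearance (1/min)
    n_L: float = 0.1578         # hepatic insulin clearance (1/min)
    n_I: float = 0.006          # plasma-interstitium transfer (1/min)
    n_C: float = 0.006          # interstitial insulin degradation (1/min)
    x_L: float = 0.67           # first-pass hepatic extraction (-)
    V_G: float = 13.3           # glucose distribution volume (L)
    V_I: float = 4.0            # insulin distribution volume (L)
    EGP: float = 1.16           # endogenous glucose production (mmol/min)
    CNS: float = 0.3            # CNS glucose uptake (mmol/min)
    u_en_k1: float = 14.9       # secretion slope (mU/min per mmol/L)
    u_en_k2: float = -49.9      # secretion intercept (mU/min)
    u_en_min: float = 16.7      # basal secretion floor (mU/min)
    u_en_max: float = 266.7     # secretion cap (mU/min)
    u_en_active: bool = True
    printed_nk_sign: bool = False

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ModelInputError(f"parameter {name} must be finite and > 0, got {v!r}")
        for name in ("EGP", "CNS", "u_en_min", "u_en_max"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ModelInputError(f"parameter {name} must be finite and >= 0, got {v!r}")
        if not (0.0 <= self.x_L < 1.0):
            raise ModelInputError(f"parameter x_L must lie in [0, 1), got {self.x_L!r}")
        if self.u_en_max < self.u_en_min:
            raise ModelInputError("u_en_max must be >= u_en_min")

    def u_en(self, G):
        """Endogenous insulin secretion (mU/min) at blood glucose G."""
        if not self.u_en_active:
            return np.zeros_like(np.asarray(G, dtype=float)) if np.ndim(G) else 0.0
        raw = self.u_en_k1 * np.asarray(G, dtype=float) + self.u_en_k2
        out = np.clip(raw, self.u_en_min, self.u_en_max)
        return float(out) if np.ndim(G) == 0 else out

    def replace(self, **changes) -> "IcingParameters":
        return replace(self, **changes)

    @classmethod
    def defaults(cls) -> "IcingParameters":
        """Load the packaged, versioned defaults file."""
        ref = resources.files("sivar._defaults").joinpath("icing_params.json")
        payload = json.loads(ref.read_text())
        return cls(**{k: v for k, v in payload.items() if not k.startswith("_")})

    @classmethod
    def from_file(cls, path: str | Path) -> "IcingParameters":
        """Read parameters from a JSON or YAML mapping of field names."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known - {k for k in payload if k.startswith("_")}
        if unknown:
            raise ModelInputError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**{k: v for k, v in payload.items() if not k.startswith("_")})


@dataclass(frozen=True)
class ModelState:
    """Instantaneous model state (G mmol/L, I and Q mU/L, t min)."""

    G: float
    I: float
    Q: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("G", "I", "Q", "t"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ModelInputError(f"state field {name} must be finite, got {v!r}")
        for name in ("G", "I", "Q"):
            if getattr(self, name) < 0:
                raise ModelInputError(f"state field {name} must be >= 0")

    @property
    def y(self) -> np.ndarray:
        return np.array([self.G, self.I, self.Q], dtype=float)


@dataclass(frozen=True)
class PiecewiseConstant:
    """Right-open step function: value ``values[i]`` holds on [times[i], times[i+1]).

    The final value extends to +inf so a schedule whose last step starts
    before the horizon covers it.
    """

    times: np.ndarray
    values: np.ndarray

    def __init__(self, times: Sequence[float], values: Sequence[float]):
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size == 0:
            raise ModelInputError("times and values must be equal-length 1-D, non-empty")
        if np.any(np.diff(t) <= 0):
            raise ModelInputError("step times must be strictly increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise ModelInputError("schedule entries must be finite")
        if np.any(v < 0):
            raise ModelInputError("schedule rates must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def rate_at(self, t) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.times[0]):
            raise ModelInputError(
                f"schedule starts at t={self.times[0]} and does not cover t={np.min(t_arr)}")
        idx = np.searchsorted(self.times, t_arr, side="right") - 1
        out = self.values[idx]
        return float(out) if np.ndim(t) == 0 else out

    def breakpoints_in(self, t0: float, t1: float) -> np.ndarray:
        m = (self.times > t0) & (self.times < t1)
        return self.times[m]

    @classmethod
    def constant(cls, value: float, start: float = 0.0) -> "PiecewiseConstant":
        return cls([start], [value])


@dataclass(frozen=True)
class InputSchedule:
    """Exogenous insulin u_ex (mU/min) and glucose appearance P (mmol/min)."""

    u_ex: PiecewiseConstant
    P: PiecewiseConstant

    def breakpoints_in(self, t0: float, t1: float) -> np.ndarray:
        return np.union1d(self.u_ex.breakpoints_in(t0, t1),
                          self.P.breakpoints_in(t0, t1))


@dataclass(frozen=True)
class SITrajectory:
    """Hourly piecewise-constant SI (L/mU/min), value i on [start+i, start+i+1) hours."""

    values: np.ndarray
    start_hour: int = 0

    def __init__(self, values: Sequence[float], start_hour: int = 0):
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ModelInputError("SI trajectory must be 1-D and non-empty")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ModelInputError("SI values must be finite and >= 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "start_hour", int(start_hour))

    @classmethod
    def constant(cls, si: float, hours: int = 1, start_hour: int = 0) -> "SITrajectory":
        return cls(np.full(int(hours), float(si)), start_hour)

    @property
    def end_hour(self) -> int:
        return self.start_hour + self.values.size

    def value_at(self, t_min) -> np.ndarray | float:
        t_arr = np.asarray(t_min, dtype=float)
        h = np.floor(t_arr / 60.0).astype(int)
        # the trajectory end boundary itself is admitted (closed horizon end)
        h = np.where(np.isclose(t_arr, self.end_hour * 60.0), self.end_hour - 1, h)
        if np.any(h < self.start_hour) or np.any(h >= self.end_hour):
            raise ModelInputError("time outside SI trajectory coverage")
        out = self.values[h - self.start_hour]
        return float(out) if np.ndim(t_min) == 0 else out

    def breakpoints_in(self, t0: float, t1: float) -> np.ndarray:
        b = 60.0 * np.arange(self.start_hour, self.end_hour + 1)
        return b[(b > t0) & (b < t1)]


def ode_rhs(state, params: IcingParameters, si: float, u_ex: float, P: float):
    """Time derivatives (dG, dI, dQ) of the model at one instant.

    ``state`` may be a ModelState or a (G, I, Q) triple. All insulin
    clearance terms act as losses on I unless ``params.printed_nk_sign``.
    """
    if isinstance(state, ModelState):
        G, I, Q = state.G, state.I, state.Q
    else:
        G, I, Q = (float(x) for x in state)
        for name, v in (("G", G), ("I", I), ("Q", Q)):
            if not np.isfinite(v):
                raise ModelInputError(f"state field {name} must be finite, got {v!r}")
    if not np.isfinite(si) or si < 0:
        raise ModelInputError(f"si must be finite and >= 0, got {si!r}")
    if not np.isfinite(u_ex) or not np.isfinite(P):
        raise ModelInputError("inputs u_ex and P must be finite")

    q_sat = Q / (1.0 + params.alpha_G * Q)
    dG = (-params.p_G * G - si * G * q_sat
          + (P + params.EGP - params.CNS) / params.V_G)
    nk_term = params.n_K * I if params.printed_nk_sign else -params.n_K * I
    dI = (nk_term - params.n_L * I / (1.0 + params.alpha_I * I)
          - params.n_I * (I - Q) + u_ex / params.V_I
          + (1.0 - params.x_L) * params.u_en(G) / params.V_I)
    dQ = params.n_I * (I - Q) - params.n_C * q_sat
    return dG, dI, dQ


class SimulationError(RuntimeError):
    """Solver failure or state blow-up; carries the failure time."""

    def __init__(self, message: str, t: float):
        super().__init__(f"{message} (at t={t:.2f} min)")
        self.t = t


def simulate(init: ModelState,
             params: IcingParameters,
             si_traj: SITrajectory | float,
             schedule: InputSchedule,
             horizon: float,
             output_grid: Sequence[float] | float = 1.0,
             method: str = "LSODA",
             rtol: float = 1e-6,
             atol: float = 1e-8) -> pd.DataFrame:
    """Integrate the model forward from ``init.t`` for ``horizon`` minutes.

    Integration restarts at every input/SI discontinuity so piecewise-constant
    steps are honoured exactly. ``output_grid`` is either a step in minutes or
    an explicit array of output times. Returns a DataFrame with columns
    time_min, G, I, Q; tiny negative excursions are clamped to 0 on output.
    """
    t0 = float(init.t)
    t1 = t0 + float(horizon)
    if horizon <= 0:
        raise ModelInputError("horizon must be > 0")
    if np.isscalar(output_grid):
        grid = np.arange(t0, t1 + 0.5 * float(output_grid), float(output_grid))
        grid = np.clip(grid, t0, t1)
    else:
        grid = np.asarray(output_grid, dtype=float)
        if np.any(grid < t0) or np.any(grid > t1):
            raise ModelInputError("output grid outside simulation horizon")
    if isinstance(si_traj, (int, float)):
        si_traj = SITrajectory.constant(float(si_traj),
                                        hours=int(np.ceil(t1 / 60.0)) + 1)

    # validate coverage up front
    schedule.u_ex.rate_at(t0)
    schedule.P.rate_at(t0)
    si_traj.value_at(t0)
    si_traj.value_at(t1)

    cuts = np.concatenate(([t0], schedule.breakpoints_in(t0, t1),
                           si_traj.breakpoints_in(t0, t1), [t1]))
    cuts = np.unique(cuts)

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    y = init.y
    if np.isclose(grid[0], t0):
        times_out.append(np.array([t0]))
        states_out.append(y[None, :])
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a + b)
        si = si_traj.value_at(mid)
        u_ex = schedule.u_ex.rate_at(mid)
        P = schedule.P.rate_at(mid)
        t_eval = grid[(grid > a + 1e-12) & (grid <= b + 1e-12)]
        t_run = np.unique(np.concatenate((t_eval, [b])))
        sol = solve_ivp(lambda t, s: ode_rhs(s, params, si, u_ex, P),
                        (a, b), y, method=method, rtol=rtol, atol=atol,
                        t_eval=t_run, dense_output=False)
        if not sol.success:
            raise SimulationError(f"integration failed: {sol.message}", a)
        if not np.all(np.isfinite(sol.y)) or np.any(np.abs(sol.y) > 1e6):
            raise SimulationError("state blow-up", b)
        keep = np.isin(sol.t, t_eval)
        if t_eval.size:
            times_out.append(sol.t[keep])
            states_out.append(sol.y[:, keep].T)
        y = sol.y[:, -1].copy()
        if np.any(y < -1e-6):
            raise SimulationError("state became negative", b)
        y = np.maximum(y, 0.0)

    t_all = np.concatenate(times_out) if times_out else np.empty(0)
    y_all = np.vstack(states_out) if states_out else np.empty((0, 3))
    y_all = np.maximum(y_all, 0.0)
    return pd.DataFrame({"time_min": t_all, "G": y_all[:, 0],
                         "I": y_all[:, 1], "Q": y_all[:, 2]})


def write_trajectory_csv(traj: pd.DataFrame, path: str | Path) -> None:
    traj.to_csv(path, index=False, float_format="%.10g")
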