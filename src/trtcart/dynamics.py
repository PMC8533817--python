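"""Three-compartment tumor/CAR-T/TRT dynamics.

The model tracks non-irradiated tumor cells ``NT``, lethally irradiated
tumor cells ``NR`` and CAR-T cells ``NC``.  Non-irradiated cells grow
exponentially at net rate ``rho``; CAR-T cells kill tumor cells (either
compartment) with mass-action rate ``k1``, are stimulated to proliferate
or exhaust on tumor contact at rate ``k2`` and die at rate ``theta``.
Targeted radionuclide therapy (TRT) moves cells from the non-irradiated
to the irradiated compartment at a dose-rate-dependent rate derived from
the linear-quadratic model with the Lea-Catcheside protraction factor;
irradiated cells do not proliferate and are cleared at rate ``k_cl``.
CAR-T cells are radiosensitive too (``alpha_C``).

For alpha-particle emitters the quadratic radiosensitivity ``beta`` is
zero and the irradiation rate reduces to ``alpha * R0 * exp(-lam * s)``
where ``s`` is the time since injection and ``R0 = eta * A0`` the initial
dose rate of injected activity ``A0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParameters",
    "TreatmentSchedule",
    "SystemState",
    "Trajectory",
    "initial_dose_rate",
    "irradiation_rate",
    "rhs",
    "apply_cart_bolus",
    "simulate",
    "SimulationError",
]

#: activity unit conversion: 1 uCi = 1000 nCi
NCI_PER_UCI = 1000.0


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails to meet its tolerances."""

    def __init__(self, message: str, t_span: tuple[float, float] | None = None):
        super().__init__(message)
        self.t_span = t_span


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and radiobiology coefficients of the combined model.

    Defaults are the experimentally derived reference values for the
    MM1S multiple-myeloma / CS1 CAR-T / Ac-225 TRT system.

    Parameters
    ----------
    rho : float
        Net tumor proliferation rate, 1/day.
    k1 : float
        CAR-T killing rate, 1/day per CAR-T cell.
    k2 : float
        CAR-T proliferation/exhaustion rate, 1/day per tumor cell.
    theta : float
        CAR-T death rate, 1/day.
    k_cl : float
        Clearance rate of irradiated tumor cells, 1/day.
    lam : float
        Effective radionuclide decay constant (physical decay plus
        biological clearance), 1/day.
    gamma : float or None
        Tissue repair rate, 1/day.  Only enters the quadratic
        (Lea-Catcheside) term and is therefore required only when
        ``beta > 0``.
    alpha_T, alpha_C : float
        Linear radiosensitivity of tumor and CAR-T cells, 1/Gy.
    beta : float
        Quadratic radiosensitivity, 1/Gy^2.  Zero for high-LET
        alpha-particle therapy.
    eta : float
        Activity-to-dose-rate conversion factor, Gy/day per uCi.
    """

    rho: float = 0.27
    k1: float = 4.49e-7
    k2: float = 3.6e-13
    theta: float = 0.042
    k_cl: float = 0.5
    lam: float = 0.07
    gamma: float | None = None
    alpha_T: float = 1.5
    alpha_C: float = 1.5
    beta: float = 0.0
    eta: float = 3.48

    def __post_init__(self) -> None:
        for name in ("rho", "k1", "k2", "theta", "k_cl", "lam",
                     "alpha_T", "alpha_C", "beta", "eta"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name!r} must be finite and >= 0, got {v}")
        if self.beta > 0:
            if self.gamma is None or self.gamma <= 0:
                raise ValueError(
                    "quadratic radiosensitivity beta > 0 requires the tissue "
                    "repair rate 'gamma' (> 0) to be set"
                )
            if self.gamma == self.lam:
                raise ValueError(
                    "gamma == lam hits a removable singularity of the "
                    "protraction factor; perturb gamma slightly"
                )

    def with_updates(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TreatmentSchedule:
    """Timed TRT injections and CAR-T boluses.

    ``trt_administrations`` holds ``(day, activity_uCi)`` pairs and
    ``cart_administrations`` holds ``(day, n_cells)`` pairs, each sorted
    by time.  Activities are stored in uCi; use :meth:`single_trt` with
    ``activity_nci`` for the conventional nCi dosing unit.
    """

    trt_administrations: tuple[tuple[float, float], ...] = ()
    cart_administrations: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        for label, admins in (("trt", self.trt_administrations),
                              ("cart", self.cart_administrations)):
            times = [t for t, _ in admins]
            if any(t < 0 for t in times):
                raise ValueError(f"{label} administration times must be >= 0")
            if any(a < 0 for _, a in admins):
                raise ValueError(f"{label} administration amounts must be >= 0")
            if times != sorted(times):
                raise ValueError(f"{label} administrations must be sorted by time")
        # tuples may arrive as lists from YAML; normalize
        object.__setattr__(self, "trt_administrations",
                           tuple((float(t), float(a)) for t, a in self.trt_administrations))
        object.__setattr__(self, "cart_administrations",
                           tuple((float(t), float(n)) for t, n in self.cart_administrations))

    @classmethod
    def build(cls,
              trt: Sequence[tuple[float, float]] = (),
              cart: Sequence[tuple[float, float]] = (),
              trt_unit: str = "uCi") -> "TreatmentSchedule":
        """Build a schedule; ``trt_unit`` may be ``"uCi"`` or ``"nCi"``."""
        if trt_unit not in ("uCi", "nCi"):
            raise ValueError(f"unknown activity unit {trt_unit!r}")
        scale = 1.0 if trt_unit == "uCi" else 1.0 / NCI_PER_UCI
        return cls(tuple((t, a * scale) for t, a in sorted(trt)),
                   tuple(sorted(cart)))

    @property
    def event_times(self) -> tuple[float, ...]:
        """Sorted unique administration times (integration break points)."""
        times = {t for t, _ in self.trt_administrations}
        times |= {t for t, _ in self.cart_administrations}
        return tuple(sorted(times))

    def cart_bolus_at(self, t: float) -> float:
        """Total CAR-T cells injected exactly at time ``t``."""
        return sum(n for tau, n in self.cart_administrations if tau == t)


@dataclass(frozen=True)
class SystemState:
    """Instantaneous model state: time and the three compartments."""

    t: float
    NT: float
    NR: float = 0.0
    NC: float = 0.0

    def __post_init__(self) -> None:
        if min(self.NT, self.NR, self.NC) < 0:
            raise ValueError("compartment counts must be >= 0")

    @property
    def total_burden(self) -> float:
        """Total tumor burden T = NT + NR."""
        return self.NT + self.NR

    def as_array(self) -> np.ndarray:
        return np.array([self.NT, self.NR, self.NC], dtype=float)


def initial_dose_rate(activity_uci: float, eta: float) -> float:
    """Initial absorbed dose rate R0 = eta * A0, in Gy/day.

    ``activity_uci`` is the injected activity in uCi and ``eta`` the
    activity-to-dose-rate conversion factor in Gy/day/uCi.
    """
    if activity_uci < 0 or eta < 0:
        raise ValueError("activity and eta must be >= 0")
    return eta * activity_uci


def irradiation_rate(s: float | np.ndarray,
                     R0: float,
                     alpha: float,
                     beta: float = 0.0,
                     lam: float = 0.07,
                     gamma: float | None = None) -> float | np.ndarray:
    """Rate at which cells become (lethally) irradiated, 1/day.

    Linear-quadratic rate with the Lea-Catcheside dose-protraction
    correction for an exponentially decaying dose rate::

        k(s) = alpha*R0*exp(-lam*s)
               + (2*beta*R0**2 / ((gamma-lam)*gamma*lam))
                 * (exp(-2*lam*s) - exp(-(lam+gamma)*s))

    ``s`` is the time in days since the governing injection (the dose
    rate is maximal at injection and decays as ``exp(-lam*s)``).  For
    alpha emitters ``beta = 0`` and only the linear term survives.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    s = np.asarray(s, dtype=float) if np.ndim(s) else float(s)
    if np.any(np.asarray(s) < 0):
        raise ValueError("time since administration must be >= 0")
    rate = alpha * R0 * np.exp(-lam * s)
    if beta > 0:
        if gamma is None or gamma <= 0:
            raise ValueError("beta > 0 requires the tissue repair rate 'gamma' (> 0)")
        if gamma == lam:
            raise ValueError("gamma == lam is a removable singularity; not supported")
        coeff = 2.0 * beta * R0 ** 2 / ((gamma - lam) * gamma * lam)
        rate = rate + coeff * (np.exp(-2.0 * lam * s) - np.exp(-(lam + gamma) * s))
    return rate


def _dose_rates(t: float, params: ModelParameters,
                schedule: TreatmentSchedule) -> tuple[float, float]:
    """Summed irradiation rates (tumor, CAR-T) from all past TRT injections."""
    k_t = 0.0
    k_c = 0.0
    for tau, activity in schedule.trt_administrations:
        if t >= tau and activity > 0:
            r0 = initial_dose_rate(activity, params.eta)
            s = t - tau
            k_t += irradiation_rate(s, r0, params.alpha_T, params.beta,
                                    params.lam, params.gamma)
            k_c += irradiation_rate(s, r0, params.alpha_C, params.beta,
                                    params.lam, params.gamma)
    return k_t, k_c


def rhs(t: float,
        y: np.ndarray | Sequence[float],
        params: ModelParameters,
        schedule: TreatmentSchedule) -> np.ndarray:
    """Time derivatives (dNT/dt, dNR/dt, dNC/dt) of the combined model.

    The TRT term is active for ``t >= tau_TRT`` of each injection (the
    Heaviside switch), with the decay clock of each injection's dose rate
    starting at its own injection time.  CAR-T terms need no explicit
    switch: NC is zero until the first bolus.  Inputs are clamped at zero
    so that tiny negative integrator undershoots cannot feed back.
    """
    nt, nr, nc = (max(v, 0.0) for v in y)
    krx_t, krx_c = _dose_rates(t, params, schedule)
    d_nt = params.rho * nt - krx_t * nt - params.k1 * nt * nc
    d_nr = krx_t * nt - params.k1 * nr * nc - params.k_cl * nr
    d_nc = params.k2 * (nt + nr) * nc - krx_c * nc - params.theta * nc
    return np.array([d_nt, d_nr, d_nc])


def apply_cart_bolus(state: SystemState, n_cells: float) -> SystemState:
    """Instantaneous CAR-T administration: NC jumps by ``n_cells``."""
    if n_cells < 0:
        raise ValueError("CAR-T bolus must be >= 0 cells")
    return SystemState(state.t, state.NT, state.NR, state.NC + n_cells)


class Trajectory:
    """Densely evaluable solution of one simulated regimen.

    Wraps the piecewise dense output of the integrator (one piece per
    inter-administration interval, so no piece straddles a therapy
    discontinuity).  Evaluation at arbitrary times within the span
    returns the interpolated, non-negativity-clamped state.
    """

    def __init__(self, segments, admin_times: tuple[float, ...],
                 t_grid: np.ndarray, states: np.ndarray):
        # segments: list of (t0, t1, OdeSolution dense interpolant)
        self._segments = segments
        self.admin_times = admin_times
        self.t = t_grid
        self.states = states  # shape (3, len(t_grid)): NT, NR, NC

    @property
    def t_span(self) -> tuple[float, float]:
        return self._segments[0][0], self._segments[-1][1]

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        """Evaluate (NT, NR, NC) at time(s) ``t``; shape (3,) or (3, n)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.t_span
        if np.any(t_arr < lo - 1e-9) or np.any(t_arr > hi + 1e-9):
            raise ValueError(f"time outside trajectory span [{lo}, {hi}]")
        t_arr = np.clip(t_arr, lo, hi)
        out = np.empty((3, t_arr.size))
        for i, (t0, t1, sol) in enumerate(self._segments):
            last = i == len(self._segments) - 1
            # right-open pieces except the final one, so states at an
            # administration time reflect the post-bolus value
            mask = (t_arr >= t0) & ((t_arr <= t1) if last else (t_arr < t1))
            if mask.any():
                out[:, mask] = sol(t_arr[mask])
        out = np.clip(out, 0.0, None)
        return out[:, 0] if np.ndim(t) == 0 else out

    def total_burden(self, t: float | np.ndarray) -> float | np.ndarray:
        """Total tumor burden NT + NR at time(s) ``t``."""
        y = self(t)
        return y[0] + y[1]

    def state_at(self, t: float) -> SystemState:
        nt, nr, nc = self(t)
        return SystemState(float(t), float(nt), float(nr), float(nc))

    def to_frame(self):
        """Trajectory as a DataFrame (t_days, NT, NR, NC, T_total)."""
        import pandas as pd

        return pd.DataFrame({
            "t_days": self.t,
            "NT": self.states[0],
            "NR": self.states[1],
            "NC": self.states[2],
            "T_total": self.states[0] + self.states[1],
        })


def simulate(params: ModelParameters,
             schedule: TreatmentSchedule,
             initial: SystemState,
             t_end: float,
             rtol: float = 1e-8,
             atol: float = 1e-2,
             grid_step: float = 0.25) -> Trajectory:
    """Integrate the model from ``initial.t`` to ``t_end``.

    Integration is split at every administration time so the stiff
    adaptive solver never steps across a discontinuity; CAR-T boluses
    are applied as state jumps at their administration times.  The
    default tolerances (rtol 1e-8, atol 1e-2 cells) keep threshold
    crossing times stable to well under 0.05 day.
    """
    t0 = initial.t
    if t_end <= t0:
        raise ValueError("t_end must exceed the initial time")
    if schedule.trt_administrations and params.lam <= 0:
        raise ValueError("lam must be > 0 when TRT is administered")
    events = [tau for tau in schedule.event_times if t0 < tau < t_end]
    for tau, _ in schedule.trt_administrations + schedule.cart_administrations:
        if tau >= t_end:
            raise ValueError("all administrations must precede t_end")

    breakpoints = [t0, *events, t_end]
    y = initial.as_array()
    # bolus exactly at the start time
    y[2] += schedule.cart_bolus_at(t0)

    segments = []
    grids = []
    states = []
    for a, b in zip(breakpoints[:-1], breakpoints[1:]):
        sol = solve_ivp(rhs, (a, b), y, args=(params, schedule),
                        method="LSODA", rtol=rtol, atol=atol,
                        dense_output=True)
        if not sol.success:
            raise SimulationError(
                f"integrator failed on [{a}, {b}]: {sol.message}", (a, b))
        segments.append((a, b, sol.sol))
        y = np.clip(sol.y[:, -1], 0.0, None)
        if b < t_end:
            y[2] += schedule.cart_bolus_at(b)
        n = max(2, int(math.ceil((b - a) / grid_step)) + 1)
        tg = np.linspace(a, b, n)
        grids.append(tg if b == t_end else tg[:-1])
        yg = np.clip(sol.sol(tg), 0.0, None)
        states.append(yg if b == t_end else yg[:, :-1])

    t_grid = np.concatenate(grids)
    state_arr = np.concatenate(states, axis=1)
    return Trajectory(segments, tuple(events), t_grid, state_arr)
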