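"""Parameter estimation from longitudinal tumor-burden data.

Calibration follows the experimental workflow of the preclinical study
design the simulator mirrors: untreated control animals are imaged by
bioluminescence (BLI), whose radiance is proportional to tumor-cell
number; the net growth rate ``rho`` comes from a log-linear fit to the
control series; the fitted exponential, anchored at a known inoculum,
converts radiance to absolute cell counts; and the CAR-T kinetic
parameters ``(k1, k2, theta)`` are then fit to the treated-animal burden
curves together with a single day-28 CAR-T:tumor percentage measured by
flow cytometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import linregress

from .dynamics import (ModelParameters, SystemState, Trajectory,
                       TreatmentSchedule, simulate)

__all__ = [
    "BurdenSeries",
    "CalibrationResult",
    "fit_growth_rate",
    "scale_series_to_cells",
    "fit_cart_params",
    "day28_ratio",
]

#: multi-start search boxes for the CAR-T parameter fit (log-uniform)
K1_BOUNDS = (1e-9, 1e-5)
K2_BOUNDS = (1e-15, 1e-10)
THETA_BOUNDS = (1e-3, 1.0)


@dataclass(frozen=True)
class BurdenSeries:
    """Timestamped tumor-burden observations.

    ``observations`` holds ``(day, signal)`` pairs; ``unit`` is either
    ``"radiance"`` (arbitrary BLI units) or ``"cells"``.  ``animal_ids``
    optionally tags each observation; series from several animals may be
    pooled and are averaged (geometric mean per day) before fitting.
    """

    observations: tuple[tuple[float, float], ...]
    unit: str = "radiance"
    animal_ids: tuple | None = None

    def __post_init__(self) -> None:
        obs = tuple((float(d), float(s)) for d, s in self.observations)
        object.__setattr__(self, "observations", obs)
        if any(d < 0 for d, _ in obs):
            raise ValueError("observation days must be >= 0")
        if any(s <= 0 for _, s in obs):
            raise ValueError("signals must be > 0 (log-transformable)")
        if self.unit not in ("radiance", "cells"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.animal_ids is not None:
            if len(self.animal_ids) != len(obs):
                raise ValueError("animal_ids must match observations")
            for aid in set(self.animal_ids):
                days = [d for (d, _), a in zip(obs, self.animal_ids) if a == aid]
                if days != sorted(days) or len(days) != len(set(days)):
                    raise ValueError(
                        f"days must be strictly increasing within animal {aid!r}")

    @property
    def days(self) -> np.ndarray:
        return np.array([d for d, _ in self.observations])

    @property
    def signals(self) -> np.ndarray:
        return np.array([s for _, s in self.observations])

    def averaged(self) -> "BurdenSeries":
        """Geometric-mean signal per day across animals."""
        df = pd.DataFrame({"day": self.days, "log_s": np.log(self.signals)})
        g = df.groupby("day", sort=True)["log_s"].mean()
        return BurdenSeries(tuple(zip(g.index, np.exp(g.values))),
                            unit=self.unit)

    def scaled(self, factor: float) -> "BurdenSeries":
        return replace(self,
                       observations=tuple((d, s * factor)
                                          for d, s in self.observations),
                       unit="cells")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: str | None = None) -> "BurdenSeries":
        """Build from a table with columns animal_id, day, signal[, unit]."""
        if unit is None:
            unit = str(df["unit"].iloc[0]) if "unit" in df else "radiance"
        df = df.sort_values(["animal_id", "day"]) if "animal_id" in df else df.sort_values("day")
        ids = tuple(df["animal_id"]) if "animal_id" in df else None
        return cls(tuple(zip(df["day"], df["signal"])), unit=unit, animal_ids=ids)

    def to_frame(self) -> pd.DataFrame:
        d = {"day": self.days, "signal": self.signals, "unit": self.unit}
        if self.animal_ids is not None:
            d = {"animal_id": list(self.animal_ids), **d}
        return pd.DataFrame(d)


@dataclass
class CalibrationResult:
    """Fit output: point estimates plus diagnostics."""

    estimates: dict
    objective: float
    scale_factor: float | None = None
    residuals: np.ndarray | None = None
    converged: bool = True
    n_starts: int = 0
    start_objectives: list = field(default_factory=list)


def fit_growth_rate(series: BurdenSeries) -> tuple[float, float]:
    """Net exponential growth rate from a burden series.

    Ordinary least squares of log(signal) on day; returns
    ``(rho_per_day, log_intercept)``.  Pooled multi-animal series are
    fit directly (equivalent to fitting the average log signal when the
    day grid is shared).
    """
    days, signals = series.days, series.signals
    if np.unique(days).size < 2:
        raise ValueError("need at least two distinct time points")
    fit = linregress(days, np.log(signals))
    return float(fit.slope), float(fit.intercept)


def scale_series_to_cells(series: BurdenSeries,
                          rho: float | None = None,
                          known_inoculum: float = 5e6,
                          inoculum_day: float = 0.0,
                          anchor_max_day: float | None = None
                          ) -> tuple[BurdenSeries, float]:
    """Convert a radiance series to absolute cell counts.

    The fitted (or supplied) exponential is extrapolated back to the
    inoculation day; the ratio of the known inoculum to the extrapolated
    signal is the radiance-to-cells scale applied to every observation.
    For a treated series only the pre-therapy observations follow the
    untreated exponential, so pass ``anchor_max_day`` (e.g. the therapy
    day) to anchor the back-extrapolation on those points alone.
    Returns ``(scaled_series, scale_factor)``.
    """
    anchor = series
    if anchor_max_day is not None:
        kept = [(i, (d, s)) for i, (d, s) in enumerate(series.observations)
                if d <= anchor_max_day]
        if not kept:
            raise ValueError("no observations at or before anchor_max_day")
        ids = (tuple(series.animal_ids[i] for i, _ in kept)
               if series.animal_ids is not None else None)
        anchor = BurdenSeries(tuple(o for _, o in kept), unit=series.unit,
                              animal_ids=ids)
    if rho is None:
        rho, intercept = fit_growth_rate(anchor)
    else:
        # least-squares intercept of the anchor points at the given slope
        intercept = float(np.mean(np.log(anchor.signals) - rho * anchor.days))
    signal_at_inoculum = math.exp(intercept + rho * inoculum_day)
    if signal_at_inoculum <= 0 or not math.isfinite(signal_at_inoculum):
        raise ValueError("extrapolated signal at the inoculation day is degenerate")
    scale = known_inoculum / signal_at_inoculum
    return series.scaled(scale), scale


def day28_ratio(traj: Trajectory, day: float = 28.0) -> float:
    """CAR-T to tumor-cell percentage at ``day``: 100 * NC / (NT + NR)."""
    nt, nr, nc = traj(day)
    total = nt + nr
    if total <= 0:
        raise ValueError("total tumor burden is zero; ratio undefined")
    return 100.0 * nc / total


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def fit_cart_params(treated: BurdenSeries,
                    day28_ratio_datum: float,
                    rho: float,
                    cart_day: float = 7.0,
                    cart_cells: float = 1e6,
                    initial_burden: float = 5e6,
                    ratio_day: float = 28.0,
                    ratio_weight: float = 1.0,
                    n_starts: int = 16,
                    n_polish: int = 4,
                    seed: int = 0,
                    rtol: float = 1e-6) -> CalibrationResult:
    """Estimate (k1, k2, theta) from treated burden curves.

    Minimizes squared residuals of log total burden at the observation
    days plus one weighted residual matching the day-28 CAR-T:tumor
    fraction on the log-odds scale.  The search runs in log10 parameter
    space over wide bounds: ``n_starts`` log-uniform starting points are
    scored by their initial objective and the best ``n_polish`` are
    refined with bounded least squares; the lowest final objective wins.

    ``rho`` is fixed (from the control fit); the treated schedule is a
    single CAR-T bolus, no TRT.
    """
    if not treated.observations:
        raise ValueError("treated series is empty")
    if not (0.0 < day28_ratio_datum <= 100.0):
        raise ValueError("day-28 ratio must be a percentage in (0, 100]")
    series = treated.averaged() if treated.animal_ids is not None else treated
    if series.unit != "cells":
        raise ValueError("treated series must be scaled to cells first")
    days, cells = series.days, series.signals
    t_end = max(days.max(), ratio_day) + 1.0
    if days.max() <= cart_day:
        raise ValueError("treated series must span the CAR-T administration")
    schedule = TreatmentSchedule.build(cart=[(cart_day, cart_cells)])
    ratio_frac = day28_ratio_datum / 100.0
    # log-odds residual saturates gracefully for 100%
    ratio_target = _logit(min(ratio_frac, 1.0 - 1e-9))

    def residuals(x: np.ndarray) -> np.ndarray:
        k1, k2, theta = 10.0 ** x
        params = ModelParameters(rho=rho, k1=k1, k2=k2, theta=theta)
        traj = simulate(params, schedule, SystemState(0.0, initial_burden),
                        t_end, rtol=rtol, atol=1e-2)
        model_burden = np.clip(traj.total_burden(days), 1e-300, None)
        res = np.log(model_burden) - np.log(cells)
        r = day28_ratio(traj, ratio_day) / 100.0
        r = min(max(r, 1e-12), 1.0 - 1e-9)
        return np.append(res, ratio_weight * (_logit(r) - ratio_target))

    lo = np.log10([K1_BOUNDS[0], K2_BOUNDS[0], THETA_BOUNDS[0]])
    hi = np.log10([K1_BOUNDS[1], K2_BOUNDS[1], THETA_BOUNDS[1]])
    rng = np.random.default_rng(seed)
    starts = lo + rng.random((n_starts, 3)) * (hi - lo)

    scored = []
    for x0 in starts:
        try:
            scored.append((float(np.sum(residuals(x0) ** 2)), x0))
        except Exception:  # noqa: BLE001 - unlucky start, skip
            continue
    if not scored:
        raise RuntimeError("no feasible starting point for the CAR-T fit")
    scored.sort(key=lambda t: t[0])

    best = None
    start_objs = [s for s, _ in scored]
    for _, x0 in scored[:max(1, n_polish)]:
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi),
                                x_scale=1.0, ftol=1e-10, xtol=1e-10)
        except Exception:  # noqa: BLE001
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("CAR-T parameter fit failed from every start")

    k1, k2, theta = (10.0 ** best.x).tolist()
    return CalibrationResult(
        estimates={"k1": k1, "k2": k2, "theta": theta},
        objective=float(2.0 * best.cost),  # sum of squared residuals
        residuals=best.fun,
        converged=bool(best.success),
        n_starts=n_starts,
        start_objectives=start_objs,
    )
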