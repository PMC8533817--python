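"""Synthetic preclinical burden data with BLI-like statistical structure.

The generator emulates the longitudinal readouts the calibration
workflow consumes: per-animal bioluminescence curves for an untreated
control cohort (exponential growth), burden curves for a CAR-T-treated
cohort (model trajectories), and per-animal day-28 CAR-T:tumor
percentage observations standing in for a terminal flow-cytometry
measurement.  Measurement error is multiplicative lognormal — radiance
is strictly positive and spans decades, so noise that is additive on
the log scale is the natural phenomenological choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import BurdenSeries, day28_ratio
from .dynamics import (ModelParameters, SystemState, TreatmentSchedule,
                       simulate)

__all__ = ["NoiseModel", "default_sampling_days",
           "generate_control_series", "generate_treated_series"]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal measurement noise.

    ``sigma`` is the log-scale standard deviation (0.2 by default, a
    typical repeat-measurement spread for whole-animal BLI); identical
    seeds reproduce identical datasets bit-for-bit.
    """

    sigma: float = 0.2
    seed: int = 0
    kind: str = "lognormal"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind != "lognormal":
            raise ValueError("only multiplicative lognormal noise is supported")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_sampling_days(t_max: float = 28.0, cadence: float = 3.0) -> np.ndarray:
    """Imaging-day grid: every ``cadence`` days from day 0 to ``t_max``."""
    return np.arange(0.0, t_max + 0.5 * cadence, cadence)


def _noised(values: np.ndarray, rng: np.random.Generator, sigma: float) -> np.ndarray:
    if sigma == 0:
        return values.copy()
    return values * np.exp(rng.normal(0.0, sigma, size=values.shape))


def generate_control_series(params: ModelParameters | None = None,
                            n_animals: int = 7,
                            days: np.ndarray | None = None,
                            noise: NoiseModel | None = None,
                            initial_burden: float = 5e6,
                            radiance_per_cell: float = 1.0) -> BurdenSeries:
    """Untreated-cohort burden series: noisy exponential growth.

    Each animal's signal is ``N0 * exp(rho * day)`` times independent
    lognormal noise times an arbitrary radiance scale.  With
    ``radiance_per_cell = 1`` the series is tagged as cell counts.
    """
    if n_animals < 1:
        raise ValueError("need at least one animal")
    params = params or ModelParameters()
    days = default_sampling_days() if days is None else np.asarray(days, float)
    noise = noise or NoiseModel()
    rng = noise.rng()

    truth = initial_burden * np.exp(params.rho * days) * radiance_per_cell
    obs, ids = [], []
    for a in range(n_animals):
        signals = _noised(truth, rng, noise.sigma)
        obs.extend(zip(days, signals))
        ids.extend([f"control_{a + 1:02d}"] * days.size)
    unit = "cells" if radiance_per_cell == 1.0 else "radiance"
    return BurdenSeries(tuple(obs), unit=unit, animal_ids=tuple(ids))


def generate_treated_series(params: ModelParameters | None = None,
                            n_animals: int = 3,
                            days: np.ndarray | None = None,
                            noise: NoiseModel | None = None,
                            cart_day: float = 7.0,
                            cart_cells: float = 1e6,
                            initial_burden: float = 5e6,
                            ratio_day: float = 28.0,
                            radiance_per_cell: float = 1.0
                            ) -> tuple[BurdenSeries, np.ndarray]:
    """CAR-T-treated cohort: model trajectories plus day-28 ratio data.

    Burden observations are the simulated total burden at the imaging
    days under a single CAR-T bolus (no TRT), perturbed per animal by
    the noise model.  The returned array holds one day-28 CAR-T:tumor
    percentage per animal: the noiseless model ratio times the same
    multiplicative noise, mimicking a terminal flow-cytometry readout.
    """
    if n_animals < 1:
        raise ValueError("need at least one animal")
    params = params or ModelParameters()
    days = default_sampling_days() if days is None else np.asarray(days, float)
    noise = noise or NoiseModel()
    rng = noise.rng()

    schedule = TreatmentSchedule.build(cart=[(cart_day, cart_cells)])
    t_end = max(days.max(), ratio_day) + 1.0
    traj = simulate(params, schedule, SystemState(0.0, initial_burden), t_end)
    truth = np.asarray(traj.total_burden(days)) * radiance_per_cell
    true_ratio = day28_ratio(traj, ratio_day)

    obs, ids = [], []
    for a in range(n_animals):
        signals = _noised(truth, rng, noise.sigma)
        obs.extend(zip(days, signals))
        ids.extend([f"treated_{a + 1:02d}"] * days.size)
    ratios = _noised(np.full(n_animals, true_ratio), rng, noise.sigma)
    unit = "cells" if radiance_per_cell == 1.0 else "radiance"
    series = BurdenSeries(tuple(obs), unit=unit, animal_ids=tuple(ids))
    return series, ratios
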