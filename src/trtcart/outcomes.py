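"""Endpoint metrics computed from a simulated trajectory.

Three deterministic per-trajectory endpoints summarize a regimen:

* **overall survival (OS)** — the day total tumor burden first reaches a
  lethal threshold (default ``1e11`` cells);
* **progression-free survival (PFS)** — the day total burden climbs back
  above its value at the moment of first therapy (progression relative
  to the pre-therapy baseline);
* **time to nadir** — the day of the post-therapy burden minimum.

All three are measured in days from tumor initiation (t = 0) and, like
the preclinical convention they mirror, reported rounded to whole days.
Exact (unrounded) crossing times are retained for sensitivity deltas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .dynamics import Trajectory

__all__ = [
    "OS_THRESHOLD_CELLS",
    "OutcomeSummary",
    "overall_survival",
    "progression_free_survival",
    "time_to_nadir",
    "summarize",
]

#: default lethal-burden threshold defining overall survival
OS_THRESHOLD_CELLS = 1e11

#: scan resolution (days) for bracketing threshold crossings
_SCAN_STEP = 0.05


def _round_day(t: float) -> int:
    """Half-up rounding of a crossing time to whole days."""
    return int(math.floor(t + 0.5))


@dataclass(frozen=True)
class OutcomeSummary:
    """Endpoints of one simulated regimen.

    ``pfs_days`` / ``os_days`` are ``None`` when the corresponding
    crossing is not reached within the simulated horizon.  ``*_exact``
    fields hold the unrounded crossing times in days.
    """

    pfs_days: int | None
    os_days: int | None
    t_nadir_days: int
    nadir_burden: float
    baseline_burden: float
    pfs_exact: float | None = None
    os_exact: float | None = None
    t_nadir_exact: float | None = None

    def as_dict(self) -> dict:
        return {
            "pfs_days": self.pfs_days,
            "os_days": self.os_days,
            "t_nadir_days": self.t_nadir_days,
            "nadir_burden": self.nadir_burden,
            "baseline_burden": self.baseline_burden,
        }


def _burden_grid(traj: Trajectory, t_start: float,
                 t_stop: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = traj.t_span
    if t_stop is not None:
        hi = min(hi, t_stop)
    t0 = max(t_start, lo)
    n = max(int(math.ceil((hi - t0) / _SCAN_STEP)) + 1, 2)
    t = np.linspace(t0, hi, n)
    # break points must be sampled exactly: burden is continuous but its
    # derivative jumps there
    t = np.unique(np.concatenate([t, [a for a in traj.admin_times if a >= t0]]))
    return t, np.asarray(traj.total_burden(t))


def overall_survival(traj: Trajectory,
                     threshold: float = OS_THRESHOLD_CELLS,
                     exact: bool = False) -> int | float | None:
    """First day total burden reaches ``threshold`` cells, from t = 0.

    The crossing is bracketed on a fine scan of the dense trajectory and
    refined by root finding to much better than 0.01 day.  Returns
    ``None`` (not reached) when the burden stays below the threshold
    over the simulated span.
    """
    t, burden = _burden_grid(traj, traj.t_span[0])
    above = burden >= threshold
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        t_cross = t[0]
    else:
        f = lambda x: traj.total_burden(x) - threshold
        t_cross = brentq(f, t[i - 1], t[i], xtol=1e-6)
    return float(t_cross) if exact else _round_day(t_cross)


def progression_free_survival(traj: Trajectory,
                              first_therapy_day: float,
                              exact: bool = False,
                              t_stop: float | None = None) -> int | float:
    """Day the burden regains its pre-therapy baseline, from t = 0.

    The baseline is the total burden at ``first_therapy_day``.  The
    returned time is the end of the post-therapy below-baseline
    interval: the first time after therapy at which the burden crosses
    the baseline from below.  If therapy never pushes the burden below
    baseline there is no progression-free interval and the therapy day
    itself is returned.  ``t_stop`` bounds the search (conventionally
    the overall-survival time: dynamics past the lethal burden are not
    biologically meaningful).
    """
    lo, hi = traj.t_span
    if not (lo <= first_therapy_day <= hi):
        raise ValueError("first_therapy_day outside the trajectory span")
    baseline = float(traj.total_burden(first_therapy_day))
    t, burden = _burden_grid(traj, first_therapy_day, t_stop)
    # strictly-below detection with a relative guard so the t == therapy
    # grid point (burden == baseline) is not itself counted
    below = burden < baseline * (1.0 - 1e-9)
    if not below.any():
        t_pfs = float(first_therapy_day)
        return t_pfs if exact else _round_day(t_pfs)
    first_below = int(np.argmax(below))
    recross = np.nonzero(~below[first_below:])[0]
    if recross.size == 0:
        # burden still below baseline at the end of the horizon
        return None
    j = first_below + int(recross[0])
    f = lambda x: traj.total_burden(x) - baseline
    t_pfs = brentq(f, t[j - 1], t[j], xtol=1e-6)
    return float(t_pfs) if exact else _round_day(t_pfs)


def time_to_nadir(traj: Trajectory,
                  first_therapy_day: float,
                  exact: bool = False,
                  t_stop: float | None = None) -> tuple[int | float, float]:
    """Time and value of the post-therapy total-burden minimum.

    The minimum of NT + NR over ``t >= first_therapy_day`` is located on
    the dense scan grid and refined locally with a bounded scalar
    minimization.  ``t_stop`` bounds the search window (conventionally
    the overall-survival time, excluding any post-lethal rebound of the
    mass-action predator-prey terms).  Returns ``(day, burden_at_nadir)``.
    """
    lo, hi = traj.t_span
    if not (lo <= first_therapy_day <= hi):
        raise ValueError("first_therapy_day outside the trajectory span")
    t, burden = _burden_grid(traj, first_therapy_day, t_stop)
    i = int(np.argmin(burden))
    a = t[max(i - 1, 0)]
    b = t[min(i + 1, t.size - 1)]
    if b > a:
        res = minimize_scalar(lambda x: traj.total_burden(x),
                              bounds=(a, b), method="bounded",
                              options={"xatol": 1e-6})
        t_min, v_min = float(res.x), float(res.fun)
        if burden[i] < v_min:  # refinement must not lose the grid minimum
            t_min, v_min = float(t[i]), float(burden[i])
    else:
        t_min, v_min = float(t[i]), float(burden[i])
    return (t_min if exact else _round_day(t_min)), v_min


def summarize(traj: Trajectory,
              first_therapy_day: float,
              os_threshold: float = OS_THRESHOLD_CELLS) -> OutcomeSummary:
    """All three endpoints of a trajectory in one record."""
    baseline = float(traj.total_burden(first_therapy_day))
    os_exact = overall_survival(traj, os_threshold, exact=True)
    pfs_exact = progression_free_survival(traj, first_therapy_day,
                                          exact=True, t_stop=os_exact)
    nadir_exact, nadir_burden = time_to_nadir(traj, first_therapy_day,
                                              exact=True, t_stop=os_exact)
    return OutcomeSummary(
        pfs_days=None if pfs_exact is None else _round_day(pfs_exact),
        os_days=None if os_exact is None else _round_day(os_exact),
        t_nadir_days=_round_day(nadir_exact),
        nadir_burden=nadir_burden,
        baseline_burden=baseline,
        pfs_exact=pfs_exact,
        os_exact=os_exact,
        t_nadir_exact=nadir_exact,
    )
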