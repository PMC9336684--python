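"""Transit-compartment model of choroid-plexus vacuolation and the
associated predictions and summaries.

The vacuole/cell-number ratio R(t) responds to serum drug concentration
C(t) through a chain of ``n`` transit compartments::

    dA1/dt = kin * C(t) - ktr * A1
    dAi/dt = ktr * (A_{i-1} - A_i)        i = 2 .. n-1
    dAn/dt = ktr * A_{n-1} - kout * An
    R(t)   = V0 + An(t)

(for ``n = 1`` the single compartment has input ``kin*C`` and loss
``kout``).  The chain delays and smooths the response; ``kout`` sets the
slow washout that governs recovery after dosing stops, and ``V0`` is the
spontaneous background ratio seen in control animals.

On top of the dynamic model the module provides the summaries used for
necropsy tables: per-group means of vacuole ratio and size, severity
grade tallies on the four-step minimal/mild/moderate/severe scale, and a
configurable monotone mapping from quantitative ratio to grade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import BracketingError, InputError, ParameterError, UnreachableError
from .pk_core import (
    ConcentrationProfile,
    DoseRegimen,
    HumanPKParams,
    MonkeyPKParams,
    simulate_human_pk,
    simulate_monkey_pk,
)
from .util import as_grid

#: severity grades in increasing order: none, minimal, moderate, severe
GRADES = ("-", "+", "++", "+++")

#: default upper cut points of the ratio bands for grades -, +, ++
DEFAULT_GRADE_CUTS = (0.06, 0.15, 0.35)

#: columns of a vacuole observation table
VAC_COLUMNS = ["animal_id", "group", "day", "vacuole_ratio", "mean_area_um2", "grade"]


@dataclass(frozen=True)
class TransitPDParams:
    """Transit-chain vacuolation parameters.

    n_transit : number of transit compartments (>= 1)
    ktr : transit rate between compartments (1/h)
    kin : input slope, ratio units per (ng/ml)*h of exposure
    kout : terminal loss rate governing recovery (1/h)
    V0 : spontaneous baseline vacuole/cell ratio
    """

    n_transit: int = 3
    ktr: float = 0.002
    kin: float = 3.0e-9
    kout: float = 5.0e-5
    V0: float = 0.0595

    def __post_init__(self):
        if int(self.n_transit) < 1:
            raise ParameterError("n_transit must be >= 1")
        for name in ("ktr", "kin", "kout"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"TransitPDParams.{name} must be > 0")
        if self.V0 < 0:
            raise ParameterError("TransitPDParams.V0 must be >= 0")


@dataclass(frozen=True)
class VacuoleTrajectory:
    """Predicted vacuole/cell ratio time course (with the underlying
    transit states at the final time, for hand-off to recovery runs)."""

    times: np.ndarray
    ratio: np.ndarray
    final_state: np.ndarray | None = None


@dataclass(frozen=True)
class ThresholdResult:
    """Result of a threshold-dose search."""

    dose: float
    at_or_below: bool
    ratio_at_horizon: float


def _rhs(pd_params: TransitPDParams, conc_fn):
    n, ktr, kin, kout = (
        int(pd_params.n_transit),
        pd_params.ktr,
        pd_params.kin,
        pd_params.kout,
    )

    def rhs(t, a):
        d = np.empty(n)
        loss0 = kout if n == 1 else ktr
        d[0] = kin * conc_fn(t) - loss0 * a[0]
        for i in range(1, n - 1):
            d[i] = ktr * (a[i - 1] - a[i])
        if n > 1:
            d[n - 1] = ktr * a[n - 2] - kout * a[n - 1]
        return d

    return rhs


def simulate_vacuole_ratio(
    conc: ConcentrationProfile, pd_params: TransitPDParams, times,
    initial_state=None,
) -> VacuoleTrajectory:
    """Drive the transit chain with a concentration profile and return
    the vacuole/cell ratio at the requested times.

    The concentration is linearly interpolated inside the profile and
    held at 0 beyond its last point (drug-free continuation).
    """
    grid = as_grid(times)
    n = int(pd_params.n_transit)
    a0 = np.zeros(n) if initial_state is None else np.asarray(initial_state, float)
    if a0.shape != (n,):
        raise InputError(f"initial_state must have length {n}")

    def conc_fn(t):
        return float(np.interp(t, conc.times, conc.conc, left=0.0, right=0.0))

    sol = solve_ivp(
        _rhs(pd_params, conc_fn),
        (min(0.0, grid[0]), grid[-1]),
        a0,
        method="LSODA",
        t_eval=grid,
        rtol=1e-8,
        atol=1e-12,
        max_step=np.inf if conc.times.size < 2 else float(np.min(np.diff(conc.times))) * 4,
    )
    ratio = np.clip(pd_params.V0 + sol.y[-1], 0.0, None)
    return VacuoleTrajectory(times=grid, ratio=ratio, final_state=sol.y[:, -1])


def recovery_time(
    pd_params: TransitPDParams,
    state_at_cessation,
    criterion: float,
    *,
    horizon_h: float = 20 * 8766.0,  # 20 years
) -> float:
    """First time (h after cessation) at which the drug-free system's
    ratio falls to ``criterion``; ``inf`` if not reached within the
    horizon (default 20 years).
    """
    if criterion < pd_params.V0:
        raise UnreachableError(
            f"criterion {criterion} is below the baseline V0={pd_params.V0}; "
            "the drug-free system can never reach it"
        )
    n = int(pd_params.n_transit)
    a0 = np.asarray(state_at_cessation, dtype=float)
    if a0.shape != (n,):
        raise InputError(f"state_at_cessation must have length {n}")
    if pd_params.V0 + a0[-1] <= criterion:
        return 0.0
    thr = criterion - pd_params.V0

    def event(t, a):
        return a[-1] - thr

    event.terminal = True
    event.direction = -1
    sol = solve_ivp(
        _rhs(pd_params, lambda t: 0.0),
        (0.0, horizon_h),
        a0,
        method="LSODA",
        events=event,
        rtol=1e-10,
        atol=1e-14,
    )
    if sol.t_events[0].size:
        return float(sol.t_events[0][0])
    return float("inf")


def _ratio_at_horizon(pk_params, pd_params, dose, tau, n_doses, horizon_h, pk_step):
    grid = np.arange(0.0, horizon_h + pk_step, pk_step)
    grid[-1] = horizon_h
    reg = DoseRegimen(dose=dose, tau=tau, nDoses=n_doses)
    if isinstance(pk_params, HumanPKParams):
        prof = simulate_human_pk(pk_params, reg, grid)
    elif isinstance(pk_params, MonkeyPKParams):
        prof = simulate_monkey_pk(pk_params, reg, grid)
    else:
        raise ParameterError(f"unknown parameter set type {type(pk_params).__name__}")
    traj = simulate_vacuole_ratio(prof, pd_params, np.array([horizon_h]))
    return float(traj.ratio[-1])


def threshold_dose(
    pk_params,
    pd_params: TransitPDParams,
    *,
    tau: float = 168.0,
    horizon_weeks: float = 52.0,
    target: float = 0.0595,
    bracket: tuple = (1e-3, 10.0),
    dose_tol: float = 1e-3,
    pk_step: float = 2.0,
) -> ThresholdResult:
    """Weekly dose (mg/kg) at which the predicted vacuole/cell ratio at
    the end of the dosing horizon equals ``target``.

    Bisection on dose to ``dose_tol`` (mg/kg).  If the target is already
    met at the bottom of the bracket (e.g. target equal to the baseline),
    the lower bound is returned with ``at_or_below=True``.
    """
    horizon_h = horizon_weeks * 168.0
    n_doses = int(np.ceil(horizon_weeks * 168.0 / tau))

    def ratio_at(d):
        return _ratio_at_horizon(
            pk_params, pd_params, d, tau, n_doses, horizon_h, pk_step
        )

    lo, hi = bracket
    r_lo = ratio_at(lo)
    if target <= r_lo:
        return ThresholdResult(dose=lo, at_or_below=True, ratio_at_horizon=r_lo)
    r_hi = ratio_at(hi)
    if target > r_hi:
        raise BracketingError(
            f"target ratio {target} not reachable at the bracket top "
            f"{hi} mg/kg/week (ratio there {r_hi:.4g})"
        )
    dose = float(brentq(lambda d: ratio_at(d) - target, lo, hi, xtol=dose_tol))
    return ThresholdResult(
        dose=dose, at_or_below=False, ratio_at_horizon=target
    )


# --------------------------------------------------------------------------
# necropsy-table summaries
# --------------------------------------------------------------------------


def grade_from_ratio(ratio: float, cuts=DEFAULT_GRADE_CUTS) -> str:
    """Map a quantitative vacuole/cell ratio to the four-step severity
    scale with a monotone step function (defaults place the control
    background median in the no-effect band)."""
    if not 0 <= ratio <= 1:
        raise InputError(f"vacuole ratio {ratio} outside [0, 1]")
    return GRADES[int(np.searchsorted(np.asarray(cuts), ratio, side="right"))]


def summarize_vacuoles(observations: pd.DataFrame) -> pd.DataFrame:
    """Per group x necropsy day: mean vacuole area, mean vacuole ratio,
    their product (composite severity), and counts per severity grade.

    ``observations`` needs columns group, day, grade, and optionally
    vacuole_ratio / mean_area_um2 (means are NaN where absent).
    """
    if observations.empty:
        raise InputError("observation table is empty")
    df = observations.copy()
    bad = set(df["grade"]) - set(GRADES)
    if bad:
        raise InputError(f"unknown severity grade symbols: {sorted(bad)}")
    for col in ("vacuole_ratio", "mean_area_um2"):
        if col not in df.columns:
            df[col] = np.nan
    rows = []
    for (group, day), g in df.groupby(["group", "day"], sort=True):
        row = {
            "group": group,
            "day": day,
            "n": len(g),
            "mean_ratio": g["vacuole_ratio"].mean(),
            "mean_area_um2": g["mean_area_um2"].mean(),
        }
        row["area_x_ratio"] = row["mean_ratio"] * row["mean_area_um2"]
        counts = g["grade"].value_counts()
        for sym, name in zip(GRADES, ("minus", "plus", "plusplus", "plusplusplus")):
            row[f"n_{name}"] = int(counts.get(sym, 0))
        rows.append(row)
    return pd.DataFrame(rows)


def grade_counts(summary_row: pd.Series) -> dict:
    """Grade tally of one summary row as a {symbol: count} dict with
    zero-count grades omitted (the layout of the report tables)."""
    names = dict(zip(("minus", "plus", "plusplus", "plusplusplus"), GRADES))
    return {
        sym: int(summary_row[f"n_{name}"])
        for name, sym in names.items()
        if summary_row[f"n_{name}"] > 0
    }
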