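"""Structural pharmacokinetic models and non-compartmental exposure metrics.

Two one-compartment structural models are implemented for a weekly
subcutaneous PEGylated rhGH:

* **Monkey (toxicokinetic) model** — zero-order absorption over a finite
  window ``Dzero`` and parallel first-order (``CL``) plus saturable
  Michaelis–Menten (``Vmax``, ``Km``) elimination from the central
  compartment::

      dA/dt = In(t) - CL*C - Vmax*C/(Km + C),     C = A/Vc

  with ``In(t) = F*dose/Dzero`` inside each dose's absorption window.

* **Pediatric (clinical) model** — parallel zero-order and first-order
  absorption (fraction ``frZero`` of the bioavailable dose enters as a
  finite infusion, the remainder through a first-order depot with rate
  ``ka``) and first-order elimination ``CL/Vc``.

Units are fixed package-wide: time in hours, concentration in ng/ml,
dose in mg of GH per kg body weight, clearances in ml/h/kg, volumes in
ml/kg.  The mg -> ng conversion happens here and nowhere else.

The amount state ``A`` is carried per kg body weight (ng/kg), so with
``Vc`` in ml/kg the concentration ``A/Vc`` is in ng/ml directly and no
body weight enters the equations.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .errors import ConvergenceError, InputError, ParameterError
from .util import as_grid

MG_TO_NG = 1.0e6

# solver tolerances; tight enough that closed-form comparisons at 1e-6
# relative are solver-noise free
_RTOL = 1e-8
_ATOL = 1e-8


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MonkeyPKParams:
    """Cynomolgus-monkey structural PK parameters.

    CL : linear clearance (ml/h/kg)
    Vc : central volume of distribution (ml/kg)
    Vmax : maximum rate of the saturable elimination pathway (ng/h/kg)
    Km : Michaelis constant (ng/ml)
    F : subcutaneous bioavailability (fraction)
    Dzero : duration of the zero-order absorption window (h)
    Q : inter-compartmental clearance (ml/h/kg).  The structural model is
        strictly one-compartment; ``Q`` is carried as an inert optional
        field because the parameterisation of the original analysis names
        it (see docs/methods.md).
    """

    CL: float
    Vc: float
    Vmax: float
    Km: float
    F: float = 1.0
    Dzero: float = 24.0
    Q: float | None = None

    def __post_init__(self):
        for name in ("CL", "Vc", "Km", "Dzero"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"MonkeyPKParams.{name} must be > 0")
        if self.Vmax < 0:
            raise ParameterError("MonkeyPKParams.Vmax must be >= 0")
        if not 0 < self.F <= 1:
            raise ParameterError("MonkeyPKParams.F must be in (0, 1]")
        if self.Q is not None and not self.Q > 0:
            raise ParameterError("MonkeyPKParams.Q must be absent or > 0")


@dataclass(frozen=True)
class HumanPKParams:
    """Pediatric-patient structural PK parameters.

    CL : clearance (ml/h/kg)
    Vc : central volume (ml/kg)
    ka : first-order absorption rate constant (1/h)
    frZero : fraction of the bioavailable dose absorbed by the zero-order
        route (the remainder goes through the first-order depot)
    Dzero : zero-order absorption duration (h)
    F : bioavailability (fraction)
    """

    CL: float
    Vc: float
    ka: float
    frZero: float = 0.5
    Dzero: float = 24.0
    F: float = 1.0

    def __post_init__(self):
        for name in ("CL", "Vc", "ka", "Dzero"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"HumanPKParams.{name} must be > 0")
        if not 0 <= self.frZero <= 1:
            raise ParameterError("HumanPKParams.frZero must be in [0, 1]")
        if not 0 < self.F <= 1:
            raise ParameterError("HumanPKParams.F must be in (0, 1]")


@dataclass(frozen=True)
class DoseRegimen:
    """A repeated subcutaneous dosing schedule.

    dose : GH dose per administration (mg/kg); weekly dosing at weekly
        dose D means ``dose=D, tau=168``
    tau : dosing interval (h)
    nDoses : number of administrations
    """

    dose: float
    tau: float = 168.0
    nDoses: int = 1
    route: str = "sc"

    def __post_init__(self):
        if self.dose < 0:
            raise ParameterError("DoseRegimen.dose must be >= 0")
        if not self.tau > 0:
            raise ParameterError("DoseRegimen.tau must be > 0")
        if int(self.nDoses) < 1:
            raise ParameterError("DoseRegimen.nDoses must be >= 1")

    @property
    def dose_times(self) -> np.ndarray:
        return np.arange(int(self.nDoses)) * self.tau


@dataclass(frozen=True)
class ConcentrationProfile:
    """A serum concentration time course on a strictly increasing grid."""

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self):
        t = as_grid(self.times)
        c = np.asarray(self.conc, dtype=float)
        if c.shape != t.shape:
            raise InputError("times and conc must have the same length")
        if np.any(c < -1e-9):
            raise InputError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", np.clip(c, 0.0, None))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.times, "conc_ng_ml": self.conc}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "ConcentrationProfile":
        df = pd.read_csv(path)
        return cls(df["time_h"].to_numpy(), df["conc_ng_ml"].to_numpy())


@dataclass(frozen=True)
class ExposureMetrics:
    """Non-compartmental exposure summary of a concentration profile.

    Cmax (ng/ml), Tmax (h, earliest time attaining Cmax), AUClast
    (ng*h/ml, linear trapezoid over the full grid) and, when computed at
    steady state, AUCtauSS over one dosing interval.
    """

    Cmax: float
    Tmax: float
    AUClast: float
    AUCtauSS: float | None = None


# --------------------------------------------------------------------------
# integration machinery
# --------------------------------------------------------------------------


def _infusion_segments(dose_times, rate, dzero, t_end):
    """Break [0, t_end] at every absorption-window edge and return
    (a, b, total_input_rate) triples.  Overlapping windows add."""
    pts = {0.0, float(t_end)}
    for t0 in dose_times:
        if t0 < t_end:
            pts.add(float(t0))
            pts.add(float(min(t0 + dzero, t_end)))
    edges = sorted(pts)
    segs = []
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        r = rate * sum(1 for t0 in dose_times if t0 <= mid < t0 + dzero)
        segs.append((a, b, r))
    return segs


def _piecewise_solve(rhs_for_rate, y0, segs, grid):
    """Integrate a piecewise-constant-input ODE segment by segment,
    evaluating the solution at the requested grid points.

    ``rhs_for_rate(rate)`` returns the RHS callable for a segment with
    constant input ``rate``.  Integrating each segment separately keeps
    the input discontinuities exactly on integration boundaries.
    """
    out = np.empty((len(grid), len(y0)))
    y = np.array(y0, dtype=float)
    if not segs:
        out[:] = y
        return out, y
    mask0 = grid <= segs[0][0] + 1e-12
    out[mask0] = y
    for a, b, r in segs:
        sel = (grid > a + 1e-12) & (grid <= b + 1e-12)
        tseq = np.unique(np.concatenate([[a], grid[sel], [b]]))
        ys = odeint(
            rhs_for_rate(r), y, tseq, rtol=_RTOL, atol=_ATOL, tfirst=True
        )
        if sel.any():
            idx = np.searchsorted(tseq, grid[sel])
            out[sel] = ys[idx]
        y = ys[-1]
    return out, y


def _sim_monkey_states(params, dose_times, dose_mg, grid, A0=0.0):
    """Amount A (ng/kg) of the monkey model at the grid points, plus the
    final state.  ``dose_times`` are absolute (h)."""
    rate = params.F * dose_mg * MG_TO_NG / params.Dzero
    segs = _infusion_segments(dose_times, rate, params.Dzero, grid[-1])
    CL, Vc, Vmax, Km = params.CL, params.Vc, params.Vmax, params.Km

    def rhs_for_rate(r):
        def rhs(t, y):
            C = y[0] / Vc
            return (r - CL * C - Vmax * C / (Km + C),)

        return rhs

    out, y_end = _piecewise_solve(rhs_for_rate, [A0], segs, grid)
    return out[:, 0], y_end


def _sim_human_states(params, dose_times, dose_mg, grid, y0=(0.0, 0.0)):
    """(depot, central) amounts (ng/kg) of the pediatric model at the
    grid points, plus the final state."""
    fdose = params.F * dose_mg * MG_TO_NG
    rate = params.frZero * fdose / params.Dzero
    bolus = (1.0 - params.frZero) * fdose
    ka, ke = params.ka, params.CL / params.Vc
    t_end = grid[-1]

    # depot boluses are state jumps; make every dose time a segment edge
    segs = _infusion_segments(dose_times, rate, params.Dzero, t_end)

    def rhs_for_rate(r):
        def rhs(t, y):
            d, a = y
            return (-ka * d, ka * d + r - ke * a)

        return rhs

    out = np.empty((len(grid), 2))
    y = np.array(y0, dtype=float)
    dose_set = {float(t) for t in dose_times if t < t_end}
    if 0.0 in dose_set:
        y[0] += bolus
        dose_set.discard(0.0)
    if not segs:
        out[:] = y
        return out, y
    mask0 = grid <= segs[0][0] + 1e-12
    out[mask0] = y
    for a, b, r in segs:
        if a in dose_set:
            y[0] += bolus
            dose_set.discard(a)
        sel = (grid > a + 1e-12) & (grid <= b + 1e-12)
        tseq = np.unique(np.concatenate([[a], grid[sel], [b]]))
        ys = odeint(
            rhs_for_rate(r), y, tseq, rtol=_RTOL, atol=_ATOL, tfirst=True
        )
        if sel.any():
            idx = np.searchsorted(tseq, grid[sel])
            out[sel] = ys[idx]
        y = ys[-1]
    return out, y


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def simulate_monkey_pk(
    params: MonkeyPKParams, regimen: DoseRegimen, times
) -> ConcentrationProfile:
    """Simulate the monkey TK model over a time grid covering one or more
    weekly doses.  Returns a non-negative concentration profile (ng/ml)."""
    grid = as_grid(times)
    if regimen.dose == 0:
        return ConcentrationProfile(grid, np.zeros_like(grid))
    A, _ = _sim_monkey_states(params, regimen.dose_times, regimen.dose, grid)
    return ConcentrationProfile(grid, A / params.Vc)


def simulate_human_pk(
    params: HumanPKParams, regimen: DoseRegimen, times
) -> ConcentrationProfile:
    """Simulate the pediatric PK model over a time grid."""
    grid = as_grid(times)
    if regimen.dose == 0:
        return ConcentrationProfile(grid, np.zeros_like(grid))
    states, _ = _sim_human_states(params, regimen.dose_times, regimen.dose, grid)
    return ConcentrationProfile(grid, states[:, 1] / params.Vc)


def simulate_doses(params, dose_times, dose_mg, times) -> ConcentrationProfile:
    """Simulate either species' model for an explicit dose schedule
    (absolute dose times in h, common dose in mg/kg).  Used by fitting,
    where the schedule comes from data records rather than a regimen."""
    grid = as_grid(times)
    dose_times = np.asarray(dose_times, dtype=float)
    if dose_mg == 0 or dose_times.size == 0:
        return ConcentrationProfile(grid, np.zeros_like(grid))
    if isinstance(params, MonkeyPKParams):
        A, _ = _sim_monkey_states(params, dose_times, dose_mg, grid)
        return ConcentrationProfile(grid, A / params.Vc)
    if isinstance(params, HumanPKParams):
        states, _ = _sim_human_states(params, dose_times, dose_mg, grid)
        return ConcentrationProfile(grid, states[:, 1] / params.Vc)
    raise ParameterError(f"unknown parameter set type {type(params).__name__}")


def nca(profile: ConcentrationProfile) -> ExposureMetrics:
    """Non-compartmental exposure metrics: Cmax, Tmax (earliest), and
    linear-trapezoid AUClast over the full grid."""
    if profile.times.size < 2:
        raise InputError("NCA requires at least two time points")
    i = int(np.argmax(profile.conc))  # argmax returns the earliest maximum
    auc = float(np.trapezoid(profile.conc, profile.times))
    return ExposureMetrics(
        Cmax=float(profile.conc[i]), Tmax=float(profile.times[i]), AUClast=auc
    )


def steady_state_metrics(
    params,
    regimen: DoseRegimen,
    *,
    rel_tol: float = 1e-3,
    max_intervals: int = 200,
    points_per_interval: int = 241,
) -> ExposureMetrics:
    """Exposure metrics over one dosing interval at steady state.

    Successive intervals of length ``tau`` are simulated (carrying the
    model state across interval boundaries, one dose at the start of
    each) until AUCtau changes by less than ``rel_tol`` (default 0.1%)
    between consecutive intervals.  Tmax is reported relative to the
    start of the converged interval.
    """
    if regimen.dose == 0:
        return ExposureMetrics(Cmax=0.0, Tmax=0.0, AUClast=0.0, AUCtauSS=0.0)
    local = np.linspace(0.0, regimen.tau, points_per_interval)
    human = isinstance(params, HumanPKParams)
    if not human and not isinstance(params, MonkeyPKParams):
        raise ParameterError(f"unknown parameter set type {type(params).__name__}")
    state = (0.0, 0.0) if human else 0.0
    auc_prev = None
    for _ in range(max_intervals):
        if human:
            states, y_end = _sim_human_states(
                params, [0.0], regimen.dose, local, y0=state
            )
            conc = states[:, 1] / params.Vc
        else:
            A, y_end = _sim_monkey_states(
                params, [0.0], regimen.dose, local, A0=state
            )
            conc = A / params.Vc
            y_end = y_end[0]
        state = y_end
        auc = float(np.trapezoid(conc, local))
        if auc_prev is not None and auc_prev > 0:
            rel = abs(auc - auc_prev) / auc_prev
            if rel < rel_tol:
                i = int(np.argmax(conc))
                return ExposureMetrics(
                    Cmax=float(conc[i]),
                    Tmax=float(local[i]),
                    AUClast=auc,
                    AUCtauSS=auc,
                )
        auc_prev = auc
    raise ConvergenceError(
        f"AUCtau did not converge within {max_intervals} intervals "
        f"(last relative change {rel:.3g})"
    )


def params_as_dict(params) -> dict:
    """Flat dict of a parameter dataclass (None fields dropped)."""
    return {
        f.name: getattr(params, f.name)
        for f in fields(params)
        if getattr(params, f.name) is not None
    }
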