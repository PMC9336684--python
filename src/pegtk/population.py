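"""Inter-individual variability, residual error, and virtual TK cohorts.

Individual parameters are log-normal around the population typical
value, ``theta_i = theta_TV * exp(eta_i)`` with ``eta_i ~ N(0, omega2)``
independently per parameter.  Observations follow the combined
proportional + additive residual model ``Y = C*(1 + eps) + xi`` with
``eps ~ N(0, sigma_prop^2)`` and ``xi ~ N(0, sigma_add^2)``; values
below the assay's lower limit of quantification are flagged BLQ (the
simulated value is retained).

Randomness is reproducible: a single integer seed, with per-individual
substreams derived deterministically from ``(seed, individual index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import pk_core
from .errors import ConfigError, InputError
from .pk_core import ConcentrationProfile, params_as_dict

TK_COLUMNS = ["ID", "GROUP", "TIME", "DV", "AMT", "EVID", "MDV", "BLQ"]


@dataclass(frozen=True)
class IIVSpec:
    """Log-normal inter-individual variability: parameter name -> omega^2."""

    omega2: dict = field(default_factory=dict)

    def __post_init__(self):
        for k, v in self.omega2.items():
            if v < 0:
                raise ConfigError(f"omega2[{k!r}] must be >= 0")


@dataclass(frozen=True)
class ResidualErrorSpec:
    """Combined residual-error model and assay quantification limit.

    sigma_prop : SD of the proportional error component (dimensionless)
    sigma_add : SD of the additive error component (ng/ml)
    lloq : lower limit of quantification of the assay (ng/ml)
    """

    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    lloq: float = 8.0

    def __post_init__(self):
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ConfigError("residual error SDs must be >= 0")
        if self.lloq < 0:
            raise ConfigError("lloq must be >= 0")


class TKDataset:
    """Long-format per-individual dosing + observation records.

    Thin wrapper around a DataFrame with NONMEM-convention columns
    ID, GROUP, TIME, DV, AMT, EVID, MDV, BLQ (EVID 1 = dose with AMT in
    mg/kg and MDV 1; EVID 0 = observation with DV in ng/ml).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in TK_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"TKDataset missing columns: {missing}")
        df = df[TK_COLUMNS].reset_index(drop=True)
        if (df["TIME"] < 0).any():
            raise InputError("TKDataset times must be non-negative")
        obs_ids = set(df.loc[df["EVID"] == 0, "ID"])
        dose_ids = set(df.loc[df["EVID"] == 1, "ID"])
        orphans = obs_ids - dose_ids
        if orphans:
            raise InputError(
                f"observations without any dose record for IDs {sorted(orphans)}"
            )
        self.df = df

    @property
    def individual_ids(self) -> list:
        return sorted(self.df["ID"].unique())

    @property
    def n_individuals(self) -> int:
        return self.df["ID"].nunique()

    def records_for(self, individual_id) -> pd.DataFrame:
        return self.df[self.df["ID"] == individual_id]

    def observations(self, include_blq: bool = True) -> pd.DataFrame:
        obs = self.df[self.df["EVID"] == 0]
        return obs if include_blq else obs[obs["BLQ"] == 0]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "TKDataset":
        return cls(pd.read_csv(path))

    def __eq__(self, other):
        return isinstance(other, TKDataset) and self.df.equals(other.df)


# --------------------------------------------------------------------------
# sampling operations
# --------------------------------------------------------------------------


def _rng_for(seed: int, index: int) -> np.random.Generator:
    """Deterministic substream for one individual."""
    return np.random.default_rng([int(seed), int(index)])


def _draw_one(typical, iiv: IIVSpec, rng: np.random.Generator):
    """One individual's parameter set, log-normal around ``typical``."""
    known = params_as_dict(typical)
    updates = {}
    for name in sorted(iiv.omega2):  # sorted: draw order is reproducible
        if name not in known:
            raise ConfigError(f"omega2 refers to unknown parameter {name!r}")
        w2 = iiv.omega2[name]
        eta = rng.normal(0.0, np.sqrt(w2)) if w2 > 0 else 0.0
        updates[name] = known[name] * float(np.exp(eta))
    return replace(typical, **updates)


def draw_individual_params(typical, iiv: IIVSpec, n: int, seed: int) -> list:
    """Draw ``n`` individual parameter sets, theta_i = theta_TV * exp(eta_i)."""
    if n < 1:
        raise InputError("n must be >= 1")
    return [_draw_one(typical, iiv, _rng_for(seed, i)) for i in range(n)]


def _observe_with_rng(conc: np.ndarray, err: ResidualErrorSpec, rng):
    eps = rng.normal(0.0, err.sigma_prop, size=conc.shape)
    xi = rng.normal(0.0, err.sigma_add, size=conc.shape)
    y = conc * (1.0 + eps) + xi
    blq = y < err.lloq
    return y, blq


def observe(profile: ConcentrationProfile, err: ResidualErrorSpec, seed: int):
    """Apply the residual-error model to a noiseless profile.

    Returns ``(values, blq_flags)``.  Values below the LLOQ are flagged
    but retained (they may be negative under the additive component).
    """
    rng = np.random.default_rng(seed)
    return _observe_with_rng(profile.conc, err, rng)


def simulate_cohort(design, typical, iiv: IIVSpec, err: ResidualErrorSpec,
                    seed: int) -> TKDataset:
    """Simulate a whole study: one TKDataset covering every group of the
    design, deterministic under ``seed``.

    ``design`` must provide ``individuals()`` yielding objects with
    ``id, group, dose, n_doses, tau, sample_times`` (see
    :mod:`pegtk.synthetic`).
    """
    individuals = list(design.individuals())
    if not individuals:
        raise InputError("study design contains no individuals")
    rows = []
    for idx, ind in enumerate(individuals):
        rng = _rng_for(seed, idx)
        params = _draw_one(typical, iiv, rng)
        dose_times = np.arange(ind.n_doses) * ind.tau
        times = np.asarray(ind.sample_times, dtype=float)
        profile = pk_core.simulate_doses(params, dose_times, ind.dose, times)
        y, blq = _observe_with_rng(profile.conc, err, rng)
        for t in dose_times:
            rows.append((ind.id, ind.group, float(t), np.nan, ind.dose, 1, 1, 0))
        for t, v, b in zip(times, y, blq):
            rows.append((ind.id, ind.group, float(t), float(v), np.nan, 0, 0, int(b)))
    df = pd.DataFrame(rows, columns=TK_COLUMNS)
    df = df.sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False])
    return TKDataset(df.reset_index(drop=True))
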