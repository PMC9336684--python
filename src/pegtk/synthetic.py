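"""Synthetic-data generators for every input the pipeline consumes.

Raw animal- and patient-level data from the toxicity and clinical
programs were never deposited, so this module generates statistically
matched stand-ins with the structure the analysis assumes:

* a monkey TK study following the published design (five groups at
  0/0.3/1/1/3 mg GH/kg/week, 64 animals, staggered necropsies), with
  log-normal inter-individual variability and combined
  proportional + additive residual error around the structural model;
* per-animal vacuolation necropsy tables with log-normal measurement
  noise around the transit-model prediction plus the spontaneous
  control background;
* patient-level Bernoulli adverse-event tables at configurable arm
  rates.

Every generator is deterministic under an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import population, vacuolation
from .errors import InputError
from .pk_core import DoseRegimen, simulate_monkey_pk
from .population import IIVSpec, ResidualErrorSpec, TKDataset, simulate_cohort
from .vacuolation import TransitPDParams, grade_from_ratio, simulate_vacuole_ratio

#: rich sampling offsets after the first and last dose (h post-dose)
RICH_OFFSETS = (1.0, 4.0, 8.0, 24.0, 48.0, 96.0, 167.0)


@dataclass(frozen=True)
class Individual:
    """One virtual animal: identity, regimen, and sampling schedule."""

    id: int
    group: str
    dose: float
    n_doses: int
    tau: float
    necropsy_day: int
    sample_times: tuple


@dataclass(frozen=True)
class GroupSpec:
    """One design group.

    necropsy : ((day, n_animals), ...) staggered necropsy subsets;
        sizes must sum to ``n_animals``
    n_doses : number of weekly administrations (dosing stops earlier
        than necropsy for recovery subsets)
    sample_times : optional explicit override of the sampling schedule
    """

    label: str
    dose: float
    n_animals: int
    necropsy: tuple
    n_doses: int = 52
    sample_times: tuple | None = None

    def __post_init__(self):
        if self.dose < 0:
            raise InputError("group dose must be >= 0")
        if sum(n for _, n in self.necropsy) > self.n_animals:
            raise InputError(
                f"group {self.label}: necropsy subset sizes exceed n_animals"
            )


@dataclass(frozen=True)
class StudyDesign:
    """A staggered-necropsy TK study design."""

    groups: tuple
    tau: float = 168.0
    trough_every: int = 4  # pre-dose trough before every k-th dose
    washout_interval_h: float = 8 * 168.0  # post-treatment samples

    def _schedule(self, group: GroupSpec, necropsy_day: int) -> tuple:
        """Default schedule: rich windows after the first and last dose,
        troughs before every ``trough_every``-th dose, and washout
        samples for recovery animals, truncated at necropsy."""
        if group.sample_times is not None:
            times = np.asarray(group.sample_times, dtype=float)
        else:
            last_dose_t = (group.n_doses - 1) * self.tau
            pieces = [np.asarray(RICH_OFFSETS), last_dose_t + np.asarray(RICH_OFFSETS)]
            troughs = np.arange(self.trough_every, group.n_doses, self.trough_every)
            pieces.append(troughs * self.tau - 1.0)
            end_of_dosing = group.n_doses * self.tau
            washout = np.arange(
                end_of_dosing + self.washout_interval_h,
                necropsy_day * 24.0 + 1.0,
                self.washout_interval_h,
            )
            pieces.append(washout)
            times = np.concatenate(pieces)
        times = np.unique(times[times <= necropsy_day * 24.0])
        return tuple(float(t) for t in times)

    def individuals(self):
        for gi, group in enumerate(self.groups):
            k = 0
            for day, n_sub in group.necropsy:
                for _ in range(n_sub):
                    k += 1
                    yield Individual(
                        id=(gi + 1) * 100 + k,
                        group=group.label,
                        dose=group.dose,
                        n_doses=min(group.n_doses, int(np.ceil(day * 24.0 / self.tau))),
                        tau=self.tau,
                        necropsy_day=day,
                        sample_times=self._schedule(group, day),
                    )

    @property
    def n_animals(self) -> int:
        return sum(g.n_animals for g in self.groups)


def default_monkey_design() -> StudyDesign:
    """The published 52-week monkey study design: five groups at
    0/0.3/1/1/3 mg GH/kg/week, 64 animals in total, with staggered
    terminal (day 184/374) and recovery (day 1096/1465) necropsies; the
    26-week arm (group 3) has its recovery necropsy at day 366."""
    return StudyDesign(
        groups=(
            GroupSpec("group1_control", 0.0, 18, ((184, 6), (374, 8), (1096, 2), (1465, 2))),
            GroupSpec("group2_0.3", 0.3, 12, ((374, 8), (1096, 2), (1465, 2))),
            GroupSpec("group3_1_26wk", 1.0, 10, ((184, 6), (366, 4)), n_doses=26),
            GroupSpec("group4_1", 1.0, 12, ((374, 8), (1096, 2), (1465, 2))),
            GroupSpec("group5_3", 3.0, 12, ((374, 8), (1096, 2), (1465, 2))),
        )
    )


def generate_tk_study(design: StudyDesign, typical, iiv: IIVSpec,
                      err: ResidualErrorSpec, seed: int) -> TKDataset:
    """Simulate a full TK study under the design (delegates to
    :func:`pegtk.population.simulate_cohort`)."""
    return simulate_cohort(design, typical, iiv, err, seed)


def generate_vacuole_study(
    design: StudyDesign,
    pk_truth,
    pd_truth: TransitPDParams,
    noise_cv: float = 0.25,
    seed: int = 0,
    *,
    area_per_ratio: float = 500.0,
    pk_step: float = 4.0,
) -> pd.DataFrame:
    """Per-animal vacuolation necropsy table.

    Each animal's ratio is the transit-model prediction at its necropsy
    day multiplied by median-1 log-normal noise of coefficient of
    variation ``noise_cv``, clipped to [0, 1]; the severity grade is
    assigned from the noisy ratio.  The synthetic mean vacuole area is
    proportional to the ratio (``area_per_ratio`` um^2 per unit ratio)
    with independent noise of the same CV.
    """
    if noise_cv < 0:
        raise InputError("noise_cv must be >= 0")
    sigma = float(np.sqrt(np.log1p(noise_cv**2)))

    # one trajectory per (dose, n_doses, horizon) group profile
    ratio_cache: dict = {}

    def model_ratio(dose: float, n_doses: int, day: int) -> float:
        key = (dose, n_doses, day)
        if key not in ratio_cache:
            if dose == 0:
                ratio_cache[key] = pd_truth.V0
            else:
                horizon = day * 24.0
                grid = np.arange(0.0, horizon + pk_step, pk_step)
                grid[-1] = horizon
                prof = simulate_monkey_pk(
                    pk_truth, DoseRegimen(dose=dose, tau=design.tau, nDoses=n_doses), grid
                )
                traj = simulate_vacuole_ratio(prof, pd_truth, np.array([horizon]))
                ratio_cache[key] = float(traj.ratio[-1])
        return ratio_cache[key]

    rows = []
    for idx, ind in enumerate(design.individuals()):
        rng = np.random.default_rng([int(seed), 1000 + idx])
        base = model_ratio(ind.dose, ind.n_doses, ind.necropsy_day)
        noise_r, noise_a = np.exp(rng.normal(0.0, sigma, size=2))
        ratio = float(np.clip(base * noise_r, 0.0, 1.0))
        rows.append(
            {
                "animal_id": f"M{ind.id}",
                "group": ind.group,
                "dose": ind.dose,
                "day": ind.necropsy_day,
                "vacuole_ratio": ratio,
                "mean_area_um2": float(area_per_ratio * base * noise_a),
                "grade": grade_from_ratio(ratio),
            }
        )
    return pd.DataFrame(rows)


def generate_ar_study(arm_specs, seed: int) -> pd.DataFrame:
    """Patient-level adverse-event table.

    ``arm_specs``: iterable of (label, n_patients, p_ar, p_cns_ar).
    CNS-related ARs are a subset of ARs, so a patient drawn with a CNS
    event always counts as having an AR.
    """
    rows = []
    for ai, (label, n, p_ar, p_cns) in enumerate(arm_specs):
        for p in (p_ar, p_cns):
            if not 0 <= p <= 1:
                raise InputError(f"arm {label!r}: probability {p} outside [0, 1]")
        rng = np.random.default_rng([int(seed), 5000 + ai])
        ar = rng.random(int(n)) < p_ar
        cns = rng.random(int(n)) < p_cns
        ar = ar | cns
        for j in range(int(n)):
            rows.append(
                {
                    "arm": label,
                    "patient_id": f"{label}-{j + 1:04d}",
                    "ar": int(ar[j]),
                    "cns_ar": int(cns[j]),
                }
            )
    return pd.DataFrame(rows)


def aggregate_ar_study(patients: pd.DataFrame) -> pd.DataFrame:
    """Collapse a patient-level AE table to per-arm counts in the shape
    expected by :func:`pegtk.clinical.period_table`."""
    rows = []
    for arm, g in patients.groupby("arm", sort=False):
        rows.append(
            {
                "arm": arm,
                "period": "overall",
                "n": len(g),
                "n_ar": int(g["ar"].sum()),
                "n_cns_ar": int(g["cns_ar"].sum()),
            }
        )
    return pd.DataFrame(rows)
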