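# pegtk

Model-based safety analysis of a weekly PEGylated recombinant human
growth hormone (PEG-rhGH: a 40 kDa branched PEG on the 22 kDa protein,
clinical dose 0.2 mg/kg/week in pediatric growth-hormone deficiency).
The package is for PK/tox scientists who need to reproduce, stress-test
or extend the quantitative backbone of such a safety program:

* **population toxicokinetics** — simulation and parameter recovery for
  the monkey and pediatric structural PK models;
* **exposure margins and interspecies bridging** — margins of exposure
  (MoE) from observed TK metrics, and AUC-matched human-equivalent
  doses;
* **choroid-plexus (CP) vacuolation** — a transit-compartment model of
  the vacuole/cell-number ratio, with threshold-dose and recovery-time
  prediction and necropsy-table summaries;
* **clinical safety** — adverse-reaction (AR) incidence arithmetic and
  two-group proportion comparisons;
* **synthetic data** — seeded generators for every input (TK cohorts,
  vacuolation necropsy tables, patient-level AE tables), since the
  underlying animal/patient data were never deposited.

## Models

Monkey TK: one-compartment, zero-order absorption over a window
`Dzero`, parallel first-order and Michaelis–Menten elimination:

```
dA/dt = In(t) − CL·C − Vmax·C/(Km + C),   C = A/Vc
In(t) = F·Dose/Dzero  inside each dose's absorption window, else 0
```

Pediatric PK: one-compartment with parallel zero-order (fraction
`frZero`) and first-order (`ka`) absorption and linear elimination
`CL/Vc`. Inter-individual variability is log-normal,
`θᵢ = θ_TV·exp(ηᵢ)`, `ηᵢ ~ N(0, ω²)`; observations carry combined
residual error `Y = C·(1+ε) + ξ` with an 8 ng/ml LLOQ.

Vacuolation PD: a transit chain driven by serum concentration,

```
dA₁/dt = kin·C(t) − ktr·A₁
dAᵢ/dt = ktr·(Aᵢ₋₁ − Aᵢ),  i = 2…n−1
dAₙ/dt = ktr·Aₙ₋₁ − kout·Aₙ,     R(t) = V0 + Aₙ
```

with `V0 = 0.0595`, the spontaneous control background ratio.
Population fitting is a documented **two-stage** estimator (individual
maximum-likelihood fits, then geometric-mean typical values and
log-variance ω²) — a transparent substitution for the original
nonlinear-mixed-effects fit, whose parameter values were never
published. See `docs/methods.md`.

## Worked example

```
$ python examples/02_safety_margins_and_bridging.py
dose (mg/kg/wk)   MoE Cmax   MoE AUC
           0.3        9.3       4.9
           1.0       39.6      30.1
           3.0      136.1     120.5
```

The margins are monkey exposure at each toxicology dose over pediatric
exposure at the clinical dose: the no-observed-adverse-effect level
(3 mg/kg/week) sits 136.1-fold above the clinical Cmax and 120.5-fold
above the clinical AUC. `examples/03_vacuolation_model.py` prints the
52-week vacuole/cell ratios (0.084 / 0.174 / 0.490 at 0.3 / 1 / 3
mg/kg/week against the 0.0595 background), the predicted threshold dose
(0.60 mg/kg/week under the canonical truth set) and the multi-year
recovery of the high-dose group. `examples/04_synthetic_cohort_and_fit.py`
simulates a 12-animal cohort and recovers CL = 0.548 (truth 0.550) and
Vc = 49.6 (truth 50.0).

TK datasets round-trip as NONMEM-dialect CSV (`ID, GROUP, TIME, DV,
AMT, EVID, MDV, BLQ`; `EVID 1` dose rows with `AMT` in mg/kg and
`MDV 1`, `EVID 0` observation rows with `DV` in ng/ml).

A thin CLI mirrors the library (`pegtk synth|fit|nca|ss|moe|bridge|
convert|pd-simulate|threshold-dose|recovery-time|vac-summary|
ar-report|run-all`); `pegtk run-all --seed 1 --out report/` writes the
full deterministic report bundle.

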