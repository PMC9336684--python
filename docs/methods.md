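# Methods

This note records the models, the canonical parameter choices, the
numerical decisions, and the limits of what the synthetic-data tests
demonstrate.

## Structural PK models

**Monkey (toxicokinetic).** One compartment; a subcutaneous dose enters
as a zero-order infusion of duration `Dzero` (default 24 h — the source
analysis never states it; a day-long absorption window is typical of a
PEGylated s.c. protein); elimination is parallel first-order (`CL`) and
Michaelis–Menten (`Vmax`, `Km`). The original model description also
names an inter-compartmental clearance `Q` while calling the model
one-compartment; we implement strictly one compartment and carry `Q` as
an inert optional field so parameter files from a two-compartment
parameterisation still parse. Amounts are carried per kg body weight
(ng/kg), so with `Vc` in ml/kg no body weight enters the equations.

**Pediatric.** One compartment; absorption is split between a
zero-order route (fraction `frZero`, default 0.5 — unstated in the
source; an even split is the neutral choice) and a first-order depot
(`ka`); elimination is linear. Units package-wide: h, ng/ml, mg/kg,
ml/kg; the single mg→ng factor lives in `pk_core`.

**Steady state** is declared when AUC over one dosing interval changes
by <0.1% between consecutive intervals (cap 200 intervals, error on
non-convergence). Tmax ties break to the earliest time. NCA uses the
linear trapezoid on the full grid.

## Canonical truth parameters

The original population fit published no parameter values, so the
package ships a documented truth set (`pegtk.config`), chosen once so
that model exposures approximate the program's printed TK summary —
the only quantitative PK information available:

| parameter | value | rationale |
|---|---|---|
| monkey CL | 0.55 ml/h/kg | with Vmax/Km it reproduces AUC at 3 mg/kg/wk (~3.8e6 vs printed 4.5e6 ng·h/ml) |
| monkey Vc | 50 ml/kg | Cmax ~46,000 ng/ml at 3 mg/kg/wk (printed 46,290) |
| monkey Vmax, Km | 2200 ng/h/kg, 2000 ng/ml | low-dose effective clearance CL+Vmax/Km ≈ 1.65, matching the printed sub-proportional AUCs (182,550 at 0.3; 1,120,960 at 1) |
| F, Dzero | 0.8, 24 h | typical s.c. bioavailability; see above |
| human CL | 4.3 ml/h/kg | AUCtau,ss = F·dose/CL ≈ 37,208 at 0.2 mg/kg/wk (printed 37,229) |
| human Vc, ka, frZero | 320 ml/kg, 0.03 /h, 0.5 | Cmax ≈ 382 (printed 340 ± 44), Tmax ~2 d |

With these values the AUC-matched human equivalent of a 0.08 mg/kg/week
monkey dose is 0.24 mg/kg/week, consistent with the reported
0.2-mg/kg-in-children ↔ 0.08-mg/kg-in-monkeys correspondence. These are
plausibility anchors, not fitting targets; no test asserts them.

## Variability, error, and the synthetic cohort

IIV is log-normal and independent across parameters (no ω covariance is
described in the source); defaults ω² = 0.04 (20% CV) on CL and Vc.
Residual error is proportional (15%) plus additive (2 ng/ml — a quarter
of the 8 ng/ml LLOQ, so blank samples essentially never quantify).
Observations below the LLOQ are flagged BLQ and retained; fitting
excludes them (simple exclusion; an M3-style censored likelihood is the
natural extension). Negative simulated observations are possible under
the additive term and are always BLQ.

Randomness: one global integer seed; per-individual substreams are
`default_rng([seed, index])`, so cohorts are reproducible and adding an
animal does not reshuffle the others.

The default monkey study design mirrors the published one: five groups
at 0/0.3/1/1/3 mg/kg/week (18/12/10/12/12 animals, 64 in total),
staggered necropsies at days 184/374/1096/1465 (the 26-week arm at
184/366), 52 weekly doses (26 for the 26-week arm). The sampling
schedule is not itemised in the source ("up to 8,736 h postdose"); the
default uses rich windows (1–167 h) after the first and last dose,
pre-dose troughs every 4th week, and 8-weekly washout samples for
recovery animals.

## Two-stage estimation

Stage 1 fits each individual by maximum likelihood under the combined
error model with **known, fixed** residual SDs (the configured values);
the Gaussian −2LL uses per-point variance `σ_prop²·C² + σ_add²`.
Optimisation is L-BFGS-B in log-parameter space (positivity by
construction), bounds two decades around the initial estimate, three
deterministically jittered starts, iteration cap 80. Stage 2 takes
geometric means and log-variances across individuals.

Identifiability: with a single rich occasion, `CL` and `(Vmax, Km)`
trade off along a likelihood ridge — only the low-concentration slope
`CL + Vmax/Km` is well determined, and individual fits can wander to
e.g. (CL 0.08, Vmax 6,700, Km 4,500) at 10% noise. Two safeguards:

* `fit_two_stage` holds `Km` at its population-typical initial value in
  the individual fits by default (`fixed=("Km",)`; pass `fixed=()` to
  free it). `fit_individual` itself keeps all four monkey parameters
  free.
* independently, `Km` is fixed with a warning when every observation
  sits below `Km/10` (the saturable pathway is then invisible).

The recovery experiment (`pegtk.experiments`) uses a 16-point rich
schedule spanning absorption, the saturated peak, and the washout below
`Km` (1–288 h after a single 1 mg/kg dose). Under the stated conditions
(12 animals, ω²_CL = 0.04, 10% proportional error, 20 replicates) it
recovers typical CL with ~5% and Vc with ~1% median error, and ω²_CL
near its simulated value. This validates the estimator on data that
match its assumptions; it says nothing about model misspecification,
covariates, or inter-occasion variability, none of which the generator
emulates.

## Vacuolation model and predictions

The transit formulation (drive `kin·C`, chain rate `ktr`, terminal loss
`kout`, additive baseline `V0`) is the standard interpretation of a
"transit-compartment PD model of vacuole/cell number"; the source never
writes the equations, so this is our documented reading. Defaults:
`n = 3` transit compartments, `ktr = 0.002 /h` (~9-week mean transit,
matching vacuolation that needs ≥6 weeks to appear), `kout = 5e-5 /h`
(~1.6-year half-life, giving multi-year recovery like the observed
only-partial reversal after 157 weeks), `kin = 3e-9 (ng/ml)⁻¹h⁻¹`
(scaled so the 3 mg/kg/week group reaches a severe-range ratio ~0.49 at
52 weeks), `V0 = 0.0595` so the drug-free trajectory sits exactly at
the observed control-background median.

`threshold_dose` bisects the weekly dose until the 52-week ratio equals
a target (tolerance 1e-3 mg/kg). Because the drug-free trajectory *is*
`V0`, a target equal to `V0` is degenerate and returns the lower
bracket with an `at_or_below` flag. The workflow and CLI therefore
define "induced vacuolation" as a drug-attributable increment equal to
one control-background median (target `V0 + 0.0595`): under the
canonical truth set this gives 0.60 mg/kg/week, and recovery of the
high-dose group back to that level takes ~4.8 years — the same order
as, but not a reproduction of, the originally reported 0.55 mg/kg/week
and 8.1 years, which depended on unpublished fitted parameters.
`recovery_time` integrates the drug-free system with terminal event
detection (horizon 20 years, `inf` beyond).

Severity grades (−/+/++/+++ = none/minimal/moderate/severe) are mapped
from the quantitative ratio by a monotone step function with
package-defined cuts 0.06/0.15/0.35 — the source grades by pathologist
judgment only. The cuts place the control background (0.0595) in "−"
while letting its noise distribution straddle into "+", mirroring the
2-of-8 minimal findings in control animals. The composite severity
in summaries is mean area × mean ratio. The synthetic vacuole
generator multiplies the model ratio by median-1 log-normal noise
(default 25% CV) and invents a vacuole area proportional to the ratio
(500 µm² per unit ratio) — area was quantified but its scale never
tabulated, so the area column is structurally, not numerically,
realistic.

## Margins, bridging, conversions

MoE is the plain ratio of animal to human exposure (Cmax and AUC),
rounded half-up to one decimal as in the source tables; raw ratios are
retained. Bridging matches steady-state AUCtau by a bracketing
root-finder on dose over [1e-4, 100] mg/kg (Brent, with steady state
itself resolved to 0.1%).

Dose-unit converters: PEG mass = GH dose × 40/22 (40 kDa PEG on a
22 kDa protein, half-up to 2 dp). The molar converter divides by an
effective 22.22 kDa per µmol and reports 3 significant figures — the
one constant that reproduces all four printed molar values (0.0135,
0.045, 0.135 µmol/kg and 0.2 → 0.009); the source's own two
conversions are mutually inconsistent at the ~1% level, and each
printed behaviour is preserved in its own converter.

## Clinical AR analysis

Incidences are exact rational percentages rounded half-up to 2 dp, with
the report's display convention (trailing zeros dropped: "10", "0").
The source does not name its two-group test; the default is chi-square
with continuity correction, switching to Fisher's exact test when any
expected cell is <5. The reproduced claim is only the p > 0.05 flag,
which is robust to that choice (phase III p ≈ 0.11, phase IV p ≈ 0.94).
Degenerate tables (zero margin) return p = 1 with a warning. In the
synthetic AE generator, CNS events imply an AR (subset property), which
inflates the AR rate by at most p_CNS ≤ 0.01.

## Numerical choices

* ODEs: LSODA (`scipy.integrate.odeint`) at rtol = atol = 1e-8,
  integrated piecewise between absorption-window edges and dose times so
  input discontinuities land exactly on integration boundaries; depot
  boluses are state jumps at segment edges.
* PD driven by PK via linear interpolation of a 2-h (4-h for the
  necropsy generator) concentration grid, held at zero beyond the
  profile (drug-free continuation); PD tolerances rtol 1e-8 /
  atol 1e-12 with the step capped at four concentration-grid intervals
  so absorption windows are never skipped.
* Rounding that matches printed tables is decimal half-up, never
  binary round-half-even.
* Optimizer/bisection tolerances as above; `human_equivalent_dose`
  raises a bracketing error if no dose in [1e-4, 100] mg/kg matches.
* Degenerate inputs fail loudly: non-monotone grids, single-point NCA,
  events > denominators, unknown grade symbols, criteria below `V0`.

## Problem sizes

The shipped experiments use 20 replicate 12-animal cohorts for
parameter recovery (~1 min), the full 64-animal published design for
the workflow bundle (~20 s), and 52-week horizons for all PD
predictions — sizes chosen so the whole pipeline stays interactive on a
laptop while keeping Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* Two-stage estimation (not FOCE/SAEM): unbiased here because cohorts
  are rich and balanced; sparse designs would need shrinkage-aware
  methods.
* Residual SDs are not estimated; they are part of the configuration.
* No covariates, no sex effects (the study was 32/sex), no
  inter-occasion variability, no joint modelling of vacuole size and
  ratio (size is summarised but not dynamically modelled).
* The threshold/recovery predictions are conditional on the canonical
  truth set; they are order-of-magnitude anchors, not reproductions of
  the originally reported 0.55 mg/kg/week and 8.1 years.
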