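"""Transit-compartment vacuolation model, predictions, and summaries."""

import numpy as np
import pandas as pd
import pytest

from pegtk import reference
from pegtk.errors import BracketingError, InputError, UnreachableError
from pegtk.pk_core import ConcentrationProfile, DoseRegimen, simulate_monkey_pk
from pegtk.vacuolation import (
    TransitPDParams,
    grade_counts,
    grade_from_ratio,
    recovery_time,
    simulate_vacuole_ratio,
    summarize_vacuoles,
    threshold_dose,
)


def constant_profile(c, t_end=20_000.0):
    t = np.linspace(0.0, t_end, 200)
    return ConcentrationProfile(t, np.full_like(t, float(c)))


def test_no_drive_stays_at_baseline(pd_truth):
    prof = constant_profile(0.0)
    traj = simulate_vacuole_ratio(prof, pd_truth, np.linspace(0.0, 5000.0, 20))
    np.testing.assert_allclose(traj.ratio, pd_truth.V0, atol=1e-10)


def test_single_compartment_steady_state_closed_form():
    """For n=1 and constant drive c the response converges to
    V0 + kin*c/kout."""
    p = TransitPDParams(n_transit=1, ktr=0.01, kin=0.01, kout=0.05, V0=0.05)
    traj = simulate_vacuole_ratio(constant_profile(10.0), p, np.array([0.0, 400.0]))
    assert traj.ratio[-1] == pytest.approx(0.05 + 0.01 * 10.0 / 0.05, rel=1e-4)


def test_multi_compartment_steady_state_closed_form():
    """The chain preserves the steady state kin*c/kout regardless of n."""
    p = TransitPDParams(n_transit=4, ktr=0.05, kin=0.002, kout=0.04, V0=0.0)
    traj = simulate_vacuole_ratio(constant_profile(5.0), p, np.array([0.0, 2000.0]))
    assert traj.ratio[-1] == pytest.approx(0.002 * 5.0 / 0.04, rel=1e-4)


def test_response_monotone_under_constant_drive_below_steady_state(pd_truth):
    traj = simulate_vacuole_ratio(
        constant_profile(5000.0, 60_000.0), pd_truth, np.linspace(0.0, 50_000.0, 300)
    )
    assert np.all(np.diff(traj.ratio) >= -1e-12)
    assert np.all(traj.ratio >= pd_truth.V0 - 1e-9)


# ---------------------------------------------------------------- recovery
def test_recovery_time_zero_when_already_recovered(pd_truth):
    state = np.zeros(pd_truth.n_transit)
    assert recovery_time(pd_truth, state, pd_truth.V0 + 0.01) == 0.0


def test_recovery_time_single_compartment_closed_form():
    """For n=1 drug-free decay is a single exponential, so the recovery
    time is ln(a/(criterion - V0))/kout."""
    p = TransitPDParams(n_transit=1, ktr=0.01, kin=0.001, kout=2e-4, V0=0.0595)
    a0 = 0.4
    criterion = 0.08
    expected = np.log(a0 / (criterion - p.V0)) / p.kout
    got = recovery_time(p, np.array([a0]), criterion)
    assert got == pytest.approx(expected, rel=1e-3)


def test_recovery_event_agrees_with_dense_grid_oracle(pd_truth):
    """Brute-force drug-free integration on a fine grid must locate the
    same crossing (within one grid step) as the event detector."""
    state = np.array([0.05, 0.1, 0.3])
    criterion = pd_truth.V0 + 0.05
    got = recovery_time(pd_truth, state, criterion)
    grid = np.linspace(0.0, 200_000.0, 40_001)  # 5 h steps
    zero = ConcentrationProfile(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
    traj = simulate_vacuole_ratio(zero, pd_truth, grid, initial_state=state)
    below = np.nonzero(traj.ratio <= criterion)[0]
    assert below.size
    assert abs(grid[below[0]] - got) <= 5.0


def test_recovery_below_baseline_unreachable(pd_truth):
    with pytest.raises(UnreachableError):
        recovery_time(pd_truth, np.zeros(pd_truth.n_transit), pd_truth.V0 / 2)


def test_unreached_criterion_returns_infinity():
    p = TransitPDParams(n_transit=1, ktr=0.01, kin=0.001, kout=1e-7, V0=0.0)
    t = recovery_time(p, np.array([1.0]), 0.5, horizon_h=1000.0)
    assert np.isinf(t)


# ---------------------------------------------------------------- threshold
def test_threshold_dose_inverts_forward_simulation(monkey_truth, pd_truth):
    """Round trip: the ratio simulated at dose d* used as the target must
    return d* to the bisection tolerance (1e-3 mg/kg)."""
    d_star = 1.0
    horizon = 52 * 168.0
    grid = np.arange(0.0, horizon + 2.0, 2.0)
    grid[-1] = horizon
    prof = simulate_monkey_pk(
        monkey_truth, DoseRegimen(dose=d_star, tau=168.0, nDoses=52), grid
    )
    target = float(
        simulate_vacuole_ratio(prof, pd_truth, np.array([horizon])).ratio[-1]
    )
    res = threshold_dose(monkey_truth, pd_truth, target=target)
    assert not res.at_or_below
    assert res.dose == pytest.approx(d_star, abs=2e-3)


def test_threshold_dose_monotone_in_target(monkey_truth, pd_truth):
    low = threshold_dose(monkey_truth, pd_truth, target=pd_truth.V0 + 0.03)
    high = threshold_dose(monkey_truth, pd_truth, target=pd_truth.V0 + 0.08)
    assert high.dose > low.dose


def test_threshold_degenerate_target_flags_lower_bracket(monkey_truth, pd_truth):
    """A target equal to the drug-free baseline is met at (or below) any
    dose: the search returns the lower bracket bound, flagged."""
    res = threshold_dose(monkey_truth, pd_truth, target=pd_truth.V0)
    assert res.at_or_below and res.dose == 1e-3


def test_threshold_unreachable_target_raises(monkey_truth, pd_truth):
    with pytest.raises(BracketingError):
        threshold_dose(monkey_truth, pd_truth, target=0.99, bracket=(1e-3, 3.0))


# ---------------------------------------------------------------- summaries
def test_summary_reproduces_published_grade_tallies():
    """The per-group tallies of the packaged necropsy-grade table must
    match the published counts (1 mg/kg day 374: 2 minimal + 6 moderate;
    0.3 mg/kg day 374: 7 none + 1 minimal)."""
    summary = summarize_vacuoles(reference.cp_grade_observations())
    row4 = summary[(summary["group"] == "group4_1") & (summary["day"] == 374)].iloc[0]
    assert grade_counts(row4) == {"+": 2, "++": 6} and row4["n"] == 8
    row2 = summary[(summary["group"] == "group2_0.3") & (summary["day"] == 374)].iloc[0]
    assert grade_counts(row2) == {"-": 7, "+": 1}
    row5 = summary[(summary["group"] == "group5_3") & (summary["day"] == 374)].iloc[0]
    assert grade_counts(row5) == {"++": 5, "+++": 3}


def test_single_row_summary_equals_that_row():
    df = pd.DataFrame(
        [{"group": "g", "day": 1, "vacuole_ratio": 0.2, "mean_area_um2": 40.0,
          "grade": "++"}]
    )
    s = summarize_vacuoles(df).iloc[0]
    assert s["n"] == 1
    assert s["mean_ratio"] == 0.2
    assert s["mean_area_um2"] == 40.0
    assert s["area_x_ratio"] == pytest.approx(8.0)
    assert grade_counts(s) == {"++": 1}


def test_unknown_grade_symbol_rejected():
    df = pd.DataFrame([{"group": "g", "day": 1, "grade": "?"}])
    with pytest.raises(InputError, match="unknown severity grade"):
        summarize_vacuoles(df)


def test_grade_mapping_examples_and_monotonicity():
    assert grade_from_ratio(0.0) == "-"
    assert grade_from_ratio(0.0595) == "-"  # control background -> no effect
    assert grade_from_ratio(0.1) == "+"
    assert grade_from_ratio(0.2) == "++"
    assert grade_from_ratio(0.9) == "+++"
    order = {g: i for i, g in enumerate(("-", "+", "++", "+++"))}
    grades = [order[grade_from_ratio(r)] for r in np.linspace(0.0, 1.0, 101)]
    assert all(a <= b for a, b in zip(grades, grades[1:]))
    with pytest.raises(InputError):
        grade_from_ratio(1.5)
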