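"""Structural PK models against closed-form oracles and NCA definitions."""

import numpy as np
import pytest

from pegtk.errors import ConvergenceError, InputError, ParameterError
from pegtk.pk_core import (
    ConcentrationProfile,
    DoseRegimen,
    ExposureMetrics,
    HumanPKParams,
    MonkeyPKParams,
    nca,
    simulate_human_pk,
    simulate_monkey_pk,
    steady_state_metrics,
)

MG_TO_NG = 1.0e6


# ---------------------------------------------------------------- oracles
def infusion_decay(t, dose_mg, F, Dzero, CL, Vc):
    """One-compartment model with a zero-order infusion over [0, Dzero]
    and linear elimination: the piecewise infusion/decay closed form."""
    t = np.asarray(t, dtype=float)
    k = CL / Vc
    r = F * dose_mg * MG_TO_NG / Dzero
    c_during = r / CL * (1.0 - np.exp(-k * t))
    c_end = r / CL * (1.0 - np.exp(-k * Dzero))
    c_after = c_end * np.exp(-k * (t - Dzero))
    return np.where(t <= Dzero, c_during, c_after)


def bateman(t, dose_mg, F, ka, CL, Vc):
    """First-order absorption / first-order elimination closed form."""
    t = np.asarray(t, dtype=float)
    k = CL / Vc
    return (
        F * dose_mg * MG_TO_NG * ka / (Vc * (ka - k))
        * (np.exp(-k * t) - np.exp(-ka * t))
    )


# ---------------------------------------------------------------- monkey
def test_zero_dose_gives_zero_concentration(monkey_truth, human_truth, week_grid):
    reg = DoseRegimen(dose=0.0, tau=168.0, nDoses=2)
    grid = np.linspace(0.0, 336.0, 100)
    assert np.all(simulate_monkey_pk(monkey_truth, reg, grid).conc == 0)
    assert np.all(simulate_human_pk(human_truth, reg, grid).conc == 0)


def test_monkey_linear_limit_matches_infusion_closed_form(week_grid):
    """With Vmax -> 0 the monkey model must reduce to the analytic
    one-compartment zero-order-input solution."""
    p = MonkeyPKParams(CL=1.5, Vc=60.0, Vmax=0.0, Km=2000.0, F=0.8, Dzero=24.0)
    reg = DoseRegimen(dose=1.0, tau=168.0, nDoses=1)
    prof = simulate_monkey_pk(p, reg, week_grid[1:])
    expected = infusion_decay(week_grid[1:], 1.0, p.F, p.Dzero, p.CL, p.Vc)
    np.testing.assert_allclose(prof.conc, expected, rtol=1e-6)


def test_monkey_huge_km_matches_linearised_clearance(week_grid):
    """With Km >> C the saturable pathway acts as extra linear clearance
    Vmax/Km, so the profile must match the linear model with total
    clearance CL + (Vmax/Km)."""
    k2 = 0.5  # ml/h/kg of extra linear clearance
    km = 1e12
    p = MonkeyPKParams(CL=1.0, Vc=50.0, Vmax=k2 * km, Km=km, F=0.8, Dzero=24.0)
    reg = DoseRegimen(dose=1.0, tau=168.0, nDoses=1)
    prof = simulate_monkey_pk(p, reg, week_grid[1:])
    expected = infusion_decay(week_grid[1:], 1.0, p.F, p.Dzero, p.CL + k2, p.Vc)
    np.testing.assert_allclose(prof.conc, expected, rtol=1e-4)


def test_simulated_concentrations_non_negative(monkey_truth, human_truth):
    grid = np.linspace(0.0, 52 * 168.0, 1000)
    reg = DoseRegimen(dose=3.0, tau=168.0, nDoses=52)
    assert np.all(simulate_monkey_pk(monkey_truth, reg, grid).conc >= 0)
    assert np.all(simulate_human_pk(human_truth, reg, grid).conc >= 0)


# ---------------------------------------------------------------- human
def test_human_first_order_limit_matches_bateman(week_grid):
    p = HumanPKParams(CL=4.0, Vc=300.0, ka=0.05, frZero=0.0, Dzero=24.0, F=0.8)
    reg = DoseRegimen(dose=0.2, tau=168.0, nDoses=1)
    prof = simulate_human_pk(p, reg, week_grid[1:])
    expected = bateman(week_grid[1:], 0.2, p.F, p.ka, p.CL, p.Vc)
    np.testing.assert_allclose(prof.conc, expected, rtol=1e-6)


def test_human_zero_order_limit_matches_infusion_closed_form(week_grid):
    p = HumanPKParams(CL=4.0, Vc=300.0, ka=0.05, frZero=1.0, Dzero=24.0, F=0.8)
    reg = DoseRegimen(dose=0.2, tau=168.0, nDoses=1)
    prof = simulate_human_pk(p, reg, week_grid[1:])
    expected = infusion_decay(week_grid[1:], 0.2, p.F, p.Dzero, p.CL, p.Vc)
    np.testing.assert_allclose(prof.conc, expected, rtol=1e-6)


# ---------------------------------------------------------------- NCA
def test_nca_rectangle_triangle_and_exponential():
    t = np.linspace(0.0, 168.0, 2)
    rect = nca(ConcentrationProfile(t, np.full_like(t, 10.0)))
    assert rect.AUClast == pytest.approx(1680.0)
    assert rect.Cmax == 10.0 and rect.Tmax == 0.0

    tri = nca(ConcentrationProfile(np.array([0.0, 10.0]), np.array([0.0, 10.0])))
    assert tri.AUClast == pytest.approx(50.0)

    t = np.linspace(0.0, 1000.0, 5001)
    expo = nca(ConcentrationProfile(t, 100.0 * np.exp(-0.01 * t)))
    analytic = 100.0 / 0.01 * (1.0 - np.exp(-10.0))
    assert expo.AUClast == pytest.approx(analytic, rel=5e-3)


def test_nca_tmax_is_earliest_maximum():
    t = np.array([0.0, 1.0, 2.0, 3.0])
    m = nca(ConcentrationProfile(t, np.array([0.0, 5.0, 5.0, 1.0])))
    assert m.Tmax == 1.0


def test_trapezoid_error_shrinks_quadratically():
    """Halving the grid step must reduce the AUC error ~4x on a smooth
    profile (second-order accuracy of the trapezoid rule)."""
    analytic = 100.0 / 0.01 * (1.0 - np.exp(-5.0))

    def auc_err(n):
        t = np.linspace(0.0, 500.0, n)
        m = nca(ConcentrationProfile(t, 100.0 * np.exp(-0.01 * t)))
        return abs(m.AUClast - analytic)

    ratio = auc_err(101) / auc_err(201)
    assert 3.0 < ratio < 5.0


# ---------------------------------------------------------------- steady state
def test_ss_equals_single_dose_auc_when_no_accumulation():
    """If the dosing interval spans many half-lives, AUCtau,ss must equal
    the single-dose AUC(0, inf) = F*dose/CL."""
    p = HumanPKParams(CL=10.0, Vc=100.0, ka=0.5, frZero=0.5, Dzero=6.0, F=0.8)
    # k = 0.1/h -> k*tau = 16.8 half... >> 1
    m = steady_state_metrics(p, DoseRegimen(dose=0.2, tau=168.0, nDoses=1))
    expected = p.F * 0.2 * MG_TO_NG / p.CL
    assert m.AUCtauSS == pytest.approx(expected, rel=5e-3)


def test_ss_superposition_under_dose_splitting():
    """In a linear model the weekly steady-state AUC is invariant to
    splitting the weekly dose across shorter intervals."""
    p = HumanPKParams(CL=4.3, Vc=320.0, ka=0.03, frZero=0.5, Dzero=24.0, F=0.8)
    weekly = steady_state_metrics(p, DoseRegimen(dose=0.2, tau=168.0, nDoses=1))
    halves = steady_state_metrics(p, DoseRegimen(dose=0.1, tau=84.0, nDoses=1))
    assert 2 * halves.AUCtauSS == pytest.approx(weekly.AUCtauSS, rel=5e-3)


def test_ss_saturation_makes_auc_supra_proportional(monkey_truth):
    """With Vmax > 0, AUCtau,ss/dose must strictly increase with dose."""
    per_dose = [
        steady_state_metrics(monkey_truth, DoseRegimen(dose=d)).AUCtauSS / d
        for d in (0.3, 1.0, 3.0)
    ]
    assert per_dose[0] < per_dose[1] < per_dose[2]


def test_ss_convergence_cap_raises(monkey_truth):
    with pytest.raises(ConvergenceError, match="relative change"):
        steady_state_metrics(
            monkey_truth, DoseRegimen(dose=3.0), max_intervals=2
        )


# ---------------------------------------------------------------- validation
@pytest.mark.parametrize(
    "kwargs",
    [
        dict(CL=-1.0, Vc=50.0, Vmax=0.0, Km=1.0),
        dict(CL=1.0, Vc=0.0, Vmax=0.0, Km=1.0),
        dict(CL=1.0, Vc=50.0, Vmax=0.0, Km=0.0),
        dict(CL=1.0, Vc=50.0, Vmax=0.0, Km=1.0, Dzero=0.0),
        dict(CL=1.0, Vc=50.0, Vmax=0.0, Km=1.0, F=1.5),
    ],
)
def test_invalid_monkey_params_rejected(kwargs):
    with pytest.raises(ParameterError):
        MonkeyPKParams(**kwargs)


def test_non_monotone_grid_rejected(monkey_truth, weekly_regimen):
    with pytest.raises(InputError):
        simulate_monkey_pk(monkey_truth, weekly_regimen, np.array([0.0, 2.0, 1.0]))


def test_single_point_profile_rejected_by_nca():
    with pytest.raises(InputError):
        nca(ConcentrationProfile(np.array([0.0]), np.array([1.0])))


def test_profile_round_trips_to_csv(tmp_path, monkey_truth, weekly_regimen, week_grid):
    prof = simulate_monkey_pk(monkey_truth, weekly_regimen, week_grid)
    path = tmp_path / "profile.csv"
    prof.to_csv(path)
    back = ConcentrationProfile.from_csv(path)
    np.testing.assert_allclose(back.times, prof.times)
    np.testing.assert_allclose(back.conc, prof.conc, rtol=1e-9)
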