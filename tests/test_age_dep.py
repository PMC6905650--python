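"""Checks of the age-dependent-loss (transport PDE) solver."""

import numpy as np
import pytest

from memfate import (
    AgeDepParams,
    HomogeneousParams,
    cumulative_loss,
    derived_quantities,
    eval_source,
    loss_rate,
    solve_age_dep,
    solve_homogeneous,
)
from oracles import survival_quad, upwind_age_dep_totals

BMT = 40.0
TIMES = np.linspace(95.0, 500.0, 15)


@pytest.mark.parametrize("a", [10.0, 100.0, 500.0])
def test_cohort_survival_matches_adaptive_quadrature(a):
    p = AgeDepParams(phi=1e-3, p=0.0, lam0=0.022, A=150.0, n=3)
    surv = np.exp(-cumulative_loss(p, a))
    assert surv == pytest.approx(survival_quad(p, a), rel=1e-8)


def test_exponential_loss_form_survival(a=200.0):
    p = AgeDepParams(phi=1e-3, p=0.0, lam0=0.02, A=80.0, form="exponential")
    assert np.exp(-cumulative_loss(p, a)) == pytest.approx(survival_quad(p, a), rel=1e-8)


def test_constant_loss_rate_reduces_to_homogeneous(cfg_clean, naive_clean, chi_naive):
    """With A -> infinity, lam(a) = lam0 and the transport model collapses to
    the one-pool ODE started from the initial-age-distribution integral."""
    lam0, p_exp = 0.012, 0.004
    ad = AgeDepParams(phi=6e-4, p=p_exp, lam0=lam0, A=1e9, n=3)
    t0 = cfg_clean.t0
    M0 = 6e-4 * eval_source(naive_clean, t0) * (np.exp(p_exp * t0) - 1.0) / p_exp
    hp = HomogeneousParams(M0=M0, phi=6e-4, lam=lam0)
    tr_a = solve_age_dep(ad, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    tr_h = solve_homogeneous(hp, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    assert np.max(np.abs(tr_a.total - tr_h.total) / tr_h.total) < 1e-4
    assert np.max(np.abs(tr_a.chi_norm - tr_h.chi_norm)) < 1e-4


def test_p_to_zero_limit_of_initial_pool(cfg_clean, naive_clean):
    ad = AgeDepParams(phi=4.3e-4, p=0.0, lam0=0.022, A=150.0)
    dq = derived_quantities(ad, naive_clean, cfg_clean)
    expected = 4.3e-4 * eval_source(naive_clean, cfg_clean.t0) * cfg_clean.t0
    assert dq["M_t0"] == pytest.approx(expected, rel=1e-12)
    # solver evaluated exactly at t0 must reproduce the same integral
    tr = solve_age_dep(ad, naive_clean, lambda t: np.zeros_like(np.asarray(t, float)),
                       cfg_clean, cfg_clean.t0 - cfg_clean.bmt_lag, [cfg_clean.t0])
    assert tr.total[0] == pytest.approx(expected, rel=1e-8)


def test_upwind_discretisation_oracle_short_horizon(cfg_clean, naive_clean):
    """Characteristics + quadrature vs brute-force age-discretised transport."""
    ad = AgeDepParams(phi=4.3e-4, p=0.003, lam0=0.022, A=150.0, n=3)
    t_eval = cfg_clean.t0 + np.array([25.0, 50.0, 100.0])
    brute = upwind_age_dep_totals(ad, naive_clean, cfg_clean, t_eval, dt=0.25)
    chi0 = lambda t: np.zeros_like(np.asarray(t, float))
    exact = solve_age_dep(ad, naive_clean, chi0, cfg_clean,
                          cfg_clean.t0 - cfg_clean.bmt_lag, t_eval).total
    assert np.max(np.abs(brute - exact) / exact) < 5e-3


def test_staggered_bmt_same_total_curve(cfg_clean, naive_clean, chi_naive):
    ad = AgeDepParams(phi=4.3e-4, p=0.003, lam0=0.022, A=150.0)
    t = np.linspace(250.0, 500.0, 8)
    tr_a = solve_age_dep(ad, naive_clean, chi_naive, cfg_clean, 40.0, t)
    tr_b = solve_age_dep(ad, naive_clean, chi_naive, cfg_clean, 180.0, t)
    assert np.max(np.abs(tr_a.total - tr_b.total) / tr_a.total) < 1e-10
    assert np.max(np.abs(tr_a.chi_norm - tr_b.chi_norm)) > 1e-3


def test_chimerism_bounded_and_rising_while_source_chimerism_rises(
    cfg_clean, naive_clean, chi_naive
):
    """Normalised chimerism stays in [0, 1] and rises while the source's does.

    Unlike the one-pool models, the age-structured model permits a late,
    gentle decline in donor fraction once the source wanes: donor cohorts are
    younger than the resident host cohort and so face higher loss rates.
    Monotonicity is therefore only asserted over the rising-source phase.
    """
    ad = AgeDepParams(phi=4.3e-4, p=0.003, lam0=0.022, A=150.0)
    t = np.linspace(70.0, 600.0, 80)
    tr = solve_age_dep(ad, naive_clean, chi_naive, cfg_clean, 40.0, t)
    rising = t[:-1] <= 40.0 + 150.0  # source chimerism still far from saturation
    assert np.all(np.diff(tr.chi_norm)[rising] > -1e-9)
    assert np.all(tr.chi_norm >= 0) and np.all(tr.chi_norm <= 1 + 1e-9)


def test_loss_rate_forms():
    p3 = AgeDepParams(phi=1e-3, p=0.0, lam0=0.02, A=100.0, n=3)
    assert loss_rate(p3, 0.0) == pytest.approx(0.02)
    assert loss_rate(p3, 100.0) == pytest.approx(0.01)
    pe = AgeDepParams(phi=1e-3, p=0.0, lam0=0.02, A=100.0, form="exponential")
    assert loss_rate(pe, 100.0) == pytest.approx(0.02 / np.e)
    with pytest.raises(ValueError):
        AgeDepParams(phi=1e-3, p=0.0, lam0=0.02, A=-5.0)
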