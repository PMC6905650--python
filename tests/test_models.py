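"""Forward-solver checks for the homogeneous, two-phase and resistant models."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from memfate import (
    HomogeneousParams,
    ResistantParams,
    TwoPhaseParams,
    derived_quantities,
    eval_source,
    homogeneous_closed_form,
    solve_homogeneous,
    solve_resistant,
    solve_two_phase,
)

BMT = 40.0
TIMES = np.linspace(95.0, 560.0, 25)


def test_no_influx_reduces_to_pure_decay(cfg_clean, naive_clean, chi_naive):
    p = HomogeneousParams(M0=1e6, phi=0.0, lam=0.01)
    tr = solve_homogeneous(p, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    expected = 1e6 * np.exp(-0.01 * (TIMES - cfg_clean.t0))
    assert np.max(np.abs(tr.total - expected) / expected) < 1e-6
    assert np.max(np.abs(tr.chi_norm)) < 1e-12


def test_numerical_solution_matches_closed_form(cfg_clean, naive_clean, chi_naive):
    p = HomogeneousParams(M0=1e6, phi=1e-3, lam=0.01)
    tr = solve_homogeneous(p, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    cf = homogeneous_closed_form(p, naive_clean, cfg_clean, TIMES)
    assert np.max(np.abs(tr.total - cf) / cf) < 1e-6


def test_removable_singularity_when_loss_equals_source_decay(cfg_clean, naive_clean, chi_naive):
    nu = naive_clean.params["nu"]
    p = HomogeneousParams(M0=1e6, phi=1e-3, lam=nu)
    tr = solve_homogeneous(p, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    cf = homogeneous_closed_form(p, naive_clean, cfg_clean, TIMES)
    assert np.max(np.abs(tr.total - cf) / cf) < 1e-6


def test_chimerism_stabilises_at_source_chimerism(cfg_clean, naive_clean):
    """With a constant source chimerism and nu < lam, memory chimerism -> c."""
    c = 0.8
    const_chi = lambda t: np.full_like(np.asarray(t, dtype=float), c)
    p = HomogeneousParams(M0=5e5, phi=1e-3, lam=0.02)
    tr = solve_homogeneous(p, naive_clean, const_chi, cfg_clean, BMT, np.array([3000.0]))
    assert tr.chi_norm[-1] == pytest.approx(c, abs=0.02)


def test_host_donor_decomposition_conserves_total(cfg_clean, naive_clean, chi_naive):
    """Integrating donor and host compartments separately reproduces the
    solver's total and chimerism (independent construction via solve_ivp)."""
    p = HomogeneousParams(M0=8e5, phi=1.2e-3, lam=0.015)
    T = cfg_clean.start_age(BMT)
    tr = solve_homogeneous(p, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    M_T = homogeneous_closed_form(p, naive_clean, cfg_clean, np.array([T]))[0]

    def rhs(t, y):
        S = eval_source(naive_clean, t)
        c = eval_source(chi_naive, t - BMT)
        d_donor = p.phi * c * S - p.lam * y[0]
        d_host = p.phi * (1 - c) * S - p.lam * y[1]
        return [d_donor, d_host]

    sol = solve_ivp(rhs, (T, TIMES[-1]), [0.0, M_T], method="LSODA",
                    rtol=1e-10, atol=1e-4, t_eval=TIMES)
    total = sol.y.sum(axis=0)
    assert np.max(np.abs(total - tr.total) / tr.total) < 1e-8
    chi = sol.y[0] / total
    assert np.max(np.abs(chi - tr.chi_norm)) < 1e-7


def test_two_phase_with_no_transition_reduces_to_homogeneous(cfg_clean, naive_clean, chi_naive):
    lam_fast = 0.05
    tp = TwoPhaseParams(Mslow0=0.0, phi=1e-3, lam_fast=lam_fast, lam_slow=0.01, gamma=0.0)
    hp = HomogeneousParams(
        M0=1e-3 * eval_source(naive_clean, cfg_clean.t0) / lam_fast, phi=1e-3, lam=lam_fast
    )
    tr2 = solve_two_phase(tp, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    tr1 = solve_homogeneous(hp, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    assert np.max(np.abs(tr2.total - tr1.total) / tr1.total) < 1e-8
    assert np.max(np.abs(tr2.chi_norm - tr1.chi_norm)) < 1e-7


def test_two_phase_with_equal_loss_rates_sums_to_homogeneous(cfg_clean, naive_clean, chi_naive):
    """When lam_fast == lam_slow the subset equations sum to the one-pool ODE."""
    lam = 0.02
    tp = TwoPhaseParams(Mslow0=2e5, phi=1e-3, lam_fast=lam, lam_slow=lam, gamma=0.01)
    Mf0 = 1e-3 * eval_source(naive_clean, cfg_clean.t0) / (lam + 0.01)
    hp = HomogeneousParams(M0=Mf0 + 2e5, phi=1e-3, lam=lam)
    tr2 = solve_two_phase(tp, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    tr1 = solve_homogeneous(hp, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    assert np.max(np.abs(tr2.total - tr1.total) / tr1.total) < 1e-6


def test_two_phase_fixed_point_with_constant_source(cfg_clean, chi_naive):
    S = 1e7
    const_src = lambda t: np.full_like(np.asarray(t, dtype=float), S)
    tp = TwoPhaseParams(Mslow0=1e4, phi=1e-3, lam_fast=0.1, lam_slow=5e-3, gamma=0.01)
    tr = solve_two_phase(tp, const_src, chi_naive, cfg_clean, BMT, np.array([5000.0]))
    mf_star = 1e-3 * S / (0.1 + 0.01)
    ms_star = 0.01 * mf_star / 5e-3
    assert tr.extras["fast"][-1] == pytest.approx(mf_star, rel=1e-4)
    assert tr.extras["slow"][-1] == pytest.approx(ms_star, rel=1e-4)


def test_two_phase_quasi_equilibrium_requires_positive_outflux():
    with pytest.raises(ValueError):
        TwoPhaseParams(Mslow0=1e5, phi=1e-3, lam_fast=0.0, lam_slow=0.01, gamma=0.0)


def test_resistant_without_incumbents_reduces_to_homogeneous(cfg_clean, naive_clean, chi_naive):
    rp = ResistantParams(M0=5e5, I0=0.0, phi=1e-3, lam=0.02)
    hp = HomogeneousParams(M0=5e5, phi=1e-3, lam=0.02)
    tr_r = solve_resistant(rp, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    tr_h = solve_homogeneous(hp, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    assert np.max(np.abs(tr_r.total - tr_h.total) / tr_h.total) < 1e-8
    assert np.max(np.abs(tr_r.chi_norm - tr_h.chi_norm)) < 1e-6


def test_resistant_without_influx_decays_to_incumbents(cfg_clean, naive_clean, chi_naive):
    rp = ResistantParams(M0=5e5, I0=2e5, phi=0.0, lam=0.05)
    tr = solve_resistant(rp, naive_clean, chi_naive, cfg_clean, BMT, np.array([2000.0]))
    assert tr.total[-1] == pytest.approx(2e5, rel=1e-4)


def test_resistant_chimerism_below_displaceable_chimerism(cfg_clean, naive_clean, chi_naive):
    """Incumbent host cells dilute the donor fraction of the whole pool."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        rp = ResistantParams(
            M0=float(rng.uniform(2e5, 2e6)), I0=float(rng.uniform(5e4, 1e6)),
            phi=float(rng.uniform(2e-4, 2e-3)), lam=float(rng.uniform(0.005, 0.05)),
        )
        tr = solve_resistant(rp, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
        chi_disp = tr.chi_norm * tr.total / tr.extras["displaceable"]
        assert np.all(tr.chi_norm[1:] < chi_disp[1:])


def test_staggered_bmt_shares_one_total_curve(cfg_clean, naive_clean, chi_naive):
    p = TwoPhaseParams(Mslow0=1e5, phi=1.4e-3, lam_fast=0.082, lam_slow=5.9e-3, gamma=3e-3)
    t = np.linspace(250, 500, 10)
    tr_a = solve_two_phase(p, naive_clean, chi_naive, cfg_clean, 40.0, t)
    tr_b = solve_two_phase(p, naive_clean, chi_naive, cfg_clean, 180.0, t)
    assert np.max(np.abs(tr_a.total - tr_b.total) / tr_a.total) < 1e-8
    assert np.max(np.abs(tr_a.chi_norm - tr_b.chi_norm)) > 1e-3  # chimerism curves differ


@pytest.mark.parametrize("solver,params", [
    (solve_homogeneous, HomogeneousParams(M0=6e5, phi=8e-4, lam=0.012)),
    (solve_two_phase, TwoPhaseParams(Mslow0=1e5, phi=1.4e-3, lam_fast=0.082,
                                     lam_slow=5.9e-3, gamma=2.9e-3)),
    (solve_resistant, ResistantParams(M0=5e5, I0=2e5, phi=8e-4, lam=0.02)),
])
def test_grid_backend_agrees_with_adaptive_solver(cfg_clean, naive_clean, chi_naive, solver, params):
    tr_l = solver(params, naive_clean, chi_naive, cfg_clean, BMT, TIMES)
    tr_g = solver(params, naive_clean, chi_naive, cfg_clean, BMT, TIMES, method="grid")
    assert np.max(np.abs(tr_g.total - tr_l.total) / tr_l.total) < 2e-3
    assert np.max(np.abs(tr_g.chi_norm - tr_l.chi_norm)) < 2e-3


def test_chimerism_nondecreasing_for_nondecreasing_source_chimerism(
    cfg_clean, naive_clean, chi_naive
):
    rng = np.random.default_rng(11)
    t = np.linspace(70.0, 600.0, 120)
    for _ in range(4):
        hp = HomogeneousParams(M0=float(rng.uniform(2e5, 2e6)),
                               phi=float(rng.uniform(2e-4, 3e-3)),
                               lam=float(rng.uniform(-0.002, 0.05)))
        tr = solve_homogeneous(hp, naive_clean, chi_naive, cfg_clean, 40.0, t)
        assert np.all(np.diff(tr.chi_norm) > -1e-9)


def test_trajectory_observation_times_precondition(cfg_clean, naive_clean, chi_naive):
    p = HomogeneousParams(M0=1e6, phi=1e-3, lam=0.01)
    with pytest.raises(ValueError):
        solve_homogeneous(p, naive_clean, chi_naive, cfg_clean, 40.0, [50.0])


def test_derived_quantities_symmetry_and_undefined_half_life(cfg_clean, naive_clean):
    tp = TwoPhaseParams(Mslow0=1e5, phi=1e-3, lam_fast=0.04, lam_slow=5e-3, gamma=0.04)
    dq = derived_quantities(tp, naive_clean, cfg_clean)
    assert dq["pct_to_slow"] == pytest.approx(50.0, rel=1e-12)
    hp = HomogeneousParams(M0=1e6, phi=1e-3, lam=-0.01)
    assert np.isnan(derived_quantities(hp, naive_clean, cfg_clean)["half_life"])
    assert dq["influx_at_tstar"] == pytest.approx(
        1e-3 * eval_source(naive_clean, cfg_clean.t_star), rel=1e-12
    )
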