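"""Likelihood, fitting, AICc and bootstrap machinery."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from memfate import (
    FitData,
    HomogeneousParams,
    Predictor,
    aicc,
    bootstrap_ci,
    fit_model,
    profiled_loglik,
    solve_homogeneous,
    transform,
)


def test_transform_endpoints_and_quarter():
    x, y = transform([1.0, np.e], [0.0, 1.0])
    assert y[0] == 0.0 and y[1] == pytest.approx(np.pi / 2)
    assert x[0] == 0.0 and x[1] == pytest.approx(1.0)
    _, y = transform([10.0], [0.25])
    assert y[0] == pytest.approx(np.pi / 6, rel=1e-12)


def test_transform_clips_overshoot_with_warning():
    with pytest.warns(UserWarning, match="clipped"):
        _, y = transform([10.0], [1.04])
    assert y[0] == pytest.approx(np.pi / 2)
    with pytest.raises(ValueError):
        transform([0.0], [0.5])


def _toy_data(cfg, source, chi_source, params, n=24, seed=5, sx=0.1, sy=0.04):
    rng = np.random.default_rng(seed)
    bmt = rng.choice([40.0, 90.0, 140.0], size=n)
    obs = bmt + rng.uniform(30.0, 400.0, size=n)
    x = np.empty(n)
    y = np.empty(n)
    for b in np.unique(bmt):
        m = bmt == b
        tr = solve_homogeneous(params, source, chi_source, cfg, b, obs[m])
        x[m] = np.log(tr.total)
        y[m] = np.arcsin(np.sqrt(tr.chi_norm))
    x += rng.normal(0, sx, n)
    y += rng.normal(0, sy, n)
    return FitData(bmt_age=bmt, obs_age=obs, x=x, y=y)


def test_profiled_loglik_equals_maximised_unprofiled(cfg_clean, naive_clean, chi_naive):
    """Profiling the error SDs analytically must agree with a 2-D numerical
    maximisation of the unprofiled Gaussian log-likelihood (fixed offset)."""
    params = HomogeneousParams(M0=6e5, phi=8e-4, lam=0.012)
    data = _toy_data(cfg_clean, naive_clean, chi_naive, params)
    n = len(data)
    pred = Predictor("homogeneous", naive_clean, chi_naive, cfg_clean, data)
    X, Y = pred.predict(params)
    ssr_x = float(np.sum((data.x - X) ** 2))
    ssr_y = float(np.sum((data.y - Y) ** 2))

    def neg_unprofiled(log_sig):
        sx, sy = np.exp(log_sig)
        return n * math.log(sx) + n * math.log(sy) + ssr_x / (2 * sx**2) + ssr_y / (2 * sy**2)

    res = minimize(neg_unprofiled, [math.log(0.1), math.log(0.05)], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-13, "maxfev": 4000})
    # max_sigma f0 = -(n/2) ln(SSRx SSRy) + n ln n - n, so the profiled form
    # -(n/2) ln(SSRx SSRy) - 2n equals f0_max minus the constant n ln n + n
    offset = n * math.log(n) + n
    ll = profiled_loglik(params, "homogeneous", naive_clean, chi_naive, cfg_clean, data)
    assert ll == pytest.approx(-res.fun - offset, abs=1e-10)


def test_profiled_loglik_direct_value():
    # SSR_x = SSR_y = 1 with n = 10 gives lnL = -20 exactly
    from memfate.inference import _profiled_from_ssr

    assert _profiled_from_ssr(1.0, 1.0, 10) == pytest.approx(-20.0, abs=1e-13)
    assert np.isfinite(_profiled_from_ssr(0.0, 0.0, 10))  # SSR floor keeps it finite


def test_profiled_loglik_invariant_under_permutation(cfg_clean, naive_clean, chi_naive):
    params = HomogeneousParams(M0=6e5, phi=8e-4, lam=0.012)
    data = _toy_data(cfg_clean, naive_clean, chi_naive, params)
    ll = profiled_loglik(params, "homogeneous", naive_clean, chi_naive, cfg_clean, data)
    perm = np.random.default_rng(0).permutation(len(data))
    ll_p = profiled_loglik(params, "homogeneous", naive_clean, chi_naive, cfg_clean,
                           data.subset(perm))
    assert ll_p == pytest.approx(ll, abs=1e-9)


def test_aicc_formula_and_edge_cases():
    assert aicc(0.0, 6, 100) == pytest.approx(12.0 + 84.0 / 93.0, abs=1e-12)
    assert aicc(-123.4, 0, 50) == pytest.approx(246.8)
    with pytest.raises(ValueError):
        aicc(0.0, 10, 11)
    # equal-K comparison: the AICc difference is exactly -2 * delta-loglik
    assert aicc(117.0, 8, 400) - aicc(110.0, 8, 400) == pytest.approx(-2 * 7.0, abs=1e-10)


def test_aicc_reproduces_published_scale_of_support():
    """lnL 124 with K=10 vs lnL 117 with K=8 at large common N differs by ~10."""
    delta = aicc(117.0, 8, 400) - aicc(124.0, 10, 400)
    assert delta == pytest.approx(10.0, abs=0.5)


def test_noiseless_fit_recovers_truth(cfg_clean, naive_clean, chi_naive):
    truth = HomogeneousParams(M0=6e5, phi=8e-4, lam=0.012)
    data = _toy_data(cfg_clean, naive_clean, chi_naive, truth, n=18, sx=0.0, sy=0.0)
    fit = fit_model("homogeneous", naive_clean, chi_naive, data, cfg_clean,
                    n_starts=2, seed=1, method="lsoda")
    assert fit.params.M0 == pytest.approx(truth.M0, rel=1e-4)
    assert fit.params.phi == pytest.approx(truth.phi, rel=1e-4)
    assert fit.params.lam == pytest.approx(truth.lam, rel=1e-4)


def test_refit_from_optimum_is_a_fixed_point(cfg_clean, naive_clean, chi_naive, cohort_factory):
    sim, _, data = cohort_factory("clean", "tcm", "homogeneous", n_mice=60, seed=3)
    fit = fit_model("homogeneous", sim.source_truth, sim.chi_source_truth, data,
                    cfg_clean, n_starts=3, seed=1)
    refit = fit_model("homogeneous", sim.source_truth, sim.chi_source_truth, data,
                      cfg_clean, n_starts=1, seed=9, x0=fit.params)
    assert refit.loglik == pytest.approx(fit.loglik, abs=1e-6)
    # profiled-variance bookkeeping invariants
    n = fit.n_obs
    assert fit.sigma_x_hat**2 == pytest.approx(fit.ssr_x / n, rel=1e-12)
    assert fit.sigma_y_hat**2 == pytest.approx(fit.ssr_y / n, rel=1e-12)


def test_fit_residuals_have_near_zero_mean(cfg_clean, cohort_factory):
    sim, _, data = cohort_factory("clean", "tcm", "homogeneous", n_mice=80, seed=4)
    fit = fit_model("homogeneous", sim.source_truth, sim.chi_source_truth, data,
                    cfg_clean, n_starts=3, seed=2)
    pred = Predictor("homogeneous", sim.source_truth, sim.chi_source_truth, cfg_clean, data)
    X, Y = pred.predict(fit.params)
    for r in (data.x - X, data.y - Y):
        assert abs(np.mean(r)) < 3 * np.std(r) / math.sqrt(len(r))


def test_estimator_rmse_shrinks_with_sample_size(cfg_clean, cohort_factory):
    """Consistency: relative RMSE of (M0, phi, lam) falls from n=40 to n=400."""
    truth = None
    rmse = {}
    for n in (40, 400):
        errs = []
        for seed in range(4):
            sim, _, data = cohort_factory("clean", "tcm", "homogeneous", n_mice=n, seed=100 + seed)
            truth = sim.truth_params
            fit = fit_model("homogeneous", sim.source_truth, sim.chi_source_truth,
                            data, cfg_clean, n_starts=2, seed=seed)
            errs.append([
                (fit.params.M0 - truth.M0) / truth.M0,
                (fit.params.phi - truth.phi) / truth.phi,
                (fit.params.lam - truth.lam) / truth.lam,
            ])
        rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
    assert rmse[400] < rmse[40]


def test_bootstrap_small_noise_gives_narrow_intervals(cfg_clean, cohort_factory):
    sim, _, data = cohort_factory("clean", "tcm", "homogeneous", n_mice=40, seed=6,
                                  sigma_x=1e-3, sigma_y=1e-3)
    fit = fit_model("homogeneous", sim.source_truth, sim.chi_source_truth, data,
                    cfg_clean, n_starts=2, seed=1)
    ci = bootstrap_ci(fit, sim.source_truth, sim.chi_source_truth, data, cfg_clean,
                      n_boot=30, seed=2, n_starts=1, include_derived=False)
    lo, hi = ci["param_ci"]["lam"]
    assert hi - lo < 5e-4
    # percentile convention: bounds are the linear-interpolation quantiles of
    # the replicate draws themselves
    reps = ci["replicates"]["lam"].to_numpy()
    assert lo == pytest.approx(np.quantile(reps, 0.025, method="linear"))
    assert hi == pytest.approx(np.quantile(reps, 0.975, method="linear"))


def test_fit_rejects_too_few_observations(cfg_clean, naive_clean, chi_naive):
    data = FitData(bmt_age=np.array([40.0]), obs_age=np.array([100.0]),
                   x=np.array([13.0]), y=np.array([0.3]))
    with pytest.raises(ValueError):
        fit_model("homogeneous", naive_clean, chi_naive, data, cfg_clean)
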