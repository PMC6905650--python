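"""Independent numerical oracles used by the tests.

These deliberately avoid the package's solution paths: the age-structured
model is brute-forced on a discretised age grid, and cohort survival uses
adaptive quadrature straight from scipy.
"""

import numpy as np
from scipy.integrate import quad

from memfate import eval_source, loss_rate


def upwind_age_dep_totals(params, source, cfg, t_eval, dt=0.25):
    """Brute-force transport solution of the age-structured model.

    Discretises cell age and host time with ``da = dt``; each step ages the
    density by one bin (exact transport along characteristics) with a
    midpoint survival factor, and injects a new age-0 cohort ``phi S(t)``.
    Totals are trapezoidal sums over the age grid.
    """
    t0 = cfg.t0
    t_eval = np.asarray(t_eval, dtype=float)
    t_end = float(np.max(t_eval))
    n_steps = int(round((t_end - t0) / dt))
    n_age0 = int(round(t0 / dt)) + 1
    ages_full = dt * np.arange(n_age0 + n_steps)
    # initial host cohort: density g(a) = phi S(t0) e^{p a} for a in [0, t0]
    dens = np.zeros(n_age0 + n_steps)
    dens[:n_age0] = params.phi * eval_source(source, t0) * np.exp(
        params.p * ages_full[:n_age0]
    )
    surv_step = np.exp(-loss_rate(params, ages_full + dt / 2.0) * dt)
    out = {}
    times = t0 + dt * np.arange(n_steps + 1)
    for j, t in enumerate(times):
        for te in t_eval:
            if abs(te - t) < dt / 2 and te not in out:
                k = n_age0 + j
                out[te] = float(np.trapezoid(dens[:k], dx=dt))
        if j == n_steps:
            break
        dens[1 : n_age0 + j + 1] = dens[: n_age0 + j] * surv_step[: n_age0 + j]
        dens[0] = params.phi * eval_source(source, t + dt)
    return np.array([out[te] for te in t_eval])


def survival_quad(params, a):
    """Cohort survival exp(-int_0^a lam(s) ds) by adaptive quadrature."""
    val, _ = quad(lambda s: float(loss_rate(params, s)), 0.0, a, limit=400,
                  epsabs=1e-12, epsrel=1e-12)
    return np.exp(-val)
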