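"""Early-life (ontogeny) predictions from adult-fitted parameters.

Adult parameter estimates say how fast memory is made and lost from the
baseline age onwards; running the same machinery forward from age 5 days
over the young-mouse source timecourse predicts how the T_CM and T_EM
compartments are first established.  Because early memory may be seeded by
stronger antigenic forcing than in adults, the force of recruitment ``phi``
is allowed a constant fold-correction ``phi_scale`` over a neonatal window
(age 5 d to 11 weeks by default), reverting to the adult value afterwards.
``estimate_phi_scaling`` inverts the prediction: it finds the fold-change
needed for the predicted pool at the end of the window to match the mean
size observed in adults of a given environment.  Predictions are
deliberately insensitive to the (small, poorly known) memory pool at age
5 d.

Chimerism is undefined here — these mice have had no transplant — so
predictions are totals only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .models import (
    AgeDepParams,
    HomogeneousParams,
    ResistantParams,
    Trajectory,
    TwoPhaseParams,
    _leggauss,
    _LossKernel,
)
from .sources import TabulatedSource, eval_source

__all__ = ["OntogenyScenario", "predict_early", "estimate_phi_scaling", "trajectory_source"]

_START_AGE = 5.0
_HORIZON = 77.0  # 11 weeks


@dataclass
class OntogenyScenario:
    """Inputs for an early-life prediction.

    ``source_desc`` is the young-mouse trajectory of the precursor (a fitted
    descriptor, or a :class:`TabulatedSource` built from a predicted
    trajectory for chained naive -> T_CM -> T_EM predictions).
    ``model_params`` comes from an adult fit; ``phi_scale`` multiplies the
    force of recruitment between ``start_age`` and ``horizon`` only.
    """

    source_desc: object
    model_params: object
    facility: str = "clean"
    M_init: float = 1e3
    phi_scale: float = 1.0
    target_mean: float | None = None
    start_age: float = _START_AGE
    horizon: float = _HORIZON

    def __post_init__(self):
        if self.phi_scale <= 0:
            raise ValueError("phi_scale must be positive")
        if self.M_init < 0:
            raise ValueError("M_init must be non-negative")
        if self.horizon <= self.start_age:
            raise ValueError("horizon must exceed start_age")


def trajectory_source(traj: Trajectory) -> TabulatedSource:
    """Wrap a predicted trajectory as a source for the next subset."""
    return TabulatedSource(times=np.asarray(traj.times), values=np.asarray(traj.total))


def _phi_eff(sc: OntogenyScenario, phi: float, t) -> np.ndarray:
    """Force of recruitment with the neonatal fold-correction applied."""
    t = np.asarray(t, dtype=float)
    return phi * np.where(t <= sc.horizon, sc.phi_scale, 1.0)


def predict_early(scenario: OntogenyScenario, ages) -> Trajectory:
    """Predict subset totals from ``start_age`` at the given host ages (days).

    The ODE models are integrated in two segments (neonatal window, then
    adult forcing); the age-dependent-loss model evaluates its
    characteristics integrals with the same split.  For the resistant model
    only the displaceable pool is propagated (incumbents are, by hypothesis,
    the product of this early seeding, not an input to it).
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    sc = scenario
    if np.any(ages < sc.start_age):
        raise ValueError(f"prediction ages must be >= start_age = {sc.start_age} d")
    eval_source(sc.source_desc, sc.start_age)  # raises if undefined
    p = sc.model_params
    if isinstance(p, AgeDepParams):
        total = _predict_age_dep(sc, p, ages)
        return Trajectory(times=ages, total=total, chi_norm=np.full_like(ages, np.nan))

    if isinstance(p, TwoPhaseParams):
        def rhs(t, y):
            infl = float(_phi_eff(sc, p.phi, t) * eval_source(sc.source_desc, t))
            return [infl - (p.lam_fast + p.gamma) * y[0],
                    p.gamma * y[0] - p.lam_slow * y[1]]
        y0 = [sc.M_init, 0.0]
        n_state = 2
    elif isinstance(p, (HomogeneousParams, ResistantParams)):
        def rhs(t, y):
            infl = float(_phi_eff(sc, p.phi, t) * eval_source(sc.source_desc, t))
            return [infl - p.lam * y[0]]
        y0 = [sc.M_init]
        n_state = 1
    else:
        raise TypeError(f"unsupported parameter container {type(p).__name__}")

    t_end = float(np.max(ages))
    pieces = [(sc.start_age, min(sc.horizon, t_end))]
    if t_end > sc.horizon:
        pieces.append((sc.horizon, t_end))
    y = np.asarray(y0, dtype=float)
    segments = []
    for a, b in pieces:
        if b <= a:
            continue
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=1e-8, atol=1e-2,
                        dense_output=True)
        if not sol.success:
            raise RuntimeError(f"ontogeny integration failed: {sol.message}")
        segments.append((a, b, sol.sol))
        y = sol.y[:, -1]
    total = np.empty(ages.shape)
    for i, t in enumerate(ages):
        if t <= sc.start_age + 1e-12:
            total[i] = float(np.sum(y0))
            continue
        for a, b, dense in segments:
            if a - 1e-12 <= t <= b + 1e-12:
                total[i] = float(np.sum(dense(t)))
                break
    return Trajectory(times=ages, total=total, chi_norm=np.full_like(ages, np.nan))


def _predict_age_dep(sc: OntogenyScenario, p: AgeDepParams, ages: np.ndarray) -> np.ndarray:
    """Characteristics solution with the initial pool treated as an age-0 cohort."""
    kern = _LossKernel(p, float(np.max(ages)))
    x, w = _leggauss(64)

    def influx_integral(t_arr, lo, hi):
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        half = 0.5 * (hi - lo)
        nodes = lo[:, None] + half[:, None] * (x[None, :] + 1.0)
        wts = half[:, None] * w[None, :]
        g = _phi_eff(sc, p.phi, nodes) * eval_source(sc.source_desc, nodes)
        surv = np.exp(np.clip(-(kern(t_arr[:, None] - nodes)), -700.0, 700.0))
        return np.sum(wts * g * surv, axis=1)

    # split the recruitment-age integral at the horizon so each panel is smooth
    seed = sc.M_init * np.exp(-kern(ages - sc.start_age))
    split = np.minimum(ages, sc.horizon)
    part1 = influx_integral(ages, np.full_like(ages, sc.start_age), split)
    part2 = influx_integral(ages, split, ages)  # zero width when t <= horizon
    return seed + part1 + part2


def estimate_phi_scaling(
    scenario: OntogenyScenario,
    target_mean: float | None = None,
    horizon: float | None = None,
    bracket: tuple = (1e-3, 1e3),
) -> float:
    """Fold-change in phi over the neonatal window matching a target size.

    Solves ``predict(horizon; phi_scale) = target_mean`` for ``phi_scale`` by
    bracketed root finding on the log scale (the map is monotone increasing).
    """
    target = target_mean if target_mean is not None else scenario.target_mean
    if target is None or target <= 0:
        raise ValueError("a positive target_mean is required")
    sc = scenario if horizon is None else replace(scenario, horizon=horizon)

    def f(log_s):
        s = math.exp(log_s)
        pred = predict_early(replace(sc, phi_scale=s), [sc.horizon]).total[0]
        return math.log(pred) - math.log(target)

    lo, hi = math.log(bracket[0]), math.log(bracket[1])
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"target {target:g} not reachable with phi_scale in [{bracket[0]:g}, {bracket[1]:g}]"
        )
    return math.exp(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))
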