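"""Forward models of memory CD4+ T cell population dynamics.

Four competing mechanisms for the generation and loss of a memory subset
(central memory T_CM or effector memory T_EM) in adult busulfan chimeric
mice.  Each model takes an empirical source trajectory ``S(t)`` (cells, host
age ``t`` in days), the source's normalised donor chimerism
``chi_source_norm(tau)`` (``tau`` = days post BMT), and a per-mouse age at
BMT, and predicts the subset's total size ``M(t)`` together with its
normalised donor chimerism ``chi_M_norm(t)``.

homogeneous
    One well-mixed pool: ``dM/dt = phi S(t) - lam M``.  ``phi`` is the force
    of recruitment (per source cell per day, times any expansion during
    recruitment); ``lam`` is the net loss rate (loss minus self-renewal) and
    may be negative.  Chimerism relaxes towards the source's:
    ``d chi/dt = (phi S / M)(chi_src - chi)``.

two_phase
    Recruitment into a fast pool with high net loss ``lam_fast``; transition
    to a slow pool at rate ``gamma`` with loss ``lam_slow``.  The fast pool is
    initialised in quasi-equilibrium with its source,
    ``Mfast(t0) = phi S(t0) / (lam_fast + gamma)``.

age_dep
    Net loss is a function ``lam(a)`` of cell age ``a`` (time since the clone
    entered memory): sigmoid ``lam0 / (1 + (a/A)^n)`` or exponential
    ``lam0 exp(-a/A)``.  The transport PDE is solved along characteristics,
    reducing the totals and donor numbers to one-dimensional integrals over
    cell age.  The host population present at ``t0`` has age density
    ``g(a) = phi S(t0) exp(p a)``.

resistant
    A displaceable pool obeying homogeneous dynamics plus an "incumbent"
    host-only population of constant size ``I0`` established early in life.

Normalised chimerism is pinned to zero at each mouse's start age
``T = bmt_age + bmt_lag`` and the thymic (DP1) normalisation cancels out of
the dynamics, so solvers work directly in normalised units.

Two numerical routes are provided: an adaptive stiff ODE solver (``lsoda``,
rtol 1e-8 — the default, used wherever accuracy is the point) and a fast
fixed-grid exponential-integrator (``grid``) used inside fitting loops; the
age-dependent model is quadrature-based on both routes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_simpson, solve_ivp
from scipy.interpolate import CubicSpline

from .config import CohortConfig
from .gridsolve import (
    accumulate_linear,
    step_integrals_const_rate,
    step_integrals_var_rate,
)
from .sources import eval_source

__all__ = [
    "HomogeneousParams",
    "TwoPhaseParams",
    "AgeDepParams",
    "ResistantParams",
    "Trajectory",
    "solve_homogeneous",
    "solve_two_phase",
    "solve_age_dep",
    "solve_resistant",
    "solve_model",
    "homogeneous_closed_form",
    "loss_rate",
    "cumulative_loss",
    "age_dep_predict",
    "derived_quantities",
    "MODEL_NAMES",
]

MODEL_NAMES = ("homogeneous", "two_phase", "age_dep", "resistant")

_RTOL = 1e-8
_ATOL_CELLS = 1e-2
_ATOL_CHI = 1e-12
_GRID_H = 0.5
_EXP_CLIP = 700.0


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class HomogeneousParams:
    """Unknowns of the homogeneous model: pool size at t0, phi, net loss."""

    M0: float
    phi: float
    lam: float

    def __post_init__(self):
        if self.M0 <= 0:
            raise ValueError("M0 must be positive")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")


@dataclass(frozen=True)
class TwoPhaseParams:
    """Unknowns of the two-phase (fast/slow) model.

    ``Mfast0`` defaults to the quasi-equilibrium value
    ``phi S(t0) / (lam_fast + gamma)``; passing it explicitly frees the
    initial condition at the cost of an extra parameter.
    """

    Mslow0: float
    phi: float
    lam_fast: float
    lam_slow: float
    gamma: float
    Mfast0: float | None = None

    def __post_init__(self):
        if self.Mslow0 < 0:
            raise ValueError("Mslow0 must be non-negative")
        if self.phi < 0 or self.gamma < 0:
            raise ValueError("phi and gamma must be non-negative")
        if self.Mfast0 is None and self.lam_fast + self.gamma <= 0:
            raise ValueError(
                "quasi-equilibrium initialisation requires lam_fast + gamma > 0"
            )


@dataclass(frozen=True)
class AgeDepParams:
    """Unknowns of the age-dependent loss model.

    ``form`` selects sigmoid ``lam0/(1+(a/A)^n)`` (default, ``n`` in
    {1,2,3,5,10}) or exponential ``lam0 exp(-a/A)`` loss.  ``p`` shapes the
    initial cell-age distribution and may take either sign.
    """

    phi: float
    p: float
    lam0: float
    A: float
    n: int = 3
    form: str = "sigmoid"

    def __post_init__(self):
        if self.phi < 0:
            raise ValueError("phi must be non-negative")
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.form not in ("sigmoid", "exponential"):
            raise ValueError("form must be 'sigmoid' or 'exponential'")
        if self.form == "sigmoid" and self.n < 1:
            raise ValueError("sigmoid exponent n must be a positive integer")


@dataclass(frozen=True)
class ResistantParams:
    """Unknowns of the resistant-memory model; incumbents are stable (lam_I=0)."""

    M0: float
    I0: float
    phi: float
    lam: float
    lam_I: float = 0.0

    def __post_init__(self):
        if self.M0 < 0 or self.I0 < 0:
            raise ValueError("M0 and I0 must be non-negative")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")
        if self.lam_I != 0.0:
            raise ValueError("incumbent cells are assumed stable: lam_I must be 0")


@dataclass
class Trajectory:
    """Model-predicted totals and normalised chimerism over host age."""

    times: np.ndarray
    total: np.ndarray
    chi_norm: np.ndarray
    extras: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        data = {"age_days": self.times, "total": self.total, "chi_norm": self.chi_norm}
        for k, v in self.extras.items():
            if np.ndim(v) == 1 and len(v) == len(self.times):
                data[k] = v
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# shared helpers


def _prep_times(times, cfg: CohortConfig, bmt_age: float):
    t = np.atleast_1d(np.asarray(times, dtype=float))
    T = cfg.start_age(bmt_age)
    if np.any(t < T - 1e-9):
        raise ValueError(
            f"observation times must be >= bmt_age + bmt_lag = {T:g} d"
        )
    return t, T


def _chi_src_fn(chi_source, bmt_age: float):
    def c(t):
        return eval_source(chi_source, np.maximum(np.asarray(t, dtype=float) - bmt_age, 0.0))

    return c


def _solve_segment(rhs, t_span, y0, t_eval=None):
    if t_span[0] == t_span[1]:
        return np.asarray(y0, dtype=float)[:, None] if t_eval is None else np.tile(
            np.asarray(y0, dtype=float)[:, None], (1, len(t_eval))
        )
    atol = [_ATOL_CELLS] * len(y0)
    sol = solve_ivp(
        rhs,
        t_span,
        y0,
        method="LSODA",
        rtol=_RTOL,
        atol=atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y


def _solve_with_chi(rhs, T, times, y0, n_cells: int):
    """Integrate a [cells..., chi...] system from T, returning values at times."""
    t_sorted, inv = np.unique(times, return_inverse=True)
    atol = [_ATOL_CELLS] * n_cells + [_ATOL_CHI] * (len(y0) - n_cells)
    if t_sorted[0] == T and len(t_sorted) == 1:
        return np.asarray(y0, dtype=float)[:, None][:, inv]
    sol = solve_ivp(
        rhs,
        (T, t_sorted[-1]),
        y0,
        method="LSODA",
        rtol=_RTOL,
        atol=atol,
        t_eval=t_sorted,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[:, inv]


# ---------------------------------------------------------------------------
# homogeneous model


def homogeneous_closed_form(params: HomogeneousParams, source, cfg: CohortConfig, times):
    """Analytic ``M(t)`` for an exponentially decaying source.

    ``M(t) = M0 e^{-lam (t-t0)} + phi S(t0) (e^{-nu (t-t0)} - e^{-lam (t-t0)})
    / (lam - nu)``, with the removable singularity at ``lam == nu`` replaced
    by its limit ``phi S(t0) (t-t0) e^{-lam (t-t0)}``.
    """
    if getattr(source, "kind", None) != "exp_decay":
        raise ValueError("closed form requires an exp_decay source")
    t = np.asarray(times, dtype=float)
    t0 = cfg.t0
    nu = source.params["nu"]
    S0 = eval_source(source, t0)
    lam, phi, M0 = params.lam, params.phi, params.M0
    dt = t - t0
    hom = M0 * np.exp(-lam * dt)
    if abs(lam - nu) < 1e-12 * max(abs(lam), abs(nu), 1e-30):
        part = phi * S0 * dt * np.exp(-lam * dt)
    else:
        part = phi * S0 * (np.exp(-nu * dt) - np.exp(-lam * dt)) / (lam - nu)
    return hom + part


def solve_homogeneous(
    params: HomogeneousParams,
    source,
    chi_source,
    cfg: CohortConfig,
    bmt_age: float,
    times,
    method: str = "lsoda",
) -> Trajectory:
    """Solve the homogeneous model for one mouse (one age at BMT)."""
    t, T = _prep_times(times, cfg, bmt_age)
    if method == "grid":
        return _solve_grid_single("homogeneous", params, source, chi_source, cfg, bmt_age, t)
    c = _chi_src_fn(chi_source, bmt_age)

    def rhs_m(s, y):
        return [params.phi * eval_source(source, s) - params.lam * y[0]]

    M_T = _solve_segment(rhs_m, (cfg.t0, T), [params.M0])[0, -1]

    def rhs(s, y):
        S = eval_source(source, s)
        dM = params.phi * S - params.lam * y[0]
        dchi = params.phi * S / y[0] * (c(s) - y[1])
        return [dM, dchi]

    y = _solve_with_chi(rhs, T, t, [M_T, 0.0], 1)
    return Trajectory(times=t, total=y[0], chi_norm=y[1])


# ---------------------------------------------------------------------------
# two-phase model


def _two_phase_init(params: TwoPhaseParams, source, cfg: CohortConfig):
    if params.Mfast0 is not None:
        return params.Mfast0
    return params.phi * eval_source(source, cfg.t0) / (params.lam_fast + params.gamma)


def solve_two_phase(
    params: TwoPhaseParams,
    source,
    chi_source,
    cfg: CohortConfig,
    bmt_age: float,
    times,
    method: str = "lsoda",
) -> Trajectory:
    """Solve the two-phase (kinetic heterogeneity) model for one mouse."""
    t, T = _prep_times(times, cfg, bmt_age)
    if method == "grid":
        return _solve_grid_single("two_phase", params, source, chi_source, cfg, bmt_age, t)
    c = _chi_src_fn(chi_source, bmt_age)
    Mf0 = _two_phase_init(params, source, cfg)

    def rhs_cells(s, y):
        S = eval_source(source, s)
        dMf = params.phi * S - (params.gamma + params.lam_fast) * y[0]
        dMs = params.gamma * y[0] - params.lam_slow * y[1]
        return [dMf, dMs]

    yT = _solve_segment(rhs_cells, (cfg.t0, T), [Mf0, params.Mslow0])[:, -1]

    def rhs(s, y):
        Mf, Ms, chf, chs = y
        S = eval_source(source, s)
        dMf = params.phi * S - (params.gamma + params.lam_fast) * Mf
        dMs = params.gamma * Mf - params.lam_slow * Ms
        dchf = params.phi * S / Mf * (c(s) - chf)
        dchs = (params.gamma * Mf / Ms * (chf - chs)) if Ms > 0 else 0.0
        return [dMf, dMs, dchf, dchs]

    y = _solve_with_chi(rhs, T, t, [yT[0], yT[1], 0.0, 0.0], 2)
    Mf, Ms, chf, chs = y
    total = Mf + Ms
    chi = (chf * Mf + chs * Ms) / total
    return Trajectory(
        times=t,
        total=total,
        chi_norm=chi,
        extras={"fast": Mf, "slow": Ms, "chi_fast": chf, "chi_slow": chs},
    )


# ---------------------------------------------------------------------------
# resistant-memory model


def solve_resistant(
    params: ResistantParams,
    source,
    chi_source,
    cfg: CohortConfig,
    bmt_age: float,
    times,
    method: str = "lsoda",
) -> Trajectory:
    """Solve the resistant (incumbent) memory model for one mouse."""
    t, T = _prep_times(times, cfg, bmt_age)
    if method == "grid":
        return _solve_grid_single("resistant", params, source, chi_source, cfg, bmt_age, t)
    c = _chi_src_fn(chi_source, bmt_age)

    def rhs_m(s, y):
        return [params.phi * eval_source(source, s) - params.lam * y[0]]

    M_T = _solve_segment(rhs_m, (cfg.t0, T), [params.M0])[0, -1]

    def rhs(s, y):
        S = eval_source(source, s)
        dM = params.phi * S - params.lam * y[0]
        dD = params.phi * c(s) * S - params.lam * y[1]
        return [dM, dD]

    y = _solve_with_chi(rhs, T, t, [M_T, 0.0], 2)
    Mdisp, Ddon = y
    total = Mdisp + params.I0
    return Trajectory(
        times=t,
        total=total,
        chi_norm=Ddon / total,
        extras={"displaceable": Mdisp, "incumbent": np.full_like(Mdisp, params.I0)},
    )


# ---------------------------------------------------------------------------
# age-dependent loss model (method of characteristics + quadrature)


def loss_rate(params: AgeDepParams, a):
    """Net loss rate ``lam(a)`` as a function of cell age ``a`` (days)."""
    a = np.asarray(a, dtype=float)
    if params.form == "exponential":
        out = params.lam0 * np.exp(np.clip(-a / params.A, -_EXP_CLIP, _EXP_CLIP))
    else:
        with np.errstate(over="ignore"):  # (a/A)^n -> inf is a valid limit (lam -> 0)
            out = params.lam0 / (1.0 + (a / params.A) ** params.n)
    return out


@lru_cache(maxsize=8)
def _leggauss(n: int):
    return np.polynomial.legendre.leggauss(n)


class _LossKernel:
    """Cumulative loss integral ``Lambda(a)`` with a cached cubic spline."""

    def __init__(self, params: AgeDepParams, a_max: float, h: float = 0.25):
        grid = np.arange(0.0, a_max + 2 * h, h)
        lam = loss_rate(params, grid)
        Lam = cumulative_simpson(lam, dx=h, initial=0.0)
        self._spline = CubicSpline(grid, Lam)
        self.a_max = grid[-1]

    def __call__(self, a):
        return self._spline(np.clip(a, 0.0, self.a_max))


def cumulative_loss(params: AgeDepParams, a, h: float = 0.25):
    """``Lambda(a) = int_0^a lam(s) ds``; survival is ``exp(-Lambda)``."""
    a_arr = np.asarray(a, dtype=float)
    kern = _LossKernel(params, float(np.max(a_arr)) if a_arr.size else 1.0, h)
    out = kern(a_arr)
    return float(out) if np.ndim(a) == 0 else out


def age_dep_predict(
    params: AgeDepParams,
    source,
    chi_source,
    cfg: CohortConfig,
    obs_age,
    bmt_age,
    n_nodes: int = 64,
    h: float = 0.25,
):
    """Vectorised totals and normalised chimerism for arrays of observations.

    ``obs_age`` and ``bmt_age`` are broadcast per observation.  Totals follow
    the characteristics solution: the surviving initial cohort (age density
    ``g`` at ``t0``) plus the surviving influx recruited after ``t0``; the
    donor numerator integrates recruitment from the mouse's own start age
    ``T = bmt_age + lag`` weighted by the source chimerism.
    """
    t = np.atleast_1d(np.asarray(obs_age, dtype=float))
    b_age = np.broadcast_to(np.asarray(bmt_age, dtype=float), t.shape).astype(float)
    t0 = cfg.t0
    T = b_age + cfg.bmt_lag
    if np.any(t < T - 1e-9):
        raise ValueError("observation times must be >= bmt_age + bmt_lag")
    if np.any(t < t0 - 1e-9):
        raise ValueError("age-dependent model is solved forward from t0")
    kern = _LossKernel(params, float(np.max(t)), h)
    x, w = _leggauss(n_nodes)
    phi = params.phi
    S_t0 = eval_source(source, t0)

    def _gl(lo, hi):
        """Map GL nodes onto per-observation intervals [lo, hi] (arrays)."""
        half = 0.5 * (hi - lo)
        nodes = lo[:, None] + half[:, None] * (x[None, :] + 1.0)
        return nodes, half[:, None] * w[None, :]

    # surviving initial cohort: integrate over cell age at t0, bb in [0, t0]
    bb, wb = _gl(np.zeros_like(t), np.full_like(t, t0))
    g = phi * S_t0 * np.exp(np.clip(params.p * bb, -_EXP_CLIP, _EXP_CLIP))
    surv_init = np.exp(np.clip(-(kern(bb + (t[:, None] - t0)) - kern(bb)), -_EXP_CLIP, _EXP_CLIP))
    M_init = np.sum(wb * g * surv_init, axis=1)

    # influx recruited after t0: recruitment age u in [t0, t]
    uu, wu = _gl(np.full_like(t, t0), t)
    S_u = eval_source(source, np.maximum(uu, 0.0))
    surv_new = np.exp(np.clip(-kern(t[:, None] - uu), -_EXP_CLIP, _EXP_CLIP))
    M_new = np.sum(wu * phi * S_u * surv_new, axis=1)
    total = M_init + M_new

    # donor influx: recruitment from the mouse's own start age T onward
    uu_d, wu_d = _gl(T, t)
    tau = np.maximum(uu_d - b_age[:, None], 0.0)
    c_u = eval_source(chi_source, tau)
    S_ud = eval_source(source, np.maximum(uu_d, 0.0))
    surv_d = np.exp(np.clip(-kern(t[:, None] - uu_d), -_EXP_CLIP, _EXP_CLIP))
    donor = np.sum(wu_d * phi * c_u * S_ud * surv_d, axis=1)
    chi = donor / total
    if not np.all(np.isfinite(total)):
        raise FloatingPointError("non-finite integrand in age-dependent solver")
    return total, chi


def solve_age_dep(
    params: AgeDepParams,
    source,
    chi_source,
    cfg: CohortConfig,
    bmt_age: float,
    times,
    method: str = "lsoda",
    n_nodes: int = 64,
) -> Trajectory:
    """Solve the age-dependent loss model for one mouse.

    Both ``method`` routes share the quadrature evaluator (the model is an
    integral solution, not an ODE system).
    """
    t, _ = _prep_times(times, cfg, bmt_age)
    total, chi = age_dep_predict(params, source, chi_source, cfg, t, bmt_age, n_nodes=n_nodes)
    return Trajectory(times=t, total=total, chi_norm=chi)


# ---------------------------------------------------------------------------
# grid backend (shared machinery for the three ODE models)


def build_grid_context(
    source,
    chi_source,
    cfg: CohortConfig,
    bmt_ages: Sequence[float],
    t_max: float,
    h: float = _GRID_H,
):
    """Precompute everything parameter-independent for grid-backend solves."""
    bmt_ages = np.asarray(bmt_ages, dtype=float)
    n = int(np.ceil((t_max - cfg.t0) / h)) + 1
    t_grid = cfg.t0 + h * np.arange(n)
    S = eval_source(source, t_grid)
    T = bmt_ages + cfg.bmt_lag
    jT = np.rint((T - cfg.t0) / h).astype(int)
    if np.any(jT < 0):
        raise ValueError("grid backend requires bmt_age + lag >= t0 for all mice")
    tau = t_grid[:, None] - bmt_ages[None, :]
    c = eval_source(chi_source, np.maximum(tau, 0.0))
    return {
        "h": h,
        "t_grid": t_grid,
        "S": S,
        "c": c,
        "jT": jT,
        "cfg": cfg,
        "phiS_unit": S,  # multiplied by phi at solve time
    }


def _grid_chi(ctx, rate_grid, src_chi_grid):
    """Chimerism relaxation towards a (per-group) target on the grid."""
    h = ctx["h"]
    F = 0.5 * h * (rate_grid[:-1] + rate_grid[1:])
    L = np.concatenate([[0.0], np.cumsum(F)])
    g = rate_grid[:, None] * src_chi_grid
    b = step_integrals_var_rate(g, F[:, None], h)
    for k, j in enumerate(ctx["jT"]):
        b[:j, k] = 0.0
    chi = accumulate_linear(
        np.broadcast_to(L[:, None], g.shape).copy(), b, 0.0
    )
    return chi


def _grid_cells_const(ctx, rate: float, g_grid, y0: float):
    h = ctx["h"]
    L = rate * (ctx["t_grid"] - ctx["t_grid"][0])
    b = step_integrals_const_rate(g_grid, rate, h)
    return accumulate_linear(L, b, y0)


def grid_solve(model: str, params, ctx):
    """Totals (1-D) and per-group chimerism (2-D) on the precomputed grid."""
    S = ctx["S"]
    if model == "homogeneous":
        M = _grid_cells_const(ctx, params.lam, params.phi * S, params.M0)
        rate = params.phi * S / M
        chi = _grid_chi(ctx, rate, ctx["c"])
        return M, chi, {}
    if model == "resistant":
        Mdisp = _grid_cells_const(ctx, params.lam, params.phi * S, params.M0)
        h = ctx["h"]
        L = params.lam * (ctx["t_grid"] - ctx["t_grid"][0])
        g = params.phi * S[:, None] * ctx["c"]
        b = step_integrals_const_rate(g, params.lam, h)
        for k, j in enumerate(ctx["jT"]):
            b[:j, k] = 0.0
        donor = accumulate_linear(np.broadcast_to(L[:, None], g.shape).copy(), b, 0.0)
        total = Mdisp + params.I0
        return total, donor / total[:, None], {"displaceable": Mdisp}
    if model == "two_phase":
        if params.Mfast0 is not None:
            Mf0 = params.Mfast0
        else:
            Mf0 = params.phi * S[0] / (params.lam_fast + params.gamma)
        Mf = _grid_cells_const(ctx, params.lam_fast + params.gamma, params.phi * S, Mf0)
        Ms = _grid_cells_const(ctx, params.lam_slow, params.gamma * Mf, params.Mslow0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate_f = np.where(Mf > 0, params.phi * S / np.where(Mf > 0, Mf, 1.0), 0.0)
        chi_f = _grid_chi(ctx, rate_f, ctx["c"])
        with np.errstate(divide="ignore", invalid="ignore"):
            rate_s = np.where(Ms > 0, params.gamma * Mf / np.where(Ms > 0, Ms, 1.0), 0.0)
        chi_s = _grid_chi(ctx, rate_s, chi_f)
        total = Mf + Ms
        with np.errstate(invalid="ignore"):
            chi = (chi_f * Mf[:, None] + chi_s * Ms[:, None]) / total[:, None]
        return total, chi, {"fast": Mf, "slow": Ms, "chi_fast": chi_f, "chi_slow": chi_s}
    raise ValueError(f"grid backend does not handle model {model!r}")


def _solve_grid_single(model, params, source, chi_source, cfg, bmt_age, times):
    ctx = build_grid_context(source, chi_source, cfg, [bmt_age], float(np.max(times)))
    total, chi, extras = grid_solve(model, params, ctx)
    tg = ctx["t_grid"]
    tot_t = np.interp(times, tg, total)
    chi_t = np.interp(times, tg, chi[:, 0])
    ex = {k: np.interp(times, tg, v if v.ndim == 1 else v[:, 0]) for k, v in extras.items()}
    return Trajectory(times=np.asarray(times, float), total=tot_t, chi_norm=chi_t, extras=ex)


_SOLVERS = {
    "homogeneous": solve_homogeneous,
    "two_phase": solve_two_phase,
    "age_dep": solve_age_dep,
    "resistant": solve_resistant,
}


def solve_model(model: str, params, source, chi_source, cfg, bmt_age, times, **kw) -> Trajectory:
    """Dispatch to the solver for ``model`` (see :data:`MODEL_NAMES`)."""
    try:
        solver = _SOLVERS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}") from None
    return solver(params, source, chi_source, cfg, bmt_age, times, **kw)


# ---------------------------------------------------------------------------
# derived quantities


def _half_life(lam: float) -> float:
    """``ln 2 / lam``; undefined (NaN) for non-positive net loss."""
    return math.log(2.0) / lam if lam > 0 else math.nan


def derived_quantities(params, source, cfg: CohortConfig) -> dict:
    """Reporting quantities for a fitted parameter set.

    Half-lives are clonal half-lives ``ln 2 / lam`` (NaN when ``lam <= 0``,
    rendered as "not shown" downstream); influx is the daily number of cells
    recruited at the reference age ``t_star``.
    """
    t_star = cfg.t_star
    out = {"influx_at_tstar": params.phi * eval_source(source, t_star)}
    if isinstance(params, HomogeneousParams):
        out["half_life"] = _half_life(params.lam)
    elif isinstance(params, TwoPhaseParams):
        out["half_life_fast"] = _half_life(params.lam_fast)
        out["half_life_slow"] = _half_life(params.lam_slow)
        out["pct_to_slow"] = 100.0 * params.gamma / (params.lam_fast + params.gamma)
        ctx = build_grid_context(
            source, lambda t: np.zeros_like(np.asarray(t, float)), cfg, [cfg.t0 - cfg.bmt_lag], t_star + 1.0, h=0.25
        )
        total, _, extras = grid_solve("two_phase", params, ctx)
        tg = ctx["t_grid"]
        out["prop_slow_at_tstar"] = float(
            np.interp(t_star, tg, extras["slow"]) / np.interp(t_star, tg, total)
        )
    elif isinstance(params, AgeDepParams):
        out["half_life_new"] = _half_life(float(loss_rate(params, 0.0)))
        ages = np.arange(0.0, 401.0, 7.0)
        lam_a = loss_rate(params, ages)
        with np.errstate(divide="ignore"):
            hl = np.where(lam_a > 0, math.log(2.0) / np.where(lam_a > 0, lam_a, 1.0), np.nan)
        out["cell_ages"] = ages
        out["half_life_by_age"] = hl
        p, t0 = params.p, cfg.t0
        S0 = eval_source(source, t0)
        out["M_t0"] = params.phi * S0 * (t0 if abs(p) < 1e-12 else (math.exp(p * t0) - 1.0) / p)
    elif isinstance(params, ResistantParams):
        out["half_life"] = _half_life(params.lam)
    else:
        raise TypeError(f"unrecognised parameter container {type(params).__name__}")
    return out
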