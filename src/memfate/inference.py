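"""Maximum-likelihood fitting, AICc model comparison, residual bootstrap.

Each mouse contributes one pair of observations for a memory subset: the
total cell count and the normalised donor chimerism.  Counts are fitted on
the natural-log scale and chimerism on the arcsin-square-root scale, both
assumed Gaussian with constant (unknown) variances.  Profiling the two error
variances analytically collapses the joint log-likelihood to

    ln L = -(n/2) ln(SSR_x * SSR_y) - 2 n,

which is maximised over the model parameters with a multi-start simplex
search refined by a quasi-Newton polish.  Model/source combinations are
ranked by the small-sample-corrected Akaike criterion with facilities fitted
independently and their log-likelihoods summed.  Confidence intervals come
from resampling (x, y) residual pairs, refitting, and taking percentile
quantiles.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .config import CohortConfig
from .models import (
    MODEL_NAMES,
    AgeDepParams,
    HomogeneousParams,
    ResistantParams,
    TwoPhaseParams,
    age_dep_predict,
    build_grid_context,
    derived_quantities,
    grid_solve,
    solve_model,
)
from .sources import eval_source

__all__ = [
    "TransformedObs",
    "FitData",
    "FitResult",
    "ModelComparison",
    "Predictor",
    "transform",
    "profiled_loglik",
    "fit_model",
    "aicc",
    "compare_models",
    "bootstrap_ci",
    "N_FREE_PARAMS",
]

logger = logging.getLogger("memfate")

_SSR_FLOOR = 1e-30
_SIGMA_FLOOR = 1e-15

#: free parameters per facility, excluding the profiled error SDs
N_FREE_PARAMS = {"homogeneous": 3, "two_phase": 5, "age_dep": 4, "resistant": 4}


def transform(counts, chi):
    """Log counts and arcsin-sqrt normalised chimerism.

    Chimerism values outside [0, 1] (normalisation by the thymic reference
    can overshoot 1) are clipped with a warning; non-positive counts raise.
    """
    counts = np.asarray(counts, dtype=float)
    chi = np.asarray(chi, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("counts must be positive; filter non-positive records upstream")
    if not np.all(np.isfinite(chi)):
        raise ValueError("chimerism values must be finite")
    n_clip = int(np.sum((chi < 0) | (chi > 1)))
    if n_clip:
        warnings.warn(
            f"clipped {n_clip} chimerism value(s) outside [0, 1] before transforming",
            stacklevel=2,
        )
        logger.warning("transform: clipped %d chimerism value(s) to [0, 1]", n_clip)
    x = np.log(counts)
    y = np.arcsin(np.sqrt(np.clip(chi, 0.0, 1.0)))
    return x, y


@dataclass(frozen=True)
class TransformedObs:
    """One mouse's transformed measurement pair for one subset."""

    x: float
    y: float
    mouse_id: str
    age_days: float
    bmt_age_days: float


@dataclass
class FitData:
    """Per-subset fitting table: one (x, y) pair per mouse."""

    bmt_age: np.ndarray
    obs_age: np.ndarray
    x: np.ndarray
    y: np.ndarray
    mouse_id: np.ndarray | None = None

    @classmethod
    def from_counts(cls, bmt_age, obs_age, counts, chi_norm, mouse_id=None) -> "FitData":
        x, y = transform(counts, chi_norm)
        return cls(
            bmt_age=np.asarray(bmt_age, dtype=float),
            obs_age=np.asarray(obs_age, dtype=float),
            x=x,
            y=y,
            mouse_id=None if mouse_id is None else np.asarray(mouse_id),
        )

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, idx) -> "FitData":
        return FitData(
            bmt_age=self.bmt_age[idx],
            obs_age=self.obs_age[idx],
            x=self.x[idx],
            y=self.y[idx],
            mouse_id=None if self.mouse_id is None else self.mouse_id[idx],
        )

    def filter_post_bmt(self, cfg: CohortConfig) -> tuple["FitData", int]:
        """Drop observations earlier than the post-BMT stabilisation lag."""
        keep = self.obs_age - self.bmt_age >= cfg.bmt_lag - 1e-9
        dropped = int(np.sum(~keep))
        if dropped:
            logger.info("excluded %d observation(s) earlier than %g d post BMT", dropped, cfg.bmt_lag)
        return self.subset(keep), dropped


# ---------------------------------------------------------------------------
# parameter packing: positive parameters are optimised on the log scale


class _ParamSpec:
    def __init__(self, names, log_mask, builder, unpacker):
        self.names = list(names)
        self.log_mask = np.asarray(log_mask, dtype=bool)
        self._build = builder
        self._unpack = unpacker

    def to_vector(self, params) -> np.ndarray:
        vals = np.array(self._unpack(params), dtype=float)
        out = vals.copy()
        out[self.log_mask] = np.log(vals[self.log_mask])
        return out

    def to_params(self, vector: np.ndarray, **fixed):
        v = np.asarray(vector, dtype=float).copy()
        v[self.log_mask] = np.exp(np.clip(v[self.log_mask], -700.0, 700.0))
        return self._build(v, **fixed)


_SPECS = {
    "homogeneous": _ParamSpec(
        ["M0", "phi", "lam"],
        [True, True, False],
        lambda v, **kw: HomogeneousParams(M0=v[0], phi=v[1], lam=v[2]),
        lambda p: (p.M0, p.phi, p.lam),
    ),
    "two_phase": _ParamSpec(
        ["Mslow0", "phi", "lam_fast", "lam_slow", "gamma"],
        [True, True, False, False, True],
        lambda v, **kw: TwoPhaseParams(
            Mslow0=v[0], phi=v[1], lam_fast=v[2], lam_slow=v[3], gamma=v[4], **kw
        ),
        lambda p: (p.Mslow0, p.phi, p.lam_fast, p.lam_slow, p.gamma),
    ),
    "two_phase_free": _ParamSpec(
        ["Mslow0", "phi", "lam_fast", "lam_slow", "gamma", "Mfast0"],
        [True, True, False, False, True, True],
        lambda v, **kw: TwoPhaseParams(
            Mslow0=v[0], phi=v[1], lam_fast=v[2], lam_slow=v[3], gamma=v[4], Mfast0=v[5]
        ),
        lambda p: (p.Mslow0, p.phi, p.lam_fast, p.lam_slow, p.gamma, p.Mfast0),
    ),
    "age_dep": _ParamSpec(
        ["phi", "p", "lam0", "A"],
        [True, False, False, True],
        lambda v, **kw: AgeDepParams(phi=v[0], p=v[1], lam0=v[2], A=v[3], **kw),
        lambda p: (p.phi, p.p, p.lam0, p.A),
    ),
    "resistant": _ParamSpec(
        ["M0", "I0", "phi", "lam"],
        [True, True, True, False],
        lambda v, **kw: ResistantParams(M0=v[0], I0=v[1], phi=v[2], lam=v[3]),
        lambda p: (p.M0, p.I0, p.phi, p.lam),
    ),
}


def _spec_for(model: str, free_init: bool = False) -> _ParamSpec:
    if model == "two_phase" and free_init:
        return _SPECS["two_phase_free"]
    return _SPECS[model]


# ---------------------------------------------------------------------------
# prediction


class Predictor:
    """Maps a parameter set to transformed predictions for a fixed dataset.

    Precomputes everything parameter-independent: the source and
    source-chimerism trajectories on a fixed grid, per-BMT-batch bookkeeping
    and the interpolation weights taking grid values to each mouse's
    observation age.  ``method='grid'`` (default) uses the fast
    fixed-grid backend; ``method='lsoda'`` the adaptive reference solver.
    """

    def __init__(
        self,
        model: str,
        source,
        chi_source,
        cfg: CohortConfig,
        data: FitData,
        method: str = "grid",
        h: float = 1.0,
        n_nodes: int = 48,
        param_kwargs: dict | None = None,
    ):
        if model not in MODEL_NAMES:
            raise ValueError(f"unknown model {model!r}")
        self.model = model
        self.source = source
        self.chi_source = chi_source
        self.cfg = cfg
        self.data = data
        self.method = method
        self.n_nodes = n_nodes
        self.param_kwargs = dict(param_kwargs or {})
        self.n = len(data)

        groups, g_idx = np.unique(data.bmt_age, return_inverse=True)
        self.bmt_groups = groups
        self.group_idx = g_idx
        t_max = float(np.max(data.obs_age))
        if model != "age_dep" and method == "grid":
            self.ctx = build_grid_context(source, chi_source, cfg, groups, t_max, h=h)
            tg = self.ctx["t_grid"]
            i0 = np.clip(np.searchsorted(tg, data.obs_age, side="right") - 1, 0, len(tg) - 2)
            self._i0 = i0
            self._frac = (data.obs_age - tg[i0]) / (tg[i0 + 1] - tg[i0])

    def predict(self, params):
        """Transformed predictions (X, Y) at the data's observation times."""
        if self.model == "age_dep":
            total, chi = age_dep_predict(
                params,
                self.source,
                self.chi_source,
                self.cfg,
                self.data.obs_age,
                self.data.bmt_age,
                n_nodes=self.n_nodes,
            )
        elif self.method == "grid":
            total_g, chi_g, _ = grid_solve(self.model, params, self.ctx)
            i0, f, g = self._i0, self._frac, self.group_idx
            total = (1 - f) * total_g[i0] + f * total_g[i0 + 1]
            chi = (1 - f) * chi_g[i0, g] + f * chi_g[i0 + 1, g]
        else:
            total = np.empty(self.n)
            chi = np.empty(self.n)
            for k, b in enumerate(self.bmt_groups):
                m = self.group_idx == k
                tr = solve_model(
                    self.model, params, self.source, self.chi_source, self.cfg,
                    b, self.data.obs_age[m], method="lsoda",
                )
                total[m] = tr.total
                chi[m] = tr.chi_norm
        if np.any(total <= 0) or not np.all(np.isfinite(total)):
            raise FloatingPointError("non-positive or non-finite predicted totals")
        X = np.log(total)
        Y = np.arcsin(np.sqrt(np.clip(chi, 0.0, 1.0)))
        return X, Y

    def ssr(self, params):
        X, Y = self.predict(params)
        return float(np.sum((self.data.x - X) ** 2)), float(np.sum((self.data.y - Y) ** 2))

    def loglik(self, params) -> float:
        """Profiled log-likelihood; failed solves count as rejected (-inf)."""
        try:
            ssr_x, ssr_y = self.ssr(params)
        except (FloatingPointError, ValueError, RuntimeError, OverflowError) as exc:
            logger.debug("rejected parameter point (%s)", exc)
            return -math.inf
        return _profiled_from_ssr(ssr_x, ssr_y, self.n)

    def loglik_vector(self, vector: np.ndarray, spec: _ParamSpec) -> float:
        try:
            params = spec.to_params(vector, **self.param_kwargs)
        except (ValueError, OverflowError):
            return -math.inf
        return self.loglik(params)


def _profiled_from_ssr(ssr_x: float, ssr_y: float, n: int) -> float:
    ssr_x = max(ssr_x, _SSR_FLOOR)
    ssr_y = max(ssr_y, _SSR_FLOOR)
    return -(n / 2.0) * math.log(ssr_x * ssr_y) - 2.0 * n


def profiled_loglik(
    params, model: str, source, chi_source, cfg: CohortConfig, data: FitData,
    method: str = "grid",
) -> float:
    """``ln L = -(n/2) ln(SSR_x SSR_y) - 2n`` at a given parameter point."""
    return Predictor(model, source, chi_source, cfg, data, method=method).loglik(params)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Maximum-likelihood estimates with profiled-variance bookkeeping."""

    model: str
    params: object
    theta: np.ndarray
    ssr_x: float
    ssr_y: float
    sigma_x_hat: float
    sigma_y_hat: float
    loglik: float
    n_obs: int
    converged: bool
    n_starts_used: int
    facility: str = ""
    source_name: str = ""
    start_logliks: list = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.theta)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self.params)
        return {
            "model": self.model,
            "facility": self.facility,
            "source": self.source_name,
            "params": {k: (v if v is None else float(v)) for k, v in d.items() if k != "form"} |
                      ({"form": self.params.form} if hasattr(self.params, "form") else {}),
            "sigma_x_hat": self.sigma_x_hat,
            "sigma_y_hat": self.sigma_y_hat,
            "ssr_x": self.ssr_x,
            "ssr_y": self.ssr_y,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "units": {"rates": "per_day", "sizes": "cells", "ages": "days"},
        }


def _heuristic_theta(model: str, predictor: Predictor, spec: _ParamSpec):
    """A data-driven central start on the packed (log where positive) scale."""
    data, cfg, source = predictor.data, predictor.cfg, predictor.source
    M_typ = float(np.exp(np.mean(data.x)))
    S_t0 = float(eval_source(source, cfg.t0))
    S_mid = float(eval_source(source, float(np.mean(data.obs_age))))
    if model == "homogeneous":
        p = HomogeneousParams(M0=M_typ, phi=0.01 * M_typ / S_mid, lam=0.01)
    elif model == "two_phase":
        base = dict(Mslow0=M_typ / 3, phi=0.06 * M_typ / S_mid, lam_fast=0.1,
                    lam_slow=5e-3, gamma=5e-3)
        if len(spec.names) == 6:
            p = TwoPhaseParams(**base, Mfast0=M_typ / 2)
        else:
            p = TwoPhaseParams(**base)
    elif model == "age_dep":
        p = AgeDepParams(phi=M_typ / (S_t0 * cfg.t0), p=1e-3, lam0=0.02, A=150.0,
                         **predictor.param_kwargs)
    else:
        p = ResistantParams(M0=0.7 * M_typ, I0=0.3 * M_typ, phi=0.014 * M_typ / S_mid, lam=0.02)
    return spec.to_vector(p)


#: sampling widths for multi-start draws: log-uniform over +/- 2 decades for
#: positive parameters, uniform windows for sign-free rates
_FREE_WINDOWS = {
    "lam": (-0.01, 0.08), "lam_fast": (0.02, 0.6), "lam_slow": (-0.005, 0.02),
    "p": (-0.02, 0.04), "lam0": (-0.005, 0.06),
}


def _draw_starts(theta0, spec: _ParamSpec, n_starts: int, rng: np.random.Generator):
    starts = [theta0]
    for _ in range(n_starts - 1):
        th = theta0.copy()
        for j, name in enumerate(spec.names):
            if spec.log_mask[j]:
                th[j] = theta0[j] + rng.uniform(-math.log(100.0), math.log(100.0))
            else:
                lo, hi = _FREE_WINDOWS.get(name, (theta0[j] - 0.05, theta0[j] + 0.05))
                th[j] = rng.uniform(lo, hi)
        starts.append(th)
    return starts


def _optimise(fun, theta0, polish: bool = True, maxfev: int | None = None,
              fatol: float | None = None):
    """Simplex exploration; the winning start gets a quasi-Newton polish."""
    n = len(theta0)
    if polish:
        opts = {"maxfev": maxfev or 400 * n, "fatol": 1e-9, "xatol": 1e-7}
    else:
        opts = {"maxfev": maxfev or 200 * n, "fatol": fatol or 1e-3, "xatol": 1e-3}
    res = minimize(fun, theta0, method="Nelder-Mead", options=opts)
    best_x, best_f = res.x, res.fun
    if polish and np.isfinite(best_f):
        res2 = minimize(fun, best_x, method="L-BFGS-B",
                        options={"maxiter": 50, "ftol": 1e-13, "gtol": 1e-10})
        if np.isfinite(res2.fun) and res2.fun < best_f:
            best_x, best_f = res2.x, res2.fun
    return best_x, best_f


def fit_model(
    model: str,
    source,
    chi_source,
    data: FitData,
    cfg: CohortConfig,
    *,
    n_starts: int = 20,
    seed: int = 0,
    method: str = "grid",
    free_init: bool = False,
    lam_form: str = "sigmoid",
    n_exponent: int = 3,
    x0=None,
    facility: str = "",
    source_name: str = "",
) -> FitResult:
    """Maximum-likelihood fit of one model to one facility's subset data.

    Multi-start: the first start is a data-driven heuristic, the rest are
    drawn log-uniformly around it (seeded, reproducible); each start runs a
    simplex search and the best is polished with L-BFGS-B.  ``x0`` (a params
    instance) replaces the heuristic centre, e.g. for warm starts.
    """
    spec = _spec_for(model, free_init)
    if len(data) < len(spec.names) + 2:
        raise ValueError("too few observations to fit this model")
    param_kwargs = {}
    if model == "age_dep":
        param_kwargs = {"form": lam_form, "n": n_exponent}
    predictor = Predictor(model, source, chi_source, cfg, data, method=method,
                          param_kwargs=param_kwargs)
    theta0 = spec.to_vector(x0) if x0 is not None else _heuristic_theta(model, predictor, spec)
    rng = np.random.default_rng(seed)
    starts = _draw_starts(theta0, spec, n_starts, rng)

    def objective(v):
        return -predictor.loglik_vector(v, spec)

    best = None
    start_lls = []
    for th in starts:
        try:
            x_opt, f_opt = _optimise(objective, th, polish=False)
        except Exception as exc:  # noqa: BLE001
            start_lls.append(-math.inf)
            logger.debug("start failed: %s", exc)
            continue
        start_lls.append(-f_opt)
        if best is None or f_opt < best[1]:
            best = (x_opt, f_opt)
    if best is None or not np.isfinite(best[1]):
        raise RuntimeError(
            f"all {n_starts} starts failed for model {model}; per-start logliks: {start_lls}"
        )
    x_opt, f_opt = _optimise(objective, best[0], polish=True)
    params = spec.to_params(x_opt, **param_kwargs)
    ssr_x, ssr_y = predictor.ssr(params)
    n = len(data)
    ll = _profiled_from_ssr(ssr_x, ssr_y, n)
    return FitResult(
        model=model,
        params=params,
        theta=x_opt,
        ssr_x=ssr_x,
        ssr_y=ssr_y,
        sigma_x_hat=max(math.sqrt(ssr_x / n), _SIGMA_FLOOR),
        sigma_y_hat=max(math.sqrt(ssr_y / n), _SIGMA_FLOOR),
        loglik=ll,
        n_obs=n,
        converged=True,
        n_starts_used=len(starts),
        facility=facility or cfg.facility,
        source_name=source_name,
        start_logliks=start_lls,
    )


# ---------------------------------------------------------------------------
# model comparison


def aicc(loglik_combined: float, K: int, N: int) -> float:
    """Corrected Akaike criterion ``-2 lnL + 2K + 2K(K+1)/(N-K-1)``."""
    if N <= K + 1:
        raise ValueError("AICc undefined: require N > K + 1")
    return -2.0 * loglik_combined + 2.0 * K + 2.0 * K * (K + 1) / (N - K - 1)


@dataclass
class ModelComparison:
    """Table-shaped AICc comparison across (model, source) combinations."""

    table: pd.DataFrame
    fits: dict

    def best(self) -> tuple[str, str]:
        row = self.table.loc[self.table["delta_aicc"].idxmin()]
        return row["model"], row["source"]


def compare_models(
    data_clean: FitData,
    data_dirty: FitData,
    source_sets: dict,
    models: Sequence[str] = MODEL_NAMES,
    *,
    cfg_clean: CohortConfig | None = None,
    cfg_dirty: CohortConfig | None = None,
    n_starts: int = 20,
    seed: int = 0,
    method: str = "grid",
) -> ModelComparison:
    """Fit every (model, source) pair per facility and rank by combined AICc.

    ``source_sets`` maps a source label (e.g. ``"naive"``, ``"tcm"``) to
    ``{"clean": (source, chi_source), "dirty": (source, chi_source)}``.  K is
    doubled (independent parameter sets per facility) and N counts two
    observations per mouse.
    """
    cfg_clean = cfg_clean or CohortConfig.for_facility("clean")
    cfg_dirty = cfg_dirty or CohortConfig.for_facility("dirty")
    N = 2 * (len(data_clean) + len(data_dirty))
    rows = []
    fits = {}
    for model in models:
        for src_label, per_fac in source_sets.items():
            ll = 0.0
            ok = True
            for fac, data, cfg in (
                ("clean", data_clean, cfg_clean),
                ("dirty", data_dirty, cfg_dirty),
            ):
                src, chi_src = per_fac[fac]
                try:
                    fit = fit_model(
                        model, src, chi_src, data, cfg,
                        n_starts=n_starts, seed=seed, method=method,
                        facility=fac, source_name=src_label,
                    )
                except Exception as exc:  # noqa: BLE001
                    logger.warning("fit failed for %s/%s/%s: %s", model, src_label, fac, exc)
                    ok = False
                    break
                fits[(model, src_label, fac)] = fit
                ll += fit.loglik
            K = 2 * N_FREE_PARAMS[model]
            rows.append({
                "model": model,
                "source": src_label,
                "K": K,
                "N": N,
                "loglik_combined": ll if ok else np.nan,
                "aicc": aicc(ll, K, N) if ok else np.nan,
                "converged": ok,
            })
    table = pd.DataFrame(rows)
    base = np.nanmin(table["aicc"].to_numpy()) if table["aicc"].notna().any() else np.nan
    table["delta_aicc"] = table["aicc"] - base
    return ModelComparison(table=table, fits=fits)


# ---------------------------------------------------------------------------
# residual bootstrap


def bootstrap_ci(
    fit: FitResult,
    source,
    chi_source,
    data: FitData,
    cfg: CohortConfig,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    n_starts: int = 4,
    method: str = "grid",
    include_derived: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Residual-bootstrap percentile confidence intervals.

    Residual (x, y) pairs are resampled jointly per observation (preserving
    any within-mouse correlation), added back onto the fitted predictions,
    and the model refit per replicate — warm-started from the original
    optimum plus ``n_starts - 1`` perturbed starts.  Quantiles use linear
    interpolation (type 7).  Replicates whose refit fails are dropped and
    counted; more than 10% dropped triggers a warning.
    """
    free_init = getattr(fit.params, "Mfast0", None) is not None
    spec = _spec_for(fit.model, free_init)
    param_kwargs = {}
    if fit.model == "age_dep":
        param_kwargs = {"form": fit.params.form, "n": fit.params.n}
    predictor = Predictor(fit.model, source, chi_source, cfg, data, method=method,
                          param_kwargs=param_kwargs)
    X, Y = predictor.predict(fit.params)
    rx, ry = data.x - X, data.y - Y
    n = len(data)
    rng = np.random.default_rng(seed)
    theta_hat = spec.to_vector(fit.params)

    rows = []
    derived_rows = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = FitData(bmt_age=data.bmt_age, obs_age=data.obs_age,
                       x=X + rx[idx], y=Y + ry[idx], mouse_id=data.mouse_id)
        pred_b = Predictor(fit.model, source, chi_source, cfg, boot, method=method,
                           param_kwargs=param_kwargs)

        def objective(v):
            return -pred_b.loglik_vector(v, spec)

        best = None
        for s in range(n_starts):
            th = theta_hat if s == 0 else theta_hat + rng.normal(0.0, 0.4, size=len(theta_hat))
            try:
                x_opt, f_opt = _optimise(objective, th, polish=False,
                                         maxfev=300 * len(th), fatol=1e-4)
            except Exception:  # noqa: BLE001
                continue
            if np.isfinite(f_opt) and (best is None or f_opt < best[1]):
                best = (x_opt, f_opt)
        if best is None:
            n_failed += 1
            continue
        try:
            params_b = spec.to_params(best[0], **param_kwargs)
        except (ValueError, OverflowError):
            n_failed += 1
            continue
        rows.append({nm: v for nm, v in zip(spec.names, _SPECS_values(params_b, spec))})
        if include_derived:
            dq = derived_quantities(params_b, source, cfg)
            derived_rows.append({k: v for k, v in dq.items() if np.isscalar(v)})
    if n_failed > 0.1 * n_boot:
        warnings.warn(f"bootstrap: {n_failed}/{n_boot} replicates failed to refit", stacklevel=2)
    reps = pd.DataFrame(rows)
    qs = [alpha / 2, 1 - alpha / 2]
    param_ci = {c: tuple(np.quantile(reps[c].to_numpy(), qs, method="linear"))
                for c in reps.columns}
    out = {"param_ci": param_ci, "replicates": reps, "n_failed": n_failed}
    if include_derived and derived_rows:
        dreps = pd.DataFrame(derived_rows)
        out["derived_ci"] = {
            c: tuple(np.nanquantile(dreps[c].to_numpy(dtype=float), qs, method="linear"))
            for c in dreps.columns
        }
        out["derived_replicates"] = dreps
    return out


def _SPECS_values(params, spec: _ParamSpec):
    return [getattr(params, nm) for nm in spec.names]
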