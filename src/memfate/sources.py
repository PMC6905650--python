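"""Parametric descriptors of precursor ("source") populations.

The dynamical models of memory need two empirical inputs per memory subset:
the size of the immediate precursor population, ``S(t)`` (cells, as a function
of host age ``t`` in days), and its normalised donor chimerism,
``chi_source_norm(tau)`` (dimensionless, as a function of time post bone
marrow transplant ``tau``).  Three families cover the data:

``exp_decay``
    ``S(t) = S0 * exp(-nu * (t - t_ref))`` — naive CD4+ T cell numbers in
    adult mice, which fall exponentially as the thymus involutes; also the
    central-memory pool in the dirty facility.

``sigmoid_growth``
    ``S(t) = Smax / (1 + exp(-r t) (Smax - Smin) / Smin)`` — a logistic growth
    curve anchored so that ``S(0) = Smin`` and ``S -> Smax``; describes
    populations accumulating from early life (young-mouse naive and
    central-memory timecourses, and the adult clean-facility T_CM source).

``gen_logistic``
    Richards curve ``lower + (upper - lower) / (1 + exp(-rate (t - midpoint)))**(1/shape)``
    — donor chimerism rising from ~0 after BMT and saturating below 1.

Size descriptors are fitted by least squares on log-transformed counts;
chimerism descriptors on the untransformed fraction with box bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SourceDescriptor",
    "TabulatedSource",
    "eval_source",
    "fit_source",
    "SourceFitError",
]

_KINDS = ("exp_decay", "sigmoid_growth", "gen_logistic")

_PARAM_NAMES = {
    "exp_decay": ("S0", "nu"),
    "sigmoid_growth": ("Smax", "Smin", "r"),
    "gen_logistic": ("lower", "upper", "rate", "midpoint", "shape"),
}


class SourceFitError(RuntimeError):
    """Raised when no multi-start attempt converges."""


@dataclass(frozen=True)
class SourceDescriptor:
    """A parametric trajectory of a precursor population's size or chimerism.

    Parameters
    ----------
    kind
        One of ``exp_decay``, ``sigmoid_growth``, ``gen_logistic``.
    params
        Named parameters for the chosen family (see module docstring).
    t_ref
        Reference age (days) at which ``S0`` applies; ``exp_decay`` only.
    """

    kind: str
    params: dict = field(default_factory=dict)
    t_ref: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")
        missing = set(_PARAM_NAMES[self.kind]) - set(self.params)
        if missing:
            raise ValueError(f"{self.kind} descriptor missing {sorted(missing)}")
        p = self.params
        if self.kind == "exp_decay":
            if p["S0"] <= 0:
                raise ValueError("S0 must be positive")
        elif self.kind == "sigmoid_growth":
            if p["Smin"] <= 0 or p["Smax"] <= 0:
                raise ValueError("Smin, Smax must be positive")
            if p["Smin"] > p["Smax"]:
                raise ValueError("require Smin <= Smax")
        else:
            if not (0.0 <= p["lower"] <= p["upper"] <= 1.0):
                raise ValueError("gen_logistic requires 0 <= lower <= upper <= 1")
            if p["shape"] <= 0:
                raise ValueError("shape must be positive")

    def __call__(self, t):
        return eval_source(self, t)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params), "t_ref": self.t_ref}

    @classmethod
    def from_dict(cls, d: dict) -> "SourceDescriptor":
        return cls(kind=d["kind"], params=dict(d["params"]), t_ref=d.get("t_ref", 0.0))


@dataclass(frozen=True)
class TabulatedSource:
    """A source trajectory given by interpolation of a computed curve.

    Used when a model-predicted population (e.g. the corrected young-mouse
    T_CM trajectory) serves as the source for a downstream subset.  Positive
    values are interpolated on the log scale; evaluation outside the tabulated
    range clamps to the endpoints.
    """

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        logv = np.log(np.asarray(self.values, dtype=float))
        return np.exp(np.interp(t, np.asarray(self.times, dtype=float), logv))


def _eval_kind(kind: str, theta: np.ndarray, t: np.ndarray, t_ref: float):
    if kind == "exp_decay":
        S0, nu = theta
        return S0 * np.exp(-nu * (t - t_ref))
    if kind == "sigmoid_growth":
        Smax, Smin, r = theta
        return Smax / (1.0 + np.exp(-r * t) * (Smax - Smin) / Smin)
    lower, upper, rate, midpoint, shape = theta
    z = 1.0 + np.exp(np.clip(-rate * (t - midpoint), -700.0, 700.0))
    return lower + (upper - lower) / z ** (1.0 / shape)


def eval_source(desc, t):
    """Evaluate a source descriptor at host age ``t`` (days).

    Accepts a :class:`SourceDescriptor`, a :class:`TabulatedSource`, or any
    callable ``t -> value``.  Negative ages are a domain error.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("source descriptors are defined for t >= 0 only")
    if callable(desc) and not isinstance(desc, SourceDescriptor):
        return desc(t_arr) if t_arr.shape else float(desc(t_arr))
    theta = np.array([desc.params[k] for k in _PARAM_NAMES[desc.kind]])
    out = _eval_kind(desc.kind, theta, t_arr, desc.t_ref)
    return float(out) if np.ndim(t) == 0 else out


# ---------------------------------------------------------------------------
# fitting

_N_STARTS = 10
_START_SEED = 20190901  # fixed multi-start schedule: fits are deterministic


def _start_ranges(kind: str, times: np.ndarray, values: np.ndarray):
    """Log-uniform (or uniform) sampling boxes for multi-start initials."""
    vmax, vmin = float(np.max(values)), float(np.min(values))
    span = max(float(np.ptp(times)), 1.0)
    if kind == "exp_decay":
        return [("log", vmax / 10, vmax * 10), ("log", 1e-4 / span * 30, 10.0 / span)]
    if kind == "sigmoid_growth":
        return [
            ("log", vmax / 3, vmax * 30),
            ("log", max(vmin / 30, 1e-12), vmin * 3 + 1e-12),
            ("log", 0.3 / span, 300.0 / span),
        ]
    return [
        ("lin", 0.0, max(vmin, 1e-6)),
        ("lin", min(vmax, 1.0), 1.0),
        ("log", 0.3 / span, 300.0 / span),
        ("lin", float(np.min(times)), float(np.max(times))),
        ("log", 0.2, 5.0),
    ]


def fit_source(
    times: Sequence[float],
    values: Sequence[float],
    kind: str,
    *,
    t_ref: float | None = None,
    n_starts: int = _N_STARTS,
) -> SourceDescriptor:
    """Least-squares fit of a source descriptor family to a timecourse.

    Size families (``exp_decay``, ``sigmoid_growth``) are fitted on
    log-transformed observations; the chimerism family (``gen_logistic``) on
    the untransformed fraction with parameters bounded to keep the curve in
    [0, 1].  A fixed multi-start schedule (log-uniform draws, fixed seed) makes
    the fit deterministic; the start with the smallest sum of squared
    residuals wins, ties broken by first-found.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if kind not in _KINDS:
        raise ValueError(f"unknown source kind {kind!r}")
    n_par = len(_PARAM_NAMES[kind])
    if times.size < n_par + 1:
        raise ValueError(f"need at least {n_par + 1} observations to fit {kind}")
    log_scale = kind in ("exp_decay", "sigmoid_growth")
    if log_scale and np.any(values <= 0):
        raise ValueError("size fits require strictly positive values")
    if t_ref is None:
        t_ref = float(np.min(times)) if kind == "exp_decay" else 0.0

    target = np.log(values) if log_scale else values

    def residuals(theta):
        pred = _eval_kind(kind, theta, times, t_ref)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (np.log(pred) if log_scale else pred) - target

    if kind == "gen_logistic":
        lb = np.array([0.0, 0.0, 1e-6, -1e4, 1e-3])
        ub = np.array([1.0, 1.0, 10.0, 1e4, 1e3])
    elif kind == "exp_decay":
        lb, ub = np.array([1e-300, -10.0]), np.array([np.inf, 10.0])
    else:
        lb, ub = np.array([1e-300, 1e-300, 1e-6]), np.array([np.inf, np.inf, 10.0])

    rng = np.random.default_rng(_START_SEED)
    ranges = _start_ranges(kind, times, values)
    best = None
    diagnostics = []
    for i in range(n_starts):
        theta0 = np.empty(n_par)
        for j, (mode, lo, hi) in enumerate(ranges):
            if mode == "log":
                theta0[j] = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            else:
                theta0[j] = rng.uniform(lo, hi)
        theta0 = np.clip(theta0, lb + 1e-12, ub - 1e-12 if np.all(np.isfinite(ub)) else theta0)
        try:
            sol = least_squares(residuals, theta0, bounds=(lb, ub), method="trf")
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            diagnostics.append(f"start {i}: {exc}")
            continue
        if not np.all(np.isfinite(sol.fun)):
            diagnostics.append(f"start {i}: non-finite residuals")
            continue
        ssr = float(np.sum(sol.fun**2))
        if best is None or ssr < best[0]:
            best = (ssr, sol.x)
    if best is None:
        raise SourceFitError(
            f"no multi-start attempt converged for {kind}: " + "; ".join(diagnostics)
        )
    theta = best[1]
    if kind == "sigmoid_growth" and theta[1] > theta[0]:
        theta = theta.copy()
        theta[[0, 1]] = theta[[1, 0]]
    params = dict(zip(_PARAM_NAMES[kind], (float(x) for x in theta)))
    if kind == "gen_logistic" and params["upper"] < params["lower"]:
        params["lower"], params["upper"] = params["upper"], params["lower"]
    return SourceDescriptor(kind=kind, params=params, t_ref=t_ref)
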