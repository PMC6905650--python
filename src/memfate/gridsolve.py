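"""Fixed-grid exponential-integrator backend for the linear compartment ODEs.

Every equation in the compartment models has the form

    dy/dt = -k(t) y + g(t),      g >= 0,

either with a constant loss rate ``k`` (total cell numbers) or a
time-varying, non-negative rate (the chimerism relaxation equations).  On a
uniform grid the solution is

    y_n = y_0 exp(-L_n) + sum_{j<n} b_j exp(-(L_n - L_{j+1})),

with ``L`` the cumulative integral of ``k`` and ``b_j`` the local
inhomogeneous integrals.  Because ``b_j >= 0`` the sum is evaluated stably in
log space with a cumulative log-sum-exp, which vectorises over the whole grid
(and over BMT groups) with no Python-level time stepping.  For constant ``k``
the local integrals are exact for piecewise-linear ``g`` (an ETD1 scheme);
for varying ``k`` they are trapezoidal.  This backend exists for the
optimiser and bootstrap loops; the reference path is an adaptive stiff solver
and the two are verified against each other.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "accumulate_linear",
    "etd_weights",
    "step_integrals_const_rate",
    "step_integrals_var_rate",
]

_EXP_CLIP = 700.0


def accumulate_linear(L: np.ndarray, b: np.ndarray, y0) -> np.ndarray:
    """Solve ``y' = -k y + g`` on a grid given cumulative rate and step loads.

    Parameters
    ----------
    L
        Cumulative rate integral, shape ``(n,)`` or ``(n, m)`` for ``m``
        independent columns; ``L[0] == 0``.
    b
        Non-negative local integrals per step, shape ``(n-1,)`` / ``(n-1, m)``.
    y0
        Initial value(s) at the first grid point.
    """
    L = np.asarray(L, dtype=float)
    b = np.asarray(b, dtype=float)
    with np.errstate(divide="ignore"):
        logb = np.log(b)
    A = np.logaddexp.accumulate(logb + L[1:], axis=0)
    out = np.empty_like(L)
    out[0] = y0
    with np.errstate(over="ignore"):
        decay = np.exp(np.clip(-L[1:], -_EXP_CLIP, _EXP_CLIP))
        out[1:] = y0 * decay + np.exp(np.clip(A - L[1:], -_EXP_CLIP, _EXP_CLIP))
    return out


def etd_weights(k: float, h: float) -> tuple[float, float]:
    """Exact step weights for piecewise-linear loads under constant rate ``k``.

    Returns ``(w0, w1)`` such that the integral of ``g(u) exp(-k (h - u))``
    over a step equals ``w0 g_j + w1 g_{j+1}`` when ``g`` is linear in ``u``.
    """
    z = k * h
    if abs(z) < 1e-5:
        phi1 = h * (1.0 - z / 2.0 + z * z / 6.0)
        c1 = h * (0.5 - z / 6.0 + z * z / 24.0)
    else:
        em = np.exp(-np.clip(z, -_EXP_CLIP, _EXP_CLIP))
        phi1 = (1.0 - em) / k
        c1 = (1.0 / k) - phi1 / z
    return phi1 - c1, c1


def step_integrals_const_rate(g: np.ndarray, k: float, h: float) -> np.ndarray:
    """Local integrals ``b_j`` for constant rate; ``g`` sampled on the grid."""
    w0, w1 = etd_weights(k, h)
    return np.maximum(w0 * g[:-1] + w1 * g[1:], 0.0)


def step_integrals_var_rate(g: np.ndarray, F: np.ndarray, h: float) -> np.ndarray:
    """Local integrals for a varying rate with per-step integrals ``F_j``.

    Trapezoidal in the exponentially-weighted sense:
    ``b_j = (h/2) (g_{j+1} + g_j exp(-F_j))``.
    """
    with np.errstate(over="ignore"):
        w = np.exp(np.clip(-F, -_EXP_CLIP, _EXP_CLIP))
    return 0.5 * h * (g[1:] + g[:-1] * w)
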