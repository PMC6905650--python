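"""Human-readable summaries: AICc comparison grids and parameter tables.

The comparison grid mirrors the published layout — one row per model, one
column per (subset source), cells showing the AICc difference with the
combined log-likelihood in parentheses ("0 (124)" marks the favoured
combination).  Parameter tables print point estimates with bootstrap 95%
confidence intervals in parentheses and a shared power of ten, e.g.
``5.9 (3.0, 9.4) x 10^-3``; clonal half-lives are given to two significant
figures and rendered "not shown" when the net loss rate is not positive.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .inference import ModelComparison

__all__ = [
    "sig2",
    "format_estimate",
    "format_half_life",
    "comparison_grid",
    "comparison_tsv",
    "parameter_rows",
]


def sig2(x: float) -> str:
    """Two significant figures, trailing-zero free (120, 8.4, 0.0048...)."""
    if x == 0 or not math.isfinite(x):
        return "0" if x == 0 else "nan"
    e = math.floor(math.log10(abs(x)))
    r = round(x, -e + 1)
    if e >= 1:
        return f"{r:.0f}"
    return f"{r:.{max(0, 1 - e)}f}"


def format_estimate(value: float, lo: float | None = None, hi: float | None = None) -> str:
    """Publication-style estimate with CI and a shared power of ten."""
    if not math.isfinite(value):
        return "NA"
    if value == 0:
        core = "0"
        return core
    e = math.floor(math.log10(abs(value)))
    if -2 <= e <= 2:
        scale, suffix = 1.0, ""
    else:
        scale, suffix = 10.0 ** (-e), f" × 10^{e}"
    if lo is None or hi is None or not (math.isfinite(lo) and math.isfinite(hi)):
        return f"{sig2(value * scale)}{suffix}"
    return f"{sig2(value * scale)} ({sig2(lo * scale)}, {sig2(hi * scale)}){suffix}"


def format_half_life(half_life: float, lo: float | None = None, hi: float | None = None) -> str:
    """Clonal half-life to 2 s.f.; NaN (non-positive loss rate) -> "not shown"."""
    if half_life is None or not math.isfinite(half_life):
        return "not shown"
    return format_estimate(half_life, lo, hi)


def comparison_grid(comparison: ModelComparison) -> pd.DataFrame:
    """Model x source grid of "delta_aicc (loglik)" strings."""
    t = comparison.table
    grid = {}
    for src in t["source"].unique():
        col = {}
        for _, row in t[t["source"] == src].iterrows():
            if not row["converged"] or not np.isfinite(row["aicc"]):
                col[row["model"]] = "failed"
            else:
                col[row["model"]] = f"{row['delta_aicc']:.0f} ({row['loglik_combined']:.0f})"
        grid[src] = col
    return pd.DataFrame(grid)


def comparison_tsv(comparison: ModelComparison) -> str:
    """Tab-separated comparison table (model, source, K, N, lnL, AICc, delta)."""
    cols = ["model", "source", "K", "N", "loglik_combined", "aicc", "delta_aicc"]
    return comparison.table[cols].to_csv(sep="\t", index=False, float_format="%.3f")


_LABELS = {
    "phi": "Force of recruitment (d^-1)",
    "influx_at_tstar": "Daily cell influx at age t* = 20 wk",
    "lam": "Net loss rate (d^-1)",
    "lam_fast": "Net loss rate of fast subset (d^-1)",
    "lam_slow": "Net loss rate of slow subset (d^-1)",
    "half_life": "Clonal half-life (d)",
    "half_life_fast": "Clonal half-life of fast subset (d)",
    "half_life_slow": "Clonal half-life of slow subset (d)",
    "pct_to_slow": "% of memory transitioning to slow",
    "prop_slow_at_tstar": "Proportion slow at t* = 20 wk",
    "lam0": "Net loss rate of new memory (d^-1)",
    "A": "Memory age threshold (d)",
    "half_life_new": "Clonal half-life of new memory (d)",
    "p": "Initial age-distribution exponent (d^-1)",
    "M0": "Pool size at t0 (cells)",
    "Mslow0": "Slow pool at t0 (cells)",
    "I0": "Incumbent pool at t0 (cells)",
    "gamma": "Fast-to-slow transition rate (d^-1)",
    "M_t0": "Pool size at t0 (cells)",
}


def parameter_rows(estimates: dict, cis: dict | None = None) -> pd.DataFrame:
    """One formatted row per scalar estimate, CIs in parentheses when given."""
    cis = cis or {}
    rows = []
    for name, value in estimates.items():
        if not np.isscalar(value):
            continue
        lo, hi = cis.get(name, (None, None))
        fmt = format_half_life if name.startswith("half_life") else format_estimate
        rows.append({
            "parameter": name,
            "quantity": _LABELS.get(name, name),
            "estimate": fmt(value, lo, hi) if value is not None else "NA",
        })
    return pd.DataFrame(rows)
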