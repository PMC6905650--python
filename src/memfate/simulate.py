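"""Synthetic busulfan-chimera cohorts with the error structure the fit assumes.

Each simulated mouse is transplanted in one of a small number of BMT batches
(real cohorts are transplanted in batches), harvested once (cross-sectional,
matching terminal harvests), and contributes a total count and a donor
fraction for the simulated memory subset plus its precursor.  Noise is
applied on the fitting scales — Gaussian on log counts (sd ``sigma_x``) and
on arcsin-sqrt normalised chimerism (sd ``sigma_y``) — so the fitted
likelihood is exactly correctly specified.  Per-mouse thymic (DP1) chimerism
is drawn uniformly to emulate variable conditioning efficiency; stored donor
fractions are un-normalised (multiplied back by the mouse's DP1 chimerism)
exactly as a reader would receive them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import CohortConfig
from .models import Trajectory, solve_model
from .sources import SourceDescriptor, eval_source
from .truths import (
    SOURCE_FOR_SUBSET,
    adult_source,
    source_chimerism,
    truth_params,
)

__all__ = ["SimConfig", "MouseObservation", "simulate_cohort", "default_truth", "COHORT_COLUMNS"]

COHORT_COLUMNS = [
    "mouse_id", "facility", "bmt_age_days", "obs_age_days",
    "count_naive", "count_tcm", "count_tem",
    "chi_naive", "chi_tcm", "chi_tem", "chi_dp1",
]

_DEFAULT_BMT_RANGE = {"clean": (40.0, 182.0), "dirty": (56.0, 182.0)}


@dataclass(frozen=True)
class MouseObservation:
    """One mouse x one terminal timepoint; donor fractions un-normalised."""

    mouse_id: str
    facility: str
    bmt_age_days: float
    obs_age_days: float
    count_naive: float
    count_tcm: float
    count_tem: float
    chi_naive: float
    chi_tcm: float
    chi_tem: float
    chi_dp1: float


@dataclass
class SimConfig:
    """Generating configuration for one synthetic cohort.

    ``truth_model``/``truth_params`` drive the simulated memory subset
    (``subset``); ``source_truth``/``chi_source_truth`` describe its
    precursor.  BMT ages are spread over ``n_batches`` evenly spaced batch
    dates within ``bmt_age_range`` (5-26 wk by default, floored so the
    earliest batch is consistent with the facility baseline age t0);
    observations fall 4-64 weeks post BMT.
    """

    facility: str
    subset: str
    truth_model: str
    truth_params: object
    source_truth: SourceDescriptor
    chi_source_truth: SourceDescriptor
    sigma_x: float = 0.15
    sigma_y: float = 0.05
    n_mice: int = 150
    bmt_age_range: tuple = ()
    obs_window_post_bmt: tuple = (28.0, 448.0)
    n_batches: int = 6
    chi_dp1_range: tuple = (0.6, 0.95)
    seed: int = 0

    def __post_init__(self):
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("noise SDs must be positive")
        if self.subset not in ("tcm", "tem"):
            raise ValueError("subset must be 'tcm' or 'tem'")
        if not self.bmt_age_range:
            self.bmt_age_range = _DEFAULT_BMT_RANGE[self.facility]

    @property
    def cohort_config(self) -> CohortConfig:
        return CohortConfig.for_facility(self.facility)


def default_truth(facility: str, subset: str, model: str, **overrides) -> SimConfig:
    """A ready-to-run :class:`SimConfig` with the reference generating truths."""
    src_pop = SOURCE_FOR_SUBSET[subset]
    cfg = SimConfig(
        facility=facility,
        subset=subset,
        truth_model=model,
        truth_params=truth_params(facility, subset, model),
        source_truth=adult_source(facility, src_pop),
        chi_source_truth=source_chimerism(src_pop),
    )
    return replace(cfg, **overrides) if overrides else cfg


def _noisy_counts(rng, truth, sigma_x):
    return np.exp(np.log(truth) + rng.normal(0.0, sigma_x, size=len(truth)))


def _noisy_chi_norm(rng, chi_true, sigma_y):
    y = np.arcsin(np.sqrt(np.clip(chi_true, 0.0, 1.0)))
    y_obs = np.clip(y + rng.normal(0.0, sigma_y, size=len(y)), 0.0, np.pi / 2)
    return np.sin(y_obs) ** 2


def simulate_cohort(cfg: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate one cross-sectional cohort; fully reproducible from the seed.

    Returns a tidy frame with one row per mouse (schema
    :data:`COHORT_COLUMNS`).  The simulated subset's columns carry the
    truth-model trajectory plus noise; the precursor population's columns are
    generated from its descriptors with the same noise model; the remaining
    subset's columns are NaN.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ccfg = cfg.cohort_config
    lo, hi = cfg.bmt_age_range
    if lo + ccfg.bmt_lag < ccfg.t0 - 1e-9:
        raise ValueError("earliest BMT batch is inconsistent with the facility t0")
    batches = np.round(np.linspace(lo, hi, cfg.n_batches))
    bmt = rng.choice(batches, size=cfg.n_mice)
    off_lo, off_hi = cfg.obs_window_post_bmt
    obs_age = bmt + rng.uniform(off_lo, off_hi, size=cfg.n_mice)

    total_true = np.empty(cfg.n_mice)
    chi_true = np.empty(cfg.n_mice)
    for b in np.unique(bmt):
        m = bmt == b
        tr: Trajectory = solve_model(
            cfg.truth_model, cfg.truth_params, cfg.source_truth,
            cfg.chi_source_truth, ccfg, float(b), obs_age[m],
        )
        total_true[m] = tr.total
        chi_true[m] = tr.chi_norm
    if np.any(total_true <= 0):
        raise ValueError("truth trajectory is non-positive; check the configuration")

    counts = _noisy_counts(rng, total_true, cfg.sigma_x)
    chi_norm = _noisy_chi_norm(rng, chi_true, cfg.sigma_y)
    chi_dp1 = rng.uniform(*cfg.chi_dp1_range, size=cfg.n_mice)

    src_pop = SOURCE_FOR_SUBSET[cfg.subset]
    src_total = eval_source(cfg.source_truth, obs_age)
    src_counts = _noisy_counts(rng, src_total, cfg.sigma_x)
    src_chi_true = eval_source(cfg.chi_source_truth, obs_age - bmt)
    src_chi = _noisy_chi_norm(rng, src_chi_true, cfg.sigma_y)

    cols = {c: np.full(cfg.n_mice, np.nan) for c in COHORT_COLUMNS[4:]}
    cols[f"count_{cfg.subset}"] = counts
    cols[f"chi_{cfg.subset}"] = chi_norm * chi_dp1
    cols[f"count_{src_pop}"] = src_counts
    cols[f"chi_{src_pop}"] = src_chi * chi_dp1
    cols["chi_dp1"] = chi_dp1

    return pd.DataFrame({
        "mouse_id": [f"{cfg.facility[0]}{i:04d}" for i in range(cfg.n_mice)],
        "facility": cfg.facility,
        "bmt_age_days": bmt,
        "obs_age_days": obs_age,
        **cols,
    })
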