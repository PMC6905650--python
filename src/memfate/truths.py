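"""Reference parameter sets used as synthetic-data generating truths.

Where the adult fits constrain a quantity, the generating truths use the
published point estimates (two-phase and age-dependent-loss parameters,
naive-pool decay half-lives of 228 d clean / 143 d dirty, baseline ages).
The homogeneous and resistant models were rejected by the data and carry no
published estimates, so their truths are plausible values of the right
magnitude chosen once for this package.  Source-descriptor and chimerism
shapes are likewise package-chosen to reproduce the qualitative features of
the cohorts: an exponentially waning naive pool, a saturating T_CM pool, and
source chimerism rising after BMT along a generalised-logistic curve.

The two-phase transition rate gamma is not reported directly; it is backed
out of the printed "% of memory transitioning to slow",
``q = 100 gamma / (lam_fast + gamma)``, as ``gamma = q lam_fast / (100 - q)``.
"""

from __future__ import annotations

import math

from .models import AgeDepParams, HomogeneousParams, ResistantParams, TwoPhaseParams
from .sources import SourceDescriptor

__all__ = [
    "gamma_from_pct_slow",
    "adult_source",
    "source_chimerism",
    "truth_params",
    "young_source",
    "TCM_TARGET_MEANS",
    "SOURCE_FOR_SUBSET",
]

#: which precursor feeds which subset (T_EM is fed by T_CM, the favoured path)
SOURCE_FOR_SUBSET = {"tcm": "naive", "tem": "tcm"}

_LN2 = math.log(2.0)


def gamma_from_pct_slow(pct: float, lam_fast: float) -> float:
    """Invert ``pct = 100 gamma / (lam_fast + gamma)`` for gamma."""
    if not 0.0 < pct < 100.0:
        raise ValueError("pct must lie strictly between 0 and 100")
    return pct / 100.0 * lam_fast / (1.0 - pct / 100.0)


_ADULT_SOURCES = {
    # naive CD4 pools decay exponentially; half-lives 228 d (clean), 143 d (dirty)
    ("clean", "naive"): SourceDescriptor(
        "exp_decay", {"S0": 2.0e7, "nu": _LN2 / 228.0}, t_ref=66.0
    ),
    ("dirty", "naive"): SourceDescriptor(
        "exp_decay", {"S0": 2.9e7, "nu": _LN2 / 143.0}, t_ref=84.0
    ),
    # T_CM as a source: saturating in the clean facility, slow decay in dirty
    ("clean", "tcm"): SourceDescriptor(
        "sigmoid_growth", {"Smax": 3.2e5, "Smin": 2.0e4, "r": 0.04}
    ),
    ("dirty", "tcm"): SourceDescriptor(
        "exp_decay", {"S0": 8.0e5, "nu": 1.0e-3}, t_ref=84.0
    ),
}

_CHI_SOURCES = {
    # normalised source chimerism vs days post BMT (generalised logistic)
    "naive": SourceDescriptor(
        "gen_logistic",
        {"lower": 0.0, "upper": 0.95, "rate": 0.05, "midpoint": 40.0, "shape": 1.0},
    ),
    "tcm": SourceDescriptor(
        "gen_logistic",
        {"lower": 0.0, "upper": 0.85, "rate": 0.035, "midpoint": 90.0, "shape": 1.0},
    ),
}


def adult_source(facility: str, population: str) -> SourceDescriptor:
    """Adult source-size descriptor for ``population`` in ``facility``."""
    try:
        return _ADULT_SOURCES[(facility, population)]
    except KeyError:
        raise ValueError(f"no adult source descriptor for {(facility, population)}") from None


def source_chimerism(population: str) -> SourceDescriptor:
    """Normalised source chimerism descriptor (argument: days post BMT)."""
    try:
        return _CHI_SOURCES[population]
    except KeyError:
        raise ValueError(f"no source-chimerism descriptor for {population!r}") from None


_TWO_PHASE = {
    ("clean", "tcm"): TwoPhaseParams(
        Mslow0=1.2e5, phi=1.4e-3, lam_fast=0.082, lam_slow=5.9e-3,
        gamma=gamma_from_pct_slow(3.4, 0.082),
    ),
    ("dirty", "tcm"): TwoPhaseParams(
        Mslow0=6.0e5, phi=1.5e-3, lam_fast=0.10, lam_slow=4.8e-3,
        gamma=gamma_from_pct_slow(5.0, 0.10),
    ),
    ("clean", "tem"): TwoPhaseParams(
        Mslow0=4.0e5, phi=1.2, lam_fast=0.23, lam_slow=2.5e-3,
        gamma=gamma_from_pct_slow(1.8, 0.23),
    ),
    ("dirty", "tem"): TwoPhaseParams(
        Mslow0=3.0e6, phi=1.1, lam_fast=0.39, lam_slow=4.8e-3,
        gamma=gamma_from_pct_slow(9.1, 0.39),
    ),
}

_AGE_DEP = {
    ("clean", "tcm"): AgeDepParams(phi=0.43e-3, p=3e-3, lam0=2.2e-2, A=150.0, n=3),
    ("dirty", "tcm"): AgeDepParams(phi=0.26e-3, p=3e-3, lam0=1.2e-2, A=190.0, n=3),
    ("clean", "tem"): AgeDepParams(phi=0.10, p=3e-3, lam0=1.2e-2, A=150.0, n=3),
    # T_EM dirty: lam0 indistinguishable from zero, A unconstrained — no truth
}

_HOMOGENEOUS = {
    ("clean", "tcm"): HomogeneousParams(M0=5.0e5, phi=0.5e-3, lam=0.010),
    ("dirty", "tcm"): HomogeneousParams(M0=1.2e6, phi=0.4e-3, lam=0.008),
    ("clean", "tem"): HomogeneousParams(M0=1.0e6, phi=0.12, lam=0.012),
    ("dirty", "tem"): HomogeneousParams(M0=4.0e6, phi=0.10, lam=0.010),
}

_RESISTANT = {
    ("clean", "tcm"): ResistantParams(M0=4.0e5, I0=1.5e5, phi=0.6e-3, lam=0.020),
    ("dirty", "tcm"): ResistantParams(M0=8.0e5, I0=5.0e5, phi=0.5e-3, lam=0.015),
    ("clean", "tem"): ResistantParams(M0=8.0e5, I0=3.0e5, phi=0.15, lam=0.025),
    ("dirty", "tem"): ResistantParams(M0=3.0e6, I0=1.5e6, phi=0.12, lam=0.020),
}

_BY_MODEL = {
    "two_phase": _TWO_PHASE,
    "age_dep": _AGE_DEP,
    "homogeneous": _HOMOGENEOUS,
    "resistant": _RESISTANT,
}


def truth_params(facility: str, subset: str, model: str):
    """Generating-truth parameters for a (facility, subset, model) triple."""
    if model == "age_dep" and (facility, subset) == ("dirty", "tem"):
        raise ValueError(
            "no age-dependent-loss truth for T_EM in the dirty facility: the "
            "fitted lam0 is indistinguishable from zero and A is unconstrained"
        )
    try:
        return _BY_MODEL[model][(facility, subset)]
    except KeyError:
        raise ValueError(f"no truth parameters for {(facility, subset, model)}") from None


# young (age 5 d - 15 wk) wild-type timecourses used for ontogeny prediction
_YOUNG_SOURCES = {
    "naive": SourceDescriptor("sigmoid_growth", {"Smax": 2.5e7, "Smin": 5.0e5, "r": 0.08}),
    "tcm": SourceDescriptor("sigmoid_growth", {"Smax": 3.0e5, "Smin": 1.0e4, "r": 0.06}),
}


def young_source(population: str) -> SourceDescriptor:
    """Young-mouse source-size descriptor (clean facility wild types)."""
    try:
        return _YOUNG_SOURCES[population]
    except KeyError:
        raise ValueError(f"no young-mouse descriptor for {population!r}") from None


#: mean adult (10-28 wk) T_CM pool sizes per environment used as ontogeny
#: targets; dirty mice carry several-fold more memory than clean, germ-free fewer
TCM_TARGET_MEANS = {"germ_free": 1.2e5, "clean": 3.0e5, "dirty": 9.0e5}
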