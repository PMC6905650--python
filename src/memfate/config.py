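"""Cohort-level constants: facilities, baseline ages, BMT lag."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CohortConfig", "FACILITIES"]

FACILITIES = ("clean", "dirty")

#: host age t0 (days) at which every model is initialised, and the post-BMT
#: lag after which donor chimerism in memory is taken to start from zero.
_FACILITY_DEFAULTS = {"clean": (66.0, 26.0), "dirty": (84.0, 28.0)}


@dataclass(frozen=True)
class CohortConfig:
    """Per-facility timing conventions.

    ``t0`` is the youngest age at BMT plus ``bmt_lag``: the earliest host age
    at which chimerism in the thymic reference population has stabilised for
    every mouse in the cohort, and the age from which all models are solved.
    ``t_star`` (20 weeks) is the reference age at which derived quantities
    such as the daily cell influx are reported.
    """

    facility: str
    t0: float
    bmt_lag: float
    t_star: float = 140.0

    @classmethod
    def for_facility(cls, facility: str) -> "CohortConfig":
        if facility not in _FACILITY_DEFAULTS:
            raise ValueError(f"unknown facility {facility!r}; expected one of {FACILITIES}")
        t0, lag = _FACILITY_DEFAULTS[facility]
        return cls(facility=facility, t0=t0, bmt_lag=lag)

    def start_age(self, bmt_age: float) -> float:
        """Host age at which a mouse's normalised chimerism is pinned to zero."""
        return float(bmt_age) + self.bmt_lag
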