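import numpy as np
import pytest

from memfate import (
    CohortConfig,
    FitData,
    adult_source,
    default_truth,
    simulate_cohort,
    source_chimerism,
)


@pytest.fixture(scope="session")
def cfg_clean():
    return CohortConfig.for_facility("clean")


@pytest.fixture(scope="session")
def cfg_dirty():
    return CohortConfig.for_facility("dirty")


@pytest.fixture(scope="session")
def naive_clean():
    return adult_source("clean", "naive")


@pytest.fixture(scope="session")
def tcm_clean_source():
    return adult_source("clean", "tcm")


@pytest.fixture(scope="session")
def chi_naive():
    return source_chimerism("naive")


@pytest.fixture(scope="session")
def chi_tcm():
    return source_chimerism("tcm")


def _cohort(facility, subset, model, n_mice=60, seed=0, **overrides):
    sim = default_truth(facility, subset, model, n_mice=n_mice, seed=seed, **overrides)
    df = simulate_cohort(sim)
    chi_norm = df[f"chi_{subset}"].to_numpy() / df["chi_dp1"].to_numpy()
    data = FitData.from_counts(
        df["bmt_age_days"].to_numpy(), df["obs_age_days"].to_numpy(),
        df[f"count_{subset}"].to_numpy(), chi_norm,
    )
    return sim, df, data


@pytest.fixture(scope="session")
def cohort_factory():
    """Session-cached factory: (facility, subset, model, ...) -> (sim, df, data)."""
    cache = {}

    def make(facility, subset, model, n_mice=60, seed=0, **overrides):
        key = (facility, subset, model, n_mice, seed, tuple(sorted(overrides.items())))
        if key not in cache:
            cache[key] = _cohort(facility, subset, model, n_mice, seed, **overrides)
        return cache[key]

    return make
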