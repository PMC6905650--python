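"""Simulate T_EM cohorts in both facilities, fit competing models, rank by AICc.

The generating truth is the two-phase model; with ~150 mice per facility the
AICc difference against the one-pool (homogeneous) model is decisive
(differences of 10 or more are considered highly significant).
"""

from memfate import FitData, compare_models, default_truth, simulate_cohort
from memfate.report import comparison_grid
from memfate.truths import adult_source, source_chimerism


def fit_data(facility, seed):
    df = simulate_cohort(default_truth(facility, "tem", "two_phase", seed=seed))
    return FitData.from_counts(
        df.bmt_age_days, df.obs_age_days, df.count_tem, df.chi_tem / df.chi_dp1
    )


sources = {"tcm": {f: (adult_source(f, "tcm"), source_chimerism("tcm"))
                   for f in ("clean", "dirty")}}
comp = compare_models(
    fit_data("clean", 1), fit_data("dirty", 2), sources,
    models=["two_phase", "homogeneous", "resistant"], n_starts=5, seed=0,
)
print(comparison_grid(comp))          # delta-AICc (combined lnL) per model
best_model, best_source = comp.best()
print(f"\nbest supported: {best_model} fed by {best_source}")
# Expect the generating two-phase model at delta = 0 and the others far
# behind: kinetic heterogeneity in T_EM is detectable from chimerism curves.
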