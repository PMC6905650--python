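"""Generate a synthetic busulfan-chimera cohort and inspect its structure.

One row per mouse: batch BMT age, one terminal observation 4-64 weeks later,
noisy counts, and donor fractions that must be normalised by the mouse's own
DP1 thymocyte chimerism before fitting.
"""

from memfate import default_truth, simulate_cohort

sim = default_truth("dirty", "tcm", "age_dep", n_mice=8, seed=42)
df = simulate_cohort(sim)
cols = ["mouse_id", "bmt_age_days", "obs_age_days", "count_tcm",
        "chi_tcm", "chi_dp1"]
print(df[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
chi_norm = df.chi_tcm / df.chi_dp1
print(f"\nnormalised T_CM chimerism range: "
      f"{chi_norm.min():.3f} - {chi_norm.max():.3f}")
# chi_tcm / chi_dp1 removes mouse-to-mouse variation in conditioning
# efficiency; it is the quantity the models predict.
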