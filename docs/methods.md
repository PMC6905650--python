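# Methods

## The system

In busulfan chimeric mice, low-dose conditioning replaces a fraction of the
haematopoietic stem cells with congenically marked donor cells while leaving
peripheral T cell compartments intact. Donor-derived cells then flow through
the thymus into the naive pool and onwards into memory, so the *donor
chimerism* of each peripheral subset — the donor fraction, normalised to the
donor fraction among early double-positive (DP1) thymocytes in the same
mouse to remove variation in conditioning efficiency — rises at a rate set
by that subset's recruitment and loss kinetics. `memfate` models the
timecourses of total cell numbers `M(t)` and normalised chimerism
`χ_norm(t)` of circulating CD4⁺ central-memory (T_CM) and effector-memory
(T_EM) subsets, with host age `t` in days throughout.

Each memory subset is fed from a precursor ("source") population at total
rate `φ S(t)`, where `φ` is the *force of recruitment* — approximately the
daily per-capita probability that a source cell is recruited, times any
clonal expansion during recruitment. T_CM is fed by naive CD4⁺ T cells; T_EM
by T_CM (the favoured pathway; naive is available as an alternative source).
Loss is parameterised as a *net* loss rate `λ` (death plus onward
differentiation, minus proliferative self-renewal), which may be negative;
`ln 2 / λ` is the *clonal half-life* of a self-renewing population and can
greatly exceed any individual cell's lifespan.

## Source descriptors

Sources are described empirically, not mechanistically:

- `exp_decay`: `S(t) = S0 e^{-ν (t - t_ref)}` — adult naive pools wane with
  thymic involution (reference half-lives `ln2/ν`: 228 d clean facility,
  143 d dirty).
- `sigmoid_growth`: `S(t) = Smax / (1 + e^{-r t} (Smax-Smin)/Smin)` — a
  logistic anchored so `S(0) = Smin`, used for accumulating pools
  (young-mouse naive and T_CM; adult clean-facility T_CM).
- `gen_logistic` (Richards): `lower + (upper-lower) / (1 + e^{-rate (τ -
  midpoint)})^{1/shape}` for the normalised *source chimerism*. The argument
  is `τ = t - bmt_age`, days post transplant: chimerism kinetics are tied to
  the transplant, not to host age, so mice transplanted at different ages
  share one chimerism-versus-τ curve. The generalised-logistic family is
  named in the source literature without a printed form; the Richards
  parameterisation is this package's choice.

Size descriptors are fitted by least squares on log-transformed counts;
chimerism descriptors on the untransformed fraction with box bounds keeping
the curve in [0, 1] (the log transform is prescribed only for counts).
Fitting uses 10 multi-starts drawn log-uniformly from plausible ranges with
a fixed internal seed — fits are deterministic; best sum of squares wins,
ties to the first found.

## The four dynamical models

All models are solved from a facility baseline age `t0` (66 d clean, 84 d
dirty: the youngest age at BMT plus the 26/28 d lag after which DP1
chimerism has stabilised). Per mouse, the normalised chimerism is pinned to
zero at `T = bmt_age + lag` and the `dχ_DP1/dt` term is dropped
(observations earlier than the lag are excluded from fitting). Because host
and donor cells obey identical kinetics, total numbers follow a single curve
regardless of BMT age; only the chimerism curves are mouse-specific.

1. **Homogeneous** (`M0, φ, λ`): `dM/dt = φ S(t) − λ M`, and
   `dχ/dt = (φ S / M)(χ_src − χ)`. With an exponentially decaying source the
   totals have the closed form
   `M(t) = M0 e^{−λ(t−t0)} + φ S(t0) (e^{−ν(t−t0)} − e^{−λ(t−t0)})/(λ−ν)`,
   with the removable singularity at `λ = ν` replaced by its limit
   `φ S(t0)(t−t0) e^{−λ(t−t0)}`. Given long enough, and if `ν < λ`, the
   subset's chimerism converges to its source's.
2. **Two-phase** (`Mslow0, φ, λ_fast, λ_slow, γ`): recruitment enters a fast
   pool with high net loss, which transitions at rate `γ` to a slow pool.
   The fast pool is initialised in quasi-equilibrium with its source,
   `Mfast(t0) = φ S(t0)/(λ_fast + γ)` (free initialisation is available at
   the cost of a parameter); `Mslow(t0)` is free. Subset chimerisms follow
   their own relaxation equations and combine as a size-weighted average.
   Despite the naming, neither loss rate is constrained during fitting.
3. **Age-dependent loss** (`φ, p, λ0, A`, plus a fixed shape): `λ(a)`
   depends on cell age `a` (time since the clone entered memory) — sigmoid
   `λ0 / (1 + (a/A)^n)` with `n ∈ {1,2,3,5,10}` (default 3) or exponential
   `λ0 e^{−a/A}`. The transport PDE is solved along characteristics: totals
   are the surviving initial cohort (age density `g(a) = φ S(t0) e^{p a}`,
   `p` of either sign) plus the surviving post-`t0` influx; the donor
   numerator integrates influx from each mouse's own `T` weighted by the
   source chimerism. `M(t0) = φ S(t0)(e^{p t0} − 1)/p`, with the `p → 0`
   limit `φ S(t0) t0`.
4. **Resistant memory** (`M0, I0, φ, λ`): a displaceable pool with
   homogeneous kinetics plus an incumbent host-only population established
   early in life, fixed in size (`λ_I = 0`) and never replenished.

Parameter counts per facility are 3 / 5 / 4 / 4; the profiled error SDs are
not counted.

## Likelihood, model selection, bootstrap

Each mouse contributes one terminal observation pair per subset:
`x = ln(count)` and `y = arcsin √(χ_norm)`, both modelled as Gaussian with
constant variances. Normalised chimerism can overshoot 1 (the DP1
denominator is itself noisy); values outside [0, 1] are clipped before
transforming, with a warning. Profiling the two error variances
(`σ̂² = SSR/n`) collapses the joint log-likelihood to

    ln L = −(n/2) ln(SSR_x · SSR_y) − 2n ,

with an SSR floor of 1e−30 (and a σ floor of 1e−15) as pure numerical
guards. The likelihood is maximised over the model parameters with positive
parameters on the log scale and sign-free rates unconstrained: 20
multi-starts by default (the first a data-driven heuristic, the rest drawn
log-uniformly over ±2 decades around it, seeded), Nelder–Mead per start, and
an L-BFGS-B polish of the winner. Solver failures at a parameter point score
−∞ and are logged.

Facilities are fitted independently; `ln L_combined = ln L_clean + ln
L_dirty` is ranked by the corrected Akaike criterion
`AICc = −2 ln L + 2K + 2K(K+1)/(N−K−1)` with `K` twice the per-facility
parameter count and `N` twice the total number of mice (two measurements
each). Differences of 10 or more are treated as decisive.

Confidence intervals bootstrap the residuals: (x, y) residual *pairs* are
resampled jointly per observation — preserving any within-mouse correlation;
the pairing convention is this package's choice — added back onto the fitted
predictions, and the model is refitted per replicate, warm-started from the
original optimum plus three perturbed starts by default. Percentile
intervals use linear-interpolation (type 7) quantiles. Failed replicates are
dropped and counted; more than 10% triggers a warning. Derived quantities
(half-lives, % transitioning, influx at `t* = 140 d`) are recomputed per
replicate so their intervals come from the same resampling.

## Numerics

- **Reference solver**: LSODA with `rtol 1e−8`, `atol 1e−2` cells (loss
  rates span ~1e−5–1 /d; chimerism states get `atol 1e−12`). Chimerism ODEs
  are integrated directly rather than as ratios of separately integrated
  donor/total solutions, avoiding cancellation at small chimerism; the two
  constructions are verified against each other in the tests.
- **Fitting backend** (`method="grid"`): every compartment equation is a
  linear ODE `y' = −k(t) y + g(t)` with `g ≥ 0`, so on a uniform grid
  (default `h = 1 d` inside the optimiser, 0.5 d for standalone solves) the
  exact variation-of-constants sum is evaluated stably in log space with a
  cumulative log-sum-exp — no time-stepping loop. Constant-rate steps use
  local integrals exact for piecewise-linear loads (ETD1); varying-rate
  steps (chimerism relaxation) are exponentially weighted trapezoids.
  Agreement with LSODA is ~1e−6 relative on totals and ~1e−4 on chimerism —
  far below the observation noise — and is asserted in the tests.
- **Age-dependent model**: the cumulative loss `Λ(a) = ∫₀ᵃ λ` is tabulated
  by cumulative Simpson on a 0.25 d grid and interpolated with a cubic
  spline (survival accurate to ~1e−10 against adaptive quadrature); the
  outer age integrals use 64-node Gauss–Legendre panels split at the
  segment boundaries (initial cohort vs new influx vs donor influx), all
  vectorised across observations. Exponents are clipped at ±700 so that
  absurd parameter proposals score poorly instead of overflowing.
- BMT batch start ages are snapped to the solution grid (exact for
  integer-day batches); simulated cohorts use 6 evenly spaced transplant
  batches, mirroring the batch structure of real transplant cohorts and
  keeping one chimerism solve per batch.

## The synthetic-cohort generator

`simulate_cohort` emulates the statistical structure the fit assumes: per
mouse, a batch BMT age (default batches span 40–182 d clean / 56–182 d
dirty, i.e. 5–26 wk floored so the facility `t0` convention holds), one
terminal observation 4–64 weeks post BMT, log-normal count noise
(`σ_x = 0.15`) and Gaussian noise on the arcsin-√ normalised chimerism
(`σ_y = 0.05`), back-transformed and clipped to [0, 1]. The residual SDs of
the original study are not published; these defaults give scatter of the
magnitude visible in fate-mapping timecourses and are fixed once. Per-mouse
DP1 chimerism is drawn from Uniform(0.6, 0.95) to emulate variable
conditioning efficiency, and stored donor fractions are un-normalised by it,
exactly as a reader receives real data. Noise is applied on the fitting
scales, making the likelihood exactly correctly specified — deliberate, so
that coverage and consistency tests probe the estimator rather than model
misspecification.

What the generator does *not* emulate: flow-cytometry gating error and
spillover, cell loss during tissue processing, litter and cage effects,
longitudinal sampling (the design is strictly cross-sectional), or any
misspecification between the generating model and the fitted one. Passing
recovery and coverage tests therefore demonstrate correctness of the
machinery under the stated error model, not robustness to real-data
pathologies.

Generating truths: where published point estimates exist they are used
verbatim (two-phase and age-dependent-loss rates, `A`, `n = 3`, `φ`; naive
decay half-lives; baseline ages). The transition rate `γ` is backed out of
the reported "% transitioning to slow" as `γ = q λ_fast/(1−q)`. Quantities
no fit constrains — `Mslow0`, the initial-age exponent `p`, source-descriptor
shapes and scales, young-mouse curves, per-facility adult T_CM target means
(germ-free 1.2e5 < clean 3.0e5 < dirty 9.0e5 cells), and all homogeneous /
resistant-model truths (models the data rejected, so no estimates exist) —
are package-chosen plausible values of the right magnitude, fixed once. The
T_EM-dirty age-dependent truth is refused: the fitted `λ0` there is
indistinguishable from zero and `A` unconstrained.

## Ontogeny predictions

`predict_early` runs a model forward from age 5 d (where young-mouse data
begin) over a young source curve, starting from a small seed pool `M_init`
(for the age-structured model, treated as an age-0 cohort). Predictions at
11 weeks change by ≲0.1% when `M_init` doubles, so its value is immaterial.
`estimate_phi_scaling` finds the constant multiplier on `φ` over the window
[5 d, 77 d] — a sharp switch back to the adult value at the horizon; a
smooth ramp was considered and rejected for parsimony — such that the
predicted pool at the horizon matches the mean adult size in a given
environment, by bracketed root finding on a monotone map (bracket 1e−3 to
1e3). Chained predictions feed the corrected T_CM trajectory into the T_EM
model via log-scale interpolation (`TabulatedSource`); in the clean facility
the observed/sigmoid-fitted T_CM curve can be used directly. Germ-free
scenarios reuse clean-facility loss parameters, for which no germ-free
estimates exist.

## Problem sizes used by the test suite and acceptance script

Statistical checks run at scales chosen for this package's default test run:
synthetic cohorts of 150 mice per facility for recovery and selection
experiments (60 for coverage sweeps); 6 recovery replicates with 70
bootstrap refits for the two-phase model and 3 replicates with 50 refits for
the age-dependent model; 10 replicate comparisons per model-selection
experiment; 80 cohorts × 80 bootstrap refits for the coverage sweep (the
acceptance script uses a 60 × 80 version). Multi-start counts are reduced
accordingly (2–6) since the generating truths put optima in well-behaved
regions. All random draws derive from fixed or CLI-provided seeds.

## Known limitations

- Only the *net* loss rate is identified; division and death are not
  separable without labelling data, and no Ki67/BrdU compartment is modelled.
- No homeostatic (density-dependent) regulation: rates are constant in pool
  size.
- The normalised chimerism of the age-structured model is not globally
  monotone even under a monotone source chimerism — donor cohorts are
  younger, so once the source wanes the donor fraction can drift down a few
  parts per thousand per week. This is a property of the model, not a
  numerical artefact.
- Plain percentile bootstrap intervals undercover modestly for the strongly
  correlated, heavily skewed parameter pairs — (φ, λ_fast) and
  (λ_slow, γ) in the two-phase model — whose published confidence intervals
  span an order of magnitude. The recovery tests measure pooled per-parameter
  coverage of ≈88–92% rather than the nominal 95%; the effect persists under
  larger bootstrap sizes and fully polished replicate refits, so it is a
  property of the percentile method in this geometry, not of the optimiser.
  Coverage for well-identified parameters (e.g. the homogeneous net loss
  rate) is nominal (~94% measured).
- Exact reproduction of the original cohort tables requires the deposited
  raw counts; with synthetic cohorts the pipeline reproduces the *structure*
  of those results (model ranking, derived-quantity magnitudes), not their
  exact values.
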