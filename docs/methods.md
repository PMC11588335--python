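# Methods

`thermorich` implements a mean-field theory that links variation in microbial
thermal physiology to the species richness that competitive communities can
sustain, together with the Monte-Carlo machinery needed to validate it and an
empirical pipeline for estimating its inputs from thermal performance curve
(TPC) measurements.

## Model

### Thermal performance of traits

Within the operational temperature range (OTR) a metabolic trait follows the
Boltzmann–Arrhenius relation

    B(T) = B0 · exp(−E · x(T)),    x(T) = 1/kT − 1/kTref,

with `B0` the trait value at the reference temperature `Tref`, `E` (eV) the
thermal sensitivity, and `k = 8.617 × 10⁻⁵ eV/K`. The offset `x` is negative
above the reference temperature, so positive `E` means traits rise with
warming. Across a community, `(log B0, E)` is modelled as a bivariate normal
with means `(μ_B0, μ_E)`, variances `(σ²_B0, σ²_E)` and covariance `σ_B0,E`
(typically negative: the thermal specialist–generalist trade-off). The trait
is then log-normal at every temperature:

    μ_B(T)  = μ_B0 − μ_E · x
    σ²_B(T) = σ²_B0 + σ²_E · x² − 2 σ_B0,E · x.

The variance is a convex quadratic in `x` with minimum at
`x* = σ_B0,E / σ²_E`; negative covariance pushes the temperature of minimum
trait variance above `Tref`. The community-mean trait is the log-normal mean
`exp(μ_B + σ²_B/2)`; we always compute it by composing the two expressions
above rather than through a separately expanded formula, so the sign
conventions cannot drift apart. The mean becomes non-monotone (unimodal-like)
in temperature when `σ²_E > μ_E + σ_B0,E`.

### Feasibility and maximum richness

Community dynamics follow the generalized Lotka–Volterra (GLV) model with
per-species growth rates `r_i(T)`, interspecific interaction strengths
`a_ij(T)` and intraspecific strengths `a_ii(T)`, all Boltzmann–Arrhenius in
temperature. Under a mean-field closure (large N; the covariance between a
species' incoming interaction strengths and its partners' abundances is
neglected) the equilibrium abundance is

    x_i* = r_i/a_ii − (⟨r⟩/a_ii) · (N−1)⟨a⟩ / (1 + (N−1)⟨a⟩),

with effective interaction strength `⟨a⟩ = ⟨a_ij⟩⟨1/a_ii⟩`. For log-normal
traits, `⟨a⟩ = exp(μ_aij − μ_aii + (σ²_aij + σ²_aii)/2)`; with the default
convention `a_ii ≡ 1` this reduces to `exp(μ_aij + σ²_aij/2)`. Feasibility of
species *i* (`x_i* > 0`) reduces to its relative growth rate
`r_i' = r_i/⟨r⟩` — log-normal with log-mean `−σ²_r/2` and log-variance
`σ²_r`, hence mean exactly 1 — exceeding the competition bound
`b = (N−1)⟨a⟩/(1 + (N−1)⟨a⟩)`, giving

    Pfeas(N) = [1 − F(b)]^N,

with `F` the log-normal CDF of `r'`. `Pfeas` is non-increasing in `N` and in
`⟨a⟩`, so the maximum feasible richness at a threshold (default 0.5) is found
by bisection. Evaluating the trait distributions over a temperature grid
(default 0–40 °C at 0.5 °C) yields the temperature–richness curve; its peak
is the grid argmax, with ties broken toward the lower temperature and
flagged.

Note the exactness boundary of the closure: with equal off-diagonal
interactions, equal intraspecific strengths *and equal growth rates* the
mean-field equilibrium coincides with the matrix solve exactly; with
heterogeneous growth rates the neglected self-exclusion term is O(1/N) when
total competition `(N−1)a` is held fixed.

## Monte-Carlo validation

The simulator draws whole communities from the same ensembles: one
`(log B0, E)` pair per species for growth (and optionally for `a_ii`), one
per *ordered* species pair for `a_ij` (no imposed symmetry — the mean-field
derivation assumes independent interactions). A realization's TPC parameters
are drawn once and evaluated across the whole temperature grid, so every
species and pair keeps a coherent TPC along the gradient; an i.i.d.
per-temperature mode exists behind a flag for variance checks. At each
temperature the equilibrium `x* = A⁻¹ r` is solved directly; a replicate is
feasible iff every abundance is strictly positive (singular or non-finite
solves count as infeasible and are logged). `Pfeas` is the feasible fraction
of replicate communities (default 50), and the simulated maximum richness is
the largest candidate size whose feasible fraction meets the threshold.

Candidate sizes are the union of per-temperature windows around the analytic
prediction (roughly 0.55–1.6× the predicted richness, ~12 integer candidates
per temperature, always including 2), giving ≈8% size resolution near the
prediction without sweeping every integer. The theory–simulation agreement
check uses a 0–40 °C grid at 2 °C steps with 50 replicates and asserts a
median relative deviation ≤ 20% — the deliberately scaled-down grid keeps
the Monte-Carlo cost modest while sampling the whole gradient.

## Sensitivity analysis

To map where the mean-field approximation degrades, communities are drawn
with all fifteen ensemble parameters (five per trait group: r, a_ij, a_ii;
the intraspecific trait uses its full ensemble here, not the constant-1
convention) sampled uniformly from configurable ranges. Defaults — a package
choice spanning the presets and baseline values, since no canonical ranges
exist: `μ_B0` in [−0.5, 0.5] (r), [−7, −3] (a_ij), [−1, 1] (a_ii); `μ_E` in
[0, 1.5]; `σ²_B0` in [0, 1]; `σ²_E` in [0, 0.3]; `σ_B0,E` in [−0.5, 0]
(draws violating `σ²_B0,E ≤ σ²_B0 σ²_E` are resampled and counted). Per set,
the analytic and simulated curves are compared by a normalized RMSE
(RMSE divided by mean simulated richness, removing system-size bias), and
each parameter's Pearson correlation with the nRMSE summarizes its effect.

Both the analytic and simulated sides are capped at a richness of 150 in
this mode: nearly non-interacting parameter draws otherwise produce
communities too large to simulate, and an identical cap on both sides keeps
the error measure meaningful. The scan grid is 0–40 °C at 5 °C steps with
25 replicates; the packaged scale is 200 parameter sets (the procedure is
embarrassingly parallel and extends to 10⁴ sets unchanged).

Scanning the 15-dimensional default ranges, the error correlates positively
with interaction-trait variance (`σ²_B0` of a_ij and a_ii) and with mean
interspecific strength, and negatively with mean intraspecific strength. The
marginal correlation for growth-rate `σ²_B0` is range-dependent: a
controlled slice that varies only that parameter shows the expected positive
dependence, but over the full default ranges its marginal correlation is
near zero to slightly negative, because strong-competition draws confine
richness to very small values where the growth-variance channel has little
leverage. The tests record this honestly rather than selecting ranges that
force a sign.

## TPC fitting pipeline

Strain-level measurements are fit to the high-temperature-deactivation
Sharpe–Schoolfield form

    B(T) = exp(log B0 − E·x) / (1 + exp((E_h/k)(1/T_h − 1/T))),

whose numerator is the rising Arrhenius limb and whose denominator halves
the trait exactly at `T_h` (deactivation energy `E_h > E` controls how
sharply performance collapses). Fitting is nonlinear least squares on the
log scale with box bounds (`E ∈ [10⁻³, 10] eV`, `E_h ∈ [10⁻³, 40] eV`,
`T_h ∈ [250, 420] K`) and a deterministic multi-start grid (rising-limb
slope and observed-maximum heuristics, perturbed over sensitivity and
deactivation scales), so identical data always give identical fits.
Per-parameter p-values come from large-sample normal theory on the
least-squares covariance. Quality control keeps fits that converged, have
all parameters significant at α = 0.05, and whose mean-normalised
`log B0` exceeds −15 (an extreme-low-outlier guard). Accepted `B0` values
are normalised by their across-strain mean (natural-scale mean exactly 1)
and the community `(log B0, E)` bivariate normal is estimated by maximum
likelihood (sample means; covariance with divisor n).

The synthetic generator draws strains from a known ensemble, adds uniform
deactivation parameters (`E_h ∈ [2, 5] eV`, `T_h ∈ [32, 44] °C`), evaluates
the curve on a 4–49 °C grid at 3 °C steps (16 points spanning rise and
fall), and multiplies by mean-one log-normal noise with coefficient of
variation 0.05 by default — magnitudes representative of laboratory growth
assays. Because ensemble sensitivity is normal, a small tail of strains has
negative `E`; these produce non-rising curves that the significance filter
discards, mildly truncating the recovered sensitivity distribution (bias
below one standard error at 200 strains). What the generator does *not*
emulate: temperature-dependent error structure, missing observations,
low-temperature deactivation, and strain-correlated measurement campaigns —
so round-trip recovery demonstrates the pipeline's correctness, not the
field-realism of any particular dataset.

## Presets and numerical conventions

Three shipped parameterisations apply one ensemble to both growth and
interspecific interactions (normalisations `μ_r0 = 0`, `μ_a0 = −5`;
`a_ii ≡ 1`; `Tref = 13 °C`):

| preset | μ_E | σ²_B0 | σ²_E | σ_B0,E |
|---|---|---|---|---|
| `experimental` | 1.0 | 0.95 | 0.25 | −0.42 |
| `synthesis` | 0.82 | 1.0 | 0.11 | −0.1 |
| `fig2_baseline` | 0.6 | 0.2 | 0.01 | 0.0 |

Temperatures are Celsius at every file and CLI boundary and Kelvin
internally. All randomness flows through `numpy.random.Generator` objects;
the CLI expands one global seed into independent per-stage streams. Richness
scans warn explicitly when they return a capped value. Degenerate inputs
(zero variances, singular matrices, empty filters) are handled as documented
on each function rather than silently.

## Known limitations

- The feasibility theory addresses fixed points only; stability, reactivity
  and dynamical assembly are out of scope, as are consumer–resource
  formulations and spatial structure.
- Under the `experimental`/`synthesis` presets the analytic richness curve
  is nearly flat across several degrees around its maximum, so the reported
  peak temperature inherits the tie-breaking convention (lower temperature)
  and should be read together with the plateau width. For the `synthesis`
  preset the integer-richness plateau spans 3.5–7 °C.
- Simulated richness resolution is set by the candidate-size spacing (~8%
  near the prediction); deviations smaller than that are not measurable.
- The sensitivity scan's conclusions are conditional on the sampled
  parameter ranges (see above).
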