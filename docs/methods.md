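# Methods

## The problem

Chronic diabetic foot ulcers (DFUs) are often treated with advanced placental
membrane allografts when standard care fails. A retrospective comparison of
two such products — a retention-processed amnion-chorion membrane (arm 1)
versus a lamination-processed one (arm 0) — asks two questions at a ~12-week
endpoint: how likely is the wound to have closed completely, and by how much
has its area shrunk on average?

The endpoint wound area is semicontinuous: a point mass at exactly zero
(closed) plus a right-skewed positive part (still-open area in cm²). This
package models it with a Bayesian hurdle-Gamma ANCOVA and derives the two
clinical quantities as marginal effects: the probability of full closure
(Ψ) and the expected percent area reduction (xPAR).

## The model

For subject *i* with arm indicator *gᵢ* ∈ {0, 1}, baseline area *preᵢ* > 0
standardized to *zᵢ* (sample mean/SD), and endpoint area *yᵢ* ≥ 0:

* Hurdle: I(yᵢ > 0) ~ Bernoulli(πᵢ), logit(πᵢ) = α₁ + β₁·gᵢ + γ·zᵢ,
  where π is the probability the wound is still **open** (Ψ is derived as
  1 − marginal π).
* Area, given open: yᵢ ~ Gamma(shape = k, rate = k/μᵢ),
  log(μᵢ) = θ + δ·gᵢ + ε·zᵢ, so E[yᵢ | open] = μᵢ.

Seven parameters: (α₁, β₁, γ, θ, δ, ε, k). Baseline adjustment (γ, ε) is the
ANCOVA part; it controls for starting-area differences between arms and, when
the baseline predicts the outcome, tightens the posterior of the treatment
effect δ — a property the suite checks directly by comparing against the
same model with γ = ε pinned at zero.

The baseline covariate enters standardized. This is an invertible
reparameterization — marginal effects are unchanged — chosen so that one
prior scale suits all slopes and the sampler sees well-scaled coordinates.

### Priors

"Weakly informative, scaled to the data" is implemented as:

| parameter | prior | rationale |
|---|---|---|
| α₁, β₁, γ | Normal(0, 2.5) | logit scale; prior predictive closure probability spans (0.05, 0.95) |
| θ | Normal(mean log y⁺, max(2.5, 2.5·SD log y⁺)) | anchored to the spread of positive endpoint areas |
| δ, ε | Normal(0, 2.5) | log scale, standardized covariate |
| k | half-Normal(10) | permits very skewed (k < 1) through near-lognormal shapes |

Priors are symmetric in the arm labels. All are overridable via `PriorSpec`.

### Sampling

The joint posterior (with k sampled as log k plus the Jacobian) is explored
by a slice-within-Gibbs sampler: univariate slice updates (stepping-out and
shrinkage) applied along the columns of a preconditioning matrix L with
L·Lᵀ ≈ posterior covariance. L is obtained from a Laplace approximation — a
BFGS mode search followed by a central finite-difference Hessian — and
refreshed once mid-warmup from the chain's own history. Slice sampling needs
no step-size tuning and always accepts, which makes runs reproducible and
robust across the cohort sizes used here; because it has no Hamiltonian
trajectory there is no divergent-transition failure mode, and the divergence
count reported alongside R-hat and ESS is structurally zero (the field is
kept because the report contract requires it and other kernels could
populate it). The `target_accept` configuration field applies only to
acceptance-based kernels and is ignored by this one.

Defaults mirror the analysis conventions: 4 chains × 1000 retained draws
(4000 total) after 1000 discarded warmup sweeps per chain. Chains are
seeded independently from (seed, chain index); identical seeds give
bit-identical draws. On the n = 500/arm recovery runs this yields
min bulk ESS ≳ 3000 of 4000 and max split-R̂ ≈ 1.002.

An independent affine-invariant ensemble sampler (emcee) run on the same
log-posterior serves as a cross-check in the test suite; it is never the
fitting path.

## Marginal effects (g-computation)

The reported clinical quantities are standardized over the **pooled** empirical
baseline distribution: for each posterior draw, every subject's baseline is
pushed through both counterfactual arm assignments,

* Ψ(a) = meanᵢ[1 − expit(α₁ + β₁·a + γ·zᵢ)],
* xPAR(a) = 100 · meanᵢ[(1 − πᵢ(a)) + πᵢ(a)·(1 − μᵢ(a)/preᵢ)],

and summaries are the posterior mean with an equal-tailed 95% credible
interval (not HPD) over draws. The xPAR expression is exact per draw because
E[(pre − Y)/pre | open] = 1 − μ/pre under the mean parameterization; a
simulation-based version (`simulated_xpar`) exists purely to cross-check it.
Arm contrasts are per-draw differences (arm 1 minus arm 0). xPAR may be
negative for a draw (a wound can grow); it is never truncated, while
Ψ ∈ [0, 1] and xPAR ≤ 100 hold by construction.

## Auxiliary ANOVAs

Starting area (Gamma likelihood), product applications and treatment days
(Negative-Binomial likelihood, variance μ + μ²/φ) are fit as one-way
Bayesian ANOVAs: arm-indexed means through a log link with a shared
dispersion by default (a per-arm option exists). The "dispersion" row in
reports is the posterior summary of the model's dispersion parameter — it is
not a raw-scale sample variance, and is labeled accordingly.

## The synthetic cohort generator

Real EHR cohorts of this kind are not publicly deposited, so every stage is
verified against synthetic cohorts drawn from the generative form of the
model itself:

* baseline areas: Gamma(mean 15.5 cm², shape 2) — right-skewed, matching
  reported per-arm means of ≈14–17 cm² — left-truncated at 0.5 cm², the
  smallest wound plausibly enrolled for advanced grafts. The truncation also
  keeps E[1/pre] (which xPAR involves) well-behaved: without it the
  Monte-Carlo xPAR estimator has unbounded variance at small shape values;
* closure and open-wound area from the hurdle-Gamma model above, with
  baseline slopes γ = 0.8 and ε = 0.5 (larger wounds close less often and
  stay larger) and k = 1.5;
* applications and treatment days: independent shifted Negative Binomials
  (support starting at 1) with arm means (7.9, 10.6) applications and
  (68.2, 77.3) days, dispersions 20 and 12. They are simulated independently
  of the area process, matching the separate-ANOVA analysis structure.

The generator's linear predictors standardize the baseline by its
*population* Gamma mean/SD; the fitter standardizes by the *sample* mean/SD.
The two coincide asymptotically, and recovery tests compare on the common
(population) scale.

### Calibration

`calibrate_to_targets` solves for (α₁, β₁, θ, δ) so the population closure
probability and xPAR per arm equal prescribed targets; the defaults are the
reference clinical estimates (Ψ = 0.740/0.738, xPAR = 52.6%/67.3% for
arms 0/1). Population functionals are evaluated by deterministic
stratified-quantile quadrature (2048 nodes) over the truncated baseline
Gamma; each of the four parameters is then a 1-d monotone root-finding
problem solved by bracketing + Brent's method to ~1e-12. Infeasible targets
(closure probability at 0 or 1, xPAR > 100%) raise a calibration error
naming the offending target.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real cohorts: informative treatment selection
(confounding beyond the baseline area), wound-measurement error and
digitization rounding, interim visits and time-to-closure structure, missing
or manually-resolved records, and any coupling between application counts
and healing. Recovery here demonstrates the estimator is correct under its
own assumptions, not that those assumptions hold in EHR data.

## Convergence diagnostics

Rank-normalized split-R̂ and bulk ESS (the current standard estimators, via
arviz) summarized per parameter; a fit passes at max R̂ ≤ 1.05,
min ESS ≥ 400, zero divergences (configurable). Degenerate all-constant
chains report R̂ = 1 and ESS = total draws rather than NaN; ESS estimates
above 1.25× the total draw count (estimator noise on antithetic chains) are
clipped with a warning.

## Problem sizes and numerical choices

* Recovery studies use n = 500/arm (effects) and n = 300/arm (count
  ANOVAs) with the default 4 × 1000 draw budget — large enough that
  posterior means sit well inside the recovery tolerances (±5 xPAR points,
  ±0.05 closure probability, ±0.5 applications), small enough that a full
  run takes about a minute on one core. The precision-gain property is
  checked at n = 200/arm over 10 seeds with a reduced draw budget.
* Root-finding tolerance 1e-12 (xtol) for calibration; quadrature depth
  2048 nodes (population functionals accurate to ≪ 0.01 in xPAR).
* `log k` is clamped to |log k| ≤ 50 (posterior log-density −∞ outside) to
  avoid overflow in the Gamma terms.
* Closure is an exact zero of the endpoint area; no "almost closed"
  threshold exists anywhere in the pipeline.
* Cohort CSVs refuse missing endpoint areas rather than imputing them, and
  all validation errors cite the offending row and column.

## Known limitations

* The two-part model shares no parameters between hurdle and area
  components; a joint shrinkage structure might help at n = 41 but is not
  part of the analysis being reproduced.
* Only the treatment arm and baseline area are modeled; demographics are
  carried through as passthrough columns.
* The Laplace preconditioner assumes a unimodal, roughly elliptical
  posterior. That holds for these likelihoods at the sample sizes used; a
  strongly multimodal posterior would mix slowly and be flagged by R̂/ESS.
* Endpoint definition (exact 12-week visit vs. window) is left to the data
  provider; the schema carries a single endpoint per subject.
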