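# woundhurdle

Bayesian analysis of two-arm wound-healing cohorts whose endpoint is
semicontinuous: a wound area at ~12 weeks that is either exactly zero
(healed) or a right-skewed positive number of cm². The package implements
the hurdle-Gamma ANCOVA used to compare placental-membrane treatments for
chronic diabetic foot ulcers — arm 1 retention-processed, arm 0
lamination-processed — together with the marginal effects clinicians
actually report, auxiliary count/area ANOVAs, a calibrated synthetic-cohort
generator, and MCMC diagnostics. It is aimed at biostatisticians who need a
reproducible, testable version of this analysis rather than a one-off
notebook.

## Model

For subject *i* with arm *gᵢ*, standardized baseline area *zᵢ* and endpoint
area *yᵢ* ≥ 0:

```
I(yᵢ > 0) ~ Bernoulli(πᵢ)          logit(πᵢ) = α₁ + β₁ gᵢ + γ zᵢ
yᵢ | yᵢ>0 ~ Gamma(k, k/μᵢ)         log(μᵢ)   = θ + δ gᵢ + ε zᵢ
```

with weakly informative priors and 4 chains × 1000 retained draws of a
preconditioned slice sampler. Posterior draws are turned into marginal
effects by g-computation over the pooled empirical baselines:

* **Ψ** — probability of full closure, `Ψ(a) = meanᵢ[1 − expit(α₁ + β₁a + γzᵢ)]`;
* **xPAR** — expected percent area reduction,
  `xPAR(a) = 100·meanᵢ[(1−πᵢ) + πᵢ(1 − μᵢ/preᵢ)]` (closed wounds count as
  100%);
* arm contrasts of both, each with an equal-tailed 95% credible interval.

Starting area, product applications and treatment days are summarized by
separate Bayesian ANOVAs (Gamma and Negative-Binomial likelihoods). See
`docs/methods.md` for priors, the sampler, calibration, and limitations.

## Worked example

```sh
$ woundhurdle simulate --n-arm1 23 --n-arm0 18 --seed 7 -o cohort.csv
simulate: seed=7, wrote 41 subjects to cohort.csv

$ woundhurdle fit cohort.csv --chains 4 --draws 1000 --warmup 1000 --seed 3 -o draws.csv
fit: seed=3, 4000 draws, max R-hat 1.005, min ESS 2186, divergences 0

$ woundhurdle report --cohort cohort.csv --draws draws.csv --seed 3 -o report.txt
$ cat report.txt
Wound and treatment summary (posterior mean, 95% credible interval)
arm coding: 1 = retention-processed, 0 = lamination-processed
subjects: arm 1 n=23, arm 0 n=18
Starting area (cm^2) (Gamma likelihood)
  arm 1 mean: 18.3 (13.4–25.2)
  arm 0 mean: 11.2 (7.7–15.8)
  dispersion parameter: 1.7 (1.1–2.5)
Product applications (Negative Binomial likelihood)
  arm 1 mean: 8.8 (7.4–10.3)
  arm 0 mean: 10.8 (9.0–12.8)
  dispersion parameter: 28.4 (7.7–82.2)
Treatment days (Negative Binomial likelihood)
  arm 1 mean: 68.3 (59.8–77.9)
  arm 0 mean: 84.2 (72.7–96.8)
  dispersion parameter: 12.4 (7.1–19.6)
Hurdle-Gamma ANCOVA marginal effects
  arm 1 probability of full closure (Psi): 0.777 (0.614–0.898)
  arm 0 probability of full closure (Psi): 0.714 (0.517–0.875)
  arm 1 xPAR: 63.2% (-13.3%–89.7%)
  arm 0 xPAR: 16.9% (-144.1%–80.9%)
  Psi contrast (arm 1 - arm 0): 0.063 (-0.166–0.302)
  xPAR contrast (arm 1 - arm 0): 46.2% (-54.5%–209.5%)
Diagnostics: max split-R-hat 1.005, min bulk ESS 2186, divergences 0 -> PASS
provenance: seed=3, chains=4, draws/chain=1000, warmup=1000, version=0.1.0
```

Reading this: in a simulated 41-subject cohort, both arms close about
three-quarters of wounds, arm 1 shows a larger expected area reduction, and
the wide credible intervals (xPAR can be negative — wounds can grow) are
exactly what a cohort this small buys you. The count ANOVAs show arm 1
needing about two fewer product applications. The diagnostics line confirms
the chains mixed (R-hat ≈ 1, no divergences).

The same pipeline is available as a library:

```python
from woundhurdle import effects
from woundhurdle.hurdle_ancova import FitConfig, build_design, default_priors, fit
from woundhurdle.synthetic_cohort import (DEFAULT_TARGETS, calibrate_to_targets,
                                          default_params, generate_cohort)

params = calibrate_to_targets(DEFAULT_TARGETS, default_params())
cohort = generate_cohort(params, n_per_arm=(500, 500), seed=1)
design = build_design(cohort)
draws = fit(design, default_priors(design), FitConfig(seed=1))
print(effects.expected_par(draws, design, arm=1))
# EffectSummary(quantity='xpar', arm=1, mean=68.92..., lower=62.32..., upper=74.80..., n_draws=4000)
```

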