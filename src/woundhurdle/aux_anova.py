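"""Auxiliary Bayesian one-way ANOVAs for cohort summary measures.

Three companion fits summarize the treatment process alongside the endpoint
model: starting area (Gamma likelihood), product applications and treatment
days (Negative-Binomial likelihood). Each model has arm-indexed means
through a log link and, by default, a shared dispersion/shape parameter:

* Gamma:        ``y_i ~ Gamma(shape=k, rate=k / mu_{arm_i})``
* NegBinomial:  ``y_i ~ NB(mean=mu_{arm_i}, dispersion=phi)``,
  ``Var = mu + mu**2/phi``

with diffuse Normal priors on the log-means (anchored at the pooled log
mean) and a half-normal prior on the natural dispersion, matching the
conventions of the endpoint ANCOVA. ``shared_dispersion=False`` switches to
arm-specific dispersions. Note the dispersion summary is a model parameter,
not a raw-scale sample variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from ._sampling import laplace_precondition, sample_posterior
from .hurdle_ancova import FitConfig

__all__ = ["ArmSummary", "AnovaResult", "fit_gamma_anova", "fit_negbin_anova"]

_PRIOR_SCALE = 2.5
_DISP_PRIOR_SCALE = 50.0


@dataclass(frozen=True)
class ArmSummary:
    """Posterior mean with a central 95% credible interval."""

    mean: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.mean <= self.upper:
            raise ValueError("interval must bracket the point estimate")


@dataclass(frozen=True)
class AnovaResult:
    """Per-arm posterior mean summaries plus dispersion-parameter summaries."""

    likelihood: str  # "gamma" | "negative binomial"
    by_arm: dict[int, ArmSummary]
    dispersion: ArmSummary
    n_draws: int
    dispersion_by_arm: dict[int, ArmSummary] | None = None

    def __post_init__(self) -> None:
        for arm, s in self.by_arm.items():
            if not s.mean > 0:
                raise ValueError(f"posterior mean for arm {arm} must be positive")


def _validate(values: np.ndarray, arms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    arms = np.asarray(arms)
    if values.shape != arms.shape:
        raise ValueError("values and arms must align")
    if not set(np.unique(arms)) == {0, 1}:
        raise ValueError("both arms (0 and 1) must be present")
    return values, arms.astype(int)


def _summary(x: np.ndarray) -> ArmSummary:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return ArmSummary(float(np.mean(x)), float(lo), float(hi))


def _run_and_summarize(log_post, x0, config: FitConfig, likelihood: str, shared: bool):
    mode, L = laplace_precondition(log_post, x0)
    draws = sample_posterior(
        log_post,
        mode,
        n_chains=config.n_chains,
        n_draws=config.n_draws_per_chain,
        n_warmup=config.n_warmup,
        seed=config.seed,
        thin=config.thin,
        preconditioner=L,
    )
    flat = draws.reshape(-1, draws.shape[-1])
    by_arm = {a: _summary(np.exp(flat[:, a])) for a in (0, 1)}
    if shared:
        return AnovaResult(likelihood, by_arm, _summary(np.exp(flat[:, 2])), flat.shape[0])
    disp_by_arm = {a: _summary(np.exp(flat[:, 2 + a])) for a in (0, 1)}
    pooled = _summary(np.exp(flat[:, 2:4]).reshape(-1))
    return AnovaResult(likelihood, by_arm, pooled, flat.shape[0], dispersion_by_arm=disp_by_arm)


def _log_prior(log_means: np.ndarray, log_disps: np.ndarray, anchor: float) -> float:
    lp = float(np.sum(-0.5 * ((log_means - anchor) / _PRIOR_SCALE) ** 2))
    disp = np.exp(log_disps)
    # half-normal on the natural dispersion, with the exp-transform Jacobian
    lp += float(np.sum(-0.5 * (disp / _DISP_PRIOR_SCALE) ** 2 + log_disps))
    return lp


def fit_gamma_anova(
    values, arms, config: FitConfig | None = None, shared_dispersion: bool = True
) -> AnovaResult:
    """Gamma ANOVA: arm-specific means via a log link, shared shape by default."""
    values, arms = _validate(np.asarray(values), np.asarray(arms))
    if np.any(values <= 0):
        bad = int(np.flatnonzero(values <= 0)[0])
        raise ValueError(f"Gamma ANOVA requires positive values; record {bad} is {values[bad]}")
    config = config if config is not None else FitConfig()
    anchor = float(np.mean(np.log(values)))
    sum_log = np.array([np.sum(np.log(values[arms == a])) for a in (0, 1)])
    sum_y = np.array([np.sum(values[arms == a]) for a in (0, 1)])
    n_by = np.array([np.sum(arms == a) for a in (0, 1)])
    n_disp = 1 if shared_dispersion else 2

    def log_post(theta):
        lm = theta[:2]
        lk = theta[2:]
        if np.any(np.abs(lk) > 30) or np.any(np.abs(lm) > 50):
            return -np.inf
        k = np.exp(lk) if not shared_dispersion else np.full(2, np.exp(lk[0]))
        rate = k * np.exp(-lm)
        ll = float(np.sum(n_by * (k * np.log(rate) - gammaln(k)) + (k - 1.0) * sum_log - rate * sum_y))
        return ll + _log_prior(lm, lk, anchor)

    x0 = np.concatenate([[anchor, anchor], np.zeros(n_disp)])
    return _run_and_summarize(log_post, x0, config, "gamma", shared_dispersion)


def fit_negbin_anova(
    counts, arms, config: FitConfig | None = None, shared_dispersion: bool = True
) -> AnovaResult:
    """Negative-Binomial ANOVA: arm-specific means via a log link."""
    counts = np.asarray(counts)
    if np.any(counts != np.floor(counts)) or np.any(counts < 0):
        raise ValueError("Negative-Binomial ANOVA requires non-negative integer counts")
    values, arms = _validate(counts.astype(float), np.asarray(arms))
    config = config if config is not None else FitConfig()
    anchor = float(np.mean(np.log1p(values)))
    y_by = [values[arms == a] for a in (0, 1)]
    n_disp = 1 if shared_dispersion else 2

    def log_post(theta):
        lm = theta[:2]
        ld = theta[2:]
        if np.any(np.abs(ld) > 30) or np.any(np.abs(lm) > 50):
            return -np.inf
        ll = 0.0
        for a in (0, 1):
            y = y_by[a]
            mu = np.exp(lm[a])
            lphi = ld[0] if shared_dispersion else ld[a]
            phi = np.exp(lphi)
            ll += float(
                np.sum(
                    gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)
                    + phi * (lphi - np.log(phi + mu))
                    + y * (lm[a] - np.log(phi + mu))
                )
            )
        return ll + _log_prior(lm, ld, anchor)

    x0 = np.concatenate([[anchor, anchor], np.ones(n_disp)])
    return _run_and_summarize(log_post, x0, config, "negative binomial", shared_dispersion)
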