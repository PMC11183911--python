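"""Closed-form log-densities and parameterization conversions.

Everything here is a pure function shared by the simulator, the
Hurdle-Gamma ANCOVA and the auxiliary ANOVAs:

* Gamma in mean/shape form (shape ``k``, rate ``k / mu``, so ``E[Y] = mu``),
* the hurdle-Gamma mixture (point mass at zero + Gamma on the positive axis),
* Negative Binomial in mean/dispersion form with ``Var[Y] = mu + mu**2 / phi``
  (Poisson in the ``phi -> inf`` limit),
* the logistic link.

All functions are vectorized over their data argument and raise
``ValueError`` for out-of-domain inputs rather than returning NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "HurdleGammaParams",
    "inv_logit",
    "gamma_logpdf_mean_shape",
    "hurdle_gamma_logpdf",
    "negbin_logpmf_mean_disp",
    "mean_shape_to_shape_rate",
]


@dataclass(frozen=True)
class HurdleGammaParams:
    """Parameters of a single hurdle-Gamma observation.

    Attributes
    ----------
    pi_open
        Probability the outcome is positive (the wound is still open).
    mu
        Conditional Gamma mean of the positive outcome.
    k
        Gamma shape; ``rate = k / mu``.
    """

    pi_open: float
    mu: float
    k: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_open <= 1.0:
            raise ValueError(f"pi_open must lie in [0, 1], got {self.pi_open}")
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")


def inv_logit(x):
    """Logistic function 1 / (1 + exp(-x)), stable for large ``|x|``."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("inv_logit requires finite input")
    out = special.expit(x)
    return float(out) if out.ndim == 0 else out


def mean_shape_to_shape_rate(mu: float, k: float) -> tuple[float, float]:
    """Convert (mean, shape) Gamma parameters to (shape, rate) = (k, k/mu)."""
    if not (mu > 0 and k > 0):
        raise ValueError(f"mu and k must be positive, got mu={mu}, k={k}")
    return float(k), float(k / mu)


def gamma_logpdf_mean_shape(y, mu, k):
    """Log-density of Gamma(shape=k, rate=k/mu) at ``y``; E[Y] = mu."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma_logpdf_mean_shape requires y > 0")
    if np.any(mu <= 0) or np.any(np.asarray(k) <= 0):
        raise ValueError("gamma_logpdf_mean_shape requires mu > 0 and k > 0")
    rate = k / mu
    out = k * np.log(rate) - special.gammaln(k) + (k - 1.0) * np.log(y) - rate * y
    return float(out) if np.ndim(out) == 0 else out


def hurdle_gamma_logpdf(y, p: HurdleGammaParams):
    """Hurdle-Gamma log-density: point mass ``1 - pi_open`` at 0, Gamma above.

    ``y == 0`` contributes ``log(1 - pi_open)``; ``y > 0`` contributes
    ``log(pi_open) + gamma_logpdf_mean_shape(y, mu, k)``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("hurdle_gamma_logpdf requires y >= 0")
    with np.errstate(divide="ignore"):
        log_closed = np.log1p(-p.pi_open)
        log_open = np.log(p.pi_open)
    out = np.where(
        y == 0.0,
        log_closed,
        log_open
        + gamma_logpdf_mean_shape(np.where(y > 0, y, 1.0), p.mu, p.k),
    )
    return float(out) if out.ndim == 0 else out


def negbin_logpmf_mean_disp(y, mu, phi):
    """Negative-Binomial log-mass with mean ``mu`` and variance ``mu + mu**2/phi``.

    This is the Gamma-Poisson mixture: ``Y | lam ~ Poisson(lam)`` with
    ``lam ~ Gamma(shape=phi, rate=phi/mu)``.
    """
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer) and np.any(y != np.floor(y)):
        raise ValueError("negbin_logpmf_mean_disp requires non-negative integer y")
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(np.asarray(phi) <= 0):
        raise ValueError("negbin_logpmf_mean_disp requires mu > 0 and phi > 0")
    # scipy's nbinom counts failures before the phi-th success, p = phi/(phi+mu)
    out = stats.nbinom.logpmf(np.asarray(y, dtype=float), phi, phi / (phi + mu))
    return float(out) if np.ndim(out) == 0 else out
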