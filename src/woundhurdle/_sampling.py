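"""Posterior sampling engine shared by the ANCOVA and ANOVA fitters.

The kernel is slice-within-Gibbs (stepping-out and shrinkage) applied along
the columns of a preconditioning matrix L, where L L' approximates the
posterior covariance from a Laplace (BFGS) fit at the mode. Sampling in this
whitened frame makes the per-coordinate conditionals well scaled, so the
chain mixes quickly without step-size tuning and has no notion of a
divergent transition. Warmup draws are discarded; chains are independent
given (seed, chain index).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

__all__ = ["laplace_precondition", "sample_posterior"]

_MAX_STEPOUT = 64
_MAX_SHRINK = 128


def _chol_of_cov(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor of a covariance, eigenvalue-clipped to positive definite."""
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    floor = max(vals.max(), 1e-4) * 1e-8
    vals = np.clip(vals, floor, None)
    return np.linalg.cholesky((vecs * vals) @ vecs.T + floor * np.eye(cov.shape[0]))


def laplace_precondition(log_post, x0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and preconditioner from a Laplace approximation.

    The mode comes from a BFGS fit; the covariance from a central
    finite-difference Hessian of ``-log_post`` at the mode (BFGS's own
    inverse-Hessian estimate is too rough to precondition with). Returns
    ``(mode, L)`` with ``L @ L.T`` approximating the posterior covariance;
    falls back to an identity-scaled preconditioner when the curvature is
    unusable.
    """
    x0 = np.asarray(x0, dtype=float)
    res = optimize.minimize(lambda x: -log_post(x), x0, method="BFGS")
    mode = np.asarray(res.x, dtype=float)
    d = mode.size
    h = 1e-4 * np.maximum(np.abs(mode), 1.0)
    hess = np.empty((d, d))
    f0 = -log_post(mode)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        hess[i, i] = (-log_post(mode + ei) - 2 * f0 + -log_post(mode - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(d)
            ej[j] = h[j]
            fpp = -log_post(mode + ei + ej)
            fpm = -log_post(mode + ei - ej)
            fmp = -log_post(mode - ei + ej)
            fmm = -log_post(mode - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        if not np.all(np.isfinite(hess)):
            raise np.linalg.LinAlgError
        L = _chol_of_cov(np.linalg.inv(hess))
    except np.linalg.LinAlgError:
        L = 0.1 * np.eye(d)
    return mode, L


def _slice_update_1d(log_post, x, direction, logp_x, rng):
    """One slice-sampling update of x along `direction` (Neal 2003)."""
    log_height = logp_x + np.log(rng.random())
    w = 1.0  # unit width is natural in the whitened frame
    lo = -w * rng.random()
    hi = lo + w
    for _ in range(_MAX_STEPOUT):
        if log_post(x + lo * direction) <= log_height:
            break
        lo -= w
    for _ in range(_MAX_STEPOUT):
        if log_post(x + hi * direction) <= log_height:
            break
        hi += w
    for _ in range(_MAX_SHRINK):
        t = lo + (hi - lo) * rng.random()
        proposal = x + t * direction
        logp = log_post(proposal)
        if logp > log_height:
            return proposal, logp
        if t < 0:
            lo = t
        else:
            hi = t
    return x, logp_x  # degenerate slice; keep the current point


def sample_posterior(
    log_post,
    x0: np.ndarray,
    n_chains: int,
    n_draws: int,
    n_warmup: int,
    seed: int,
    thin: int = 1,
    preconditioner: np.ndarray | None = None,
) -> np.ndarray:
    """Draw ``(n_chains, n_draws, d)`` retained samples of ``log_post``.

    Each chain starts from a jittered copy of ``x0`` and is advanced with
    slice-within-Gibbs sweeps along the preconditioner columns. Halfway
    through warmup the preconditioner is refreshed from the chain's own
    warmup history (the Laplace curvature only has to be good enough to get
    there); ``n_warmup`` sweeps are discarded and one retained draw is kept
    every ``thin`` sweeps thereafter.
    """
    x0 = np.asarray(x0, dtype=float)
    d = x0.size
    L0 = preconditioner if preconditioner is not None else np.eye(d)
    refresh_at = max(n_warmup // 2, 8)
    draws = np.empty((n_chains, n_draws, d))
    for chain in range(n_chains):
        rng = np.random.default_rng([abs(int(seed)) % (2**31), chain])
        L = L0
        x = x0 + L @ rng.normal(scale=0.5, size=d)
        logp = log_post(x)
        if not np.isfinite(logp):
            x = x0.copy()
            logp = log_post(x)
        order = np.arange(d)
        history = np.empty((refresh_at, d))
        it = 0
        kept = 0
        while kept < n_draws:
            rng.shuffle(order)
            for j in order:
                x, logp = _slice_update_1d(log_post, x, L[:, j], logp, rng)
            if it < refresh_at:
                history[it] = x
            it += 1
            if it == refresh_at and it < n_warmup and refresh_at >= max(2 * d, 8):
                tail = history[refresh_at // 4:]
                cov = np.cov(tail, rowvar=False)
                if np.all(np.isfinite(cov)) and np.linalg.matrix_rank(cov) == d:
                    L = _chol_of_cov(cov)
            if it > n_warmup and (it - n_warmup) % thin == 0:
                draws[chain, kept] = x
                kept += 1
    return draws
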