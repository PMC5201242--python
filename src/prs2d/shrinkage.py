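"""Winner's curse corrections for threshold-selected marginal GWAS effects.

Selecting SNPs at a two-sided P-value threshold alpha is the same event as
|beta_hat| exceeding lambda(alpha) = Phi^{-1}(1 - alpha/2) * se.  Conditioning
on that event biases beta_hat away from zero; two corrections are provided:

* lasso: the soft-threshold solution sign(b)(|b| - lambda) I(|b| > lambda),
  i.e. the single-coordinate minimizer of 0.5 (b - beta)^2 + lambda |beta|
  (the lasso under an orthonormal design);
* mle: the maximizer over beta of the likelihood of beta_hat ~ N(beta, se^2)
  conditional on |beta_hat| > lambda (Zhong-Prentice-type conditional MLE).

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = [
    "threshold_lambda",
    "lasso_correct",
    "conditional_loglik",
    "mle_correct",
    "correct_effects",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _check_alpha(alpha) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha <= 0) | (alpha > 1)):
        raise ValueError("alpha must lie in (0, 1]")
    return alpha


def threshold_lambda(alpha, se):
    """Absolute-effect threshold lambda(alpha) = Phi^{-1}(1 - alpha/2) * se.

    Nonnegative and strictly decreasing in alpha; lambda(1) = 0.
    """
    alpha = _check_alpha(alpha)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    # ndtri on 1 - alpha/2 loses precision for tiny alpha; isf form is exact there
    out = np.maximum(stats.norm.isf(alpha / 2.0), 0.0) * se
    return out if out.ndim else float(out)


def lasso_correct(beta_hat, se, alpha):
    """Soft-threshold correction sign(b)(|b| - lambda(alpha)) I(|b| > lambda)."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    lam = threshold_lambda(alpha, se)
    shrunk = np.sign(beta_hat) * np.maximum(np.abs(beta_hat) - lam, 0.0)
    return shrunk if shrunk.ndim else float(shrunk)


def _log_denominator(beta, se, lam):
    """log P(|X| > lam) for X ~ N(beta, se^2), stable for lam/se up to ~40."""
    a = beta / se - lam / se
    b = -beta / se - lam / se
    return np.logaddexp(special.log_ndtr(a), special.log_ndtr(b))


def conditional_loglik(beta, beta_hat, se, lam):
    """Log density of beta_hat ~ N(beta, se^2) given |beta_hat| > lam.

    The selection indicator applies to the *estimate*: callers must pass a
    selected record (|beta_hat| >= lam).  Finite for every real beta.
    """
    beta = np.asarray(beta, dtype=float)
    beta_hat = np.asarray(beta_hat, dtype=float)
    se = np.asarray(se, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if np.any(np.abs(beta_hat) < lam):
        raise ValueError("record not selected: |beta_hat| < lambda")
    z = (beta_hat - beta) / se
    logphi = -0.5 * (z * z + _LOG_2PI) - np.log(se)
    out = logphi - _log_denominator(beta, se, lam)
    return out if out.ndim else float(out)


def _conditional_loglik_unchecked(beta, beta_hat, se, lam):
    z = (beta_hat - beta) / se
    return -0.5 * z * z - _log_denominator(beta, se, lam)


def mle_correct(beta_hat, se, alpha, *, tol: float = 1e-10):
    """Conditional-likelihood MLE of the effect size of a selected SNP.

    Maximizes :func:`conditional_loglik` over real beta.  By symmetry the
    maximizer shares beta_hat's sign (or is 0), and |mle| <= |beta_hat|, so the
    search runs on [0, |beta_hat|] in the folded parameterization: a coarse
    vectorized grid localizes the mode, golden-section refines to ``tol``.
    Records with |beta_hat| < lambda(alpha) are not selected and raise.
    """
    beta_hat = np.atleast_1d(np.asarray(beta_hat, dtype=float))
    se = np.broadcast_to(np.asarray(se, dtype=float), beta_hat.shape).copy()
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    lam = np.broadcast_to(threshold_lambda(alpha, se), beta_hat.shape)
    if np.any(np.abs(beta_hat) < lam):
        raise ValueError("record not selected: |beta_hat| < lambda(alpha)")
    scalar = np.isscalar(alpha) and np.ndim(beta_hat) == 1 and beta_hat.size == 1

    sign = np.where(beta_hat >= 0, 1.0, -1.0)
    b_abs = np.abs(beta_hat)
    if np.all(lam == 0):
        out = beta_hat.copy()
        return float(out[0]) if scalar else out

    # folded objective on [0, b_abs]; the unconditional peak at b_abs is pulled
    # toward 0 by the selection-probability denominator, never pushed past it
    def f(b):
        return _conditional_loglik_unchecked(b, b_abs, se, lam)

    n_grid = 64
    frac = np.linspace(0.0, 1.0, n_grid)[:, None]
    grid = frac * b_abs[None, :]
    vals = f(grid)
    best = np.argmax(vals, axis=0)
    lo = grid[np.maximum(best - 1, 0), np.arange(b_abs.size)]
    hi = grid[np.minimum(best + 1, n_grid - 1), np.arange(b_abs.size)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    for _ in range(90):
        x1 = hi - invphi * (hi - lo)
        x2 = lo + invphi * (hi - lo)
        move_right = f(x1) < f(x2)
        lo = np.where(move_right, x1, lo)
        hi = np.where(move_right, hi, x2)
        if np.max(hi - lo) < tol:
            break
    est = sign * 0.5 * (lo + hi)
    # exact endpoint checks: the mode can sit at 0 (estimate barely selected)
    at0 = f(np.zeros_like(b_abs)) >= f(0.5 * (lo + hi))
    est = np.where(at0, 0.0, est)
    return float(est[0]) if scalar else est


def correct_effects(beta_hat, se, alpha, method: str):
    """Corrected weights for already-selected effects under a named method.

    method "none" returns beta_hat unchanged; "lasso" and "mle" apply the
    respective correction at threshold alpha.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    if method == "none":
        return beta_hat.copy()
    if method == "lasso":
        return np.asarray(lasso_correct(beta_hat, se, alpha))
    if method == "mle":
        return np.atleast_1d(mle_correct(beta_hat, se, alpha))
    raise ValueError(f"unknown correction method {method!r}")
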