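"""Dirichlet-Multinomial density, maximum-likelihood fitting and sampling.

The Dirichlet-Multinomial (DirMult) compounds a Multinomial with a Dirichlet
prior on the base probabilities and so captures the overdispersion of allele
counts across sequencing replicates that a plain Multinomial misses.  For a
count vector x with n = sum(x) and concentration vector alpha
(alpha0 = sum(alpha)):

    DirMult(x; alpha) = n! Gamma(alpha0) / Gamma(n + alpha0)
                        * prod_k Gamma(x_k + alpha_k) / (Gamma(x_k + 1) Gamma(alpha_k))

All factorials are generalized through the Gamma function, so the density
accepts the real-valued pseudocount-adjusted vectors produced by
:mod:`snvcomp.quality`.  Everything is evaluated in log space.

Fitting uses a Minka-style fixed-point iteration with a method-of-moments
start; if an iteration fails to increase the log-likelihood the routine
falls back to bounded quasi-Newton on log(alpha).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, psi

ALPHA_FLOOR = 1e-6
_REL_TOL = 1e-6
_MAX_ITER = 100
#: upper bound of log(alpha_k) in the quasi-Newton fallback; beyond this the
#: DirMult is numerically indistinguishable from its multinomial limit
_LOG_ALPHA_CAP = 16.0


@dataclass
class ConcentrationVector:
    """Fitted Dirichlet concentration parameters for one sample."""

    alpha: np.ndarray
    log_likelihood_at_fit: float
    converged: bool
    iterations: int

    @property
    def alpha0(self) -> float:
        return float(self.alpha.sum())

    @property
    def mean_proportions(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()


def log_dirmult(x_tilde, alpha) -> float:
    """Log DirMult density of one (possibly real-valued) count 4-vector."""
    x = np.asarray(x_tilde, dtype=float)
    a = np.asarray(alpha, dtype=float) if not isinstance(alpha, ConcentrationVector) else alpha.alpha
    if (a <= 0).any():
        raise ValueError("all concentration parameters must be > 0")
    if (x < 0).any():
        raise ValueError("counts must be >= 0")
    n = x.sum()
    a0 = a.sum()
    return float(
        gammaln(n + 1)
        - gammaln(x + 1).sum()
        + gammaln(a0)
        - gammaln(n + a0)
        + (gammaln(x + a) - gammaln(a)).sum()
    )


def log_likelihood(X: np.ndarray, alpha) -> float:
    """Sum of log DirMult densities over the rows of X (N, 4)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    a = alpha.alpha if isinstance(alpha, ConcentrationVector) else np.asarray(alpha, float)
    if (a <= 0).any():
        raise ValueError("all concentration parameters must be > 0")
    n = X.sum(axis=1)
    a0 = a.sum()
    return float(
        np.sum(gammaln(n + 1))
        - np.sum(gammaln(X + 1))
        + X.shape[0] * gammaln(a0)
        - np.sum(gammaln(n + a0))
        + np.sum(gammaln(X + a))
        - X.shape[0] * np.sum(gammaln(a))
    )


def _moment_start(X: np.ndarray) -> np.ndarray:
    """Method-of-moments initial alpha.

    Mean proportions set alpha/alpha0; alpha0 comes from matching the
    Dirichlet variance Var(p_k) = m_k (1 - m_k) / (1 + alpha0) channelwise.
    With one replicate (or zero empirical variance) alpha0 defaults to the
    mean total count, a neutral mid-dispersion start.
    """
    n = X.sum(axis=1)
    P = X / n[:, None]
    m = np.clip(P.mean(axis=0), 1e-8, None)
    m = m / m.sum()
    a0_default = float(np.clip(n.mean(), 1.0, 1e6))
    if X.shape[0] >= 2:
        v = P.var(axis=0)
        ok = (v > 1e-12) & (m > 1e-6) & (m < 1 - 1e-6)
        if ok.any():
            ests = m[ok] * (1 - m[ok]) / v[ok] - 1.0
            ests = ests[ests > 0]
            if ests.size:
                a0_default = float(np.clip(np.median(ests), 1e-2, 1e6))
    return np.maximum(m * a0_default, ALPHA_FLOOR)


def _grad_log_likelihood(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """d ll / d alpha_k = N psi(a0) - sum_i psi(n_i + a0)
    + sum_i psi(x_ik + alpha_k) - N psi(alpha_k)."""
    n = X.sum(axis=1)
    N = X.shape[0]
    a0 = alpha.sum()
    common = N * psi(a0) - np.sum(psi(n + a0))
    return common + psi(X + alpha).sum(axis=0) - N * psi(alpha)


def _fixed_point_step(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    n = X.sum(axis=1)
    N = X.shape[0]
    a0 = alpha.sum()
    num = psi(X + alpha).sum(axis=0) - N * psi(alpha)
    den = np.sum(psi(n + a0)) - N * psi(a0)
    if den <= 0 or not np.isfinite(den):
        return alpha
    new = alpha * num / den
    return np.maximum(new, ALPHA_FLOOR)


def fit_alpha(
    X,
    tol: float = _REL_TOL,
    max_iter: int = _MAX_ITER,
) -> ConcentrationVector:
    """Maximum-likelihood concentration vector for replicate counts X (N, 4).

    Iterates the Minka fixed point from a method-of-moments start; each
    accepted step does not decrease the log-likelihood (a decreasing step
    triggers the quasi-Newton fallback on log(alpha)).  ``converged`` is
    False when the iteration cap is reached; the best alpha seen is returned
    either way.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != 4 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty (N, 4) array")
    if (X.sum(axis=1) <= 0).any():
        raise ValueError("every replicate needs positive total mass")
    # canonical row order makes the fit exactly invariant under replicate
    # permutation (and sample swap for the pooled fit)
    X = X[np.lexsort(X.T[::-1])]

    n = X.sum(axis=1)
    N = X.shape[0]
    # the alpha-free data term is constant across iterations
    const = float(np.sum(gammaln(n + 1)) - np.sum(gammaln(X + 1)))

    def ll_at(a: np.ndarray) -> float:
        a0 = a.sum()
        return const + float(
            N * gammaln(a0)
            - np.sum(gammaln(n + a0))
            + np.sum(gammaln(X + a))
            - N * np.sum(gammaln(a))
        )

    alpha = _moment_start(X)
    ll = ll_at(alpha)
    converged = False
    it = 0
    need_fallback = False
    for it in range(1, max_iter + 1):
        new = _fixed_point_step(X, alpha)
        new_ll = ll_at(new)
        if not np.isfinite(new_ll) or new_ll < ll - 1e-9 * (abs(ll) + 1.0):
            need_fallback = True
            break
        improved = new_ll - ll
        alpha, ll = new, new_ll
        if improved < tol * (abs(ll) + 1.0):
            converged = True
            break

    if not converged and not need_fallback:
        # a vanishing log-space gradient means the iteration cap was hit on
        # the flat multinomial-limit plateau; the fit is effectively done
        g = _grad_log_likelihood(X, alpha) * alpha
        if np.max(np.abs(g)) < 1e-4 * (abs(ll) + 1.0):
            converged = True

    if need_fallback or not converged:

        def neg_ll_and_grad(t):
            a = np.exp(t)
            return -ll_at(a), -_grad_log_likelihood(X, a) * a

        res = minimize(
            neg_ll_and_grad,
            np.log(alpha),
            jac=True,
            method="L-BFGS-B",
            bounds=[(np.log(ALPHA_FLOOR), _LOG_ALPHA_CAP)] * 4,
        )
        cand = np.maximum(np.exp(res.x), ALPHA_FLOOR)
        cand_ll = ll_at(cand)
        if np.isfinite(cand_ll) and cand_ll >= ll:
            alpha, ll = cand, cand_ll
            converged = converged or bool(res.success)
    return ConcentrationVector(alpha, ll, converged, it)


def sample_dirmult(alpha, n: int, N: int, seed=None, rng=None) -> np.ndarray:
    """Draw N replicate count 4-vectors from DirMult(n, alpha).

    Hierarchical sampling: p ~ Dirichlet(alpha), then x ~ Multinomial(n, p),
    independently per replicate.  Reproducible given ``seed`` (or pass an
    existing numpy Generator as ``rng``).
    """
    a = alpha.alpha if isinstance(alpha, ConcentrationVector) else np.asarray(alpha, float)
    if n < 0 or N < 1:
        raise ValueError("need n >= 0 and N >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    ps = rng.dirichlet(a, size=N)
    return np.array([rng.multinomial(n, p) for p in ps], dtype=np.int64)
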