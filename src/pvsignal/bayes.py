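"""Bayesian and empirical-Bayes shrinkage detectors.

Four methods, all built on the relative reporting rate
``lambda_ij = n_ij / E_ij`` with ``E_ij = n_i. n_.j / n_..``:

* **GPS** (gamma-Poisson shrinker): ``n_ij | lambda ~ Poisson(lambda E_ij)``
  with a two-component gamma mixture prior
  ``lambda ~ w Gamma(a1, b1) + (1-w) Gamma(a2, b2)`` whose five
  hyperparameters are fit by maximum marginal likelihood over *all* cells of
  the count matrix (the marginal of each cell is a mixture of negative
  binomials).  The decision statistic is EB05, the 5th percentile of the
  mixture-gamma posterior.
* **BCPNN**: beta-binomial model for the joint and marginal reporting
  probabilities; posterior mean and variance of the information component
  IC = log2(theta_ij / (theta_i. theta_.j)) by the delta method, decision on
  the credible lower bound.
* **new IC**: conjugate ``Gamma(0.5, 0.5)`` prior on lambda, exact posterior
  gamma quantiles; decision on the 2.5% posterior quantile.
* **sB** (simplified Bayes): single ``Gamma(alpha, alpha)`` prior (mean 1,
  variance 1/alpha) and the moment-based lower bound
  ``posterior mean - 1.645 posterior sd``.

sB with alpha = 0.5 shares the exact posterior distribution with new IC;
only the interval construction differs (moment bound versus exact quantile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

try:  # single-pass likelihood kernel; pure-numpy fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

from .core import TwoByTwo, DrugEventTable

__all__ = [
    "GpsPrior",
    "GpsPosterior",
    "BcpnnResult",
    "GammaPosterior",
    "gps_fit",
    "fit_gps_prior",
    "gps_eb05",
    "gps_eb05_arrays",
    "gps_marginal_loglik",
    "bcpnn",
    "bcpnn_arrays",
    "new_ic",
    "new_ic_arrays",
    "sb",
    "sb_arrays",
]

_LN2 = np.log(2.0)

#: DuMouchel-style default starting point (alpha1, beta1, alpha2, beta2, w).
GPS_DEFAULT_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class GpsPrior:
    """Fitted mixture-gamma prior for the relative reporting rate."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shapes and rates must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("mixture weight must be in (0, 1)")


@dataclass(frozen=True)
class GpsPosterior:
    """Mixture-gamma posterior for one cell, with its 5th percentile (EB05)."""

    w_star: float
    shape1: float
    rate1: float
    shape2: float
    rate2: float
    eb05: float

    def cdf(self, lam) -> np.ndarray:
        return self.w_star * stats.gamma.cdf(lam, self.shape1, scale=1.0 / self.rate1) + (
            1.0 - self.w_star
        ) * stats.gamma.cdf(lam, self.shape2, scale=1.0 / self.rate2)

    def mean(self) -> float:
        return self.w_star * self.shape1 / self.rate1 + (1 - self.w_star) * self.shape2 / self.rate2

    def is_signal(self, cutoff: float = 2.0) -> bool:
        return self.eb05 > cutoff


# ---------------------------------------------------------------------------
# GPS marginal likelihood and empirical-Bayes fit
# ---------------------------------------------------------------------------

def _nb_loglik_terms(n, log_e, log_ratio_e, alpha, beta, gl_lookup, inv):
    """log NB(n | alpha, E/(E+beta)) for all cells.

    ``gl_lookup``/``inv`` map each cell to gammaln(alpha + n) via the unique
    observed counts; ``log_ratio_e`` caches log(E + beta) per call.
    """
    # log p = log E - log(E+beta); log(1-p) = log beta - log(E+beta)
    return (
        gl_lookup[inv]
        - special.gammaln(alpha)
        + n * log_e
        + alpha * np.log(beta)
        - (n + alpha) * log_ratio_e
    )


def _prepare_cells(n, e):
    """Flatten, drop structurally-empty cells (E = 0) and cache count lookups."""
    n = np.asarray(n, dtype=np.float64).ravel()
    e = np.asarray(e, dtype=np.float64).ravel()
    if n.shape != e.shape:
        raise ValueError("counts and expected counts must align")
    keep = e > 0
    if not np.all(keep):
        if np.any(n[~keep] > 0):
            raise ValueError("cell with E_ij = 0 but n_ij > 0")
        n, e = n[keep], e[keep]
    n_unique, inv = np.unique(n, return_inverse=True)
    const = -special.gammaln(n + 1.0).sum()
    return n, e, n_unique, inv, const


if _HAVE_NUMBA:

    @njit(fastmath=False)
    def _mix_nll_grad_kernel(n, e, log_e, inv, gl1, gl2, dg1, dg2,
                             a1, b1, a2, b2, w):  # pragma: no cover - jitted
        lw = math.log(w)
        l1w = math.log1p(-w)
        lb1 = math.log(b1)
        lb2 = math.log(b2)
        total = 0.0
        g_a1 = 0.0
        g_b1 = 0.0
        g_a2 = 0.0
        g_b2 = 0.0
        g_w = 0.0
        for i in range(n.shape[0]):
            k = inv[i]
            l1e = math.log(e[i] + b1)
            l2e = math.log(e[i] + b2)
            ll1 = gl1[k] + n[i] * log_e[i] + a1 * lb1 - (n[i] + a1) * l1e
            ll2 = gl2[k] + n[i] * log_e[i] + a2 * lb2 - (n[i] + a2) * l2e
            m1 = lw + ll1
            m2 = l1w + ll2
            d = m2 - m1
            # past ~37 log-units the smaller component is below double eps
            if d < -37.0:
                llc = m1
                r1 = 1.0
            elif d > 37.0:
                llc = m2
                r1 = 0.0
            elif d <= 0.0:
                t = math.exp(d)
                llc = m1 + math.log1p(t)
                r1 = 1.0 / (1.0 + t)
            else:
                t = math.exp(-d)
                llc = m2 + math.log1p(t)
                r1 = t / (1.0 + t)
            total += llc
            r2 = 1.0 - r1
            g_a1 += r1 * (dg1[k] + lb1 - l1e)
            g_a2 += r2 * (dg2[k] + lb2 - l2e)
            g_b1 += r1 * (a1 / b1 - (n[i] + a1) / (e[i] + b1))
            g_b2 += r2 * (a2 / b2 - (n[i] + a2) / (e[i] + b2))
            g_w += r1 - w
        return total, g_a1 * a1, g_b1 * b1, g_a2 * a2, g_b2 * b2, g_w


def _mixture_negloglik_grad(theta, n, e, log_e, n_unique, inv, const):
    """Negative mixture-NB log marginal likelihood and its gradient.

    Parameters are unconstrained: theta = (log a1, log b1, log a2, log b2,
    logit w).
    """
    a1, b1, a2, b2 = np.exp(theta[:4])
    w = float(special.expit(theta[4]))
    w = min(max(w, 1e-300), 1.0 - 1e-16)
    if _HAVE_NUMBA:
        # count-dependent transcendentals via lookups over the unique counts
        gl1 = special.gammaln(a1 + n_unique) - special.gammaln(a1)
        gl2 = special.gammaln(a2 + n_unique) - special.gammaln(a2)
        dg1 = special.digamma(a1 + n_unique) - special.digamma(a1)
        dg2 = special.digamma(a2 + n_unique) - special.digamma(a2)
        total, ga1, gb1, ga2, gb2, gw = _mix_nll_grad_kernel(
            n, e, log_e, inv, gl1, gl2, dg1, dg2,
            float(a1), float(b1), float(a2), float(b2), w,
        )
        return -(total + const), -np.array([ga1, gb1, ga2, gb2, gw])
    l1e = np.log(e + b1)
    l2e = np.log(e + b2)
    gl1 = special.gammaln(a1 + n_unique)
    gl2 = special.gammaln(a2 + n_unique)
    ll1 = _nb_loglik_terms(n, log_e, l1e, a1, b1, gl1, inv)
    ll2 = _nb_loglik_terms(n, log_e, l2e, a2, b2, gl2, inv)
    m1 = np.log(w) + ll1
    m2 = np.log1p(-w) + ll2
    hi = np.maximum(m1, m2)
    ll = hi + np.log(np.exp(m1 - hi) + np.exp(m2 - hi))
    total = ll.sum() + const
    # responsibilities
    r1 = np.exp(m1 - ll)
    r2 = 1.0 - r1
    dg1 = special.digamma(a1 + n_unique) - special.digamma(a1)
    dg2 = special.digamma(a2 + n_unique) - special.digamma(a2)
    g_a1 = a1 * np.sum(r1 * (dg1[inv] + np.log(b1) - l1e))
    g_a2 = a2 * np.sum(r2 * (dg2[inv] + np.log(b2) - l2e))
    g_b1 = b1 * np.sum(r1 * (a1 / b1 - (n + a1) / (e + b1)))
    g_b2 = b2 * np.sum(r2 * (a2 / b2 - (n + a2) / (e + b2)))
    g_w = np.sum(r1 - w)
    grad = np.array([g_a1, g_b1, g_a2, g_b2, g_w])
    return -total, -grad


def gps_marginal_loglik(n, e, prior: GpsPrior) -> float:
    """Log marginal likelihood of counts under a mixture-gamma prior."""
    n, e, n_unique, inv, const = _prepare_cells(n, e)
    theta = np.array(
        [np.log(prior.alpha1), np.log(prior.beta1), np.log(prior.alpha2),
         np.log(prior.beta2), special.logit(prior.w)]
    )
    with np.errstate(divide="ignore"):
        log_e = np.where(n > 0, np.log(np.where(e > 0, e, 1.0)), 0.0)
    nll, _ = _mixture_negloglik_grad(theta, n, e, log_e, n_unique, inv, const)
    return -float(nll)


def fit_gps_prior(
    n,
    e,
    starts: int = 5,
    tol: float = 1e-8,
    seed: int = 0,
) -> GpsPrior:
    """Fit the five mixture-gamma hyperparameters by maximum marginal likelihood.

    All cells (including zeros) contribute.  The optimiser runs on
    unconstrained transforms (log shapes/rates, logit weight) from the
    DuMouchel-style default start plus ``starts - 1`` jittered restarts; the
    best converged optimum wins.
    """
    n, e, n_unique, inv, const = _prepare_cells(n, e)
    with np.errstate(divide="ignore"):
        # n * log(E): only enters where n > 0, so a zero placeholder is exact
        log_e = np.where(n > 0, np.log(np.where(e > 0, e, 1.0)), 0.0)
    base = np.array(
        [np.log(GPS_DEFAULT_START[0]), np.log(GPS_DEFAULT_START[1]),
         np.log(GPS_DEFAULT_START[2]), np.log(GPS_DEFAULT_START[3]),
         special.logit(GPS_DEFAULT_START[4])]
    )
    rng = np.random.default_rng(seed)
    best = None
    # bounds keep exp()/expit() finite; the optimum lies far inside except
    # for degenerate (point-mass) priors, which the bound then represents
    bounds = [(-30.0, 30.0)] * 5
    for k in range(max(1, int(starts))):
        x0 = base if k == 0 else base + rng.normal(scale=0.7, size=5)
        with np.errstate(all="ignore"):
            res = optimize.minimize(
                _mixture_negloglik_grad,
                np.clip(x0, -29.0, 29.0),
                args=(n, e, log_e, n_unique, inv, const),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 500, "ftol": tol, "gtol": 1e-6},
            )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("GPS hyperparameter fit failed to converge from any start")
    a1, b1, a2, b2 = np.exp(best.x[:4])
    w = float(special.expit(best.x[4]))
    w = min(max(w, 1e-12), 1 - 1e-12)
    return GpsPrior(float(a1), float(b1), float(a2), float(b2), w, loglik=-float(best.fun))


def gps_fit(table: DrugEventTable, starts: int = 5, tol: float = 1e-8, seed: int = 0) -> GpsPrior:
    """Fit the GPS prior to a whole drug-event count table."""
    if table.total == 0:
        raise ValueError("cannot fit the GPS prior to an empty table")
    x = table.ae_margins.astype(float)
    y = table.drug_margins.astype(float)
    e = np.outer(x, y) / table.total
    return fit_gps_prior(table.counts, e, starts=starts, tol=tol, seed=seed)


def _nb_logpmf(n: float, alpha: float, beta: float, e: float) -> float:
    """log NB(n | alpha, E/(E+beta)), the GPS marginal for one cell."""
    ll = (
        special.gammaln(alpha + n) - special.gammaln(n + 1) - special.gammaln(alpha)
        + alpha * np.log(beta / (e + beta))
    )
    if n > 0:
        ll += n * np.log(e / (e + beta))
    return float(ll)


def _posterior_w_star(n: float, e: float, prior: GpsPrior) -> float:
    lp1 = np.log(prior.w) + _nb_logpmf(n, prior.alpha1, prior.beta1, e)
    lp2 = np.log1p(-prior.w) + _nb_logpmf(n, prior.alpha2, prior.beta2, e)
    return float(special.expit(lp1 - lp2))


def gps_eb05(n_ij: int, e_ij: float, prior: GpsPrior, q: float = 0.05) -> GpsPosterior:
    """Posterior for one cell and its lower posterior quantile (EB05 at q=0.05).

    The posterior is the mixture of ``Gamma(alpha_k + n, beta_k + E)`` with
    weight ``w*`` (the posterior probability of the first component, computed
    from the two negative-binomial marginals); EB05 solves
    ``posterior CDF = q`` by bracketed root finding.
    """
    if e_ij <= 0:
        raise ValueError(f"expected count must be positive, got {e_ij}")
    n = float(n_ij)
    w_star = _posterior_w_star(n, float(e_ij), prior)
    s1, r1 = prior.alpha1 + n, prior.beta1 + float(e_ij)
    s2, r2 = prior.alpha2 + n, prior.beta2 + float(e_ij)
    eb = _mixture_gamma_ppf(q, w_star, s1, r1, s2, r2)
    return GpsPosterior(w_star=w_star, shape1=s1, rate1=r1, shape2=s2, rate2=r2, eb05=eb)


def _mixture_gamma_ppf(q, w, s1, r1, s2, r2) -> float:
    def cdf(lam):
        return w * special.gammainc(s1, r1 * lam) + (1 - w) * special.gammainc(s2, r2 * lam)

    hi = max(
        stats.gamma.ppf(min(0.999, q + 0.5), s1, scale=1.0 / r1),
        stats.gamma.ppf(min(0.999, q + 0.5), s2, scale=1.0 / r2),
    )
    while cdf(hi) < q:
        hi *= 2.0
    return float(optimize.brentq(lambda lam: cdf(lam) - q, 0.0, hi, xtol=1e-14, rtol=1e-14))


def gps_eb05_arrays(n_ij, e_ij, prior: GpsPrior, q: float = 0.05) -> np.ndarray:
    """EB05 for vectors of cells (cells with E = 0 yield NaN, never a signal)."""
    n = np.asarray(n_ij, dtype=float).ravel()
    e = np.asarray(e_ij, dtype=float).ravel()
    out = np.full(n.shape, np.nan)
    for k in range(n.size):
        if e[k] > 0:
            out[k] = gps_eb05(n[k], e[k], prior, q=q).eb05
    return out


# ---------------------------------------------------------------------------
# BCPNN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BcpnnResult:
    """Delta-method posterior mean/variance of the IC, and its credible lower bound."""

    mean_ic: float
    var_ic: float
    lower: float
    gamma_term: float

    def is_signal(self, cutoff: float = 1.0) -> bool:
        return self.lower > cutoff


def bcpnn_arrays(n_ij, n_i_dot, n_dot_j, n_dot_dot, confidence: float = 0.95):
    """BCPNN IC posterior mean, variance and credible lower bound (vectorised).

    With gamma = (n_.. + 2)^2 / ((n_i. + 1)(n_.j + 1)):

        E[IC]   = log2[ (n_ij + 1)(n_.. + 2)^2 / ((n_.. + gamma)(n_i. + 1)(n_.j + 1)) ]
        Var[IC] = (1/ln2)^2 [ (n_.. - n_ij + gamma - 1) / ((n_ij + 1)(1 + n_.. + gamma))
                              + (n_.. - n_i. + 1) / ((n_i. + 1)(n_.. + 3))
                              + (n_.. - n_.j + 1) / ((n_.j + 1)(n_.. + 3)) ]

    Returns ``(mean_ic, var_ic, lower, gamma)``.
    """
    a = np.asarray(n_ij, dtype=float)
    ni = np.asarray(n_i_dot, dtype=float)
    nj = np.asarray(n_dot_j, dtype=float)
    n = np.asarray(n_dot_dot, dtype=float)
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    gamma = (n + 2.0) ** 2 / ((ni + 1.0) * (nj + 1.0))
    mean = np.log2((a + 1.0) * (n + 2.0) ** 2 / ((n + gamma) * (ni + 1.0) * (nj + 1.0)))
    var = (
        (n - a + gamma - 1.0) / ((a + 1.0) * (1.0 + n + gamma))
        + (n - ni + 1.0) / ((ni + 1.0) * (n + 3.0))
        + (n - nj + 1.0) / ((nj + 1.0) * (n + 3.0))
    ) / _LN2**2
    lower = mean - z * np.sqrt(var)
    return mean, var, lower, gamma


def bcpnn(t: TwoByTwo, confidence: float = 0.95) -> BcpnnResult:
    """BCPNN IC posterior for one 2x2 table."""
    mean, var, lower, gamma = bcpnn_arrays(
        t.n_ij, t.n_i_dot, t.n_dot_j, t.n_dot_dot, confidence
    )
    return BcpnnResult(
        mean_ic=float(mean), var_ic=float(var), lower=float(lower), gamma_term=float(gamma)
    )


# ---------------------------------------------------------------------------
# new IC and simplified Bayes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaPosterior:
    """Single-gamma posterior of the relative reporting rate.

    Used by both the new IC method (prior Gamma(0.5, 0.5), decision on the
    exact 2.5% quantile ``q025``) and the simplified Bayes method (prior
    Gamma(alpha, alpha), decision on the moment bound ``sb_lower``).
    """

    shape: float
    rate: float
    mean_log2: float
    q025: float
    q975: float
    sb_lower: float

    @property
    def mean(self) -> float:
        return self.shape / self.rate


def _gamma_posterior(shape: float, rate: float) -> GammaPosterior:
    q025, q975 = stats.gamma.ppf([0.025, 0.975], shape, scale=1.0 / rate)
    return GammaPosterior(
        shape=float(shape),
        rate=float(rate),
        mean_log2=float(np.log2(shape / rate)),
        q025=float(q025),
        q975=float(q975),
        sb_lower=float(shape / rate - 1.645 * np.sqrt(shape) / rate),
    )


def new_ic(n_ij: int, e_ij: float) -> GammaPosterior:
    """Posterior Gamma(n_ij + 0.5, E_ij + 0.5) of the relative reporting rate."""
    if n_ij < 0 or e_ij < 0:
        raise ValueError("counts and expected counts must be non-negative")
    return _gamma_posterior(n_ij + 0.5, e_ij + 0.5)


def sb(n_ij: int, e_ij: float, alpha: float = 0.5) -> GammaPosterior:
    """Posterior Gamma(alpha + n_ij, alpha + E_ij) under the Gamma(alpha, alpha) prior."""
    if alpha <= 0:
        raise ValueError("prior parameter alpha must be positive")
    if n_ij < 0 or e_ij < 0:
        raise ValueError("counts and expected counts must be non-negative")
    return _gamma_posterior(alpha + n_ij, alpha + e_ij)


def new_ic_arrays(n_ij, e_ij) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean_log2, q025, q975) of the Gamma(n+0.5, E+0.5) posterior (vectorised)."""
    shape = np.asarray(n_ij, dtype=float) + 0.5
    rate = np.asarray(e_ij, dtype=float) + 0.5
    q025 = stats.gamma.ppf(0.025, shape, scale=1.0 / rate)
    q975 = stats.gamma.ppf(0.975, shape, scale=1.0 / rate)
    return np.log2(shape / rate), q025, q975


def sb_arrays(n_ij, e_ij, alpha: float = 0.5) -> np.ndarray:
    """Moment-based 95% lower bound mean - 1.645 sd of the sB posterior (vectorised)."""
    shape = np.asarray(n_ij, dtype=float) + alpha
    rate = np.asarray(e_ij, dtype=float) + alpha
    return shape / rate - 1.645 * np.sqrt(shape) / rate
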