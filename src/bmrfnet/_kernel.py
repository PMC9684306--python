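"""Numba-compiled Gibbs kernel for the CAR / spike-and-slab-lasso posterior.

The target density over (beta, gamma, p, sigma^2) is

    prod_j prod_i N(x_ij ; sum_{k!=j} beta_jk x_ik, sigma_j^2)      (CAR pseudo-likelihood)
  x prod_(j<k) [ gamma_jk psi_1(beta_jk) + (1-gamma_jk) psi_0(beta_jk) ]
  x prod_(j<k) Ber(gamma_jk ; p_jk) Beta(p_jk ; a_jk, b_jk)
  x prod_j InvGamma(sigma_j^2 ; a0, b0)

with psi_g(b) = (tau_g/2) exp(-tau_g |b|) Laplace densities.  Because the
pseudo-likelihood terms from rows j and k are jointly Gaussian in the
shared coefficient beta_jk, its full conditional under a Laplace
component is a two-piece truncated normal and can be sampled exactly;
all other updates are conjugate.  A random-walk Metropolis update for
beta is available as a fallback.

Everything here operates on flat per-pair arrays; the object-level API
lives in :mod:`bmrfnet.sampler`.
"""

import math

import numpy as np
from numba import njit

LOG_2PI = math.log(2.0 * math.pi)
SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _log_ndtr(z):
    """log Phi(z), stable far into the left tail."""
    if z > -37.0:
        return math.log(0.5 * math.erfc(-z / SQRT2))
    # asymptotic expansion: Phi(z) ~ phi(z)/|z| for z << 0
    return -0.5 * z * z - math.log(-z) - 0.5 * LOG_2PI


@njit(cache=True)
def _sample_std_lower_trunc(a):
    """Draw z ~ N(0,1) conditioned on z > a (Robert's exponential rejection)."""
    if a < 0.25:
        while True:
            z = np.random.normal()
            if z > a:
                return z
    alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        z = a + np.random.exponential() / alpha
        d = z - alpha
        if np.random.random() < math.exp(-0.5 * d * d):
            return z


@njit(cache=True)
def _draw_beta_exact(a, b, tau):
    """Exact draw from density prop. to exp(-a/2 b^2 + b*beta - tau|beta|).

    The density splits at zero into two truncated Gaussian pieces with
    common variance 1/a and means (b -+ tau)/a; the piece is chosen by
    its (log-space) normalizing mass, then sampled by truncation.
    """
    sd = 1.0 / math.sqrt(a)
    m_pos = (b - tau) / a
    m_neg = (b + tau) / a
    lw_pos = 0.5 * a * m_pos * m_pos + _log_ndtr(m_pos / sd)
    lw_neg = 0.5 * a * m_neg * m_neg + _log_ndtr(-m_neg / sd)
    mx = max(lw_pos, lw_neg)
    w_pos = math.exp(lw_pos - mx)
    w_neg = math.exp(lw_neg - mx)
    if np.random.random() < w_pos / (w_pos + w_neg):
        # positive side: beta = m_pos + sd*z with z > -m_pos/sd
        z = _sample_std_lower_trunc(-m_pos / sd)
        return m_pos + sd * z
    # negative side: -beta ~ N(-m_neg, sd^2) truncated to -beta > 0
    z = _sample_std_lower_trunc(m_neg / sd)
    return m_neg - sd * z


@njit(cache=True)
def _draw_beta_metropolis(beta, a, b, tau):
    """Random-walk Metropolis step on the same full conditional."""
    scale = 2.4 / math.sqrt(a)
    prop = beta + scale * np.random.normal()
    dlog = (
        -0.5 * a * (prop * prop - beta * beta)
        + b * (prop - beta)
        - tau * (abs(prop) - abs(beta))
    )
    if math.log(np.random.random() + 1e-300) < dlog:
        return prop
    return beta


@njit(cache=True)
def run_chain(
    x,
    jidx,
    kidx,
    prior_a,
    prior_b,
    tau1,
    tau0,
    ig_a,
    ig_b,
    n_iter,
    burn_in,
    thin,
    seed,
    exact_gibbs,
):
    """Run the Gibbs sweep; returns retained draws and a log-pseudo-lik trace.

    Parameters are flat per-candidate-pair arrays (jidx, kidx, prior_a,
    prior_b).  Initialization: beta = 0, gamma = 0, p at prior mean,
    sigma^2 = 1.
    """
    np.random.seed(seed)
    n, p = x.shape
    m = jidx.size
    n_keep = (n_iter - burn_in + thin - 1) // thin

    sxx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += x[i, j] * x[i, j]
        sxx[j] = s

    beta = np.zeros(m)
    gamma = np.zeros(m, dtype=np.int8)
    pjk = np.empty(m)
    for e in range(m):
        pjk[e] = prior_a[e] / (prior_a[e] + prior_b[e])
    sigma2 = np.ones(p)
    resid = x.copy()  # resid[:, j] = x_j - sum_k beta_jk x_k (beta starts at 0)

    beta_draws = np.empty((n_keep, m))
    gamma_draws = np.empty((n_keep, m), dtype=np.int8)
    p_draws = np.empty((n_keep, m))
    sigma2_draws = np.empty((n_keep, p))
    loglik_trace = np.empty(n_keep)

    log_half_tau1 = math.log(0.5 * tau1)
    log_half_tau0 = math.log(0.5 * tau0)
    keep = 0

    for it in range(n_iter):
        # -- beta sweep (one shared coefficient per unordered candidate pair)
        for e in range(m):
            j = jidx[e]
            k = kidx[e]
            bjk = beta[e]
            dot_kj = 0.0  # x_k . resid_j
            dot_jk = 0.0  # x_j . resid_k
            for i in range(n):
                dot_kj += x[i, k] * resid[i, j]
                dot_jk += x[i, j] * resid[i, k]
            a_quad = sxx[k] / sigma2[j] + sxx[j] / sigma2[k]
            b_lin = (dot_kj + bjk * sxx[k]) / sigma2[j] + (
                dot_jk + bjk * sxx[j]
            ) / sigma2[k]
            tau = tau1 if gamma[e] == 1 else tau0
            if exact_gibbs:
                new = _draw_beta_exact(a_quad, b_lin, tau)
            else:
                new = _draw_beta_metropolis(bjk, a_quad, b_lin, tau)
            d = new - bjk
            if d != 0.0:
                for i in range(n):
                    resid[i, j] -= d * x[i, k]
                    resid[i, k] -= d * x[i, j]
                beta[e] = new

        # -- gamma and p updates (conjugate given beta)
        for e in range(m):
            ab = abs(beta[e])
            l1 = math.log(pjk[e] + 1e-300) + log_half_tau1 - tau1 * ab
            l0 = math.log(1.0 - pjk[e] + 1e-300) + log_half_tau0 - tau0 * ab
            q = 1.0 / (1.0 + math.exp(l0 - l1))
            g = 1 if np.random.random() < q else 0
            gamma[e] = g
            pjk[e] = np.random.beta(prior_a[e] + g, prior_b[e] + 1 - g)

        # -- sigma^2 (conjugate inverse-gamma per node)
        for j in range(p):
            ssr = 0.0
            for i in range(n):
                ssr += resid[i, j] * resid[i, j]
            sigma2[j] = (ig_b + 0.5 * ssr) / np.random.gamma(ig_a + 0.5 * n)

        # periodic residual refresh against floating-point drift
        if (it + 1) % 1000 == 0:
            for j in range(p):
                for i in range(n):
                    resid[i, j] = x[i, j]
            for e in range(m):
                j = jidx[e]
                k = kidx[e]
                if beta[e] != 0.0:
                    for i in range(n):
                        resid[i, j] -= beta[e] * x[i, k]
                        resid[i, k] -= beta[e] * x[i, j]

        if it >= burn_in and (it - burn_in) % thin == 0:
            beta_draws[keep] = beta
            gamma_draws[keep] = gamma
            p_draws[keep] = pjk
            sigma2_draws[keep] = sigma2
            ll = 0.0
            for j in range(p):
                ssr = 0.0
                for i in range(n):
                    ssr += resid[i, j] * resid[i, j]
                ll += -0.5 * n * (LOG_2PI + math.log(sigma2[j])) - 0.5 * ssr / sigma2[j]
            loglik_trace[keep] = ll
            keep += 1

    return beta_draws, gamma_draws, p_draws, sigma2_draws, loglik_trace
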