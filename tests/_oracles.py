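"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the posterior
oracle works by exhaustive enumeration over indicator configurations
with Simpson quadrature over the strength coefficients (conditional
variances and inclusion probabilities integrated out analytically), the
partial-correlation oracle goes through covariance-algebra regression
residuals, and the metric oracles are naive pair loops.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def posterior_gamma_oracle(
    x: np.ndarray,
    tau1: float = 2.0,
    tau0: float = 20.0,
    ig_a: float = 0.01,
    ig_b: float = 0.01,
    prior_mean: float = 0.5,
    half_width: float = 1.2,
    n_grid: int = 201,
) -> np.ndarray:
    """Exact posterior P(gamma_jk = 1 | x) for p in {2, 3}, all pairs candidates.

    The conditional variances are integrated out analytically against
    their inverse-gamma prior (each node's Gaussian conditional
    likelihood marginalizes to a Student-type factor
    (ig_b + SSR_j/2)^-(ig_a + n/2)), as are the Beta-distributed
    inclusion probabilities (leaving Bernoulli(prior_mean) indicators).
    The remaining strength coefficients are integrated on a Simpson
    grid, one dimension per pair, and the 2^m indicator configurations
    are enumerated.
    """
    n, p = x.shape
    if p not in (2, 3):
        raise ValueError("oracle supports p = 2 or 3 only")
    pairs = list(itertools.combinations(range(p), 2))
    m = len(pairs)
    if n_grid % 2 == 0:
        n_grid += 1
    grid = np.linspace(-half_width, half_width, n_grid)
    h = grid[1] - grid[0]
    w = np.ones(n_grid)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    w *= h / 3.0

    S = x.T @ x
    expo = ig_a + 0.5 * n

    # log node factors on the grid; axes of the joint grid follow `pairs` order
    def node_log_factor(j: int) -> np.ndarray:
        others = [k for k in range(p) if k != j]
        axes = [pairs.index(tuple(sorted((j, k)))) for k in others]
        shape = [1] * m
        ssr = np.full([n_grid] * m if m > 1 else [n_grid], S[j, j], dtype=float)
        # SSR_j = S_jj - 2 sum_k b_k S_jk + sum_kl b_k b_l S_kl over others
        for k, ax in zip(others, axes):
            sh = shape.copy()
            sh[ax] = n_grid
            b = grid.reshape(sh)
            ssr = ssr - 2.0 * b * S[j, k]
        for (k, ax1), (l, ax2) in itertools.product(
            zip(others, axes), zip(others, axes)
        ):
            sh1 = shape.copy()
            sh1[ax1] = n_grid
            sh2 = shape.copy()
            sh2[ax2] = n_grid
            ssr = ssr + grid.reshape(sh1) * grid.reshape(sh2) * S[k, l]
        return -expo * np.log(ig_b + 0.5 * ssr)

    log_like = node_log_factor(0)
    for j in range(1, p):
        log_like = log_like + node_log_factor(j)
    amax = log_like.max()
    like = np.exp(log_like - amax)

    u1 = 0.5 * tau1 * np.exp(-tau1 * np.abs(grid))
    u0 = 0.5 * tau0 * np.exp(-tau0 * np.abs(grid))

    weights = np.zeros(2**m)
    for ci, config in enumerate(itertools.product((0, 1), repeat=m)):
        val = like.copy()
        for ax, g in enumerate(config):
            dens = (u1 if g else u0) * w
            sh = [1] * m
            sh[ax] = n_grid
            val = val * dens.reshape(sh)
        prior = np.prod([prior_mean if g else 1 - prior_mean for g in config])
        weights[ci] = prior * val.sum()
    weights /= weights.sum()

    probs = np.zeros(m)
    for ci, config in enumerate(itertools.product((0, 1), repeat=m)):
        for ax, g in enumerate(config):
            if g:
                probs[ax] += weights[ci]
    return probs


def partial_corr_by_regression(omega: np.ndarray) -> np.ndarray:
    """Partial correlations from covariance-algebra regression residuals.

    For each pair (j,k): regress X_j and X_k on the remaining variables
    (population coefficients from Sigma = Omega^-1) and correlate the
    residuals.
    """
    sigma = np.linalg.inv(omega)
    p = sigma.shape[0]
    rho = np.eye(p)
    for j in range(p):
        for k in range(j + 1, p):
            rest = [i for i in range(p) if i not in (j, k)]
            s_jj = sigma[j, j]
            s_kk = sigma[k, k]
            s_jk = sigma[j, k]
            if rest:
                srr = sigma[np.ix_(rest, rest)]
                sjr = sigma[j, rest]
                skr = sigma[k, rest]
                sol = np.linalg.solve(srr, np.column_stack([sjr, skr]))
                s_jj = s_jj - sjr @ sol[:, 0]
                s_kk = s_kk - skr @ sol[:, 1]
                s_jk = s_jk - sjr @ sol[:, 1]
            rho[j, k] = rho[k, j] = s_jk / math.sqrt(s_jj * s_kk)
    return rho


def confusion_loop(est_adj: np.ndarray, true_adj: np.ndarray) -> dict:
    """Naive pair-loop confusion counts and derived metrics."""
    p = true_adj.shape[0]
    tp = fp = fn = tn = 0
    for j in range(p):
        for k in range(j + 1, p):
            e, t = est_adj[j, k], true_adj[j, k]
            if e and t:
                tp += 1
            elif e and not t:
                fp += 1
            elif not e and t:
                fn += 1
            else:
                tn += 1
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    fdr = fp / (tp + fp) if tp + fp else 0.0
    den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return dict(TP=tp, FP=fp, FN=fn, TN=tn, SEN=sen, SPE=spe, FDR=fdr, MCC=mcc, F1=f1)


def brier_loop(prob_matrix: np.ndarray, true_adj: np.ndarray) -> float:
    """Naive pair-loop Brier score over all unordered pairs."""
    p = true_adj.shape[0]
    total = 0.0
    count = 0
    for j in range(p):
        for k in range(j + 1, p):
            total += (float(true_adj[j, k]) - prob_matrix[j, k]) ** 2
            count += 1
    return total / count


def pseudo_loglik_loop(x: np.ndarray, beta: np.ndarray, sigma2: np.ndarray) -> float:
    """Naive double-loop CAR pseudo-log-likelihood."""
    n, p = x.shape
    total = 0.0
    for j in range(p):
        for i in range(n):
            mu = 0.0
            for k in range(p):
                if k != j:
                    mu += beta[j, k] * x[i, k]
            total += (
                -0.5 * math.log(2 * math.pi * sigma2[j])
                - 0.5 * (x[i, j] - mu) ** 2 / sigma2[j]
            )
    return total


def batch_means_se(draws: np.ndarray, n_batches: int = 50) -> float:
    """Monte-Carlo standard error of a chain mean via batch means."""
    n = draws.shape[0]
    size = n // n_batches
    means = draws[: size * n_batches].reshape(n_batches, size).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_batches))
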