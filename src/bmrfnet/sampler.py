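"""MCMC for the Bayesian Markov random field: configuration, posterior containers
and the sampling entry points.

The model couples the Gaussian CAR pseudo-likelihood (one conditional
regression per gene, with a single shared strength coefficient beta_jk
per unordered pair) with a spike-and-slab lasso prior: conditional on a
binary indicator gamma_jk, beta_jk follows a Laplace density with rate
tau1 (slab, diffuse) or tau0 (spike, sharp at zero).  The posterior mean
of gamma_jk is the edge-existence probability, the package's primary
probabilistic output; the retained beta_jk draws quantify the edge's
strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .gaussian import CARParameters, ExpressionMatrix
from .networks import NetworkGraph
from .priors import EdgePriorSpec

__all__ = [
    "SSLPrior",
    "MCMCConfig",
    "PosteriorSamples",
    "EdgePosterior",
    "log_pseudo_likelihood",
    "gamma_conditional_probability",
    "run_mcmc",
    "summarize_edges",
    "select_network",
]


@dataclass(frozen=True)
class SSLPrior:
    """Spike-and-slab lasso rates: slab Laplace(tau1), spike Laplace(tau0)."""

    tau1: float = 2.0
    tau0: float = 20.0

    def __post_init__(self):
        if not self.tau0 > self.tau1 > 0:
            raise ValueError("require tau0 > tau1 > 0")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length and update-rule settings for the Gibbs sampler."""

    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0
    beta_update: str = "exact_gibbs"
    #: inverse-gamma (shape, rate) prior on each conditional variance
    sigma2_prior: tuple[float, float] = (0.01, 0.01)

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.beta_update not in {"exact_gibbs", "metropolis"}:
            raise ValueError("beta_update must be 'exact_gibbs' or 'metropolis'")
        if min(self.sigma2_prior) <= 0:
            raise ValueError("sigma2 prior parameters must be positive")


@dataclass
class PosteriorSamples:
    """Retained MCMC draws on the candidate pairs.

    ``pair_j``/``pair_k`` give the (j < k) node indices of each sampled
    pair; draw arrays have one row per retained iteration.
    """

    pair_j: np.ndarray
    pair_k: np.ndarray
    gene_ids: list[str]
    beta_draws: np.ndarray
    gamma_draws: np.ndarray
    sigma2_draws: np.ndarray
    p_draws: np.ndarray
    loglik_trace: np.ndarray
    config: MCMCConfig = field(default_factory=MCMCConfig)
    ssl: SSLPrior = field(default_factory=SSLPrior)

    def __post_init__(self):
        m = self.pair_j.size
        n_keep = self.beta_draws.shape[0]
        for name in ("beta_draws", "gamma_draws", "p_draws"):
            arr = getattr(self, name)
            if arr.shape != (n_keep, m):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n_keep}, {m})")
        if not np.isin(self.gamma_draws, (0, 1)).all():
            raise ValueError("gamma draws must be binary")

    @property
    def n_retained(self) -> int:
        return self.beta_draws.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.pair_j.size


@dataclass
class EdgePosterior:
    """Per-candidate-pair posterior summaries as a tidy table.

    Columns: gene_i, gene_j, existence_probability, beta_mean, beta_q025,
    beta_median, beta_q975, selected.  ``selected`` is probability >
    threshold.
    """

    table: pd.DataFrame
    threshold: float
    p: int
    gene_ids: list[str]

    def __post_init__(self):
        probs = self.table["existence_probability"].to_numpy()
        if probs.size and (probs.min() < 0 or probs.max() > 1):
            raise ValueError("existence probabilities must lie in [0, 1]")
        expect = probs > self.threshold
        if not np.array_equal(expect, self.table["selected"].to_numpy(dtype=bool)):
            raise ValueError("selected flags inconsistent with threshold")

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    def probability_matrix(self) -> np.ndarray:
        """Existence probabilities as a symmetric p x p matrix (0 off-candidates)."""
        out = np.zeros((self.p, self.p))
        jj = self.table["_j"].to_numpy()
        kk = self.table["_k"].to_numpy()
        pr = self.table["existence_probability"].to_numpy()
        out[jj, kk] = pr
        out[kk, jj] = pr
        return out


def log_pseudo_likelihood(x: ExpressionMatrix, car: CARParameters) -> float:
    """Log CAR pseudo-likelihood: sum over genes of the conditional Gaussian
    log density of each column given the others, with shared symmetric beta."""
    if not x.standardized:
        raise ValueError("expression data must be standardized")
    vals = x.values
    n, p = vals.shape
    if car.beta.shape != (p, p):
        raise ValueError("CAR parameter dimension does not match the data")
    mean = vals @ car.beta.T  # row j of beta gives gene j's regression weights
    resid = vals - mean
    ssr = (resid**2).sum(axis=0)
    return float(
        np.sum(-0.5 * n * (math.log(2 * math.pi) + np.log(car.sigma2)) - 0.5 * ssr / car.sigma2)
    )


def gamma_conditional_probability(
    beta_value: float, p_jk: float, prior: SSLPrior
) -> float:
    """P(gamma=1 | beta, p_jk): posterior weight of the slab component.

    Computed in log space from the two Laplace densities, so it is
    stable for large |beta| * tau.
    """
    if not 0.0 <= p_jk <= 1.0:
        raise ValueError("p_jk must lie in [0, 1]")
    if p_jk == 0.0:
        return 0.0
    if p_jk == 1.0:
        return 1.0
    ab = abs(beta_value)
    l1 = math.log(p_jk) + math.log(prior.tau1 / 2) - prior.tau1 * ab
    l0 = math.log(1 - p_jk) + math.log(prior.tau0 / 2) - prior.tau0 * ab
    return 1.0 / (1.0 + math.exp(l0 - l1))


def _candidate_pairs(priors: EdgePriorSpec) -> tuple[np.ndarray, np.ndarray]:
    j, k = np.nonzero(np.triu(priors.candidate_mask.adjacency, 1))
    return j.astype(np.int64), k.astype(np.int64)


def run_mcmc(
    x: ExpressionMatrix,
    priors: EdgePriorSpec,
    ssl: SSLPrior | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorSamples:
    """Sample the BMRF posterior over the candidate pairs.

    One sweep updates, in order: every candidate beta_jk from its exact
    two-piece truncated-normal full conditional (or by random-walk
    Metropolis), every gamma_jk from its Bernoulli conditional, every
    p_jk from its conjugate Beta conditional, and every sigma_j^2 from
    its conjugate inverse-gamma conditional.  Non-candidate strengths
    stay fixed at zero.  Reproducible given ``config.seed``.
    """
    ssl = ssl or SSLPrior()
    config = config or MCMCConfig()
    if not x.standardized:
        raise ValueError("expression data must be standardized before sampling")
    if priors.p != x.n_genes:
        raise ValueError(
            f"prior masks are for {priors.p} genes but data has {x.n_genes}"
        )
    jidx, kidx = _candidate_pairs(priors)
    prior_a = priors.beta_a[jidx, kidx].astype(float)
    prior_b = priors.beta_b[jidx, kidx].astype(float)
    ig_a, ig_b = config.sigma2_prior
    beta_d, gamma_d, p_d, sig_d, ll = _kernel.run_chain(
        np.ascontiguousarray(x.values),
        jidx,
        kidx,
        prior_a,
        prior_b,
        float(ssl.tau1),
        float(ssl.tau0),
        float(ig_a),
        float(ig_b),
        int(config.n_iter),
        int(config.burn_in),
        int(config.thin),
        int(config.seed),
        config.beta_update == "exact_gibbs",
    )
    if not np.all(np.isfinite(ll)):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(
            f"chain diverged: non-finite log pseudo-likelihood at retained draw {bad}"
        )
    return PosteriorSamples(
        pair_j=jidx,
        pair_k=kidx,
        gene_ids=list(x.gene_ids),
        beta_draws=beta_d,
        gamma_draws=gamma_d,
        sigma2_draws=sig_d,
        p_draws=p_d,
        loglik_trace=ll,
        config=config,
        ssl=ssl,
    )


def summarize_edges(samples: PosteriorSamples, threshold: float = 0.5) -> EdgePosterior:
    """Reduce retained draws to per-pair existence probabilities and strength
    summaries; an edge is selected when its probability exceeds the threshold."""
    if samples.n_retained < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    probs = samples.gamma_draws.mean(axis=0)
    beta = samples.beta_draws
    q025, q50, q975 = np.percentile(beta, [2.5, 50.0, 97.5], axis=0)
    genes = samples.gene_ids
    table = pd.DataFrame(
        {
            "gene_i": [genes[j] for j in samples.pair_j],
            "gene_j": [genes[k] for k in samples.pair_k],
            "existence_probability": probs,
            "beta_mean": beta.mean(axis=0),
            "beta_q025": q025,
            "beta_median": q50,
            "beta_q975": q975,
            "selected": probs > threshold,
            "_j": samples.pair_j,
            "_k": samples.pair_k,
        }
    )
    return EdgePosterior(
        table=table, threshold=threshold, p=len(genes), gene_ids=list(genes)
    )


def select_network(edges: EdgePosterior) -> NetworkGraph:
    """Adjacency matrix of the selected edges (probability > threshold)."""
    sel = edges.table[edges.table["selected"]]
    return NetworkGraph.from_edges(edges.p, zip(sel["_j"], sel["_k"]))
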