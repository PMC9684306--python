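"""Candidate-edge screening and per-edge Bernoulli-Beta priors.

Each potential edge (j,k) carries a latent inclusion indicator
gamma_jk ~ Bernoulli(p_jk) with a conjugate Beta prior on p_jk.  Two
binary masks steer this prior:

* ``G*`` — candidate edges from marginal-correlation screening (the
  pairs with the largest absolute Pearson correlations);
* ``M*`` — edges flagged by an external sparse estimate or by experts;
  here the default source is an L1-penalized node-wise regression
  neighborhood screen (lasso per node, OR rule), and a user-supplied
  mask can replace it.

The model with every candidate prior mean at 0.5 is the objective setup
(BMRF.O); giving pairs in the intersection G* ^ M* an informative Beta
prior with mean 0.8 yields the data-driven setup (BMRF.P).  Candidate
pairs are G* u M*; pairs outside the candidate set have their strength
fixed at zero, which saves computation on large gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso

from .gaussian import ExpressionMatrix
from .networks import NetworkGraph

__all__ = [
    "EdgePriorSpec",
    "screen_correlation",
    "screen_neighborhood",
    "build_edge_priors",
    "default_lasso_penalty",
]


@dataclass
class EdgePriorSpec:
    """Per-edge Beta(a, b) priors on inclusion probabilities, plus edge masks.

    ``candidate_mask`` marks the pairs whose strengths are sampled at
    all; ``informative_mask`` (a subset) marks those receiving the
    informative prior.  ``beta_a``/``beta_b`` are full p x p matrices,
    read only on candidate pairs.
    """

    candidate_mask: NetworkGraph
    informative_mask: NetworkGraph
    beta_a: np.ndarray
    beta_b: np.ndarray

    def __post_init__(self):
        p = self.candidate_mask.p
        if self.informative_mask.p != p:
            raise ValueError("mask size mismatch")
        if np.any(self.informative_mask.adjacency > self.candidate_mask.adjacency):
            raise ValueError("informative pairs must be a subset of candidate pairs")
        self.beta_a = np.asarray(self.beta_a, dtype=float)
        self.beta_b = np.asarray(self.beta_b, dtype=float)
        for name, m in (("beta_a", self.beta_a), ("beta_b", self.beta_b)):
            if m.shape != (p, p):
                raise ValueError(f"{name} must be {p}x{p}")
        cand = self.candidate_mask.adjacency.astype(bool)
        if np.any(self.beta_a[cand] <= 0) or np.any(self.beta_b[cand] <= 0):
            raise ValueError("Beta parameters must be positive on candidate pairs")

    @property
    def p(self) -> int:
        return self.candidate_mask.p

    @classmethod
    def noninformative(cls, p: int, candidate_mask: NetworkGraph | None = None) -> "EdgePriorSpec":
        """The objective (BMRF.O) prior: Beta(1,1), mean 0.5, on every candidate pair.

        With no ``candidate_mask`` every one of the p(p-1)/2 pairs is a
        candidate.
        """
        if candidate_mask is None:
            a = np.ones((p, p), dtype=np.int8)
            np.fill_diagonal(a, 0)
            candidate_mask = NetworkGraph(a)
        return cls(
            candidate_mask=candidate_mask,
            informative_mask=NetworkGraph.empty(p),
            beta_a=np.ones((p, p)),
            beta_b=np.ones((p, p)),
        )


def _pair_order(p: int):
    j, k = np.triu_indices(p, 1)
    return j, k


def screen_correlation(x: ExpressionMatrix, top_fraction: float) -> NetworkGraph:
    """Keep the ceil(top_fraction * p(p-1)/2) pairs with largest |Pearson r|.

    Ties are broken by lexicographic pair order so the result is
    deterministic.  Input must be standardized.
    """
    if not x.standardized:
        raise ValueError("screen_correlation expects standardized expression data")
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    p = x.n_genes
    r = (x.values.T @ x.values) / (x.n_samples - 1)
    j, k = _pair_order(p)
    absr = np.abs(r[j, k])
    n_keep = int(np.ceil(top_fraction * j.size))
    # stable sort on -|r|: equal values keep lexicographic (j,k) order
    order = np.argsort(-absr, kind="stable")[:n_keep]
    return NetworkGraph.from_edges(p, zip(j[order], k[order]))


def default_lasso_penalty(n: int, p: int) -> float:
    """Default neighborhood-screen penalty sqrt(2 log p / n).

    The classical order of the lasso regularization weight for
    consistent neighborhood selection with standardized predictors.
    """
    return float(np.sqrt(2.0 * np.log(p) / n))


def screen_neighborhood(x: ExpressionMatrix, penalty: float | None = None) -> NetworkGraph:
    """Sparse neighborhood screen: lasso of each gene on all others, OR rule.

    Edge (j,k) is flagged if either node's L1-penalized regression on
    the remaining genes assigns the other a nonzero coefficient.
    Deterministic given the data and penalty.
    """
    if not x.standardized:
        raise ValueError("screen_neighborhood expects standardized expression data")
    n, p = x.values.shape
    if penalty is None:
        penalty = default_lasso_penalty(n, p)
    a = np.zeros((p, p), dtype=np.int8)
    vals = x.values
    lasso = Lasso(alpha=penalty, fit_intercept=False, max_iter=10_000)
    for j in range(p):
        others = np.delete(np.arange(p), j)
        lasso.fit(vals[:, others], vals[:, j])
        nz = others[np.abs(lasso.coef_) > 0]
        a[j, nz] = 1
    a = np.maximum(a, a.T)  # OR rule keeps the union of directed selections
    return NetworkGraph(a)


def build_edge_priors(
    g_star: NetworkGraph,
    m_star: NetworkGraph,
    informative_mean: float = 0.8,
    concentration: float = 10.0,
) -> EdgePriorSpec:
    """Combine screened masks into the data-driven (BMRF.P) prior.

    Candidate pairs are G* u M*; pairs in G* ^ M* get an informative
    Beta prior with the given mean and concentration a+b (mean 0.8 and
    concentration 10 give Beta(8,2)); the remaining candidates keep the
    flat Beta(1,1), mean 0.5.
    """
    if not 0.5 < informative_mean < 1.0:
        raise ValueError("informative_mean must lie in (0.5, 1)")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    cand = g_star.union(m_star)
    inf = g_star.intersection(m_star)
    p = cand.p
    beta_a = np.ones((p, p))
    beta_b = np.ones((p, p))
    mask = inf.adjacency.astype(bool)
    beta_a[mask] = informative_mean * concentration
    beta_b[mask] = (1.0 - informative_mean) * concentration
    return EdgePriorSpec(
        candidate_mask=cand, informative_mask=inf, beta_a=beta_a, beta_b=beta_b
    )
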