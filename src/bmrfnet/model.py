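"""The BMRF model and results objects.

`BMRF` wraps an expression matrix together with its edge priors and
spike-and-slab settings; `fit()` runs the Gibbs sampler and returns a
`BMRFResults` carrying posterior edge-existence probabilities, strength
summaries with credible intervals, diagnostics and a `summary()` table.

    >>> model = BMRF.from_dataframe(df)              # n samples x p genes
    >>> res = model.fit(seed=1)
    >>> res.summary()                                # top edges by probability
    >>> net = res.select_network(threshold=0.5)      # binary adjacency
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gaussian import ExpressionMatrix, standardize
from .networks import NetworkGraph
from .priors import EdgePriorSpec
from .sampler import (
    EdgePosterior,
    MCMCConfig,
    PosteriorSamples,
    SSLPrior,
    run_mcmc,
    select_network,
    summarize_edges,
)

__all__ = ["BMRF", "BMRFResults"]


class BMRF:
    """Bayesian Markov random field for probabilistic gene-network inference.

    Parameters
    ----------
    data
        Expression values, samples in rows and genes in columns; an
        `ExpressionMatrix`, a pandas DataFrame or a plain array.
        Standardized automatically unless already flagged.
    priors
        Per-edge inclusion priors and candidate masks.  Defaults to flat
        Beta(1,1) priors on every pair.
    ssl
        Spike-and-slab lasso rates (slab tau1=2, spike tau0=20).
    """

    def __init__(
        self,
        data,
        priors: EdgePriorSpec | None = None,
        ssl: SSLPrior | None = None,
    ):
        if isinstance(data, pd.DataFrame):
            data = ExpressionMatrix.from_dataframe(data)
        elif not isinstance(data, ExpressionMatrix):
            data = ExpressionMatrix(np.asarray(data, dtype=float))
        if not data.standardized:
            data = standardize(data)
        self.data = data
        self.priors = priors or EdgePriorSpec.noninformative(data.n_genes)
        if self.priors.p != data.n_genes:
            raise ValueError(
                f"priors are for {self.priors.p} genes, data has {data.n_genes}"
            )
        self.ssl = ssl or SSLPrior()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "BMRF":
        return cls(df, **kwargs)

    @property
    def exog_names(self) -> list[str]:
        return list(self.data.gene_ids)

    def fit(
        self,
        n_iter: int = 10_000,
        burn_in: int = 5_000,
        thin: int = 1,
        seed: int = 0,
        beta_update: str = "exact_gibbs",
        threshold: float = 0.5,
    ) -> "BMRFResults":
        """Sample the posterior and summarize it.

        ``threshold`` is the existence-probability cut-off used for the
        default network selection (an edge is reported when
        P(gamma_jk = 1 | data) exceeds it).
        """
        config = MCMCConfig(
            n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed, beta_update=beta_update
        )
        samples = run_mcmc(self.data, self.priors, ssl=self.ssl, config=config)
        edges = summarize_edges(samples, threshold=threshold)
        return BMRFResults(self, samples, edges)


class BMRFResults:
    """Posterior summaries from a fitted BMRF model."""

    def __init__(self, model: BMRF, samples: PosteriorSamples, edges: EdgePosterior):
        self.model = model
        self.samples = samples
        self.edges = edges

    @property
    def threshold(self) -> float:
        return self.edges.threshold

    @property
    def existence_probabilities(self) -> np.ndarray:
        """Symmetric p x p matrix of posterior edge probabilities."""
        return self.edges.probability_matrix()

    @property
    def edge_table(self) -> pd.DataFrame:
        """Per-pair summaries sorted by descending existence probability."""
        cols = [
            "gene_i",
            "gene_j",
            "existence_probability",
            "beta_mean",
            "beta_q025",
            "beta_median",
            "beta_q975",
            "selected",
        ]
        return (
            self.edges.table[cols]
            .sort_values("existence_probability", ascending=False, kind="stable")
            .reset_index(drop=True)
        )

    def select_network(self, threshold: float | None = None) -> NetworkGraph:
        """Binary network of edges whose probability exceeds the threshold."""
        if threshold is None:
            return select_network(self.edges)
        return select_network(summarize_edges(self.samples, threshold=threshold))

    def summary(self, top: int = 10) -> str:
        """Readable overview: fit configuration and the strongest edges."""
        cfg = self.samples.config
        tab = self.edge_table
        lines = [
            "Bayesian Markov random field (CAR + spike-and-slab lasso)",
            "=" * 60,
            f"genes: {len(self.samples.gene_ids)}   samples: {self.model.data.n_samples}"
            f"   candidate pairs: {self.samples.n_pairs}",
            f"slab/spike rates: tau1={self.samples.ssl.tau1}, tau0={self.samples.ssl.tau0}",
            f"iterations: {cfg.n_iter} (burn-in {cfg.burn_in}, thin {cfg.thin}, "
            f"seed {cfg.seed}, {cfg.beta_update})",
            f"edges selected at probability > {self.threshold}: {self.edges.n_selected}",
            "-" * 60,
            f"top {min(top, len(tab))} edges by existence probability:",
            tab.head(top).to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}",
            ),
        ]
        return "\n".join(lines)

    def plot_edge_probabilities(self, ax=None):
        """Ordered existence probabilities of all candidate edges."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        probs = np.sort(
            self.edges.table["existence_probability"].to_numpy()
        )[::-1]
        ax.plot(np.arange(1, probs.size + 1), probs, marker=".", lw=1)
        ax.axhline(self.threshold, color="grey", ls="--", lw=1)
        ax.set_xlabel("edge rank")
        ax.set_ylabel("posterior existence probability")
        return ax

    def __repr__(self) -> str:
        return (
            f"<BMRFResults: {self.samples.n_pairs} candidate pairs, "
            f"{self.edges.n_selected} selected at >{self.threshold}>"
        )
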