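"""Gaussian graphical model algebra.

A Gaussian graphical model (GGM) represents a set of p genes as a
multivariate normal vector whose precision matrix Omega (the inverse
covariance) encodes the network: a zero off-diagonal entry omega_jk means
genes j and k are conditionally independent given the rest, i.e. there is
no edge between them.  The same model can be written conditionally, one
gene at a time, as a Gaussian conditional autoregression (CAR):

    X_j | X_(-j)  ~  N( sum_{k != j} beta_jk X_k ,  sigma_j^2 )

with beta_jk = -omega_jk / omega_jj and sigma_j^2 = 1 / omega_jj.  The
CAR coefficients beta_jk are the "edge strengths" this package infers;
beta_jk = 0 exactly when the partial correlation
rho_jk = -omega_jk / sqrt(omega_jj omega_kk) is zero, i.e. when the edge
is absent.  When Omega has a constant diagonal the coefficient matrix is
symmetric, so each unordered pair carries a single strength parameter.

This module holds the containers for expression data and the precision /
partial-correlation / CAR parameterisations, the exact conversions
between them, multivariate-normal data generation, and per-gene
standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular

__all__ = [
    "ExpressionMatrix",
    "PrecisionMatrix",
    "PartialCorrelationMatrix",
    "CARParameters",
    "precision_to_car",
    "precision_to_partial_corr",
    "sample_mvn",
    "standardize",
]

#: absolute tolerance for symmetry of precision matrices
SYMMETRY_TOL = 1e-10


def _as_float_matrix(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    return a


def _default_labels(prefix: str, k: int) -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(k)]


@dataclass
class ExpressionMatrix:
    """An n x p matrix of expression values (samples in rows, genes in columns)."""

    values: np.ndarray
    gene_ids: list[str] = None
    sample_ids: list[str] = None
    standardized: bool = False

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-d array")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 samples and 2 genes, got n={n}, p={p}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain NaN or infinite entries")
        if self.gene_ids is None:
            self.gene_ids = _default_labels("G", p)
        if self.sample_ids is None:
            self.sample_ids = _default_labels("S", n)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match number of columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        if len(set(self.gene_ids)) != p:
            dup = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dup}")
        if self.standardized:
            self._check_standardized()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def _check_standardized(self, atol: float = 1e-8) -> None:
        mu = self.values.mean(axis=0)
        var = self.values.var(axis=0, ddof=1)
        if np.max(np.abs(mu)) > atol or np.max(np.abs(var - 1.0)) > atol:
            raise ValueError(
                "matrix flagged standardized but columns are not mean-0 / variance-1"
            )

    @classmethod
    def from_dataframe(cls, df, standardized: bool = False) -> "ExpressionMatrix":
        import pandas as pd  # local: keeps numpy-only paths light

        if not isinstance(df, pd.DataFrame):
            raise TypeError("expected a pandas DataFrame")
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(c) for c in df.columns],
            sample_ids=[str(i) for i in df.index],
            standardized=standardized,
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class PrecisionMatrix:
    """Symmetric positive-definite precision matrix Omega of a GGM."""

    omega: np.ndarray

    def __post_init__(self):
        self.omega = _as_float_matrix(self.omega, "omega")
        self.validate()

    def validate(self) -> None:
        om = self.omega
        asym = np.max(np.abs(om - om.T)) if om.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"precision matrix is not symmetric (max |w_jk - w_kj| = {asym:.3g})"
            )
        if np.any(np.diag(om) <= 0):
            raise ValueError("precision matrix has a non-positive diagonal entry")
        lam_min = float(np.linalg.eigvalsh(om)[0])
        if lam_min <= 0:
            raise ValueError(
                f"precision matrix is not positive definite (lambda_min = {lam_min:.3g})"
            )

    @property
    def p(self) -> int:
        return self.omega.shape[0]


@dataclass
class PartialCorrelationMatrix:
    """Matrix of partial correlations rho_jk = -omega_jk / sqrt(omega_jj omega_kk)."""

    rho: np.ndarray

    def __post_init__(self):
        self.rho = _as_float_matrix(self.rho, "rho")
        if np.max(np.abs(self.rho - self.rho.T)) > SYMMETRY_TOL:
            raise ValueError("partial correlation matrix is not symmetric")
        if np.max(np.abs(np.diag(self.rho) - 1.0)) > 1e-10:
            raise ValueError("partial correlation matrix must have unit diagonal")
        if np.max(np.abs(self.rho)) > 1.0 + 1e-10:
            raise ValueError("partial correlations must lie in [-1, 1]")


@dataclass
class CARParameters:
    """CAR strength coefficients beta (zero diagonal) and conditional variances."""

    beta: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self):
        self.beta = _as_float_matrix(self.beta, "beta")
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if np.any(np.diag(self.beta) != 0.0):
            raise ValueError("CAR coefficient matrix must have an exactly zero diagonal")
        if self.sigma2.shape != (self.beta.shape[0],):
            raise ValueError("sigma2 must be a p-vector matching beta")
        if np.any(self.sigma2 <= 0):
            raise ValueError("conditional variances must be strictly positive")


def precision_to_car(omega: PrecisionMatrix) -> CARParameters:
    """Convert a precision matrix to its CAR parameterisation.

    beta_jk = -omega_jk / omega_jj for j != k, and sigma_j^2 = 1/omega_jj:
    the unique coefficients for which the node-wise Gaussian conditionals
    are exactly the conditionals of MVN(0, Omega^{-1}).
    """
    om = omega.omega
    d = np.diag(om)
    beta = -om / d[:, None]
    np.fill_diagonal(beta, 0.0)
    return CARParameters(beta=beta, sigma2=1.0 / d)


def precision_to_partial_corr(omega: PrecisionMatrix) -> PartialCorrelationMatrix:
    """Partial correlations rho_jk = -omega_jk / sqrt(omega_jj * omega_kk)."""
    om = omega.omega
    d = np.sqrt(np.diag(om))
    rho = -om / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return PartialCorrelationMatrix(rho=rho)


def sample_mvn(
    omega: PrecisionMatrix,
    n: int,
    seed: int,
    gene_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """Draw n iid samples from MVN(0, Omega^{-1}).

    Uses the Cholesky factor L of Omega: if z ~ N(0, I) then z L^{-1} has
    covariance (L L^T)^{-1} = Omega^{-1}.  Reproducible given `seed`.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    try:
        L = cholesky(omega.omega, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - validate() catches first
        raise ValueError("precision matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, omega.p))
    # x = z @ L^{-1}  via triangular solve of L^T w = z^T
    x = solve_triangular(L, z.T, lower=True, trans="T").T
    return ExpressionMatrix(values=x, gene_ids=gene_ids)


def standardize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene to mean 0 and scale to unit sample variance (ddof=1).

    Raises if a gene is constant across samples (zero variance), naming it.
    """
    vals = x.values
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [x.gene_ids[i] for i in bad]
        raise ValueError(f"cannot standardize constant gene(s): {names}")
    out = (vals - mu) / sd
    return ExpressionMatrix(
        values=out,
        gene_ids=list(x.gene_ids),
        sample_ids=list(x.sample_ids),
        standardized=True,
    )
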