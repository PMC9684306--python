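"""Benchmark network simulators.

Three families of synthetic gene networks are provided, matching common
benchmarking practice for Gaussian graphical model structure learning:

* random (Erdos-Renyi style) networks with a given sparsity S, paired
  with diagonally-dominant random precision matrices;
* scale-free trees grown by preferential attachment (one edge per new
  node, so exactly p-1 edges and pronounced hubs);
* a fixed 50-node two-hub tree used for studying edge-probability
  calibration, with every edge's partial correlation set to -0.216.

All precision matrices produced here are symmetric positive definite
with unit diagonal; data are drawn from MVN(0, Omega^{-1}).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .gaussian import PrecisionMatrix

__all__ = [
    "NetworkGraph",
    "SimulationSetting",
    "PRESETS",
    "random_network",
    "random_precision",
    "scale_free_network",
    "homogeneous_precision",
    "m3_fixture",
]


@dataclass
class NetworkGraph:
    """Undirected graph as a symmetric 0/1 adjacency matrix with zero diagonal."""

    adjacency: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8)
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero (no self loops)")
        if np.any(a != a.T):
            raise ValueError("adjacency must be symmetric")
        self.adjacency = a

    @classmethod
    def empty(cls, p: int) -> "NetworkGraph":
        return cls(np.zeros((p, p), dtype=np.int8))

    @classmethod
    def from_edges(cls, p: int, edges) -> "NetworkGraph":
        a = np.zeros((p, p), dtype=np.int8)
        for j, k in edges:
            if j == k:
                raise ValueError(f"self loop ({j},{k}) not allowed")
            a[j, k] = a[k, j] = 1
        return cls(a)

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[int, int]]:
        j, k = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(j.tolist(), k.tolist()))

    def degree(self, node: int) -> int:
        if not 0 <= node < self.p:
            raise IndexError(f"node {node} outside 0..{self.p - 1}")
        return int(self.adjacency[node].sum())

    def union(self, other: "NetworkGraph") -> "NetworkGraph":
        self._check_same_size(other)
        return NetworkGraph(np.maximum(self.adjacency, other.adjacency))

    def intersection(self, other: "NetworkGraph") -> "NetworkGraph":
        self._check_same_size(other)
        return NetworkGraph(self.adjacency * other.adjacency)

    def _check_same_size(self, other: "NetworkGraph") -> None:
        if other.p != self.p:
            raise ValueError(f"graph size mismatch: {self.p} vs {other.p}")


@dataclass
class SimulationSetting:
    """One benchmark regime: node count, sparsity, sample size and family."""

    regime: str  # "M1", "M2" or "M3"
    p: int
    S: float = 0.0  # Bernoulli edge probability; used by M1 only
    n: int = 250

    def __post_init__(self):
        if self.regime not in {"M1", "M2", "M3"}:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.p < 2 or self.n < 2:
            raise ValueError("need p >= 2 and n >= 2")
        if not 0.0 <= self.S <= 1.0:
            raise ValueError("sparsity S must lie in [0, 1]")

    def simulate(self, seed: int) -> tuple[NetworkGraph, PrecisionMatrix]:
        """Draw (or build) the true graph and its precision matrix."""
        if self.regime == "M1":
            g = random_network(self.p, self.S, seed)
            return g, random_precision(g, seed + 1)
        if self.regime == "M2":
            g = scale_free_network(self.p, seed)
            return g, homogeneous_precision(g, -0.216)
        return m3_fixture()


#: the benchmark sub-settings (n = 250 everywhere)
PRESETS: dict[str, SimulationSetting] = {
    "M1.1": SimulationSetting("M1", p=25, S=0.05),
    "M1.2": SimulationSetting("M1", p=25, S=0.10),
    "M1.3": SimulationSetting("M1", p=50, S=0.05),
    "M1.4": SimulationSetting("M1", p=50, S=0.10),
    "M2.1": SimulationSetting("M2", p=25),
    "M2.2": SimulationSetting("M2", p=50),
    "M3": SimulationSetting("M3", p=50),
}


def random_network(p: int, S: float, seed: int) -> NetworkGraph:
    """Random graph: each unordered pair is an edge independently with prob S."""
    if not 0.0 <= S <= 1.0:
        raise ValueError("edge probability S must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((p, p)) < S, 1)
    return NetworkGraph((upper | upper.T).astype(np.int8))


def random_precision(graph: NetworkGraph, seed: int) -> PrecisionMatrix:
    """Random diagonally-dominant precision matrix supported on a graph.

    Edge entries are drawn uniformly on W = [-1,-0.05] u [0.05,1] (sign
    +/-1 with equal probability, magnitude U(0.05, 1)); each row's
    off-diagonal entries are then divided by 1.5x the row's absolute sum,
    and the matrix is averaged with its transpose.  The rescaling makes
    every row strictly diagonally dominant (off-diagonal absolute sum
    2/3 < 1 against a unit diagonal), which guarantees positive
    definiteness and is preserved by the symmetrization.
    """
    p = graph.p
    rng = np.random.default_rng(seed)
    a = graph.adjacency.astype(float)
    sign = np.where(rng.random((p, p)) < 0.5, -1.0, 1.0)
    mag = rng.uniform(0.05, 1.0, size=(p, p))
    om = a * sign * mag
    # draws must agree across the diagonal before row-rescaling breaks symmetry
    om = np.triu(om, 1)
    om = om + om.T
    row_abs = np.abs(om).sum(axis=1)
    scale = 1.5 * row_abs
    with np.errstate(invalid="ignore"):
        om = np.where(scale[:, None] > 0, om / scale[:, None], 0.0)
    om = 0.5 * (om + om.T)
    np.fill_diagonal(om, 1.0)
    return PrecisionMatrix(om)


def scale_free_network(p: int, seed: int) -> NetworkGraph:
    """Preferential-attachment tree (Barabasi-Albert, m=1): exactly p-1 edges."""
    if p < 2:
        raise ValueError("need p >= 2")
    g = nx.barabasi_albert_graph(p, 1, seed=int(seed))
    a = nx.to_numpy_array(g, nodelist=range(p), dtype=np.int8)
    return NetworkGraph(a)


def homogeneous_precision(graph: NetworkGraph, rho_target: float) -> PrecisionMatrix:
    """Unit-diagonal precision giving every edge the same partial correlation.

    Omega = I + |rho| * A yields rho_jk = -omega_jk = rho_target on edges
    (taking omega_jk = |rho_target| with the sign chosen so that the
    partial correlation equals rho_target) and 0 elsewhere.  Positive
    definiteness requires |rho_target| < 1/|lambda_min(A)|, which is
    checked and reported.
    """
    p = graph.p
    if rho_target == 0.0:
        return PrecisionMatrix(np.eye(p))
    if not abs(rho_target) < 1.0:
        raise ValueError("|rho_target| must be < 1")
    a = graph.adjacency.astype(float)
    s = np.sign(rho_target)
    lam = np.linalg.eigvalsh(a)
    # Omega = I - s|rho|A is PD iff s*lambda_i(A) < 1/|rho| for every eigenvalue
    lam_crit = float(np.max(s * lam))
    if lam_crit > 0 and abs(rho_target) >= 1.0 / lam_crit:
        raise ValueError(
            f"rho_target={rho_target} infeasible: critical adjacency eigenvalue "
            f"{lam_crit:.4f} requires |rho| < {1.0 / lam_crit:.4f} for positive "
            "definiteness"
        )
    om = np.eye(p) - s * abs(rho_target) * a
    return PrecisionMatrix(om)


def _m3_graph() -> NetworkGraph:
    """Deterministic 50-node two-hub tree: deg(node index 1) = 14, deg(3) = 7.

    Construction: hub A (index 1) and hub B (index 3) are joined through
    the intermediate node 0 (keeping the hubs non-adjacent, which keeps
    the adjacency spectrum small enough for the -0.216 edge strength);
    13 further leaves attach to A and 6 to B; the remaining 28 nodes
    attach one at a time by preferential attachment over non-hub nodes,
    with a fixed seed.
    """
    p, hub_a, hub_b = 50, 1, 3
    edges = [(0, hub_a), (0, hub_b)]
    # nodes 2, 4..15 -> hub A (13 leaves, degree 14 with node 0)
    leaves_a = [2] + list(range(4, 16))
    edges += [(hub_a, v) for v in leaves_a]
    # nodes 16..21 -> hub B (6 leaves, degree 7 with node 0)
    leaves_b = list(range(16, 22))
    edges += [(hub_b, v) for v in leaves_b]
    rng = np.random.default_rng(20221110)
    degree = np.zeros(p, dtype=float)
    for j, k in edges:
        degree[j] += 1
        degree[k] += 1
    attached = [0] + leaves_a + leaves_b
    for v in range(22, p):
        w = degree[attached]
        target = int(rng.choice(attached, p=w / w.sum()))
        edges.append((target, v))
        degree[target] += 1
        degree[v] += 1
        attached.append(v)
    return NetworkGraph.from_edges(p, edges)


_M3_RHO = -0.216


def m3_fixture() -> tuple[NetworkGraph, PrecisionMatrix]:
    """The fixed 50-node, 49-edge two-hub benchmark network.

    Hub "Node-2" (index 1) has degree 14 and hub "Node-4" (index 3) has
    degree 7; every edge's partial correlation is exactly -0.216.
    """
    g = _m3_graph()
    return g, homogeneous_precision(g, _M3_RHO)
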