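"""File formats and run configuration.

Plain-text formats only: expression matrices as delimited text (tab or
comma, auto-detected) with gene identifiers in the header row and one
sample per row; graphs either as 2-column edge lists (TSV) or square 0/1
CSV adjacency matrices with gene ids on both margins; edge tables as TSV
sorted by descending existence probability.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .gaussian import ExpressionMatrix
from .networks import NetworkGraph
from .sampler import EdgePosterior

__all__ = [
    "read_expression",
    "write_expression",
    "write_edge_table",
    "read_edge_table",
    "read_graph",
    "write_graph_edges",
    "write_adjacency_csv",
    "RunConfig",
    "end_to_end",
]


def _detect_delimiter(path: Path) -> str:
    head = path.open().readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_expression(path) -> ExpressionMatrix:
    """Read a delimited expression matrix (header of gene ids, numeric body)."""
    path = Path(path)
    sep = _detect_delimiter(path)
    header = path.open().readline().rstrip("\n").split(sep)
    dup = sorted({g for g in header if header.count(g) > 1})
    if dup:
        raise ValueError(f"duplicate gene ids in header of {path}: {dup}")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric expression column(s) in {path}: {bad}")
    if df.isna().any().any():
        cells = df.isna().stack()
        first = cells[cells].index[0]
        raise ValueError(f"missing value in {path} at row {first[0]}, gene {first[1]!r}")
    return ExpressionMatrix.from_dataframe(df)


def write_expression(x: ExpressionMatrix, path) -> None:
    x.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")


EDGE_TABLE_COLUMNS = [
    "gene_i",
    "gene_j",
    "existence_probability",
    "beta_mean",
    "beta_q025",
    "beta_median",
    "beta_q975",
    "selected",
]


def write_edge_table(edges: EdgePosterior, path) -> None:
    """Write per-edge posterior summaries, sorted by descending probability."""
    tab = (
        edges.table[EDGE_TABLE_COLUMNS]
        .sort_values("existence_probability", ascending=False, kind="stable")
    )
    tab.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_edge_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def _gene_index(gene_ids: list[str]) -> dict[str, int]:
    return {g: i for i, g in enumerate(gene_ids)}


def read_graph(path, gene_ids: list[str]) -> NetworkGraph:
    """Read a graph as either a 2-column edge list (TSV) or a square 0/1 CSV.

    A file whose header starts with an empty first field (or whose first
    column repeats the gene ids) is treated as a square adjacency matrix.
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    p = len(gene_ids)
    if list(df.columns) == list(gene_ids):
        if list(df.index) != list(gene_ids):
            raise ValueError(f"adjacency row labels in {path} do not match gene ids")
        return NetworkGraph(df.to_numpy())
    # else: edge list; re-read without index column
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError(f"{path} is neither an adjacency matrix nor an edge list")
    idx = _gene_index(gene_ids)
    edges = []
    for a, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        for g in (a, b):
            if str(g) not in idx:
                raise ValueError(f"unknown gene id {g!r} in {path}")
        edges.append((idx[str(a)], idx[str(b)]))
    return NetworkGraph.from_edges(p, edges)


def write_graph_edges(graph: NetworkGraph, gene_ids: list[str], path) -> None:
    """Write a graph as a 2-column TSV of lexicographically sorted gene pairs."""
    rows = sorted(
        tuple(sorted((gene_ids[j], gene_ids[k]))) for j, k in graph.edges()
    )
    pd.DataFrame(rows, columns=["gene_i", "gene_j"]).to_csv(path, sep="\t", index=False)


def write_adjacency_csv(matrix: np.ndarray, gene_ids: list[str], path) -> None:
    """Write a square matrix as CSV with gene ids on both margins."""
    pd.DataFrame(matrix, index=gene_ids, columns=gene_ids).to_csv(path)


_CONFIG_TYPES = {
    "input": str,
    "output_dir": str,
    "mode": str,  # "BMRF.O" or "BMRF.P"
    "tau1": float,
    "tau0": float,
    "n_iter": int,
    "burn_in": int,
    "thin": int,
    "seed": int,
    "threshold": float,
    "top_fraction": float,
    "lasso_penalty": float,
    "informative_mean": float,
    "concentration": float,
    "g_star": str,
    "m_star": str,
    "truth": str,
}


@dataclass
class RunConfig:
    """Flat key=value run configuration for the end-to-end workflow."""

    input: str
    output_dir: str
    mode: str = "BMRF.O"
    tau1: float = 2.0
    tau0: float = 20.0
    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 1
    seed: int = 0
    threshold: float = 0.5
    top_fraction: float = 0.10
    lasso_penalty: float | None = None
    informative_mean: float = 0.8
    concentration: float = 10.0
    g_star: str | None = None  # optional user-supplied candidate mask file
    m_star: str | None = None  # optional user-supplied interest mask file
    truth: str | None = None  # optional true graph for evaluation

    def __post_init__(self):
        if self.mode not in {"BMRF.O", "BMRF.P"}:
            raise ValueError("mode must be 'BMRF.O' or 'BMRF.P'")
        if not Path(self.input).exists():
            raise FileNotFoundError(f"input file not found: {self.input}")
        for name in ("g_star", "m_star", "truth"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{name} file not found: {val}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` text file; unrecognized keys are errors."""
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = (s.strip() for s in line.partition("="))
            if key not in _CONFIG_TYPES:
                raise ValueError(f"{path}:{lineno}: unrecognized key {key!r}")
            kwargs[key] = _CONFIG_TYPES[key](value)
        return cls(**kwargs)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def end_to_end(config: RunConfig) -> dict:
    """Run screening (if BMRF.P), fitting, summarization and optional
    evaluation; write all artifacts plus a reproducibility manifest.

    Returns a dict of the paths written.
    """
    from . import __version__
    from .model import BMRF
    from .priors import EdgePriorSpec, build_edge_priors, screen_correlation, screen_neighborhood
    from .evaluation import brier_score, confusion_metrics

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = lambda msg: print(f"[bmrfnet] {msg}", file=sys.stderr)  # noqa: E731

    stage = "read"
    artifacts: dict[str, str] = {}
    try:
        x = read_expression(config.input)
        from .gaussian import standardize

        x = standardize(x)

        stage = "screen"
        if config.g_star:
            g_star = read_graph(config.g_star, x.gene_ids)
        else:
            g_star = screen_correlation(x, config.top_fraction)
        if config.mode == "BMRF.P":
            if config.m_star:
                m_star = read_graph(config.m_star, x.gene_ids)
            else:
                m_star = screen_neighborhood(x, penalty=config.lasso_penalty)
            priors = build_edge_priors(
                g_star,
                m_star,
                informative_mean=config.informative_mean,
                concentration=config.concentration,
            )
            log(
                f"screen: |G*|={g_star.n_edges} |M*|={m_star.n_edges} "
                f"informative |G* ^ M*|={priors.informative_mask.n_edges}"
            )
            write_graph_edges(m_star, x.gene_ids, out / "m_star.tsv")
            artifacts["m_star"] = str(out / "m_star.tsv")
        else:
            priors = EdgePriorSpec.noninformative(x.n_genes, candidate_mask=g_star)
            log(f"screen: |G*|={g_star.n_edges} candidate pairs")
        write_graph_edges(g_star, x.gene_ids, out / "g_star.tsv")
        artifacts["g_star"] = str(out / "g_star.tsv")

        stage = "fit"
        from .sampler import SSLPrior

        model = BMRF(x, priors=priors, ssl=SSLPrior(config.tau1, config.tau0))
        res = model.fit(
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            thin=config.thin,
            seed=config.seed,
            threshold=config.threshold,
        )
        log(
            f"fit: {res.samples.n_pairs} candidate pairs, "
            f"{res.edges.n_selected} edges at >{config.threshold}, "
            f"final log pseudo-likelihood {res.samples.loglik_trace[-1]:.2f}"
        )

        stage = "write"
        write_edge_table(res.edges, out / "edges.tsv")
        artifacts["edges"] = str(out / "edges.tsv")
        net = res.select_network()
        write_graph_edges(net, x.gene_ids, out / "network.tsv")
        artifacts["network"] = str(out / "network.tsv")

        if config.truth:
            stage = "evaluate"
            truth = read_graph(config.truth, x.gene_ids)
            report = confusion_metrics(net, truth).as_dict()
            report["brier"] = brier_score(res.edges, truth)
            (out / "report.json").write_text(json.dumps(report, indent=2))
            artifacts["report"] = str(out / "report.json")
            log(f"evaluate: F1={report['F1']:.3f} brier={report['brier']:.4f}")

        manifest = {
            "package": "bmrfnet",
            "version": __version__,
            "config": config.as_dict(),
            "artifacts": artifacts,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        artifacts["manifest"] = str(out / "manifest.json")
        return artifacts
    except Exception as exc:
        raise RuntimeError(f"workflow failed at stage {stage!r}: {exc}") from exc
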