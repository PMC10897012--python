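"""Topology statistics and centrality scores for comorbidity networks.

The summary row per network carries node/link counts, average neighbors
(2L/n), mean local clustering, Freeman degree centralization and density —
all on the unweighted topology. PageRank is the one score that uses the MI
edge weights: the random walker moves along edges with probability
proportional to MI, so strongly comorbid neighborhoods concentrate score,
and a disease's PageRank measures its overall comorbidity burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .inference import ComorbidityNetwork

__all__ = [
    "NetworkSummary",
    "PageRankConvergenceError",
    "summarize",
    "degree_centralization",
    "pagerank",
    "betweenness",
    "closeness",
    "top_k",
    "rank_table",
]

SUMMARY_COLUMNS = [
    "stratum",
    "nodes",
    "links",
    "avg_neighbors",
    "clustering_coefficient",
    "centralization",
    "density",
]


@dataclass(frozen=True)
class NetworkSummary:
    """One network's topology row (all zeros for an empty network)."""

    stratum: str | None
    nodes: int
    links: int
    avg_neighbors: float
    clustering_coefficient: float
    centralization: float
    density: float

    def to_row(self) -> dict:
        return {c: getattr(self, c) for c in SUMMARY_COLUMNS}


class PageRankConvergenceError(RuntimeError):
    """Power iteration failed to converge; carries the last iterate and residual."""

    def __init__(self, message: str, scores: Mapping[str, float], residual: float):
        super().__init__(message)
        self.scores = dict(scores)
        self.residual = residual


def _graph_of(network) -> nx.Graph:
    return network.graph if isinstance(network, ComorbidityNetwork) else network


def degree_centralization(graph: nx.Graph) -> float:
    """Freeman degree centralization, sum(d_max - d_i) / ((N-1)(N-2)).

    1 for a star (N >= 3), 0 for regular graphs; defined as 0 for N < 3.
    """
    n = graph.number_of_nodes()
    if n < 3:
        return 0.0
    degrees = np.array([d for _, d in graph.degree()])
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def summarize(network) -> NetworkSummary:
    """Topology summary of one network (Table-1-style row)."""
    G = _graph_of(network)
    stratum = network.stratum if isinstance(network, ComorbidityNetwork) else None
    n, m = G.number_of_nodes(), G.number_of_edges()
    if n == 0:
        return NetworkSummary(stratum, 0, 0, 0.0, 0.0, 0.0, 0.0)
    # nx.clustering is 0 for degree < 2, so the mean counts those nodes as 0
    clustering = float(nx.average_clustering(G)) if n > 0 else 0.0
    return NetworkSummary(
        stratum=stratum,
        nodes=n,
        links=m,
        avg_neighbors=2.0 * m / n,
        clustering_coefficient=clustering,
        centralization=degree_centralization(G),
        density=float(nx.density(G)),
    )


def pagerank(
    network,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 200,
    weight: str | None = "mi",
) -> dict[str, float]:
    """Weighted PageRank by dense power iteration.

    The undirected graph is treated as bidirected; transition probability
    from a node is proportional to the incident edge weight (``weight=None``
    gives the unweighted walk). Teleportation is uniform with probability
    1 - damping. Converged when the L1 change falls below ``tol``; the
    scores sum to 1. Output is invariant under node relabeling (nodes are
    processed in sorted order).

    Raises
    ------
    PageRankConvergenceError
        After ``max_iter`` sweeps, carrying the last iterate and residual.
    """
    G = _graph_of(network)
    nodes = sorted(G.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("pagerank of an empty network is undefined")
    W = nx.to_numpy_array(G, nodelist=nodes, weight=weight)
    strength = W.sum(axis=1)
    dangling = strength == 0.0
    P = np.divide(W, np.where(dangling, 1.0, strength)[:, None])
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = damping * (P.T @ x + x[dangling].sum() / n) + (1.0 - damping) / n
        residual = float(np.abs(x_new - x).sum())
        x = x_new
        if residual < tol:
            return dict(zip(nodes, x / x.sum()))
    raise PageRankConvergenceError(
        f"power iteration did not converge in {max_iter} sweeps (residual {residual:.3e})",
        scores=dict(zip(nodes, x)),
        residual=residual,
    )


def betweenness(network) -> dict[str, float]:
    """Shortest-path betweenness on the unweighted topology (hop counts).

    Normalized by (N-1)(N-2)/2; contributions split equally among
    equal-length shortest paths.
    """
    return dict(nx.betweenness_centrality(_graph_of(network), normalized=True))


def closeness(network) -> dict[str, float]:
    """Per-component closeness, (n_comp - 1) / sum of hop distances."""
    return dict(nx.closeness_centrality(_graph_of(network), wf_improved=False))


def top_k(scores: Mapping[str, float], k: int) -> list[tuple[str, float]]:
    """Top-k entries by descending score, ties broken by code lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:k]


def rank_table(
    network,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Per-node centrality table sorted like the top-k ranking.

    Columns: code, pagerank, betweenness, closeness, degree; rows in
    descending PageRank order (ties by code).
    """
    G = _graph_of(network)
    if G.number_of_nodes() == 0:
        return pd.DataFrame(
            columns=["code", "pagerank", "betweenness", "closeness", "degree"]
        )
    pr = pagerank(network, damping=damping, tol=tol, max_iter=max_iter)
    bc = betweenness(network)
    cc = closeness(network)
    deg = dict(G.degree())
    order = top_k(pr, len(pr))
    return pd.DataFrame(
        {
            "code": [c for c, _ in order],
            "pagerank": [s for _, s in order],
            "betweenness": [bc[c] for c, _ in order],
            "closeness": [cc[c] for c, _ in order],
            "degree": [deg[c] for c, _ in order],
        }
    )
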