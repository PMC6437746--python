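"""Topological statistics of the gene networks.

Node-level: degree, betweenness (Brandes' algorithm, unordered-pair
convention, both raw and normalized), closeness (reciprocal of the mean
shortest-path distance) and farness (the raw sum of distances).  Network
level: density, degree heterogeneity (coefficient of variation of the degree
distribution), mean local clustering coefficient, diameter, Freeman-style
degree centralization, the count of finite ordered shortest paths, and the
characteristic path length.  Edges are treated as unweighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NetworkMetrics",
    "degree",
    "betweenness",
    "closeness",
    "node_metrics",
    "network_metrics",
]


@dataclass
class NetworkMetrics:
    """Whole-network statistics (density, heterogeneity, clustering,
    diameter, centralization, shortest-path count, characteristic path
    length); distance-based fields are None for edgeless graphs and are
    computed over finite distances only when the graph is disconnected."""

    n_nodes: int
    n_edges: int
    density: float
    heterogeneity: float
    clustering_coefficient: float
    diameter: int | None
    centralization: float | None
    shortest_paths: int
    characteristic_path_length: float | None
    connected: bool

    def as_row(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def _require_node(g: nx.Graph, v) -> None:
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")


def degree(g: nx.Graph, v) -> int:
    """Number of edges incident to ``v``."""
    _require_node(g, v)
    return int(g.degree(v))


def betweenness(g: nx.Graph, v) -> float:
    """Raw betweenness of ``v``: the sum over unordered node pairs {s, t}
    (both distinct from v) of the fraction of shortest s-t paths through v."""
    _require_node(g, v)
    return float(nx.betweenness_centrality(g, normalized=False)[v])


def closeness(g: nx.Graph, v) -> tuple[float, float]:
    """(closeness, farness) of ``v`` within its connected component.

    Farness is the sum of shortest-path distances from v to every reachable
    node; closeness is the reachable count divided by farness, i.e. the
    reciprocal of the mean distance.  Undefined (raises) for isolated nodes.
    """
    _require_node(g, v)
    dist = nx.single_source_shortest_path_length(g, v)
    del dist[v]
    if not dist:
        raise ValueError(f"closeness undefined for isolated node {v!r}")
    farness = float(sum(dist.values()))
    return len(dist) / farness, farness


def node_metrics(g: nx.Graph) -> pd.DataFrame:
    """Per-node metrics table: degree, raw and normalized betweenness,
    closeness and farness (NaN closeness/farness for isolated nodes)."""
    n = g.number_of_nodes()
    btw = nx.betweenness_centrality(g, normalized=False)
    norm = (n - 1) * (n - 2) / 2.0 if n >= 3 else math.nan
    rows = []
    for v in g.nodes():
        try:
            clo, far = closeness(g, v)
        except ValueError:
            clo, far = math.nan, math.nan
        rows.append(
            {
                "node_id": v,
                "degree": int(g.degree(v)),
                "betweenness": btw[v],
                "betweenness_normalized": btw[v] / norm if norm else math.nan,
                "closeness": clo,
                "farness": far,
            }
        )
    return pd.DataFrame(rows)


def network_metrics(g: nx.Graph) -> NetworkMetrics:
    """Whole-network statistics.

    density = 2E / (N(N-1)); heterogeneity = sd(degree)/mean(degree)
    (population variance); clustering = mean local clustering with
    degree-<2 nodes contributing 0; centralization =
    (N/(N-2)) (max_degree/(N-1) - density), defined for N >= 3;
    shortest_paths counts ordered pairs (s, t), s != t, at finite distance,
    and the characteristic path length averages over those pairs.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("network metrics require at least two nodes")
    e = g.number_of_edges()
    degs = np.array([d for _, d in g.degree()], dtype=float)
    density = 2.0 * e / (n * (n - 1))
    mean_deg = degs.mean()
    heterogeneity = float(degs.std() / mean_deg) if mean_deg > 0 else 0.0
    clustering = float(nx.average_clustering(g)) if e else 0.0
    centralization = (
        (n / (n - 2.0)) * (degs.max() / (n - 1.0) - density) if n >= 3 else None
    )

    diameter: int | None = None
    cpl: float | None = None
    n_paths = 0
    if e:
        total = 0
        longest = 0
        for _, dist in nx.all_pairs_shortest_path_length(g):
            for d in dist.values():
                if d > 0:
                    n_paths += 1
                    total += d
                    if d > longest:
                        longest = d
        if n_paths:
            diameter = longest
            cpl = total / n_paths
    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        density=density,
        heterogeneity=heterogeneity,
        clustering_coefficient=clustering,
        diameter=diameter,
        centralization=centralization,
        shortest_paths=n_paths,
        characteristic_path_length=cpl,
        connected=nx.is_connected(g) if n else False,
    )
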