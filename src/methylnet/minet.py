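"""Mutual-information network construction over gene methylation profiles.

Each gene's methylation profile across samples is discretized into equal-width
bins and the plug-in (maximum-likelihood) mutual information, in nats, is
estimated for every unordered pair from the joint frequency table:

    MI(X, Y) = sum_{x,y} p(x,y) ln[ p(x,y) / (p(x) p(y)) ]

Pairs with MI above the threshold (default 0, i.e. any detected dependence)
become edges of an undirected weighted network, one network per gene class.
The plug-in estimator makes MI exactly zero attainable whenever the empirical
joint factorizes, which is what allows the networks to be sparse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .synthetic import MethylationMatrix

__all__ = [
    "MIMatrix",
    "discretize",
    "estimate_mi",
    "build_mi_matrix",
    "threshold_network",
    "average_mi",
    "default_n_bins",
    "write_edge_list",
    "read_edge_list",
    "write_sif",
    "read_sif",
]

#: Edges whose MI is below this are treated as exact zeros (floating-point
#: phantom dependence).
MI_TOL = 1e-12


@dataclass
class MIMatrix:
    """Symmetric matrix of pairwise MI estimates with a zero diagonal."""

    node_ids: list[str]
    values: np.ndarray
    estimator_tag: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.node_ids), len(self.node_ids)):
            raise ValueError("MI matrix shape does not match node list")
        self.values = v


def default_n_bins(n_samples: int) -> int:
    """Equal-width bin count: ceil(sqrt(n_samples)), never below 2."""
    return max(2, math.ceil(math.sqrt(n_samples)))


def discretize(profile: np.ndarray, n_bins: int) -> np.ndarray:
    """Map a profile onto ``n_bins`` equal-width bins spanning [min, max].

    Interior bin edges are right-closed, so a value sitting exactly on an
    edge falls into the lower bin; constant profiles map to a single bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    x = np.asarray(profile, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretize an empty profile")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return np.zeros(x.shape, dtype=np.intp)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.digitize(x, edges[1:-1], right=True)


def estimate_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two equal-length label vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def build_mi_matrix(matrix: MethylationMatrix, n_bins: int | None = None) -> MIMatrix:
    """Pairwise plug-in MI over all genes of one class.

    Each gene's profile is discretized independently (equal-width bins over
    its own range) before the joint tables are formed.
    """
    vals = matrix.values.to_numpy(dtype=float)
    n_nodes, n_samples = vals.shape
    if n_nodes < 2:
        raise ValueError("need at least two genes to build an MI matrix")
    if n_samples < 3:
        raise ValueError("need at least three samples to estimate MI")
    if np.isnan(vals).any():
        raise ValueError("MI estimation requires complete profiles; drop missing rows first")
    bins = n_bins if n_bins is not None else default_n_bins(n_samples)
    labels = np.vstack([discretize(row, bins) for row in vals])
    n = n_nodes
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = estimate_mi(labels[i], labels[j])
    return MIMatrix(
        node_ids=list(matrix.values.index),
        values=out,
        estimator_tag=f"plugin-equalwidth-{bins}bins-nats",
    )


def threshold_network(mi: MIMatrix, tau: float = 0.0, tol: float = MI_TOL) -> nx.Graph:
    """Keep edges with MI > max(tau, tol); isolated nodes are preserved."""
    g = nx.Graph()
    g.add_nodes_from(mi.node_ids)
    cut = max(tau, tol)
    n = len(mi.node_ids)
    for i in range(n):
        for j in range(i + 1, n):
            w = mi.values[i, j]
            if w > cut:
                g.add_edge(mi.node_ids[i], mi.node_ids[j], weight=float(w))
    return g


def average_mi(net: nx.Graph) -> float:
    """Arithmetic mean of edge MI weights."""
    weights = [d["weight"] for _, _, d in net.edges(data=True)]
    if not weights:
        raise ValueError("average MI undefined for an empty edge set")
    return float(np.mean(weights))


def write_edge_list(net: nx.Graph, path) -> None:
    rows = [
        {"source": u, "target": v, "mi": d["weight"]} for u, v, d in net.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "mi"])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_edge_list(path, nodes=None) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for row in df.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.mi))
    return g


def write_sif(net: nx.Graph, path, interaction: str = "mi") -> None:
    """SIF interchange format: source <interaction> target, isolated nodes bare."""
    with open(path, "w") as fh:
        for u, v in net.edges():
            fh.write(f"{u}\t{interaction}\t{v}\n")
        for node in net.nodes():
            if net.degree(node) == 0:
                fh.write(f"{node}\n")


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                g.add_edge(parts[0], parts[2])
            elif parts[0]:
                g.add_node(parts[0])
    return g
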