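"""Graph measures on binary undirected networks.

Global measures: global efficiency and mean clustering coefficient.
Nodal measures: degree, clustering coefficient, flow coefficient,
betweenness centrality and participation coefficient — the three nodal
measures used to classify a node as local bridge, global bridge and
connector, respectively.

Conventions for degenerate degrees: clustering and flow coefficients are
0 for nodes of degree < 2 and participation is 0 for isolated nodes, so
hub rankings stay well defined.  Betweenness counts each unordered pair
of endpoints once (undirected convention), unnormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .construction import BinaryNetwork

__all__ = [
    "NodalMetricsTable",
    "shortest_paths",
    "global_efficiency",
    "clustering_coefficient",
    "betweenness_centrality",
    "flow_coefficient",
    "participation_coefficient",
    "nodal_metrics",
]


@dataclass
class NodalMetricsTable:
    """Per-node metric values plus the two network-level summaries."""

    nodal: pd.DataFrame  # columns: degree, clustering, flow, betweenness, participation
    global_efficiency: float
    mean_clustering: float
    participant: str = ""
    condition: str = ""

    def to_tsv(self, path) -> None:
        self.nodal.to_csv(path, sep="\t", index_label="node")


def _as_igraph(bn: BinaryNetwork) -> ig.Graph:
    iu, ju = np.nonzero(np.triu(bn.a, k=1))
    return ig.Graph(n=bn.n_nodes, edges=list(zip(iu.tolist(), ju.tolist())))


def shortest_paths(bn: BinaryNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Hop-count distances and shortest-path counts for every pair.

    Returns ``(dist, sigma)`` where ``dist[s, t]`` is the BFS distance
    (``inf`` for unreachable pairs) and ``sigma[s, t]`` is the number of
    distinct shortest paths between s and t (0 when unreachable,
    1 on the diagonal).
    """
    a = bn.a.astype(bool)
    n = bn.n_nodes
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    neighbors = [np.flatnonzero(a[i]) for i in range(n)]
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            nxt: list[int] = []
            for u in frontier:
                for v in neighbors[u]:
                    if dist[s, v] == np.inf:
                        dist[s, v] = d + 1
                        nxt.append(v)
                    if dist[s, v] == d + 1:
                        sigma[s, v] += sigma[s, u]
            frontier = nxt
            d += 1
    return dist, sigma


def global_efficiency(bn: BinaryNetwork) -> float:
    """Mean inverse shortest-path length over all ordered pairs.

    E = (1/(n(n-1))) * sum_{i != j} 1/d(i, j), with 1/inf taken as 0.
    """
    n = bn.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    dist = _csgraph_shortest_path(
        sp.csr_matrix(bn.a), method="D", directed=False, unweighted=True
    )
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def clustering_coefficient(bn: BinaryNetwork) -> tuple[np.ndarray, float]:
    """Nodal clustering coefficients and their unweighted network mean.

    C_i = 2 t_i / (k_i (k_i - 1)) with t_i the number of edges among the
    neighbors of i; C_i = 0 for k_i < 2.
    """
    a = bn.a.astype(float)
    k = a.sum(axis=1)
    # t_i = number of triangles through i = (A^3)_ii / 2
    t = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, t / denom, 0.0)
    return c, float(c.mean())


def betweenness_centrality(bn: BinaryNetwork, normalized: bool = False) -> np.ndarray:
    """Shortest-path betweenness, unordered-pair convention.

    B_i = sum over unordered pairs {s, t} (s, t != i) of the fraction of
    s-t shortest paths passing through i.  Optionally normalized by
    (n-1)(n-2)/2.
    """
    g = _as_igraph(bn)
    b = np.asarray(g.betweenness(), dtype=float)
    if normalized:
        n = bn.n_nodes
        if n > 2:
            b = b / ((n - 1) * (n - 2) / 2.0)
    return b


def flow_coefficient(bn: BinaryNetwork) -> np.ndarray:
    """Fraction of each node's neighbor pairs with no direct edge.

    f_i = (# unordered neighbor pairs of i not directly connected)
          / (k_i (k_i - 1) / 2); f_i = 0 when k_i < 2.  High values mark
    nodes whose neighbors can only communicate in two hops through the
    node itself ("local bridges").
    """
    a = bn.a.astype(bool)
    n = bn.n_nodes
    f = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            continue
        pairs = k * (k - 1) / 2.0
        linked = np.triu(a[np.ix_(nbrs, nbrs)], k=1).sum()
        f[i] = (pairs - linked) / pairs
    return f


def participation_coefficient(bn: BinaryNetwork, partition: np.ndarray) -> np.ndarray:
    """Spread of a node's edges across communities.

    P_i = 1 - sum_m (k_im / k_i)^2 with k_im the number of edges from i
    into community m; P_i = 0 for isolated nodes.
    """
    part = np.asarray(partition)
    n = bn.n_nodes
    if part.shape != (n,):
        raise ValueError("partition must assign every node exactly once")
    if np.any(part < 0):
        raise ValueError("partition contains unassigned (negative) nodes")
    labels = np.unique(part)
    onehot = (part[:, None] == labels[None, :]).astype(float)
    kim = bn.a.astype(float) @ onehot  # n x modules
    k = kim.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        shares = np.where(k[:, None] > 0, kim / k[:, None], 0.0)
    p = 1.0 - (shares**2).sum(axis=1)
    p[k == 0] = 0.0
    return p


def nodal_metrics(
    bn: BinaryNetwork, partition: np.ndarray | None = None
) -> NodalMetricsTable:
    """All nodal measures plus the network-level summaries in one table."""
    k = bn.a.sum(axis=1).astype(float)
    c, c_mean = clustering_coefficient(bn)
    f = flow_coefficient(bn)
    b = betweenness_centrality(bn)
    cols = {
        "degree": k,
        "clustering": c,
        "flow": f,
        "betweenness": b,
    }
    if partition is not None:
        cols["participation"] = participation_coefficient(bn, partition)
    nodal = pd.DataFrame(cols)
    return NodalMetricsTable(
        nodal=nodal,
        global_efficiency=global_efficiency(bn),
        mean_clustering=c_mean,
        participant=bn.participant,
        condition=bn.condition,
    )
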