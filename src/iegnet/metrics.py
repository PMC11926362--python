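"""Graph centrality and structure measures for functional networks.

Measures follow the standard brain-network definitions: giant component
(largest connected subgraph by node count, with isolated nodes counting
as components of size 1), unweighted degree, local transitivity
(per-node clustering coefficient, 0 for nodes of degree < 2), nodal
efficiency (mean inverse shortest-path length to every other node,
unreachable nodes contributing 0), and a hub score (eigenvector
centrality of the weighted adjacency, scaled so the maximum is 1).

Shortest paths use unweighted hop counts by default; a weighted mode
treats distance as 1/weight, for analyses that want strong correlations
to shorten paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .coactivation import mann_whitney
from .data import ComparisonResult, FunctionalNetwork


def _graph(net: FunctionalNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, FunctionalNetwork) else net


def giant_component(net: FunctionalNetwork | nx.Graph) -> int:
    """Node count of the largest connected component (>= 1)."""
    g = _graph(net)
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(g))


def degree(net: FunctionalNetwork | nx.Graph) -> dict:
    """Unweighted degree per node."""
    return dict(_graph(net).degree())


def local_clustering(net: FunctionalNetwork | nx.Graph) -> dict:
    """Local transitivity per node: 2 T(v) / (k(v) (k(v)-1)) with T(v)
    the triangles through v; 0 for nodes of degree 0 or 1."""
    return {v: float(c) for v, c in nx.clustering(_graph(net)).items()}


def nodal_efficiency(
    net: FunctionalNetwork | nx.Graph, weighted: bool = False
) -> dict:
    """Average inverse shortest-path length from each node to all others.

    Unreachable targets contribute 0.  With ``weighted=True`` path length
    is the sum of 1/weight over the path's edges.
    """
    g = _graph(net)
    n = g.number_of_nodes()
    if n < 2:
        return {v: 0.0 for v in g}
    if weighted:
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        h.add_weighted_edges_from(
            (a, b, 1.0 / w) for a, b, w in g.edges(data="weight", default=1.0)
        )
        lengths = dict(nx.all_pairs_dijkstra_path_length(h))
    else:
        lengths = dict(nx.all_pairs_shortest_path_length(g))
    eff = {}
    for v in g:
        dists = lengths.get(v, {})
        eff[v] = sum(1.0 / d for u, d in dists.items() if u != v and d > 0) / (n - 1)
    return eff


def hub_score(
    net: FunctionalNetwork | nx.Graph,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict:
    """Eigenvector centrality of the weighted adjacency, max-normalized.

    Power iteration until the relative change of the normalized vector
    falls below ``tol``; the result is scaled so the largest score is 1.
    The iteration runs on A + sI (s = largest weight), which shares A's
    eigenvectors but is primitive, so bipartite components cannot make
    it oscillate.  Isolated nodes score 0; an edgeless graph scores all
    zeros.
    """
    g = _graph(net)
    nodes = list(g.nodes)
    n = len(nodes)
    if g.number_of_edges() == 0:
        return {v: 0.0 for v in nodes}
    a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    shifted = a + np.eye(n) * np.abs(a).max()
    v = np.ones(n) / np.sqrt(n)
    prev_change = np.inf
    for _ in range(max_iter):
        w = shifted @ v
        w /= np.linalg.norm(w)
        change = float(np.linalg.norm(w - v))
        # changes decay geometrically with ratio ~ lambda2/lambda1;
        # extrapolate the remaining error so tol bounds the true error
        v = w
        if change == 0:
            break
        if np.isfinite(prev_change) and prev_change > 0:
            ratio = min(change / prev_change, 0.9999)
            if change * ratio / (1.0 - ratio) <= tol:
                break
        prev_change = change
    else:
        lam = float(v @ (shifted @ v))
        resid = float(np.linalg.norm(shifted @ v - lam * v))
        raise RuntimeError(
            f"power iteration did not converge in {max_iter} steps "
            f"(residual {resid:.3g})"
        )
    v = np.abs(v)
    v[a.sum(axis=1) == 0] = 0.0  # isolated nodes score exactly 0
    v /= v.max()
    return {node: float(s) for node, s in zip(nodes, v)}


@dataclass
class NetworkMetrics:
    """Per-node and global measures of one functional network."""

    group: str
    marker: str
    per_node: pd.DataFrame  # index: region; columns: degree, clustering,
    #                         efficiency, hub_score
    n_edges: int
    giant_component_size: int


def compute_metrics(
    net: FunctionalNetwork, efficiency_weighted: bool = False
) -> NetworkMetrics:
    g = net.graph
    per_node = pd.DataFrame({
        "degree": pd.Series(degree(g), dtype=int),
        "clustering": pd.Series(local_clustering(g)),
        "efficiency": pd.Series(nodal_efficiency(g, weighted=efficiency_weighted)),
        "hub_score": pd.Series(hub_score(g)),
    }).loc[list(net.nodes)]
    per_node.index.name = "region"
    return NetworkMetrics(
        group=net.group, marker=net.marker, per_node=per_node,
        n_edges=g.number_of_edges(),
        giant_component_size=giant_component(g),
    )


def compare_metric(
    metrics_a: NetworkMetrics, metrics_b: NetworkMetrics, metric_name: str
) -> ComparisonResult:
    """Two-sided Mann-Whitney on the nodewise values of one measure
    between two networks (degree, clustering or efficiency)."""
    if metric_name not in ("degree", "clustering", "efficiency"):
        raise ValueError(f"unsupported metric {metric_name!r}")
    x = metrics_a.per_node[metric_name].to_numpy(float)
    y = metrics_b.per_node[metric_name].to_numpy(float)
    label = (
        f"{metric_name}:{metrics_b.group}/{metrics_b.marker}"
        f"_vs_{metrics_a.group}/{metrics_a.marker}"
    )
    return mann_whitney(x, y, label=label)
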