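"""Empirical structural measurements on simple undirected graphs.

All functions accept a :class:`~bitsimnet.network.SimilarityNetwork`, a
``networkx.Graph``, or a dense boolean adjacency matrix; internally they
work on the adjacency matrix, which is the fast path for the realization
sweeps.  Quantities that can be degenerate on small or regular graphs
(assortativity, mean clustering, mean geodesic distance) return ``None``
when undefined rather than propagating NaN.

The Erdos-Renyi generator here is the G(N, M) ensemble — a fixed number of
uniformly placed links — matching the comparator used throughout: an ER
graph with the same ``N`` and ``mu * N(N-1)/2`` links has exactly the same
degree distribution as a similarity network with connectivity ``mu``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.sparse.csgraph import shortest_path as _sp

from .network import SimilarityNetwork

__all__ = [
    "components",
    "largest_component_fraction",
    "richness",
    "mean_clustering",
    "assortativity",
    "mean_geodesic",
    "er_graph",
    "degree_histogram",
    "MetricsReport",
    "report",
]


def _as_adjacency(graph) -> np.ndarray:
    """Coerce any supported graph representation to a dense bool adjacency."""
    if isinstance(graph, SimilarityNetwork):
        return graph.adjacency
    if isinstance(graph, nx.Graph):
        return nx.to_numpy_array(graph, dtype=bool)
    adj = np.asarray(graph)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    return adj.astype(bool)


def _node_labels(graph) -> list | None:
    return list(graph.nodes) if isinstance(graph, nx.Graph) else None


def components(graph) -> list[set]:
    """Partition of the nodes into maximal connected sets, largest first.

    For a ``networkx`` input the sets contain the original node labels;
    otherwise they contain 0-based indices.
    """
    adj = _as_adjacency(graph)
    n_comp, member = _cc(csr_matrix(adj), directed=False)
    sets: list[set] = [set() for _ in range(n_comp)]
    labels = _node_labels(graph)
    for idx, comp in enumerate(member):
        sets[comp].add(labels[idx] if labels is not None else int(idx))
    sets.sort(key=len, reverse=True)
    return sets


def largest_component_fraction(graph) -> float:
    comps = components(graph)
    return len(comps[0]) / sum(len(c) for c in comps)


def richness(graph) -> float:
    """Number of connected components divided by N — a diversity proxy
    where each component plays the role of a 'species'."""
    comps = components(graph)
    return len(comps) / sum(len(c) for c in comps)


def degree_histogram(graph) -> np.ndarray:
    """Counts of nodes with degree k, k = 0..N-1 (length-N array)."""
    adj = _as_adjacency(graph)
    k = adj.sum(axis=1).astype(np.int64)
    return np.bincount(k, minlength=adj.shape[0])


def mean_clustering(graph, include_low_degree: bool = False) -> float | None:
    """Mean of the local clustering coefficients.

    The local coefficient of node i is the fraction of its neighbor pairs
    that are themselves linked.  Nodes of degree < 2 have no neighbor pair:
    by default they are excluded from the average (their coefficient is
    undefined); with ``include_low_degree=True`` they enter as zeros, which
    matches ``networkx.average_clustering``.  Returns None when no node has
    degree >= 2 under the default convention.
    """
    adj = _as_adjacency(graph)
    k = adj.sum(axis=1).astype(np.int64)
    eligible = k >= 2
    if not include_low_degree and not eligible.any():
        return None
    a32 = adj.astype(np.float32)
    # diag(A^3)/2 = triangles through each node; exact in float32 for N < 2^24
    tri = ((a32 @ a32) * a32).sum(axis=1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = tri / (k * (k - 1) / 2.0)
    if include_low_degree:
        ci = np.where(eligible, ci, 0.0)
        return float(ci.mean())
    return float(ci[eligible].mean())


def assortativity(graph) -> float | None:
    """Degree assortativity: the Pearson correlation of the endpoint degrees
    over all links, in its symmetric form

        A = (4<k1 k2> - <k1 + k2>^2) / (2<k1^2 + k2^2> - <k1 + k2>^2),

    where <.> averages over links and each unordered link contributes once
    (the symmetric form makes the orientation irrelevant).  Returns None
    for a graph with no links or when the denominator vanishes (all link
    endpoints have equal degree, e.g. regular graphs).

    The numerator/denominator signs are decided in exact integer
    arithmetic to avoid calling a zero-variance graph weakly assortative
    through rounding.
    """
    adj = _as_adjacency(graph)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    n_links = iu.size
    if n_links == 0:
        return None
    k = adj.sum(axis=1).astype(np.int64)
    k1 = k[iu]
    k2 = k[ju]
    s_prod = int((k1 * k2).sum())
    s_sum = int((k1 + k2).sum())
    s_sq = int((k1 * k1 + k2 * k2).sum())
    # A = (4 E * s_prod - s_sum^2) / (2 E * s_sq - s_sum^2), all integers
    num = 4 * n_links * s_prod - s_sum * s_sum
    den = 2 * n_links * s_sq - s_sum * s_sum
    if den == 0:
        return None
    return num / den


def mean_geodesic(graph) -> float | None:
    """Mean geodesic (shortest-path) distance over all unordered node pairs
    lying in the same component; pairs in different components (infinite
    distance) and self-pairs are excluded.  Returns None if the graph has
    no linked pair at all.
    """
    adj = _as_adjacency(graph)
    if not adj.any():
        return None
    dist = _sp(csr_matrix(adj), method="auto", directed=False, unweighted=True)
    iu, ju = np.triu_indices(adj.shape[0], k=1)
    vals = dist[iu, ju]
    finite = np.isfinite(vals)
    if not finite.any():
        return None
    return float(vals[finite].mean())


def er_graph(
    N: int, n_links: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Erdos-Renyi G(N, M) graph: exactly ``n_links`` edges placed uniformly
    among the N(N-1)/2 pairs.  Returns a dense bool adjacency matrix."""
    rng = np.random.default_rng(rng)
    total = N * (N - 1) // 2
    if not 0 <= n_links <= total:
        raise ValueError(f"n_links must be in [0, {total}]")
    adj = np.zeros((N, N), dtype=bool)
    if n_links:
        picked = rng.choice(total, size=n_links, replace=False)
        iu, ju = np.triu_indices(N, k=1)
        adj[iu[picked], ju[picked]] = True
        adj |= adj.T
    return adj


@dataclass
class MetricsReport:
    """Bundle of the empirical structural measurements of one graph."""

    n_nodes: int
    n_edges: int
    largest_component_fraction: float
    richness: float
    mean_clustering: float | None
    assortativity: float | None
    mean_geodesic: float | None
    degree_histogram: np.ndarray

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["degree_histogram"] = [int(v) for v in self.degree_histogram]
        return d


def report(graph) -> MetricsReport:
    """Compute the full metrics report for one graph."""
    adj = _as_adjacency(graph)
    comps = components(adj)
    n = adj.shape[0]
    return MetricsReport(
        n_nodes=n,
        n_edges=int(np.count_nonzero(adj)) // 2,
        largest_component_fraction=len(comps[0]) / n,
        richness=len(comps) / n,
        mean_clustering=mean_clustering(adj),
        assortativity=assortativity(adj),
        mean_geodesic=mean_geodesic(adj),
        degree_histogram=degree_histogram(adj),
    )
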