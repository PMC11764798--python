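"""Similarity-network construction from distinct bit-string sets.

Nodes are distinct bit strings; an undirected link joins every pair at
Hamming distance at most the threshold ``G``.  The graph is kept as a dense
boolean adjacency matrix — for the sizes of interest (N ~ 10^3) this is both
the fastest representation for the metric computations downstream and the
natural by-product of the all-pairs distance matrix, which is cached so
that networks for a whole sweep of thresholds come from a single distance
computation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .bitstrings import pairwise_hamming

__all__ = [
    "SimilarityNetwork",
    "pairwise_distances",
    "build_network",
    "network_from_distances",
    "write_edges",
    "read_edges",
]


@dataclass
class SimilarityNetwork:
    """A bit-string similarity network.

    Attributes
    ----------
    labels : (N, B) uint8 array
        The bit strings; node ``i`` is ``labels[i]``.
    threshold : int
        The Hamming threshold G used to place links.
    adjacency : (N, N) bool array
        Symmetric, zero diagonal; ``adjacency[i, j]`` iff
        ``hamming(labels[i], labels[j]) <= G``.
    """

    labels: np.ndarray
    threshold: int
    adjacency: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def B(self) -> int:
        return self.labels.shape[1]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency)) // 2

    def edges(self) -> np.ndarray:
        """Edge list as an (E, 2) array of node index pairs, i < j."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([iu, ju])

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges()))
        return g


def pairwise_distances(strings: np.ndarray) -> np.ndarray:
    """Symmetric N x N matrix of Hamming distances (zero diagonal).

    Thresholding this matrix at each G reproduces :func:`build_network` for
    that G, which is how threshold sweeps are run.
    """
    return pairwise_hamming(np.asarray(strings, dtype=np.uint8))


def _check_distinct(strings: np.ndarray) -> None:
    if len({row.tobytes() for row in strings}) != strings.shape[0]:
        raise ValueError("bit-string set contains duplicates; nodes must be distinct")


def build_network(strings: np.ndarray, G: int) -> SimilarityNetwork:
    """Build the similarity network on a distinct string set with threshold G."""
    strings = np.asarray(strings, dtype=np.uint8)
    B = strings.shape[1]
    if not 1 <= G <= B:
        raise ValueError(f"G must be in [1, B]; got G={G}, B={B}")
    _check_distinct(strings)
    return network_from_distances(pairwise_distances(strings), G, labels=strings)


def network_from_distances(
    dist: np.ndarray, G: int, labels: np.ndarray | None = None
) -> SimilarityNetwork:
    """Threshold a precomputed distance matrix into a network (sweep helper)."""
    adj = dist <= G
    np.fill_diagonal(adj, False)
    if labels is None:
        labels = np.empty((dist.shape[0], 0), dtype=np.uint8)
    return SimilarityNetwork(labels=labels, threshold=int(G), adjacency=adj)


def write_edges(path: str | Path, net: SimilarityNetwork) -> None:
    """Write the edge list as TSV: columns i, j, H with a ``# N= B= G=``
    header line."""
    dist = pairwise_distances(net.labels) if net.labels.size else None
    with open(path, "w") as fh:
        fh.write(f"# N={net.n_nodes} B={net.B} G={net.threshold}\n")
        for i, j in net.edges():
            if dist is not None:
                fh.write(f"{i}\t{j}\t{int(dist[i, j])}\n")
            else:
                fh.write(f"{i}\t{j}\n")


def read_edges(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an edge-list TSV written by :func:`write_edges`.

    Returns ``(edges, meta)`` where ``edges`` is an (E, 2) int array and
    ``meta`` holds the N, B, G header values (when present).
    """
    meta: dict = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for key, val in re.findall(r"(\w+)=(\d+)", line):
                    meta[key] = int(val)
                continue
            parts = line.split("\t")
            rows.append((int(parts[0]), int(parts[1])))
    edges = np.array(rows, dtype=np.int64) if rows else np.empty((0, 2), dtype=np.int64)
    return edges, meta
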