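"""Network construction from lfdr values and community detection.

Edges are called by thresholding the pairwise lfdr matrix.  Because the
underlying distance is directional, each unordered pair {i, j} has two lfdr
values; the supporting lfdr of the pair is their min (union rule: evidence
of predictability in either direction suffices) or max (intersection rule),
selectable via `symmetrization`.  The cutoff is chosen dynamically so the
network hits a target average node degree, then clamped to [0.05, 0.2] so
the realized false-discovery level stays in a sane band regardless of how
dense a network was requested.  Communities are found by multilevel
(Louvain-type) modularity optimization or by asynchronous label
propagation; communities smaller than `min_size` are relabeled 0
("unassigned") rather than merged.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np

from .inference import LfdrMatrix

__all__ = [
    "GeneNetwork",
    "Partition",
    "pair_support",
    "select_cutoff",
    "build_network",
    "communities_multilevel",
    "communities_label_propagation",
]

LFDR_FLOOR = 0.05
LFDR_CEILING = 0.2


@dataclass(frozen=True)
class GeneNetwork:
    """Simple undirected graph over gene ids with the lfdr cutoff used.

    `graph` is a networkx Graph whose edges carry the supporting lfdr as
    attribute ``"lfdr"``; isolated genes are kept as nodes.
    """

    graph: nx.Graph
    cutoff_used: float
    target_degree: float | None = None

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)

    def average_degree(self) -> float:
        n = self.graph.number_of_nodes()
        return 2.0 * self.graph.number_of_edges() / n if n else 0.0

    def edge_table(self) -> list[tuple[str, str, float]]:
        """Lexicographically ordered (gene_a, gene_b, lfdr) rows."""
        rows = [tuple(sorted((a, b))) + (float(d["lfdr"]),)
                for a, b, d in self.graph.edges(data=True)]
        return sorted(rows)


@dataclass(frozen=True)
class Partition:
    """Community labels over the network's nodes; 0 = unassigned."""

    labels: dict[str, int]
    min_size: int

    def __post_init__(self) -> None:
        sizes = self.sizes()
        bad = [c for c, sz in sizes.items() if c != 0 and sz < self.min_size]
        if bad:
            raise ValueError(f"communities below min_size: {bad}")

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.labels.values():
            out[c] = out.get(c, 0) + 1
        return out

    def as_array(self, gene_ids) -> np.ndarray:
        return np.array([self.labels[g] for g in gene_ids], dtype=int)


def pair_support(l: LfdrMatrix, symmetrization: str = "union") -> np.ndarray:
    """Supporting lfdr per unordered pair: elementwise min (union) or max
    (intersection) of the matrix and its transpose."""
    if symmetrization == "union":
        return np.minimum(l.l, l.l.T)
    if symmetrization == "intersection":
        return np.maximum(l.l, l.l.T)
    raise ValueError(f"unknown symmetrization {symmetrization!r}")


def select_cutoff(l: LfdrMatrix, target_degree: float,
                  symmetrization: str = "union") -> float:
    """Lfdr cutoff whose network has average degree closest to target,
    clamped to [0.05, 0.2].

    A network with average degree t over p nodes has t*p/2 edges; the
    unclamped cutoff is therefore the (t*p/2)-th order statistic of the
    p(p-1)/2 pairwise supporting-lfdr values.
    """
    p = l.l.shape[0]
    if not 0 < target_degree < p - 1:
        raise ValueError(f"target_degree must be in (0, {p - 1})")
    support = pair_support(l, symmetrization)
    vals = np.sort(support[np.triu_indices(p, k=1)])
    k = int(round(target_degree * p / 2.0))
    k = max(k, 1)
    if k > vals.size:
        warnings.warn(
            f"target average degree {target_degree} unreachable even at cutoff 1; "
            f"using ceiling {LFDR_CEILING}", stacklevel=2)
        return LFDR_CEILING
    c_star = float(vals[k - 1])
    return float(np.clip(c_star, LFDR_FLOOR, LFDR_CEILING))


def build_network(l: LfdrMatrix, cutoff: float,
                  symmetrization: str = "union",
                  target_degree: float | None = None) -> GeneNetwork:
    """Threshold the lfdr matrix into an undirected gene network.

    Pair {i, j} becomes an edge iff its supporting lfdr is <= cutoff.
    Isolated genes remain as nodes.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    p = l.l.shape[0]
    ids = list(l.gene_ids) if l.gene_ids else [str(i) for i in range(p)]
    support = pair_support(l, symmetrization)
    g = nx.Graph()
    g.add_nodes_from(ids)
    ii, jj = np.triu_indices(p, k=1)
    keep = support[ii, jj] <= cutoff
    g.add_edges_from(
        (ids[a], ids[b], {"lfdr": float(support[a, b])})
        for a, b in zip(ii[keep], jj[keep])
    )
    return GeneNetwork(graph=g, cutoff_used=float(cutoff), target_degree=target_degree)


def _to_igraph(net: GeneNetwork) -> tuple[ig.Graph, list[str]]:
    nodes = list(net.graph.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in net.graph.edges]
    return ig.Graph(n=len(nodes), edges=edges), nodes


def _finalize(nodes: list[str], membership, min_size: int) -> Partition:
    """Relabel communities 1..K by decreasing size; drop small ones to 0."""
    membership = np.asarray(membership)
    labels = {g: 0 for g in nodes}
    comms = sorted(
        (np.flatnonzero(membership == c) for c in np.unique(membership)),
        key=len, reverse=True)
    nxt = 1
    for idx in comms:
        if idx.size >= min_size:
            for i in idx:
                labels[nodes[i]] = nxt
            nxt += 1
    return Partition(labels=labels, min_size=min_size)


def _seeded_igraph_rng(seed: int):
    ig.set_random_number_generator(random.Random(seed))


def communities_multilevel(net: GeneNetwork, seed: int = 0,
                           min_size: int = 1) -> Partition:
    """Louvain-type multilevel modularity optimization."""
    g, nodes = _to_igraph(net)
    if g.ecount() == 0:
        return _finalize(nodes, np.arange(len(nodes)), max(min_size, 2))
    _seeded_igraph_rng(seed)
    try:
        memb = g.community_multilevel().membership
    finally:
        ig.set_random_number_generator(random)
    return _finalize(nodes, memb, min_size)


def communities_label_propagation(net: GeneNetwork, seed: int = 0,
                                  min_size: int = 1) -> Partition:
    """Asynchronous label propagation with a seeded update order."""
    g, nodes = _to_igraph(net)
    if g.ecount() == 0:
        return _finalize(nodes, np.arange(len(nodes)), max(min_size, 2))
    _seeded_igraph_rng(seed)
    try:
        memb = g.community_label_propagation().membership
    finally:
        ig.set_random_number_generator(random)
    return _finalize(nodes, memb, min_size)
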