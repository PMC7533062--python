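"""Thresholded weighted graphs and island decomposition.

An *m-island* (line island) is a maximal connected cluster C with
``min_size <= |C| <= m`` such that some spanning tree of C has a minimum
edge weight strictly exceeding the weight of every edge leaving C.  The
implementation builds the maximum-spanning-forest dendrogram with a single
weight-ordered union-find pass (O(E log E)) and then reads the maximal
qualifying clusters per m off that hierarchy, so the whole maximum-size
continuum is answered from one decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, Iterable, List, Mapping, Sequence

import networkx as nx
import numpy as np

from ampconn.phaseconn import StageConnectivity

__all__ = [
    "DEFAULT_THRESHOLD",
    "default_m_values",
    "build_graph",
    "IslandSet",
    "IslandHierarchy",
    "island_decompose",
    "island_continuum",
]

DEFAULT_THRESHOLD = 1.96


def default_m_values(n_nodes: int = 776) -> List[int]:
    """The maximum-island-size continuum: 50..750 step 50, plus n/2 and n."""
    values = list(range(50, 751, 50))
    for extra in (n_nodes // 2, n_nodes):
        if extra not in values:
            values.append(extra)
    return values


def build_graph(
    z,
    threshold: float = DEFAULT_THRESHOLD,
    labels: Sequence[Hashable] | None = None,
    partition: Mapping[Hashable, int] | None = None,
) -> nx.Graph:
    """Graph with an edge wherever the normalized PLV strictly exceeds ``threshold``.

    ``z`` may be a square matrix or a :class:`StageConnectivity` (its ``z``
    is used and zero-SD edges are excluded).  All nodes are retained even
    when isolated.  The module partition, when given, is stored as the node
    attribute ``module`` and in ``G.graph["partition"]``.
    """
    mask = None
    if isinstance(z, StageConnectivity):
        mask = z.zero_sd_edges
        z = z.z
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("z must be a square matrix")
    if not np.allclose(z, z.T, atol=1e-9):
        raise ValueError("z must be symmetric")
    n = z.shape[0]
    nodes = list(labels) if labels is not None else list(range(n))
    if len(nodes) != n:
        raise ValueError("labels length must match the matrix size")
    g = nx.Graph()
    g.add_nodes_from(nodes)
    rows, cols = np.nonzero(np.triu(z > threshold, k=1))
    for i, j in zip(rows, cols):
        if mask is not None and mask[i, j]:
            continue
        g.add_edge(nodes[i], nodes[j], weight=float(z[i, j]))
    if partition is not None:
        nx.set_node_attributes(g, dict(partition), "module")
        g.graph["partition"] = dict(partition)
    return g


@dataclass
class IslandSet:
    """Islands obtained at one maximum size ``m``."""

    m: int
    islands: List[frozenset]

    def membership(self) -> Dict[Hashable, int]:
        out: Dict[Hashable, int] = {}
        for k, isl in enumerate(self.islands):
            for v in isl:
                out[v] = k
        return out

    @property
    def nodes(self) -> frozenset:
        return frozenset().union(*self.islands) if self.islands else frozenset()


class IslandHierarchy:
    """Maximum-spanning-forest merge dendrogram of a weighted graph.

    Each internal node of the dendrogram is a cluster created by a Kruskal
    union in decreasing weight order; it stores the minimum weight of its
    spanning-tree edges and, once its parent forms, the weight of the edge
    that merged it (which is also the maximum weight of any edge leaving
    the cluster — later edges are no heavier, and an earlier heavier edge
    would already have pulled its endpoint inside).
    """

    def __init__(self, g: nx.Graph):
        nodes = list(g.nodes)
        index = {v: i for i, v in enumerate(nodes)}
        n = len(nodes)
        # dendrogram arrays; leaves are 0..n-1
        self._members: List[Hashable] = nodes
        self._left: List[int] = [-1] * n
        self._right: List[int] = [-1] * n
        self._size: List[int] = [1] * n
        self._min_internal: List[float] = [np.inf] * n
        self._death: List[float] = [-np.inf] * n  # parent merge weight

        parent = list(range(n))  # union-find over dendrogram node ids

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        edges = sorted(
            g.edges(data="weight"),
            key=lambda e: (-e[2], index[e[0]], index[e[1]]),
        )
        for u, v, w in edges:
            ru, rv = find(index[u]), find(index[v])
            if ru == rv:
                continue  # cycle edge: internal, affects neither criterion
            new = len(self._size)
            self._left.append(ru)
            self._right.append(rv)
            self._size.append(self._size[ru] + self._size[rv])
            self._min_internal.append(
                min(self._min_internal[ru], self._min_internal[rv], w)
            )
            self._death.append(-np.inf)
            self._death[ru] = w
            self._death[rv] = w
            parent.extend([new])
            parent[ru] = new
            parent[rv] = new
        self._roots = [find(i) for i in set(find(i) for i in range(n))] if n else []
        self._roots = sorted(set(self._roots))

    def _collect(self, node: int) -> frozenset:
        out = []
        stack = [node]
        while stack:
            i = stack.pop()
            if i < len(self._members) and self._left[i] == -1:
                out.append(self._members[i])
            else:
                stack.extend((self._left[i], self._right[i]))
        return frozenset(out)

    def islands(self, min_size: int = 3, max_size: int | None = None) -> IslandSet:
        """Maximal clusters with size in [min_size, max_size] whose internal
        spanning-tree minimum strictly exceeds every leaving edge weight."""
        if min_size < 3:
            raise ValueError("min_size must be >= 3")
        m = max_size if max_size is not None else len(self._members)
        if m < min_size:
            raise ValueError("max_size must be >= min_size")
        found: List[frozenset] = []
        stack = list(self._roots)
        while stack:
            i = stack.pop()
            size = self._size[i]
            if size < min_size:
                continue
            if size <= m and self._min_internal[i] > self._death[i]:
                found.append(self._collect(i))
                continue
            if self._left[i] != -1:
                stack.extend((self._left[i], self._right[i]))
        found.sort(key=lambda s: (-len(s), sorted(map(str, s))))
        return IslandSet(m=m, islands=found)


def island_decompose(
    g: nx.Graph, min_size: int = 3, max_size: int | None = None
) -> IslandSet:
    """Island decomposition of a weighted graph at one maximum size."""
    return IslandHierarchy(g).islands(min_size=min_size, max_size=max_size)


def island_continuum(
    g: nx.Graph,
    m_values: Iterable[int] | None = None,
    min_size: int = 3,
) -> Dict[int, IslandSet]:
    """Island sets across the maximum-size continuum (one dendrogram pass).

    The default grid is the published continuum for the 776-node scheme
    (50..750 in steps of 50, plus 388 and 776).
    """
    if m_values is None:
        m_values = default_m_values()
    m_values = list(m_values)
    if not m_values:
        raise ValueError("m_values must be non-empty")
    hierarchy = IslandHierarchy(g)
    return {m: hierarchy.islands(min_size=min_size, max_size=m) for m in m_values}
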