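"""Per-node graph measures on weighted undirected brain networks.

Nine measures per node, with the weighted/unweighted conventions used in
whole-cortex PLV network analyses:

======  =====================================  =========
column  measure                                weights
======  =====================================  =========
DEG     degree centrality (strength)           weighted
BET     betweenness centrality                 weighted
TRA     transitivity (Barrat local clustering) weighted
KVL     k-coreness                             unweighted
LAP     Laplacian centrality (energy drop)     unweighted
EIG     eigenvector centrality (max = 1)       weighted
PART    participation coefficient              weighted
GATE    gateway coefficient                    weighted
WMDZ    within-module degree z-score           weighted
======  =====================================  =========

PART, GATE and WMDZ additionally require the functional-module partition.
"""

from __future__ import annotations

from typing import Dict, Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "METRIC_COLUMNS",
    "weighted_degree",
    "weighted_betweenness",
    "weighted_transitivity",
    "k_coreness",
    "laplacian_centrality",
    "eigenvector_centrality",
    "participation_coefficient",
    "gateway_coefficient",
    "within_module_degree_z",
    "metrics_table",
    "island_metrics",
]

METRIC_COLUMNS = (
    "amplitude",
    "DEG",
    "BET",
    "TRA",
    "KVL",
    "LAP",
    "EIG",
    "PART",
    "GATE",
    "WMDZ",
)


def weighted_degree(g: nx.Graph, v: Hashable) -> float:
    """Strength: the sum of edge weights incident to ``v``."""
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    return float(g.degree(v, weight="weight"))


def weighted_betweenness(g: nx.Graph, mode: str = "reciprocal") -> Dict[Hashable, float]:
    """Betweenness with weighted shortest paths, endpoints excluded.

    ``mode="reciprocal"`` treats weights as affinities (distance = 1/weight,
    the default); ``mode="raw"`` treats the weight itself as the traversal
    cost, replicating tools that interpret weights as lengths.
    """
    if mode not in ("reciprocal", "raw"):
        raise ValueError("mode must be 'reciprocal' or 'raw'")
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for u, v, w in g.edges(data="weight", default=1.0):
        h.add_edge(u, v, dist=(1.0 / w) if mode == "reciprocal" else float(w))
    return nx.betweenness_centrality(h, weight="dist", normalized=False)


def weighted_transitivity(g: nx.Graph, v: Hashable) -> float:
    """Barrat local weighted clustering coefficient.

    ``c_v = 1/(s_v (k_v - 1)) * sum over ordered neighbor pairs (j, h) with
    an edge j-h of (w_vj + w_vh)/2``; 0 when v has fewer than two neighbors.
    Reduces to the unweighted local clustering coefficient for constant
    weights.
    """
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    neigh = list(g.neighbors(v))
    k = len(neigh)
    if k < 2:
        return 0.0
    s = weighted_degree(g, v)
    total = 0.0
    for a_i, j in enumerate(neigh):
        wj = g[v][j].get("weight", 1.0)
        for h in neigh[a_i + 1 :]:
            if g.has_edge(j, h):
                total += wj + g[v][h].get("weight", 1.0)  # both ordered pairs
    return total / (s * (k - 1))


def k_coreness(g: nx.Graph) -> Dict[Hashable, int]:
    """Largest k such that the node belongs to the k-core (unweighted)."""
    return nx.core_number(g)


def laplacian_centrality(g: nx.Graph, v: Hashable) -> float:
    """Drop in unweighted Laplacian energy ``sum_i d_i^2 + d_i`` when ``v`` is removed."""
    if v not in g:
        raise KeyError(f"node {v!r} not in graph")
    d_v = g.degree(v)
    # removing v: its own term disappears and each neighbor loses one degree
    loss = d_v * d_v + d_v
    for u in g.neighbors(v):
        d_u = g.degree(u)
        loss += d_u * d_u + d_u - ((d_u - 1) ** 2 + (d_u - 1))
    return float(loss)


def eigenvector_centrality(g: nx.Graph) -> Dict[Hashable, float]:
    """Weighted eigenvector centrality, max-normalized per connected component.

    The principal eigenvector of the weighted adjacency of each component,
    taken non-negative and scaled so its largest entry is 1.  Isolated nodes
    score 0.  An edgeless graph is rejected.
    """
    if g.number_of_edges() == 0:
        raise ValueError("eigenvector centrality requires at least one edge")
    scores: Dict[Hashable, float] = {v: 0.0 for v in g.nodes}
    for comp in nx.connected_components(g):
        nodes = sorted(comp, key=str)
        if len(nodes) == 1:
            continue
        a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        vals, vecs = np.linalg.eigh(a)
        vec = vecs[:, int(np.argmax(vals))]
        vec = np.abs(vec)
        peak = vec.max()
        if peak > 0:
            vec = vec / peak
        for node, s in zip(nodes, vec):
            scores[node] = float(s)
    return scores


def _module_strengths(
    g: nx.Graph, partition: Mapping[Hashable, int]
) -> Dict[Hashable, Dict[int, float]]:
    kappa: Dict[Hashable, Dict[int, float]] = {v: {} for v in g.nodes}
    for u, v, w in g.edges(data="weight", default=1.0):
        kappa[u][partition[v]] = kappa[u].get(partition[v], 0.0) + w
        kappa[v][partition[u]] = kappa[v].get(partition[u], 0.0) + w
    return kappa


def _check_partition(g: nx.Graph, partition: Mapping[Hashable, int]) -> None:
    missing = [v for v in g.nodes if v not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")


def participation_coefficient(
    g: nx.Graph, partition: Mapping[Hashable, int]
) -> Dict[Hashable, float]:
    """``P_v = 1 - sum_M (kappa_vM / s_v)^2`` with module strengths ``kappa_vM``.

    Zero when all of a node's strength stays in one module (and, by
    convention, for isolated nodes).
    """
    _check_partition(g, partition)
    kappa = _module_strengths(g, partition)
    out: Dict[Hashable, float] = {}
    for v in g.nodes:
        s = sum(kappa[v].values())
        if s <= 0:
            out[v] = 0.0
        else:
            out[v] = 1.0 - sum((k / s) ** 2 for k in kappa[v].values())
    return out


def gateway_coefficient(
    g: nx.Graph,
    partition: Mapping[Hashable, int],
    centrality_variant: str = "degree",
) -> Dict[Hashable, float]:
    """Gateway coefficient: participation weighted by the uniqueness of links.

    ``G_v = 1 - sum_M (kappa_vM / s_v)^2 (g_vM)^2`` with
    ``g_vM = 1 - abar_vM * bbar_vM`` for modules other than v's own, where
    ``abar_vM`` is v's share of the total inter-modular strength entering M
    and ``bbar_vM`` is v's centrality relative to the most central node
    linking into M from outside.  For v's own module ``g_vM = 1``, so a node
    with no unique inter-modular role falls back to its participation
    coefficient.  ``centrality_variant`` selects strength ("degree") or
    weighted betweenness ("betweenness") for the b-term.
    """
    if centrality_variant not in ("degree", "betweenness"):
        raise ValueError("centrality_variant must be 'degree' or 'betweenness'")
    _check_partition(g, partition)
    kappa = _module_strengths(g, partition)
    if centrality_variant == "degree":
        cent = {v: float(g.degree(v, weight="weight")) for v in g.nodes}
    else:
        cent = weighted_betweenness(g)
    modules = sorted(set(partition[v] for v in g.nodes))
    # total inter-modular strength entering each module, and the peak
    # centrality among outside nodes linking into it
    enter = {m: 0.0 for m in modules}
    peak = {m: 0.0 for m in modules}
    for v in g.nodes:
        for m, k in kappa[v].items():
            if m != partition[v]:
                enter[m] += k
                peak[m] = max(peak[m], cent[v])
    out: Dict[Hashable, float] = {}
    for v in g.nodes:
        s = sum(kappa[v].values())
        if s <= 0:
            out[v] = 0.0
            continue
        acc = 0.0
        for m, k in kappa[v].items():
            if m == partition[v]:
                gvm = 1.0
            else:
                abar = k / enter[m] if enter[m] > 0 else 0.0
                bbar = cent[v] / peak[m] if peak[m] > 0 else 0.0
                gvm = 1.0 - abar * bbar
            acc += (k / s) ** 2 * gvm**2
        out[v] = 1.0 - acc
    return out


def within_module_degree_z(
    g: nx.Graph, partition: Mapping[Hashable, int]
) -> Dict[Hashable, float]:
    """Intra-module strength z-scored within each module (population SD).

    Singleton modules and modules with constant intra-module strength get
    z = 0.
    """
    _check_partition(g, partition)
    kappa = _module_strengths(g, partition)
    intra = {v: kappa[v].get(partition[v], 0.0) for v in g.nodes}
    out: Dict[Hashable, float] = {}
    by_module: Dict[int, list] = {}
    for v in g.nodes:
        by_module.setdefault(partition[v], []).append(v)
    for m, members in by_module.items():
        vals = np.array([intra[v] for v in members])
        sd = vals.std()  # population SD
        mean = vals.mean()
        for v in members:
            out[v] = float((intra[v] - mean) / sd) if sd > 0 else 0.0
    return out


def metrics_table(
    g: nx.Graph,
    amplitudes: Mapping[Hashable, float] | Sequence[float],
    partition: Mapping[Hashable, int] | None = None,
    betweenness_mode: str = "reciprocal",
    gateway_variant: str = "degree",
) -> pd.DataFrame:
    """All nine measures plus amplitude, one row per node of ``g``.

    ``amplitudes`` must cover every node (mapping, or a sequence aligned
    with ``g.nodes``).  The partition defaults to ``g.graph["partition"]``;
    without one the module-dependent columns are NaN.
    """
    nodes = list(g.nodes)
    if not isinstance(amplitudes, Mapping):
        if len(amplitudes) != len(nodes):
            raise ValueError("amplitudes length must match the node count")
        amplitudes = dict(zip(nodes, amplitudes))
    missing = [v for v in nodes if v not in amplitudes]
    if missing:
        raise ValueError(f"amplitude missing for nodes: {missing[:5]}")
    if partition is None:
        partition = g.graph.get("partition")

    bet = weighted_betweenness(g, mode=betweenness_mode)
    core = k_coreness(g)
    eig = (
        eigenvector_centrality(g)
        if g.number_of_edges() > 0
        else {v: 0.0 for v in nodes}
    )
    if partition is not None:
        part = participation_coefficient(g, partition)
        gate = gateway_coefficient(g, partition, gateway_variant)
        wmdz = within_module_degree_z(g, partition)
    else:
        part = gate = wmdz = {v: np.nan for v in nodes}

    rows = []
    for v in nodes:
        rows.append(
            {
                "node": v,
                "amplitude": float(amplitudes[v]),
                "DEG": weighted_degree(g, v),
                "BET": float(bet[v]),
                "TRA": weighted_transitivity(g, v),
                "KVL": int(core[v]),
                "LAP": laplacian_centrality(g, v),
                "EIG": float(eig[v]),
                "PART": float(part[v]),
                "GATE": float(gate[v]),
                "WMDZ": float(wmdz[v]),
            }
        )
    return pd.DataFrame(rows).set_index("node")


def island_metrics(
    g: nx.Graph,
    islands,
    amplitudes: Mapping[Hashable, float] | Sequence[float],
    partition: Mapping[Hashable, int] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Metrics computed island by island on the induced subgraphs.

    Nodes outside every island are omitted; an ``island`` column records the
    island index of each node.
    """
    nodes = list(g.nodes)
    if not isinstance(amplitudes, Mapping):
        if len(amplitudes) != len(nodes):
            raise ValueError("amplitudes length must match the node count")
        amplitudes = dict(zip(nodes, amplitudes))
    if partition is None:
        partition = g.graph.get("partition")
    island_list = islands.islands if hasattr(islands, "islands") else list(islands)
    frames = []
    for k, isl in enumerate(island_list):
        sub = g.subgraph(isl).copy()
        sub_part = (
            {v: partition[v] for v in sub.nodes} if partition is not None else None
        )
        tbl = metrics_table(sub, {v: amplitudes[v] for v in sub.nodes}, sub_part, **kwargs)
        tbl["island"] = k
        frames.append(tbl)
    if not frames:
        empty = pd.DataFrame(columns=list(METRIC_COLUMNS) + ["island"])
        empty.index.name = "node"
        return empty
    return pd.concat(frames)
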