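"""Independent brute-force oracles used to validate the implementation.

Everything here is written from the definitions (exhaustive enumeration,
eigen-decompositions, power iteration, direct formulas) and deliberately
shares no code with the package.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Set, Tuple

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# islands: exhaustive subset enumeration
# ---------------------------------------------------------------------------


def exhaustive_line_islands(g: nx.Graph, min_size: int, max_size: int) -> List[frozenset]:
    """All maximal clusters C (min_size <= |C| <= max_size) such that C is
    connected and the minimum edge of C's maximum spanning tree strictly
    exceeds every edge weight leaving C."""
    nodes = list(g.nodes)
    qualifying: List[Set] = []
    for k in range(min_size, min(max_size, len(nodes)) + 1):
        for combo in itertools.combinations(nodes, k):
            c = set(combo)
            sub = g.subgraph(c)
            if not nx.is_connected(sub):
                continue
            mst_edges = list(nx.maximum_spanning_edges(sub, data=True))
            internal_min = min(d["weight"] for *_, d in mst_edges)
            external = [
                d["weight"]
                for u in c
                for v, d in g[u].items()
                if v not in c
            ]
            if external and internal_min <= max(external):
                continue
            qualifying.append(c)
    maximal = [
        frozenset(c)
        for c in qualifying
        if not any(c < other for other in qualifying)
    ]
    return sorted(set(maximal), key=lambda s: (-len(s), sorted(map(str, s))))


# ---------------------------------------------------------------------------
# node metrics from definitions
# ---------------------------------------------------------------------------


def strength_oracle(g: nx.Graph, v) -> float:
    return sum(d.get("weight", 1.0) for d in g[v].values())


def betweenness_oracle(g: nx.Graph, mode: str = "reciprocal") -> Dict:
    """All-pairs shortest-path betweenness from the definition.

    Distances via Floyd-Warshall on the chosen edge-cost transform; path
    counts via dynamic programming over the shortest-path DAG.
    """
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v, w in g.edges(data="weight", default=1.0):
        c = 1.0 / w if mode == "reciprocal" else float(w)
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = c
    for k in range(n):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    tol = 1e-9
    cost = np.full((n, n), np.inf)
    for u, v, w in g.edges(data="weight", default=1.0):
        c = 1.0 / w if mode == "reciprocal" else float(w)
        cost[idx[u], idx[v]] = cost[idx[v], idx[u]] = c
    # sigma[s, t]: number of shortest s-t paths, by DP in distance order
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        for t in np.argsort(dist[s]):
            if t == s or not np.isfinite(dist[s, t]):
                continue
            preds = [
                p
                for p in range(n)
                if np.isfinite(cost[p, t])
                and abs(dist[s, p] + cost[p, t] - dist[s, t]) < tol
            ]
            sigma[s, t] = sum(sigma[s, p] for p in preds)
    bet = {v: 0.0 for v in nodes}
    for si, ti in itertools.combinations(range(n), 2):
        if not np.isfinite(dist[si, ti]) or sigma[si, ti] == 0:
            continue
        for vi in range(n):
            if vi in (si, ti):
                continue
            if abs(dist[si, vi] + dist[vi, ti] - dist[si, ti]) < tol:
                bet[nodes[vi]] += sigma[si, vi] * sigma[vi, ti] / sigma[si, ti]
    return bet


def barrat_oracle(g: nx.Graph, v) -> float:
    neigh = list(g.neighbors(v))
    k = len(neigh)
    if k < 2:
        return 0.0
    s = strength_oracle(g, v)
    total = 0.0
    for j in neigh:
        for h in neigh:
            if j != h and g.has_edge(j, h):
                total += (g[v][j].get("weight", 1.0) + g[v][h].get("weight", 1.0)) / 2.0
    return total / (s * (k - 1))


def kcore_oracle(g: nx.Graph) -> Dict:
    """Iterative peeling."""
    core = {}
    remaining = nx.Graph(g)
    k = 0
    while remaining.number_of_nodes():
        while True:
            low = [v for v in remaining.nodes if remaining.degree(v) <= k]
            if not low:
                break
            for v in low:
                core[v] = k
                remaining.remove_node(v)
        k += 1
    return core


def laplacian_energy_oracle(g: nx.Graph) -> float:
    if g.number_of_nodes() == 0:
        return 0.0
    lap = nx.laplacian_matrix(g, weight=None).toarray().astype(float)
    eig = np.linalg.eigvalsh(lap)
    return float(np.sum(eig**2))


def laplacian_centrality_oracle(g: nx.Graph, v) -> float:
    h = nx.Graph(g)
    h.remove_node(v)
    return laplacian_energy_oracle(g) - laplacian_energy_oracle(h)


def eigenvector_oracle(g: nx.Graph, iters: int = 20000, tol: float = 1e-14) -> Dict:
    """Power iteration per connected component, max-normalized."""
    scores = {v: 0.0 for v in g.nodes}
    for comp in nx.connected_components(g):
        nodes = sorted(comp, key=str)
        if len(nodes) == 1:
            continue
        a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        # shift by the identity so the top eigenvalue strictly dominates in
        # magnitude (bipartite components have a symmetric +/- spectrum)
        a = a + (1.0 + a.sum(axis=1).max()) * np.eye(len(nodes))
        x = np.ones(len(nodes))
        for _ in range(iters):
            y = a @ x
            nrm = np.linalg.norm(y)
            if nrm == 0:
                break
            y = y / nrm
            if np.linalg.norm(y - x) < tol:
                x = y
                break
            x = y
        x = np.abs(x)
        if x.max() > 0:
            x = x / x.max()
        for node, s in zip(nodes, x):
            scores[node] = float(s)
    return scores


def module_strength_oracle(g: nx.Graph, v, partition) -> Dict[int, float]:
    out: Dict[int, float] = {}
    for u, d in g[v].items():
        out[partition[u]] = out.get(partition[u], 0.0) + d.get("weight", 1.0)
    return out


def participation_oracle(g: nx.Graph, v, partition) -> float:
    km = module_strength_oracle(g, v, partition)
    s = sum(km.values())
    if s <= 0:
        return 0.0
    return 1.0 - sum((k / s) ** 2 for k in km.values())


def gateway_oracle(g: nx.Graph, v, partition, variant: str = "degree") -> float:
    km = module_strength_oracle(g, v, partition)
    s = sum(km.values())
    if s <= 0:
        return 0.0
    if variant == "degree":
        cent = {u: strength_oracle(g, u) for u in g.nodes}
    else:
        cent = betweenness_oracle(g)
    acc = 0.0
    for m, k in km.items():
        if m == partition[v]:
            gvm = 1.0
        else:
            linkers = [
                u for u in g.nodes
                if partition[u] != m and module_strength_oracle(g, u, partition).get(m, 0.0) > 0
            ]
            total_in = sum(module_strength_oracle(g, u, partition)[m] for u in linkers)
            abar = k / total_in if total_in > 0 else 0.0
            peak = max((cent[u] for u in linkers), default=0.0)
            bbar = cent[v] / peak if peak > 0 else 0.0
            gvm = 1.0 - abar * bbar
        acc += (k / s) ** 2 * gvm**2
    return 1.0 - acc


def wmdz_oracle(g: nx.Graph, v, partition) -> float:
    members = [u for u in g.nodes if partition[u] == partition[v]]
    intra = {
        u: module_strength_oracle(g, u, partition).get(partition[u], 0.0)
        for u in members
    }
    vals = np.array(list(intra.values()))
    sd = vals.std()
    if sd <= 0:
        return 0.0
    return float((intra[v] - vals.mean()) / sd)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def mc_null_plv(n_trials: int, n_draws: int, rng: np.random.Generator) -> float:
    """Monte-Carlo E|mean of n_trials iid uniform phasors|."""
    phases = rng.uniform(-np.pi, np.pi, size=(n_draws, n_trials))
    return float(np.abs(np.exp(1j * phases).mean(axis=1)).mean())


def partial_r_oracle(x, y, subject) -> float:
    """Pearson r of OLS residuals after regressing x and y on subject dummies."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    subject = np.asarray(subject)
    levels = sorted(set(subject.tolist()))
    design = np.column_stack(
        [np.ones(len(x))] + [(subject == s).astype(float) for s in levels[1:]]
    )
    bx, *_ = np.linalg.lstsq(design, x, rcond=None)
    by, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ bx
    ry = y - design @ by
    return float(np.corrcoef(rx, ry)[0, 1])


def exhaustive_diff_distribution(data, groups) -> Tuple[float, np.ndarray]:
    """All distinct equal-size reassignments of subjects to two groups.

    Returns the observed difference of pooled within-subject correlations
    (sorted label order) and the exhaustive distribution over assignments.
    """
    labels = sorted(set(groups.values()))
    g1 = sorted(s for s in data if groups[s] == labels[0])
    g2 = sorted(s for s in data if groups[s] == labels[1])
    subjects = g1 + g2

    def pooled(members) -> float:
        xs, ys, subj = [], [], []
        for s in members:
            x, y = data[s]
            xs.extend(x)
            ys.extend(y)
            subj.extend([s] * len(x))
        return partial_r_oracle(xs, ys, subj)

    observed = pooled(g1) - pooled(g2)
    diffs = []
    for combo in itertools.combinations(subjects, len(g1)):
        rest = [s for s in subjects if s not in combo]
        diffs.append(pooled(list(combo)) - pooled(rest))
    return observed, np.array(diffs)
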