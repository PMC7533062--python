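"""Hothub / coldhub node taxonomy and dark-network extraction.

Hotspots are nodes whose stage amplitude strictly exceeds the mean plus one
standard deviation across nodes; hubs are the top-k nodes by weighted
eigenvector centrality with k set to the hotspot count, so the hub share
always equals the hotspot share.  Crossing the two dichotomies yields four
node types; the subgraph induced by the coldhubs — strongly connected but
weakly activated nodes invisible to amplitude-based mapping — is the dark
functional network.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Hashable, Iterable, Mapping, Set

import networkx as nx
import numpy as np
import pandas as pd

from ampconn import pajek
from ampconn.netmetrics import eigenvector_centrality, weighted_degree
from ampconn.synthcohort import RoiAtlas

log = logging.getLogger(__name__)

__all__ = [
    "LABELS",
    "CLASS_CODES",
    "detect_hotspots",
    "detect_hubs",
    "classify_nodes",
    "classification_table",
    "dark_network",
    "aggregate_to_original",
    "export_four_color_network",
]

#: The four node types, in Pajek class-code order 1..4.
LABELS = ("hothub", "coldhub", "nonhub_hotspot", "nonhub_coldspot")
CLASS_CODES = {label: code for code, label in enumerate(LABELS, start=1)}


def detect_hotspots(amplitudes: Mapping[Hashable, float] | pd.Series) -> Set[Hashable]:
    """Nodes whose amplitude strictly exceeds mean + 1 sample SD.

    Constant amplitude fields have no hotspots (SD = 0, strict inequality).
    """
    series = pd.Series(dict(amplitudes) if not isinstance(amplitudes, pd.Series) else amplitudes)
    if len(series) < 2:
        raise ValueError("hotspot detection needs at least 2 nodes")
    threshold = series.mean() + series.std(ddof=1)
    return set(series.index[series > threshold])


def detect_hubs(g: nx.Graph, k: int) -> Set[Hashable]:
    """Top-k nodes by weighted eigenvector centrality.

    Ties at the k-boundary are broken by stable node-id order (smaller id
    retained); a log entry records every tie-break.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > g.number_of_nodes():
        raise ValueError("k cannot exceed the node count")
    if k == 0:
        return set()
    scores = (
        eigenvector_centrality(g)
        if g.number_of_edges() > 0
        else {v: 0.0 for v in g.nodes}
    )
    # round away eigensolver noise so tie-breaking is reproducible
    ranked = {v: round(s, 12) for v, s in scores.items()}
    order = sorted(ranked, key=lambda v: (-ranked[v], str(v)))
    if k < len(order) and ranked[order[k - 1]] == ranked[order[k]]:
        log.info(
            "detect_hubs: tie at the k=%d boundary (score %.6g); kept %r by node order",
            k, ranked[order[k - 1]], order[k - 1],
        )
    return set(order[:k])


def classify_nodes(
    hotspots: Iterable[Hashable],
    hubs: Iterable[Hashable],
    all_nodes: Iterable[Hashable],
) -> Dict[Hashable, str]:
    """Four-way label per node from the hotspot and hub sets."""
    hotspots = set(hotspots)
    hubs = set(hubs)
    nodes = list(all_nodes)
    stray = (hotspots | hubs) - set(nodes)
    if stray:
        raise ValueError(f"hotspots/hubs outside the node set: {sorted(map(str, stray))[:5]}")
    out = {}
    for v in nodes:
        if v in hubs:
            out[v] = "hothub" if v in hotspots else "coldhub"
        else:
            out[v] = "nonhub_hotspot" if v in hotspots else "nonhub_coldspot"
    return out


def classification_table(
    g: nx.Graph,
    amplitude_z: Mapping[Hashable, float] | pd.Series,
    stage: str = "",
    group: str = "",
) -> pd.DataFrame:
    """Full classification flow on one graph.

    Detects hotspots on the amplitude z-scores, sets the hub count to the
    hotspot count, classifies every node and returns a table with the label,
    amplitude z, eigenvector score and hub rank (1 = strongest hub, NaN for
    non-hubs).
    """
    amplitude_z = pd.Series(dict(amplitude_z) if not isinstance(amplitude_z, pd.Series) else amplitude_z)
    missing = [v for v in g.nodes if v not in amplitude_z.index]
    if missing:
        raise ValueError(f"amplitude z missing for nodes: {missing[:5]}")
    amplitude_z = amplitude_z.loc[list(g.nodes)]
    hotspots = detect_hotspots(amplitude_z)
    hubs = detect_hubs(g, len(hotspots))
    labels = classify_nodes(hotspots, hubs, g.nodes)
    scores = (
        eigenvector_centrality(g)
        if g.number_of_edges() > 0
        else {v: 0.0 for v in g.nodes}
    )
    order = sorted(scores, key=lambda v: (-scores[v], str(v)))
    rank = {v: i + 1 for i, v in enumerate(order) if v in hubs}
    return pd.DataFrame(
        {
            "node": list(g.nodes),
            "label": [labels[v] for v in g.nodes],
            "amplitude_z": [float(amplitude_z[v]) for v in g.nodes],
            "eigenvector": [float(scores[v]) for v in g.nodes],
            "hub_rank": [rank.get(v, np.nan) for v in g.nodes],
            "stage": stage,
            "group": group,
        }
    ).set_index("node")


def dark_network(g: nx.Graph, classification: Mapping[Hashable, str]) -> nx.Graph:
    """Subgraph induced by the coldhubs, weights preserved."""
    cold = [v for v in g.nodes if classification.get(v) == "coldhub"]
    return g.subgraph(cold).copy()


def aggregate_to_original(
    classification: Mapping[Hashable, str] | pd.DataFrame,
    atlas: RoiAtlas,
) -> pd.DataFrame:
    """Original-scout hothub list: flagged iff >= 1 refined child is a hothub.

    Returns one row per original scout carrying a hothub, annotated with the
    module id and module/system name.  Idempotent in the number of flagged
    children.
    """
    if isinstance(classification, pd.DataFrame):
        labels = dict(zip(classification.index, classification["label"]))
    else:
        labels = dict(classification)
    original_of = atlas.original_of()
    module_of = atlas.module_of()
    names = atlas.module_names()
    unmapped = [v for v in labels if v not in original_of]
    if unmapped:
        raise ValueError(f"atlas does not map nodes: {sorted(map(str, unmapped))[:5]}")
    flagged: Dict[str, Dict] = {}
    for v, label in labels.items():
        if label != "hothub":
            continue
        o = original_of[v]
        entry = flagged.setdefault(
            o,
            {
                "original_id": o,
                "module": module_of[v],
                "module_name": names.get(module_of[v], ""),
                "n_hothub_children": 0,
            },
        )
        entry["n_hothub_children"] += 1
    return (
        pd.DataFrame(sorted(flagged.values(), key=lambda d: d["original_id"]))
        if flagged
        else pd.DataFrame(
            columns=["original_id", "module", "module_name", "n_hothub_children"]
        )
    )


def export_four_color_network(
    g: nx.Graph,
    classification: Mapping[Hashable, str] | pd.DataFrame,
    path_prefix,
    amplitude_z: Mapping[Hashable, float] | None = None,
    top_edges: int = 100,
) -> Dict[str, Path]:
    """Write the four-color network: Pajek NET + class CLU + two size VECs.

    The NET file keeps all nodes but only the ``top_edges`` heaviest edges
    (fewer when the graph is smaller).  The CLU codes the four node types
    1..4 in the order hothub, coldhub, nonhub_hotspot, nonhub_coldspot.  The
    two vector files carry the amplitude z-scores and the weighted degrees —
    the two node-size conventions of the visualization.
    """
    if isinstance(classification, pd.DataFrame):
        amplitude_z = dict(zip(classification.index, classification["amplitude_z"]))
        labels = dict(zip(classification.index, classification["label"]))
    else:
        labels = dict(classification)
        if amplitude_z is None:
            raise ValueError("amplitude_z is required with a plain classification mapping")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    ranked = sorted(
        g.edges(data="weight", default=1.0), key=lambda e: (-e[2], str(e[0]), str(e[1]))
    )[:top_edges]
    top = nx.Graph()
    top.add_nodes_from(g.nodes)
    top.add_weighted_edges_from(ranked)

    order = list(g.nodes)
    paths = {
        "net": prefix.with_suffix(".net"),
        "clu": prefix.with_suffix(".clu"),
        "amplitude_vec": prefix.parent / (prefix.name + "_amplitude.vec"),
        "degree_vec": prefix.parent / (prefix.name + "_degree.vec"),
    }
    pajek.write_net(top, paths["net"], node_order=order)
    pajek.write_clu([CLASS_CODES[labels[v]] for v in order], paths["clu"])
    pajek.write_vec([float(amplitude_z[v]) for v in order], paths["amplitude_vec"])
    pajek.write_vec([weighted_degree(g, v) for v in order], paths["degree_vec"])
    return paths
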