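"""Pajek NET / CLU / VEC readers and writers.

Minimal, self-contained support for the subset of the Pajek format family
used here: ``*Vertices`` with quoted labels, ``*Edges`` with weights
(1-based vertex numbering), class partitions (CLU) and size vectors (VEC).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Hashable, List, Sequence

import networkx as nx

__all__ = ["write_net", "read_net", "write_clu", "read_clu", "write_vec", "read_vec"]


def write_net(g: nx.Graph, path, node_order: Sequence[Hashable] | None = None) -> List[Hashable]:
    """Write a weighted undirected graph; returns the vertex order used."""
    order = list(node_order) if node_order is not None else list(g.nodes)
    index = {v: i + 1 for i, v in enumerate(order)}
    lines = [f"*Vertices {len(order)}"]
    lines += [f'{i + 1} "{v}"' for i, v in enumerate(order)]
    lines.append("*Edges")
    for u, v, w in g.edges(data="weight", default=1.0):
        lines.append(f"{index[u]} {index[v]} {w:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")
    return order


def read_net(path) -> nx.Graph:
    g = nx.Graph()
    labels: Dict[int, str] = {}
    mode = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            mode = "vertices"
            continue
        if low.startswith("*edges") or low.startswith("*arcs"):
            mode = "edges"
            continue
        if mode == "vertices":
            parts = line.split(None, 1)
            idx = int(parts[0])
            label = parts[1].strip() if len(parts) > 1 else str(idx)
            if label.startswith('"') and '"' in label[1:]:
                label = label[1 : label.index('"', 1)]
            labels[idx] = label
            g.add_node(label)
        elif mode == "edges":
            parts = line.split()
            u, v = int(parts[0]), int(parts[1])
            w = float(parts[2]) if len(parts) > 2 else 1.0
            g.add_edge(labels.get(u, str(u)), labels.get(v, str(v)), weight=w)
    return g


def write_clu(classes: Sequence[int], path) -> None:
    lines = [f"*Vertices {len(classes)}"] + [str(int(c)) for c in classes]
    Path(path).write_text("\n".join(lines) + "\n")


def read_clu(path) -> List[int]:
    out: List[int] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("*") or line.startswith("%"):
            continue
        out.append(int(float(line)))
    return out


def write_vec(values: Sequence[float], path) -> None:
    lines = [f"*Vertices {len(values)}"] + [f"{float(v):.10g}" for v in values]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vec(path) -> List[float]:
    out: List[float] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("*") or line.startswith("%"):
            continue
        out.append(float(line))
    return out
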