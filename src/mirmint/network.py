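"""Bipartite miR-gene evidence networks and degree centralization.

One undirected node per distinct miR and gene, one edge per integrated
couple on the requested day.  Topology metrics (components, Freeman degree
centralization) treat the graph as simple and undirected, ignoring edge
sign.  A star (every edge on one hub) has centralization exactly 1, a
regular graph exactly 0:

    C = sum_i (d_max - d_i) / ((n - 1) * (n - 2))

Exports are SIF (``miR regulates gene``) for quick loading into viewers
such as Cytoscape, and GraphML carrying node-type and edge-sign attributes.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import DegenerateInputError, ParameterError


def build_network(records: pd.DataFrame, day: int | None = None) -> nx.Graph:
    """Bipartite graph from couple records (columns mir, gene, optionally day/sign/r).

    ``day=None`` uses all rows.  Node attribute ``kind`` is ``"mir"`` or
    ``"gene"``; edge attributes carry sign and day when available.
    """
    g = nx.Graph()
    if records.empty:
        return g
    sub = records if day is None else records.loc[records["day"] == day]
    for _, row in sub.iterrows():
        mir = f"mir:{row['mir']}"
        gene = f"gene:{row['gene']}"
        g.add_node(mir, kind="mir", label=str(row["mir"]))
        g.add_node(gene, kind="gene", label=str(row["gene"]))
        attrs = {}
        if "sign" in row:
            attrs["sign"] = str(row["sign"])
        elif "r" in row and pd.notna(row["r"]):
            attrs["sign"] = "positive" if row["r"] >= 0 else "negative"
        if "day" in row:
            attrs["day"] = int(row["day"])
        g.add_edge(mir, gene, **attrs)
    return g


def connected_subnetworks(net: nx.Graph) -> list[nx.Graph]:
    """Connected components as subgraph copies, largest (by node count) first."""
    comps = [net.subgraph(c).copy() for c in nx.connected_components(net)]
    return sorted(comps, key=lambda g: (-g.number_of_nodes(), sorted(g.nodes)[0]))


def degree_centralization(net: nx.Graph) -> float:
    """Freeman degree centralization of a simple undirected graph (n >= 3)."""
    n = net.number_of_nodes()
    if n < 3:
        raise DegenerateInputError(f"degree centralization needs >= 3 nodes, got {n}")
    degrees = [d for _, d in net.degree()]
    d_max = max(degrees)
    return float(sum(d_max - d for d in degrees)) / ((n - 1) * (n - 2))


def export_network(net: nx.Graph, path: str | Path, format: str = "sif") -> Path:
    """Write the network as SIF or GraphML; returns the path written."""
    path = Path(path)
    if format == "sif":
        lines = []
        for u, v in sorted(net.edges()):
            mir, gene = (u, v) if net.nodes[u].get("kind") == "mir" else (v, u)
            lines.append(f"{net.nodes[mir].get('label', mir)}\tregulates\t{net.nodes[gene].get('label', gene)}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ParameterError(f"unknown export format {format!r}; use 'sif' or 'graphml'")
    return path


def read_network(path: str | Path, format: str = "sif") -> nx.Graph:
    """Read back an exported network (round-trips :func:`export_network`)."""
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        out = nx.Graph()
        for node, attrs in g.nodes(data=True):
            out.add_node(node, **attrs)
        for u, v, attrs in g.edges(data=True):
            out.add_edge(u, v, **{k: v2 for k, v2 in attrs.items() if k != "id"})
        return out
    if format != "sif":
        raise ParameterError(f"unknown import format {format!r}")
    g = nx.Graph()
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParameterError(f"{path.name}: malformed SIF line {lineno}: {line!r}")
        mir, _, gene = parts
        g.add_node(f"mir:{mir}", kind="mir", label=mir)
        g.add_node(f"gene:{gene}", kind="gene", label=gene)
        g.add_edge(f"mir:{mir}", f"gene:{gene}")
    return g
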