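"""Weighted social networks aggregated from the contact table.

Nodes are animal IDs (isolated animals are kept so the graph always
shows the whole group); an undirected edge's weight is the contact
frequency between the pair — either the number of per-frame contact
rows (default) or the number of merged contact episodes.  Networks can
be restricted to one contact type, which never increases a weight.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx
import pandas as pd

from .contacts import ContactTable, HEAD_HEAD, HEAD_TAIL

TYPE_FILTERS = ("all", HEAD_HEAD, HEAD_TAIL)
UNITS = ("frames", "episodes")


def build_network(table: ContactTable, type_filter: str = "all",
                  unit: str = "frames", node_ids: Optional[Iterable[int]] = None,
                  gap_tolerance: int = 5) -> nx.Graph:
    """Aggregate contacts into a weighted undirected graph.

    ``node_ids`` should list all tracked animals so isolated ones appear;
    when omitted, only animals seen in the table become nodes.
    """
    if type_filter not in TYPE_FILTERS:
        raise ValueError(f"unknown type filter {type_filter!r}; "
                         f"expected one of {TYPE_FILTERS}")
    if unit not in UNITS:
        raise ValueError(f"unknown weighting unit {unit!r}; "
                         f"expected one of {UNITS}")
    g = nx.Graph(type_filter=type_filter, unit=unit)
    if node_ids is not None:
        g.add_nodes_from(int(i) for i in node_ids)
    if unit == "frames":
        items = [(e.id_a, e.id_b, e.type) for e in table.events]
    else:
        items = [(ep.id_a, ep.id_b, ep.type)
                 for ep in table.episodes(gap_tolerance)]
    for (a, b, typ) in items:
        if type_filter != "all" and typ != type_filter:
            continue
        g.add_node(a)
        g.add_node(b)
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
        else:
            g.add_edge(a, b, weight=1)
    return g


def export_network(net: nx.Graph, path, fmt: Optional[str] = None) -> Path:
    """Write the network as GraphML or an edge-list CSV (by extension)."""
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix.lower() == ".graphml" else "csv"
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "csv":
        rows = [{"id_a": a, "id_b": b, "weight": int(d["weight"])}
                for a, b, d in net.edges(data=True)]
        df = pd.DataFrame(rows, columns=["id_a", "id_b", "weight"])
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def import_network(path, fmt: Optional[str] = None) -> nx.Graph:
    """Read back a network written by :func:`export_network`."""
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix.lower() == ".graphml" else "csv"
    if fmt == "graphml":
        g = nx.read_graphml(path)
        # GraphML stringifies node ids; restore integers
        mapping = {n: int(n) for n in g.nodes}
        g = nx.relabel_nodes(g, mapping)
        for _, _, d in g.edges(data=True):
            d["weight"] = int(d["weight"])
        return g
    g = nx.Graph()
    df = pd.read_csv(path)
    for row in df.itertuples(index=False):
        g.add_edge(int(row.id_a), int(row.id_b), weight=int(row.weight))
    return g


def plot_network(net: nx.Graph, path=None, seed: int = 0, ax=None):
    """Draw the network with edge thickness proportional to weight."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    pos = nx.spring_layout(net, seed=seed)
    weights = [net[a][b]["weight"] for a, b in net.edges]
    wmax = max(weights) if weights else 1
    nx.draw_networkx_nodes(net, pos, ax=ax, node_color="#e8a0a0",
                           node_size=500)
    nx.draw_networkx_labels(net, pos, ax=ax)
    nx.draw_networkx_edges(net, pos, ax=ax,
                           width=[0.5 + 4.0 * w / wmax for w in weights])
    title = net.graph.get("type_filter", "all")
    ax.set_title(f"contacts: {title}")
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
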