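"""Pairwise-screen enumeration and interaction-network construction.

An all-vs-all screen over n proteins (homodimers included) has
n*(n+1)/2 unique combinations. Pairs whose ensemble mean ranking
confidence reaches the cutoff (default 0.4, inclusive) become edges of
the interaction graph; relative to a chosen hub protein, component edges
are classified as direct (incident to the hub) or indirect (reached
through a neighbor).
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import networkx as nx

from .types import ProteinEntry, ScreenEntry

__all__ = ["enumerate_pairs", "build_network", "hub_component", "graph_to_dict"]

DEFAULT_MEAN_RC_CUTOFF = 0.4


def enumerate_pairs(proteins: Sequence[ProteinEntry]) -> list[tuple[str, str]]:
    """All unordered pairs including self-pairs, lexicographically ordered.

    For n proteins this is exactly n*(n+1)/2 combinations (15 -> 120).
    """
    names = [p.name for p in proteins]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate protein names: {dupes}")
    ordered = sorted(names)
    return [
        (ordered[i], ordered[j])
        for i in range(len(ordered))
        for j in range(i, len(ordered))
    ]


def build_network(
    entries: Iterable[ScreenEntry],
    cutoff: float = DEFAULT_MEAN_RC_CUTOFF,
    proteins: Optional[Sequence[ProteinEntry]] = None,
) -> nx.Graph:
    """Threshold the screen into an interaction graph.

    An edge is kept iff its ensemble mean rc >= cutoff (inclusive).
    Nodes cover every screened protein, including isolated ones;
    homodimers become self-loops. The graph records ``cutoff_used`` and
    each edge carries its :class:`ScreenEntry`.
    """
    g = nx.Graph(cutoff_used=cutoff)
    sides = {p.name: p.side for p in proteins} if proteins else {}
    for entry in entries:
        a, b = entry.pair
        for name in (a, b):
            g.add_node(name, side=sides.get(name))
        if entry.mean_rc >= cutoff:
            g.add_edge(a, b, entry=entry, mean_rc=entry.mean_rc, top_rc=entry.top_rc)
    if proteins:
        for p in proteins:
            g.add_node(p.name, side=p.side)
    return g


def hub_component(graph: nx.Graph, hub: str) -> nx.Graph:
    """Connected component of ``hub``, edges classified direct/indirect.

    Edges incident to the hub are ``direct``; every other edge of the
    component is ``indirect`` and annotated with the first-hop neighbor
    (``via``) on a shortest path from the hub to the edge's nearer
    endpoint, ties broken lexicographically. Self-loops are classified
    ``homodimer``: a protein's self-interaction is one interaction of its
    own kind and never a direct (or indirect) hub edge.
    """
    if hub not in graph:
        raise KeyError(f"hub {hub!r} not in graph")
    component = nx.node_connected_component(graph, hub)
    sub = graph.subgraph(component).copy()
    dist = nx.single_source_shortest_path_length(sub, hub)
    for u, v, data in sub.edges(data=True):
        if u == v:
            # a homodimer never counts as a direct (or indirect) hub edge
            data["classification"] = "homodimer"
            data["via"] = None
        elif hub in (u, v):
            data["classification"] = "direct"
            data["via"] = None
        else:
            # nearer endpoint to the hub; its own predecessor neighbor
            near = min((u, v), key=lambda n: (dist[n], n))
            if dist[near] == 1:
                via = near
            else:
                preds = [
                    n for n in sorted(sub.neighbors(near)) if dist.get(n, 1 << 30) == dist[near] - 1
                ]
                via = preds[0] if preds else None
            data["classification"] = "indirect"
            data["via"] = via
    return sub


def graph_to_dict(graph: nx.Graph) -> dict:
    """JSON-serializable form of an interaction graph."""
    nodes = [
        {"name": n, "side": data.get("side")} for n, data in sorted(graph.nodes(data=True))
    ]
    edges = []
    for u, v, data in sorted(graph.edges(data=True)):
        entry: Optional[ScreenEntry] = data.get("entry")
        edges.append(
            {
                "pair": sorted((u, v)),
                "mean_rc": round(data.get("mean_rc", float("nan")), 3),
                "top_rc": round(data.get("top_rc", float("nan")), 3),
                "n_models": entry.n_models if entry else None,
                "classification": data.get("classification"),
                "via": data.get("via"),
            }
        )
    return {
        "cutoff_used": graph.graph.get("cutoff_used"),
        "nodes": nodes,
        "edges": edges,
    }
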