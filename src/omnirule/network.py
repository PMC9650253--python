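"""Association-rule graphs and Gephi-ready export.

Mined rules are flattened into a directed item graph: every
(antecedent item, consequent item) pair of a rule contributes one
edge, parallel contributions are aggregated (maximum lift, rule
multiplicity), and the graph is exported as GEXF (Gephi's native
format) or GraphML for interactive exploration.  Ego subgraphs around
focus items (a cluster-class item, a species, a habitat) reproduce
the "rules centred on X" views.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .apriori import AssociationRule

__all__ = ["rules_to_graph", "ego_subgraph", "export_graph", "read_graph"]


def _node_attrs(item: str) -> dict[str, str]:
    # "ns:var=level" -> namespace/level; "key=value" -> namespace=key
    head, _, level = item.partition("=")
    ns, sep, _ = head.partition(":")
    return {"namespace": ns if (sep or "=" in item) else "item", "level": level}


def rules_to_graph(rules: Sequence[AssociationRule]) -> nx.DiGraph:
    """Directed item graph from association rules.

    Nodes are items (with ``namespace`` and ``level`` attributes);
    for each rule every antecedent item points at every consequent
    item.  Parallel edges from multiple rules are merged keeping the
    maximum lift (with that rule's support and confidence) and a
    ``multiplicity`` counting contributing rules.  An empty rule list
    yields an empty graph with a warning.
    """
    g = nx.DiGraph()
    if not rules:
        warnings.warn("no rules given; returning an empty graph", stacklevel=2)
        return g
    for rule in rules:
        for a in sorted(rule.antecedent):
            for c in sorted(rule.consequent):
                if a == c:  # disjointness makes this unreachable; keep the guard
                    continue
                for node in (a, c):
                    if node not in g:
                        g.add_node(node, **_node_attrs(node))
                if g.has_edge(a, c):
                    e = g[a][c]
                    e["multiplicity"] += 1
                    if rule.lift > e["lift"]:
                        e.update(
                            lift=rule.lift,
                            support=rule.support,
                            confidence=rule.confidence,
                        )
                else:
                    g.add_edge(
                        a,
                        c,
                        lift=rule.lift,
                        support=rule.support,
                        confidence=rule.confidence,
                        multiplicity=1,
                    )
    return g


def ego_subgraph(
    graph: nx.DiGraph, focus_items: Iterable[str], radius: int = 1
) -> nx.DiGraph:
    """Induced subgraph within ``radius`` undirected hops of any focus item.

    Radius 0 returns the focus nodes alone (with any edges among
    them).  Unknown focus items only warn; if none exist the result is
    empty.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    focus = list(focus_items)
    present = [f for f in focus if f in graph]
    missing = sorted(set(focus) - set(present))
    if missing:
        warnings.warn(f"focus item(s) not in graph: {missing}", stacklevel=2)
    undirected = graph.to_undirected(as_view=True)
    keep: set[str] = set()
    for f in present:
        keep |= set(
            nx.single_source_shortest_path_length(undirected, f, cutoff=radius)
        )
    return graph.subgraph(keep).copy()


def export_graph(
    graph: nx.DiGraph, path: str | Path, format: str = "gexf"
) -> Path:
    """Write the graph as GEXF (default) or GraphML.

    Both formats preserve node and edge attributes and re-import
    losslessly with any standards-conformant reader (Gephi, igraph,
    networkx).
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "gexf":
        nx.write_gexf(graph, path)
    elif fmt == "graphml":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"format must be gexf|graphml, got {format!r}")
    return path


def read_graph(path: str | Path, format: str | None = None) -> nx.DiGraph:
    """Read a graph written by :func:`export_graph` (format from suffix)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "gexf":
        return nx.DiGraph(nx.read_gexf(path))
    if fmt == "graphml":
        return nx.DiGraph(nx.read_graphml(path))
    raise ValueError(f"cannot infer graph format from {path}")
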