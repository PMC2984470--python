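"""Explaining subgraphs: why was this entity ranked where it was?

For a content ranker (BM25) the explanation is the result plus its direct
neighbors that themselves contain a query keyword.  For authority-flow
ranking the explanation is the union of all short directed paths from
keyword-bearing (base-set) entities to the result: entities on those
paths either contain the keywords themselves or act as intermediates
passing authority along.  Members are categorized as ``result``,
``keyword_bearing`` or ``intermediate`` (a node can be both the result
and keyword-bearing); the subgraph can be exported as Graphviz DOT with
the category encoded as a fill colour and the entity's attributes as a
tooltip.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .graph import DataGraph, Edge
from .text import CollectionStats, EmptyBaseSetError, Query, base_set, build_stats

__all__ = ["ExplainingSubgraph", "explain_bm25", "explain_co", "to_dot"]

_CATEGORY_COLOURS = {
    "result": "gold",
    "keyword_bearing": "palegreen",
    "intermediate": "lightsteelblue",
}


@dataclass(frozen=True)
class ExplainingSubgraph:
    """A result-centred subgraph justifying one ranked entity."""

    result: str
    members: dict[str, frozenset[str]]  # node id -> categories
    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        if self.result not in self.members:
            raise ValueError("the result node must be a member of its explanation")

    @property
    def member_ids(self) -> frozenset[str]:
        return frozenset(self.members)

    def categories(self, node_id: str) -> frozenset[str]:
        return self.members[node_id]


def _bears_keyword(node_id: str, query: Query, stats: CollectionStats) -> bool:
    return any(
        node_id in stats.postings.get(term, {}) for term in query.terms
    )


def explain_bm25(
    result: str,
    query: Query,
    graph: DataGraph,
    stats: CollectionStats | None = None,
) -> ExplainingSubgraph:
    """Result plus direct neighbors (either direction) bearing ≥1 query term."""
    graph.node(result)  # raises for unknown ids
    if stats is None:
        stats = build_stats(graph)

    members: dict[str, set[str]] = {result: {"result"}}
    if _bears_keyword(result, query, stats):
        members[result].add("keyword_bearing")
    keep: set[str] = set()
    for neighbor in graph.neighbors(result):
        if _bears_keyword(neighbor, query, stats):
            keep.add(neighbor)
            members[neighbor] = {"keyword_bearing"}
    edges = tuple(
        e for e in graph.edges
        if {e.source, e.target} <= keep | {result}
        and result in (e.source, e.target)
    )
    return ExplainingSubgraph(
        result, {nid: frozenset(cats) for nid, cats in members.items()}, edges
    )


def explain_co(
    result: str,
    query: Query,
    graph: DataGraph,
    max_path_len: int = 3,
    stats: CollectionStats | None = None,
    base_set_mode: str = "conjunctive",
) -> ExplainingSubgraph:
    """Union of directed paths (≤ max_path_len edges) from base-set
    entities to the result; on-path entities that bear no query term are
    categorized as intermediates."""
    graph.node(result)
    if max_path_len < 1:
        raise ValueError("max_path_len must be at least 1")
    if stats is None:
        stats = build_stats(graph)
    try:
        sources, _ = base_set(query, graph, stats=stats, mode=base_set_mode)
    except EmptyBaseSetError:
        sources = frozenset()

    g = nx.DiGraph()
    g.add_nodes_from(graph.node_ids)
    g.add_edges_from((e.source, e.target) for e in graph.edges)

    on_path: set[str] = {result}
    path_edges: set[tuple[str, str]] = set()
    for src in sources:
        if src == result:
            continue
        for path in nx.all_simple_paths(g, src, result, cutoff=max_path_len):
            on_path.update(path)
            path_edges.update(zip(path, path[1:]))

    members: dict[str, frozenset[str]] = {}
    for nid in on_path:
        cats = set()
        if nid == result:
            cats.add("result")
        if _bears_keyword(nid, query, stats):
            cats.add("keyword_bearing")
        if not cats:
            cats.add("intermediate")
        members[nid] = frozenset(cats)

    edges = tuple(
        e for e in graph.edges if (e.source, e.target) in path_edges
    )
    return ExplainingSubgraph(result, members, edges)


def to_dot(sub: ExplainingSubgraph, graph: DataGraph) -> str:
    """Render as Graphviz DOT; categories colour nodes, attributes become
    tooltips so detail shows on hover in rendered output."""
    lines = ["digraph explanation {", "  rankdir=LR;"]
    for nid in sorted(sub.member_ids):
        node = graph.node(nid)
        cats = sorted(sub.categories(nid))
        colour = next(
            (_CATEGORY_COLOURS[c] for c in ("result", "keyword_bearing",
                                            "intermediate") if c in cats),
            "white",
        )
        tooltip = "; ".join(f"{k}: {v}" for k, v in node.attributes) or node.label
        lines.append(
            f'  "{nid}" [label="{nid}\\n{node.label}", style=filled, '
            f'fillcolor={colour}, category="{",".join(cats)}", '
            f'tooltip="{tooltip}"];'
        )
    for edge in sub.edges:
        lines.append(f'  "{edge.source}" -> "{edge.target}" [label="{edge.role}"];')
    lines.append("}")
    return "\n".join(lines)
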