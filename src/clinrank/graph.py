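"""Labelled directed entity graphs for clinical record collections.

A clinical web is modelled as a data graph ``D(V, E)``: every node is an
entity (a patient, a hospitalization, a medication, ...) carrying a label
and an ordered list of attribute name/value pairs whose text forms the
entity's bag of words; every edge is a typed relationship between two
entities.  A schema graph describes which labels and which
(source label, target label, role) triples are allowed.

Graphs are serialized as two tab-delimited tables (``nodes.tsv`` and
``edges.tsv``) and can also be extracted from simple XML documents whose
elements cross-reference each other through ID/IDREF attributes, in the
style of HL7 CDA documents.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

__all__ = [
    "Node",
    "Edge",
    "DataGraph",
    "SchemaGraph",
    "GraphError",
    "load_data_graph",
    "write_data_graph",
    "validate_against_schema",
    "parse_idref_xml",
]

#: delimiter separating serialized name=value attribute pairs in nodes.tsv
ATTR_SEP = "\x1f"


class GraphError(ValueError):
    """Raised when a graph violates its structural invariants."""


@dataclass(frozen=True)
class Node:
    """An entity: unique id, role label, and attribute name/value pairs."""

    id: str
    label: str
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.label:
            raise GraphError(f"node {self.id!r} has an empty label")
        names = [name for name, _ in self.attributes]
        if len(names) != len(set(names)):
            raise GraphError(f"node {self.id!r} has duplicate attribute names")

    @property
    def text(self) -> str:
        """All attribute values concatenated — the node's bag-of-words source."""
        return " ".join(value for _, value in self.attributes)


@dataclass(frozen=True)
class Edge:
    """A typed relationship from one entity to another."""

    source: str
    target: str
    role: str = ""


class DataGraph:
    """A labelled directed graph of clinical entities.

    Node order is significant: it fixes the row/column indexing of the
    authority-transfer matrix, so it is preserved exactly as given
    (node-table row order for loaded graphs).
    """

    def __init__(self, nodes: Iterable[Node] = (), edges: Iterable[Edge] = ()):
        self._nodes: list[Node] = []
        self._index: dict[str, int] = {}
        self._edges: list[Edge] = []
        for node in nodes:
            self.add_node(node)
        for edge in edges:
            self.add_edge(edge)

    # -- construction -------------------------------------------------

    def add_node(self, node: Node) -> None:
        if node.id in self._index:
            raise GraphError(f"duplicate node id {node.id!r}")
        self._index[node.id] = len(self._nodes)
        self._nodes.append(node)

    def add_edge(self, edge: Edge) -> None:
        for endpoint in (edge.source, edge.target):
            if endpoint not in self._index:
                raise GraphError(
                    f"edge {edge.source!r}->{edge.target!r} references "
                    f"unknown node {endpoint!r}"
                )
        self._edges.append(edge)

    # -- access --------------------------------------------------------

    @property
    def nodes(self) -> tuple[Node, ...]:
        return tuple(self._nodes)

    @property
    def edges(self) -> tuple[Edge, ...]:
        return tuple(self._edges)

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(node.id for node in self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def __iter__(self) -> Iterator[Node]:
        return iter(self._nodes)

    def node(self, node_id: str) -> Node:
        try:
            return self._nodes[self._index[node_id]]
        except KeyError:
            raise GraphError(f"unknown node id {node_id!r}") from None

    def index_of(self, node_id: str) -> int:
        """Position of the node in insertion (matrix) order."""
        try:
            return self._index[node_id]
        except KeyError:
            raise GraphError(f"unknown node id {node_id!r}") from None

    def out_degree(self, node_id: str) -> int:
        self.node(node_id)
        return sum(1 for e in self._edges if e.source == node_id)

    def out_edges(self, node_id: str) -> tuple[Edge, ...]:
        return tuple(e for e in self._edges if e.source == node_id)

    def in_edges(self, node_id: str) -> tuple[Edge, ...]:
        return tuple(e for e in self._edges if e.target == node_id)

    def neighbors(self, node_id: str) -> set[str]:
        """Adjacent node ids in either edge direction (excluding self)."""
        self.node(node_id)
        out = {e.target for e in self._edges if e.source == node_id}
        inc = {e.source for e in self._edges if e.target == node_id}
        return (out | inc) - {node_id}

    def self_loops(self) -> list[Edge]:
        return [e for e in self._edges if e.source == e.target]

    def to_networkx(self):
        """Export as a networkx MultiDiGraph (labels/roles as attributes)."""
        import networkx as nx

        g = nx.MultiDiGraph()
        for node in self._nodes:
            g.add_node(node.id, label=node.label)
        for edge in self._edges:
            g.add_edge(edge.source, edge.target, role=edge.role)
        return g


@dataclass
class SchemaGraph:
    """Allowed node labels and (source label, target label, role) edge rules."""

    labels: set[str]
    edge_rules: set[tuple[str, str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for src, tgt, role in self.edge_rules:
            if src not in self.labels or tgt not in self.labels:
                raise GraphError(
                    f"edge rule ({src!r}, {tgt!r}, {role!r}) references an "
                    "undeclared label"
                )

    def allows_edge(self, src_label: str, tgt_label: str, role: str) -> bool:
        return (src_label, tgt_label, role) in self.edge_rules


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _serialize_attributes(attrs: tuple[tuple[str, str], ...]) -> str:
    return ATTR_SEP.join(f"{name}={value}" for name, value in attrs)


def _parse_attributes(raw: str) -> tuple[tuple[str, str], ...]:
    if not raw:
        return ()
    pairs = []
    for chunk in raw.split(ATTR_SEP):
        name, _, value = chunk.partition("=")
        pairs.append((name, value))
    return tuple(pairs)


def load_data_graph(node_table: str | Path, edge_table: str | Path) -> DataGraph:
    """Load a graph from its two tab-delimited dump tables.

    ``nodes.tsv`` has columns ``id``, ``label``, ``attributes`` (name=value
    pairs joined by a reserved delimiter); ``edges.tsv`` has columns
    ``source``, ``target``, ``role``.  Row order is preserved as node and
    edge order.  Duplicate node ids and dangling edge endpoints are
    rejected with the offending id named.
    """
    graph = DataGraph()
    for row in _read_tsv(node_table, ("id", "label", "attributes")):
        graph.add_node(
            Node(row["id"], row["label"], _parse_attributes(row["attributes"]))
        )
    for row in _read_tsv(edge_table, ("source", "target", "role")):
        graph.add_edge(Edge(row["source"], row["target"], row["role"]))
    return graph


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> Iterator[dict[str, str]]:
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        return
    header = lines[0].split("\t")
    missing = set(required) - set(header)
    if missing:
        raise GraphError(f"{path}: missing required columns {sorted(missing)}")
    for line in lines[1:]:
        if not line:
            continue
        fields = line.split("\t")
        yield dict(itertools.zip_longest(header, fields, fillvalue=""))


def write_data_graph(graph: DataGraph, node_table: str | Path,
                     edge_table: str | Path) -> None:
    """Write the two dump tables; inverse of :func:`load_data_graph`."""
    node_lines = ["id\tlabel\tattributes"]
    for node in graph.nodes:
        node_lines.append(
            f"{node.id}\t{node.label}\t{_serialize_attributes(node.attributes)}"
        )
    edge_lines = ["source\ttarget\trole"]
    for edge in graph.edges:
        edge_lines.append(f"{edge.source}\t{edge.target}\t{edge.role}")
    Path(node_table).write_text("\n".join(node_lines) + "\n", encoding="utf-8")
    Path(edge_table).write_text("\n".join(edge_lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Schema validation
# ---------------------------------------------------------------------------

def validate_against_schema(graph: DataGraph, schema: SchemaGraph) -> list[str]:
    """Check every node label and edge against the schema.

    Returns a list of human-readable violations (empty iff conformant).
    Violations are data, not exceptions: a loaded graph may legitimately
    predate its schema.  Self-loops are flagged as well.
    """
    violations: list[str] = []
    for node in graph.nodes:
        if node.label not in schema.labels:
            violations.append(
                f"node {node.id!r}: label {node.label!r} not declared in schema"
            )
    for edge in graph.edges:
        if edge.source == edge.target:
            violations.append(
                f"edge {edge.source!r}->{edge.target!r}: self-loop"
            )
        src_label = graph.node(edge.source).label
        tgt_label = graph.node(edge.target).label
        if (src_label in schema.labels and tgt_label in schema.labels
                and not schema.allows_edge(src_label, tgt_label, edge.role)):
            violations.append(
                f"edge {edge.source!r}->{edge.target!r} ({src_label!r}->"
                f"{tgt_label!r}, role {edge.role!r}) matches no schema rule"
            )
    return violations


# ---------------------------------------------------------------------------
# ID/IDREF XML extraction
# ---------------------------------------------------------------------------

def parse_idref_xml(document: str | bytes) -> DataGraph:
    """Extract a data graph from an XML document with ID/IDREF links.

    One node per element (labelled with the element tag); parent-child
    pairs become ``containment`` edges pointing parent→child, so authority
    flows from the document root toward its content; every ``IDREF``
    attribute adds an ``idref`` edge from the referring element to the
    element whose ``ID`` matches.  Attribute names ``ID``/``IDREF`` are
    recognized case-insensitively.  A dangling IDREF is rejected, naming
    the unresolved reference.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    root = etree.fromstring(document)

    graph = DataGraph()
    # hold references to every element proxy: their identity is only
    # stable while referenced, and the second pass relies on it
    elements = [e for e in root.iter() if isinstance(e.tag, str)]
    elem_id: dict[int, str] = {}       # python object id -> node id
    by_xml_id: dict[str, str] = {}     # declared ID value -> node id
    idrefs: list[tuple[str, str]] = []  # (referring node id, IDREF value)

    for i, elem in enumerate(elements):
        node_id = f"e{i + 1}"
        elem_id[id(elem)] = node_id
        tag = etree.QName(elem).localname
        attrs: list[tuple[str, str]] = []
        if elem.text and elem.text.strip():
            attrs.append(("text", elem.text.strip()))
        for name, value in elem.attrib.items():
            local = etree.QName(name).localname
            if local.upper() == "ID":
                by_xml_id[value] = node_id
            elif local.upper() == "IDREF":
                idrefs.append((node_id, value))
            else:
                attrs.append((local, value))
        graph.add_node(Node(node_id, tag, tuple(attrs)))

    for elem in elements:
        for child in elem:
            if id(child) in elem_id:
                graph.add_edge(
                    Edge(elem_id[id(elem)], elem_id[id(child)], "containment")
                )

    for referrer, ref in idrefs:
        if ref not in by_xml_id:
            raise GraphError(
                f"IDREF {ref!r} on node {referrer!r} matches no ID in the document"
            )
        graph.add_edge(Edge(referrer, by_xml_id[ref], "idref"))

    return graph
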