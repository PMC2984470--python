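"""Synthetic clinical webs: schema, generator, fixture and judgments.

Everything the rest of the package needs for testing and benchmarking is
generated here programmatically: a 9-entity-type cardiology schema
(patients, hospitalizations, employees, medications, diagnoses,
diagnostics, cardiac records, event plans, labs), a configurable random
corpus generator with controlled injection of query phrases into chosen
entity types, the small 7-node worked-example graph used throughout the
documentation, and synthetic relevance judgments implementing the two
scenarios that matter for comparing content and authority-flow rankers:
the query phrase sits in the result itself, or only in records linked to
it.

The shipped study-scale configuration reproduces the shape of a
six-month cardiology EHR extract: 15,092 entities of which 850 are
hospitalizations, connected by 31,492 typed relationships.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import DataGraph, Edge, GraphError, Node, SchemaGraph
from .text import Query, tokenize

__all__ = [
    "GeneratorConfig",
    "Manifest",
    "ehr_schema",
    "figure1_fixture",
    "generate",
    "make_judgments",
    "study_scale_config",
    "DEFAULT_QUERIES",
    "STUDY_NODE_COUNTS",
    "STUDY_EDGE_COUNTS",
]

#: queries named in the study prose; the full survey list is unpublished
DEFAULT_QUERIES = (
    "respiratory distress",
    "pericardial effusion",
    "tetralogy of fallot",
    "edema",
)

# background vocabulary: clinical-flavoured filler, deliberately disjoint
# from the default query phrases so injected phrases are the only match
_VOCAB = tuple((
    "patient stable ventricular atrial septal defect repair surgery recovery "
    "postoperative murmur auscultation echocardiogram catheter oxygen "
    "saturation discharge admission ward nurse attending rounds medication "
    "dose twice daily oral intravenous fluid balance chest examination "
    "normal sinus rhythm rate pressure systolic diastolic followup clinic "
    "weight height temperature afebrile alert feeding tolerated well plan "
    "continue monitor labs panel electrolyte hemoglobin count culture "
    "negative pending consult cardiology service note documented reviewed "
    "signed history unremarkable allergy none known improving"
).split())

_LABELS = (
    "Patient", "Hospitalization", "Employee", "Medication", "Diagnosis",
    "Diagnostics", "Cardiac", "Events", "Labs",
)

_EDGE_RULES = (
    ("Patient", "Hospitalization", "has_hospitalization"),
    ("Hospitalization", "Medication", "administered"),
    ("Hospitalization", "Diagnosis", "diagnosed_with"),
    ("Hospitalization", "Diagnostics", "underwent"),
    ("Hospitalization", "Events", "associated_events"),
    ("Hospitalization", "Labs", "ordered_labs"),
    ("Hospitalization", "Cardiac", "cardiac_record"),
    ("Medication", "Employee", "prescribed_by"),
    ("Events", "Employee", "created_by"),
    ("Diagnostics", "Employee", "performed_by"),
    ("Labs", "Employee", "reported_by"),
)

#: per-label entity counts of the study-scale corpus (sum 15,092; the
#: hospitalization count is fixed at 850, the rest allocated plausibly)
STUDY_NODE_COUNTS = {
    "Patient": 1200,
    "Hospitalization": 850,
    "Employee": 300,
    "Medication": 2500,
    "Diagnosis": 1900,
    "Diagnostics": 2342,
    "Cardiac": 1100,
    "Events": 2700,
    "Labs": 2200,
}

#: per-rule relationship counts of the study-scale corpus (sum 31,492)
STUDY_EDGE_COUNTS = {
    ("Patient", "Hospitalization", "has_hospitalization"): 850,
    ("Hospitalization", "Medication", "administered"): 4200,
    ("Hospitalization", "Diagnosis", "diagnosed_with"): 3600,
    ("Hospitalization", "Diagnostics", "underwent"): 4000,
    ("Hospitalization", "Events", "associated_events"): 3000,
    ("Hospitalization", "Labs", "ordered_labs"): 4100,
    ("Hospitalization", "Cardiac", "cardiac_record"): 2000,
    ("Medication", "Employee", "prescribed_by"): 2500,
    ("Events", "Employee", "created_by"): 2700,
    ("Diagnostics", "Employee", "performed_by"): 2342,
    ("Labs", "Employee", "reported_by"): 2200,
}


def ehr_schema() -> SchemaGraph:
    """The cardiology EHR schema: 9 entity labels, 11 edge rules."""
    return SchemaGraph(labels=set(_LABELS), edge_rules=set(_EDGE_RULES))


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random clinical-web generator.

    counts:          entities per label.
    edges_per_rule:  exact edge count per (source label, target label,
                     role) rule; endpoints drawn uniformly per rule.
    vocab:           background term pool sampled i.i.d. per node.
    text_len:        inclusive (min, max) background token count per node.
    injections:      (phrase, label, count) placements — the phrase is
                     appended verbatim to ``count`` distinct nodes of
                     ``label`` and every site recorded in the manifest.
    seed:            random seed; identical seed+config give identical output.
    """

    counts: dict[str, int] = field(default_factory=dict)
    edges_per_rule: dict[tuple[str, str, str], int] = field(default_factory=dict)
    vocab: tuple[str, ...] = _VOCAB
    text_len: tuple[int, int] = (20, 60)
    injections: tuple[tuple[str, str, int], ...] = ()
    seed: int = 0

    @classmethod
    def from_density(
        cls, counts: dict[str, int], edge_density: float, **kwargs
    ) -> "GeneratorConfig":
        """Convenience: derive per-rule edge counts from a mean out-degree
        applied to each rule's source-label population."""
        rules = {
            rule: int(round(edge_density * counts.get(rule[0], 0)))
            for rule in _EDGE_RULES
            if counts.get(rule[0], 0) and counts.get(rule[1], 0)
        }
        return cls(counts=counts, edges_per_rule=rules, **kwargs)

    def validate(self, schema: SchemaGraph) -> None:
        for label, count in self.counts.items():
            if label not in schema.labels:
                raise GraphError(f"count for undeclared label {label!r}")
            if count < 0:
                raise GraphError(f"negative count for label {label!r}")
        for rule, m in self.edges_per_rule.items():
            if rule not in schema.edge_rules:
                raise GraphError(f"edge counts for rule {rule} not in schema")
            if m < 0:
                raise GraphError(f"negative edge count for rule {rule}")
            if m > 0 and (
                self.counts.get(rule[0], 0) == 0 or self.counts.get(rule[1], 0) == 0
            ):
                raise GraphError(
                    f"impossible edge rule {rule}: no candidate endpoints"
                )
        for phrase, label, count in self.injections:
            if label not in schema.labels:
                raise GraphError(f"injection into undeclared label {label!r}")
            if count > self.counts.get(label, 0):
                raise GraphError(
                    f"cannot inject {phrase!r} into {count} nodes of "
                    f"{label!r}: only {self.counts.get(label, 0)} exist"
                )


def study_scale_config(
    injections: tuple[tuple[str, str, int], ...] = (), seed: int = 0
) -> GeneratorConfig:
    """The shipped configuration emulating the study corpus shape."""
    return GeneratorConfig(
        counts=dict(STUDY_NODE_COUNTS),
        edges_per_rule=dict(STUDY_EDGE_COUNTS),
        injections=injections,
        seed=seed,
    )


@dataclass(frozen=True)
class Manifest:
    """Ground truth of one generated corpus."""

    seed: int
    n_nodes: int
    n_edges: int
    injections: tuple[tuple[str, str, str], ...]  # (phrase, label, node id)

    def sites(self, phrase: str) -> set[str]:
        return {nid for p, _, nid in self.injections if p == phrase}


def generate(
    cfg: GeneratorConfig, schema: SchemaGraph | None = None
) -> tuple[DataGraph, Manifest]:
    """Generate a schema-conforming random clinical web.

    Node counts are exactly as configured; each edge realizes one schema
    rule with endpoints drawn uniformly within the rule's labels; every
    injected phrase lands verbatim in exactly the requested number of
    nodes, with all sites recorded in the manifest.
    """
    schema = schema or ehr_schema()
    cfg.validate(schema)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.text_len
    vocab = np.array(cfg.vocab)

    ids_by_label: dict[str, list[str]] = {}
    texts: dict[str, str] = {}
    for label in _LABELS:
        count = cfg.counts.get(label, 0)
        ids_by_label[label] = [f"{label}_{i + 1:05d}" for i in range(count)]
        for nid in ids_by_label[label]:
            length = int(rng.integers(lo, hi + 1))
            texts[nid] = " ".join(rng.choice(vocab, size=length))

    injection_sites: list[tuple[str, str, str]] = []
    for phrase, label, count in cfg.injections:
        chosen = rng.choice(len(ids_by_label[label]), size=count, replace=False)
        for idx in sorted(int(i) for i in chosen):
            nid = ids_by_label[label][idx]
            texts[nid] = f"{texts[nid]} {phrase}"
            injection_sites.append((phrase, label, nid))

    graph = DataGraph()
    for label in _LABELS:
        for nid in ids_by_label[label]:
            if label == "Hospitalization":
                stamp = str(int(rng.integers(0, 16_000_000)))
                attrs = (
                    ("TimeStampCreated", stamp),
                    ("history", texts[nid]),
                    ("allergies", "none known"),
                )
            else:
                attrs = (("description", texts[nid]),)
            graph.add_node(Node(nid, label, attrs))

    for rule in _EDGE_RULES:  # fixed order keeps output deterministic
        m = cfg.edges_per_rule.get(rule, 0)
        if m == 0:
            continue
        src_label, tgt_label, role = rule
        sources = rng.choice(ids_by_label[src_label], size=m)
        targets = rng.choice(ids_by_label[tgt_label], size=m)
        for s, t in zip(sources, targets):
            graph.add_edge(Edge(str(s), str(t), role))

    manifest = Manifest(
        seed=cfg.seed,
        n_nodes=len(graph),
        n_edges=len(graph.edges),
        injections=tuple(injection_sites),
    )
    return graph, manifest


# ---------------------------------------------------------------------------
# Synthetic judgments
# ---------------------------------------------------------------------------

def make_judgments(
    manifest: Manifest,
    graph: DataGraph,
    queries: list[Query | str],
    mode: str = "phrase_in_result",
    rater_id: str = "synthetic",
):
    """Synthesize rater-like relevance marks for hospitalization results.

    ``phrase_in_result`` marks as relevant the hospitalizations that
    themselves contain every query term; ``phrase_in_neighbors`` marks
    the hospitalizations with at least one adjacent entity (either edge
    direction) containing every query term — results that a content
    ranker cannot score above zero, the scenario where authority flow
    earns its keep.  Returns a list of :class:`~clinrank.evaluation.Judgment`
    rows (relevant marks only), one rater.
    """
    from .evaluation import Judgment

    if mode not in ("phrase_in_result", "phrase_in_neighbors"):
        raise ValueError(f"unknown judgment mode {mode!r}")

    bearing_cache: dict[tuple[str, ...], set[str]] = {}

    def bearers(terms: tuple[str, ...]) -> set[str]:
        if terms not in bearing_cache:
            bearing_cache[terms] = {
                node.id for node in graph
                if set(terms) <= set(tokenize(node.text))
            }
        return bearing_cache[terms]

    judgments: list[Judgment] = []
    for q in queries:
        query = q if isinstance(q, Query) else Query.from_string(q)
        qid = str(query)
        with_phrase = bearers(query.terms)
        for node in graph:
            if node.label != "Hospitalization":
                continue
            if mode == "phrase_in_result":
                relevant = node.id in with_phrase
            else:
                relevant = bool(graph.neighbors(node.id) & with_phrase)
            if relevant:
                judgments.append(Judgment(qid, node.id, rater_id, True))
    return judgments


# ---------------------------------------------------------------------------
# The 7-node worked-example graph
# ---------------------------------------------------------------------------

def figure1_fixture() -> DataGraph:
    """The small worked-example clinical web used in the documentation.

    Seven entities v1..v7; v1 (an events plan), v4 and v5 contain the
    phrase "pericardial effusion" — v1 three times, alongside "residual"
    and the date token "2004-11-03".  The seven directed edges reproduce
    the example's authority-transfer matrix exactly: each nonzero entry
    equals 1/OutDeg of the source entity (0.5 for the two two-edge
    sources v3 and v4, 1.0 for the single-edge sources v1, v5 and v6).
    """
    nodes = [
        Node("v1", "Events Plan", (
            ("plan", "residual pericardial effusion 2004-11-03"),
            ("note", "pericardial effusion monitored and pericardial "
                     "effusion stable"),
        )),
        Node("v2", "Employee", (
            ("name", "Employee2"), ("department", "cardiology"),
        )),
        Node("v3", "Medication", (
            ("name", "furosemide"), ("dose", "20 mg twice daily"),
        )),
        Node("v4", "Hospitalization", (
            ("TimeStampCreated", "13046400"),
            ("history", "pericardial effusion noted after surgery"),
            ("allergies", "none known"),
        )),
        Node("v5", "Diagnostics", (
            ("report", "echocardiogram shows pericardial effusion"),
        )),
        Node("v6", "Patient", (("name", "Patient6"),)),
        Node("v7", "Hospitalization", (
            ("TimeStampCreated", "13132800"),
            ("history", "postoperative recovery visit"),
            ("allergies", "penicillin"),
        )),
    ]
    edges = [
        Edge("v3", "v2", "prescribed_by"),
        Edge("v3", "v6", "prescribed_for"),
        Edge("v4", "v6", "admits"),
        Edge("v5", "v6", "performed_on"),
        Edge("v1", "v7", "planned_for"),
        Edge("v4", "v7", "related_visit"),
        Edge("v6", "v7", "has_hospitalization"),
    ]
    return DataGraph(nodes, edges)
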