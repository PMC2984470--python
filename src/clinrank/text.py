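"""Tokenization, collection statistics and the query base set.

Every entity's attribute values are concatenated into one bag of words.
Collection statistics over those bags (document frequency n(q), document
length dl, average document length avdl) feed the tf·idf and BM25 rankers;
the base set S — the entities matching the query — is the teleport target
set of the query-specific random surfer.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import DataGraph, Node

__all__ = [
    "tokenize",
    "Query",
    "CollectionStats",
    "EmptyBaseSetError",
    "term_frequency",
    "build_stats",
    "base_set",
    "write_inverted_index",
]

# split on anything that is not a letter, digit or hyphen, so hyphenated
# dates like "2004-11-03" survive as single tokens
_TOKEN_RE = re.compile(r"[^0-9a-z\-]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split free text into tokens.

    >>> tokenize("residual, pericardial effusion, 2004-11-03")
    ['residual', 'pericardial', 'effusion', '2004-11-03']
    """
    return [tok for tok in _TOKEN_RE.split(text.lower()) if tok]


@dataclass(frozen=True)
class Query:
    """A keyword query q1..qn; optionally matched as a contiguous phrase."""

    terms: tuple[str, ...]
    phrase_mode: bool = False

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("a query needs at least one term")
        object.__setattr__(self, "terms", tuple(t.lower() for t in self.terms))

    @classmethod
    def from_string(cls, text: str, phrase_mode: bool = False) -> "Query":
        terms = tokenize(text)
        if not terms:
            raise ValueError(f"query {text!r} contains no tokens")
        return cls(tuple(terms), phrase_mode)

    def __str__(self) -> str:
        return " ".join(self.terms)


class EmptyBaseSetError(ValueError):
    """The query matches no entity; authority-flow ranking is undefined."""


@dataclass
class CollectionStats:
    """Per-collection term statistics.

    ``postings`` maps each term to {node id: term frequency}; ``doc_freq``
    n(q) is the number of entities containing the term; ``dl`` the token
    count per entity; ``avdl`` their mean.  ``N`` defaults to the number
    of entities but can be overridden (together with ``doc_freq``) to
    score a node against statistics of a larger collection of which the
    graph is only a displayed subset.
    """

    N: int
    doc_freq: dict[str, int] = field(default_factory=dict)
    dl: dict[str, int] = field(default_factory=dict)
    postings: dict[str, dict[str, int]] = field(default_factory=dict)
    tokens: dict[str, list[str]] = field(default_factory=dict)
    avdl_value: float | None = None  # set when stats describe a larger
    #                                  collection than the dl table covers

    def __post_init__(self) -> None:
        for term, n in self.doc_freq.items():
            if not 0 <= n <= self.N:
                raise ValueError(f"doc_freq[{term!r}]={n} outside [0, N={self.N}]")

    @property
    def avdl(self) -> float:
        if self.avdl_value is not None:
            return self.avdl_value
        if self.N == 0 or not self.dl:
            raise ValueError("avdl undefined: collection has no text")
        return sum(self.dl.values()) / self.N

    def n(self, term: str) -> int:
        return self.doc_freq.get(term.lower(), 0)


def term_frequency(node: Node, term: str) -> int:
    """Occurrences of ``term`` across the node's attribute values."""
    return sum(1 for tok in tokenize(node.text) if tok == term.lower())


def build_stats(graph: DataGraph) -> CollectionStats:
    """Scan the graph once and build its collection statistics."""
    postings: dict[str, dict[str, int]] = {}
    dl: dict[str, int] = {}
    tokens: dict[str, list[str]] = {}
    for node in graph:
        toks = tokenize(node.text)
        tokens[node.id] = toks
        dl[node.id] = len(toks)
        for term, tf in Counter(toks).items():
            postings.setdefault(term, {})[node.id] = tf
    doc_freq = {term: len(plist) for term, plist in postings.items()}
    return CollectionStats(
        N=len(graph), doc_freq=doc_freq, dl=dl, postings=postings, tokens=tokens
    )


def _contains_phrase(tokens: list[str], phrase: tuple[str, ...]) -> bool:
    n = len(phrase)
    return any(
        tuple(tokens[i:i + n]) == phrase for i in range(len(tokens) - n + 1)
    )


def base_set(
    query: Query,
    graph: DataGraph,
    stats: CollectionStats | None = None,
    mode: str = "conjunctive",
) -> tuple[frozenset[str], np.ndarray]:
    """Compute the base set S and its indicator vector s.

    In the default conjunctive mode an entity belongs to S iff it contains
    every query term; ``query.phrase_mode`` additionally requires the terms
    to occur contiguously in token order.  ``mode="disjunctive"`` relaxes
    membership to any single term.  ``s[i]`` is 1 iff the node at matrix
    position i belongs to S.

    Raises :class:`EmptyBaseSetError` when no entity matches — the caller
    decides whether that means an empty result list or a hard failure —
    rather than silently yielding an all-zero teleport vector.
    """
    if mode not in ("conjunctive", "disjunctive"):
        raise ValueError(f"unknown base-set mode {mode!r}")
    if stats is None:
        stats = build_stats(graph)

    per_term = [set(stats.postings.get(term, {})) for term in query.terms]
    if mode == "disjunctive":
        members = set().union(*per_term)
    else:
        members = set.intersection(*per_term) if per_term else set()
        if query.phrase_mode:
            members = {
                nid for nid in members
                if _contains_phrase(stats.tokens[nid], query.terms)
            }

    if not members:
        raise EmptyBaseSetError(f"no entity matches query {str(query)!r}")

    s = np.zeros(len(graph))
    for nid in members:
        s[graph.index_of(nid)] = 1.0
    return frozenset(members), s


def write_inverted_index(stats: CollectionStats, path: str | Path) -> None:
    """Persist the inverted index as plain text, one term per line:
    ``term<TAB>node:tf node:tf ...`` — for inspection, not speed."""
    lines = []
    for term in sorted(stats.postings):
        plist = " ".join(
            f"{nid}:{tf}" for nid, tf in sorted(stats.postings[term].items())
        )
        lines.append(f"{term}\t{plist}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
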