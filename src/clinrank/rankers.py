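"""Content-only rankers: tf·idf and Okapi BM25.

Both score each entity against the query independently of the graph
structure, from term frequencies and collection statistics alone.  All
logarithms are base 10; ranking order is invariant to the base.

tf·idf:   score(D, Q) = Σ_i tf(q_i, D) · log10(N / n(q_i))

Okapi BM25 (k1 = 2.0, b = 0.75 by default):

    score(D, Q) = Σ_i idf(q_i) · tf(q_i)·(k1 + 1)
                          / (tf(q_i) + k1·(1 − b + b·dl/avdl))
    idf(q_i)    = log10((N − n(q_i) + 0.5) / (n(q_i) + 0.5)),

with negative idf (terms in more than half the collection) clamped at
zero by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .graph import DataGraph, Node
from .text import CollectionStats, Query, build_stats, term_frequency

__all__ = [
    "BM25Config",
    "RankedList",
    "idf_tfidf",
    "tfidf_score",
    "idf_bm25",
    "bm25_score",
    "rank",
]


@dataclass(frozen=True)
class BM25Config:
    k1: float = 2.0
    b: float = 0.75
    idf_floor: bool = True

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValueError("k1 must be non-negative")
        if not 0 <= self.b <= 1:
            raise ValueError("b must lie in [0, 1]")


@dataclass(frozen=True)
class RankedList:
    """Query results, descending by score, ties broken by ascending node id."""

    query: Query
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        scores = [score for _, score in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("entries must be sorted by non-increasing score")
        ids = [nid for nid, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate node id in ranked list")

    @classmethod
    def from_scores(
        cls, query: Query, scores: dict[str, float], k: int | None = None
    ) -> "RankedList":
        """Sort nonzero scores (desc, id asc on ties) and truncate to k."""
        entries = sorted(
            ((nid, sc) for nid, sc in scores.items() if sc != 0.0),
            key=lambda item: (-item[1], item[0]),
        )
        if k is not None:
            entries = entries[:max(k, 0)]
        return cls(query, tuple(entries))

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(nid for nid, _ in self.entries)

    def top(self, k: int) -> "RankedList":
        return RankedList(self.query, self.entries[:max(k, 0)])

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def idf_tfidf(N: int, n: int) -> float:
    """log10(N/n); the term must occur somewhere (n ≥ 1)."""
    if n < 1:
        raise ValueError("idf undefined for a term absent from the collection")
    if n > N:
        raise ValueError(f"n={n} exceeds collection size N={N}")
    return math.log10(N / n)


def tfidf_score(node: Node, query: Query, stats: CollectionStats) -> float:
    """Sum over query terms of tf·idf; absent terms contribute zero."""
    score = 0.0
    for term in query.terms:
        n = stats.n(term)
        if n == 0:
            continue
        score += term_frequency(node, term) * idf_tfidf(stats.N, n)
    return score


def idf_bm25(N: int, n: int, idf_floor: bool = True) -> float:
    """BM25 idf: log10((N − n + 0.5)/(n + 0.5)), clamped at 0 if floored."""
    if not 0 <= n <= N:
        raise ValueError(f"n={n} outside [0, N={N}]")
    value = math.log10((N - n + 0.5) / (n + 0.5))
    if idf_floor:
        value = max(value, 0.0)
    return value


def bm25_score(
    node: Node,
    query: Query,
    stats: CollectionStats,
    cfg: BM25Config = BM25Config(),
) -> float:
    avdl = stats.avdl  # raises when the collection has no text
    dl = stats.dl.get(node.id)
    if dl is None:
        dl = len(node.text.split())
    norm = cfg.k1 * (1 - cfg.b + cfg.b * dl / avdl)
    score = 0.0
    for term in query.terms:
        tf = term_frequency(node, term)
        if tf == 0:
            continue
        idf = idf_bm25(stats.N, stats.n(term), cfg.idf_floor)
        score += idf * tf * (cfg.k1 + 1) / (tf + norm)
    return score


def rank(
    query: Query,
    graph: DataGraph,
    method: str = "bm25",
    k: int | None = None,
    stats: CollectionStats | None = None,
    cfg: BM25Config = BM25Config(),
) -> RankedList:
    """Score every entity with the chosen content ranker and sort.

    Zero-score entities are omitted, so the list holds only entities
    containing at least one query term with positive idf.
    """
    if stats is None:
        stats = build_stats(graph)
    if method == "tfidf":
        scorer = lambda node: tfidf_score(node, query, stats)
    elif method == "bm25":
        scorer = lambda node: bm25_score(node, query, stats, cfg)
    else:
        raise ValueError(f"unknown ranking method {method!r}")

    # only nodes on some query term's posting list can score nonzero
    candidates: set[str] = set()
    for term in query.terms:
        candidates.update(stats.postings.get(term, {}))
    scores = {nid: scorer(graph.node(nid)) for nid in candidates}
    return RankedList.from_scores(query, scores, k)
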