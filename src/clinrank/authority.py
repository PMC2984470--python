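"""Query-specific authority flow: ObjectRank and global PageRank.

A random surfer walks the entity graph: with probability ``d`` (the
damping factor) it follows an outgoing edge of the current entity, and
with probability ``1 − d`` it teleports to a uniformly chosen member of
the base set S — the entities that match the query.  The stationary
probability r(v) is the entity's authority for that query:

    r = d·A·r + (1 − d)/|S| · s

where A is the column-oriented transfer matrix with
A[i, j] = rate(role of edge v_j→v_i) / OutDeg(v_j), s the indicator
vector of S, and rate(·) a per-role authority-transfer weight
(1 for every role by default).  Global PageRank is the special case
S = V.  The fixed point is found by power iteration; because every
column sum of A is at most 1, the iteration contracts in L1 norm by a
factor of at least d per step and converges geometrically.

Dangling entities (no outgoing edges) yield zero columns: their mass
leaks rather than being redistributed, matching the matrix formulation
above, so Σr ≤ 1 with equality only on dangling-free graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import DataGraph
from .rankers import BM25Config, RankedList, bm25_score
from .text import CollectionStats, Query, base_set, build_stats

__all__ = [
    "AuthorityConfig",
    "TransitionMatrix",
    "ScoreVector",
    "CO_VARIANTS",
    "build_transition_matrix",
    "objectrank_step",
    "objectrank_solve",
    "pagerank_global",
    "rank_co",
]


@dataclass(frozen=True)
class AuthorityConfig:
    """Parameters of the authority-flow computation.

    d:            damping factor in (0, 1); 0.85 spreads authority widely,
                  0.30 keeps it near the base set.
    epsilon:      L1 convergence threshold of the power iteration.
    max_iters:    iteration cap (geometric convergence makes 200 generous).
    rates:        per-edge-role authority-transfer rate in [0, 1]; roles
                  not listed default to 1 (pure out-degree normalization).
    reverse_edges: also let authority flow against each edge, normalized
                  by the target's reverse out-degree (off by default).
    """

    d: float = 0.85
    epsilon: float = 1e-10
    max_iters: int = 200
    rates: dict[str, float] = field(default_factory=dict)
    reverse_edges: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.d < 1:
            raise ValueError("damping factor d must lie strictly in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be at least 1")
        for role, rate in self.rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"rate for role {role!r} outside [0, 1]")

    def rate(self, role: str) -> float:
        return self.rates.get(role, 1.0)


@dataclass(frozen=True)
class TransitionMatrix:
    """Sparse column-oriented transfer matrix with its node-id mapping."""

    matrix: sp.csr_matrix
    node_ids: tuple[str, ...]

    @property
    def order(self) -> int:
        return len(self.node_ids)

    def __getitem__(self, ij: tuple[int, int]) -> float:
        return float(self.matrix[ij])


@dataclass(frozen=True)
class ScoreVector:
    """Authority scores with convergence diagnostics."""

    r: np.ndarray
    node_ids: tuple[str, ...]
    iterations_used: int
    converged: bool
    residuals: tuple[float, ...] = ()

    def score(self, node_id: str) -> float:
        return float(self.r[self.node_ids.index(node_id)])

    def as_dict(self) -> dict[str, float]:
        return {nid: float(v) for nid, v in zip(self.node_ids, self.r)}


def build_transition_matrix(
    graph: DataGraph, cfg: AuthorityConfig = AuthorityConfig()
) -> TransitionMatrix:
    """Assemble A with A[i, j] = rate(role) / OutDeg(v_j) per edge v_j→v_i.

    Node indexing follows graph insertion order.  With ``reverse_edges``
    on, every edge also contributes a reversed entry normalized by the
    target's reverse out-degree (its in-degree in the original graph).
    """
    if len(graph) == 0:
        raise ValueError("cannot build a transition matrix for an empty graph")
    n = len(graph)
    out_deg = np.zeros(n, dtype=int)
    in_deg = np.zeros(n, dtype=int)
    for edge in graph.edges:
        out_deg[graph.index_of(edge.source)] += 1
        in_deg[graph.index_of(edge.target)] += 1

    rows, cols, vals = [], [], []
    for edge in graph.edges:
        j = graph.index_of(edge.source)
        i = graph.index_of(edge.target)
        rows.append(i)
        cols.append(j)
        vals.append(cfg.rate(edge.role) / out_deg[j])
        if cfg.reverse_edges:
            rows.append(j)
            cols.append(i)
            vals.append(cfg.rate(edge.role) / in_deg[i])

    matrix = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return TransitionMatrix(matrix, graph.node_ids)


def objectrank_step(
    A: TransitionMatrix, s: np.ndarray, d: float, r: np.ndarray
) -> np.ndarray:
    """One power-iteration update: d·A·r + (1 − d)/|S| · s."""
    size = float(s.sum())
    if size < 1:
        raise ValueError("empty base set: the teleport term is undefined")
    if len(r) != A.order or len(s) != A.order:
        raise ValueError("vector dimensions do not match the matrix order")
    return d * (A.matrix @ r) + (1 - d) / size * s


def objectrank_solve(
    graph: DataGraph,
    query: Query,
    cfg: AuthorityConfig = AuthorityConfig(),
    stats: CollectionStats | None = None,
    base_set_mode: str = "conjunctive",
) -> ScoreVector:
    """Iterate the authority-flow update to its fixed point.

    Starts from r0 = s/|S| and stops when the L1 change drops below
    ``cfg.epsilon`` or after ``cfg.max_iters`` iterations.  Raises
    :class:`~clinrank.text.EmptyBaseSetError` when the query matches
    nothing — never a silent all-zero vector.
    """
    _, s = base_set(query, graph, stats=stats, mode=base_set_mode)
    A = build_transition_matrix(graph, cfg)
    return _power_iteration(A, s, cfg)


def _power_iteration(
    A: TransitionMatrix, s: np.ndarray, cfg: AuthorityConfig
) -> ScoreVector:
    r = s / s.sum()
    residuals: list[float] = []
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iters + 1):
        r_next = objectrank_step(A, s, cfg.d, r)
        delta = float(np.abs(r_next - r).sum())
        residuals.append(delta)
        r = r_next
        if delta < cfg.epsilon:
            converged = True
            break
    return ScoreVector(r, A.node_ids, iterations, converged, tuple(residuals))


def pagerank_global(
    graph: DataGraph, cfg: AuthorityConfig = AuthorityConfig()
) -> ScoreVector:
    """Query-independent authority: the base set is the whole node set."""
    A = build_transition_matrix(graph, cfg)
    s = np.ones(len(graph))
    return _power_iteration(A, s, cfg)


#: damping factor per ranking variant; CO085BM25 multiplies in BM25 scores
CO_VARIANTS = {"CO085": 0.85, "CO030": 0.30, "CO085BM25": 0.85}


def rank_co(
    query: Query,
    graph: DataGraph,
    variant: str = "CO085",
    k: int | None = None,
    cfg: AuthorityConfig = AuthorityConfig(),
    bm25_cfg: BM25Config = BM25Config(),
    stats: CollectionStats | None = None,
    base_set_mode: str = "conjunctive",
) -> RankedList:
    """Rank entities with a Clinical ObjectRank variant.

    CO085 and CO030 sort the authority scores at d = 0.85 and d = 0.30;
    CO085BM25 multiplies the d = 0.85 authority score by the BM25 score
    per entity (so any entity BM25 gives zero is excluded).  Unlike the
    content rankers, CO variants can return entities that contain none of
    the query keywords, if enough matching entities link to them.
    """
    variant = variant.upper()
    if variant not in CO_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {sorted(CO_VARIANTS)}"
        )
    if stats is None:
        stats = build_stats(graph)
    cfg = AuthorityConfig(
        d=CO_VARIANTS[variant],
        epsilon=cfg.epsilon,
        max_iters=cfg.max_iters,
        rates=cfg.rates,
        reverse_edges=cfg.reverse_edges,
    )
    authority = objectrank_solve(
        graph, query, cfg, stats=stats, base_set_mode=base_set_mode
    )
    scores = authority.as_dict()
    if variant == "CO085BM25":
        scores = {
            nid: score * bm25_score(graph.node(nid), query, stats, bm25_cfg)
            for nid, score in scores.items()
        }
    return RankedList.from_scores(query, scores, k)
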