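"""End-to-end search runs: load a graph, run every ranker, write results.

A run configuration names the graph dump, the query set, the rankers to
compare, the pooling depth k and an optional entity-type filter (the
study restricts results to hospitalizations).  Outputs are one TSV per
(query, ranker) with columns rank, node_id, score — deterministic given
identical inputs, so reruns are byte-identical and diff-able.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .authority import AuthorityConfig, CO_VARIANTS, rank_co
from .evaluation import filter_by_label
from .graph import DataGraph, load_data_graph
from .rankers import BM25Config, RankedList, rank
from .text import EmptyBaseSetError, Query, build_stats

__all__ = ["RunConfig", "run_search", "ALL_METHODS"]

log = logging.getLogger("clinrank")

ALL_METHODS = ("bm25", "CO085", "CO030", "CO085BM25")


@dataclass
class RunConfig:
    """Everything one search run needs."""

    graph_dir: Path
    queries: tuple[str, ...]
    methods: tuple[str, ...] = ALL_METHODS
    k: int = 5
    type_filter: str | None = "Hospitalization"
    authority: AuthorityConfig = field(default_factory=AuthorityConfig)
    bm25: BM25Config = field(default_factory=BM25Config)
    base_set_mode: str = "conjunctive"
    out_dir: Path = Path("results")

    def __post_init__(self) -> None:
        self.graph_dir = Path(self.graph_dir)
        self.out_dir = Path(self.out_dir)
        if self.k < 1:
            raise ValueError("k must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        auth = AuthorityConfig(
            d=raw.get("d", 0.85),
            epsilon=raw.get("epsilon", 1e-10),
            max_iters=raw.get("max_iters", 200),
            rates=raw.get("rates", {}),
            reverse_edges=raw.get("reverse_edges", False),
        )
        bm25 = BM25Config(
            k1=raw.get("k1", 2.0), b=raw.get("b", 0.75),
            idf_floor=raw.get("idf_floor", True),
        )
        return cls(
            graph_dir=Path(raw["graph_dir"]),
            queries=tuple(raw["queries"]),
            methods=tuple(raw.get("methods", ALL_METHODS)),
            k=raw.get("k", 5),
            type_filter=raw.get("type_filter", "Hospitalization"),
            authority=auth,
            bm25=bm25,
            base_set_mode=raw.get("base_set_mode", "conjunctive"),
            out_dir=Path(raw.get("out_dir", "results")),
        )


def _slug(text: str) -> str:
    return "-".join(text.lower().split())


def _rank_one(
    method: str, query: Query, graph: DataGraph, stats, cfg: RunConfig
) -> RankedList:
    if method.lower() in ("bm25", "tfidf"):
        return rank(query, graph, method=method.lower(), stats=stats,
                    cfg=cfg.bm25)
    if method.upper() in CO_VARIANTS:
        return rank_co(
            query, graph, variant=method.upper(), cfg=cfg.authority,
            bm25_cfg=cfg.bm25, stats=stats, base_set_mode=cfg.base_set_mode,
        )
    raise ValueError(f"unknown method {method!r}")


def write_ranked_list(rl: RankedList, path: Path) -> None:
    lines = ["rank\tnode_id\tscore"]
    for i, (nid, score) in enumerate(rl.entries, 1):
        lines.append(f"{i}\t{nid}\t{score:.10g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_search(cfg: RunConfig) -> dict[tuple[str, str], Path]:
    """Rank every query with every method; write one TSV per pair.

    Scores are computed over all entities, the optional type filter is
    applied after scoring, and the list is truncated to the top k.  A
    query whose base set is empty produces empty result files (with a
    logged warning) for every method rather than failing the run.
    """
    graph = load_data_graph(
        cfg.graph_dir / "nodes.tsv", cfg.graph_dir / "edges.tsv"
    )
    stats = build_stats(graph)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)

    outputs: dict[tuple[str, str], Path] = {}
    for query_text in cfg.queries:
        query = Query.from_string(query_text)
        for method in cfg.methods:
            try:
                rl = _rank_one(method, query, graph, stats, cfg)
            except EmptyBaseSetError:
                log.warning(
                    "query %r matches no entity; writing empty %s results",
                    query_text, method,
                )
                rl = RankedList(query, ())
            if cfg.type_filter:
                rl = filter_by_label(rl, graph, cfg.type_filter)
            rl = rl.top(cfg.k)
            path = cfg.out_dir / f"{_slug(query_text)}__{method}.tsv"
            write_ranked_list(rl, path)
            outputs[(query_text, method)] = path
            log.info(
                "query %r method %s: %d results -> %s",
                query_text, method, len(rl), path,
            )
    return outputs
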