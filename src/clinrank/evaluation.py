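"""Pooled sensitivity/specificity evaluation of competing rankers.

The protocol mirrors a blinded pooled-relevance study: for each query the
top-k lists of all compared algorithms are merged into a single pool, the
pool is judged for relevance, and each algorithm's top-k list is scored
against the judged pool as a 2×2 contingency table:

    TP = |top-k ∩ relevant|        FN = |relevant \\ top-k|
    FP = |top-k \\ relevant|        TN = |pool \\ relevant \\ top-k|

    sensitivity = TP/(TP+FN)       specificity = TN/(TN+FP)

The pool is the negative universe — the only universe consistent with
what the raters actually saw.  A zero denominator leaves the metric
undefined (None) and the row is excluded from macro averages.  Results
are typically restricted to one entity type (the hospitalization filter)
before truncation; that is post-processing, not part of any ranker.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .graph import DataGraph
from .rankers import RankedList

__all__ = [
    "Judgment",
    "filter_by_label",
    "pool_topk",
    "contingency",
    "sensitivity_specificity",
    "macro_average",
    "improvement_ratio",
    "load_judgments",
    "write_judgments",
    "relevant_sets",
]


@dataclass(frozen=True)
class Judgment:
    """One rater's binary relevance mark for one result of one query."""

    query_id: str
    node_id: str
    rater_id: str
    relevant: bool


def filter_by_label(
    rl: RankedList, graph: DataGraph, label: str
) -> RankedList:
    """Keep only entities of the given label, preserving order and scores.

    Applied after scoring and before top-k truncation; scores are
    untouched because the filter is post-processing, not ranking.
    """
    entries = tuple(
        (nid, score) for nid, score in rl.entries
        if graph.node(nid).label == label
    )
    return RankedList(rl.query, entries)


def pool_topk(lists: dict[str, RankedList], k: int) -> set[str]:
    """Union of each algorithm's first k node ids (the judged universe)."""
    if k < 1:
        raise ValueError("pooling depth k must be at least 1")
    pool: set[str] = set()
    for rl in lists.values():
        pool.update(rl.node_ids[:k])
    return pool


def contingency(
    list_k: set[str] | tuple[str, ...],
    relevant: set[str],
    pool: set[str],
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) of one algorithm's list against the judged pool."""
    list_k = set(list_k)
    if not relevant <= pool:
        raise ValueError("judged-relevant set must be a subset of the pool")
    if not list_k <= pool:
        raise ValueError("the evaluated list must be a subset of the pool")
    tp = len(list_k & relevant)
    fp = len(list_k - relevant)
    fn = len(relevant - list_k)
    tn = len(pool - relevant - list_k)
    return tp, fp, fn, tn


def sensitivity_specificity(
    list_k: set[str] | tuple[str, ...],
    relevant: set[str],
    pool: set[str],
) -> tuple[float | None, float | None]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP); None when the
    denominator is zero (no relevant / no negative items in the pool)."""
    tp, fp, fn, tn = contingency(list_k, relevant, pool)
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    return sens, spec


def macro_average(rows: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-algorithm means over queries.

    ``rows`` needs columns algorithm, sensitivity, specificity (and any
    grouping column such as rater_id is preserved if present); undefined
    metrics (NaN/None) are excluded from their mean.
    """
    keys = ["algorithm"]
    if "rater_id" in rows.columns:
        keys = ["rater_id", "algorithm"]
    out = (
        rows.groupby(keys, dropna=False)[["sensitivity", "specificity"]]
        .mean()
        .reset_index()
    )
    return out


def improvement_ratio(a: float, b: float) -> float:
    """Relative improvement (a − b)/b of algorithm a over baseline b."""
    if b == 0:
        raise ValueError("baseline value is zero; ratio undefined")
    return (a - b) / b


# ---------------------------------------------------------------------------
# Judgment table I/O (judgments.tsv: query_id, node_id, rater_id, relevant)
# ---------------------------------------------------------------------------

def load_judgments(path: str | Path) -> list[Judgment]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"query_id", "node_id", "rater_id", "relevant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = [
        Judgment(r.query_id, r.node_id, r.rater_id, r.relevant in ("1", "true", "True"))
        for r in df.itertuples()
    ]
    seen = set()
    for j in out:
        key = (j.query_id, j.node_id, j.rater_id)
        if key in seen:
            raise ValueError(f"duplicate judgment for {key}")
        seen.add(key)
    return out


def write_judgments(judgments: list[Judgment], path: str | Path) -> None:
    lines = ["query_id\tnode_id\trater_id\trelevant"]
    for j in judgments:
        lines.append(f"{j.query_id}\t{j.node_id}\t{j.rater_id}\t{int(j.relevant)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def relevant_sets(
    judgments: list[Judgment], consensus: str = "union"
) -> dict[str, set[str]]:
    """Per-query relevant node sets, combining raters by union (default)
    or intersection of their relevant marks."""
    if consensus not in ("union", "intersection"):
        raise ValueError(f"unknown consensus mode {consensus!r}")
    per_rater: dict[str, dict[str, set[str]]] = {}
    for j in judgments:
        if j.relevant:
            per_rater.setdefault(j.query_id, {}).setdefault(
                j.rater_id, set()
            ).add(j.node_id)
    out: dict[str, set[str]] = {}
    for qid, raters in per_rater.items():
        sets = list(raters.values())
        out[qid] = (
            set.union(*sets) if consensus == "union" else set.intersection(*sets)
        )
    return out
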