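"""Frequent sub-activity n-grams mined from constructed merge trees.

A node whose subtree spans exactly n leaves contributes its left-to-right
leaf token tuple as an n-gram.  Candidates come from the globally
lowest-error nodes across all training trees; patterns are then counted
and ranked per activity class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .event_io import SensorRegistry
from .rae_core import RAETree


@dataclass(frozen=True)
class NGramPattern:
    activity: str
    tokens: tuple[str, ...]
    count: int
    mean_error: float

    def __post_init__(self) -> None:
        if len(self.tokens) not in (2, 3):
            raise ValueError("n-grams are restricted to n in {2, 3}")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class NodeRef:
    """A single internal node of some tree, with its error and class label."""

    tree_id: int
    node_index: int
    error: float
    activity: str | None
    leaf_tokens: tuple[int, ...]  # left-to-right sensor indices under the node


def extract_top_nodes(trees: Iterable[RAETree], k: int = 500) -> list[NodeRef]:
    """The k nodes with least reconstruction error across all trees.

    Sorted ascending by error; stable in (tree, node) order on ties.  All
    nodes are returned when fewer than k exist.
    """
    refs: list[NodeRef] = []
    for tree_id, tree in enumerate(trees):
        tokens = tree.tokens
        for node_index in range(len(tree.nodes)):
            span = tree.leaf_span(node_index)
            leaf_tokens = tuple(tokens[i] for i in span) if tokens is not None else tuple(span)
            refs.append(NodeRef(tree_id=tree_id, node_index=node_index,
                                error=tree.nodes[node_index].error,
                                activity=tree.label, leaf_tokens=leaf_tokens))
    refs.sort(key=lambda r: (r.error, r.tree_id, r.node_index))
    return refs[:k]


def ngram_patterns(top_nodes: list[NodeRef], n: int,
                   registry: SensorRegistry | None = None) -> dict[str, list[NGramPattern]]:
    """Count and rank n-leaf subtrees per activity class.

    Ranked by frequency (descending), ties broken lexicographically by
    sensor id.  Token indices are rendered through *registry* when given.
    """
    if n not in (2, 3):
        raise ValueError("n must be 2 or 3")
    buckets: dict[tuple[str, tuple[str, ...]], list[float]] = {}
    for ref in top_nodes:
        if len(ref.leaf_tokens) != n:
            continue
        names = tuple(registry.name(t) for t in ref.leaf_tokens) if registry is not None \
            else tuple(str(t) for t in ref.leaf_tokens)
        key = (ref.activity or "", names)
        buckets.setdefault(key, []).append(ref.error)
    out: dict[str, list[NGramPattern]] = {}
    for (activity, names), errors in buckets.items():
        out.setdefault(activity, []).append(
            NGramPattern(activity=activity, tokens=names, count=len(errors),
                         mean_error=float(np.mean(errors)))
        )
    for activity in out:
        out[activity].sort(key=lambda p: (-p.count, p.tokens))
    return out


def patterns_to_frame(per_activity: dict[str, list[NGramPattern]]) -> pd.DataFrame:
    rows = [
        {
            "activity": p.activity,
            "n": len(p.tokens),
            "pattern": " ".join(p.tokens),
            "count": p.count,
            "mean_error": p.mean_error,
        }
        for patterns in per_activity.values()
        for p in patterns
    ]
    return pd.DataFrame(rows, columns=["activity", "n", "pattern", "count", "mean_error"])
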