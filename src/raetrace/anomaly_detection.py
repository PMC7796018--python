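"""Reconstruction-error scoring of windows and thresholding.

Token-sequence windows are scored by the errors of their greedy merge
tree (mean over all parents, or root only); presence-vector streams are
scored per block of ``w`` consecutive one-minute rows via a linear tree.
A confidence-based wrapper for external classifiers is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .event_io import SensorRegistry
from .features import WindowChunk, rsm_sequence, stack_bos_chunks
from .rae_core import RAEParams, RAETree, build_greedy_tree, build_linear_tree


@dataclass
class ScoredWindow:
    """A window (or window block) with its anomaly score."""

    start: object  # datetime of the scored span
    end: object
    score: float
    truth: bool | None = None
    predicted: bool | None = None
    degenerate: bool = False  # too few tokens to reconstruct

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")


def score_rsm_window(tree: RAETree, mode: str = "avg_parents") -> float:
    """Tree score: mean of all parent errors, or the root's error."""
    if mode not in ("avg_parents", "root"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    if tree.is_degenerate:
        return 0.0
    errors = tree.node_errors()
    return float(errors.mean()) if mode == "avg_parents" else float(errors[-1])


def score_bos_chunk(rows: np.ndarray, params: RAEParams) -> float:
    """Mean parent error of the linear tree over w stacked presence rows."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise ValueError("need at least 2 rows to score a chunk")
    tree = build_linear_tree(rows, params)
    return float(tree.node_errors().mean())


def threshold_scores(scored: list[ScoredWindow], threshold: float) -> list[bool]:
    """Predict abnormal iff score > threshold (flags also set in place)."""
    flags = []
    for sw in scored:
        sw.predicted = sw.score > threshold
        flags.append(sw.predicted)
    return flags


def mean_confidence_threshold(train_confidences: dict[object, list[float]]) -> dict[object, float]:
    """Per-class mean confidence of training instances.

    A test instance recognised with confidence below (a fraction of) its
    class mean is flagged abnormal; see :func:`flag_by_confidence`.
    """
    means = {}
    for cls, values in train_confidences.items():
        if len(values) == 0:
            raise ValueError(f"class {cls!r} has no training confidences")
        means[cls] = float(np.mean(values))
    return means


def flag_by_confidence(cls: object, confidence: float, class_means: dict[object, float],
                       fraction: float = 1.0) -> bool:
    """True (abnormal) iff confidence < fraction * class mean."""
    return confidence < fraction * class_means[cls]


# ---------------------------------------------------------------------------
# Batch scoring helpers used by the pipeline


def score_rsm_windows(
    chunks: list[WindowChunk],
    registry: SensorRegistry,
    params: RAEParams,
    mode: str = "avg_parents",
    skip_empty: bool = True,
) -> list[ScoredWindow]:
    """Greedy-tree score per window; 0/1-token windows score 0 (flagged)."""
    out = []
    for chunk in chunks:
        if skip_empty and len(chunk) == 0:
            continue
        if len(chunk) < 2:
            out.append(ScoredWindow(chunk.start, chunk.end, 0.0, truth=chunk.abnormal,
                                    degenerate=True))
            continue
        seq = rsm_sequence(chunk, registry)
        tree = build_greedy_tree(seq.onehot, params, tokens=seq.tokens, label=chunk.label)
        out.append(ScoredWindow(chunk.start, chunk.end, score_rsm_window(tree, mode),
                                truth=chunk.abnormal))
    return out


def score_bos_stream(
    chunks: list[WindowChunk],
    registry: SensorRegistry,
    params: RAEParams,
    w: int = 25,
) -> list[ScoredWindow]:
    """Score w-row blocks of consecutive windows with the linear tree.

    A block's truth flag is true iff any member window is abnormal (when
    ground truth is present on the members).
    """
    out = []
    for rows, members in stack_bos_chunks(chunks, registry, w=w):
        truths = [c.abnormal for c in members if c.abnormal is not None]
        truth = any(truths) if truths else None
        out.append(ScoredWindow(members[0].start, members[-1].end,
                                score_bos_chunk(rows, params), truth=truth))
    return out
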