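"""Scoring inferred networks against a gold standard.

Edges are directed ``(source, target)`` pairs; the score of edge (m, n) is
taken from the weight-style matrix entry ``scores[n, m]`` (row = target).
The candidate universe is every ordered gene pair, excluding self-loops by
default (the convention of community gold standards, which list no
self-edges).

Thresholded counts follow the usual confusion terminology: T true
connections, F false alarms, M missed detections; the Hamming distance is
``(F + M)`` normalized by the number of gold edges.  Ranking metrics
(AUROC via mid-rank Mann–Whitney, AUPR via the non-interpolated step rule)
score the full ranked candidate list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .model import GeneNetwork

__all__ = [
    "EvaluationReport",
    "confusion",
    "hamming_distance",
    "auroc",
    "aupr",
    "roc_points",
    "pr_points",
    "evaluate",
]


def _as_edge_set(gold) -> set[tuple[int, int]]:
    if isinstance(gold, GeneNetwork):
        return gold.edge_set()
    return {(int(m), int(n)) for (m, n) in gold}


def _universe(n_genes: int, include_self_loops: bool):
    """Arrays of (source, target) pairs spanning the candidate universe."""
    tgt, src = np.meshgrid(np.arange(n_genes), np.arange(n_genes), indexing="ij")
    tgt, src = tgt.ravel(), src.ravel()
    if not include_self_loops:
        keep = tgt != src
        tgt, src = tgt[keep], src[keep]
    return src, tgt


def _labels_and_scores(gold, scores, include_self_loops):
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != scores.shape[1]:
        raise ValueError("scores must be a square matrix")
    n = scores.shape[0]
    edges = _as_edge_set(gold)
    for m, t in edges:
        if not (0 <= m < n and 0 <= t < n):
            raise ValueError(f"gold edge ({m}, {t}) outside the {n}-gene universe")
    src, tgt = _universe(n, include_self_loops)
    labels = np.array([(m, t) in edges for m, t in zip(src, tgt)])
    vals = np.abs(scores[tgt, src])
    return labels, vals


def confusion(gold, scores, threshold: float | None = None,
              top_k: int | None = None, include_self_loops: bool = False):
    """Thresholded confusion counts (T, F, M).

    The predicted edge set is either ``|score| > threshold`` or, when
    ``top_k`` is given instead, the top-k scored candidates.
    """
    labels, vals = _labels_and_scores(gold, scores, include_self_loops)
    if (threshold is None) == (top_k is None):
        raise ValueError("provide exactly one of threshold or top_k")
    if top_k is not None:
        order = np.argsort(-vals, kind="stable")
        predicted = np.zeros(vals.size, dtype=bool)
        predicted[order[:top_k]] = True
    else:
        predicted = vals > threshold
    T = int(np.count_nonzero(predicted & labels))
    F = int(np.count_nonzero(predicted & ~labels))
    M = int(np.count_nonzero(~predicted & labels))
    return T, F, M


def hamming_distance(T: int, F: int, M: int, n_gold_edges: int) -> float:
    """(false alarms + missed detections) / gold edge count."""
    if n_gold_edges <= 0:
        raise ValueError("gold standard has no edges")
    return (F + M) / n_gold_edges


def _check_degenerate(labels):
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("gold standard is degenerate: need positives and negatives")
    return n_pos, n_neg


def auroc(gold, scores, include_self_loops: bool = False) -> float:
    """Area under the ROC curve by the mid-rank Mann–Whitney statistic."""
    labels, vals = _labels_and_scores(gold, scores, include_self_loops)
    n_pos, n_neg = _check_degenerate(labels)
    ranks = rankdata(vals, method="average")
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _sweep(labels, vals):
    """Cumulative TP / FP at each distinct descending threshold."""
    order = np.argsort(-vals, kind="stable")
    vals, labels = vals[order], labels[order]
    tp = np.cumsum(labels)
    fp = np.cumsum(~labels)
    # keep the last index of each tied block
    distinct = np.flatnonzero(np.diff(vals, append=-np.inf))
    return tp[distinct], fp[distinct]


def roc_points(gold, scores, include_self_loops: bool = False) -> np.ndarray:
    """(FPR, TPR) pairs over the threshold sweep, including (0,0) and (1,1)."""
    labels, vals = _labels_and_scores(gold, scores, include_self_loops)
    n_pos, n_neg = _check_degenerate(labels)
    tp, fp = _sweep(labels, vals)
    fpr = np.concatenate([[0.0], fp / n_neg])
    tpr = np.concatenate([[0.0], tp / n_pos])
    return np.column_stack([fpr, tpr])


def pr_points(gold, scores, include_self_loops: bool = False) -> np.ndarray:
    """(recall, precision) pairs over the threshold sweep."""
    labels, vals = _labels_and_scores(gold, scores, include_self_loops)
    n_pos, _ = _check_degenerate(labels)
    tp, fp = _sweep(labels, vals)
    recall = tp / n_pos
    precision = tp / np.maximum(tp + fp, 1)
    return np.column_stack([recall, precision])


def aupr(gold, scores, include_self_loops: bool = False) -> float:
    """Area under the precision-recall curve, non-interpolated step rule."""
    pts = pr_points(gold, scores, include_self_loops)
    recall, precision = pts[:, 0], pts[:, 1]
    prev = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev) * precision))


@dataclass
class EvaluationReport:
    """Full evaluation of a scored network against a gold standard."""

    T: int
    F: int
    M: int
    hamming: float
    precision: float
    recall: float
    auroc: float
    aupr: float
    roc_points: np.ndarray
    pr_points: np.ndarray
    n_gold_edges: int
    include_self_loops: bool = False
    threshold: float | None = None
    top_k: int | None = None

    def summary(self) -> dict:
        return {
            "T": self.T,
            "F": self.F,
            "M": self.M,
            "hamming": self.hamming,
            "precision": self.precision,
            "recall": self.recall,
            "auroc": self.auroc,
            "aupr": self.aupr,
            "n_gold_edges": self.n_gold_edges,
        }


def evaluate(gold, scores, threshold: float | None = None,
             top_k: int | str | None = None,
             include_self_loops: bool = False) -> EvaluationReport:
    """Complete report: confusion counts at a working point plus the
    threshold-free ranking metrics.

    When neither ``threshold`` nor ``top_k`` is given, the working point
    keeps the top-E candidates where E is the gold edge count.
    """
    edges = _as_edge_set(gold)
    if not include_self_loops:
        edges = {(m, t) for m, t in edges if m != t}
    E = len(edges)
    if threshold is None and top_k is None:
        top_k = E
    if top_k == "gold":
        top_k = E
    T, F, M = confusion(edges, scores, threshold=threshold, top_k=top_k,
                        include_self_loops=include_self_loops)
    precision = T / (T + F) if (T + F) > 0 else 0.0
    recall = T / (T + M) if (T + M) > 0 else 0.0
    return EvaluationReport(
        T=T, F=F, M=M,
        hamming=hamming_distance(T, F, M, E),
        precision=precision, recall=recall,
        auroc=auroc(edges, scores, include_self_loops),
        aupr=aupr(edges, scores, include_self_loops),
        roc_points=roc_points(edges, scores, include_self_loops),
        pr_points=pr_points(edges, scores, include_self_loops),
        n_gold_edges=E,
        include_self_loops=include_self_loops,
        threshold=threshold, top_k=top_k,
    )
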