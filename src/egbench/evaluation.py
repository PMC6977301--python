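"""Precision-recall evaluation and dataset characterization statistics.

The benchmark's figure of merit is the area under the precision-recall
curve (AUPR), computed step-wise (non-interpolated): thresholds are placed
at distinct score values, all tied pairs enter the confusion counts
together, and AUPR = sum_i (R_i - R_{i-1}) * P_i.  Under this convention a
score-free (all-equal) ranking has AUPR equal to the positive class
fraction, which is the random baseline the curves are compared against.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .curation import BenchmarkDataset, negative_cutoff

__all__ = [
    "PrecisionRecallCurve",
    "DatasetSummary",
    "pr_curve",
    "aupr",
    "overall_precision_recall",
    "overlap_coefficient",
    "characterize_dataset",
]


@dataclass(frozen=True)
class PrecisionRecallCurve:
    thresholds: np.ndarray  # descending distinct score values
    precision: np.ndarray
    recall: np.ndarray
    aupr: float

    def __post_init__(self):
        if not 0.0 <= self.aupr <= 1.0:
            raise ValueError(f"AUPR out of [0, 1]: {self.aupr}")


def pr_curve(scores: Sequence[float], labels: Sequence[int]) -> PrecisionRecallCurve:
    """Step-wise precision-recall curve over distinct score thresholds.

    ``labels`` are 1 for positive pairs and 0 for negatives; higher scores
    mean higher confidence.  Requires at least one pair of each class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("PR curve requires both classes")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # last index of each tie block = threshold point
    distinct = np.nonzero(np.diff(s, append=-np.inf))[0]
    thresholds = s[distinct]
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / n_pos
    area = float(np.sum(np.diff(recall, prepend=0.0) * precision))
    return PrecisionRecallCurve(
        thresholds=thresholds, precision=precision, recall=recall, aupr=area
    )


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    return pr_curve(scores, labels).aupr


def overall_precision_recall(
    predicted: set, positives: set
) -> tuple[float, float]:
    """Set-level precision and recall of a hard prediction.

    ``predicted`` and ``positives`` are sets of (element_id, gene_id)
    pairs.  An empty prediction set has precision 0 by policy; an empty
    positive set is an error.
    """
    if not positives:
        raise ValueError("positive set is empty")
    hits = len(predicted & positives)
    precision = hits / len(predicted) if predicted else 0.0
    recall = hits / len(positives)
    return precision, recall


def overlap_coefficient(pos_a: set, pos_b: set) -> float:
    """|A intersect B| / min(|A|, |B|) over two positive pair sets."""
    if not pos_a or not pos_b:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(pos_a & pos_b) / min(len(pos_a), len(pos_b))


@dataclass(frozen=True)
class DatasetSummary:
    n_pos: int
    n_neg: int
    positive_fraction: float
    distance_percentiles: dict  # percentile -> bp (nearest-rank)
    genes_per_element: dict  # n linked genes -> n elements (positives only)
    expression_summary: dict | None = None  # summary of mean-TPM of positive genes
    n_missing_expression: int = 0
    mean_element_signal: float | None = None


def characterize_dataset(
    dataset: BenchmarkDataset,
    expression: Mapping[str, Sequence[float]] | None = None,
    element_signal: Mapping[str, float] | None = None,
) -> DatasetSummary:
    """Summary statistics of a benchmark dataset.

    Distance percentiles use the same nearest-rank convention as the
    negative-pair cutoff, so the 95th percentile reported here equals the
    dataset's cutoff.  Genes-per-element is tallied over positive pairs
    only.  ``expression`` maps gene_id -> replicate TPM values; each gene
    is summarized by the mean of its replicates, and genes absent from the
    table are counted.
    """
    pos = dataset.positives()
    neg = dataset.negatives()
    n_pos, n_neg = len(pos), len(neg)
    total = n_pos + n_neg
    percentiles = {}
    if pos:
        for q in (5, 25, 50, 75, 95):
            percentiles[q] = negative_cutoff(pos, percentile=q)
    genes_per_element = Counter()
    by_element: dict[str, set[str]] = {}
    for p in pos:
        by_element.setdefault(p.element_id, set()).add(p.gene_id)
    for genes in by_element.values():
        genes_per_element[len(genes)] += 1
    expression_summary = None
    n_missing = 0
    if expression is not None:
        gene_ids = sorted({p.gene_id for p in pos})
        means = []
        for g in gene_ids:
            reps = expression.get(g)
            if reps is None:
                n_missing += 1
                continue
            means.append(float(np.mean(reps)))
        if means:
            arr = np.array(means)
            expression_summary = {
                "n": len(arr),
                "mean": float(arr.mean()),
                "median": float(np.median(arr)),
            }
    mean_signal = None
    if element_signal is not None:
        vals = [
            element_signal[eid] for eid in sorted(by_element) if eid in element_signal
        ]
        if vals:
            mean_signal = float(np.mean(vals))
    return DatasetSummary(
        n_pos=n_pos,
        n_neg=n_neg,
        positive_fraction=n_pos / total if total else 0.0,
        distance_percentiles=percentiles,
        genes_per_element=dict(genes_per_element),
        expression_summary=expression_summary,
        n_missing_expression=n_missing,
        mean_element_signal=mean_signal,
    )
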