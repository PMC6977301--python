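"""Chromosome-balanced cross-validation (chromCV) group assignment.

All pairs on one chromosome always share a fold, which prevents leakage of
locus-level features between training and test sets.  Fold sizes are
balanced greedily: the chromosome with the most pairs forms its own group,
and the remaining chromosomes are repeatedly paired largest-with-smallest.
With 23 chromosomes carrying pairs (1-22 and X) this yields 12 groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .curation import BenchmarkDataset, CandidatePair

__all__ = ["CvAssignment", "assign_chrom_cv", "transfer_cv", "apply_chrom_cv"]


@dataclass(frozen=True)
class CvAssignment:
    """chrom -> group id mapping plus per-group pair totals."""

    groups: dict  # chrom -> group_id
    sizes: dict  # group_id -> total pair count

    def group_of(self, chrom: str) -> str:
        return self.groups[chrom]

    @property
    def n_groups(self) -> int:
        return len(self.sizes)


def assign_chrom_cv(pair_counts: Mapping[str, int]) -> CvAssignment:
    """Greedy chromosome pairing into balanced CV groups.

    Chromosomes with zero pairs are ignored.  The chromosome with the most
    pairs is assigned its own group; the rest, ordered by count, are
    iteratively combined current-max with current-min; an odd leftover
    chromosome forms its own group.  Ties in counts are broken by
    chromosome name so the assignment is deterministic.  The number of
    groups is therefore 1 + ceil((C - 1) / 2) for C chromosomes.
    """
    chroms = sorted(
        (c for c, n in pair_counts.items() if n > 0),
        key=lambda c: (-pair_counts[c], c),
    )
    if not chroms:
        raise ValueError("no chromosome carries any pair")
    grouped: list[list[str]] = [[chroms[0]]]
    rest = chroms[1:]
    lo, hi = 0, len(rest) - 1
    while lo < hi:
        grouped.append([rest[lo], rest[hi]])
        lo += 1
        hi -= 1
    if lo == hi:
        grouped.append([rest[lo]])
    assert len(grouped) == 1 + math.ceil((len(chroms) - 1) / 2)
    totals = [(sum(pair_counts[c] for c in g), g) for g in grouped]
    totals.sort(key=lambda t: (-t[0], t[1][0]))
    groups: dict[str, str] = {}
    sizes: dict[str, int] = {}
    for i, (total, members) in enumerate(totals):
        gid = f"cv-{i}"
        sizes[gid] = total
        for c in members:
            groups[c] = gid
    return CvAssignment(groups=groups, sizes=sizes)


def apply_chrom_cv(dataset: BenchmarkDataset) -> CvAssignment:
    """Compute the chromCV assignment for a dataset and stamp each pair.

    Counts include both positive and negative pairs, since both are held
    out together.
    """
    counts: dict[str, int] = {}
    for p in dataset.pairs:
        counts[p.chrom] = counts.get(p.chrom, 0) + 1
    assignment = assign_chrom_cv(counts)
    dataset.pairs = [
        _with_group(p, assignment.groups[p.chrom]) for p in dataset.pairs
    ]
    return assignment


def transfer_cv(
    train_assignment: CvAssignment, test_pairs: Sequence[CandidatePair]
) -> list[CandidatePair]:
    """Stamp test pairs with the training assignment's groups.

    Used for cross-cell-type evaluation: the test set inherits the training
    folds so that no chromosome is split between training and testing.
    Chromosomes absent from the training assignment are an error.
    """
    missing = sorted({p.chrom for p in test_pairs} - set(train_assignment.groups))
    if missing:
        raise KeyError(
            f"test chromosomes absent from training assignment: {', '.join(missing)}"
        )
    return [_with_group(p, train_assignment.groups[p.chrom]) for p in test_pairs]


def _with_group(pair: CandidatePair, group: str) -> CandidatePair:
    from dataclasses import replace

    return replace(pair, cv_group=group)
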