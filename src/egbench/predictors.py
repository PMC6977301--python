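"""Scoring methods for element-gene pairs.

Implemented predictors:

* ``closest_gene_prediction`` — assign each element to the gene with the
  nearest TSS (a classification, evaluated by overall precision/recall).
* ``distance_score`` — rank pairs by inverse linear distance (1/d).
* ``dnase_dnase_score`` — Pearson correlation between the accessibility
  profile of the element and of the TSS-proximal element(s) of the gene,
  after averaging biosample columns within cell-type groups; the score of a
  multi-TSS gene is the maximum correlation over its TSS-proximal elements.
* ``dnase_expression_score`` — Pearson correlation between the chosen
  accessibility site of the element and the gene's expression profile over
  a shared biosample panel; pairs without a usable site or expression row
  receive the sentinel score -100 so they rank below every finite score.
* ``average_rank_score`` — combine two score lists by averaging their ranks.
* feature extraction plus a chromosome-grouped supervised harness
  (gradient-boosted trees) with out-of-fold scoring and cross-cell-type
  application.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier

from .annotations import GenomicInterval, RegulatoryElement, TssIndex
from .curation import CandidatePair

__all__ = [
    "SENTINEL_SCORE",
    "PairScore",
    "SignalMatrix",
    "ClosestGeneResult",
    "closest_gene_prediction",
    "distance_score",
    "dnase_dnase_score",
    "dnase_expression_score",
    "average_rank_score",
    "build_tss_element_map",
    "extract_features",
    "default_learner",
    "supervised_cv",
    "cross_cell_apply",
    "CORE4_TRACKS",
    "CORE3_TRACKS",
]

SENTINEL_SCORE = -100.0

CORE4_TRACKS = ("DNase", "H3K4me3", "H3K27ac", "CTCF")
CORE3_TRACKS = ("DNase", "H3K4me3", "H3K27ac")


@dataclass(frozen=True, order=True)
class PairScore:
    element_id: str
    gene_id: str
    score: float
    method: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.element_id, self.gene_id)


class SignalMatrix:
    """Element-or-gene x biosample numeric panel with optional column groups.

    Wraps a pandas DataFrame (rows: element or gene ids; columns:
    biosamples).  ``column_groups`` maps each column to a cell-type group
    label; ``group_averaged`` collapses the panel to one mean value per
    group, the scheme used by the accessibility-correlation predictor.
    """

    def __init__(self, values: pd.DataFrame, column_groups: Mapping[str, str] | None = None):
        if values.index.has_duplicates:
            raise ValueError("duplicate row ids in signal matrix")
        self.values = values.astype(float)
        if column_groups is not None:
            missing = set(values.columns) - set(column_groups)
            if missing:
                raise ValueError(f"columns without a group label: {sorted(missing)}")
            self.column_groups = pd.Series(
                {c: column_groups[c] for c in values.columns}
            )
        else:
            self.column_groups = None

    @property
    def row_ids(self) -> pd.Index:
        return self.values.index

    @property
    def columns(self) -> pd.Index:
        return self.values.columns

    def row(self, row_id: str) -> np.ndarray:
        return self.values.loc[row_id].to_numpy()

    def __contains__(self, row_id: str) -> bool:
        return row_id in self.values.index

    def group_averaged(self) -> "SignalMatrix":
        if self.column_groups is None:
            raise ValueError("no column grouping attached")
        avg = self.values.T.groupby(self.column_groups).mean().T
        return SignalMatrix(avg.sort_index(axis=1))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with population denominators; NaN when degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


class ClosestGeneResult(NamedTuple):
    predictions: dict  # element_id -> gene_id
    n_skipped: int


def closest_gene_prediction(
    elements: Sequence[RegulatoryElement], tss: TssIndex
) -> ClosestGeneResult:
    """Assign each element to the gene owning its nearest TSS.

    Equidistant TSSs of different genes are resolved toward the
    lexicographically smaller gene id.  Elements on chromosomes without any
    TSS are skipped and counted.
    """
    predictions: dict[str, str] = {}
    skipped = 0
    for el in elements:
        try:
            site, _ = tss.nearest_site(el.interval)
        except LookupError:
            skipped += 1
            continue
        predictions[el.element_id] = site.gene_id
    return ClosestGeneResult(predictions, skipped)


def distance_score(pairs: Sequence[CandidatePair]) -> list[PairScore]:
    """Inverse-distance ranking: score = 1/distance, capped at 1 for d = 0.

    Curated pairs involve distal elements, so distances are > 2000 in
    practice; the cap only guards degenerate inputs.
    """
    return [
        PairScore(
            p.element_id,
            p.gene_id,
            1.0 if p.distance == 0 else 1.0 / p.distance,
            "distance",
        )
        for p in pairs
    ]


def build_tss_element_map(
    tss: TssIndex, elements: Sequence[RegulatoryElement]
) -> dict[str, list[str]]:
    """For each gene, the element closest to each of its TSSs.

    This is the "TSS-proximal element" set against which the accessibility
    correlation of a candidate element is computed.
    """
    from .curation import _ElementLookup  # shared vectorized lookup

    lookup = _ElementLookup(elements)
    by_chrom = {
        chrom: sorted(
            (el for el in elements if el.chrom == chrom),
            key=lambda e: (e.interval.start, e.element_id),
        )
        for chrom in {el.chrom for el in elements}
    }
    starts = {
        chrom: np.array([e.interval.start for e in els])
        for chrom, els in by_chrom.items()
    }
    result: dict[str, list[str]] = {}
    for site in tss:
        els = by_chrom.get(site.chrom)
        if not els:
            continue
        # candidates: containing elements, plus flanking neighbours by start
        cands = set(lookup.containing(site.chrom, site.pos))
        i = int(np.searchsorted(starts[site.chrom], site.pos))
        for j in (i - 1, i):
            if 0 <= j < len(els):
                cands.add(els[j])
        best = min(
            cands,
            key=lambda e: (
                abs_gap(e.interval, site.pos),
                e.element_id,
            ),
        )
        bucket = result.setdefault(site.gene_id, [])
        if best.element_id not in bucket:
            bucket.append(best.element_id)
    return result


def abs_gap(iv: GenomicInterval, pos: int) -> int:
    from .annotations import interval_point_gap

    return interval_point_gap(iv.start, iv.end, pos)


def dnase_dnase_score(
    pairs: Sequence[CandidatePair],
    element_signals: SignalMatrix,
    tss_element_map: Mapping[str, Sequence[str]],
    min_groups: int = 3,
) -> list[PairScore]:
    """Accessibility-accessibility correlation over cell-type groups.

    Columns are first averaged within groups; the pair score is the highest
    Pearson correlation between the element's group profile and the group
    profile of any TSS-proximal element of the gene.  Pairs with fewer than
    ``min_groups`` grouped columns, missing rows, or zero-variance profiles
    receive the -100 sentinel.
    """
    grouped = (
        element_signals.group_averaged()
        if element_signals.column_groups is not None
        else element_signals
    )
    n_groups = grouped.values.shape[1]
    scores = []
    for p in pairs:
        score = SENTINEL_SCORE
        if n_groups >= min_groups and p.element_id in grouped:
            evec = grouped.row(p.element_id)
            best = None
            for proxy in tss_element_map.get(p.gene_id, ()):
                if proxy not in grouped:
                    continue
                r = _pearson(evec, grouped.row(proxy))
                if not np.isnan(r) and (best is None or r > best):
                    best = r
            if best is not None:
                score = best
        scores.append(PairScore(p.element_id, p.gene_id, score, "dnase-dnase"))
    return scores


def dnase_expression_score(
    pairs: Sequence[CandidatePair],
    site_signals: SignalMatrix,
    expression: SignalMatrix,
    element_site_overlap: Mapping[str, Sequence[str]],
    focal_biosample: str,
) -> list[PairScore]:
    """Accessibility-expression correlation over a shared biosample panel.

    When an element overlaps several accessibility sites, the site with the
    strongest signal in ``focal_biosample`` is used.  Pairs without an
    overlapping site, without an expression row, or with a zero-variance
    profile receive the -100 sentinel.
    """
    if list(site_signals.columns) != list(expression.columns):
        raise ValueError("site and expression matrices must share a column panel")
    scores = []
    for p in pairs:
        score = SENTINEL_SCORE
        sites = [s for s in element_site_overlap.get(p.element_id, ()) if s in site_signals]
        if sites and p.gene_id in expression:
            site = max(
                sites,
                key=lambda s: (site_signals.values.at[s, focal_biosample], s),
            )
            r = _pearson(site_signals.row(site), expression.row(p.gene_id))
            if not np.isnan(r):
                score = r
        scores.append(PairScore(p.element_id, p.gene_id, score, "dnase-expression"))
    return scores


def average_rank_score(
    a: Sequence[PairScore], b: Sequence[PairScore]
) -> list[PairScore]:
    """Combine two methods by averaging the rank of each pair.

    Rank 1 is the best (highest) score in each list, ties receive the mean
    rank, and the combined score is -(rank_a + rank_b)/2 so that higher
    remains better.  Both lists must cover the same pairs.
    """
    keys_a = {s.key for s in a}
    keys_b = {s.key for s in b}
    if keys_a != keys_b:
        diff = sorted(keys_a ^ keys_b)
        raise ValueError(f"pair universes differ; symmetric difference: {diff}")
    a = sorted(a, key=lambda s: s.key)
    b = sorted(b, key=lambda s: s.key)
    ranks_a = rankdata([-s.score for s in a], method="average")
    ranks_b = rankdata([-s.score for s in b], method="average")
    return [
        PairScore(s.element_id, s.gene_id, -(ra + rb) / 2.0, "average-rank")
        for s, ra, rb in zip(a, ranks_a, ranks_b)
    ]


def _region_mean(track: Mapping[str, np.ndarray], chrom: str, start: int, end: int,
                 track_name: str) -> float:
    if chrom not in track:
        raise KeyError(f"track {track_name!r} has no data for chromosome {chrom}")
    arr = track[chrom]
    start = max(start, 0)
    end = min(end, len(arr))
    if end <= start:
        return 0.0
    return float(np.mean(arr[start:end]))


def extract_features(
    pairs: Sequence[CandidatePair],
    tracks: Mapping[str, Mapping[str, np.ndarray]],
    tss: TssIndex,
    schema: str = "core4",
    promoter_window: int = 2000,
) -> pd.DataFrame:
    """Per-pair epigenomic features at enhancer, promoter, and window regions.

    For every track, the mean per-base signal is computed over (i) the
    element, (ii) the promoter (nearest TSS of the gene +/-
    ``promoter_window``), and (iii) the intervening window between element
    and promoter (zero when they touch or overlap), plus the element-gene
    distance.  ``core4`` uses DNase, H3K4me3, H3K27ac, and CTCF (13
    features); ``core3`` drops CTCF (10); ``full`` uses every provided
    track.
    """
    if schema == "core4":
        names = CORE4_TRACKS
    elif schema == "core3":
        names = CORE3_TRACKS
    else:
        names = tuple(sorted(tracks))
    missing = [t for t in names if t not in tracks]
    if missing:
        raise KeyError(f"schema {schema!r} requires missing tracks: {missing}")
    rows = []
    for p in pairs:
        site, _ = tss.nearest_site(
            GenomicInterval(p.chrom, p.element_start, p.element_end), gene_id=p.gene_id
        )
        prom_start = max(site.pos - promoter_window, 0)
        prom_end = site.pos + promoter_window + 1
        win_start = min(p.element_end, prom_end)
        win_end = max(p.element_start, prom_start)
        row: dict[str, float] = {}
        for t in names:
            row[f"{t}|enhancer"] = _region_mean(
                tracks[t], p.chrom, p.element_start, p.element_end, t
            )
            row[f"{t}|promoter"] = _region_mean(tracks[t], p.chrom, prom_start, prom_end, t)
            row[f"{t}|window"] = (
                _region_mean(tracks[t], p.chrom, win_start, win_end, t)
                if win_end > win_start
                else 0.0
            )
        row["distance"] = float(p.distance)
        rows.append(row)
    columns = [f"{t}|{r}" for t in names for r in ("enhancer", "promoter", "window")]
    columns.append("distance")
    return pd.DataFrame(rows, columns=columns)


def default_learner(seed: int = 0) -> GradientBoostingClassifier:
    """Gradient-boosted trees with the conventional configuration for this task."""
    return GradientBoostingClassifier(
        n_estimators=4000, learning_rate=0.1, max_depth=5, random_state=seed
    )


def supervised_cv(
    features: pd.DataFrame,
    labels: Sequence[int],
    groups: Sequence[str],
    learner=None,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Out-of-fold scores under grouped cross-validation.

    For each fold (unique group label), a fresh learner is trained on all
    other folds and scores the held-out fold; every pair is scored exactly
    once by a model that never saw its group.  A fold whose training labels
    are single-class is an error.  Returns the score array aligned with
    ``features`` rows and a provenance record (learner parameters, seed,
    fold sizes).
    """
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(groups)
    if len(features) != len(labels) or len(features) != len(groups):
        raise ValueError("features, labels, and groups must align")
    base = learner if learner is not None else default_learner(seed)
    scores = np.full(len(labels), np.nan)
    fold_sizes = {}
    for g in sorted(set(groups)):
        test_mask = groups == g
        train_mask = ~test_mask
        train_y = labels[train_mask]
        if len(np.unique(train_y)) < 2:
            raise ValueError(f"fold {g!r}: training labels are single-class")
        model = clone(base)
        model.fit(features.iloc[train_mask.nonzero()[0]], train_y)
        scores[test_mask] = model.predict_proba(
            features.iloc[test_mask.nonzero()[0]]
        )[:, 1]
        fold_sizes[g] = int(test_mask.sum())
    assert not np.isnan(scores).any()
    provenance = {
        "learner": type(base).__name__,
        "params": base.get_params(),
        "seed": seed,
        "fold_sizes": fold_sizes,
    }
    return scores, provenance


def cross_cell_apply(
    train_features: pd.DataFrame,
    train_labels: Sequence[int],
    train_groups: Sequence[str],
    test_features: pd.DataFrame,
    test_groups: Sequence[str],
    learner=None,
    seed: int = 0,
) -> np.ndarray:
    """Score one biosample's pairs with models trained on another biosample.

    The test set must carry CV groups transferred from the training
    assignment (see :func:`egbench.cv.transfer_cv`); per fold, a model
    trained on the training biosample's *other* folds scores the test
    fold, so no chromosome contributes to both sides.  Feature schemas
    must match exactly.
    """
    if list(train_features.columns) != list(test_features.columns):
        diff = sorted(
            set(train_features.columns) ^ set(test_features.columns)
        )
        raise ValueError(f"feature schemas differ: {diff}")
    train_labels = np.asarray(train_labels, dtype=int)
    train_groups = np.asarray(train_groups)
    test_groups = np.asarray(test_groups)
    base = learner if learner is not None else default_learner(seed)
    scores = np.full(len(test_features), np.nan)
    for g in sorted(set(test_groups)):
        train_mask = train_groups != g
        train_y = train_labels[train_mask]
        if len(np.unique(train_y)) < 2:
            raise ValueError(f"fold {g!r}: training labels are single-class")
        model = clone(base)
        model.fit(train_features.iloc[train_mask.nonzero()[0]], train_y)
        test_mask = test_groups == g
        scores[test_mask] = model.predict_proba(
            test_features.iloc[test_mask.nonzero()[0]]
        )[:, 1]
    assert not np.isnan(scores).any()
    return scores
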