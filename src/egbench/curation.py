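"""Benchmark curation: labeled element-gene pairs, negatives, and variants.

The curation procedure turns assay evidence into a labeled benchmark:

* 3D-chromatin links (ChIA-PET / Hi-C loops / capture Hi-C) yield a positive
  pair when one anchor overlaps a distal candidate element and the opposite
  anchor lies within the promoter window (+/- 2 kb) of at least one TSS.
  When the TSS-side anchor reaches the promoter windows of several genes the
  derived pairs are flagged *ambiguous*.
* Variant-gene (eQTL) and perturbation (crisprQTL) evidence yields a
  positive pair when the element contains the variant or overlaps the
  perturbed region; the target gene is stated explicitly, so no ambiguity
  flagging is needed.
* Negatives: for each element carrying a positive within the distance
  cutoff (the 95th percentile of positive-pair distances, nearest-rank
  convention), every other annotated gene whose nearest TSS lies within the
  cutoff becomes a negative pair.
* Dataset variants: with/without ambiguous pairs, and natural-ratio vs a
  fixed 1:4 positive:negative ratio obtained by seeded down-sampling.
  Elements with fewer than four eligible negatives are excluded from the
  fixed-ratio sets entirely.
* Matched subsets (for dissecting supervised models): 1:2 ratio, promoter-
  matched, distance-matched over 5 equal-occupancy distance bins, and the
  combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    GenomicInterval,
    RegulatoryElement,
    TssIndex,
    interval_point_gap,
)
from .interaction_io import (
    ChromatinLink,
    ParseResult,
    PerturbationLink,
    VariantGeneAssociation,
)

__all__ = [
    "CurationPolicy",
    "CandidatePair",
    "BenchmarkDataset",
    "pairs_from_links",
    "pairs_from_associations",
    "negative_cutoff",
    "generate_negatives",
    "strip_ambiguous",
    "fixed_ratio_variant",
    "matched_subsets",
    "curate_dataset",
    "write_benchmark_tsv",
    "read_benchmark_tsv",
]

THREE_D_ASSAYS = {"chiapet", "hic", "chic"}


@dataclass(frozen=True)
class CurationPolicy:
    """All tunable curation constants.

    promoter_window     bp each side of a TSS defining "promoter-proximal"
    negative_percentile percentile of positive-pair distances bounding negatives
    fixed_ratio         negatives per positive in fixed-ratio variants
    min_negatives       minimum eligible negatives for an element to survive
                        fixed-ratio construction
    matched_ratio       negatives per positive in matched subsets
    n_distance_bins     equal-occupancy distance bins for distance matching
    rng_seed            seed for every random draw during curation
    """

    promoter_window: int = 2000
    negative_percentile: float = 95.0
    fixed_ratio: int = 4
    min_negatives: int = 4
    matched_ratio: int = 2
    n_distance_bins: int = 5
    rng_seed: int = 13

    def __post_init__(self):
        if min(self.promoter_window, self.fixed_ratio, self.min_negatives,
               self.matched_ratio, self.n_distance_bins) <= 0:
            raise ValueError("policy counts must be positive")
        if not 0 < self.negative_percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")


@dataclass(frozen=True, order=True)
class CandidatePair:
    element_id: str
    gene_id: str
    label: str  # "positive" | "negative"
    ambiguous: bool
    distance: int
    chrom: str
    element_start: int
    element_end: int
    dataset_id: str = ""
    cv_group: str | None = None

    def __post_init__(self):
        if self.label not in ("positive", "negative"):
            raise ValueError(f"bad label {self.label!r}")
        if self.distance < 0:
            raise ValueError("negative distance")
        if self.ambiguous and self.label != "positive":
            raise ValueError("only positive pairs may be ambiguous")

    @property
    def key(self) -> tuple[str, str]:
        return (self.element_id, self.gene_id)


@dataclass
class BenchmarkDataset:
    dataset_id: str
    assay: str
    biosample: str
    variant: str  # all_natural | all_fixed | noambig_natural | noambig_fixed | matched_*
    pairs: list[CandidatePair]
    policy: CurationPolicy = field(default_factory=CurationPolicy)
    cutoff: int | None = None
    provenance: dict = field(default_factory=dict)
    # curation context carried along so derived variants can regenerate
    # negatives; never serialized
    ambiguous_genes: dict[str, set[str]] = field(default_factory=dict, repr=False)
    _elements: list[RegulatoryElement] | None = field(default=None, repr=False)
    _tss: TssIndex | None = field(default=None, repr=False)

    def positives(self) -> list[CandidatePair]:
        return [p for p in self.pairs if p.label == "positive"]

    def negatives(self) -> list[CandidatePair]:
        return [p for p in self.pairs if p.label == "negative"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset_id": [p.dataset_id or self.dataset_id for p in self.pairs],
                "element_id": [p.element_id for p in self.pairs],
                "chrom": [p.chrom for p in self.pairs],
                "start": [p.element_start for p in self.pairs],
                "end": [p.element_end for p in self.pairs],
                "gene_id": [p.gene_id for p in self.pairs],
                "label": [1 if p.label == "positive" else 0 for p in self.pairs],
                "ambiguous": [int(p.ambiguous) for p in self.pairs],
                "distance": [p.distance for p in self.pairs],
                "cv_group": [p.cv_group or "" for p in self.pairs],
            }
        )


class _ElementLookup:
    """Per-chromosome vectorized interval overlap / containment queries."""

    def __init__(self, elements: Sequence[RegulatoryElement]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[RegulatoryElement]]] = {}
        grouped: dict[str, list[RegulatoryElement]] = {}
        for el in elements:
            grouped.setdefault(el.chrom, []).append(el)
        for chrom, els in grouped.items():
            els.sort(key=lambda e: (e.interval.start, e.interval.end, e.element_id))
            self._by_chrom[chrom] = (
                np.array([e.interval.start for e in els], dtype=np.int64),
                np.array([e.interval.end for e in els], dtype=np.int64),
                els,
            )

    def overlapping(self, interval: GenomicInterval) -> list[RegulatoryElement]:
        entry = self._by_chrom.get(interval.chrom)
        if entry is None:
            return []
        starts, ends, els = entry
        mask = (starts < interval.end) & (ends > interval.start)
        return [els[i] for i in np.nonzero(mask)[0]]

    def containing(self, chrom: str, pos: int) -> list[RegulatoryElement]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, els = entry
        mask = (starts <= pos) & (pos < ends)
        return [els[i] for i in np.nonzero(mask)[0]]


def _pair_distance(el: RegulatoryElement, tss: TssIndex, gene_id: str) -> int:
    _, dist = tss.nearest_site(el.interval, gene_id=gene_id)
    return dist


def pairs_from_links(
    links: Iterable[ChromatinLink],
    elements: Sequence[RegulatoryElement],
    tss: TssIndex,
    policy: CurationPolicy = CurationPolicy(),
    allow_same_anchor: bool = False,
) -> tuple[list[CandidatePair], dict[str, set[str]]]:
    """Positive pairs from 3D-chromatin links, plus the per-element ambiguity map.

    Both orientations of every link are evaluated: the element must overlap
    one anchor and at least one TSS must lie within the promoter window of
    the *opposite* anchor (same-anchor pairings are excluded unless
    ``allow_same_anchor``; they are indistinguishable from self-ligation).
    A TSS-side anchor reaching the windows of two or more distinct genes
    marks all its pairs ambiguous.  Pairs seen through at least one
    unambiguous anchor are not flagged.  Returns the deduplicated positives
    and a map element_id -> genes linked through ambiguous anchors.
    """
    lookup = _ElementLookup(elements)
    element_by_id = {el.element_id: el for el in elements}
    # (element_id, gene_id) -> saw an unambiguous supporting anchor?
    support: dict[tuple[str, str], bool] = {}
    amb_events: dict[str, set[str]] = {}
    for link in links:
        orientations = [(link.anchor1, link.anchor2), (link.anchor2, link.anchor1)]
        if allow_same_anchor:
            orientations += [(link.anchor1, link.anchor1), (link.anchor2, link.anchor2)]
        for el_anchor, tss_anchor in orientations:
            hit_elements = lookup.overlapping(el_anchor)
            if not hit_elements:
                continue
            sites = tss.sites_within_window(tss_anchor, policy.promoter_window)
            genes = sorted({s.gene_id for s in sites})
            if not genes:
                continue
            ambiguous = len(genes) >= 2
            for el in hit_elements:
                for gene in genes:
                    key = (el.element_id, gene)
                    support[key] = support.get(key, False) or not ambiguous
                    if ambiguous:
                        amb_events.setdefault(el.element_id, set()).add(gene)
    positives = []
    for (eid, gene), unambiguous in sorted(support.items()):
        el = element_by_id[eid]
        positives.append(
            CandidatePair(
                element_id=eid,
                gene_id=gene,
                label="positive",
                ambiguous=not unambiguous,
                distance=_pair_distance(el, tss, gene),
                chrom=el.chrom,
                element_start=el.interval.start,
                element_end=el.interval.end,
            )
        )
    ambiguous_genes = {
        eid: {g for g in genes if not support[(eid, g)]}
        for eid, genes in amb_events.items()
    }
    ambiguous_genes = {eid: g for eid, g in ambiguous_genes.items() if g}
    return positives, ambiguous_genes


def pairs_from_associations(
    associations: Iterable[VariantGeneAssociation | PerturbationLink],
    elements: Sequence[RegulatoryElement],
    tss: TssIndex,
) -> ParseResult:
    """Positive pairs from eQTL / perturbation evidence.

    An element containing the variant position (or overlapping the perturbed
    region) is paired with the stated gene.  Associations whose gene is
    absent from the annotation are skipped and counted in ``n_skipped``.
    """
    lookup = _ElementLookup(elements)
    known_genes = tss.genes()
    seen: set[tuple[str, str]] = set()
    positives: list[CandidatePair] = []
    skipped = 0
    for assoc in associations:
        if assoc.gene_id not in known_genes:
            skipped += 1
            continue
        if isinstance(assoc, PerturbationLink):
            hits = lookup.overlapping(assoc.region)
        else:
            hits = lookup.containing(assoc.chrom, assoc.pos)
        for el in hits:
            key = (el.element_id, assoc.gene_id)
            if key in seen:
                continue
            seen.add(key)
            positives.append(
                CandidatePair(
                    element_id=el.element_id,
                    gene_id=assoc.gene_id,
                    label="positive",
                    ambiguous=False,
                    distance=_pair_distance(el, tss, assoc.gene_id),
                    chrom=el.chrom,
                    element_start=el.interval.start,
                    element_end=el.interval.end,
                )
            )
    positives.sort()
    return ParseResult(positives, n_skipped=skipped)


def negative_cutoff(positives: Sequence[CandidatePair], percentile: float = 95.0) -> int:
    """Nearest-rank percentile of positive-pair distances.

    The value returned is the ``ceil(p/100 * n)``-th smallest distance, so
    it is always one of the observed distances and is permutation
    invariant.
    """
    if not positives:
        raise ValueError("cannot take a percentile of zero positive pairs")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    distances = sorted(p.distance for p in positives)
    rank = int(np.ceil(percentile / 100.0 * len(distances)))
    return distances[max(rank, 1) - 1]


def generate_negatives(
    positives: Sequence[CandidatePair],
    ambiguous_gene_ids: Mapping[str, set[str]],
    elements: Sequence[RegulatoryElement],
    tss: TssIndex,
    cutoff: int,
    exclude_ambiguous: bool = False,
) -> list[CandidatePair]:
    """All unpaired genes within ``cutoff`` of each positive-bearing element.

    Only elements that carry at least one positive pair with distance <=
    ``cutoff`` spawn negatives.  Genes already positive for the element are
    never negatives; with ``exclude_ambiguous``, genes the element is
    ambiguously linked to are excluded as well.
    """
    element_by_id = {el.element_id: el for el in elements}
    pos_genes: dict[str, set[str]] = {}
    eligible_elements: set[str] = set()
    for p in positives:
        pos_genes.setdefault(p.element_id, set()).add(p.gene_id)
        if p.distance <= cutoff:
            eligible_elements.add(p.element_id)
    negatives: list[CandidatePair] = []
    for eid in sorted(eligible_elements):
        el = element_by_id[eid]
        iv = el.interval
        excluded = set(pos_genes.get(eid, ()))
        if exclude_ambiguous:
            excluded |= set(ambiguous_gene_ids.get(eid, ()))
        # a TSS at gap distance <= cutoff lies in [start-1-cutoff, end+cutoff]
        sites = tss.sites_in_range(iv.chrom, iv.start - 1 - cutoff, iv.end + cutoff)
        genes = sorted(
            {
                s.gene_id
                for s in sites
                if interval_point_gap(iv.start, iv.end, s.pos) <= cutoff
            }
            - excluded
        )
        for gene in genes:
            negatives.append(
                CandidatePair(
                    element_id=eid,
                    gene_id=gene,
                    label="negative",
                    ambiguous=False,
                    distance=_pair_distance(el, tss, gene),
                    chrom=el.chrom,
                    element_start=iv.start,
                    element_end=iv.end,
                )
            )
    return negatives


def curate_dataset(
    dataset_id: str,
    assay: str,
    biosample: str,
    positives: Sequence[CandidatePair],
    ambiguous_genes: Mapping[str, set[str]],
    elements: Sequence[RegulatoryElement],
    tss: TssIndex,
    policy: CurationPolicy = CurationPolicy(),
) -> BenchmarkDataset:
    """Assemble the natural-ratio, all-pairs benchmark dataset."""
    positives = sorted(positives)
    cutoff = negative_cutoff(positives, policy.negative_percentile)
    negatives = generate_negatives(
        positives, ambiguous_genes, elements, tss, cutoff, exclude_ambiguous=False
    )
    pairs = [replace(p, dataset_id=dataset_id) for p in positives + negatives]
    return BenchmarkDataset(
        dataset_id=dataset_id,
        assay=assay,
        biosample=biosample,
        variant="all_natural",
        pairs=pairs,
        policy=policy,
        cutoff=cutoff,
        provenance={"rng_seed": policy.rng_seed, "cutoff": cutoff},
        ambiguous_genes={k: set(v) for k, v in ambiguous_genes.items()},
        _elements=list(elements),
        _tss=tss,
    )


def strip_ambiguous(dataset: BenchmarkDataset) -> BenchmarkDataset:
    """Remove ambiguous positives and regenerate negatives accordingly.

    Only meaningful for 3D-chromatin datasets; assays that state the linked
    gene explicitly (eQTL, crisprQTL) have no ambiguous pairs, and the call
    is a no-op with a warning.  The distance cutoff is recomputed from the
    retained positives, and genes in ambiguous pairs are excluded from the
    regenerated negatives.
    """
    if dataset.assay not in THREE_D_ASSAYS:
        warnings.warn(
            f"strip_ambiguous is a no-op for assay {dataset.assay!r}: the linked "
            "gene is stated explicitly, so no ambiguity filtering is required",
            stacklevel=2,
        )
        return dataset
    if dataset._elements is None or dataset._tss is None:
        raise ValueError("dataset lacks curation context; rebuild with curate_dataset")
    kept = [p for p in dataset.positives() if not p.ambiguous]
    if not kept:
        return replace(dataset, variant="noambig_natural", pairs=[], cutoff=None)
    cutoff = negative_cutoff(kept, dataset.policy.negative_percentile)
    negatives = generate_negatives(
        kept,
        dataset.ambiguous_genes,
        dataset._elements,
        dataset._tss,
        cutoff,
        exclude_ambiguous=True,
    )
    pairs = [replace(p, dataset_id=dataset.dataset_id) for p in kept + negatives]
    return replace(
        dataset,
        variant="noambig_natural",
        pairs=pairs,
        cutoff=cutoff,
        provenance={**dataset.provenance, "cutoff": cutoff},
    )


def fixed_ratio_variant(
    dataset: BenchmarkDataset,
    cross_dataset_positives: Mapping[str, set[str]] | None = None,
) -> BenchmarkDataset:
    """Down-sample negatives to a fixed per-element positive:negative ratio.

    Per element: negatives whose gene is a positive for that element in any
    other benchmark dataset (``cross_dataset_positives``) are removed
    first; elements left with fewer than ``policy.min_negatives`` eligible
    negatives are dropped entirely, positives included; the remaining
    negatives are sampled without replacement (seeded) down to
    ``policy.fixed_ratio`` per positive pair of the element.
    """
    cross = cross_dataset_positives or {}
    policy = dataset.policy
    rng = np.random.default_rng(policy.rng_seed)
    by_element: dict[str, dict[str, list[CandidatePair]]] = {}
    for p in dataset.pairs:
        by_element.setdefault(p.element_id, {"positive": [], "negative": []})[
            p.label
        ].append(p)
    out: list[CandidatePair] = []
    for eid in sorted(by_element):
        pos = sorted(by_element[eid]["positive"])
        neg = sorted(by_element[eid]["negative"])
        if not pos:
            continue
        blocked = cross.get(eid, set())
        eligible = [n for n in neg if n.gene_id not in blocked]
        if len(eligible) < policy.min_negatives:
            continue
        want = min(policy.fixed_ratio * len(pos), len(eligible))
        idx = rng.choice(len(eligible), size=want, replace=False)
        out.extend(pos)
        out.extend(eligible[i] for i in sorted(idx))
    variant = "noambig_fixed" if dataset.variant.startswith("noambig") else "all_fixed"
    return replace(dataset, variant=variant, pairs=sorted(out))


def _quantile_bin_edges(distances: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    inner = np.quantile(distances, qs)
    return np.concatenate(([-np.inf], inner, [np.inf]))


def matched_subsets(
    dataset: BenchmarkDataset,
    mode: str,
) -> BenchmarkDataset:
    """Matched positive/negative subsets for model dissection.

    ``ratio``             per element: 1 positive and ``matched_ratio`` negatives.
    ``promoter``          keep only genes in >=1 positive and >=1 negative pair,
                          then enforce the global 1:``matched_ratio`` ratio.
    ``distance``          bin pairs by ``n_distance_bins`` equal-occupancy
                          quantiles of positive distances, sample the same
                          number of positives per bin at 1:``matched_ratio``.
    ``promoter_distance`` promoter restriction, then distance matching.
    """
    if mode not in ("ratio", "promoter", "distance", "promoter_distance"):
        raise ValueError(f"unknown matching mode {mode!r}")
    policy = dataset.policy
    rng = np.random.default_rng(policy.rng_seed + 1)
    pos = sorted(dataset.positives())
    neg = sorted(dataset.negatives())

    if mode in ("promoter", "promoter_distance"):
        pos_genes = {p.gene_id for p in pos}
        neg_genes = {n.gene_id for n in neg}
        shared = pos_genes & neg_genes
        pos = [p for p in pos if p.gene_id in shared]
        neg = [n for n in neg if n.gene_id in shared]

    out: list[CandidatePair] = []
    if mode == "ratio":
        by_element: dict[str, tuple[list, list]] = {}
        for p in pos:
            by_element.setdefault(p.element_id, ([], []))[0].append(p)
        for n in neg:
            by_element.setdefault(n.element_id, ([], []))[1].append(n)
        for eid in sorted(by_element):
            epos, eneg = by_element[eid]
            if not epos or len(eneg) < policy.matched_ratio:
                continue
            pi = rng.choice(len(epos), size=1, replace=False)
            ni = rng.choice(len(eneg), size=policy.matched_ratio, replace=False)
            out.extend([epos[i] for i in sorted(pi)])
            out.extend([eneg[i] for i in sorted(ni)])
    elif mode == "promoter":
        want_neg = policy.matched_ratio * len(pos)
        if len(neg) >= want_neg:
            ni = rng.choice(len(neg), size=want_neg, replace=False)
            out.extend(pos)
            out.extend(neg[i] for i in sorted(ni))
        else:
            want_pos = len(neg) // policy.matched_ratio
            pi = rng.choice(len(pos), size=want_pos, replace=False)
            out.extend(pos[i] for i in sorted(pi))
            out.extend(neg)
    else:  # distance or promoter_distance
        if not pos:
            return replace(dataset, variant=f"matched_{mode}", pairs=[])
        edges = _quantile_bin_edges(
            np.array([p.distance for p in pos], dtype=float), policy.n_distance_bins
        )
        pos_bins = np.digitize([p.distance for p in pos], edges[1:-1], right=True)
        neg_bins = np.digitize([n.distance for n in neg], edges[1:-1], right=True)
        per_bin_pos = [
            [p for p, b in zip(pos, pos_bins) if b == k]
            for k in range(policy.n_distance_bins)
        ]
        per_bin_neg = [
            [n for n, b in zip(neg, neg_bins) if b == k]
            for k in range(policy.n_distance_bins)
        ]
        feasible = [
            min(len(bp), len(bn) // policy.matched_ratio)
            for bp, bn in zip(per_bin_pos, per_bin_neg)
        ]
        usable = [m for m in feasible if m > 0]
        take = min(usable) if usable else 0
        for bp, bn, m in zip(per_bin_pos, per_bin_neg, feasible):
            if m == 0 or take == 0:
                continue  # bin without eligible pairs dropped
            pi = rng.choice(len(bp), size=take, replace=False)
            ni = rng.choice(len(bn), size=take * policy.matched_ratio, replace=False)
            out.extend(bp[i] for i in sorted(pi))
            out.extend(bn[i] for i in sorted(ni))
    return replace(dataset, variant=f"matched_{mode}", pairs=sorted(out))


BENCHMARK_COLUMNS = [
    "dataset_id",
    "element_id",
    "chrom",
    "start",
    "end",
    "gene_id",
    "label",
    "ambiguous",
    "distance",
    "cv_group",
]


def write_benchmark_tsv(dataset: BenchmarkDataset, path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def read_benchmark_tsv(path) -> BenchmarkDataset:
    df = pd.read_csv(path, sep="\t", dtype={"cv_group": str}, keep_default_na=False)
    pairs = [
        CandidatePair(
            element_id=row.element_id,
            gene_id=row.gene_id,
            label="positive" if row.label == 1 else "negative",
            ambiguous=bool(row.ambiguous),
            distance=int(row.distance),
            chrom=row.chrom,
            element_start=int(row.start),
            element_end=int(row.end),
            dataset_id=row.dataset_id,
            cv_group=row.cv_group or None,
        )
        for row in df.itertuples()
    ]
    dataset_id = pairs[0].dataset_id if pairs else ""
    return BenchmarkDataset(
        dataset_id=dataset_id,
        assay="",
        biosample="",
        variant="",
        pairs=pairs,
    )
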