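# egbench

Curation and evaluation framework for enhancer–gene interaction benchmarks.

## The problem

Genome-wide registries annotate hundreds of thousands of candidate
cis-regulatory elements with enhancer-like signatures (high DNase
accessibility and H3K27ac, more than 2 kb from any transcription start
site), but knowing *which gene* each element regulates remains unsolved.
Experimental evidence — ChIA-PET clusters, Hi-C loops, promoter capture
Hi-C, cis-eQTLs, and CRISPR-perturbation screens — is sparse and
assay-biased, and computational predictors (nearest gene, inverse
distance, cross-biosample signal correlation, supervised classifiers on
epigenomic features) need a common, leakage-free benchmark to be compared
on.

`egbench` is for researchers developing or evaluating such target-gene
predictors. It implements the full benchmark-construction procedure and
the reference predictors, and ships a synthetic-fixture generator with
planted ground truth so every stage is testable without any external
downloads.

## What it does

**Curation.** A 3D-chromatin link becomes a positive pair (E, G) when one
anchor overlaps a distal element E and the opposite anchor falls within
±2 kb of a TSS of gene G; if the anchor reaches the promoter windows of
several genes, the pairs are flagged *ambiguous*. eQTL/CRISPR evidence
pairs an element containing the variant (or overlapping the perturbed
region) with the stated gene. Negatives are all unpaired genes whose TSS
lies within the 95th percentile (nearest-rank) of positive-pair
distances, per element. Variants: with/without ambiguous pairs, natural
vs fixed 1:4 positive:negative ratio (elements with fewer than four
eligible negatives are dropped), plus 1:2 matched subsets (ratio-,
promoter-, and distance-matched over 5 equal-occupancy distance bins).

**chromCV.** All pairs on a chromosome share a cross-validation fold;
chromosomes are greedily paired largest-with-smallest so folds balance.
23 chromosomes (1–22, X) always produce 12 groups. For cross-cell-type
evaluation the test set inherits the training folds.

**Predictors.** Closest gene; inverse distance (score = 1/d);
accessibility–accessibility correlation over cell-type column groups
(max Pearson r over the gene's TSS-proximal elements);
accessibility–expression correlation over a shared biosample panel (−100
sentinel for unmappable pairs); rank averaging of two methods; and a
gradient-boosted supervised harness over enhancer/promoter/window mean
signals + distance (core4 = DNase, H3K4me3, H3K27ac, CTCF → 13 features;
core3 drops CTCF), scored strictly out-of-fold under chromCV.

**Evaluation.** Step-wise precision–recall curves with tie grouping;
AUPR; overall precision/recall for hard assignments; overlap
coefficients between positive sets; dataset characterization (distance
percentiles, genes-per-element, expression of positive genes). A
score-free ranking has AUPR equal to the positive fraction — the random
baseline.

## Worked example

```sh
$ egbench simulate --seed 5 --outdir fixtures/
wrote fixtures to fixtures
$ egbench curate --assay chiapet --links fixtures/chiapet.tsv \
    --elements fixtures/elements.bed --gtf fixtures/annotation.gtf \
    --out bench.tsv
dataset [all_natural]: 42 positives, 108 negatives
$ egbench cv --pairs bench.tsv --out bench.cv.tsv
2 CV groups
$ egbench predict --method distance --pairs bench.cv.tsv --out scores.tsv
scored 150 pairs with distance
$ egbench evaluate --pairs bench.cv.tsv --scores scores.tsv --out pr.tsv
AUPR = 0.5227
```

The toy genome has 3 chromosomes, so the greedy pairing gives 2 CV
groups. 42 of 150 pairs are positive (positive fraction 0.28), so a
random ranking would score AUPR ≈ 0.28; the inverse-distance baseline
reaches 0.52 because the planted positives follow a short-range
(log-normal, median 30 kb) distance law while negatives spread out to the
95th-percentile cutoff.

The same operations are available as a library:

```python
from egbench import (simulate_annotation, simulate_links, SimulationConfig,
                     read_chiapet, pairs_from_links, curate_dataset,
                     apply_chrom_cv, distance_score, aupr)
```

## Layout

```
src/egbench/
  annotations.py     GTF/BED parsing, TSS index, distance queries, distality
  interaction_io.py  the five assay evidence dialects -> normalized records
  curation.py        positives, ambiguity, negatives, variants, matched subsets
  cv.py              chromCV assignment and cross-cell-type transfer
  predictors.py      closest gene, distance, correlations, rank average,
                     supervised harness
  evaluation.py      PR curves / AUPR, precision-recall, dataset summaries
  simulate.py        synthetic genomes, evidence, and signal panels
  cli.py             simulate / curate / cv / predict / evaluate commands
```

See `docs/methods.md` for the model, conventions, and design decisions.
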