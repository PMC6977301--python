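# Methods

This note documents the procedures `egbench` implements, the conventions
it fixes where the field leaves room, and what the synthetic fixtures do
and do not establish about real data.

## Coordinate and distance conventions

All coordinates are 0-based half-open internally (BED convention); GTF
input (1-based inclusive) is converted on read. The TSS of a transcript
is its 5′ end: the first base on the plus strand, the last transcribed
base (`end − 1`) on the minus strand. Transcripts of a gene that share a
start are collapsed to one TSS.

Two distance notions coexist and are deliberately distinct:

* **Gap distance** (element–gene distance, distality, negative cutoff):
  the number of intervening bases between a TSS point and an interval.
  A TSS inside or immediately adjacent to the interval is at distance 0.
  This definition is symmetric under reflection of the chromosome, which
  the asymmetric `start − pos` / `pos − end` alternative is not.
* **Promoter-window distance** (anchor-to-TSS test): |TSS − nearest
  interval base|, read inclusively, so "within ±2 kb" means window
  distance ≤ 2000.

"Distal" means gap distance strictly greater than 2000 from every TSS;
an element exactly 2000 bases from a TSS is proximal.

## Curation

Positive pairs from 3D-chromatin links evaluate **both orientations** of
each link: the element must overlap one anchor and a TSS must fall in
the promoter window of the *opposite* anchor. Same-anchor pairings
(element and TSS under one anchor) are excluded by default — they are
indistinguishable from self-ligation artifacts — behind an
`allow_same_anchor` flag. An anchor reaching the promoter windows of two
or more distinct genes marks its pairs ambiguous; a pair supported by at
least one unambiguous anchor is not flagged, because removing ambiguous
links still leaves that pair derivable from the clean link.

Evidence filters are applied at parse time: ChIA-PET clusters need a
read count ≥ 4 (column 7), capture Hi-C interactions a
log(observed/expected) strictly > 10 (column 11), and loop lists pass
unfiltered. Trans-chromosomal links are dropped (and counted) since
element–gene distance is undefined across chromosomes. Chromosome names
are normalized to the `chr`-prefixed convention on read; eQTL gene ids
lose their trailing version suffix.

The negative-cutoff percentile uses the **nearest-rank** convention
(`ceil(p/100·n)`-th order statistic), which is always an observed
distance and needs no interpolation choice. Positives farther than the
cutoff are retained as positives but spawn no negatives: the negative
rule keys on the cutoff, and there is no ground for discarding
evidence-supported pairs. The candidate-gene universe for negatives is
whatever gene set backs the TSS index, so a protein-coding restriction
is applied by loading the index with that flag.

Fixed-ratio variants work **per element**: negatives that are positives
for the same element in another benchmark dataset are removed first;
elements with fewer than `min_negatives` (default 4) eligible negatives
are dropped entirely, positives included; the rest are down-sampled
without replacement to `fixed_ratio` (default 4) negatives per positive.
When an element has several positives but not enough eligible negatives
to reach the full multiple, all its eligible negatives are kept — only
the minimum-4 rule removes elements. Ambiguous-gene exclusion is also
per element: only genes the element itself is ambiguously linked to are
banned as its negatives. After removing ambiguous positives
(`strip_ambiguous`) the cutoff is recomputed from the retained positives
and negatives are regenerated under the exclusion.

Matched subsets (for dissecting supervised models) use a 1:2 ratio:
*ratio* keeps 1 positive and 2 negatives per element; *promoter* keeps
only genes present in at least one positive and one negative pair before
enforcing the ratio; *distance* defines 5 equal-occupancy quantile bins
from positive distances and samples the same number of positives (and
twice as many negatives) from every bin, dropping bins without eligible
pairs; *promoter_distance* composes both.

Every random draw flows from one seeded generator recorded in the
dataset provenance, so benchmark TSVs are byte-reproducible.

## Chromosome-balanced cross-validation

Pair counts are computed per chromosome (positives and negatives
together, as both are held out together). The chromosome with the most
pairs forms its own group; the remaining chromosomes, ordered by count,
are repeatedly paired current-largest with current-smallest; an odd
leftover forms its own group. With C chromosomes carrying pairs this
gives `1 + ceil((C−1)/2)` groups — 12 for the 23 human chromosomes
(1–22, X). Count ties break lexicographically by chromosome name; group
labels `cv-0, cv-1, …` are ordered by descending group size. The
assignment is computed per dataset, since counts differ per dataset.
For cross-cell-type evaluation, the test set inherits the training
assignment so no chromosome contributes to both sides of any fold.

## Predictors

* **Closest gene**: nearest-TSS gene per element, ties toward the
  lexicographically smaller gene id (determinism).
* **Distance**: score = 1/d. Distance 0 is capped at score 1; curated
  pairs involve distal elements (d > 2000), so the cap only guards
  degenerate inputs.
* **Accessibility–accessibility correlation**: biosample columns are
  averaged within cell-type groups; the pair score is the maximum
  Pearson correlation between the element's group profile and the
  profile of any TSS-proximal element of the gene (the closest element
  to each of the gene's TSSs). Fewer than 3 grouped columns, missing
  rows, or zero-variance profiles yield the −100 sentinel.
* **Accessibility–expression correlation**: the element's strongest
  overlapping accessibility site in the focal biosample is correlated
  with the gene's expression row over a shared column panel. Pairs
  without a usable site or expression row get −100, ranking below every
  finite score. Pearson correlations use population denominators (the
  normalization cancels, so this matters only for documenting the
  zero-variance policy: sentinel, never NaN).
* **Average rank**: each method's scores become ranks (1 = best, ties
  at the mean rank); the combined score is −(rankA + rankB)/2 so higher
  stays better. Both inputs must cover the same pair universe.
* **Supervised harness**: mean per-base signal of each track over the
  element, the promoter (nearest TSS of the gene ±2 kb), and the
  intervening window (zero-vector when element and promoter touch or
  overlap), plus the pair distance. The core4 schema (DNase, H3K4me3,
  H3K27ac, CTCF) gives 13 features; core3 drops CTCF (10). Window means
  rather than sums are used; regions are clipped at chromosome bounds.
  The default learner is gradient-boosted trees (4000 estimators,
  learning rate 0.1, depth 5 — the conventional configuration for this
  task; fully overridable, and the tests use smaller learners). Scoring
  is strictly out-of-fold: each fold is scored by a model trained on all
  other folds, and a fold whose training labels are single-class is an
  error rather than a silent skip.

## Evaluation

PR curves are step-wise (non-interpolated): thresholds sit at distinct
score values, all tied pairs enter the confusion counts together (no
intra-tie ordering, hence no seed dependence), and
AUPR = Σ (R_i − R_{i−1})·P_i. Linear PR interpolation is known to be
biased, which is why it is not offered. Under this convention an
all-equal scoring has AUPR exactly equal to the positive fraction — the
random baseline — and the fixed 1:4 variant's baseline is exactly 0.2.
Published AUPRs computed with other integration conventions may differ
in the third decimal. Dataset summaries reuse the nearest-rank
percentile, so the reported 95th-percentile distance equals the
dataset's negative cutoff by construction. Expression summaries average
replicate TPM values per gene.

## Synthetic fixtures

The generator emulates the *structure* of the real inputs, not their
content:

* Genes are placed in evenly spaced, jittered slots (minimum slot
  spacing 8 kb, so unrelated promoter windows never touch); a slot
  becomes a divergent pair with probability f/(2−f), making a target
  fraction f of genes share a < 4 kb TSS neighborhood — the mechanism
  behind ambiguous anchors. Elements (200–350 bp) are
  rejection-sampled to be non-overlapping and strictly distal.
* Planted pair distances follow a log-normal law (default median 30 kb,
  σ = 1 on the log scale), truncated naturally by chromosome bounds;
  the planted gene is the one whose realized distance is closest to the
  sampled value. Each assay dialect is emitted with its own planted
  truth plus decoys: sub-threshold ChIA-PET counts, capture-Hi-C scores
  ≤ 10, and loop anchors in TSS-free regions. Loop lists are written
  without the `chr` prefix to exercise name normalization.
* Signal panels: every gene has a latent activity vector over the
  biosample panel; expression rows are broadly active (log-baseline
  1.5) and track the latent factor; element rows are sparse
  (log-baseline −0.5), and for true pairs the element's log-signal
  mixes the target gene's latent factor at weight `coactivity` with the
  element's own factor at weight √(1−coactivity²). Noise is column-wise
  Gaussian on the log signal. At coactivity 0 no signal is planted and
  correlation scores must match the random baseline.
* `simulate_locus_features` builds pairs whose features are shared
  within a locus while the locus positive-rate is assigned at random —
  features that help only through memorization. Randomized CV, which
  splits loci across folds, therefore scores above chromosome-held-out
  CV, reproducing the overfitting that motivates chromCV.

What passing tests show: the curation, CV, scoring, and evaluation
machinery is exactly equivalent to brute-force enumeration on inputs
with known truth, and the statistical behaviours (random baselines,
planted-signal recovery, CV leakage) are as derived. What they do not
show: anything about the biological accuracy of any predictor on real
genomes — real anchors are wider and noisier, real distance and
expression distributions are not log-normal/log-Gaussian, and real
ambiguity arises from annotation density, not only divergent promoters.

## Problem sizes

The default toy genome (3 × 1.2 Mb chromosomes, 60 genes, 40 elements,
40 links per assay) makes full-pipeline tests run in milliseconds; the
distance-distribution check uses a wider universe (4 × 4 Mb, 1200
genes, 400 elements, 2000 planted pairs) so that duplicate-pair
rejection does not thin the short-distance mass; the leakage check uses
23 chromosomes × 4 loci × 12 pairs. These sizes were chosen as the
smallest at which the statistical assertions are stable across seeds.

## Known limitations

* The cell-type grouping of biosample columns is an input, not bundled:
  real groupings come from external curation of biosample similarity.
* The GTF reader handles GENCODE-style and `key=value` attribute
  dialects only, and reads transcript records (not exon-derived TSSs).
* eQTL export layouts vary by release; the two bundled dialects cover a
  coordinate-column layout and a composite-variant-id layout, and
  custom layouts are supplied as `EqtlDialect` objects.
* No liftover; alternate-haplotype contigs are treated as ordinary
  chromosomes. No LD expansion of eQTL variants, no loop calling, no
  motif-based feature generation.
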