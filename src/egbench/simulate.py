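"""Synthetic fixtures: toy genomes, assay evidence, and signal panels.

The generator emulates the structures the curation pipeline consumes
without copying any real data:

* a toy annotation with genes spaced along a few chromosomes, a configured
  fraction of them arranged as divergent promoter pairs with TSSs less
  than ~4 kb apart (the mechanism behind ambiguous interaction anchors),
  and candidate elements placed strictly more than 2 kb from every TSS;
* evidence files in each assay dialect whose curated positives equal the
  planted ground-truth pairs, with element-gene distances drawn from a
  log-normal distribution (heavy right tail, truncated by chromosome
  bounds) and sub-threshold decoy records that must never survive
  filtering;
* signal/expression panels in which true pairs share a latent cell-type
  activity factor whose strength is configurable, genes are broadly active
  across the panel while elements are sparsely active, and noise is
  column-wise Gaussian on the log signal.

All randomness flows from ``SimulationConfig.seed``; identical seeds give
byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import (
    GenomicInterval,
    RegulatoryElement,
    TranscriptionStartSite,
    TssIndex,
    interval_point_gap,
    window_distance,
)

__all__ = [
    "SimulationConfig",
    "Annotation",
    "SimulatedEvidence",
    "simulate_annotation",
    "simulate_links",
    "simulate_signal_panels",
    "simulate_locus_features",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    ``bidirectional_rate`` is the target fraction of genes arranged in
    divergent promoter pairs (TSSs within ~4 kb), which is what makes
    interaction anchors ambiguous.  ``distance_log_mean``/``_sd`` are the
    natural-log parameters of the positive-pair distance distribution
    (default median 30 kb with a heavy right tail, matching the scale at
    which regulatory interactions concentrate).  ``coactivity`` in [0, 1]
    controls how strongly a true pair's element shares its gene's latent
    activity across the biosample panel; 0 plants no signal at all.
    """

    n_chromosomes: int = 3
    chrom_length: int = 1_200_000
    n_genes: int = 60
    n_elements: int = 40
    bidirectional_rate: float = 0.2
    lncrna_fraction: float = 0.15
    links_per_assay: int = 40
    distance_log_mean: float = math.log(30_000)
    distance_log_sd: float = 1.0
    panel_width: int = 32
    group_size: int = 2
    coactivity: float = 0.8
    noise: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if min(self.n_chromosomes, self.chrom_length, self.n_genes,
               self.n_elements, self.links_per_assay, self.panel_width,
               self.group_size) <= 0:
            raise ValueError("all counts must be positive")
        for name in ("bidirectional_rate", "lncrna_fraction", "coactivity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    gene_type: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Annotation:
    genes: list[Gene]
    tss: TssIndex
    elements: list[RegulatoryElement]
    gene_symbols: dict  # gene_id -> symbol

    def to_gtf(self) -> str:
        lines = []
        for g in self.genes:
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                f'gene_type "{g.gene_type}";'
            )
            lines.append(
                f"{g.chrom}\tsim\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
            )
        return "\n".join(lines) + "\n"

    def elements_bed(self) -> str:
        lines = [
            f"{el.chrom}\t{el.interval.start}\t{el.interval.end}\t{el.element_id}"
            for el in self.elements
        ]
        return "\n".join(lines) + "\n"


_MARGIN = 10_000
_MIN_SLOT_SPACING = 8_000


def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Toy annotation: genes (some in divergent pairs) plus distal elements.

    Raises ``ValueError`` when the requested gene count cannot be placed on
    the configured chromosomes at a spacing that keeps unrelated promoter
    windows from touching.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    # a fraction f of genes in divergent pairs needs slot-pairing prob f/(2-f)
    pair_prob = config.bidirectional_rate / (2.0 - config.bidirectional_rate)
    genes: list[Gene] = []
    gid = 0

    def next_gene(chrom: str, pos: int, strand: str) -> Gene:
        nonlocal gid
        gid += 1
        gene_type = (
            "lncRNA" if rng.random() < config.lncrna_fraction else "protein_coding"
        )
        length = int(rng.integers(2_000, 20_000))
        if strand == "+":
            start, end = pos, min(pos + length, config.chrom_length)
        else:
            start, end = max(pos + 1 - length, 0), pos + 1
        return Gene(
            gene_id=f"GENE{gid:04d}",
            gene_type=gene_type,
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
        )

    chroms = config.chromosomes
    n_slots_total = config.n_genes  # upper bound; pairs fill two at once
    slots_per_chrom = math.ceil(n_slots_total / len(chroms))
    span = config.chrom_length - 2 * _MARGIN
    spacing = span / slots_per_chrom
    if spacing < _MIN_SLOT_SPACING:
        raise ValueError(
            f"infeasible spacing: {config.n_genes} genes on "
            f"{len(chroms)} x {config.chrom_length} bp chromosomes"
        )
    for chrom in chroms:
        for i in range(slots_per_chrom):
            if len(genes) >= config.n_genes:
                break
            center = _MARGIN + (i + 0.5) * spacing
            jitter = rng.uniform(-0.1, 0.1) * spacing
            pos = int(center + jitter)
            if rng.random() < pair_prob and len(genes) <= config.n_genes - 2:
                gap = int(rng.integers(300, 3_800))
                genes.append(next_gene(chrom, pos, "+"))
                genes.append(next_gene(chrom, pos - gap, "-"))
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(next_gene(chrom, pos, strand))
    if len(genes) < config.n_genes:
        raise ValueError("infeasible spacing: not enough slots for requested genes")

    tss_positions = {
        chrom: np.array(sorted(g.tss for g in genes if g.chrom == chrom))
        for chrom in chroms
    }
    elements: list[RegulatoryElement] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    max_tries = 200 * config.n_elements
    tries = 0
    eid = 0
    while len(elements) < config.n_elements and tries < max_tries:
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(200, 351))
        start = int(rng.integers(_MARGIN // 2, config.chrom_length - _MARGIN // 2 - length))
        end = start + length
        pos = tss_positions[chrom]
        i = np.searchsorted(pos, start)
        neighbors = pos[max(i - 1, 0): i + 2]
        if any(interval_point_gap(start, end, int(p)) <= 2_000 for p in neighbors):
            continue
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        eid += 1
        occupied[chrom].append((start, end))
        elements.append(
            RegulatoryElement(
                element_id=f"E{eid:05d}",
                interval=GenomicInterval(chrom, start, end),
                biosamples=frozenset({"simB"}),
            )
        )
    if len(elements) < config.n_elements:
        raise ValueError("infeasible spacing: could not place all elements")
    elements.sort(key=lambda e: (e.chrom, e.interval.start))

    sites = [
        TranscriptionStartSite(
            gene_id=g.gene_id,
            gene_type=g.gene_type,
            chrom=g.chrom,
            pos=g.tss,
            strand=g.strand,
        )
        for g in genes
    ]
    symbols = {g.gene_id: f"SYM{g.gene_id[4:]}" for g in genes}
    return Annotation(
        genes=genes, tss=TssIndex(sites), elements=elements, gene_symbols=symbols
    )


@dataclass
class SimulatedEvidence:
    """Assay-dialect file contents plus the planted ground truth per assay."""

    chiapet: str
    hiccups: str
    chic: str
    eqtl_geuvadis: str
    eqtl_gtex: str
    crisprqtl: str
    truth: dict  # assay -> sorted list of (element_id, gene_id, ambiguous)

    def truth_pairs(self, assay: str) -> set:
        return {(e, g) for e, g, _ in self.truth[assay]}


def _gene_distances(annotation: Annotation, element: RegulatoryElement) -> list[tuple[str, int]]:
    iv = element.interval
    return [
        (g.gene_id, interval_point_gap(iv.start, iv.end, g.tss))
        for g in annotation.genes
        if g.chrom == iv.chrom
    ]


def _plant_pairs(annotation, config, rng, n, seen):
    """Choose (element, gene) pairs whose distances follow the configured law."""
    pairs = []
    tries = 0
    dist_cache: dict[str, list[tuple[str, int]]] = {}
    while len(pairs) < n and tries < 50 * n:
        tries += 1
        el = annotation.elements[int(rng.integers(len(annotation.elements)))]
        target = float(rng.lognormal(config.distance_log_mean, config.distance_log_sd))
        if el.element_id not in dist_cache:
            dist_cache[el.element_id] = _gene_distances(annotation, el)
        cands = dist_cache[el.element_id]
        if not cands:
            continue
        gene, dist = min(cands, key=lambda gd: (abs(gd[1] - target), gd[0]))
        if (el.element_id, gene) in seen:
            continue
        seen.add((el.element_id, gene))
        pairs.append((el, gene, dist))
    return pairs


def _tss_anchor(annotation: Annotation, gene_id: str, rng) -> GenomicInterval:
    gene = next(g for g in annotation.genes if g.gene_id == gene_id)
    half = int(rng.integers(100, 200))
    start = max(gene.tss - half, 0)
    return GenomicInterval(gene.chrom, start, gene.tss + half)


def _anchor_genes(annotation: Annotation, anchor: GenomicInterval, window: int = 2000):
    return sorted(
        {
            g.gene_id
            for g in annotation.genes
            if g.chrom == anchor.chrom
            and window_distance(anchor.start, anchor.end, g.tss) <= window
        }
    )


def _desert_anchor(annotation, config, rng) -> GenomicInterval:
    """An anchor with no TSS within the promoter window and no element overlap."""
    chroms = config.chromosomes
    for _ in range(1000):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(_MARGIN, config.chrom_length - _MARGIN))
        anchor = GenomicInterval(chrom, max(pos - 150, 0), pos + 150)
        if _anchor_genes(annotation, anchor, window=2_100):
            continue
        if any(
            el.chrom == chrom and el.interval.start < anchor.end and anchor.start < el.interval.end
            for el in annotation.elements
        ):
            continue
        return anchor
    raise ValueError("could not place a TSS-free anchor")


def _truth_from_links(link_events):
    """Aggregate (element, genes, ambiguous) anchor events into final truth."""
    support: dict[tuple[str, str], bool] = {}
    for eid, genes, ambiguous in link_events:
        for g in genes:
            support[(eid, g)] = support.get((eid, g), False) or not ambiguous
    return sorted((e, g, not unamb) for (e, g), unamb in support.items())


def simulate_links(annotation: Annotation, config: SimulationConfig) -> SimulatedEvidence:
    """Emit every assay dialect with planted, recoverable ground truth.

    Each assay receives its own planted pair set.  The 3D dialects also
    carry decoy records: sub-threshold ChIA-PET read counts, capture-Hi-C
    scores at or below the log-ratio cutoff, and loop anchors in TSS-free
    regions; none of these may survive curation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.links_per_assay
    seen: set = set()
    truth: dict[str, list] = {}

    def chrom_plain(chrom: str) -> str:
        return chrom[3:] if chrom.startswith("chr") else chrom

    # --- ChIA-PET ---------------------------------------------------------
    rows, events = [], []
    for el, gene, _ in _plant_pairs(annotation, config, rng, n, seen):
        anchor = _tss_anchor(annotation, gene, rng)
        genes = _anchor_genes(annotation, anchor)
        count = int(rng.integers(4, 13))
        a, b = el.interval, anchor
        if rng.random() < 0.5:
            a, b = b, a
        rows.append(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{count}")
        events.append((el.element_id, genes, len(genes) >= 2))
    for el, gene, _ in _plant_pairs(annotation, config, rng, max(n // 3, 1), seen):
        anchor = _tss_anchor(annotation, gene, rng)
        count = int(rng.integers(1, 4))  # below the read-count threshold
        rows.append(
            f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}"
            f"\t{anchor.chrom}\t{anchor.start}\t{anchor.end}\t{count}"
        )
    for _ in range(max(n // 4, 1)):
        el = annotation.elements[int(rng.integers(len(annotation.elements)))]
        anchor = _desert_anchor(annotation, config, rng)
        count = int(rng.integers(4, 13))
        rows.append(
            f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}"
            f"\t{anchor.chrom}\t{anchor.start}\t{anchor.end}\t{count}"
        )
    chiapet = "\n".join(rows) + "\n"
    truth["chiapet"] = _truth_from_links(events)

    # --- Hi-C loop list (no chr prefix, header, no filtering) -------------
    rows, events = ["chr1\tx1\tx2\tchr2\ty1\ty2\tobserved"], []
    for el, gene, _ in _plant_pairs(annotation, config, rng, n, seen):
        anchor = _tss_anchor(annotation, gene, rng)
        genes = _anchor_genes(annotation, anchor)
        a, b = el.interval, anchor
        if rng.random() < 0.5:
            a, b = b, a
        rows.append(
            f"{chrom_plain(a.chrom)}\t{a.start}\t{a.end}"
            f"\t{chrom_plain(b.chrom)}\t{b.start}\t{b.end}\t{int(rng.integers(5, 80))}"
        )
        events.append((el.element_id, genes, len(genes) >= 2))
    for _ in range(max(n // 4, 1)):
        el = annotation.elements[int(rng.integers(len(annotation.elements)))]
        anchor = _desert_anchor(annotation, config, rng)
        rows.append(
            f"{chrom_plain(el.interval.chrom)}\t{el.interval.start}\t{el.interval.end}"
            f"\t{chrom_plain(anchor.chrom)}\t{anchor.start}\t{anchor.end}"
            f"\t{int(rng.integers(5, 80))}"
        )
    hiccups = "\n".join(rows) + "\n"
    truth["hic"] = _truth_from_links(events)

    # --- capture Hi-C (header; score in column 11, strict > 10) -----------
    header = "\t".join(
        ["chrA", "startA", "endA", "chrB", "startB", "endB",
         "nReads", "expected", "baitA", "baitB", "logRatio"]
    )
    rows, events = [header], []
    for el, gene, _ in _plant_pairs(annotation, config, rng, n, seen):
        anchor = _tss_anchor(annotation, gene, rng)
        genes = _anchor_genes(annotation, anchor)
        score = float(rng.uniform(10.5, 40.0))
        a, b = el.interval, anchor
        if rng.random() < 0.5:
            a, b = b, a
        rows.append(
            f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
            f"\t10\t1.0\t.\t.\t{score:.3f}"
        )
        events.append((el.element_id, genes, len(genes) >= 2))
    for el, gene, _ in _plant_pairs(annotation, config, rng, max(n // 3, 1), seen):
        anchor = _tss_anchor(annotation, gene, rng)
        score = float(rng.uniform(2.0, 10.0))  # at or below the cutoff
        rows.append(
            f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}"
            f"\t{anchor.chrom}\t{anchor.start}\t{anchor.end}\t10\t1.0\t.\t.\t{score:.3f}"
        )
    chic = "\n".join(rows) + "\n"
    truth["chic"] = _truth_from_links(events)

    # --- eQTL dialects -----------------------------------------------------
    rows = ["CHROM\tPOS\tSNP_ID\tGENE_ID"]
    pairs = []
    for i, (el, gene, _) in enumerate(_plant_pairs(annotation, config, rng, n, seen)):
        pos = int(rng.integers(el.interval.start, el.interval.end))
        version = int(rng.integers(1, 10))
        rows.append(f"{el.interval.chrom}\t{pos + 1}\trs{900000 + i}\t{gene}.{version}")
        pairs.append((el.element_id, gene, False))
    eqtl_geuvadis = "\n".join(rows) + "\n"
    truth["eqtl_geuvadis"] = sorted(set(pairs))

    rows = ["variant_id\tgene_id\ttss_distance\tpval_nominal"]
    pairs = []
    for el, gene, _ in _plant_pairs(annotation, config, rng, n, seen):
        pos = int(rng.integers(el.interval.start, el.interval.end))
        version = int(rng.integers(1, 10))
        variant = f"{chrom_plain(el.interval.chrom)}_{pos + 1}_A_G_b37"
        rows.append(f"{variant}\t{gene}.{version}\t0\t{rng.uniform(1e-12, 1e-5):.3e}")
        pairs.append((el.element_id, gene, False))
    eqtl_gtex = "\n".join(rows) + "\n"
    truth["eqtl_gtex"] = sorted(set(pairs))

    # --- CRISPR perturbations ----------------------------------------------
    rows = ["chrom\tstart\tend\tgene"]
    pairs = []
    for el, gene, _ in _plant_pairs(annotation, config, rng, n, seen):
        symbol = annotation.gene_symbols[gene]
        rows.append(
            f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}\t{symbol}"
        )
        pairs.append((el.element_id, gene, False))
    el = annotation.elements[0]
    rows.append(
        f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}\tUNMAPPED_SYMBOL"
    )
    crisprqtl = "\n".join(rows) + "\n"
    truth["crisprqtl"] = sorted(set(pairs))

    return SimulatedEvidence(
        chiapet=chiapet,
        hiccups=hiccups,
        chic=chic,
        eqtl_geuvadis=eqtl_geuvadis,
        eqtl_gtex=eqtl_gtex,
        crisprqtl=crisprqtl,
        truth=truth,
    )


def simulate_signal_panels(
    annotation: Annotation,
    truth_pairs: Sequence[tuple],
    config: SimulationConfig,
):
    """Element and expression panels with planted co-activity.

    Every gene carries a latent activity vector across the biosample panel.
    Gene expression rows are broadly active (high baseline) and track the
    latent factor; element rows are sparsely active, and for elements in a
    true pair the log-signal mixes the target gene's latent factor with the
    element's own at weight ``config.coactivity``.  Column-wise Gaussian
    noise is added on the log scale.  Returns ``(element_signals,
    expression)`` as :class:`~egbench.predictors.SignalMatrix` objects
    sharing the column panel; the element matrix carries the cell-type
    column grouping.
    """
    from .predictors import SignalMatrix

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    W = config.panel_width
    cols = [f"BS{i:03d}" for i in range(W)]
    groups = {c: f"grp{i // config.group_size}" for i, c in enumerate(cols)}
    gene_ids = [g.gene_id for g in annotation.genes]
    latent = {g: rng.normal(0.0, 1.0, W) for g in gene_ids}
    expr_rows = {}
    for g in gene_ids:
        log_e = 1.5 + 0.6 * latent[g] + config.noise * rng.normal(0.0, 1.0, W)
        expr_rows[g] = np.maximum(np.exp(log_e), 0.0)
    target_of: dict[str, str] = {}
    for eid, gid, *_ in truth_pairs:
        target_of.setdefault(eid, gid)
    c = config.coactivity
    elem_rows = {}
    for el in annotation.elements:
        own = rng.normal(0.0, 1.0, W)
        base = rng.normal(-0.5, 0.3)
        shared = latent.get(target_of.get(el.element_id), None)
        factor = own if shared is None else c * shared + math.sqrt(1 - c * c) * own
        log_s = base + factor + config.noise * rng.normal(0.0, 1.0, W)
        elem_rows[el.element_id] = np.maximum(np.exp(log_s), 0.0)
    element_signals = SignalMatrix(
        pd.DataFrame.from_dict(elem_rows, orient="index", columns=cols).sort_index(),
        column_groups=groups,
    )
    expression = SignalMatrix(
        pd.DataFrame.from_dict(expr_rows, orient="index", columns=cols).sort_index()
    )
    return element_signals, expression


def simulate_locus_features(
    n_chromosomes: int = 23,
    loci_per_chrom: int = 4,
    pairs_per_locus: int = 12,
    n_features: int = 6,
    rate_low: float = 0.1,
    rate_high: float = 0.6,
    seed: int = 0,
):
    """Pairs whose features are shared within a locus but carry no
    generalizable label signal.

    Every locus has a latent feature vector (plus small per-pair noise) and
    a positive rate drawn from {rate_low, rate_high}; labels are Bernoulli
    at the locus rate.  A model can learn locus -> rate only by seeing the
    locus during training, so randomized cross-validation (which splits
    loci across folds) inflates performance relative to chromosome-held-out
    folds.  Returns (features DataFrame, labels, chromosome labels).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows, labels, chroms = [], [], []
    for ci in range(n_chromosomes):
        chrom = f"chr{ci + 1}"
        for _ in range(loci_per_chrom):
            center = rng.normal(0.0, 1.0, n_features)
            rate = rate_high if rng.random() < 0.5 else rate_low
            for _ in range(pairs_per_locus):
                rows.append(center + rng.normal(0.0, 0.1, n_features))
                labels.append(int(rng.random() < rate))
                chroms.append(chrom)
    features = pd.DataFrame(rows, columns=[f"f{i}" for i in range(n_features)])
    return features, np.array(labels), chroms
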