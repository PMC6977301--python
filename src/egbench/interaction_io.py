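"""Readers for the heterogeneous interaction-evidence dialects.

Five kinds of evidence feed the benchmark: ChIA-PET clusters, Hi-C loop
lists (HiCCUPS output), promoter capture Hi-C interaction tables, cis-eQTL
variant-gene tables, and CRISPR-perturbation region-gene tables.  Each
reader normalizes its dialect into one of three record shapes
(:class:`ChromatinLink`, :class:`VariantGeneAssociation`,
:class:`PerturbationLink`) and applies the evidence-specific support filter
at parse time (read-count >= 4 for ChIA-PET, log(obs/exp) > 10 for capture
Hi-C, no filtering for HiCCUPS loops).

Trans-chromosomal links are dropped (the benchmark is strictly cis; the
element-gene distance would otherwise be undefined) and the drop count is
reported on the returned list.  Chromosome names are normalized to the
``chr``-prefixed convention at parse time because the source files mix
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .annotations import GenomicInterval

__all__ = [
    "ChromatinLink",
    "VariantGeneAssociation",
    "PerturbationLink",
    "ParseResult",
    "LinkParseError",
    "EqtlDialect",
    "EQTL_DIALECTS",
    "read_chiapet",
    "read_hiccups",
    "read_chic",
    "read_eqtl",
    "read_crisprqtl",
    "write_links_tsv",
    "strip_gene_version",
    "normalize_chrom",
]


class LinkParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


@dataclass(frozen=True, order=True)
class ChromatinLink:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    support: float
    assay: str

    def __post_init__(self):
        if self.support < 0:
            raise ValueError("negative support")


@dataclass(frozen=True, order=True)
class VariantGeneAssociation:
    chrom: str
    pos: int
    gene_id: str

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError("negative variant position")


@dataclass(frozen=True, order=True)
class PerturbationLink:
    region: GenomicInterval
    gene_id: str


class ParseResult(list):
    """A list of parsed records with bookkeeping counters attached.

    ``n_skipped`` counts malformed or unmappable records that were skipped
    with a warning; ``n_dropped_trans`` counts trans-chromosomal links.
    """

    def __init__(self, records=(), n_skipped: int = 0, n_dropped_trans: int = 0):
        super().__init__(records)
        self.n_skipped = n_skipped
        self.n_dropped_trans = n_dropped_trans


def normalize_chrom(name: str, use_chr_prefix: bool = True) -> str:
    if use_chr_prefix:
        return name if name.startswith("chr") else f"chr{name}"
    return name[3:] if name.startswith("chr") else name


def strip_gene_version(gene_id: str) -> str:
    """``ENSG00000123.4`` -> ``ENSG00000123``."""
    base, dot, suffix = gene_id.rpartition(".")
    if dot and suffix.isdigit():
        return base
    return gene_id


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def _anchor(cols, lineno, offset, use_chr_prefix) -> GenomicInterval:
    try:
        start = int(cols[offset + 1])
        end = int(cols[offset + 2])
    except (ValueError, IndexError):
        raise LinkParseError(lineno, "bad anchor coordinates") from None
    chrom = normalize_chrom(cols[offset], use_chr_prefix)
    if end <= start:
        raise LinkParseError(lineno, f"anchor end <= start: {start}..{end}")
    return GenomicInterval(chrom, start, end)


def read_chiapet(source, min_reads: int = 4, use_chr_prefix: bool = True) -> ParseResult:
    """Read ChIA-PET cluster TSV: anchors in columns 1-6, read count in 7.

    Only clusters supported by at least ``min_reads`` reads are retained.
    """
    links, dropped = [], 0
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 7:
            raise LinkParseError(lineno, f"expected >=7 columns, got {len(cols)}")
        try:
            count = float(cols[6])
        except ValueError:
            raise LinkParseError(lineno, f"non-numeric read count {cols[6]!r}") from None
        if count < min_reads:
            continue
        a1 = _anchor(cols, lineno, 0, use_chr_prefix)
        a2 = _anchor(cols, lineno, 3, use_chr_prefix)
        if a1.chrom != a2.chrom:
            dropped += 1
            continue
        links.append(ChromatinLink(a1, a2, support=count, assay="chiapet"))
    return ParseResult(links, n_dropped_trans=dropped)


def read_hiccups(source, use_chr_prefix: bool = True) -> ParseResult:
    """Read a HiCCUPS loop list (header line, anchors in the first six columns).

    No score filtering is applied; every well-formed data row becomes a link
    with support 1.
    """
    links, dropped = [], 0
    lines = _iter_lines(source)
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1:  # header
            continue
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 6:
            raise LinkParseError(lineno, f"expected >=6 columns, got {len(cols)}")
        a1 = _anchor(cols, lineno, 0, use_chr_prefix)
        a2 = _anchor(cols, lineno, 3, use_chr_prefix)
        if a1.chrom != a2.chrom:
            dropped += 1
            continue
        links.append(ChromatinLink(a1, a2, support=1.0, assay="hic"))
    return ParseResult(links, n_dropped_trans=dropped)


def read_chic(source, min_log_ratio: float = 10.0, use_chr_prefix: bool = True) -> ParseResult:
    """Read a capture Hi-C interaction table.

    Anchors sit in columns 1-6 and the log(observed/expected) score in
    column 11; records are retained when the score is strictly greater than
    ``min_log_ratio``.
    """
    links, dropped = [], 0
    lines = _iter_lines(source)
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1:  # header
            continue
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 11:
            raise LinkParseError(lineno, f"expected >=11 columns, got {len(cols)}")
        try:
            score = float(cols[10])
        except ValueError:
            raise LinkParseError(lineno, f"non-numeric score {cols[10]!r}") from None
        if not score > min_log_ratio:
            continue
        a1 = _anchor(cols, lineno, 0, use_chr_prefix)
        a2 = _anchor(cols, lineno, 3, use_chr_prefix)
        if a1.chrom != a2.chrom:
            dropped += 1
            continue
        links.append(ChromatinLink(a1, a2, support=score, assay="chic"))
    return ParseResult(links, n_dropped_trans=dropped)


@dataclass(frozen=True)
class EqtlDialect:
    """Column layout of an eQTL export.

    ``variant_col`` may address a composite variant id of the form
    ``chrom_pos_ref_alt_build`` (set ``composite_variant=True``) or the
    dialect may carry explicit ``chrom_col``/``pos_col``.  Exported
    positions are 1-based; they are converted to 0-based points on read.
    """

    name: str
    has_header: bool
    gene_col: int
    chrom_col: int | None = None
    pos_col: int | None = None
    variant_col: int | None = None
    composite_variant: bool = False


EQTL_DIALECTS: dict[str, EqtlDialect] = {
    # chrom / 1-based position / variant id / gene id columns
    "geuvadis": EqtlDialect(
        name="geuvadis", has_header=True, chrom_col=0, pos_col=1, gene_col=3
    ),
    # composite variant id "1_13550_G_A_b37" + versioned gene id
    "gtex": EqtlDialect(
        name="gtex", has_header=True, variant_col=0, gene_col=1, composite_variant=True
    ),
}


def read_eqtl(source, dialect: str | EqtlDialect = "geuvadis", use_chr_prefix: bool = True) -> ParseResult:
    """Read variant-gene associations from an eQTL export.

    Gene identifiers are normalized by stripping trailing version suffixes
    and duplicated (variant, gene) rows are collapsed.  Rows whose variant
    coordinate cannot be mapped are skipped and counted in ``n_skipped``.
    """
    spec = EQTL_DIALECTS[dialect] if isinstance(dialect, str) else dialect
    seen: set[VariantGeneAssociation] = set()
    records: list[VariantGeneAssociation] = []
    skipped = 0
    lines = _iter_lines(source)
    for lineno, line in enumerate(lines, start=1):
        if spec.has_header and lineno == 1:
            continue
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        try:
            gene = strip_gene_version(cols[spec.gene_col])
            if spec.composite_variant:
                parts = cols[spec.variant_col].split("_")
                chrom, pos1 = parts[0], int(parts[1])
            else:
                chrom, pos1 = cols[spec.chrom_col], int(cols[spec.pos_col])
        except (ValueError, IndexError):
            skipped += 1
            continue
        if pos1 < 1:
            skipped += 1
            continue
        assoc = VariantGeneAssociation(
            chrom=normalize_chrom(chrom, use_chr_prefix), pos=pos1 - 1, gene_id=gene
        )
        if assoc not in seen:
            seen.add(assoc)
            records.append(assoc)
    return ParseResult(records, n_skipped=skipped)


def read_crisprqtl(
    source,
    gene_names_to_ids: Mapping[str, str],
    use_chr_prefix: bool = True,
) -> ParseResult:
    """Read perturbation region-gene rows (header; chrom, start, end, gene symbol).

    Symbols are mapped to annotation gene ids through ``gene_names_to_ids``;
    rows with unmapped symbols are counted in ``n_skipped``.
    """
    records: list[PerturbationLink] = []
    skipped = 0
    lines = _iter_lines(source)
    for lineno, line in enumerate(lines, start=1):
        if lineno == 1:
            continue
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 4:
            raise LinkParseError(lineno, f"expected >=4 columns, got {len(cols)}")
        symbol = cols[3]
        gene_id = gene_names_to_ids.get(symbol)
        if gene_id is None:
            skipped += 1
            continue
        try:
            region = GenomicInterval(
                normalize_chrom(cols[0], use_chr_prefix), int(cols[1]), int(cols[2])
            )
        except ValueError as exc:
            raise LinkParseError(lineno, str(exc)) from None
        link = PerturbationLink(region=region, gene_id=gene_id)
        if link not in records:
            records.append(link)
    return ParseResult(records, n_skipped=skipped)


def write_links_tsv(links: Iterable[ChromatinLink], stream) -> None:
    """Normalized link TSV: chromA startA endA chromB startB endB support assay."""
    for ln in links:
        a, b = ln.anchor1, ln.anchor2
        stream.write(
            f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}"
            f"\t{ln.support:g}\t{ln.assay}\n"
        )
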