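"""Gene annotations, candidate regulatory elements, and TSS distance queries.

Coordinates are 0-based half-open throughout (BED convention).  GTF input,
which is 1-based inclusive, is converted on read.  The transcription start
site (TSS) of a transcript is its 5' end: the first base for plus-strand
transcripts and the last base for minus-strand transcripts.

Distances between a point and an interval are counted as the number of
intervening bases (the bedtools convention): a TSS inside or immediately
adjacent to an interval is at distance 0, and a TSS at position 1700 is
500 bp from the interval [1000, 1200).  This definition is symmetric under
reflection of the chromosome.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "TranscriptionStartSite",
    "RegulatoryElement",
    "TssIndex",
    "GtfParseError",
    "load_tss",
    "read_elements_bed",
    "select_distal_elements",
    "nearest_tss_distance",
    "write_tss_bed",
    "interval_point_gap",
    "window_distance",
]


class GtfParseError(ValueError):
    """A malformed annotation record; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class TranscriptionStartSite:
    gene_id: str
    gene_type: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative TSS position: {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")


@dataclass(frozen=True)
class RegulatoryElement:
    element_id: str
    interval: GenomicInterval
    biosamples: frozenset = field(default_factory=frozenset)

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def interval_point_gap(start: int, end: int, pos: int) -> int:
    """Number of bases strictly between the point ``pos`` and ``[start, end)``."""
    if start <= pos < end:
        return 0
    if pos < start:
        return start - 1 - pos
    return pos - end


def window_distance(start: int, end: int, pos: int) -> int:
    """Distance from ``pos`` to the nearest base of ``[start, end)``.

    Used for the promoter-window test ("within +/- 2 kb of a TSS"): the
    distance is |pos - nearest interval base|, 0 if the point lies inside.
    """
    if start <= pos < end:
        return 0
    if pos < start:
        return start - pos
    return pos - (end - 1)


class TssIndex:
    """Per-chromosome searchable collection of TSSs.

    Identical (gene_id, chrom, pos, strand) records are collapsed, since
    annotation transcripts of a gene frequently share a start.
    """

    def __init__(self, sites: Iterable[TranscriptionStartSite]):
        uniq = sorted(set(sites))
        self._sites: list[TranscriptionStartSite] = uniq
        self._by_chrom: dict[str, tuple[np.ndarray, list[TranscriptionStartSite]]] = {}
        by_chrom: dict[str, list[TranscriptionStartSite]] = {}
        for s in uniq:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, group in by_chrom.items():
            group.sort(key=lambda s: (s.pos, s.gene_id, s.strand))
            self._by_chrom[chrom] = (
                np.array([s.pos for s in group], dtype=np.int64),
                group,
            )
        self._by_gene: dict[str, list[TranscriptionStartSite]] = {}
        for s in uniq:
            self._by_gene.setdefault(s.gene_id, []).append(s)

    def __len__(self) -> int:
        return len(self._sites)

    def __iter__(self) -> Iterator[TranscriptionStartSite]:
        return iter(self._sites)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._by_chrom)

    def genes(self) -> set[str]:
        return set(self._by_gene)

    def gene_sites(self, gene_id: str) -> list[TranscriptionStartSite]:
        return list(self._by_gene.get(gene_id, ()))

    def sites_in_range(self, chrom: str, lo: int, hi: int) -> list[TranscriptionStartSite]:
        """All sites with ``lo <= pos <= hi`` on ``chrom``."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        pos, sites = entry
        i = int(np.searchsorted(pos, lo, side="left"))
        j = int(np.searchsorted(pos, hi, side="right"))
        return sites[i:j]

    def sites_within_window(
        self, interval: GenomicInterval, window: int
    ) -> list[TranscriptionStartSite]:
        """Sites whose window distance to ``interval`` is <= ``window``."""
        cands = self.sites_in_range(
            interval.chrom, interval.start - window, interval.end - 1 + window
        )
        return [
            s
            for s in cands
            if window_distance(interval.start, interval.end, s.pos) <= window
        ]

    def nearest_site(
        self, interval: GenomicInterval, gene_id: str | None = None
    ) -> tuple[TranscriptionStartSite, int]:
        """Nearest TSS to ``interval`` and its gap distance.

        With ``gene_id``, the minimum is over that gene's sites only.  Ties
        are broken by lexicographic (gene_id, pos).  Raises ``LookupError``
        when no eligible site exists on the interval's chromosome.
        """
        if gene_id is not None:
            sites = [
                s for s in self._by_gene.get(gene_id, ()) if s.chrom == interval.chrom
            ]
            if not sites:
                raise LookupError(
                    f"no TSS for gene {gene_id!r} on {interval.chrom}"
                )
            best = None
            for s in sites:
                d = interval_point_gap(interval.start, interval.end, s.pos)
                key = (d, s.gene_id, s.pos)
                if best is None or key < best[0]:
                    best = (key, s)
            return best[1], best[0][0]

        entry = self._by_chrom.get(interval.chrom)
        if entry is None:
            raise LookupError(f"no TSS on chromosome {interval.chrom}")
        pos, sites = entry
        i = int(np.searchsorted(pos, interval.start, side="left"))
        j = int(np.searchsorted(pos, interval.end, side="left"))
        candidates: list[TranscriptionStartSite] = sites[i:j]  # inside -> gap 0
        if i > 0:
            candidates = candidates + [sites[i - 1]]
        if j < len(sites):
            candidates = candidates + [sites[j]]
        best = None
        for s in candidates:
            d = interval_point_gap(interval.start, interval.end, s.pos)
            key = (d, s.gene_id, s.pos)
            if best is None or key < best[0]:
                best = (key, s)
        return best[1], best[0][0]


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


_GTF_ATTR_QUOTED = ('"', "'")


def parse_gtf_attributes(raw: str) -> dict[str, str]:
    """Parse GTF attribute strings in either ``key "value";`` or ``key=value`` form."""
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk and '"' not in chunk:
            key, _, value = chunk.partition("=")
        else:
            key, _, value = chunk.partition(" ")
        key = key.strip()
        value = value.strip()
        if value and value[0] in _GTF_ATTR_QUOTED and value[-1] == value[0]:
            value = value[1:-1]
        if key:
            attrs[key] = value
    return attrs


def load_tss(
    source,
    protein_coding_only: bool = False,
    exclude_gene_ids: Iterable[str] = (),
) -> TssIndex:
    """Build a :class:`TssIndex` from a GTF stream or path.

    One TSS per transcript record: plus strand maps to the transcript start,
    minus strand to the last transcribed base.  With ``protein_coding_only``
    set, only transcripts of genes with gene_type ``protein_coding`` are
    kept.  ``exclude_gene_ids`` removes specific genes (e.g., problematic
    annotations) without further interpretation.
    """
    excluded = set(exclude_gene_ids)
    sites: list[TranscriptionStartSite] = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 9:
            raise GtfParseError(lineno, f"expected 9 columns, got {len(cols)}")
        if cols[2] != "transcript":
            continue
        try:
            start0 = int(cols[3]) - 1
            end0 = int(cols[4])
        except ValueError as exc:
            raise GtfParseError(lineno, f"bad coordinates: {exc}") from None
        strand = cols[6]
        if strand not in ("+", "-"):
            raise GtfParseError(lineno, f"missing or bad strand {strand!r}")
        attrs = parse_gtf_attributes(cols[8])
        gene_id = attrs.get("gene_id")
        if not gene_id:
            raise GtfParseError(lineno, "missing gene_id attribute")
        gene_type = attrs.get("gene_type") or attrs.get("gene_biotype") or ""
        if protein_coding_only and gene_type != "protein_coding":
            continue
        if gene_id in excluded:
            continue
        pos = start0 if strand == "+" else end0 - 1
        sites.append(
            TranscriptionStartSite(
                gene_id=gene_id,
                gene_type=gene_type,
                chrom=cols[0],
                pos=pos,
                strand=strand,
            )
        )
    return TssIndex(sites)


def read_elements_bed(source, biosample: str | None = None) -> list[RegulatoryElement]:
    """Read candidate elements from BED4+ (chrom, start, end, element_id).

    Extra columns are ignored.  ``biosample``, when given, is recorded as the
    biosample in which every element in the file is active.
    """
    biosamples = frozenset([biosample]) if biosample else frozenset()
    elements: list[RegulatoryElement] = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 4:
            raise GtfParseError(lineno, f"expected >=4 BED columns, got {len(cols)}")
        try:
            interval = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
        except ValueError as exc:
            raise GtfParseError(lineno, str(exc)) from None
        elements.append(
            RegulatoryElement(element_id=cols[3], interval=interval, biosamples=biosamples)
        )
    return elements


def nearest_tss_distance(
    interval: GenomicInterval,
    tss: TssIndex,
    gene_restriction: str | None = None,
) -> tuple[str, int]:
    """Gene and gap distance of the TSS nearest to ``interval``.

    Distance is 0 when a TSS lies within the interval, otherwise the number
    of intervening bases to the nearest interval edge.  With
    ``gene_restriction`` the minimum is over that gene's TSSs only.
    """
    site, dist = tss.nearest_site(interval, gene_id=gene_restriction)
    return site.gene_id, dist


def select_distal_elements(
    elements: Sequence[RegulatoryElement],
    tss: TssIndex,
    min_distance: int = 2000,
) -> list[RegulatoryElement]:
    """Retain elements strictly farther than ``min_distance`` from every TSS.

    Elements on chromosomes without any TSS are retained (no TSS can make
    them proximal), but an entirely empty index is an error since distality
    is then undefined.
    """
    if len(tss) == 0:
        raise ValueError("cannot assess distality against an empty TSS index")
    kept = []
    for el in elements:
        try:
            _, dist = tss.nearest_site(el.interval)
        except LookupError:
            kept.append(el)
            continue
        if dist > min_distance:
            kept.append(el)
    return kept


def write_tss_bed(tss: TssIndex, stream=sys.stdout) -> None:
    """Export TSSs as BED6 (name = gene_id, score = 0)."""
    for s in sorted(tss, key=lambda s: (s.chrom, s.pos, s.gene_id)):
        stream.write(
            f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.gene_id}\t0\t{s.strand}\n"
        )
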