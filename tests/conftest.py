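import io

import pytest

from egbench.annotations import (
    GenomicInterval,
    RegulatoryElement,
    TranscriptionStartSite,
    TssIndex,
)
from egbench.simulate import SimulationConfig, simulate_annotation, simulate_links

TOY_GTF = """\
chr1\ttoy\ttranscript\t101\t500\t.\t+\t.\tgene_id "GA"; transcript_id "GA.t1"; gene_type "protein_coding";
chr1\ttoy\ttranscript\t101\t500\t.\t-\t.\tgene_id "GB"; transcript_id "GB.t1"; gene_type "protein_coding";
chr1\ttoy\ttranscript\t9001\t12000\t.\t+\t.\tgene_id "GC"; transcript_id "GC.t1"; gene_type "lncRNA";
"""


@pytest.fixture
def toy_gtf():
    return io.StringIO(TOY_GTF)


def make_tss(*specs):
    """specs: (gene_id, chrom, pos[, strand[, gene_type]])"""
    sites = []
    for spec in specs:
        gene, chrom, pos = spec[:3]
        strand = spec[3] if len(spec) > 3 else "+"
        gene_type = spec[4] if len(spec) > 4 else "protein_coding"
        sites.append(
            TranscriptionStartSite(
                gene_id=gene, gene_type=gene_type, chrom=chrom, pos=pos, strand=strand
            )
        )
    return TssIndex(sites)


def make_element(eid, chrom, start, end):
    return RegulatoryElement(eid, GenomicInterval(chrom, start, end))


@pytest.fixture
def small_config():
    return SimulationConfig(seed=7, bidirectional_rate=0.3)


@pytest.fixture
def annotation(small_config):
    return simulate_annotation(small_config)


@pytest.fixture
def evidence(annotation, small_config):
    return simulate_links(annotation, small_config)
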