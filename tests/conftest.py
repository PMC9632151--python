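import numpy as np
import pandas as pd
import pytest

from hervkit.core_io import GeneModel, GenomicInterval, HERVElement
from hervkit.detection import HervLocus
from hervkit.simulate import SimConfig, simulate_annotation, simulate_transcripts


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def annotation(sim_cfg):
    """(elements, genes, truth) for the standard planted fixture."""
    return simulate_annotation(sim_cfg)


@pytest.fixture(scope="session")
def per_sample_alignments(sim_cfg, annotation):
    _, _, truth = annotation
    return simulate_transcripts(sim_cfg, truth)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_locus(locus_id, chrom, start, end, strand="+", samples=("S1",)):
    return HervLocus(
        locus_id=locus_id,
        exons=(GenomicInterval(chrom, start, end, strand),),
        strand=strand,
        supporting_samples=frozenset(samples),
    )


def make_gene(gene_id, chrom, start, end, strand, exons=None):
    if exons is None:
        exons = ((start, end),)
    chains = (tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),)
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, end, strand),
        strand=strand,
        transcripts=chains,
    )


def make_element(element_id, chrom, start, end, family="LTR12C", component="LTR", provirus_id=None):
    return HERVElement(
        element_id=element_id,
        interval=GenomicInterval(chrom, start, end, "+"),
        family=family,
        component=component,
        provirus_id=provirus_id,
    )


@pytest.fixture
def helpers():
    class H:
        locus = staticmethod(make_locus)
        gene = staticmethod(make_gene)
        element = staticmethod(make_element)

    return H
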