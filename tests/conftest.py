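import numpy as np
import pytest

from regulomekit import synth
from regulomekit.genome import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    Peak,
    PeakSet,
)


@pytest.fixture(scope="session")
def toy_layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 80_000, "chr3": 60_000, "chr4": 40_000})


@pytest.fixture(scope="session")
def small_genome():
    """Deterministic synthetic genome shared by recovery tests."""
    layout, genes, truth = synth.gen_genome(
        {"chr1": 4_000_000, "chr2": 4_000_000},
        {"protein_coding": 400, "lincRNA": 50, "snRNA": 30, "snoRNA": 20, "miRNA": 10},
        seed=7,
    )
    return layout, genes, truth


def make_peak(chrom, start, end, summit_pos=None, score=1.0):
    iv = GenomicInterval(chrom, start, end)
    summit = (start + end) // 2 - start if summit_pos is None else summit_pos - start
    return Peak(iv, summit, score)


def make_gene(gene_id, chrom, start, end, strand="+", gene_class="protein_coding",
              exons=None):
    iv = GenomicInterval(chrom, start, end, strand)
    if exons is None:
        exon_ivs = (iv,)
    else:
        exon_ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    return GeneModel(gene_id, iv, exon_ivs, gene_class)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
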