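import numpy as np
import pytest

from phoscycle.models import GeneFeature, GenomeRecord


def make_genome(genes, contig_len=50_000, genome_id="G1", clade="test",
                n_contigs=None, completeness=1.0):
    """Small single/multi-contig genome around a provided gene list."""
    contig_ids = {g.contig_id for g in genes} or {"c0"}
    contigs = [(cid, contig_len) for cid in sorted(contig_ids)]
    return GenomeRecord(
        genome_id=genome_id,
        clade=clade,
        contigs=contigs,
        genes=list(genes),
        completeness=completeness,
    )


@pytest.fixture
def pepm_protein():
    return "MA" + "EDKQWRTY" + "NS" + "LLGGHH"  # EDK(X)5NS with X5=QWRTY


@pytest.fixture
def producer_genome(pepm_protein):
    genes = [
        GeneFeature("g_pepm", "c0", 1_000, 2_000, "+", "pepM", pepm_protein),
        GeneFeature("g_ppd", "c0", 2_100, 3_000, "+", "ppd", "MKKLL"),
        GeneFeature("g_other", "c0", 30_000, 31_000, "+", "other", ""),
    ]
    return make_genome(genes, genome_id="Gprod")


def rng(seed=0):
    return np.random.default_rng(seed)
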