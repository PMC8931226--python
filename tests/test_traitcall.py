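"""Trait calling: motif validation, producer/consumer verdicts,
colocalization windows and hypergeometric enrichment."""

import math

import pytest

from phoscycle.models import GeneFeature, HitRecord
from phoscycle.traitcall import (
    PathwayRule,
    call_consumer,
    call_producer,
    colocalize,
    default_pathway_rules,
    enrichment_test,
    summarize_calls,
    validate_pepm_motif,
)
from phoscycle.models import TraitCall

from conftest import make_genome


@pytest.mark.parametrize(
    "protein,expected",
    [
        ("MAEDKQWRTYNSLL", True),   # E-D-K-QWRTY-N-S
        ("MAEDKQWRTNSLL", False),   # only 4 spacer residues
        ("MAKDENSAAAA", False),     # no motif at all
        ("EDKABCDENS", True),       # motif at position 0 (B allowed as IUPAC)
        ("XXXEDKAAAAANSEDK", True),
    ],
)
def test_pepm_motif(protein, expected):
    assert validate_pepm_motif(protein) is expected


def test_pepm_motif_rejects_bad_input():
    with pytest.raises(ValueError):
        validate_pepm_motif("")
    with pytest.raises(ValueError):
        validate_pepm_motif("MAE1DK")


class TestCallProducer:
    def test_valid_pepm_without_downstream_genes_is_producer(self, pepm_protein):
        """pepM alone suffices; ppd/pdh/mpnS are not required."""
        genome = make_genome(
            [GeneFeature("g1", "c0", 1_000, 2_000, "+", "pepM", pepm_protein)]
        )
        hits = [HitRecord("g1", "pepM", 80.0, True)]
        call = call_producer(genome, hits)
        assert call.is_producer
        assert call.adjacent_biosynthesis == set()
        assert call.operon_length_bp == 1_000

    def test_motif_less_pepm_hit_is_rejected(self):
        """An above-cutoff homology hit is not enough without the
        catalytic signature."""
        genome = make_genome(
            [GeneFeature("g1", "c0", 1_000, 2_000, "+", "pepM", "MMMMAAAACCCC")]
        )
        call = call_producer(genome, [HitRecord("g1", "pepM", 120.0, True)])
        assert not call.is_producer
        assert call.operon_length_bp == 0
        assert ("g1", False) in call.pepm_genes

    def test_below_cutoff_hit_ignored(self, pepm_protein):
        genome = make_genome(
            [GeneFeature("g1", "c0", 1_000, 2_000, "+", "pepM", pepm_protein)]
        )
        call = call_producer(genome, [HitRecord("g1", "pepM", 3.0, False)])
        assert not call.is_producer

    def test_empty_genome(self):
        genome = make_genome([])
        call = call_producer(genome, [])
        assert not call.is_producer and call.operon_length_bp == 0

    def test_adjacent_biosynthesis_recorded_and_span(self, producer_genome):
        hits = [
            HitRecord("g_pepm", "pepM", 90.0, True),
            HitRecord("g_ppd", "ppd", 50.0, True),
        ]
        call = call_producer(producer_genome, hits)
        assert call.is_producer
        assert call.adjacent_biosynthesis == {"ppd"}
        # span min(start) to max(end) over the cassette, gaps included
        assert call.operon_length_bp == 3_000 - 1_000

    def test_distant_ppd_not_recorded(self, pepm_protein):
        """ppd beyond both the bp window and the gene-rank window is
        not part of the cassette."""
        fillers = [
            GeneFeature(f"f{i}", "c0", 5_000 + 2_000 * i, 6_000 + 2_000 * i,
                        "+", "other", "")
            for i in range(8)
        ]
        genes = fillers + [
            GeneFeature("g1", "c0", 1_000, 2_000, "+", "pepM", pepm_protein),
            GeneFeature("g2", "c0", 40_000, 41_000, "+", "ppd", "MK"),
        ]
        genome = make_genome(genes)
        call = call_producer(
            genome,
            [HitRecord("g1", "pepM", 90.0, True), HitRecord("g2", "ppd", 50.0, True)],
        )
        assert call.is_producer
        assert call.adjacent_biosynthesis == set()

    def test_cross_contig_cassette_flagged_not_verdict_changing(self, pepm_protein):
        genes = [
            GeneFeature("g1", "c0", 1_000, 2_000, "+", "pepM", pepm_protein),
            GeneFeature("g2", "c1", 5_000, 6_000, "+", "pdh", "MK"),
        ]
        genome = make_genome(genes)
        call = call_producer(genome, [HitRecord("g1", "pepM", 90.0, True)])
        assert call.is_producer and call.cross_contig_cassette

    def test_gene_order_permutation_invariance(self, producer_genome):
        hits = [
            HitRecord("g_pepm", "pepM", 90.0, True),
            HitRecord("g_ppd", "ppd", 50.0, True),
        ]
        call1 = call_producer(producer_genome, hits)
        shuffled = make_genome(
            list(reversed(producer_genome.genes)), genome_id="Gprod"
        )
        call2 = call_producer(shuffled, list(reversed(hits)))
        assert call1.is_producer == call2.is_producer
        assert call1.operon_length_bp == call2.operon_length_bp
        assert call1.adjacent_biosynthesis == call2.adjacent_biosynthesis


class TestCallConsumer:
    def _genome_with(self, fams, positions=None):
        positions = positions or [(1_000 + 1_200 * i, 2_000 + 1_200 * i) for i in range(len(fams))]
        genes = [
            GeneFeature(f"g{i}", "c0", s, e, "+", fam, "")
            for i, (fam, (s, e)) in enumerate(zip(fams, positions))
        ]
        return make_genome(genes), [
            HitRecord(f"g{i}", fam, 60.0, True) for i, fam in enumerate(fams)
        ]

    def test_phnwx_adjacent_calls_aep(self):
        genome, hits = self._genome_with(["phnW", "phnX"])
        call = call_consumer(genome, hits)
        assert "AEP_PhnWX" in call.pathways and call.is_consumer

    def test_phny_alone_does_not_call_phnyz(self):
        genome, hits = self._genome_with(["phnY"])
        call = call_consumer(genome, hits)
        assert "PhnYZ" not in call.pathways

    def test_cp_lyase_needs_phnj_plus_two(self):
        genome, hits = self._genome_with(["phnJ", "phnG", "phnH"])
        assert "CP_lyase" in call_consumer(genome, hits).pathways
        genome2, hits2 = self._genome_with(["phnJ", "phnG"])
        assert "CP_lyase" not in call_consumer(genome2, hits2).pathways
        # phnJ itself is mandatory
        genome3, hits3 = self._genome_with(["phnG", "phnH", "phnI"])
        assert "CP_lyase" not in call_consumer(genome3, hits3).pathways

    def test_window_scan_matches_exhaustive_oracle(self):
        """Genes too far apart on one contig must not co-occur."""
        genome, hits = self._genome_with(
            ["phnW", "phnX"], positions=[(1_000, 2_000), (30_000, 31_000)]
        )
        call = call_consumer(genome, hits)
        assert "AEP_PhnWX" not in call.pathways

    def test_unknown_family_in_rule_is_config_error(self):
        with pytest.raises(ValueError):
            PathwayRule(name="bad", required=frozenset({"nope"}), min_count=1)

    def test_min_count_cannot_exceed_required(self):
        with pytest.raises(ValueError):
            PathwayRule(name="bad", required=frozenset({"phnW"}), min_count=2)


class TestColocalize:
    def test_within_segment(self, pepm_protein):
        genes = [
            GeneFeature("a", "c0", 1_000, 2_000, "+", "pepM", pepm_protein),
            GeneFeature("b", "c0", 8_000, 9_000, "+", "pglL", ""),
        ]
        res = colocalize(make_genome(genes), "pepM", "pglL", 10_000)
        assert res["colocalized"] and res["min_span"] == 8_000

    def test_beyond_segment(self, pepm_protein):
        genes = [
            GeneFeature("a", "c0", 1_000, 2_000, "+", "pepM", pepm_protein),
            GeneFeature("b", "c0", 16_000, 17_000, "+", "pglL", ""),
        ]
        assert not colocalize(make_genome(genes), "pepM", "pglL", 10_000)["colocalized"]

    def test_relaxed_mode_ignores_contigs(self, pepm_protein):
        genes = [
            GeneFeature("a", "c0", 1_000, 2_000, "+", "pepM", pepm_protein),
            GeneFeature("b", "c1", 1_000, 2_000, "+", "pglL", ""),
        ]
        genome = make_genome(genes)
        assert not colocalize(genome, "pepM", "pglL", 10_000, same_contig=True)["colocalized"]
        assert colocalize(genome, "pepM", "pglL", 10_000, same_contig=False)["colocalized"]

    def test_same_contig_implies_relaxed(self, producer_genome):
        """Monotone relaxation: a same-contig colocalization always
        holds under the relaxed condition too."""
        strict = colocalize(producer_genome, "pepM", "ppd", 10_000, same_contig=True)
        relaxed = colocalize(producer_genome, "pepM", "ppd", 10_000, same_contig=False)
        assert not strict["colocalized"] or relaxed["colocalized"]


def brute_force_upper_tail(n_genes, n_hits, N_genes, N_hits):
    """Sum the hypergeometric pmf directly from binomial coefficients."""
    total = 0.0
    for k in range(n_hits, min(N_hits, n_genes) + 1):
        total += (
            math.comb(N_hits, k)
            * math.comb(N_genes - N_hits, n_genes - k)
            / math.comb(N_genes, n_genes)
        )
    return total


class TestEnrichment:
    def test_matches_brute_force_summation(self):
        p = enrichment_test(20, 5, 100, 10)
        assert p == pytest.approx(brute_force_upper_tail(20, 5, 100, 10), abs=1e-12)

    def test_brute_force_over_many_universes(self):
        for N, K, n, k in [(50, 7, 12, 2), (200, 30, 40, 10), (9, 3, 4, 1), (120, 60, 60, 35)]:
            assert enrichment_test(n, k, N, K) == pytest.approx(
                brute_force_upper_tail(n, k, N, K), abs=1e-12
            )

    def test_zero_observed_gives_one(self):
        assert enrichment_test(20, 0, 100, 10) == 1.0

    def test_neighborhood_equals_universe_gives_one(self):
        assert enrichment_test(100, 10, 100, 10) == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            enrichment_test(20, 25, 100, 10)
        with pytest.raises(ValueError):
            enrichment_test(200, 5, 100, 10)


class TestSummarize:
    def test_dual_trait_percentage(self):
        calls = [
            TraitCall(genome_id=f"g{i}", is_producer=(i < 9), is_consumer=(i < 9))
            for i in range(1_234)
        ]
        s = summarize_calls(calls)
        assert s["n_dual"] == 9 and s["pct_dual"] == 0.7

    def test_no_dual(self):
        calls = [TraitCall(genome_id=f"g{i}", is_producer=True) for i in range(10)]
        assert summarize_calls(calls)["pct_dual"] == 0.0

    def test_small_table(self):
        calls = [
            TraitCall(genome_id=f"g{i}", is_producer=i < 3, is_consumer=i < 3)
            for i in range(10)
        ]
        assert summarize_calls(calls)["pct_dual"] == 30.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_calls([])
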