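"""Synthetic-data generator: planted cassettes, contig dropout,
metagenome reads, Lorentzian spectra, sample tables, and format
round trips."""

import numpy as np
import pandas as pd
import pytest

from phoscycle import io, synthio, traitcall
from phoscycle.models import MARKER_FAMILIES, Spectrum
from phoscycle.synthio import GenomeConfig, gen_genomes, gen_metagenome, gen_spectrum


class TestGenGenomes:
    def test_all_producers_complete(self):
        cfg = GenomeConfig(n_genomes=5, producer_freq=1.0, consumer_freq=0.0,
                           dual_freq=0.0, completeness=1.0, decoy_freq=0.0)
        genomes, truth = gen_genomes(cfg, seed=1)
        assert len(genomes) == 5
        assert all(t.is_producer for t in truth.genomes.values())
        assert all(t.cassette_retained for t in truth.genomes.values())
        for g in genomes:
            fams = {x.family for x in g.genes}
            assert "pepM" in fams

    def test_no_producers_no_pepm(self):
        cfg = GenomeConfig(n_genomes=10, producer_freq=0.0, consumer_freq=0.0,
                           dual_freq=0.0, decoy_freq=0.0)
        genomes, truth = gen_genomes(cfg, seed=2)
        assert all(not g.genes_by_family("pepM") for g in genomes)

    def test_detectable_fraction_tracks_freq_times_completeness(self):
        """Cassette survival is Bernoulli(completeness) by construction,
        so detectable producers ~ freq x mean completeness."""
        cfg = GenomeConfig(n_genomes=1_000, producer_freq=0.15,
                           completeness=(0.5, 0.9), consumer_freq=0.0, dual_freq=0.0)
        _, truth = gen_genomes(cfg, seed=1)
        t = list(truth.genomes.values())
        detectable = np.mean([x.is_producer and x.cassette_retained for x in t])
        expected = 0.15 * 0.7
        # 3 sigma binomial band around freq * mean(c)
        sigma = np.sqrt(expected * (1 - expected) / 1_000)
        assert abs(detectable - expected) < 3 * sigma + 0.01

    def test_realized_completeness_within_band(self):
        """Whole-contig dropout lands within +-0.05 of the target for
        genomes with >= 20 contigs."""
        cfg = GenomeConfig(n_genomes=50, n_contigs=25, completeness=(0.4, 0.95))
        _, truth = gen_genomes(cfg, seed=3)
        for t in truth.genomes.values():
            assert abs(t.realized_completeness - t.target_completeness) <= 0.05

    def test_truth_for_every_genome_and_seed_recorded(self):
        cfg = GenomeConfig(n_genomes=7)
        genomes, truth = gen_genomes(cfg, seed=11)
        assert truth.seed == 11
        assert {g.genome_id for g in genomes} == set(truth.genomes)

    def test_determinism(self):
        cfg = GenomeConfig(n_genomes=5)
        g1, _ = gen_genomes(cfg, seed=9)
        g2, _ = gen_genomes(cfg, seed=9)
        assert [g.genome_id for g in g1] == [g.genome_id for g in g2]
        assert [g.assembly_length for g in g1] == [g.assembly_length for g in g2]
        assert [[x.protein for x in g.genes] for g in g1] == \
               [[x.protein for x in g.genes] for g in g2]

    def test_bad_frequency_rejected(self):
        with pytest.raises(ValueError):
            gen_genomes(GenomeConfig(producer_freq=1.5), seed=0)

    def test_impossible_cassette_layout_rejected(self):
        cfg = GenomeConfig(n_genomes=3, producer_freq=1.0,
                           mean_genome_length=60_000, n_contigs=25)
        with pytest.raises(ValueError):
            gen_genomes(cfg, seed=0)

    def test_planted_pepm_has_motif_and_decoys_do_not(self):
        cfg = GenomeConfig(n_genomes=30, producer_freq=0.5, decoy_freq=1.0,
                           consumer_freq=0.0, dual_freq=0.0)
        genomes, truth = gen_genomes(cfg, seed=4)
        for g in genomes:
            for gene in g.genes_by_family("pepM"):
                valid = traitcall.validate_pepm_motif(gene.protein)
                if gene.gene_id.endswith("_decoy"):
                    assert not valid
                else:
                    assert valid


class TestGenMetagenome:
    def test_single_family_all_reads_trace_back(self):
        refs = synthio.make_family_references(["pepM"], 200, seed=1)
        reads, truth = gen_metagenome({"pepM": 1.0}, refs, 100, 30, seed=2)
        assert len(reads) == 100
        assert set(truth.read_sources.values()) == {"pepM"}
        for rid, seq in reads:
            assert seq in refs["pepM"]

    def test_balanced_two_family_counts_binomial(self):
        refs = synthio.make_family_references(["pepM", "marker01"], 200, seed=3)
        reads, truth = gen_metagenome(
            {"pepM": 0.5, "marker01": 0.5}, refs, 10_000, 30, seed=7
        )
        n_pepm = sum(1 for f in truth.read_sources.values() if f == "pepM")
        sigma = np.sqrt(10_000 * 0.25)
        assert abs(n_pepm - 5_000) <= 3 * sigma

    def test_zero_reads(self):
        refs = synthio.make_family_references(["pepM"], 200, seed=1)
        reads, truth = gen_metagenome({"pepM": 1.0}, refs, 0, 30, seed=2)
        assert reads == [] and truth.read_sources == {}

    def test_read_longer_than_reference_rejected(self):
        refs = synthio.make_family_references(["pepM"], 50, seed=1)
        with pytest.raises(ValueError):
            gen_metagenome({"pepM": 1.0}, refs, 10, 60, seed=2)


class TestGenSpectrum:
    def test_lorentzian_area_closed_form(self):
        """Trapezoid over [18, 27] captures the analytic arctan mass of
        a unit peak at 20 ppm."""
        spec, _ = gen_spectrum([(20.0, 1.0, 0.3)], noise_sd=0.0,
                               n_points=20_001, ppm_range=(-30, 40), seed=0)
        mask = (spec.ppm >= 18) & (spec.ppm <= 27)
        got = np.trapezoid(spec.intensity[mask], spec.ppm[mask])
        expected = (1 / np.pi) * (
            np.arctan((27 - 20) / 0.3) - np.arctan((18 - 20) / 0.3)
        )
        assert got == pytest.approx(expected, rel=1e-3)
        assert got >= 0.9

    def test_empty_peak_list_zero_intensity(self):
        spec, _ = gen_spectrum([], noise_sd=0.0, baseline=0.0, seed=0)
        assert np.all(spec.intensity == 0.0)

    def test_truth_records_configured_areas(self):
        peaks = [(21.0, 0.72, 0.3), (2.0, 1.0, 0.3)]
        _, truth = gen_spectrum(peaks, seed=5)
        areas = {c: a for c, a, _ in truth.spectrum_peaks}
        assert areas[21.0] / areas[2.0] == pytest.approx(0.72)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            gen_spectrum([(0.0, 1.0, 0.0)], seed=0)

    def test_descending_axis_normalized(self):
        s = Spectrum(ppm=np.array([3.0, 2.0, 1.0]), intensity=np.array([1.0, 2.0, 3.0]))
        assert list(s.ppm) == [1.0, 2.0, 3.0]
        assert list(s.intensity) == [3.0, 2.0, 1.0]


class TestGenSampleMetadata:
    def test_flat_depth_effect(self):
        df, _ = synthio.gen_sample_metadata(
            200, (0, 250), ("A", "P"), beta0=-2.0, beta_depth=0.0,
            beta_basin=0.0, phi=0.0, genomes_per_sample=241, seed=1)
        shallow = df[df.depth_m < 125].n_producers.sum() / df[df.depth_m < 125].n_genomes.sum()
        deep = df[df.depth_m >= 125].n_producers.sum() / df[df.depth_m >= 125].n_genomes.sum()
        assert abs(shallow - deep) < 0.02

    def test_positive_depth_slope_raises_deep_fraction(self):
        """The logistic mean is monotone in depth."""
        df, _ = synthio.gen_sample_metadata(
            200, (0, 250), ("A", "P"), beta0=-2.197, beta_depth=0.004,
            beta_basin=0.0, phi=0.0, genomes_per_sample=241, seed=11)
        frac = df.n_producers / df.n_genomes
        assert frac[df.depth_m > 200].mean() > frac[df.depth_m < 50].mean()

    def test_overdispersion_inflates_variance(self):
        """Beta-binomial variance m*mu*(1-mu)*(1+(m-1)rho) exceeds the
        binomial variance when phi > 0."""
        kw = dict(n_samples=400, depth_range=(50, 50), basins=("A", "P"),
                  beta0=-2.0, beta_depth=0.0, beta_basin=0.0,
                  genomes_per_sample=241)
        df0, _ = synthio.gen_sample_metadata(**kw, phi=0.0, seed=21)
        df1, _ = synthio.gen_sample_metadata(**kw, phi=0.1, seed=21)
        v0 = np.var(df0.n_producers / df0.n_genomes)
        v1 = np.var(df1.n_producers / df1.n_genomes)
        assert v1 > 3 * v0

    def test_truth_stores_parameters(self):
        _, truth = synthio.gen_sample_metadata(
            5, (0, 100), ("A", "P"), -2.0, 0.004, -1.0, 0.05, 241, seed=3)
        assert truth.sample_params["beta_depth"] == 0.004
        assert truth.sample_params["phi"] == 0.05


class TestRoundTrips:
    def test_fasta(self, tmp_path):
        recs = {"a": "MKL", "b": "EDKAAAAANS"}
        io.write_fasta(recs, tmp_path / "x.faa")
        assert io.read_fasta(tmp_path / "x.faa") == recs

    def test_genome_dir_gff3_fasta(self, tmp_path):
        cfg = GenomeConfig(n_genomes=3, producer_freq=0.7, completeness=(0.6, 1.0))
        genomes, _ = gen_genomes(cfg, seed=6)
        io.write_genome_dir(genomes, tmp_path)
        back = io.read_genome_dir(tmp_path)
        assert len(back) == len(genomes)
        for a, b in zip(genomes, sorted(back, key=lambda g: g.genome_id)):
            assert a.genome_id == b.genome_id
            assert a.contigs == b.contigs
            assert a.completeness == pytest.approx(b.completeness)
            ga = sorted(a.genes, key=lambda g: g.gene_id)
            gb = sorted(b.genes, key=lambda g: g.gene_id)
            assert [(g.gene_id, g.start, g.end, g.strand, g.family) for g in ga] == \
                   [(g.gene_id, g.start, g.end, g.strand, g.family) for g in gb]
            protein_a = {g.gene_id: g.protein for g in ga if g.protein}
            protein_b = {g.gene_id: g.protein for g in gb if g.protein}
            assert protein_a == protein_b

    def test_spectrum_tsv(self, tmp_path):
        spec, _ = gen_spectrum([(2.0, 1.0, 0.3)], noise_sd=0.01, n_points=501,
                               ppm_range=(-10, 10), seed=1, label="exp")
        io.write_spectrum(spec, tmp_path / "s.tsv")
        back = io.read_spectrum(tmp_path / "s.tsv")
        assert back.label == "exp"
        np.testing.assert_allclose(back.ppm, spec.ppm, rtol=1e-9)
        np.testing.assert_allclose(back.intensity, spec.intensity, rtol=1e-9)

    def test_hits_tsv(self, tmp_path):
        cfg = GenomeConfig(n_genomes=2, producer_freq=1.0)
        genomes, _ = gen_genomes(cfg, seed=8)
        hits = synthio.hits_from_genomes(genomes)
        io.write_hits(hits, tmp_path / "h.tsv")
        back = io.read_hits(tmp_path / "h.tsv")
        assert [(h.query_id, h.family, h.score, h.above_cutoff) for h in hits] == \
               [(h.query_id, h.family, h.score, h.above_cutoff) for h in back]

    def test_newick(self, tmp_path):
        nwk = synthio.random_tree_newick([f"t{i}" for i in range(8)], seed=4)
        import dendropy
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        io.write_newick(tree, tmp_path / "t.nwk")
        back = io.read_newick(tmp_path / "t.nwk")
        from phoscycle import treedist
        t1 = treedist.extract_splits(nwk)
        t2 = treedist.splits_from_tree(back)
        assert t1.leaves == t2.leaves and t1.splits == t2.splits
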