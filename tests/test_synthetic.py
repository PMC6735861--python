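"""Generator behaviour: determinism, planted structure, fixture round-trips."""
import numpy as np
import pytest

from phasiclust.io_alignments import load_alignments, load_annotation
from phasiclust.synthetic import (
    SimClusterSpec,
    SimSampleSpec,
    simulate_expression,
    simulate_genome,
    simulate_reads,
    write_fixtures,
)


class TestSimulateGenome:
    def test_deterministic_for_fixed_seed(self):
        g1, genes1 = simulate_genome(1, 100_000, 20, 3, seed=7)
        g2, genes2 = simulate_genome(1, 100_000, 20, 3, seed=7)
        assert g1 == g2
        assert genes1 == genes2
        assert len(genes1) == 20
        assert sum(len(g.introns) for g in genes1) == 40

    def test_different_seed_differs(self):
        g1, _ = simulate_genome(1, 50_000, 5, 2, seed=1)
        g2, _ = simulate_genome(1, 50_000, 5, 2, seed=2)
        assert g1 != g2

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="intergenic"):
            simulate_genome(1, 1000, 50, 3, seed=1)

    def test_single_exon_genes_have_no_introns(self):
        _, genes = simulate_genome(2, 50_000, 10, 1, seed=3)
        assert len(genes) == 10
        assert all(g.n_exons == 1 and not g.introns for g in genes)

    def test_gene_geometry_constraints(self, toy_genome_genes):
        genome, genes = toy_genome_genes
        by_chrom = {}
        for g in genes:
            assert all(e - s >= 60 for s, e in g.exons)
            assert all(e - s >= 20 for s, e in g.introns)
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs = sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                assert b.start - a.end >= 200


class TestSimulateReads:
    def _sample(self, seed=5, **kw):
        return SimSampleSpec(sample_id="s", serotype="A", seed=seed, **kw)

    def test_phased_sense_starts_on_register(self):
        genome = {"chr1": "A" * 2000}
        spec = SimClusterSpec(
            locus_id="L1", chrom="chr1", start=460, phased=True, register_offset=0,
            n_cycles=6, mean_reads=60, sense_fraction=1.0,
        )
        reads = simulate_reads(genome, [], [spec], self._sample(background_rate=0.0))
        assert reads
        assert all(r.strand == "+" for r in reads)
        assert all((r.five_prime - spec.start) % 23 == 0 for r in reads)

    def test_minus_strand_offset_by_dicer_overhang(self):
        genome = {"chr1": "A" * 2000}
        spec = SimClusterSpec(
            locus_id="L1", chrom="chr1", start=460, phased=True, register_offset=4,
            n_cycles=6, mean_reads=60, sense_fraction=0.0,
        )
        reads = simulate_reads(genome, [], [spec], self._sample(background_rate=0.0))
        assert reads and all(r.strand == "-" for r in reads)
        assert all((r.five_prime - spec.start - 4 - 2) % 23 == 0 for r in reads)

    def test_total_depletion_in_mutant(self):
        genome = {"chr1": "A" * 2000}
        spec = SimClusterSpec(
            locus_id="L1", chrom="chr1", start=100, phased=True, n_cycles=5,
            mean_reads=100, mutant_depletion=1.0,
        )
        mut = SimSampleSpec(sample_id="m", genotype="rdr1", seed=3, background_rate=0.0)
        assert simulate_reads(genome, [], [spec], mut) == []
        wt = SimSampleSpec(sample_id="w", genotype="WT", seed=3, background_rate=0.0)
        assert len(simulate_reads(genome, [], [spec], wt)) > 0

    def test_unphased_register_occupancy_is_uniform(self):
        """Binomial oracle: any single mod-23 register holds ~1/23 of 5' ends."""
        genome = {"chr1": "A" * 60_000}
        spec = SimClusterSpec(
            locus_id="L1", chrom="chr1", start=1000, phased=False, n_cycles=46,
            mean_reads=1000, sense_fraction=1.0,
        )
        reads = simulate_reads(genome, [], [spec], self._sample(seed=17, background_rate=0.0))
        n = len(reads)
        p = 1 / 23
        frac = sum(1 for r in reads if (r.five_prime - spec.start) % 23 == 0) / n
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_locus_outside_genome_raises(self):
        genome = {"chr1": "A" * 100}
        spec = SimClusterSpec(locus_id="L1", chrom="chr1", start=50, n_cycles=5)
        with pytest.raises(ValueError, match="outside genome"):
            simulate_reads(genome, [], [spec], self._sample())

    def test_library_size_matches_poisson_expectation(self):
        """Observed totals stay inside 4-sigma Poisson bounds over 100 seeds."""
        genome = {"chr1": "A" * 10_000}
        specs = [
            SimClusterSpec(locus_id=f"L{i}", chrom="chr1", start=500 + i * 800,
                           n_cycles=6, mean_reads=40)
            for i in range(5)
        ]
        bg_rate = 0.5
        expected = 5 * 40 + bg_rate * 10
        totals = [
            len(simulate_reads(genome, [], specs, self._sample(seed=s, background_rate=bg_rate)))
            for s in range(100)
        ]
        sigma = np.sqrt(expected)
        assert abs(np.mean(totals) - expected) < 4 * sigma / np.sqrt(100)

    def test_phased_spec_requires_three_cycles(self):
        with pytest.raises(ValueError, match="n_cycles"):
            SimClusterSpec(locus_id="x", chrom="c", start=0, phased=True, n_cycles=2)

    def test_length_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimSampleSpec(sample_id="s", length_distribution={23: 0.5})


class TestFixtures:
    def test_round_trip_preserves_read_multiset(self, tmp_path):
        genome, genes = simulate_genome(1, 20_000, 4, 2, seed=9)
        spec = SimClusterSpec(
            locus_id="L1", chrom="chr1", start=genes[0].start, phased=False, n_cycles=8,
            mean_reads=80,
        )
        sample = SimSampleSpec(sample_id="s1", seed=4)
        reads = simulate_reads(genome, genes, [spec], sample)
        paths = write_fixtures(genome, genes, {"s1": reads}, tmp_path)
        lib = load_alignments(paths["sam"]["s1"])
        orig = sorted((r.chrom, r.start, r.length, r.strand) for r in reads)
        back = sorted((r.chrom, r.start, r.length, r.strand) for r in lib.reads)
        assert orig == back

    def test_fixture_files_byte_identical_for_fixed_seed(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            genome, genes = simulate_genome(1, 10_000, 3, 2, seed=13)
            sample = SimSampleSpec(sample_id="s1", seed=8)
            spec = SimClusterSpec(locus_id="L1", chrom="chr1", start=2000, n_cycles=6,
                                  mean_reads=50)
            reads = simulate_reads(genome, genes, [spec], sample)
            paths = write_fixtures(genome, genes, {"s1": reads}, tmp_path / sub)
            outs.append(paths)
        for key in ("fasta", "gff3"):
            assert outs[0][key].read_bytes() == outs[1][key].read_bytes()
        assert outs[0]["sam"]["s1"].read_bytes() == outs[1]["sam"]["s1"].read_bytes()

    def test_empty_read_list_gives_header_only_sam(self, tmp_path):
        genome, genes = simulate_genome(1, 5_000, 2, 1, seed=2)
        paths = write_fixtures(genome, genes, {"s1": []}, tmp_path)
        lines = paths["sam"]["s1"].read_text().splitlines()
        assert lines and all(l.startswith("@") for l in lines)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert load_alignments(paths["sam"]["s1"]).total_aligned == 0

    def test_one_sam_per_sample(self, tmp_path):
        genome, genes = simulate_genome(1, 5_000, 2, 1, seed=2)
        paths = write_fixtures(genome, genes, {"a": [], "b": [], "c": []}, tmp_path)
        assert set(paths["sam"]) == {"a", "b", "c"}

    def test_gff3_round_trip(self, tmp_path):
        genome, genes = simulate_genome(1, 30_000, 6, 3, seed=21)
        paths = write_fixtures(genome, genes, {}, tmp_path)
        loaded = load_annotation(paths["gff3"])
        assert [(g.gene_id, g.chrom, g.strand, g.exons) for g in loaded] == [
            (g.gene_id, g.chrom, g.strand, g.exons) for g in sorted(genes, key=lambda g: (g.chrom, g.start))
        ]


class TestExpression:
    def test_derepression_applies_to_mutant_samples_only(self):
        genome, genes = simulate_genome(1, 30_000, 4, 1, seed=5)
        host = max(genes, key=lambda g: g.length)
        spec = SimClusterSpec(
            locus_id="L1", chrom=host.chrom, start=host.start, gene_linked=True,
            phased=True, n_cycles=3, mutant_depletion=0.6,
        )
        samples = [
            SimSampleSpec(sample_id="wt", genotype="WT", seed=1),
            SimSampleSpec(sample_id="mut", genotype="rdr1", seed=2),
        ]
        # identical replicate noise is not guaranteed, so compare expectation
        dfs = [
            simulate_expression(genes, samples, [spec], seed=3, replicate_sigma=0.0,
                                derepression=1.5)
        ]
        df = dfs[0]
        ratio = df.loc[host.gene_id, "mut"] / df.loc[host.gene_id, "wt"]
        assert ratio == pytest.approx(1.5)
        others = [g.gene_id for g in genes if g.gene_id != host.gene_id]
        assert np.allclose(df.loc[others, "mut"], df.loc[others, "wt"])
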