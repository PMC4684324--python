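"""Synthetic-data generator: determinism, planted truth, count models, DE table."""

import re

import numpy as np
import pytest

from damidkit import windows as win
from damidkit.genome import GeneModel
from damidkit.simulate import (
    SimulationConfig,
    TruthSite,
    _child_rngs,
    _RNG_NAMES,
    plant_binding_sites,
    simulate_dataset,
    simulate_expression_table,
    simulate_genome,
    truth_from_frame,
    truth_to_frame,
)

SMALL = SimulationConfig(seed=1, chrom_lengths=(300_000, 300_000), n_genes=80, n_sites=30)


def gen_genome(config):
    rngs = _child_rngs(config.seed, _RNG_NAMES)
    genome, genes = simulate_genome(config, rngs["genome"])
    return genome, genes, rngs


class TestSimulateGenome:
    def test_requested_counts_and_bounds(self):
        genome, genes, _ = gen_genome(SMALL)
        assert len(genome) == 2
        assert len(genes) == 80
        for g in genes:
            assert 0 <= g.start < g.end <= genome.length(g.chrom)

    def test_genes_non_overlapping_and_both_strands(self):
        _, genes, _ = gen_genome(SMALL)
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for sub in by_chrom.values():
            sub.sort(key=lambda g: g.start)
            assert all(a.end <= b.start for a, b in zip(sub, sub[1:]))
        assert {g.strand for g in genes} == {"+", "-"}

    def test_zero_genes_is_valid(self):
        cfg = SimulationConfig(seed=1, chrom_lengths=(200_000,), n_genes=0, n_sites=0)
        genome, genes, _ = gen_genome(cfg)
        assert genes == []

    def test_impossible_placement_suggests_longer_chromosomes(self):
        cfg = SimulationConfig(seed=1, chrom_lengths=(50_000,), n_genes=40, n_sites=0)
        with pytest.raises(ValueError, match="longer chromosomes"):
            gen_genome(cfg)

    def test_seeded_determinism_bytes(self):
        g1, genes1, _ = gen_genome(SMALL)
        g2, genes2, _ = gen_genome(SMALL)
        assert g1.sequence("chr1") == g2.sequence("chr1")
        assert genes1 == genes2


class TestPlantBindingSites:
    def test_offset_model_recovered_from_truth(self):
        cfg = SimulationConfig(seed=3, chrom_lengths=(2_000_000, 2_000_000), n_genes=400, n_sites=200)
        genome, genes, rngs = gen_genome(cfg)
        truth, _ = plant_binding_sites(genome, genes, cfg, rngs["sites"])
        by_id = {g.gene_id: g for g in genes}
        offsets = []
        for s in truth:
            g = by_id[s.gene_id]
            raw = s.center - g.tss
            offsets.append(raw if g.strand == "+" else -raw)
        assert -540 <= np.mean(offsets) <= -460

    def test_no_motifs_when_probability_zero(self):
        cfg = SimulationConfig(seed=2, chrom_lengths=(300_000,), n_genes=50, n_sites=20, motif_plant_prob=0.0)
        genome, genes, rngs = gen_genome(cfg)
        truth, planted = plant_binding_sites(genome, genes, cfg, rngs["sites"])
        assert all(s.motif_positions == () for s in truth)

    def test_planted_motifs_rescan_from_sequence(self):
        cfg = SimulationConfig(seed=2, chrom_lengths=(300_000,), n_genes=50, n_sites=20, motif_plant_prob=1.0)
        genome, genes, rngs = gen_genome(cfg)
        truth, planted = plant_binding_sites(genome, genes, cfg, rngs["sites"])
        pattern = re.compile("TGAATG[AG]A")
        for s in truth:
            assert len(s.motif_positions) >= 1
            for pos in s.motif_positions:
                assert s.start <= pos <= s.end - 8
                assert pattern.fullmatch(planted.sequence(s.chrom)[pos : pos + 8])

    def test_more_sites_than_genes_rejected(self):
        cfg = SimulationConfig(seed=2, chrom_lengths=(300_000,), n_genes=10, n_sites=20)
        genome, genes, rngs = gen_genome(SimulationConfig(seed=2, chrom_lengths=(300_000,), n_genes=10, n_sites=0))
        with pytest.raises(ValueError, match="exceeds"):
            plant_binding_sites(genome, genes, cfg, rngs["sites"])

    def test_truth_table_round_trip(self):
        cfg = SimulationConfig(seed=4, chrom_lengths=(300_000,), n_genes=40, n_sites=15)
        genome, genes, rngs = gen_genome(cfg)
        truth, _ = plant_binding_sites(genome, genes, cfg, rngs["sites"])
        assert truth_from_frame(truth_to_frame(truth)) == truth


class TestSimulateReads:
    def test_same_seed_identical_bed(self):
        a = simulate_dataset(SMALL)
        b = simulate_dataset(SMALL)
        for key in a.reads:
            assert a.reads[key].equals(b.reads[key])

    def test_poisson_limit_dispersion(self):
        # with Poisson generation the counted background windows stay at
        # variance/mean ~ 1 (sums of independent Poisson contributions)
        cfg = SimulationConfig(
            seed=5, chrom_lengths=(500_000,), n_genes=0, n_sites=0, depth=50.0, nb_size=None
        )
        ds = simulate_dataset(cfg)
        grid = win.build_windows(ds.genome)
        track = win.count_reads(grid, ds.reads["dam_control"])
        counts = track.counts[:-1]  # drop the truncated terminal window
        ratio = counts.var(ddof=1) / counts.mean()
        assert 0.9 <= ratio <= 1.1

    def test_overdispersed_generation_exceeds_poisson(self):
        cfg = SimulationConfig(
            seed=5, chrom_lengths=(500_000,), n_genes=0, n_sites=0, depth=50.0, nb_size=5.0
        )
        ds = simulate_dataset(cfg)
        grid = win.build_windows(ds.genome)
        counts = win.count_reads(grid, ds.reads["dam_control"]).counts[:-1]
        assert counts.var(ddof=1) / counts.mean() > 1.5

    def test_reads_are_fixed_length_within_bounds(self):
        ds = simulate_dataset(SMALL)
        for key, df in ds.reads.items():
            assert ((df["end"] - df["start"]) == SMALL.read_length).all()
            lengths = df["chrom"].map(ds.genome.lengths())
            assert (df["start"] >= 0).all() and (df["end"] <= lengths).all()
            assert set(df["strand"]) == {"+", "-"}

    def test_enrichment_zero_makes_tracks_exchangeable(self):
        from scipy import stats

        pvals = []
        for seed in range(1, 6):
            cfg = SimulationConfig(
                seed=seed, chrom_lengths=(400_000,), n_genes=60, n_sites=30, enrichment_log2fc=0.0
            )
            ds = simulate_dataset(cfg)
            grid = win.build_windows(ds.genome)
            # a 350-bp footprint spans at most 6 windows; stride 6 keeps the
            # KS test's independence assumption honest
            t = win.count_reads(grid, ds.reads["fusion_control"]).counts[::6]
            b = win.count_reads(grid, ds.reads["dam_control"]).counts[::6]
            pvals.append(stats.ks_2samp(t, b).pvalue)
        assert sum(p > 0.01 for p in pvals) >= 4


class TestExpressionTable:
    def _table(self, n_peak, n_null, seed=0, peak_mean=1.2):
        genes = [GeneModel(f"g{i:05d}", "chr1", 100 * i + 10, 100 * i + 60, "+") for i in range(n_peak + n_null)]
        truth = [
            TruthSite("chr1", g.start, g.start + 10, g.gene_id, False) for g in genes[:n_peak]
        ]
        cfg = SimulationConfig(seed=seed, de_peak_mean=peak_mean)
        rng = np.random.default_rng(seed)
        return simulate_expression_table(truth, genes, cfg, rng), genes[:n_peak]

    def test_peak_gene_effect_recovered(self):
        table, peak_genes = self._table(200, 200)
        ids = {g.gene_id for g in peak_genes}
        mean = table[table["gene_id"].isin(ids)]["log2fc"].mean()
        assert mean == pytest.approx(1.2, abs=0.1)

    def test_null_gene_effect_centred(self):
        table, peak_genes = self._table(0, 1000)
        assert table["log2fc"].mean() == pytest.approx(0.0, abs=0.05)

    def test_zero_effect_config_yields_few_up_calls(self):
        table, _ = self._table(0, 1000)
        up = (table["log2fc"] > np.log2(1.5)) & (table["padj"] < 0.1)
        assert up.mean() < 0.02

    def test_padj_monotone_with_effect(self):
        table, _ = self._table(300, 300)
        strong = table[table["log2fc"].abs() > 1.5]["padj"].median()
        weak = table[table["log2fc"].abs() < 0.2]["padj"].median()
        assert strong < weak

    def test_means_positive_and_consistent(self):
        table, _ = self._table(100, 100)
        assert (table["mean_treatment"] > 0).all() and (table["mean_background"] > 0).all()
        implied = np.log2(table["mean_treatment"] / table["mean_background"])
        assert np.allclose(implied, table["log2fc"], atol=1e-9)
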