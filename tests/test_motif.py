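"""Motif scanning, peak relocation null and negative-binomial fitting."""

import numpy as np
import pytest
from scipy import stats

from damidkit import motif as mot
from damidkit.genome import Genome, GenomeIndex, Interval


class TestScanSequence:
    @pytest.mark.parametrize(
        "seq,n",
        [
            ("TGAATGAA", 1),
            ("TGAATGGA", 1),
            ("TGAATGCA", 0),
            ("TGAATGAATGAA", 2),  # overlapping matches both counted
            ("NGAATGAA", 0),
        ],
    )
    def test_forward_matches(self, seq, n):
        assert len(mot.scan_sequence(seq, strand_mode="forward")) == n

    def test_overlap_positions(self):
        assert mot.scan_sequence("TGAATGAATGAA", strand_mode="forward") == [0, 4]

    def test_reverse_strand_hit_reported_on_forward_coordinates(self):
        # TTCATTCA is the reverse complement of TGAATGAA
        assert mot.scan_sequence("TTCATTCA", strand_mode="forward") == []
        assert mot.scan_sequence("TTCATTCA", strand_mode="both") == [0]

    def test_rc_pattern_construction(self):
        assert mot._rc_pattern("TGAATG[AG]A") == "T[CT]CATTCA"

    def test_case_insensitive(self):
        assert mot.scan_sequence("tgaatgaa", strand_mode="forward") == [0]


class TestScanPeaks:
    def test_counts_and_positions(self):
        seq = "A" * 100 + "TGAATGAA" + "A" * 92 + "TGAATGGA" + "A" * 92
        genome = Genome([GenomeIndex("chr1", len(seq), seq)])
        peaks = [Interval("chr1", 90, 130), Interval("chr1", 150, 250), Interval("chr1", 260, 292)]
        res = mot.scan_peaks(peaks, genome, strand_mode="forward")
        assert res.total_occurrences == 2
        assert res.peaks_with_motif == 2
        assert res.positions[0] == (100,)
        assert res.positions[1] == (200,)
        assert res.positions[2] == ()


class TestRelocatePeaks:
    def _genome(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), 50_000)) for _ in range(2)]
        return Genome([GenomeIndex(f"chr{i + 1}", 50_000, s) for i, s in enumerate(seqs)])

    def test_lengths_and_chromosomes_preserved(self):
        genome = self._genome()
        peaks = [Interval("chr1", 100, 700), Interval("chr1", 900, 1200), Interval("chr2", 0, 450)]
        for relocated in mot.relocate_peaks(peaks, genome, n_relocations=20, seed=3):
            assert [len(p) for p in relocated] == [600, 300, 450]
            assert [p.chrom for p in relocated] == ["chr1", "chr1", "chr2"]
            assert all(0 <= p.start and p.end <= genome.length(p.chrom) for p in relocated)

    def test_start_distribution_uniform(self):
        genome = self._genome()
        peaks = [Interval("chr1", 0, 500)]
        starts = [
            relocated[0].start
            for relocated in mot.relocate_peaks(peaks, genome, n_relocations=1000, seed=11)
        ]
        counts, _ = np.histogram(starts, bins=10, range=(0, 50_000 - 500 + 1))
        chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
        assert stats.chi2.sf(chi2, df=9) > 0.01

    def test_peak_longer_than_chromosome_rejected(self):
        genome = Genome([GenomeIndex("chr1", 100, "A" * 100)])
        with pytest.raises(ValueError, match="longer"):
            mot.relocate_peaks([Interval("chr1", 0, 150)], genome, n_relocations=1)
        # length == chromosome is fine (start pinned to 0)
        (only,) = next(iter(mot.relocate_peaks([Interval("chr1", 0, 100)], genome, 1)))
        assert only.start == 0

    def test_seeded_determinism(self):
        genome = self._genome()
        peaks = [Interval("chr1", 100, 700), Interval("chr2", 5, 400)]
        a = [tuple((p.start, p.end) for p in r) for r in mot.relocate_peaks(peaks, genome, 5, seed=9)]
        b = [tuple((p.start, p.end) for p in r) for r in mot.relocate_peaks(peaks, genome, 5, seed=9)]
        assert a == b


class TestNegativeBinomialFit:
    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(42)
        x = rng.negative_binomial(5, 5 / 25, size=2000)  # size 5, mean 20
        fit = mot.fit_negative_binomial(x)
        assert not fit.poisson_fallback
        assert 4 <= fit.size <= 6
        assert 19 <= fit.mean <= 21

    def test_fitted_mean_matches_sample_mean(self):
        rng = np.random.default_rng(1)
        x = rng.negative_binomial(3, 0.2, size=500)
        fit = mot.fit_negative_binomial(x)
        assert fit.mean == pytest.approx(x.mean(), rel=1e-12)

    def test_underdispersed_counts_fall_back_to_poisson(self):
        x = np.array([10, 10, 10, 11, 10, 9, 10, 10] * 10)  # var << mean
        fit = mot.fit_negative_binomial(x)
        assert fit.poisson_fallback
        assert fit.size is None

    def test_all_equal_input_rejected(self):
        with pytest.raises(ValueError):
            mot.fit_negative_binomial([7] * 50)

    def test_matches_r_fitdistr_reference(self, tmp_path):
        """Cross-check the profiled NB likelihood against MASS::fitdistr."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(30)
        x = rng.negative_binomial(4, 4 / 16, size=400)
        np.savetxt(tmp_path / "counts.txt", x, fmt="%d")
        script = tmp_path / "fit.R"
        script.write_text(
            'x <- scan("%s")\n'
            "fit <- MASS::fitdistr(x, 'negative binomial')\n"
            'cat(fit$estimate["size"], fit$estimate["mu"], "\\n")\n' % (tmp_path / "counts.txt")
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        r_size, r_mu = map(float, out.stdout.split())
        fit = mot.fit_negative_binomial(x)
        assert fit.size == pytest.approx(r_size, rel=1e-3)
        assert fit.mean == pytest.approx(r_mu, rel=1e-6)


class TestEnrichmentPvalue:
    def test_observed_zero_gives_p_one(self):
        fit = mot.CountDistributionFit(size=5.0, mean=20.0, poisson_fallback=False, n=100)
        assert mot.motif_enrichment_pvalue(0, fit) == 1.0

    def test_p_at_null_median_is_central(self):
        rng = np.random.default_rng(17)
        x = rng.negative_binomial(5, 5 / 25, size=1000)
        fit = mot.fit_negative_binomial(x)
        p = mot.motif_enrichment_pvalue(int(np.median(x)), fit)
        assert 0.3 <= p <= 0.7

    def test_model_tail_tracks_empirical_tail(self):
        rng = np.random.default_rng(23)
        x = rng.negative_binomial(6, 6 / 30, size=1000)
        fit = mot.fit_negative_binomial(x)
        for obs in (int(np.quantile(x, q)) for q in (0.5, 0.75, 0.9)):
            empirical = float((x >= obs).mean())
            if empirical >= 10 / len(x):
                assert abs(mot.motif_enrichment_pvalue(obs, fit) - empirical) <= 0.05

    def test_upper_tail_convention(self):
        fit = mot.CountDistributionFit(size=None, mean=10.0, poisson_fallback=True, n=50)
        assert mot.motif_enrichment_pvalue(15, fit) == pytest.approx(
            float(stats.poisson.sf(14, 10.0))
        )
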