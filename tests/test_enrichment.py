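"""Permutation null, binomial tails, chi-square and correlation machinery."""

import numpy as np
import pandas as pd
import pytest

from hotregions.enrichment import (
    PermutationParams,
    assign_regions_to_genes,
    chi2_2x2,
    density_correlation,
    geneset_region_enrichment,
    hot_lot_disproportion,
    interval_binomial_enrichment,
    shift_permutation_test,
    stage_enrichment,
)
from hotregions.intervals import GenomeLayout, Interval, RegionSet
from hotregions.variant_mapping import SNP


class TestShiftPermutation:
    def test_whole_chromosome_region_p_one(self):
        genome = GenomeLayout((("chr1", 1000),))
        regions = RegionSet([Interval("chr1", 0, 1000)])
        snps = [SNP(f"s{i}", "chr1", 100 * i) for i in range(5)]
        res = shift_permutation_test(snps, regions, genome, PermutationParams(200, 1))
        assert res.observed == 5
        assert res.p_value == 1.0

    def test_observed_zero_p_one(self):
        genome = GenomeLayout((("chr1", 10_000), ("chr2", 10_000)))
        regions = RegionSet([Interval("chr2", 0, 100)])
        snps = [SNP("s1", "chr1", 5000)]
        res = shift_permutation_test(snps, regions, genome, PermutationParams(200, 1))
        assert res.observed == 0
        assert res.p_value == 1.0

    def test_region_longer_than_chromosome_rejected(self):
        genome = GenomeLayout((("chr1", 50),))
        regions = RegionSet([Interval("chr1", 0, 50)])
        snps = [SNP("s1", "chr1", 10)]
        # same length is fine; build an over-long region via a fake layout
        bad_genome = GenomeLayout((("chr1", 40),))
        with pytest.raises(ValueError):
            shift_permutation_test(snps, regions, bad_genome, PermutationParams(10, 0))

    def test_monte_carlo_matches_exhaustive_placement(self):
        """One 10-bp region on a 100-bp chromosome, 3 clustered SNPs: the
        Monte-Carlo p must sit within 3 standard errors of the exact p from
        enumerating all 91 placements."""
        genome = GenomeLayout((("chr1", 100),))
        regions = RegionSet([Interval("chr1", 45, 55)])
        snps = [SNP("a", "chr1", 48), SNP("b", "chr1", 50), SNP("c", "chr1", 52)]
        observed = 3
        exceed = 0
        for start in range(0, 91):
            n = sum(1 for s in snps if start <= s.pos < start + 10)
            if n >= observed:
                exceed += 1
        p_exact = exceed / 91
        n_iter = 4000
        res = shift_permutation_test(snps, regions, genome, PermutationParams(n_iter, 42))
        assert res.observed == observed
        se = np.sqrt(p_exact * (1 - p_exact) / n_iter)
        assert abs(res.p_value - p_exact) <= 3 * se + 2 / n_iter

    def test_p_never_zero_and_bounded(self):
        genome = GenomeLayout((("chr1", 1_000_000),))
        regions = RegionSet([Interval("chr1", 0, 100)])
        snps = [SNP(f"s{i}", "chr1", i) for i in range(20)]  # all in region now
        res = shift_permutation_test(snps, regions, genome, PermutationParams(500, 3))
        assert 0 < res.p_value <= 1
        assert res.p_value >= 1 / 501

    def test_reproducible_given_seed(self, hot_2pct_genome):
        genome, hot = hot_2pct_genome
        snps = [SNP(f"s{i}", "chr1", 10_000 * i) for i in range(100)]
        r1 = shift_permutation_test(snps, hot, genome, PermutationParams(300, 7))
        r2 = shift_permutation_test(snps, hot, genome, PermutationParams(300, 7))
        assert np.array_equal(r1.null_counts, r2.null_counts)
        assert r1.p_value == r2.p_value

    def test_rigid_mode_runs_and_preserves_spacing_counts(self):
        genome = GenomeLayout((("chr1", 10_000),))
        regions = RegionSet([Interval("chr1", 1000, 1100), Interval("chr1", 2000, 2100)])
        snps = [SNP(f"s{i}", "chr1", p) for i, p in enumerate(range(0, 10_000, 57))]
        res = shift_permutation_test(
            snps, regions, genome, PermutationParams(300, 5, shift_mode="rigid")
        )
        assert 0 < res.p_value <= 1


class TestStageEnrichment:
    def test_observed_equals_expected_zero_pct(self):
        e = stage_enrichment(10, 20, 0.5)
        assert e.enrichment_pct == 0.0

    def test_full_enrichment_closed_form(self):
        e = stage_enrichment(5, 5, 0.44)
        assert e.enrichment_pct == pytest.approx((1 / 0.44 - 1) * 100, rel=1e-9)
        assert e.binom_p == pytest.approx(0.44 ** 5, rel=1e-9)

    def test_full_depletion_closed_form(self):
        e = stage_enrichment(0, 10, 0.24)
        assert e.enrichment_pct == -100.0
        assert e.binom_p == pytest.approx(0.76 ** 10, rel=1e-9)

    def test_tail_direction_follows_sign(self):
        up = stage_enrichment(15, 20, 0.5)
        down = stage_enrichment(5, 20, 0.5)
        assert up.enrichment_pct > 0 and down.enrichment_pct < 0
        # symmetric binomial: the two one-sided tails agree
        assert up.binom_p == pytest.approx(down.binom_p, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            stage_enrichment(6, 5, 0.5)
        with pytest.raises(ValueError):
            stage_enrichment(1, 5, 0.0)


class TestHotLotDisproportion:
    def test_perfect_proportionality(self):
        chi2, p = hot_lot_disproportion(10, 90, 1_000_000, 9_000_000)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        chi2, _ = hot_lot_disproportion(100, 100, 10_000_000, 90_000_000)
        assert chi2 == pytest.approx(80 ** 2 / 20 + 80 ** 2 / 180, rel=1e-12)

    def test_doubling_counts_doubles_chi2(self):
        c1, _ = hot_lot_disproportion(30, 70, 1_000_000, 4_000_000)
        c2, _ = hot_lot_disproportion(60, 140, 1_000_000, 4_000_000)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)


class TestDensityCorrelation:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 5.0, 7.0]
        r, _ = density_correlation(x, x)
        assert r == pytest.approx(1.0)
        r, _ = density_correlation(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        r, p = density_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6, abs=1e-12)
        assert 0 < p <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            density_correlation([1, 1, 1], [1, 2, 3])


class TestIntervalBinomial:
    GENOME = GenomeLayout((("chr1", 1_000_000),))

    def _regions(self, midpoints):
        return RegionSet([Interval("chr1", m - 50, m + 50) for m in midpoints])

    def test_k_zero_p_one(self):
        targets = RegionSet([Interval("chr1", 900_000, 1_000_000)])
        regions = self._regions([1_000, 2_000, 3_000])
        k, m, q, p = interval_binomial_enrichment(regions, targets, self.GENOME)
        assert (k, m) == (0, 3) and p == 1.0

    def test_all_inside_closed_form(self):
        targets = RegionSet([Interval("chr1", 0, 100_000)])  # q = 0.1
        regions = self._regions(range(5_000, 100_000, 10_000))  # 10 regions inside
        k, m, q, p = interval_binomial_enrichment(regions, targets, self.GENOME)
        assert (k, m) == (10, 10) and q == pytest.approx(0.1)
        assert p == pytest.approx(0.1 ** 10, rel=1e-9)

    def test_two_of_ten_closed_form(self):
        targets = RegionSet([Interval("chr1", 0, 100_000)])
        mids = [5_000, 15_000] + list(range(200_000, 1_000_000, 100_000))
        k, m, q, p = interval_binomial_enrichment(self._regions(mids), targets, self.GENOME)
        assert (k, m) == (2, 10)
        assert p == pytest.approx(1 - 0.9 ** 10 - 10 * 0.1 * 0.9 ** 9, rel=1e-9)


class TestRegionGeneAssignment:
    TSS = pd.DataFrame(
        {"gene_id": ["geneA", "geneB"], "chrom": ["chr1", "chr1"],
         "tss": [90, 500], "strand": ["+", "+"]}
    )

    def test_nearest_tss_wins(self):
        regions = RegionSet([Interval("chr1", 50, 150)])  # midpoint 100
        assert assign_regions_to_genes(regions, self.TSS) == {"chr1:50-150": "geneA"}

    def test_equidistant_tie_lexicographic(self):
        tss = pd.DataFrame(
            {"gene_id": ["geneB", "geneA"], "chrom": ["chr1", "chr1"],
             "tss": [90, 110], "strand": ["+", "+"]}
        )
        regions = RegionSet([Interval("chr1", 50, 150)])
        assert assign_regions_to_genes(regions, tss)["chr1:50-150"] == "geneA"

    def test_single_gene_takes_all(self):
        tss = self.TSS.iloc[:1]
        regions = RegionSet([Interval("chr1", 0, 10), Interval("chr1", 900, 950)])
        assert set(assign_regions_to_genes(regions, tss).values()) == {"geneA"}

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            assign_regions_to_genes(RegionSet([Interval("chr1", 0, 10)]), self.TSS.iloc[:0])


class TestGenesetEnrichment:
    def test_identical_proportions_chi2_zero(self):
        chi2, p = chi2_2x2(20, 20, 80, 80)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_formula(self):
        chi2, _ = chi2_2x2(30, 10, 70, 90)
        n = 200
        expected = n * (30 * 90 - 10 * 70) ** 2 / (40 * 160 * 100 * 100)
        assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_row_swap_invariance(self):
        assert chi2_2x2(30, 10, 70, 90)[0] == pytest.approx(chi2_2x2(70, 90, 30, 10)[0])

    def test_geneset_wrapper_counts(self):
        geneset = {"g1", "g2", "g3"}
        hot = {"g1", "g2", "g4", "g5"}
        lot = {"g3", "g6", "g7", "g8"}
        chi2, p = geneset_region_enrichment(geneset, hot, lot)
        assert chi2 == pytest.approx(chi2_2x2(2, 1, 2, 3)[0])

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(0, 0, 5, 5)
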