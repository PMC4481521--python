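"""Catalog curation, coding classification, densities and LD."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hotregions.io import GWASCatalogRow, HaplotypeMatrix
from hotregions.intervals import Interval, RegionSet
from hotregions.variant_mapping import (
    LDParams,
    MonomorphicError,
    SNP,
    classify_coding,
    filter_catalog,
    ld_expand,
    ld_r2,
    map_snps,
    snp_density,
)


def row(snp, trait, study, pos=100):
    return GWASCatalogRow(snp, "chr1", pos, trait, study)


class TestFilterCatalog:
    def test_two_study_and_id_filters(self):
        rows = [
            row("rs1", "T", "S1"), row("rs1", "T", "S2"),
            row("rs2", "T", "S1"),
            row("", "T", "S1"), row("", "T", "S2"),
        ]
        assoc = filter_catalog(rows)
        assert [(a.snp.snp_id, a.trait) for a in assoc] == [("rs1", "T")]

    def test_same_study_twice_insufficient(self):
        assoc = filter_catalog([row("rs3", "T", "S1"), row("rs3", "T", "S1")])
        assert assoc == []

    def test_per_trait_grouping(self):
        rows = [
            row("rs4", "T1", "S1"), row("rs4", "T1", "S2"),
            row("rs4", "T2", "S3"),
        ]
        assoc = filter_catalog(rows)
        assert [(a.snp.snp_id, a.trait) for a in assoc] == [("rs4", "T1")]

    def test_position_converted_to_zero_based(self):
        (a,) = filter_catalog([row("rs1", "T", "S1", pos=100), row("rs1", "T", "S2", pos=100)])
        assert a.snp.pos == 99


class TestClassifyCoding:
    CDS = RegionSet([Interval("chr1", 100, 200)], label="CDS")

    @pytest.mark.parametrize(
        "pos,expected",
        [(150, "coding"), (50, "noncoding"), (200, "noncoding"), (100, "coding")],
    )
    def test_membership_with_halfopen_boundary(self, pos, expected):
        s = classify_coding(SNP("rs1", "chr1", pos), self.CDS)
        assert s.coding_flag == expected


class TestMapSnps:
    REGIONS = RegionSet([Interval("chr1", 100, 200), Interval("chr1", 150, 300)])

    def test_count_unique_inside(self):
        snps = [SNP("a", "chr1", 150), SNP("b", "chr1", 400), SNP("c", "chr2", 150)]
        membership, n = map_snps(snps, self.REGIONS)
        assert n == 1 and membership == {"a": True, "b": False, "c": False}

    def test_snp_in_merged_overlap_counted_once(self):
        membership, n = map_snps([SNP("a", "chr1", 175)], self.REGIONS)
        assert n == 1

    def test_empty_regions(self):
        _, n = map_snps([SNP("a", "chr1", 150)], RegionSet([]))
        assert n == 0


class TestSnpDensity:
    def test_basic(self):
        rs = RegionSet([Interval("chr1", 0, 2_000_000)])
        assert snp_density(5, rs) == pytest.approx(2.5)

    def test_zero_snps(self):
        rs = RegionSet([Interval("chr1", 0, 1000)])
        assert snp_density(0, rs) == 0.0

    def test_exact_formula(self):
        rs = RegionSet([Interval("chr1", 0, 3_500_001)])
        assert snp_density(7, rs) == pytest.approx(1.9999994, abs=1e-6)

    def test_invariant_to_splitting_region(self):
        whole = RegionSet([Interval("chr1", 0, 1_000_000)])
        split = RegionSet([Interval("chr1", 0, 400_000), Interval("chr1", 400_000, 1_000_000)])
        assert snp_density(13, whole) == snp_density(13, split)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            snp_density(1, RegionSet([]))


class TestLdR2:
    def test_perfect_ld(self):
        assert ld_r2(np.array([1, 1, 0, 0]), np.array([1, 1, 0, 0])).r2 == pytest.approx(1.0)

    def test_independence(self):
        pair = ld_r2(np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]))
        assert pair.D == pytest.approx(0.0)
        assert pair.r2 == pytest.approx(0.0)

    def test_hand_worked_example(self):
        pair = ld_r2(np.array([1, 1, 0, 0]), np.array([1, 0, 0, 0]))
        assert (pair.p_a, pair.p_b) == (0.5, 0.25)
        assert pair.D == pytest.approx(0.125)
        assert pair.r2 == pytest.approx(1 / 3)

    def test_monomorphic_rejected(self):
        with pytest.raises(MonomorphicError):
            ld_r2(np.array([1, 1, 1, 1]), np.array([0, 1, 0, 1]))

    def test_exhaustive_two_by_two_table_oracle(self):
        """All 4-haplotype column pairs against direct 2x2-count arithmetic."""
        checked = 0
        for a in itertools.product([0, 1], repeat=4):
            for b in itertools.product([0, 1], repeat=4):
                av, bv = np.array(a), np.array(b)
                if av.min() == av.max() or bv.min() == bv.max():
                    continue
                n11 = sum(1 for x, y in zip(a, b) if (x, y) == (1, 1))
                n10 = sum(1 for x, y in zip(a, b) if (x, y) == (1, 0))
                n01 = sum(1 for x, y in zip(a, b) if (x, y) == (0, 1))
                n00 = 4 - n11 - n10 - n01
                oracle = (n11 * n00 - n10 * n01) ** 2 / (
                    (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
                )
                assert ld_r2(av, bv).r2 == pytest.approx(oracle, abs=1e-12)
                checked += 1
        assert checked == 196  # 14 polymorphic columns squared

    @given(
        st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=4, max_size=40)
    )
    @settings(deadline=None, max_examples=100)
    def test_symmetry_and_allele_relabelling(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        if a.min() == a.max() or b.min() == b.max():
            return
        r_ab = ld_r2(a, b).r2
        assert ld_r2(b, a).r2 == pytest.approx(r_ab)
        assert ld_r2(1 - a, b).r2 == pytest.approx(r_ab)
        assert ld_r2(a, 1 - b).r2 == pytest.approx(r_ab)


def make_panel(ids, chroms, positions, alleles):
    return HaplotypeMatrix(
        snp_ids=ids,
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        alleles=np.array(alleles, dtype=np.uint8).T,
    )


class TestLdExpand:
    REGIONS = RegionSet([Interval("chr1", 500_000, 520_000)], label="HOT")

    def _panel(self, partner_pos, partner_col):
        # catalog SNP at 0-based 400_000 (outside), partner inside region
        return make_panel(
            ["rsCat", "rsIn"],
            ["chr1", "chr1"],
            [400_001, partner_pos + 1],
            [[1, 1, 0, 0], partner_col],
        )

    def test_identical_columns_flagged(self):
        panel = self._panel(501_000, [1, 1, 0, 0])
        snps = [SNP("rsCat", "chr1", 400_000)]
        results, skipped = ld_expand(snps, panel, self.REGIONS, LDParams())
        r = results["rsCat"]
        assert r.ld_flagged and r.best_r2 == pytest.approx(1.0)
        assert r.witness_snp == "rsIn" and skipped == 0

    def test_partner_beyond_radius_not_examined(self):
        panel = self._panel(400_000 + 126_000 + 100_001, [1, 1, 0, 0])
        # move partner inside a region far away
        regions = RegionSet([Interval("chr1", 526_000, 530_000)])
        panel = make_panel(
            ["rsCat", "rsFar"], ["chr1", "chr1"], [400_001, 526_501],
            [[1, 1, 0, 0], [1, 1, 0, 0]],
        )
        snps = [SNP("rsCat", "chr1", 400_000)]
        results, _ = ld_expand(snps, panel, regions, LDParams(radius=125_000))
        assert not results["rsCat"].ld_flagged  # 126.5 kb away: outside radius

    def test_threshold_is_strict(self):
        # construct a pair with r2 exactly 0.8: not flagged
        snps = [SNP("rsCat", "chr1", 400_000)]
        panel = self._panel(501_000, [1, 1, 0, 0])
        results, _ = ld_expand(snps, panel, self.REGIONS, LDParams(r2_threshold=1.0))
        assert results["rsCat"].best_r2 == pytest.approx(1.0)
        assert not results["rsCat"].ld_flagged  # 1.0 > 1.0 is false

    def test_snp_inside_region_not_expanded(self):
        panel = self._panel(501_000, [1, 1, 0, 0])
        snps = [SNP("rsCat", "chr1", 510_000)]
        results, _ = ld_expand(snps, panel, self.REGIONS)
        assert results["rsCat"].in_region and not results["rsCat"].ld_flagged

    def test_absent_from_panel_skipped(self):
        panel = self._panel(501_000, [1, 1, 0, 0])
        snps = [SNP("rsUnknown", "chr1", 400_000)]
        results, skipped = ld_expand(snps, panel, self.REGIONS)
        assert skipped == 1 and not results["rsUnknown"].ld_flagged

    def test_three_class_partition(self):
        """Every SNP lands in exactly one class: inside, LD-flagged, neither."""
        panel = make_panel(
            ["rsA", "rsB", "rsC", "rsIn"],
            ["chr1"] * 4,
            [400_001, 410_001, 900_001, 501_001],
            [[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 1, 0], [1, 1, 0, 0]],
        )
        snps = [
            SNP("rsA", "chr1", 400_000),   # outside, perfect LD with rsIn
            SNP("rsB", "chr1", 410_000),   # outside, independent of rsIn
            SNP("rsC", "chr1", 900_000),   # outside, beyond radius
            SNP("rsD", "chr1", 510_000),   # inside
        ]
        results, _ = ld_expand(snps, panel, self.REGIONS)
        classes = {
            sid: ("in" if r.in_region else "ld" if r.ld_flagged else "neither")
            for sid, r in results.items()
        }
        assert classes == {"rsA": "ld", "rsB": "neither", "rsC": "neither", "rsD": "in"}
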