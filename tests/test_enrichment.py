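"""Overlap statistics, the common-set shuffle null, GC skew and occupancy."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from agsmeth import enrichment as enr
from agsmeth import methylome as me
from agsmeth import simulate as sim
from conftest import bitmap, random_intervals


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestPercentOverlap:
    def test_containment_is_100(self):
        q = bed([("c", 10, 20)])
        f = bed([("c", 0, 100)])
        assert enr.percent_length_overlap(q, f) == 100.0

    def test_disjoint_is_0(self):
        assert enr.percent_length_overlap(bed([("c", 0, 10)]), bed([("c", 50, 60)])) == 0.0

    def test_matches_bitmap_oracle(self):
        rng = np.random.default_rng(1)
        q = random_intervals(rng, 20, 100_000, 3000)
        f = random_intervals(rng, 20, 100_000, 3000)
        bq, bf = bitmap(q, 100_000), bitmap(f, 100_000)
        assert enr.percent_length_overlap(q, f) == pytest.approx(100 * (bq & bf).sum() / bq.sum())

    def test_partition_of_features_sums_to_100(self):
        rng = np.random.default_rng(2)
        q = random_intervals(rng, 15, 50_000, 2000)
        f1 = bed([("chr1", 0, 20_000)])
        f2 = bed([("chr1", 20_000, 50_000)])
        total = enr.percent_length_overlap(q, f1) + enr.percent_length_overlap(q, f2)
        assert total == pytest.approx(100.0)

    def test_empty_query_signalled(self):
        with pytest.raises(me.EmptyInputError):
            enr.percent_length_overlap(bed([]), bed([("c", 0, 10)]))


class TestFoldChange:
    def test_identity(self):
        s = bed([("c", 0, 100), ("c", 500, 800)])
        f = bed([("c", 50, 600)])
        assert enr.fold_change_vs_common(s, s, f) == 1.0

    def test_arithmetic(self):
        u = bed([("c", 0, 100)])   # 30% overlap
        c = bed([("c", 1000, 2000)])  # 10% overlap
        f = bed([("c", 70, 100), ("c", 1000, 1100)])
        assert enr.fold_change_vs_common(u, c, f) == pytest.approx(3.0)

    def test_zero_common_overlap_signalled_as_inf(self):
        u = bed([("c", 0, 100)])
        c = bed([("c", 1000, 2000)])
        f = bed([("c", 0, 50)])
        assert np.isinf(enr.fold_change_vs_common(u, c, f))


class TestShuffleFromCommon:
    COMMON = bed([("c", 0, 1000), ("c", 5000, 5200), ("c", 9000, 9100)])

    def test_always_contained_in_a_common_peak(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            chrom, s, e = enr.shuffle_from_common(150, self.COMMON, rng)
            assert any(s >= cs and e <= ce for _, cs, ce in
                       self.COMMON.itertuples(index=False))

    def test_degenerate_equal_lengths_returns_whole_peak(self):
        common = bed([("c", 0, 100), ("c", 500, 600)])
        rng = np.random.default_rng(4)
        seen = set()
        for _ in range(50):
            chrom, s, e = enr.shuffle_from_common(100, common, rng)
            assert e - s == 100
            seen.add(s)
        assert seen == {0, 500}

    def test_oversized_query_returns_longest_whole(self):
        rng = np.random.default_rng(5)
        chrom, s, e = enr.shuffle_from_common(10_000, self.COMMON, rng)
        assert (s, e) == (0, 1000)

    def test_start_positions_uniform_chi_square(self):
        common = bed([("c", 0, 60)])  # 11 valid starts for a 50 bp query
        rng = np.random.default_rng(6)
        counts = np.zeros(11)
        n = 30_000
        for _ in range(n):
            _, s, _ = enr.shuffle_from_common(50, common, rng)
            counts[s] += 1
        chi2 = ((counts - n / 11) ** 2 / (n / 11)).sum()
        assert sps.chi2.sf(chi2, df=10) > 1e-4

    def test_empty_common_rejected(self):
        with pytest.raises(ValueError):
            enr.shuffle_from_common(10, bed([]), np.random.default_rng(0))


class TestMonteCarlo:
    def setup_sets(self, seed=0):
        rng = np.random.default_rng(seed)
        common = random_intervals(rng, 300, 500_000, 1500)
        feature = bed([("chr1", 0, 150_000)])
        return common, feature

    def test_minimum_p_and_planted_bias(self):
        common, feature = self.setup_sets()
        unique = bed([("chr1", int(s), int(s) + 500) for s in
                      np.linspace(0, 140_000, 100)])  # all inside the feature
        res = enr.monte_carlo_enrichment(unique, common, feature, n_shuffles=500, seed=1)
        assert res.empirical_p == pytest.approx(1 / 501)
        assert res.direction == "enriched"
        assert res.significant

    def test_bitwise_reproducible_under_seed(self):
        common, feature = self.setup_sets()
        unique = common.iloc[:50]
        r1 = enr.monte_carlo_enrichment(unique, common, feature, n_shuffles=100, seed=7)
        r2 = enr.monte_carlo_enrichment(unique, common, feature, n_shuffles=100, seed=7)
        np.testing.assert_array_equal(r1.null_pcts, r2.null_pcts)
        assert r1.empirical_p == r2.empirical_p

    def test_null_queries_give_unextreme_p(self):
        # unique set drawn by the shuffle procedure itself: p should not be small
        common, feature = self.setup_sets(2)
        rng = np.random.default_rng(8)
        unique = bed([enr.shuffle_from_common(400, common, rng) for _ in range(80)])
        res = enr.monte_carlo_enrichment(unique, common, feature, n_shuffles=200,
                                         seed=9, alternative="enriched")
        assert res.empirical_p > 1 / 201

    def test_bad_shuffle_count_rejected(self):
        common, feature = self.setup_sets()
        with pytest.raises(ValueError):
            enr.monte_carlo_enrichment(common, common, feature, n_shuffles=0)


class TestGcSkew:
    def test_poly_g_single_block_full_skew(self):
        blocks = enr.gc_skew_blocks({"c": "G" * 3000})
        assert len(blocks) == 1
        assert blocks.loc[0, "skew"] == 1.0
        assert blocks.loc[0, "strand"] == "+"

    def test_null_genome_low_coverage(self):
        g = sim.make_genome({"c": 1_000_000}, gc_fraction=0.42, seed=13)
        blocks = enr.gc_skew_blocks(g.sequences)
        frac = (blocks["end"] - blocks["start"]).sum() / 1_000_000
        assert frac < 0.05

    def test_planted_block_mostly_recovered(self):
        g = sim.make_genome({"c": 200_000}, 0.42, [("c", 80_000, 85_000, 0.3)], seed=14)
        blocks = enr.gc_skew_blocks(g.sequences)
        plus = blocks[blocks["strand"] == "+"]
        covered = sum(max(0, min(e, 85_000) - max(s, 80_000))
                      for s, e in plus[["start", "end"]].itertuples(index=False))
        assert covered >= 0.8 * 5000

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            enr.gc_skew_blocks({"c": "ACGT"}, window=0)


class TestOverlapWithSkew:
    def test_all_inside_and_none(self):
        skew = bed([("c", 0, 10_000)])
        inside = {"common": bed([("c", 100, 200), ("c", 5000, 5100)])}
        assert enr.overlap_with_skew(inside, skew)["common"] == 100.0
        assert enr.overlap_with_skew(inside, bed([]))["common"] == 0.0

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(15)
        skew = random_intervals(rng, 10, 50_000, 2000)
        peaks = random_intervals(rng, 40, 50_000, 800)
        got = enr.overlap_with_skew({"x": peaks}, skew)["x"]
        bm = bitmap(skew, 50_000)
        expect = 100 * np.mean([bm[s:e].any() for s, e in
                                peaks[["start", "end"]].itertuples(index=False)])
        assert got == pytest.approx(expect)

    def test_empty_category_flagged(self):
        out = enr.overlap_with_skew({"empty": bed([])}, bed([("c", 0, 10)]))
        assert np.isnan(out["empty"])


class TestDomainOccupancy:
    SEG = pd.DataFrame([("c", 0, 10_000, "HMD"), ("c", 10_000, 30_000, "PMD")],
                       columns=["chrom", "start", "end", "label"])

    def test_all_in_one_domain(self):
        peaks = {"x": bed([("c", 100, 300), ("c", 4000, 4400)])}
        occ = enr.domain_occupancy(peaks, self.SEG)
        assert occ.loc[0, "pct_HMD"] == 100.0

    def test_boundary_midpoint_goes_right(self):
        # midpoint exactly 10_000 -> PMD (the domain starting there)
        peaks = {"x": bed([("c", 9000, 11_000)])}
        occ = enr.domain_occupancy(peaks, self.SEG)
        assert occ.loc[0, "pct_PMD"] == 100.0

    def test_unsegmented_gap_counted_unassigned(self):
        peaks = {"x": bed([("c", 50_000, 50_100)])}
        occ = enr.domain_occupancy(peaks, self.SEG)
        assert occ.loc[0, "pct_unassigned"] == 100.0

    def test_matches_midpoint_lookup_oracle(self):
        rng = np.random.default_rng(16)
        peaks = random_intervals(rng, 50, 30_000, 500, chrom="c")
        occ = enr.domain_occupancy({"x": peaks}, self.SEG)
        mids = (peaks["start"] + peaks["end"]) // 2
        expect_pmd = 100 * np.mean([10_000 <= m < 30_000 for m in mids])
        assert occ.loc[0, "pct_PMD"] == pytest.approx(expect_pmd)


class TestFoldVsGenome:
    def test_whole_genome_query_fold_one(self):
        lengths = {"c": 100_000}
        mark = bed([("c", 0, 10_000)])
        out = enr.fold_change_vs_genome(bed([("c", 0, 100_000)]), mark, lengths, n_shuffles=10)
        assert out["fold_change"] == pytest.approx(1.0)

    def test_arithmetic(self):
        lengths = {"c": 100_000}
        mark = bed([("c", 0, 10_000)])   # 10% of genome
        query = bed([("c", 0, 3000), ("c", 50_000, 57_000)])  # 30% overlapping
        out = enr.fold_change_vs_genome(query, mark, lengths, n_shuffles=10)
        assert out["fold_change"] == pytest.approx(3.0)

    def test_null_placement_fold_near_one(self):
        rng = np.random.default_rng(17)
        lengths = {"c": 200_000}
        mark = random_intervals(rng, 20, 200_000, 3000, chrom="c")
        query = random_intervals(rng, 30, 200_000, 1000, chrom="c")
        out = enr.fold_change_vs_genome(query, mark, lengths, n_shuffles=200, seed=3)
        assert out["null_mean"] == pytest.approx(1.0, abs=0.15)

    def test_empty_mark_signalled(self):
        with pytest.raises(me.EmptyInputError):
            enr.fold_change_vs_genome(bed([("c", 0, 10)]), bed([]), {"c": 100})


class TestPeakMethylation:
    def make_methylome(self, depressed_regions=None, base=0.8, rng=None):
        rng = rng or np.random.default_rng(0)
        rows = []
        for pos in range(0, 50_000, 97):
            level = base
            for s, e in (depressed_regions or []):
                if s <= pos < e:
                    level = base - 0.3
            m = rng.binomial(12, level)
            rows.append(("c", pos, "+", "CG", m, 12))
        return pd.DataFrame(rows, columns=["chrom", "pos0", "strand", "context",
                                           "meth_count", "total_count"])

    def test_identical_methylomes_uninformative(self):
        meth = self.make_methylome()
        peaks = {"common": bed([("c", i * 1000, i * 1000 + 500) for i in range(20)])}
        out = enr.peak_methylation_by_sample(peaks, {"control": meth, "AGS": meth.copy()}, "control")
        p = out[out["sample"] == "AGS"]["p_less_than_control"].iloc[0]
        assert np.isnan(p)  # fully tied pairs carry no evidence

    def test_planted_hypomethylation_only_in_unique_peaks(self):
        rng = np.random.default_rng(18)
        unique = [(i * 2000, i * 2000 + 800) for i in range(5, 20)]
        ctrl = self.make_methylome(rng=np.random.default_rng(1))
        ags = self.make_methylome(depressed_regions=unique, rng=np.random.default_rng(2))
        peaks = {
            "ags_unique": bed([("c", s, e) for s, e in unique]),
            "common": bed([("c", 40_000 + i * 500, 40_000 + i * 500 + 300) for i in range(15)]),
        }
        out = enr.peak_methylation_by_sample(peaks, {"control": ctrl, "AGS": ags}, "control")
        p_unique = out[(out["category"] == "ags_unique") & (out["sample"] == "AGS")][
            "p_less_than_control"].iloc[0]
        p_common = out[(out["category"] == "common") & (out["sample"] == "AGS")][
            "p_less_than_control"].iloc[0]
        assert p_unique < 0.01
        assert p_common >= 0.05
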