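"""Methylome QC and quantification: merges, filters, tracks, metaplots, tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agsmeth import methylome as me


def make_records(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos0", "strand", "context",
                                       "meth_count", "total_count"])


class TestCombineStrands:
    def test_additive_merge(self):
        recs = make_records([("c", 10, "+", "CG", 3, 5), ("c", 11, "-", "CG", 2, 5)])
        out = me.combine_strands(recs)
        assert len(out) == 1
        assert out.loc[0, "pos0"] == 10
        assert (out.loc[0, "meth_count"], out.loc[0, "total_count"]) == (5, 10)

    def test_unpaired_passthrough(self):
        recs = make_records([("c", 10, "+", "CG", 3, 5)])
        out = me.combine_strands(recs)
        assert len(out) == 1 and out.loc[0, "total_count"] == 5

    def test_non_cg_dropped_from_units(self):
        recs = make_records([("c", 10, "+", "CHH", 0, 4), ("c", 20, "+", "CG", 1, 2)])
        out = me.combine_strands(recs)
        assert (out["context"] == "CG").all() and len(out) == 1

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 8), st.integers(0, 8)),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_count_conservation(self, dyads):
        rows = []
        for pos, m_p, m_m in dyads:
            rows.append(("c", 2 * pos, "+", "CG", min(m_p, 8), 8))
            rows.append(("c", 2 * pos + 1, "-", "CG", min(m_m, 8), 8))
        recs = make_records(rows)
        out = me.combine_strands(recs)
        assert out["meth_count"].sum() == recs["meth_count"].sum()
        assert out["total_count"].sum() == recs["total_count"].sum()


class TestConversionAndCoverage:
    def test_perfect_conversion(self):
        recs = make_records([("c", 1, "+", "CHH", 0, 7), ("c", 5, "+", "CHG", 0, 3)])
        assert me.conversion_rate(recs) == 1.0

    def test_direct_formula(self):
        recs = make_records([("c", 1, "+", "CHH", 1, 4)])
        assert me.conversion_rate(recs) == 0.75

    def test_no_noncpg_coverage_signalled(self):
        recs = make_records([("c", 1, "+", "CG", 1, 4)])
        with pytest.raises(me.EmptyInputError):
            me.conversion_rate(recs)

    def test_mean_coverage(self):
        recs = make_records([("c", 1, "+", "CG", 0, 4), ("c", 3, "+", "CG", 0, 6)])
        assert me.cpg_coverage(recs) == 5.0
        with pytest.raises(me.EmptyInputError):
            me.cpg_coverage(recs[recs["pos0"] > 10])

    def test_poisson_coverage_within_3_sd(self):
        rng = np.random.default_rng(0)
        totals = rng.poisson(10, size=5000)
        totals = totals[totals > 0]
        recs = make_records([("c", i, "+", "CG", 0, t) for i, t in enumerate(totals)])
        # conditional-on-positive Poisson mean is slightly above 10
        mu = 10 / (1 - np.exp(-10))
        assert me.cpg_coverage(recs) == pytest.approx(mu, abs=3 * np.sqrt(10) / np.sqrt(len(totals)))


class TestCoverageFilter:
    def test_all_below_min(self):
        recs = make_records([("c", i, "+", "CG", 0, t) for i, t in enumerate([1, 2, 3])])
        out, rep = me.coverage_filter(recs, min_cov=4)
        assert len(out) == 0 and rep["dropped_low"] == 3

    def test_extreme_outlier_dropped_high(self):
        totals = list(range(4, 1003)) + [10**6]
        recs = make_records([("c", i, "+", "CG", 0, t) for i, t in enumerate(totals)])
        out, rep = me.coverage_filter(recs, min_cov=4, upper_pct=99.9)
        assert rep["dropped_high"] == 1
        assert 10**6 not in out["total_count"].values

    def test_exact_match_with_bruteforce_percentile(self):
        rng = np.random.default_rng(5)
        totals = rng.poisson(8, size=1000) + 1
        recs = make_records([("c", i, "+", "CG", 0, t) for i, t in enumerate(totals)])
        out, _ = me.coverage_filter(recs, min_cov=4, upper_pct=99.9)
        # independent percentile: sort + linear interpolation by hand
        s = np.sort(totals)
        rank = 0.999 * (len(s) - 1)
        lo, frac = int(np.floor(rank)), rank - np.floor(rank)
        cut = s[lo] + frac * (s[lo + 1] - s[lo]) if lo + 1 < len(s) else s[lo]
        expect = {i for i, t in enumerate(totals) if 4 <= t <= cut}
        assert set(out["pos0"]) == expect

    def test_idempotent_with_fixed_bounds(self):
        rng = np.random.default_rng(6)
        recs = make_records([("c", i, "+", "CG", 0, t)
                             for i, t in enumerate(rng.poisson(10, 500) + 1)])
        once, rep = me.coverage_filter(recs)
        twice, rep2 = me.coverage_filter(once, upper_value=rep["upper_value"])
        pd.testing.assert_frame_equal(once, twice)
        assert rep2["dropped_low"] == rep2["dropped_high"] == 0

    def test_min_cov_below_one_rejected(self):
        with pytest.raises(ValueError):
            me.coverage_filter(make_records([]), min_cov=0)


class TestRegionMethylation:
    def test_agreeing_modes(self):
        recs = make_records([("c", 5, "+", "CG", 2, 4), ("c", 7, "+", "CG", 4, 4)])
        region = pd.DataFrame([("c", 0, 10)], columns=["chrom", "start", "end"])
        w = me.region_methylation(recs, region, mode="weighted")
        s = me.region_methylation(recs, region, mode="sitemean")
        assert w.loc[0, "pct_methylation"] == pytest.approx(75.0)
        assert s.loc[0, "pct_methylation"] == pytest.approx(75.0)

    def test_modes_differ_as_bruteforce_says(self):
        recs = make_records([("c", 5, "+", "CG", 1, 10), ("c", 7, "+", "CG", 9, 10),
                             ("c", 15, "+", "CG", 1, 2), ("c", 17, "+", "CG", 9, 10)])
        region = pd.DataFrame([("c", 10, 20)], columns=["chrom", "start", "end"])
        w = me.region_methylation(recs, region, "weighted").loc[0, "pct_methylation"]
        s = me.region_methylation(recs, region, "sitemean").loc[0, "pct_methylation"]
        # brute-force accumulators over the two sites in [10, 20)
        assert w == pytest.approx(100 * (1 + 9) / (2 + 10))
        assert s == pytest.approx((100 * 1 / 2 + 100 * 9 / 10) / 2)
        assert w != s

    def test_empty_interval_flagged_missing(self):
        recs = make_records([("c", 5, "+", "CG", 2, 4)])
        region = pd.DataFrame([("c", 100, 200)], columns=["chrom", "start", "end"])
        out = me.region_methylation(recs, region)
        assert np.isnan(out.loc[0, "pct_methylation"]) and out.loc[0, "n_sites"] == 0

    def test_partition_recombines_to_genome_value(self, half_and_half):
        _, _, records, _ = half_and_half
        units = me.combine_strands(records)
        parts = pd.DataFrame([("chr1", 0, 130_000), ("chr1", 130_000, 260_000),
                              ("chr1", 260_000, 400_000)], columns=["chrom", "start", "end"])
        per = me.region_methylation(units, parts)
        pooled = 100.0 * per["meth_sum"].sum() / per["total_sum"].sum()
        assert pooled == pytest.approx(me.weighted_pct(units))

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            me.region_methylation(make_records([]),
                                  pd.DataFrame([("c", 10, 5)], columns=["chrom", "start", "end"]))


class TestBinnedTrack:
    def test_constant_methylome_constant_track(self):
        recs = make_records([("c", i * 50, "+", "CG", 4, 5) for i in range(100)])
        track = me.binned_track(recs, {"c": 5000}, bin_size=1000)
        vals = track["pct_methylation"].dropna()
        assert (vals == 80.0).all()

    def test_half_open_bin_boundaries(self):
        recs = make_records([("c", 999, "+", "CG", 1, 1), ("c", 1000, "+", "CG", 0, 1)])
        track = me.binned_track(recs, {"c": 2000}, bin_size=1000)
        assert track.loc[0, "pct_methylation"] == 100.0
        assert track.loc[1, "pct_methylation"] == 0.0

    def test_count_conservation(self, half_and_half):
        _, _, records, _ = half_and_half
        units = me.combine_strands(records)
        track = me.binned_track(units, {"chr1": 400_000}, bin_size=7000)
        assert track["meth_sum"].sum() == units["meth_count"].sum()
        assert track["total_sum"].sum() == units["total_count"].sum()

    def test_bad_bin_size(self):
        with pytest.raises(ValueError):
            me.binned_track(make_records([]), {"c": 100}, bin_size=0)


class TestMetaplot:
    def test_constant_methylome_flat_profile(self):
        recs = make_records([("c", i * 10, "+", "CG", 3, 5) for i in range(2000)])
        anchors = pd.DataFrame({"chrom": "c", "start": [5000, 9000, 13000], "strand": "+"})
        prof = me.metaplot(recs, anchors, flank_bp=2000, n_bins=10)
        vals = prof["pct_methylation"].dropna()
        assert vals.max() - vals.min() < 1e-12

    def test_minus_strand_anchor_mirrors(self):
        # asymmetric methylome: methylated only downstream of position 500
        recs = make_records([("c", i, "+", "CG", (1 if i >= 500 else 0), 1) for i in range(0, 1000, 7)])
        plus = me.metaplot(recs, pd.DataFrame({"chrom": "c", "start": [500], "strand": "+"}),
                           flank_bp=200, n_bins=10)
        L = 1000
        mirrored = recs.copy()
        mirrored["pos0"] = L - 1 - mirrored["pos0"]
        minus_on_mirror = me.metaplot(mirrored,
                                      pd.DataFrame({"chrom": "c", "start": [L - 1 - 500], "strand": "-"}),
                                      flank_bp=200, n_bins=10)
        pd.testing.assert_series_equal(plus["pct_methylation"], minus_on_mirror["pct_methylation"])

    def test_step_methylome_steps_at_bin_zero(self):
        anchors = pd.DataFrame({"chrom": "c", "start": [10_000], "strand": "+"})
        recs = make_records([("c", p, "+", "CG", (4 if p >= 10_000 else 0), 5)
                             for p in range(5000, 15_000, 13)])
        prof = me.metaplot(recs, anchors, flank_bp=4000, n_bins=8)
        up = prof[prof["bin"] < 0]["pct_methylation"]
        down = prof[prof["bin"] >= 0]["pct_methylation"]
        assert (up == 0).all() and (down == 80).all()
        # brute-force per-site binning oracle
        width = 4000 // 8
        msum = np.zeros(16); tsum = np.zeros(16)
        for p in range(5000, 15_000, 13):
            rel = p - 10_000
            if -4000 <= rel < 4000:
                b = rel // width + 8
                msum[b] += 4 if p >= 10_000 else 0
                tsum[b] += 5
        np.testing.assert_allclose(prof["pct_methylation"], 100 * msum / tsum)

    def test_no_anchors_rejected(self):
        with pytest.raises(ValueError):
            me.metaplot(make_records([]), pd.DataFrame(columns=["chrom", "start", "strand"]))


def enumeration_p_less(a, b):
    """Exhaustive sign-assignment oracle for the one-sided signed-rank test."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if w <= w_obs:
            count += 1
    return count / 2 ** n


class TestPairedWilcoxon:
    def test_uniform_shift_n5_exact(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 3.0, 4.0, 5.0, 6.0]
        assert me.paired_wilcoxon_less(a, b) == pytest.approx(1 / 32)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        a = rng.normal(size=n)
        b = a + rng.normal(scale=1.5, size=n)
        assert me.paired_wilcoxon_less(a, b) == pytest.approx(enumeration_p_less(a, b))

    def test_all_tied_signalled(self):
        with pytest.raises(me.EmptyInputError):
            me.paired_wilcoxon_less([1.0, 2.0], [1.0, 2.0])

    def test_shift_down_never_increases_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        ps = [me.paired_wilcoxon_less(a - shift, b) for shift in (0.0, 0.5, 1.0, 2.0)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=60)
        b = a + 0.8 + rng.normal(scale=0.3, size=60)
        p = me.paired_wilcoxon_less(a, b)
        assert 0 < p < 1e-6
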