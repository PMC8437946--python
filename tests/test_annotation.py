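import numpy as np
import pandas as pd
import pytest

from epilayers.annotation import (
    aggregate_methylation,
    bin_time_of_replication,
    call_enhancers,
    exclude_overlapping_fragments,
    make_promoter_window,
    resolve_promoter,
    tss_distance,
)
from epilayers.core import Parameters


class TestPromoterWindow:
    @pytest.mark.parametrize(
        "tss,strand,expected",
        [
            (10_000, "+", (9_500, 10_050)),
            (10_000, "-", (9_950, 10_500)),
            (100, "+", (0, 150)),  # clipped at chromosome start
        ],
    )
    def test_window_coordinates(self, tss, strand, expected):
        loc = make_promoter_window("chr1", tss, strand)
        assert (loc.start, loc.end) == expected
        assert loc.locus_class == "promoter"

    def test_unknown_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            make_promoter_window("chr1", 1000, ".")

    def test_strands_mirror_around_tss(self):
        # the +/- windows are mirror images; width is upstream+downstream
        for tss in (5_000, 123_456):
            plus = make_promoter_window("chr1", tss, "+")
            minus = make_promoter_window("chr1", tss, "-")
            assert plus.end - plus.start == minus.end - minus.start == 550
            assert tss - plus.start == minus.end - tss


class TestResolvePromoter:
    def _frame(self, means):
        ids = [f"p{i}" for i in range(len(means))]
        normals = pd.DataFrame(
            {"n1": means, "n2": means}, index=ids, dtype=float
        )
        coords = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(len(means)) * 1000 + 500,
             "end": np.arange(len(means)) * 1000 + 1000},
            index=ids,
        )
        return ids, normals, coords

    def test_minimal_normal_methylation_wins(self):
        ids, normals, coords = self._frame([0.40, 0.05])
        assert resolve_promoter(ids, normals, coords) == "p1"

    def test_single_candidate_is_identity(self):
        ids, normals, coords = self._frame([0.3])
        assert resolve_promoter(ids, normals, coords) == "p0"

    def test_tie_breaks_to_five_prime_most(self):
        ids, normals, coords = self._frame([0.10, 0.10])
        coords.loc["p1", "start"] = 10  # p1 is now 5'-most
        assert resolve_promoter(ids, normals, coords) == "p1"

    def test_exhaustive_two_candidate_oracle(self):
        # brute force over mean pairs: result always min mean, ties 5'-most
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = rng.choice([0.1, 0.2, 0.3], size=2)
            ids, normals, coords = self._frame(list(m))
            got = resolve_promoter(ids, normals, coords)
            if m[0] == m[1]:
                expected = ids[int(np.argmin(coords["start"].to_numpy()))]
            else:
                expected = ids[int(np.argmin(m))]
            assert got == expected

    def test_no_normal_coverage_flags_unresolved(self):
        ids, normals, coords = self._frame([0.1, 0.2])
        normals.loc[:, :] = np.nan
        assert resolve_promoter(ids, normals, coords) is None


class TestAggregateMethylation:
    def test_pooled_ratio(self):
        assert aggregate_methylation([3, 7], [10, 10]) == pytest.approx(0.5)

    def test_all_methylated(self):
        assert aggregate_methylation([5, 5], [5, 5]) == 1.0

    def test_zero_coverage_is_missing(self):
        assert np.isnan(aggregate_methylation([0, 0], [0, 0]))

    def test_permutation_invariant_and_bounded(self):
        rng = np.random.default_rng(1)
        tot = rng.integers(1, 50, 20)
        meth = rng.integers(0, tot + 1)
        perm = rng.permutation(20)
        a = aggregate_methylation(meth, tot)
        b = aggregate_methylation(meth[perm], tot[perm])
        assert a == pytest.approx(b)
        assert 0.0 <= a <= 1.0

    def test_unweighted_mode_averages_fractions(self):
        # 3/10 and 1/2 -> pooled 4/12 vs unweighted mean 0.4
        assert aggregate_methylation([3, 1], [10, 2]) == pytest.approx(4 / 12)
        assert aggregate_methylation([3, 1], [10, 2], weighted=False) == pytest.approx(0.4)

    def test_fragment_overlapping_promoter_excluded(self):
        frags = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 5000], "end": [400, 5200]},
            index=["f_hit", "f_clear"],
        )
        promoters = pd.DataFrame({"chrom": ["chr1"], "start": [300], "end": [800]})
        kept = exclude_overlapping_fragments(frags, promoters)
        assert list(kept) == ["f_clear"]


class TestEnhancerCalling:
    def _coverage(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        start = np.arange(n) * 10_000
        return pd.DataFrame({
            "chrom": "chr1", "start": start, "end": start + 1000,
            "value": rng.uniform(0, 1, n),
        })

    def test_top_quantile_and_width(self):
        cov = self._coverage()
        enh = call_enhancers(cov, pd.DataFrame(columns=["chrom", "start", "end"]))
        # brute-force oracle: intervals at/above the 97% coverage quantile
        thresh = np.quantile(cov["value"], 0.97)
        assert len(enh) == int((cov["value"] >= thresh).sum())
        for e in enh:
            assert e.end - e.start == 200

    def test_recentering_midpoint(self):
        cov = pd.DataFrame(
            {"chrom": ["chr1"], "start": [10_000], "end": [11_000], "value": [1.0]}
        )
        enh = call_enhancers(cov, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert (enh[0].start, enh[0].end) == (10_400, 10_600)

    def test_promoter_proximity_exclusion(self):
        cov = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [10_000, 100_000], "end": [10_200, 100_200],
            "value": [1.0, 1.0],
        })
        promoters = pd.DataFrame(
            {"chrom": ["chr1"], "start": [11_500], "end": [12_050]}
        )  # 1.3-1.5 kb from the first interval -> excluded
        enh = call_enhancers(cov, promoters)
        assert len(enh) == 1 and enh[0].start == 100_000
        assert all(e.locus_class == "enhancer" for e in enh)

    def test_all_equal_coverage_keeps_ties(self):
        cov = self._coverage()
        cov["value"] = 0.5
        enh = call_enhancers(cov, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert len(enh) == len(cov)  # everything sits at the threshold

    def test_empty_coverage(self):
        empty = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        assert call_enhancers(empty, empty) == []


class TestTorBinning:
    def test_two_bin_median_split(self):
        tor = pd.Series(np.arange(1.0, 11.0))
        bins = bin_time_of_replication(tor, "two")
        assert bins[2] == "late"  # value 3
        assert bins[9] == "early"

    def test_value_at_median_is_late(self):
        tor = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        bins = bin_time_of_replication(tor, "two")
        assert bins[2] == "late"  # exactly the median
        # even n: values <= interpolated median also late
        tor = pd.Series([1.0, 2.0, 3.0, 4.0])
        assert bin_time_of_replication(tor, "two")[1] == "late"

    def test_three_bin_quantiles(self):
        tor = pd.Series(np.arange(1.0, 101.0))
        bins = bin_time_of_replication(tor, "three")
        assert bins[49] == "intermediate"  # value 50
        assert bins[4] == "late"
        assert bins[95] == "early"

    def test_all_missing_undefined(self):
        bins = bin_time_of_replication(pd.Series([np.nan, np.nan]), "two")
        assert bins.isna().all()


def test_tss_distance_same_chromosome_only():
    loci = pd.DataFrame(
        {"chrom": ["chr1", "chr2"], "start": [1000, 1000], "end": [1200, 1200]},
        index=["a", "b"],
    )
    tss = pd.DataFrame({"chrom": ["chr1"], "tss": [5000]})
    d = tss_distance(loci, tss)
    assert d["a"] == pytest.approx(5000 - 1100 - 1, abs=2)
    assert np.isinf(d["b"])
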