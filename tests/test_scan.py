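"""Moving averages, window tests, BH correction, and region calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from quartetscan.model import GenomeTable, SupportTrack
from quartetscan.scan import (
    ScanParams,
    bh_adjust,
    call_outlier_regions,
    moving_average,
    msc_window_test,
    scan_track,
    window_means,
)


def make_table(n, chroms=("chr1",), spacing=1000, length=500):
    rows = []
    per = [n // len(chroms)] * len(chroms)
    per[0] += n - sum(per)
    i = 0
    for chrom, k in zip(chroms, per):
        for j in range(k):
            start = 1 + j * spacing
            rows.append((f"L{i}", chrom, start, start + length - 1))
            i += 1
    return GenomeTable(pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "end"]))


class TestMovingAverage:
    def test_constant_track(self):
        t = SupportTrack(make_table(10), np.full(10, 0.4))
        ma = moving_average(t, 3)
        defined = ~np.isnan(ma.values)
        assert defined.sum() == 8
        np.testing.assert_allclose(ma.values[defined], 0.4)

    def test_percent_of_preceding_semantics(self):
        t = SupportTrack(make_table(4), np.array([1.0, 1.0, 0.0, 0.0]))
        ma = moving_average(t, 2)
        assert np.isnan(ma.values[0])
        np.testing.assert_allclose(ma.values[1:], [1.0, 0.5, 0.0])

    def test_never_bridges_chromosomes(self):
        table = make_table(20, chroms=("chr1", "chr2"))
        values = np.concatenate([np.zeros(10), np.ones(10)])
        ma = moving_average(SupportTrack(table, values), 5)
        chr2 = table.chroms == "chr2"
        defined2 = ~np.isnan(ma.values[chr2])
        # if windows bridged the boundary, early chr2 averages would
        # mix zeros in and be < 1
        np.testing.assert_allclose(ma.values[chr2][defined2], 1.0)
        assert np.isnan(ma.values[chr2][:4]).all()

    def test_skips_missing_values(self):
        vals = np.array([1.0, np.nan, 0.0, 1.0])
        ma = moving_average(SupportTrack(make_table(4), vals), 2)
        assert np.isnan(ma.values[1])
        assert ma.values[2] == pytest.approx(0.5)  # mean of loci 1 and 3

    def test_oversized_window_warns_all_missing(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            ma = moving_average(SupportTrack(make_table(5), np.ones(5)), 10)
        assert np.isnan(ma.values).all()
        assert any("exceeds" in r.message for r in caplog.records)


class TestWindowMeans:
    def test_window_count_arithmetic(self):
        w = window_means(SupportTrack(make_table(25), np.ones(25)), w=20)
        assert len(w) == 6

    def test_all_ones(self):
        w = window_means(SupportTrack(make_table(30), np.ones(30)), w=20)
        np.testing.assert_allclose(w["q"], 1.0)

    def test_matches_hand_computed_means(self, nprng):
        vals = nprng.random(40)
        w = window_means(SupportTrack(make_table(40), vals), w=10)
        for _, row in w.iterrows():
            expect = vals[row["first_row"] : row["last_row"] + 1].mean()
            assert row["q"] == pytest.approx(expect)

    def test_missing_loci_excluded_entirely(self):
        vals = np.ones(30)
        vals[5] = np.nan
        w = window_means(SupportTrack(make_table(30), vals), w=20)
        # 29 qualifying loci -> 10 windows, each averaging exactly 20
        assert len(w) == 10
        np.testing.assert_allclose(w["q"], 1.0)

    def test_short_chromosome_yields_no_windows(self):
        table = make_table(31, chroms=("chr1", "chr2"))
        w = window_means(SupportTrack(table, np.ones(31)), w=16)
        assert set(w["chrom"]) == {"chr1"}  # chr2 has 15 loci only


class TestWindowTest:
    def _wins(self, qs):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "first_qi": range(len(qs)),
                "last_qi": range(len(qs)),
                "first_row": range(len(qs)),
                "last_row": range(len(qs)),
                "start": np.arange(len(qs)) + 1,
                "end": np.arange(len(qs)) + 10,
                "q": qs,
            }
        )

    def test_null_center_gives_half(self):
        out = msc_window_test(self._wins([0.3]), mu=0.3, sigma=0.1)
        assert out["z"][0] == pytest.approx(0.0)
        assert out["p"][0] == pytest.approx(0.5)

    def test_standard_normal_quantile(self):
        out = msc_window_test(self._wins([0.3 + 2.5758 * 0.1]), mu=0.3, sigma=0.1)
        assert out["p"][0] == pytest.approx(0.005, rel=1e-3)

    def test_p_at_most_half_and_symmetric(self, nprng):
        qs = nprng.normal(0.3, 0.1, size=500)
        out = msc_window_test(self._wins(qs), mu=0.3, sigma=0.1)
        assert (out["p"] <= 0.5).all()
        flipped = msc_window_test(self._wins(0.6 - qs), mu=0.3, sigma=0.1)
        np.testing.assert_allclose(out["p"], flipped["p"])

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            msc_window_test(self._wins([0.3]), mu=0.3, sigma=0.0)

    def test_min_form_is_two_tailed_at_double_size(self, nprng):
        """Under the exchangeable null, P(p < alpha) ~ 2*alpha."""
        qs = nprng.normal(0.0, 1.0, size=40_000)
        out = msc_window_test(self._wins(qs), mu=0.0, sigma=1.0)
        for alpha in (0.01, 0.05):
            rate = (out["p"] < alpha).mean()
            se = np.sqrt(2 * alpha * (1 - 2 * alpha) / len(qs))
            assert abs(rate - 2 * alpha) < 4 * se


class TestBH:
    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0

    def test_adjusted_bounded_and_monotone(self, nprng):
        p = nprng.random(200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestRegions:
    def _wins(self, sig_mask, w=20):
        rows = []
        for i, sig in enumerate(sig_mask):
            rows.append(
                {
                    "chrom": "chr1",
                    "first_qi": i,
                    "last_qi": i + w - 1,
                    "first_row": i,
                    "last_row": i + w - 1,
                    "start": 1 + i * 1000,
                    "end": (i + w) * 1000,
                    "q": 0.9 if sig else 0.3,
                    "p": 1e-6 if sig else 0.5,
                    "p_adj": 1e-4 if sig else 0.9,
                }
            )
        return pd.DataFrame(rows)

    def test_no_significant_windows(self):
        assert call_outlier_regions(self._wins([False] * 10)) == []

    def test_single_block_index_arithmetic(self):
        mask = [False] * 5 + [True] * 30 + [False] * 5
        regions = call_outlier_regions(self._wins(mask))
        assert len(regions) == 1
        r = regions[0]
        assert r.n_windows == 30
        assert r.n_loci == 49  # 30 windows of 20 loci, step 1

    def test_gap_merging(self):
        mask = [True] * 3 + [False] * 25 + [True] * 3
        # first run: windows 0..2 covering loci 0..21; second run
        # starts at window 28: gap = 28 - 21 - 1 = 6 loci between runs
        assert len(call_outlier_regions(self._wins(mask), max_gap_loci=0)) == 2
        assert len(call_outlier_regions(self._wins(mask), max_gap_loci=5)) == 2
        assert len(call_outlier_regions(self._wins(mask), max_gap_loci=6)) == 1


class TestScanDeterminism:
    def test_identical_inputs_identical_outputs(self, nprng):
        table = make_table(300, chroms=("chr1", "chr2", "chrZ"))
        vals = nprng.random(300)
        vals[nprng.random(300) < 0.1] = np.nan
        t = SupportTrack(table, vals)
        w1, r1, mu1, s1 = scan_track(t, ScanParams())
        w2, r2, mu2, s2 = scan_track(t, ScanParams())
        pd.testing.assert_frame_equal(w1, w2)
        assert r1 == r2 and mu1 == mu2 and s1 == s2

    def test_sex_chromosomes_excluded(self, nprng):
        table = make_table(300, chroms=("chr1", "chrZ"))
        vals = nprng.random(300)
        t = SupportTrack(table, vals)
        w, _, mu, _ = scan_track(t, ScanParams())
        assert set(w["chrom"]) == {"chr1"}
        assert mu == pytest.approx(np.nanmean(vals[table.chroms == "chr1"]))
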