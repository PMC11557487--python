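"""Bulked-allele-frequency scan: per-site statistics, windows, intervals."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsamap.scan import (VARIANT_COLUMNS, IntervalCall, ScanConfig, add_bfr,
                         call_intervals, compute_baf, compute_bfr, site_filter,
                         window_scan)


class TestPerSite:
    @pytest.mark.parametrize("aa,rd,expected", [(10, 20, 0.5), (0, 15, 0.0),
                                                (55, 55, 1.0)])
    def test_baf_is_depth_fraction(self, aa, rd, expected):
        assert compute_baf(aa, rd) == expected

    def test_baf_undefined_at_zero_depth(self):
        with pytest.raises(ValueError, match="missing"):
            compute_baf(0, 0)

    @pytest.mark.parametrize("mut,wt,expected", [(1.0, 0.0, 1.0),
                                                 (0.5, 0.5, 0.0),
                                                 (0.83, 0.17, 0.66)])
    def test_bfr_is_signed_difference(self, mut, wt, expected):
        assert compute_bfr(mut, wt) == pytest.approx(expected)

    @given(aa=st.integers(0, 500), rd=st.integers(1, 500))
    def test_baf_bounds(self, aa, rd):
        aa = min(aa, rd)
        assert 0.0 <= compute_baf(aa, rd) <= 1.0

    @given(mut=st.floats(0, 1), wt=st.floats(0, 1))
    def test_bfr_bounds_and_antisymmetry(self, mut, wt):
        v = compute_bfr(mut, wt)
        assert -1.0 <= v <= 1.0
        assert v == -compute_bfr(wt, mut)


class TestSiteFilter:
    def test_rules_applied_per_bulk(self, variant_table):
        surviving = site_filter(variant_table)
        assert list(surviving["pos"]) == [200, 300]

    def test_idempotent(self, variant_table):
        once = site_filter(variant_table)
        twice = site_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_output_subset_of_input(self, variant_table):
        out = site_filter(variant_table)
        merged = out.merge(variant_table, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()


def _records(positions, bfrs, chrom="chr1"):
    n = len(positions)
    df = pd.DataFrame({
        "chrom": chrom, "pos": positions, "ref": "C", "alt": "T", "qual": 99.0,
        "aa_mut": 0, "rd_mut": 50, "aa_wt": 0, "rd_wt": 50,
        "is_indel": False, "is_missing_mut": False, "is_missing_wt": False,
    })
    df["bfr"] = bfrs
    return df


def brute_force_windows(records, config, chrom_len):
    """Independent oracle: explicit interval membership per window."""
    out = []
    start = 0
    while start < chrom_len:
        end = min(start + config.window_bp, chrom_len)
        members = [b for p, b in zip(records["pos"], records["bfr"])
                   if start < p <= end]
        out.append((start, end, len(members),
                    float(np.mean(members)) if len(members) >= config.min_variants_per_window
                    else math.nan))
        start += config.jump_bp
    return out


class TestWindowScan:
    def test_single_variant_reported_by_covering_windows(self):
        cfg = ScanConfig(window_bp=27_500_000, jump_bp=1_500_000,
                         min_variants_per_window=1)
        recs = _records([10_000_000], [1.0])
        windows = window_scan(recs, cfg, {"chr1": 30_000_000})
        covering = windows[(windows["start"] < 10_000_000)
                           & (windows["end"] >= 10_000_000)]
        assert (covering["value"] == 1.0).all()
        rest = windows.drop(covering.index)
        assert not rest["called"].any()

    def test_constant_field_gives_constant_windows(self):
        cfg = ScanConfig(window_bp=10_000_000, jump_bp=5_000_000,
                         min_variants_per_window=1)
        recs = _records(list(range(1_000_000, 30_000_000, 1_000_000)), 0.42)
        windows = window_scan(recs, cfg, {"chr1": 30_000_000})
        called = windows.loc[windows["called"], "value"]
        np.testing.assert_allclose(called, 0.42)

    def test_matches_brute_force_oracle(self, rng):
        cfg = ScanConfig(window_bp=10_000_000, jump_bp=5_000_000,
                         min_variants_per_window=1)
        pos = np.sort(rng.choice(40_000_000, 20, replace=False)) + 1
        recs = _records(pos, rng.uniform(-1, 1, 20))
        windows = window_scan(recs, cfg, {"chr1": 40_000_000})
        oracle = brute_force_windows(recs, cfg, 40_000_000)
        assert len(windows) == len(oracle)
        for (_, win), (start, end, n, value) in zip(windows.iterrows(), oracle):
            assert (win["start"], win["end"], win["n"]) == (start, end, n)
            if not math.isnan(value):
                assert win["value"] == pytest.approx(value)

    def test_variant_contribution_count(self, rng):
        # each variant lands in at most ceil(window/jump) windows
        cfg = ScanConfig(window_bp=10_000_000, jump_bp=3_000_000,
                         min_variants_per_window=1)
        pos = np.sort(rng.choice(50_000_000, 100, replace=False)) + 1
        recs = _records(pos, np.zeros(100))
        windows = window_scan(recs, cfg, {"chr1": 50_000_000})
        max_cover = -(-cfg.window_bp // cfg.jump_bp)
        coverage = [sum(1 for _, w in windows.iterrows()
                        if w["start"] < p <= w["end"]) for p in pos]
        assert all(1 <= c <= max_cover for c in coverage)
        assert windows["n"].sum() == sum(coverage)

    def test_unsorted_input_rejected(self):
        recs = _records([200, 100], [0.0, 0.0])
        with pytest.raises(ValueError, match="sorted"):
            window_scan(recs, ScanConfig(), {"chr1": 1000})

    def test_swapping_bulks_negates_values(self, rng):
        base = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.sort(rng.choice(20_000_000, 50, replace=False)) + 1,
            "ref": "C", "alt": "T", "qual": 99.0,
            "aa_mut": rng.integers(0, 30, 50), "rd_mut": 30,
            "aa_wt": rng.integers(0, 30, 50), "rd_wt": 30,
            "is_indel": False, "is_missing_mut": False, "is_missing_wt": False,
        })
        swapped = base.rename(columns={"aa_mut": "aa_wt", "aa_wt": "aa_mut",
                                       "rd_mut": "rd_wt", "rd_wt": "rd_mut"})
        cfg = ScanConfig(window_bp=5_000_000, jump_bp=2_000_000,
                         min_variants_per_window=1)
        w1 = window_scan(add_bfr(base), cfg, {"chr1": 20_000_000})
        w2 = window_scan(add_bfr(swapped), cfg, {"chr1": 20_000_000})
        np.testing.assert_allclose(w1["value"], -w2["value"])


class TestIntervals:
    def _windows(self, values, called=None, width=10, jump=5):
        rows = []
        for i, v in enumerate(values):
            rows.append({"chrom": "chr1", "start": i * jump,
                         "end": i * jump + width, "n": 10, "value": v,
                         "called": True if called is None else called[i]})
        return pd.DataFrame(rows)

    def test_no_window_qualifies(self):
        assert call_intervals(self._windows([0.1, 0.2, 0.3]), 0.5) == []

    def test_single_qualifying_window(self):
        windows = pd.DataFrame([{"chrom": "3A", "start": 584_000_000,
                                 "end": 611_500_000, "n": 20, "value": 0.6,
                                 "called": True}])
        (iv,) = call_intervals(windows, 0.5)
        assert (iv.start, iv.end) == (584_000_000, 611_500_000)
        assert iv.peak_pos == (584_000_000 + 611_500_000) // 2

    def test_overlapping_windows_merge(self):
        (iv,) = call_intervals(self._windows([0.6, 0.7, 0.55]), 0.5)
        assert (iv.start, iv.end) == (0, 20)
        assert iv.max_value == 0.7

    def test_disjoint_runs_stay_separate(self):
        windows = self._windows([0.6, 0.0, 0.0, 0.0, 0.6], width=4, jump=5)
        calls = call_intervals(windows, 0.5)
        assert len(calls) == 2

    def test_peak_tie_breaks_low_coordinate(self):
        (iv,) = call_intervals(self._windows([0.6, 0.6]), 0.5)
        assert iv.peak_pos == 5  # midpoint of the first window

    def test_no_call_windows_excluded(self):
        windows = self._windows([0.9, 0.9], called=[True, False])
        (iv,) = call_intervals(windows, 0.5)
        assert iv.end == 10


class TestConfigValidation:
    def test_jump_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            ScanConfig(window_bp=1_000_000, jump_bp=2_000_000)

    def test_interval_requires_ordered_bounds(self):
        with pytest.raises(ValueError):
            IntervalCall("chr1", 10, 10, 0.5, 0.6, 10)
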