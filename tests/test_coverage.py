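import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import regions_oracle
from zwstrata.coverage import (
    WindowSeries,
    autosomal_median,
    depth_to_windows,
    detect_regions,
    log2_ratio,
    rolling_median,
)


def series(values, chrom="Z", ws=10_000):
    return WindowSeries(chrom, ws, np.asarray(values, dtype=float))


class TestDepthToWindows:
    def test_constant_depth(self):
        df = pd.DataFrame({"chrom": "c", "pos": range(100), "depth": 30})
        ws = depth_to_windows(df, 100)["c"]
        assert ws.values.tolist() == [30.0]

    def test_absent_positions_count_as_zero(self):
        df = pd.DataFrame({"chrom": "c", "pos": range(50), "depth": 30})
        ws = depth_to_windows(df, 100, chrom_len=100)["c"]
        assert ws.values.tolist() == [15.0]

    def test_trailing_partial_window_uses_true_size(self):
        df = pd.DataFrame({"chrom": "c", "pos": range(150), "depth": 10})
        ws = depth_to_windows(df, 100, chrom_len=150)["c"]
        assert ws.values.tolist() == [10.0, 10.0]

    def test_unsorted_input_rejected(self):
        df = pd.DataFrame({"chrom": "c", "pos": [5, 3], "depth": 1})
        with pytest.raises(ValueError, match="sorted"):
            depth_to_windows(df, 100)


class TestLog2Ratio:
    def test_half_coverage_gives_minus_one(self):
        # female one Z dose vs male two: log2(15/30) = -1
        r = log2_ratio(series([15.0]), series([30.0]))
        assert r.values[0] == pytest.approx(-1.0)

    def test_equal_coverage_gives_zero(self):
        assert log2_ratio(series([30.0]), series([30.0])).values[0] == 0.0

    def test_zero_male_depth_is_missing(self):
        assert math.isnan(log2_ratio(series([30.0]), series([0.0])).values[0])

    def test_mismatched_series_rejected(self):
        with pytest.raises(ValueError):
            log2_ratio(series([1.0, 2.0]), series([1.0]))

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=20))
    def test_antisymmetry(self, depths):
        f = series(depths)
        m = series(depths[::-1])
        ab = log2_ratio(f, m).values
        ba = log2_ratio(m, f).values
        ok = ~np.isnan(ab)
        assert np.isnan(ab).tolist() == np.isnan(ba).tolist()
        assert np.allclose(ab[ok], -ba[ok])


class TestRollingMedian:
    def test_hand_example(self):
        out = rolling_median(series([1, 5, 2, 8, 3]), span=3).values
        assert math.isnan(out[0]) and math.isnan(out[4])
        assert out[1:4].tolist() == [2.0, 5.0, 3.0]

    def test_constant_series_unchanged_interior(self):
        out = rolling_median(series([4.0] * 10), span=3).values
        assert np.allclose(out[1:-1], 4.0)

    def test_span_one_is_identity(self):
        vals = [3.0, 1.0, 2.0]
        assert rolling_median(series(vals), span=1).values.tolist() == vals

    def test_span_larger_than_series_all_missing(self):
        out = rolling_median(series([1.0, 2.0]), span=5).values
        assert np.isnan(out).all()

    def test_missing_inputs_excluded(self):
        out = rolling_median(series([1.0, math.nan, 3.0, 5.0, 7.0]), span=3).values
        assert out[1] == 2.0  # median of {1, 3}
        assert out[2] == 4.0  # median of {3, 5}


class TestAutosomalMedian:
    def test_basic_and_even_count_convention(self):
        d = {"A1": series([0.0, 1.0], chrom="A1")}
        assert autosomal_median(d, ["A1"]) == 0.5
        d2 = {"A1": series([-0.1, 0.0, 0.1], chrom="A1")}
        assert autosomal_median(d2, ["A1"]) == 0.0

    def test_no_autosomes_rejected(self):
        with pytest.raises(ValueError):
            autosomal_median({}, [])


class TestDetectRegions:
    def test_enumerated_example(self):
        vals = [0.0, -0.6, -0.9, -0.4, -0.7, 0.1]
        regions = detect_regions(series(vals), threshold=-0.5)
        spans = [(r.window_span, (r.coords.start, r.coords.end)) for r in regions]
        assert spans == [((1, 2), (10_000, 30_000)), ((4, 4), (40_000, 50_000))]

    def test_one_based_report(self):
        vals = [0.0, -0.6, -0.9, 0.0]
        (r,) = detect_regions(series(vals), threshold=-0.5)
        assert r.to_1based() == (10_001, 30_000)

    def test_no_window_below_threshold(self):
        assert detect_regions(series([0.0, 0.1]), -0.5) == []

    def test_all_below_is_one_chromosome_wide_region(self):
        (r,) = detect_regions(series([-1.0] * 4), -0.5)
        assert r.window_span == (0, 3)

    def test_missing_values_terminate_runs(self):
        vals = [-1.0, math.nan, -1.0]
        regions = detect_regions(series(vals), -0.5)
        assert [r.window_span for r in regions] == [(0, 0), (2, 2)]

    def test_max_gap_merging_optional(self):
        vals = [-1.0, 0.0, -1.0]
        assert len(detect_regions(series(vals), -0.5)) == 2
        assert len(detect_regions(series(vals), -0.5, max_gap=1)) == 1

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.one_of(st.floats(-2, 2, allow_nan=False), st.just(math.nan)),
            min_size=1,
            max_size=30,
        ),
        st.floats(-1.5, 1.5, allow_nan=False),
    )
    def test_matches_run_enumeration_oracle(self, vals, threshold):
        got = [r.window_span for r in detect_regions(series(vals), threshold)]
        assert got == regions_oracle(vals, threshold)
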