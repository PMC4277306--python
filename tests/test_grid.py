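import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from streamtemp.grid import (
    DailySeries,
    RegularSeries,
    STEPS_PER_YEAR,
    aggregate_to_5day,
    moving_average,
    window_of,
)


def make_daily(values, start="2001-01-01"):
    dates = pd.date_range(start, periods=len(values), freq="D")
    return DailySeries(dates, values)


class TestAggregate:
    def test_block_is_arithmetic_mean(self):
        vals = np.full(365, np.nan)
        vals[:5] = [10, 11, 12, 13, 14]
        reg = aggregate_to_5day(make_daily(vals), min_days_present=5)
        assert reg.values[0] == pytest.approx(12.0)

    def test_partial_block_mean_and_threshold(self):
        vals = np.full(365, np.nan)
        vals[:5] = [10, np.nan, 12, np.nan, 14]
        reg3 = aggregate_to_5day(make_daily(vals), min_days_present=3)
        assert reg3.values[0] == pytest.approx(12.0)
        reg4 = aggregate_to_5day(make_daily(vals), min_days_present=4)
        assert np.isnan(reg4.values[0])

    def test_all_missing_block_is_missing_not_zero(self):
        vals = np.full(365, np.nan)
        vals[10:] = 1.0  # block 0 and part of block 1 missing
        reg = aggregate_to_5day(make_daily(vals), min_days_present=1)
        assert np.isnan(reg.values[0])
        assert reg.values[3] == 1.0

    def test_leap_day_merges_into_last_block(self):
        # 2004 is a leap year: day 366 joins block 73 (6-day block)
        vals = np.arange(366, dtype=float)
        reg = aggregate_to_5day(make_daily(vals, start="2004-01-01"))
        assert len(reg) == STEPS_PER_YEAR
        assert reg.values[-1] == pytest.approx(np.mean(vals[360:366]))

    def test_blockwise_reconstruction_exact(self):
        # on a 365-day year every block mean equals the brute-force mean
        rng = np.random.default_rng(0)
        vals = rng.normal(size=365)
        reg = aggregate_to_5day(make_daily(vals))
        brute = [vals[5 * i : 5 * i + 5].mean() for i in range(72)] + [vals[360:].mean()]
        np.testing.assert_allclose(reg.values, brute, rtol=0, atol=1e-12)

    def test_year_padding(self):
        dates = pd.date_range("2001-03-01", periods=400, freq="D")
        reg = aggregate_to_5day(DailySeries(dates, np.ones(400)))
        assert reg.n_years == 2
        assert np.isnan(reg.values[0])  # January of year 1 padded as missing

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            DailySeries(pd.DatetimeIndex([]), np.array([]))
        dates = pd.DatetimeIndex(["2001-01-01", "2001-01-02", "2001-01-05"])
        with pytest.raises(ValueError, match="2001-01-02"):
            DailySeries(dates, np.ones(3))
        with pytest.raises(ValueError, match="min_days_present"):
            aggregate_to_5day(make_daily(np.ones(365)), min_days_present=0)


class TestWindows:
    @pytest.mark.parametrize(
        "year,t,expected", [(1, 1, 1), (1, 36, 1), (1, 37, 2), (1, 73, 2), (2, 1, 3)]
    )
    def test_window_of_examples(self, year, t, expected):
        assert window_of(year, t) == expected

    def test_window_of_out_of_range(self):
        with pytest.raises(ValueError):
            window_of(1, 0)
        with pytest.raises(ValueError):
            window_of(1, 74)

    def test_windows_partition_year_into_36_and_37(self):
        wins = [window_of(1, t) for t in range(1, 74)]
        assert set(wins) == {1, 2}
        assert sorted([wins.count(1), wins.count(2)]) == [36, 37]

    def test_series_window_index_matches_scalar_op(self):
        reg = RegularSeries(1, np.zeros(2 * STEPS_PER_YEAR))
        expect = [window_of(y, t) for y, t in zip(reg.year_index, reg.t)]
        np.testing.assert_array_equal(reg.window, expect)

    def test_window_means_with_missing(self):
        vals = np.ones(STEPS_PER_YEAR)
        vals[:36] = np.nan
        vals[40] = 5.0
        reg = RegularSeries(1, vals)
        wm = reg.window_means()
        assert np.isnan(wm[0])
        assert wm[1] == pytest.approx((36 * 1 + 5) / 37)


class TestMovingAverage:
    def test_brute_force_shrinking_ends(self):
        x = np.array([1.0, 2, 3, 4, 5])
        np.testing.assert_allclose(moving_average(x, 3), [1.5, 2, 3, 4, 4.5], atol=1e-12)

    def test_width_one_is_identity_and_constant_invariant(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(moving_average(x, 1), x)
        c = np.full(20, 3.3)
        np.testing.assert_allclose(moving_average(c, 7), c, atol=1e-12)

    def test_skips_missing(self):
        x = np.array([1.0, np.nan, 3.0])
        np.testing.assert_allclose(moving_average(x, 3), [1, 2, 3], atol=1e-12)

    def test_width_exceeds_length(self):
        with pytest.raises(ValueError):
            moving_average(np.ones(3), 4)

    @given(
        hst.integers(min_value=1, max_value=9),
        hst.floats(-3, 3),
        hst.floats(-3, 3),
        hst.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_linearity(self, width, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 12))
        lhs = moving_average(a * x + b * y, width)
        rhs = a * moving_average(x, width) + b * moving_average(y, width)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_preserves_series_kind(self):
        reg = RegularSeries(1, np.arange(73.0))
        out = moving_average(reg, 5)
        assert isinstance(out, RegularSeries) and out.start_year == 1


class TestIO:
    def test_regular_roundtrip(self, tmp_path):
        vals = np.arange(73.0)
        vals[5] = np.nan
        reg = RegularSeries(2000, vals, "wt")
        p = tmp_path / "s.csv"
        reg.write_csv(p)
        back = RegularSeries.read_csv(p, "wt")
        assert back.start_year == 2000
        np.testing.assert_allclose(back.values, vals, equal_nan=True)
        assert "NA" in p.read_text()

    def test_daily_roundtrip(self, tmp_path):
        d = make_daily(np.array([1.0, np.nan, 3.0]))
        p = tmp_path / "d.csv"
        d.write_csv(p)
        back = DailySeries.read_csv(p)
        np.testing.assert_allclose(back.values, d.values, equal_nan=True)
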