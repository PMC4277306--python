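"""Time-grid handling for 5-day-step environmental series.

The modelling grid has exactly 73 five-day steps per year (73 x 5 = 365;
day 366 of leap years is folded into the final block, which then spans six
days).  Each year splits into two 6-month windows: steps 1-36 and 37-73.
Series are stored as dense arrays with NaN marking missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STEPS_PER_YEAR = 73
#: first step index (1-based) of the second half-year window
WINDOW_SPLIT = 37
WINDOWS_PER_YEAR = 2


@dataclass
class DailySeries:
    """Daily observations on a contiguous calendar grid.

    Parameters
    ----------
    dates : pandas.DatetimeIndex
        Strictly increasing, contiguous at daily step.
    values : numpy.ndarray
        Observation per day; NaN marks missing.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) == 0:
            raise ValueError("empty series")
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values length mismatch")
        deltas = np.diff(self.dates.to_numpy())
        gaps = np.nonzero(deltas != np.timedelta64(1, "D"))[0]
        if gaps.size:
            i = gaps[0]
            raise ValueError(
                f"dates not contiguous: gap after {self.dates[i].date()} "
                f"(next is {self.dates[i + 1].date()})"
            )
        if not np.isfinite(self.values).any():
            raise ValueError("series has no non-missing value")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def read_csv(cls, path) -> "DailySeries":
        df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected columns date,value")
        dates = pd.to_datetime(df.iloc[:, 0])
        return cls(pd.DatetimeIndex(dates), df.iloc[:, 1].to_numpy(dtype=float))

    def write_csv(self, path) -> None:
        pd.DataFrame(
            {"date": self.dates.strftime("%Y-%m-%d"), "value": self.values}
        ).to_csv(path, index=False, na_rep="NA")


def window_of(year: int, t: int) -> int:
    """Global 6-month window index of step ``t`` (1..73) in ``year`` (1-based).

    Window 1 covers steps 1-36 of year 1, window 2 steps 37-73, window 3
    steps 1-36 of year 2, and so on.
    """
    if not 1 <= t <= STEPS_PER_YEAR:
        raise ValueError(f"step index t={t} outside 1..{STEPS_PER_YEAR}")
    return WINDOWS_PER_YEAR * (year - 1) + (1 if t < WINDOW_SPLIT else 2)


@dataclass
class RegularSeries:
    """One variable on the fixed 5-day grid (73 steps per year)."""

    start_year: int
    values: np.ndarray
    name: str = field(default="value")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-d array")
        if self.values.size % STEPS_PER_YEAR:
            raise ValueError(
                f"length {self.values.size} is not a multiple of {STEPS_PER_YEAR}"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_years(self) -> int:
        return self.values.size // STEPS_PER_YEAR

    @property
    def n_windows(self) -> int:
        return WINDOWS_PER_YEAR * self.n_years

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    @property
    def t(self) -> np.ndarray:
        """Step index within the year, 1..73."""
        return np.tile(np.arange(1, STEPS_PER_YEAR + 1), self.n_years)

    @property
    def year_index(self) -> np.ndarray:
        """Year index, 1-based."""
        return np.repeat(np.arange(1, self.n_years + 1), STEPS_PER_YEAR)

    @property
    def year(self) -> np.ndarray:
        return self.start_year + self.year_index - 1

    @property
    def window(self) -> np.ndarray:
        """Global window index, 1-based, two windows per year."""
        return WINDOWS_PER_YEAR * (self.year_index - 1) + np.where(
            self.t < WINDOW_SPLIT, 1, 2
        )

    def window_starts(self) -> np.ndarray:
        """0-based start offset of each window in ``values``."""
        per_year = np.array([0, WINDOW_SPLIT - 1])
        return (
            np.arange(self.n_years)[:, None] * STEPS_PER_YEAR + per_year
        ).ravel()

    def window_means(self) -> np.ndarray:
        """Mean of non-missing values per 6-month window (NaN if empty)."""
        w = self.window
        out = np.full(self.n_windows, np.nan)
        for i in range(self.n_windows):
            block = self.values[w == i + 1]
            if np.isfinite(block).any():
                out[i] = np.nanmean(block)
        return out

    def slice_years(self, first: int, n_years: int) -> "RegularSeries":
        """Sub-series of ``n_years`` whole years starting at year index ``first`` (0-based)."""
        lo, hi = first * STEPS_PER_YEAR, (first + n_years) * STEPS_PER_YEAR
        return RegularSeries(self.start_year + first, self.values[lo:hi].copy(), self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year,
                "t": self.t,
                "window": self.window,
                "value": self.values,
                "missing": self.missing_mask.astype(int),
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "value") -> "RegularSeries":
        df = df.sort_values(["year", "t"])
        years = df["year"].to_numpy()
        return cls(int(years.min()), df["value"].to_numpy(dtype=float), name)

    @classmethod
    def read_csv(cls, path, name: str = "value") -> "RegularSeries":
        return cls.from_frame(pd.read_csv(path, na_values=["NA"]), name)


def aggregate_to_5day(daily: DailySeries, min_days_present: int = 3) -> RegularSeries:
    """Aggregate a daily series to the 73-step grid by 5-day arithmetic means.

    Each year is cut into 73 blocks of five days (the last block absorbs day
    366 in leap years).  A block is the mean of its non-missing days and is
    marked missing when fewer than ``min_days_present`` days are present.
    The series is padded with missing blocks so that it spans whole calendar
    years from Jan 1 of the first year to Dec 31 of the last.
    """
    if not 1 <= min_days_present <= 5:
        raise ValueError("min_days_present must be in 1..5")
    y0, y1 = daily.dates[0].year, daily.dates[-1].year
    full = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    vals = pd.Series(daily.values, index=daily.dates).reindex(full).to_numpy()

    doy = full.dayofyear.to_numpy()
    block = np.minimum((doy - 1) // 5, STEPS_PER_YEAR - 1)
    yidx = full.year.to_numpy() - y0
    flat = yidx * STEPS_PER_YEAR + block

    n = (y1 - y0 + 1) * STEPS_PER_YEAR
    present = np.isfinite(vals)
    counts = np.bincount(flat[present], minlength=n)
    sums = np.bincount(flat[present], weights=vals[present], minlength=n)
    out = np.full(n, np.nan)
    ok = counts >= min_days_present
    out[ok] = sums[ok] / counts[ok]
    return RegularSeries(y0, out)


def moving_average(series, width: int):
    """Centred moving mean over non-missing values; ends shrink.

    Accepts a :class:`DailySeries` or :class:`RegularSeries` (or a bare
    array) and returns the same kind.  Windows that contain only missing
    values stay missing.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    x = series.values if hasattr(series, "values") else np.asarray(series, float)
    if width > x.size:
        raise ValueError(f"width {width} exceeds series length {x.size}")
    sm = (
        pd.Series(x)
        .rolling(width, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    if isinstance(series, DailySeries):
        return DailySeries(series.dates, sm)
    if isinstance(series, RegularSeries):
        return RegularSeries(series.start_year, sm, series.name)
    return sm
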