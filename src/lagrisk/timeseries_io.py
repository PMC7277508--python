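"""Daily time-series container, calendar covariates, and lag matrices.

The analyses in this package operate on aligned daily records of a count
outcome (hospitalizations), an exposure (daily maximum 8-h mean ozone,
µg/m³), and meteorology (temperature °C, relative humidity %, wind speed
m/s).  This module owns the :class:`DailySeries` container and the
deterministic calendar machinery derived from it: weekday labels,
astronomical seasons, thermally-defined climatic seasons, the daily max
8-h mean aggregation of hourly ozone, and the lag matrix used by every
distributed-lag model.

Lag convention: day 0 is the event day; lag ``l`` refers to exposure ``l``
days *before* the event.  All model modules share this orientation.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("lagrisk")

__all__ = [
    "DailySeries",
    "LagMatrix",
    "ValidationError",
    "ConfigurationError",
    "read_daily_series",
    "write_daily_series",
    "classify_astronomical_season",
    "classify_climatic_season",
    "daily_max_8h_mean",
    "build_lag_matrix",
]

ASTRO_SEASONS = ("spring", "summer", "autumn", "winter")
CLIMATIC_SEASONS = ("pre-spring", "spring", "summer", "autumn", "pre-winter", "winter")
WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

#: Thermal thresholds (°C) of the Polish climatic-season convention, applied
#: to a centered moving mean of daily temperature.
CLIMATIC_THRESHOLDS = (0.0, 5.0, 15.0)
#: Window (days) of the centered moving mean used for climatic classification.
CLIMATIC_SMOOTH_WINDOW = 15

#: Minimum number of valid hours for an 8-h running-mean window to count.
MIN_VALID_HOURS_8H = 6


class ValidationError(ValueError):
    """Input data violates a structural invariant (dates, counts, ranges)."""


class ConfigurationError(ValueError):
    """Input does not match the declared layout (missing columns etc.)."""


# ---------------------------------------------------------------------------
# DailySeries
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("date", "y", "o3_8h", "temp", "rh", "wind")
DERIVED_COLUMNS = ("dow", "season_astro", "season_climatic")


@dataclass
class DailySeries:
    """Aligned daily records of counts, exposure, meteorology and calendar.

    ``data`` holds one row per consecutive calendar day with columns
    ``date, y, o3_8h, temp, rh, wind`` plus the derived ``dow``,
    ``season_astro`` and ``season_climatic`` labels.  Construction
    validates the invariants: strictly consecutive dates, integer
    non-negative counts, humidity in [0, 100], non-negative wind.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing required column(s): {missing}")
        df = df.sort_values("date", kind="stable").reset_index(drop=True)

        dates = pd.to_datetime(df["date"]).dt.normalize()
        dup = dates[dates.duplicated()]
        if len(dup):
            raise ValidationError(
                "duplicate dates: " + ", ".join(d.date().isoformat() for d in dup)
            )
        step = dates.diff().dropna()
        gaps = step[step != pd.Timedelta(days=1)]
        if len(gaps):
            missing_days: list[str] = []
            for i in gaps.index:
                lo, hi = dates.iloc[i - 1], dates.iloc[i]
                missing_days += [
                    d.date().isoformat()
                    for d in pd.date_range(lo, hi, freq="D")[1:-1]
                ]
            raise ValidationError("gap in dates, missing: " + ", ".join(missing_days))
        df["date"] = dates

        y = df["y"].to_numpy()
        if not np.all(np.isfinite(y)) or np.any(y < 0) or np.any(y != np.floor(y)):
            bad = df.loc[~(np.isfinite(y) & (y >= 0) & (y == np.floor(y))), "date"]
            raise ValidationError(
                "counts must be non-negative integers; offending dates: "
                + ", ".join(d.date().isoformat() for d in bad)
            )
        df["y"] = y.astype(np.int64)

        rh = df["rh"].to_numpy(dtype=float)
        if np.any((rh < 0) | (rh > 100)):
            raise ValidationError("relative humidity outside [0, 100]")
        wind = df["wind"].to_numpy(dtype=float)
        if np.any(wind < 0):
            raise ValidationError("negative wind speed")

        df["dow"] = pd.Categorical(
            [WEEKDAYS[d.weekday()] for d in dates], categories=WEEKDAYS
        )
        df["season_astro"] = pd.Categorical(
            [classify_astronomical_season(d.date()) for d in dates],
            categories=ASTRO_SEASONS,
        )
        if "season_climatic" not in df.columns:
            df["season_climatic"] = pd.Categorical(
                classify_climatic_season(dates, df["temp"].to_numpy(dtype=float)),
                categories=CLIMATIC_SEASONS,
            )
        else:
            df["season_climatic"] = pd.Categorical(
                df["season_climatic"], categories=CLIMATIC_SEASONS
            )
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dates(self) -> pd.Series:
        return self.data["date"]

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy()

    @property
    def o3_8h(self) -> np.ndarray:
        return self.data["o3_8h"].to_numpy(dtype=float)

    def day_index(self) -> np.ndarray:
        """0-based day index across the study window (seasonality spline axis)."""
        return np.arange(len(self.data))


# ---------------------------------------------------------------------------
# Calendar classification
# ---------------------------------------------------------------------------

def classify_astronomical_season(date: _dt.date) -> str:
    """Astronomical season of a date.

    Boundaries (fixed convention): spring Mar 21 – Jun 21, summer
    Jun 22 – Sep 22, autumn Sep 23 – Dec 21, winter Dec 22 – Mar 20.
    """
    if isinstance(date, pd.Timestamp):
        date = date.date()
    m, d = date.month, date.day
    key = (m, d)
    if (3, 21) <= key <= (6, 21):
        return "spring"
    if (6, 22) <= key <= (9, 22):
        return "summer"
    if (9, 23) <= key <= (12, 21):
        return "autumn"
    return "winter"


def classify_climatic_season(dates, temp: np.ndarray) -> list[str]:
    """Thermal (climatic) season labels from a smoothed temperature series.

    A centered 15-day moving mean of temperature is classified by the
    Polish thermal convention: < 0 °C winter; [0, 5) °C pre-spring or
    pre-winter; [5, 15) °C spring or autumn; ≥ 15 °C summer.  The
    pre-spring/pre-winter and spring/autumn ambiguity is resolved by
    calendar half-year: before July 1 the ascending label (pre-spring,
    spring), from July 1 the descending one (pre-winter, autumn).
    """
    temp = np.asarray(temp, dtype=float)
    if temp.size == 0 or np.all(np.isnan(temp)):
        raise ValidationError("temperature series is entirely missing")
    dates = pd.to_datetime(pd.Series(list(dates))).dt.normalize()
    smooth = (
        pd.Series(temp)
        .rolling(CLIMATIC_SMOOTH_WINDOW, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    t0, t1, t2 = CLIMATIC_THRESHOLDS
    labels = []
    for d, t in zip(dates, smooth):
        first_half = d.month < 7
        if t < t0:
            labels.append("winter")
        elif t < t1:
            labels.append("pre-spring" if first_half else "pre-winter")
        elif t < t2:
            labels.append("spring" if first_half else "autumn")
        else:
            labels.append("summer")
    return labels


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_daily_series(path, column_map: dict[str, str] | None = None) -> DailySeries:
    """Read a daily series from CSV.

    Expected columns (after applying ``column_map``, which maps file column
    names onto the canonical names): ``date, count, o3_8h, temp, rh, wind``
    with ISO-8601 dates.  ``count`` is accepted as an alias of ``y``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if "count" in df.columns and "y" not in df.columns:
        df = df.rename(columns={"count": "y"})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"missing required column(s) {missing}; found {list(df.columns)}"
        )
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"unparseable date column: {exc}") from exc
    return DailySeries(df[list(REQUIRED_COLUMNS)].copy())


def write_daily_series(series: DailySeries, path) -> None:
    """Write the tidy daily series (including derived columns) to CSV."""
    out = series.data.copy()
    out["date"] = out["date"].dt.date
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# 8-h aggregation
# ---------------------------------------------------------------------------

def daily_max_8h_mean(hourly: pd.DataFrame) -> pd.DataFrame:
    """Collapse hourly ozone to the daily maximum 8-h running mean.

    ``hourly`` is long format with columns ``date, hour, o3``.  For each
    calendar day the 8-h windows start at each hour of that day and use
    following hours (possibly reaching into the next day); a window needs
    at least 6 valid hours to count.  A day with no valid window yields a
    missing value and is logged.

    Returns a frame with columns ``date, o3_8h``.
    """
    for col in ("date", "hour", "o3"):
        if col not in hourly.columns:
            raise ConfigurationError(f"hourly input lacks column {col!r}")
    h = hourly.copy()
    h["date"] = pd.to_datetime(h["date"]).dt.normalize()
    h = h.sort_values(["date", "hour"], kind="stable")
    days = pd.date_range(h["date"].min(), h["date"].max(), freq="D")
    # dense hourly vector across the full span; absent hours are missing
    idx = (
        (h["date"] - days[0]).dt.days.to_numpy() * 24
        + h["hour"].to_numpy(dtype=int)
    )
    dense = np.full(len(days) * 24, np.nan)
    dense[idx] = h["o3"].to_numpy(dtype=float)

    valid = np.isfinite(dense)
    vals = np.where(valid, dense, 0.0)
    # running 8-h sums and valid-hour counts for windows starting at each hour
    kernel = np.ones(8)
    sums = np.convolve(vals, kernel)[7 : 7 + len(dense) - 7]
    counts = np.convolve(valid.astype(float), kernel)[7 : 7 + len(dense) - 7]
    means = np.full(len(dense), np.nan)
    ok = counts >= MIN_VALID_HOURS_8H
    means[: len(sums)][ok] = sums[ok] / counts[ok]

    out = []
    for i, day in enumerate(days):
        window_means = means[i * 24 : (i + 1) * 24]
        if np.all(np.isnan(window_means)):
            logger.warning("no valid 8-h window on %s", day.date())
            out.append(np.nan)
        else:
            out.append(np.nanmax(window_means))
    return pd.DataFrame({"date": days, "o3_8h": out})


# ---------------------------------------------------------------------------
# Lag matrix
# ---------------------------------------------------------------------------

@dataclass
class LagMatrix:
    """n×(L+1) matrix of lagged exposure: ``values[t, l] == x[t - l]``.

    Column ``l = 0`` is the exposure series itself; cells with ``t - l < 0``
    (incomplete lag history) are NaN.  ``valid_from`` is the first row with
    complete history.
    """

    values: np.ndarray
    L: int
    valid_from: int

    def complete_rows(self) -> np.ndarray:
        """Boolean mask of rows with no missing lag cell."""
        return ~np.isnan(self.values).any(axis=1)


def build_lag_matrix(x: np.ndarray, L: int) -> LagMatrix:
    """Build the lag matrix of a daily series for lags 0…L."""
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if L < 0:
        raise ValidationError("maximum lag must be non-negative")
    if L >= n:
        raise ValidationError(f"maximum lag L={L} must be < series length n={n}")
    values = np.full((n, L + 1), np.nan)
    for l in range(L + 1):
        values[l:, l] = x[: n - l]
    return LagMatrix(values=values, L=L, valid_from=L)
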