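"""Weekly absolute gain and relative growth-rate tables.

Given weekly mean trait values, the absolute gain at week *w* is the
difference from the previous observed week, and the relative growth
rate is that gain expressed as a percentage of the previous week's
value.  The first observed week has no gain or rate (missing, not
zero).  Gaps in the observation grid are allowed: the gain then spans
the actual interval and the interval length is recorded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import TraitSeries

__all__ = ["rate_table", "peak_gain", "surge_window", "write_rate_csv"]


def rate_table(series: TraitSeries) -> pd.DataFrame:
    """Per-week gains and relative growth rates for one trait series.

    Returns a DataFrame with columns ``week``, ``value``, ``interval``
    (weeks since the previous observation), ``gain`` (trait units over
    the interval) and ``relative_rate_pct`` (100 × gain / previous
    value).  The first row carries NaN for the three derived columns.
    Rates are kept at full precision; rounding is for display only.
    """
    if len(series) < 2:
        raise ValueError("a rate table requires at least 2 observations")
    weeks = series.weeks
    values = series.values
    interval = np.concatenate([[np.nan], np.diff(weeks)])
    gain = np.concatenate([[np.nan], np.diff(values)])
    prev = np.concatenate([[np.nan], values[:-1]])
    with np.errstate(invalid="ignore"):
        rate = 100.0 * gain / prev
    return pd.DataFrame(
        {
            "week": weeks,
            "value": values,
            "interval": interval,
            "gain": gain,
            "relative_rate_pct": rate,
        }
    )


def peak_gain(table: pd.DataFrame) -> tuple[float, float]:
    """Week and size of the maximal per-interval gain; ties go to the earliest week."""
    gains = table["gain"].to_numpy()
    if np.all(np.isnan(gains)):
        raise ValueError("rate table has no gains")
    i = int(np.nanargmax(gains))
    return float(table["week"].iloc[i]), float(gains[i])


def surge_window(
    table: pd.DataFrame, gain_threshold: float, rate_threshold: float
) -> tuple[float, float] | None:
    """Maximal contiguous run of weeks with gain and rate above thresholds.

    A week qualifies when ``gain >= gain_threshold`` and
    ``relative_rate_pct >= rate_threshold``.  Among contiguous runs of
    qualifying weeks the longest is returned as ``(first, last)`` week;
    ties go to the earliest run.  ``None`` if no week qualifies.
    """
    if gain_threshold < 0 or rate_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    gains = table["gain"].to_numpy()
    rates = table["relative_rate_pct"].to_numpy()
    with np.errstate(invalid="ignore"):
        ok = (gains >= gain_threshold) & (rates >= rate_threshold)
    best: tuple[int, int] | None = None
    start = None
    for i, flag in enumerate(np.append(ok, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if best is None or (i - start) > (best[1] - best[0] + 1):
                best = (start, i - 1)
            start = None
    if best is None:
        return None
    weeks = table["week"].to_numpy()
    return float(weeks[best[0]]), float(weeks[best[1]])


def write_rate_csv(table: pd.DataFrame, path) -> None:
    """Write a rate table as CSV (week, value, gain, relative_rate_pct)."""
    out = table[["week", "value", "gain", "relative_rate_pct"]].copy()
    out.to_csv(path, index=False, float_format="%.6g")
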