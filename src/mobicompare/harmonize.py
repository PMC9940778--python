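"""Harmonisation: weekly aggregates and baseline-relative change.

Each channel produces a level series on its own scale (a mobility index,
a median ROG in km, an activity measure).  Comparison across channels is
only meaningful on relative changes versus a common baseline week — here
the first survey field week — so every weekly series is converted to
100 * (v_t - v_base) / v_base, which is exactly 0 at the baseline week
and invariant to rescaling the channel's level.

Weeks are Monday-start ISO weeks.  Weekly values are means of available
daily values, with a minimum-days completeness rule; a centred moving
average and an alternative baseline week are available as robustness
variants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import ValidationError

__all__ = [
    "week_start",
    "weekly_aggregate",
    "relative_change_from_baseline",
    "match_to_waves",
    "moving_average",
    "BaselineError",
]


class BaselineError(ValueError):
    """The baseline week is missing or has a zero level."""


def week_start(dates) -> pd.Series | pd.Timestamp:
    """Monday of the ISO week containing each date."""
    if isinstance(dates, (str, pd.Timestamp)):
        d = pd.Timestamp(dates)
        return d - pd.Timedelta(days=int(d.dayofweek))
    dates = pd.to_datetime(pd.Series(dates))
    return dates - pd.to_timedelta(dates.dt.dayofweek, unit="D")


def weekly_aggregate(daily: pd.Series, min_days: int = 4) -> pd.Series:
    """Mean of available daily values per Monday-start week.

    Weeks with fewer than ``min_days`` non-missing daily values are
    missing.  The result is indexed by week start date.
    """
    if min_days < 1:
        raise ValidationError("min_days must be >= 1")
    daily = daily.dropna()
    wk = week_start(daily.index.to_series().reset_index(drop=True))
    grouped = pd.Series(daily.to_numpy(), index=wk.to_numpy()).groupby(level=0)
    mean = grouped.mean()
    count = grouped.size()
    out = mean.where(count >= min_days)
    out.index.name = "week"
    return out.sort_index()


def relative_change_from_baseline(
    weekly: pd.Series, baseline_week, label: str = "series"
) -> pd.Series:
    """Percent change of each week versus the baseline week.

    100 * (v_t - v_base) / v_base; the baseline week maps to exactly 0.
    Raises :class:`BaselineError` (naming ``label``) when the baseline
    week is absent, missing or has level 0.
    """
    base_wk = week_start(baseline_week)
    if base_wk not in weekly.index:
        raise BaselineError(f"{label}: baseline week {base_wk.date()} not in series")
    base = weekly.loc[base_wk]
    if pd.isna(base) or base == 0:
        raise BaselineError(f"{label}: baseline week {base_wk.date()} level is 0 or missing")
    out = 100.0 * (weekly - base) / base
    out.loc[base_wk] = 0.0
    out.name = "rel_change_pct"
    return out


def match_to_waves(weekly_panel: pd.DataFrame, schedule: pd.DataFrame) -> pd.DataFrame:
    """Align weekly series to survey waves.

    ``weekly_panel`` is long format with columns channel, subgroup, week,
    level, rel_change_pct.  Each wave's field week (Monday start) selects
    one row per channel x subgroup; weeks outside the schedule are
    dropped.  Missing channel-weeks simply yield no row for that wave.

    Returns columns channel, subgroup, wave, week_start, level,
    rel_change_pct.
    """
    sched = schedule.copy()
    sched["week_start"] = [week_start(d) for d in sched["start_date"]]
    merged = weekly_panel.merge(
        sched[["wave", "week_start"]], left_on="week", right_on="week_start", how="inner"
    )
    out = merged[
        ["channel", "subgroup", "wave", "week_start", "level", "rel_change_pct"]
    ].sort_values(["channel", "subgroup", "wave"], ignore_index=True)
    return out


def moving_average(daily: pd.Series, window: int = 7) -> pd.Series:
    """Centred moving average; edge positions with an incomplete window
    are missing.  ``window`` must be odd."""
    if window < 1 or window % 2 == 0:
        raise ValidationError("moving-average window must be a positive odd integer")
    return daily.rolling(window=window, center=True, min_periods=window).mean()
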