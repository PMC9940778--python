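"""GPS-style observation channel: place-category mobility a la Google CMR.

Opted-in persons' stays become place visits in one of the six Community
Mobility Report categories.  The daily per-category measure blends visit
counts and total length of stay (the upstream measure is documented only
as "visits and length of stay", so the blend weight alpha is an explicit
free parameter).  Daily values are expressed as percent change from a
day-of-week-specific baseline (median over a five-week window), and the
six categories sum to an additive composite index.

A bit-faithful reader/writer for the published CMR CSV dialect is
included so real report files can flow through the same pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import ACTIVITY_CATEGORIES, HOME_CATEGORY, ValidationError

__all__ = [
    "PLACE_CATEGORIES",
    "DEFAULT_CATEGORY_MAP",
    "CmrFormatError",
    "observe_place_visits",
    "daily_category_measure",
    "compute_baseline",
    "percent_change_vs_baseline",
    "composite_gps_index",
    "read_cmr_csv",
    "write_cmr_csv",
]

PLACE_CATEGORIES = (
    "grocery_and_pharmacy",
    "parks",
    "transit_stations",
    "retail_and_recreation",
    "residential",
    "workplaces",
)

#: Activity reason -> place category (home stays map to residential).
DEFAULT_CATEGORY_MAP = {
    "food": "grocery_and_pharmacy",
    "medicine": "grocery_and_pharmacy",
    "nonfood": "retail_and_recreation",
    "work": "workplaces",
    "sports": "parks",
    "friends": "retail_and_recreation",
    "pets": "parks",
    "boredom": "parks",
    "other": "transit_stations",
    HOME_CATEGORY: "residential",
}

CMR_META_COLUMNS = [
    "country_region_code",
    "country_region",
    "sub_region_1",
    "sub_region_2",
    "metro_area",
    "iso_3166_2_code",
    "census_fips_code",
    "place_id",
]
CMR_VALUE_COLUMNS = [f"{c}_percent_change_from_baseline" for c in (
    "retail_and_recreation",
    "grocery_and_pharmacy",
    "parks",
    "transit_stations",
    "workplaces",
    "residential",
)]
CMR_HEADER = CMR_META_COLUMNS + ["date"] + CMR_VALUE_COLUMNS


class CmrFormatError(ValueError):
    """A CSV does not follow the published CMR header."""


def observe_place_visits(
    stays: pd.DataFrame,
    category_map: dict[str, str] | None = None,
    optin_prob: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Turn stays of opted-in persons into place visits.

    Each of the 9 activity categories must map to one of the six place
    categories; home stays become 'residential' visits.  Visit duration is
    the stay duration.

    Returns columns device_id, place_category, date, duration_h.
    """
    cmap = dict(DEFAULT_CATEGORY_MAP if category_map is None else category_map)
    missing = (set(ACTIVITY_CATEGORIES) | {HOME_CATEGORY}) - set(cmap)
    if missing:
        raise ValidationError(f"category_map missing activity categories: {sorted(missing)}")
    bad = set(cmap.values()) - set(PLACE_CATEGORIES)
    if bad:
        raise ValidationError(f"category_map targets outside the six place categories: {sorted(bad)}")
    if not (0.0 <= optin_prob <= 1.0):
        raise ValidationError("optin_prob must be in [0, 1]")

    person_ids = np.sort(stays["person_id"].unique())
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    opted = person_ids[rng.random(len(person_ids)) < optin_prob]
    sub = stays[stays["person_id"].isin(opted)]
    return pd.DataFrame(
        {
            "device_id": sub["person_id"].to_numpy(),
            "place_category": sub["category"].map(cmap).to_numpy(),
            "date": sub["date"].to_numpy(),
            "duration_h": sub["duration_h"].to_numpy(),
        }
    )


def daily_category_measure(
    visits: pd.DataFrame,
    alpha: float = 0.5,
    dates: pd.DatetimeIndex | None = None,
) -> pd.DataFrame:
    """Daily activity measure per place category.

    value = alpha * (number of visits) + (1 - alpha) * (total duration_h).
    Category-dates without visits are 0.  ``dates`` fixes the calendar
    (defaults to the observed date range).

    Returns a wide DataFrame indexed by date with one column per place
    category.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError("alpha must be in [0, 1]")
    if dates is None:
        if visits.empty:
            raise ValidationError("cannot infer dates from an empty visit set")
        dates = pd.date_range(visits["date"].min(), visits["date"].max(), freq="D")
    if visits.empty:
        g = pd.DataFrame(index=pd.DatetimeIndex([], name="date"))
    else:
        g = (
            visits.groupby([pd.to_datetime(visits["date"]), "place_category"])["duration_h"]
            .agg(n="size", dur="sum")
            .assign(value=lambda t: alpha * t["n"] + (1.0 - alpha) * t["dur"])["value"]
            .unstack("place_category")
        )
    out = g.reindex(index=dates, columns=list(PLACE_CATEGORIES)).fillna(0.0)
    out.index.name = "date"
    return out


def compute_baseline(
    daily: pd.DataFrame, window_start, window_end
) -> pd.DataFrame:
    """Day-of-week baseline: per category, the median of the five matching
    daily values inside the window.

    The window must contain exactly five of each day of week (a five-week
    span, like Jan 3 - Feb 6, 2020).

    Returns a 7 x 6 DataFrame indexed by day of week (0 = Monday).
    """
    start, end = pd.Timestamp(window_start), pd.Timestamp(window_end)
    window = daily.loc[(daily.index >= start) & (daily.index <= end)]
    dow = window.index.dayofweek
    counts = pd.Series(dow).value_counts()
    if len(counts) != 7 or not (counts == 5).all():
        raise ValidationError(
            "baseline window must contain exactly 5 of each day of week "
            f"(got counts {counts.sort_index().to_dict()})"
        )
    base = window.groupby(dow).median()
    base.index.name = "dayofweek"
    return base[list(PLACE_CATEGORIES)]


def percent_change_vs_baseline(daily: pd.DataFrame, baseline: pd.DataFrame) -> pd.DataFrame:
    """100 * (value - baseline) / baseline per category-date.

    The baseline cell is matched on category and day of week.  A zero
    baseline yields a missing value (never +/-inf).
    """
    dow = daily.index.dayofweek
    base = baseline.reindex(dow)[daily.columns].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (daily.to_numpy() - base) / base
    pct = np.where(base > 0, pct, np.nan)
    return pd.DataFrame(pct, index=daily.index, columns=daily.columns)


def composite_gps_index(
    pct_change: pd.DataFrame, invert_residential: bool = False
) -> pd.Series:
    """Additive index: sum of the six categories' percent changes per date.

    With ``invert_residential`` the residential category enters with
    reversed sign (more time at home pulls the index down); the default
    keeps the plain sum of all six.  A date missing any category is
    missing in the composite.
    """
    missing = set(PLACE_CATEGORIES) - set(pct_change.columns)
    if missing:
        raise ValidationError(f"percent-change table missing categories: {sorted(missing)}")
    df = pct_change[list(PLACE_CATEGORIES)].copy()
    if invert_residential:
        df["residential"] = -df["residential"]
    out = df.sum(axis=1, skipna=False)
    out.name = "composite"
    return out


def write_cmr_csv(records: pd.DataFrame, path) -> None:
    """Write records in the published CMR dialect.

    ``records`` must carry 'date' and the six percent-change columns;
    absent metadata columns are written empty.  Percent changes are
    integers in the published files; missing cells stay empty.
    """
    records = records.reset_index(drop=True)
    data: dict[str, object] = {}
    for col in CMR_META_COLUMNS:
        data[col] = records[col] if col in records.columns else pd.Series([""] * len(records))
    data["date"] = pd.to_datetime(records["date"]).dt.strftime("%Y-%m-%d")
    for col in CMR_VALUE_COLUMNS:
        if col not in records.columns:
            raise CmrFormatError(f"records missing required column '{col}'")
        data[col] = records[col].astype("Float64").round().astype("Int64")
    pd.DataFrame(data)[CMR_HEADER].to_csv(path, index=False)


def read_cmr_csv(path) -> pd.DataFrame:
    """Read a CMR CSV, preserving missing cells as pandas NA.

    Raises :class:`CmrFormatError` naming the first missing required
    column if the header does not match the published dialect.
    """
    df = pd.read_csv(path, dtype={c: "string" for c in CMR_META_COLUMNS})
    for col in ["date"] + CMR_VALUE_COLUMNS:
        if col not in df.columns:
            raise CmrFormatError(f"CMR file missing required column '{col}'")
    df["date"] = pd.to_datetime(df["date"])
    for col in CMR_VALUE_COLUMNS:
        df[col] = df[col].astype("Int64")
    for col in CMR_META_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[CMR_HEADER]
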