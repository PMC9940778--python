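"""Panel-survey observation channel: self-reported mobility frequencies.

Emulates a 22-wave web panel asked how often, in the preceding 7 days,
they left home for each of the nine activity reasons, on a 5-point scale
from never (0) to daily (4).  The true number of active days per category
in a wave's field week is read off the simulated stays, perturbed by
recall noise, mapped to item codes via fixed day-count thresholds,
optionally shifted downward by a social-desirability mechanism, and
thinned by item nonresponse and panel attrition (with refreshment, so
wave sizes stay roughly constant).

Processing mirrors standard panel practice: drop the oldest age group,
listwise-delete incomplete responses, sum the nine item codes into an
additive mobility index (0-36) with food+medicine, non-food and work
subindices, and aggregate per wave with poststratification weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ACTIVITY_CATEGORIES, HOME_CATEGORY, ValidationError

__all__ = [
    "ITEM_COLUMNS",
    "ResponseModel",
    "build_wave_schedule",
    "administer_survey",
    "filter_sample",
    "mobility_index",
    "stay_home_measure",
]

logger = logging.getLogger(__name__)

ITEM_COLUMNS = [f"item_{c}" for c in ACTIVITY_CATEGORIES]

#: Active-day count -> item code: {0}->0, {1}->1, {2,3}->2, {4,5,6}->3, {7}->4.
DEFAULT_CODE_THRESHOLDS = (0, 1, 3, 6, 7)


def code_from_days(days: np.ndarray, thresholds=DEFAULT_CODE_THRESHOLDS) -> np.ndarray:
    """Map 0-7 active-day counts to 0-4 item codes via upper bounds."""
    bounds = np.asarray(thresholds)
    days = np.clip(np.asarray(days), 0, 7)
    return np.searchsorted(bounds, days, side="left").astype(int)


def build_wave_schedule(first_wave_start: str = "2020-03-23") -> pd.DataFrame:
    """22-wave field schedule: weekly (1-10), bi-weekly (11-14), monthly
    (15-22, 28-day cadence).  Each field week is a Monday-start ISO week.

    Returns columns wave, start_date, end_date.
    """
    start = pd.Timestamp(first_wave_start)
    if start.dayofweek != 0:
        raise ValidationError("first wave must start on a Monday (ISO week)")
    starts = []
    t = start
    for wave in range(1, 23):
        starts.append(t)
        if wave < 10:
            t = t + pd.Timedelta(days=7)
        elif wave < 14:
            t = t + pd.Timedelta(days=14)
        else:
            t = t + pd.Timedelta(days=28)
    return pd.DataFrame(
        {
            "wave": np.arange(1, 23),
            "start_date": starts,
            "end_date": [s + pd.Timedelta(days=6) for s in starts],
        }
    )


@dataclass
class ResponseModel:
    """Measurement-error and panel dynamics of the emulated survey.

    recall_noise_sd: SD of Gaussian noise added to the true active-day
    count before coding (days).  desirability_shift: probability that an
    item code is reported one step lower than measured; with
    ``desirability_stringency_scale`` the probability becomes
    shift * S(t)/100, i.e., under-reporting grows with policy stringency.
    item_nonresponse_prob: per-item missingness.  attrition_prob:
    per-wave probability a panelist drops out; dropped slots are refilled
    from the never-sampled pool, holding the wave size near ``panel_size``.
    """

    panel_size: int = 300
    recall_noise_sd: float = 0.7
    desirability_shift: float = 0.05
    desirability_stringency_scale: bool = False
    item_nonresponse_prob: float = 0.02
    attrition_prob: float = 0.05
    code_thresholds: tuple = DEFAULT_CODE_THRESHOLDS

    def validate(self) -> None:
        for name in ("desirability_shift", "item_nonresponse_prob", "attrition_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.recall_noise_sd < 0:
            raise ValidationError("recall_noise_sd must be >= 0")
        if self.panel_size < 1:
            raise ValidationError("panel_size must be >= 1")


def _active_days(stays: pd.DataFrame, schedule: pd.DataFrame) -> pd.DataFrame:
    """Per person x wave x category: number of field-week days with >= 1 trip,
    plus the number of days fully at home (the stay-home item's truth)."""
    trips = stays[stays["category"] != HOME_CATEGORY]
    wave_of_date = {}
    for row in schedule.itertuples(index=False):
        for d in pd.date_range(row.start_date, row.end_date, freq="D"):
            wave_of_date[d] = row.wave
    dates = pd.to_datetime(trips["date"])
    wave = dates.map(wave_of_date)
    in_wave = wave.notna()
    sub = pd.DataFrame(
        {
            "person_id": trips["person_id"][in_wave],
            "wave": wave[in_wave].astype(int),
            "category": trips["category"][in_wave],
            "date": dates[in_wave],
        }
    )
    active = (
        sub.drop_duplicates()
        .groupby(["person_id", "wave", "category"])
        .size()
        .unstack("category", fill_value=0)
        .reindex(columns=list(ACTIVITY_CATEGORIES), fill_value=0)
    )
    # days with any trip at all, for the stay-home complement
    any_trip = (
        sub[["person_id", "wave", "date"]]
        .drop_duplicates()
        .groupby(["person_id", "wave"])
        .size()
        .rename("days_out")
    )
    active = active.join(any_trip, how="left").fillna(0)
    return active


def administer_survey(
    persons: pd.DataFrame,
    stays: pd.DataFrame,
    schedule: pd.DataFrame,
    model: ResponseModel,
    seed: int,
    stringency: pd.Series | None = None,
) -> pd.DataFrame:
    """Field the panel survey over the simulated stays.

    Returns one row per retained panelist x wave with the nine item codes
    (NaN = item nonresponse), the stay-home item and demographics.
    """
    model.validate()
    stay_min, stay_max = stays["date"].min(), stays["date"].max()
    if schedule["start_date"].min() < stay_min or schedule["end_date"].max() > stay_max:
        raise ValidationError(
            "wave schedule extends outside the simulated date range "
            f"({stay_min.date()}..{stay_max.date()})"
        )
    if model.desirability_stringency_scale and stringency is None:
        raise ValidationError("stringency series required for stringency-scaled desirability")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    active = _active_days(stays, schedule)

    pool = persons["person_id"].to_numpy()
    panel = rng.choice(pool, size=min(model.panel_size, len(pool)), replace=False)
    never_sampled = list(np.setdiff1d(pool, panel))
    rng.shuffle(never_sampled)

    wave_mid_S = {}
    if stringency is not None:
        for row in schedule.itertuples(index=False):
            days = pd.date_range(row.start_date, row.end_date, freq="D")
            wave_mid_S[row.wave] = float(stringency.reindex(days).mean())

    demo = persons.set_index("person_id")[["age_group", "gender", "region"]]
    rows: list[pd.DataFrame] = []
    n_attrited = 0
    for row in schedule.itertuples(index=False):
        wave = int(row.wave)
        if wave > 1 and model.attrition_prob > 0:
            keep = rng.random(len(panel)) >= model.attrition_prob
            dropped = int((~keep).sum())
            n_attrited += dropped
            refresh = [never_sampled.pop() for _ in range(min(dropped, len(never_sampled)))]
            panel = np.concatenate([panel[keep], np.array(refresh, dtype=panel.dtype)])

        idx = pd.MultiIndex.from_product([panel, [wave]], names=["person_id", "wave"])
        truth = active.reindex(idx).fillna(0.0)
        days = truth[list(ACTIVITY_CATEGORIES)].to_numpy(dtype=float)
        if model.recall_noise_sd > 0:
            days = days + rng.normal(0.0, model.recall_noise_sd, size=days.shape)
        days = np.clip(np.rint(days), 0, 7)
        codes = code_from_days(days, model.code_thresholds).astype(float)

        shift_p = model.desirability_shift
        if model.desirability_stringency_scale:
            shift_p = shift_p * wave_mid_S[wave] / 100.0
        if shift_p > 0:
            shifted = rng.random(codes.shape) < shift_p
            codes = np.maximum(codes - shifted, 0.0)

        stay_days = np.clip(7.0 - truth["days_out"].to_numpy(dtype=float), 0, 7)
        stay_codes = code_from_days(stay_days, model.code_thresholds).astype(float)

        if model.item_nonresponse_prob > 0:
            miss = rng.random(codes.shape) < model.item_nonresponse_prob
            codes[miss] = np.nan

        frame = pd.DataFrame(codes, columns=ITEM_COLUMNS)
        frame.insert(0, "wave", wave)
        frame.insert(0, "respondent_id", panel)
        frame["item_stayhome"] = stay_codes
        rows.append(frame)

    responses = pd.concat(rows, ignore_index=True)
    responses = responses.join(demo, on="respondent_id")
    logger.info(
        "survey fielded: %d waves, %d responses, %d unique respondents, %d attrition events",
        schedule["wave"].nunique(),
        len(responses),
        responses["respondent_id"].nunique(),
        n_attrited,
    )
    return responses[
        ["respondent_id", "wave", "age_group", "gender", "region"]
        + ITEM_COLUMNS
        + ["item_stayhome"]
    ]


def filter_sample(
    responses: pd.DataFrame, max_age_group_excluded: str = "75+"
) -> pd.DataFrame:
    """Apply the analysis sample filters.

    Drops respondents in the oldest (75+) age group, then listwise-deletes
    any response with a missing value among the nine items.  The counts
    dropped by each rule are logged.
    """
    too_old = responses["age_group"] == max_age_group_excluded
    kept = responses[~too_old]
    incomplete = kept[ITEM_COLUMNS].isna().any(axis=1)
    out = kept[~incomplete].reset_index(drop=True)
    logger.info(
        "sample filter: dropped %d responses for age %s, %d listwise (missing items); "
        "%d observations from %d unique individuals retained",
        int(too_old.sum()),
        max_age_group_excluded,
        int(incomplete.sum()),
        len(out),
        out["respondent_id"].nunique(),
    )
    return out


def mobility_index(responses: pd.DataFrame) -> pd.DataFrame:
    """Additive mobility index and category subindices per response.

    index = sum of the nine item codes (0-36); food_medicine = food +
    medicine (0-8); nonfood (0-4); work (0-4).  Responses must be complete
    (run :func:`filter_sample` first).
    """
    if responses[ITEM_COLUMNS].isna().any().any():
        raise ValidationError("mobility_index requires complete responses (listwise-filtered)")
    items = responses[ITEM_COLUMNS]
    out = responses[["respondent_id", "wave"]].copy()
    out["index"] = items.sum(axis=1).astype(int)
    out["food_medicine"] = (items["item_food"] + items["item_medicine"]).astype(int)
    out["nonfood"] = items["item_nonfood"].astype(int)
    out["work"] = items["item_work"].astype(int)
    return out


def stay_home_measure(
    responses: pd.DataFrame, weights: pd.Series | None = None
) -> pd.Series:
    """Per-wave (weighted) mean of the stay-home item code.

    ``weights`` is indexed like ``responses`` (per response row); equal
    weights by default.  Waves with no valid item are missing.
    """
    v = responses["item_stayhome"]
    w = pd.Series(1.0, index=responses.index) if weights is None else weights
    ok = v.notna()
    num = (v[ok] * w[ok]).groupby(responses["wave"][ok]).sum()
    den = w[ok].groupby(responses["wave"][ok]).sum()
    out = (num / den).reindex(sorted(responses["wave"].unique()))
    out.name = "stay_home"
    return out
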