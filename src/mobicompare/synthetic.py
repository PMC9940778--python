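"""Synthetic population and ground-truth mobility.

A population of persons with demographic attributes is generated on a
planar km grid, and their daily out-of-home activity (``stays``) is driven
by a latent Poisson log-linear process: for activity category ``c`` and
person subgroup ``g``,

    log lambda_{c,g}(t) = log base_rate[c, g]
                          + stringency_coef[c] * S(t)
                          + seasonal(t) + Normal(0, noise_sd)

where ``S(t)`` is a 0-100 policy stringency index.  Every downstream
observation channel (GSM events, place-visit measures, survey
self-reports) watches these same stays, so true effects are known and
recoverable in tests.

Coordinates are planar kilometres on a synthetic grid: Euclidean geometry
makes the radius-of-gyration oracles analytic.  Days tile 00:00-24:00;
out-of-home stays are scheduled back-to-back inside a waking window and
home stays fill the remainder, so time weights always sum to 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITY_CATEGORIES",
    "PopulationSpec",
    "LatentMobilityModel",
    "ValidationError",
    "largest_remainder_counts",
    "generate_population",
    "simulate_stringency",
    "default_latent_model",
    "simulate_stays",
    "true_weekly_mobility",
    "stays_to_csv",
    "stays_from_csv",
]

#: The nine out-of-home activity categories (reasons for leaving home).
ACTIVITY_CATEGORIES = (
    "work",
    "sports",
    "friends",
    "medicine",
    "food",
    "nonfood",
    "pets",
    "boredom",
    "other",
)

#: Category label used for the residual at-home stay.
HOME_CATEGORY = "home"


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def _check_margin(name: str, margin: dict[str, float]) -> None:
    if not margin:
        raise ValidationError(f"margin '{name}' is empty")
    for level, p in margin.items():
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"margin '{name}' level '{level}' proportion {p} outside [0, 1]")
    total = sum(margin.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"margin '{name}' sums to {total}, expected 1 within 1e-9")


@dataclass
class PopulationSpec:
    """Target composition of the synthetic population.

    ``margins`` maps each weighting variable (``age_group``, ``gender``,
    ``region``) to target proportions per level; each variable's targets
    must sum to 1.  ``employment_rate_by_age`` gives the share in work per
    age group (the work category only applies to employed persons).
    ``region_boxes`` gives a planar bounding box (x0, y0, x1, y1) in km per
    region in which home locations are drawn uniformly.
    """

    n_persons: int
    margins: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "age_group": {"14-29": 0.25, "30-59": 0.50, "60-74": 0.25},
            "gender": {"female": 0.51, "male": 0.49},
            "region": {"east": 0.45, "west": 0.55},
        }
    )
    employment_rate_by_age: dict[str, float] = field(
        default_factory=lambda: {"14-29": 0.55, "30-59": 0.85, "60-74": 0.15}
    )
    region_boxes: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_persons < 1:
            raise ValidationError("n_persons must be >= 1")
        for var in ("age_group", "gender", "region"):
            if var not in self.margins:
                raise ValidationError(f"margins must include '{var}'")
        for name, margin in self.margins.items():
            _check_margin(name, margin)
        for age, p in self.employment_rate_by_age.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"employment rate for '{age}' outside [0, 1]")

    def box_for(self, region_index: int, region: str) -> tuple[float, float, float, float]:
        """Bounding box for a region; defaults tile regions along x in 50-km cells."""
        if region in self.region_boxes:
            return self.region_boxes[region]
        x0 = 50.0 * region_index
        return (x0, 0.0, x0 + 50.0, 50.0)


def largest_remainder_counts(proportions: np.ndarray, n: int) -> np.ndarray:
    """Integer counts summing to ``n`` by largest-remainder rounding.

    Each level receives ``floor(p * n)``; the remaining units go to the
    levels with the largest fractional parts (ties broken by position).
    """
    proportions = np.asarray(proportions, dtype=float)
    quotas = proportions * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        frac = quotas - np.floor(quotas)
        # stable: larger fraction first, then lower index
        order = np.lexsort((np.arange(len(frac)), -frac))
        counts[order[:remainder]] += 1
    return counts


def generate_population(
    spec: PopulationSpec, seed: int, mode: str = "quota"
) -> pd.DataFrame:
    """Generate ``spec.n_persons`` persons as a DataFrame.

    In ``quota`` mode each margin variable's level counts equal the
    largest-remainder rounding of ``margin * n`` exactly (levels are then
    randomly permuted across persons, so variables are independent).  In
    ``probabilistic`` mode levels are i.i.d. draws from the margins.

    Columns: person_id, age_group, gender, region, home_x_km, home_y_km,
    employed, work_x_km, work_y_km (NaN when not employed).
    """
    spec.validate()
    if mode not in ("quota", "probabilistic"):
        raise ValidationError(f"unknown population mode '{mode}'")
    n = spec.n_persons
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    cols: dict[str, np.ndarray] = {"person_id": np.arange(n)}
    for var in ("age_group", "gender", "region"):
        levels = list(spec.margins[var])
        props = np.array([spec.margins[var][lv] for lv in levels])
        if mode == "quota":
            counts = largest_remainder_counts(props, n)
            assigned = np.repeat(np.array(levels, dtype=object), counts)
            cols[var] = rng.permutation(assigned)
        else:
            cols[var] = rng.choice(np.array(levels, dtype=object), size=n, p=props)
    persons = pd.DataFrame(cols)

    region_levels = list(spec.margins["region"])
    home = np.empty((n, 2))
    for idx, region in enumerate(region_levels):
        mask = (persons["region"] == region).to_numpy()
        x0, y0, x1, y1 = spec.box_for(idx, region)
        m = int(mask.sum())
        home[mask, 0] = rng.uniform(x0, x1, m)
        home[mask, 1] = rng.uniform(y0, y1, m)
    persons["home_x_km"] = home[:, 0]
    persons["home_y_km"] = home[:, 1]

    emp_rate = persons["age_group"].map(spec.employment_rate_by_age).fillna(0.0).to_numpy()
    employed = rng.random(n) < emp_rate
    persons["employed"] = employed
    # workplace at a lognormal commute distance from home, uniform bearing
    dist = rng.lognormal(mean=np.log(5.0), sigma=0.7, size=n)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    persons["work_x_km"] = np.where(employed, home[:, 0] + dist * np.cos(theta), np.nan)
    persons["work_y_km"] = np.where(employed, home[:, 1] + dist * np.sin(theta), np.nan)
    return persons


def simulate_stringency(
    dates: pd.DatetimeIndex, breakpoints: list[tuple[str, float]]
) -> pd.Series:
    """Piecewise-constant stringency series S(t) in [0, 100].

    ``breakpoints`` is a list of (start_date, level); each level holds from
    its start date until the next breakpoint.  Dates before the first
    breakpoint take the first level.
    """
    if len(dates) == 0:
        raise ValidationError("dates must be nonempty")
    if not breakpoints:
        raise ValidationError("at least one stringency breakpoint is required")
    for d, level in breakpoints:
        if not (0.0 <= level <= 100.0):
            raise ValidationError(f"stringency level {level} at {d} outside [0, 100]")
    bp = sorted((pd.Timestamp(d), float(level)) for d, level in breakpoints)
    values = np.full(len(dates), bp[0][1])
    for start, level in bp:
        values[np.asarray(dates >= start)] = level
    return pd.Series(values, index=dates, name="stringency")


@dataclass
class LatentMobilityModel:
    """Parameters of the latent Poisson log-linear activity process.

    base_rate: expected trips/day per category at S=0 for the reference
    subgroup; modulated multiplicatively per age group by
    ``age_multipliers`` and set to 0 for ``work`` when not employed.
    stringency_coef: response of the log-rate per stringency point
    (non-positive: restrictions reduce mobility).  Distances are lognormal
    in km; durations are the category mean with a +/-30% uniform jitter.
    """

    base_rate: dict[str, float]
    stringency_coef: dict[str, float]
    trip_distance_logmean: dict[str, float]
    trip_distance_logsd: dict[str, float]
    trip_duration_mean: dict[str, float]
    seasonal_amplitude: float = 0.0
    seasonal_peak_doy: int = 182
    noise_sd: float = 0.0
    age_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    waking_start_h: float = 8.0
    max_active_hours: float = 15.0

    def validate(self) -> None:
        for name, d in (
            ("base_rate", self.base_rate),
            ("stringency_coef", self.stringency_coef),
            ("trip_distance_logmean", self.trip_distance_logmean),
            ("trip_distance_logsd", self.trip_distance_logsd),
            ("trip_duration_mean", self.trip_duration_mean),
        ):
            if set(d) != set(ACTIVITY_CATEGORIES):
                raise ValidationError(f"{name} must cover exactly the 9 activity categories")
        for c in ACTIVITY_CATEGORIES:
            if self.base_rate[c] < 0:
                raise ValidationError("base_rate must be >= 0")
            if self.stringency_coef[c] > 0:
                raise ValidationError("stringency_coef must be <= 0")
            if self.trip_distance_logsd[c] < 0:
                raise ValidationError("trip_distance_logsd must be >= 0")
            if self.trip_duration_mean[c] <= 0:
                raise ValidationError("trip_duration_mean must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def default_latent_model() -> LatentMobilityModel:
    """Plausible pandemic-era defaults (trips/day, km, hours)."""
    return LatentMobilityModel(
        base_rate={
            "work": 0.80,
            "sports": 0.25,
            "friends": 0.35,
            "medicine": 0.06,
            "food": 0.45,
            "nonfood": 0.30,
            "pets": 0.20,
            "boredom": 0.15,
            "other": 0.12,
        },
        stringency_coef={
            "work": -0.008,
            "sports": -0.010,
            "friends": -0.016,
            "medicine": -0.002,
            "food": -0.004,
            "nonfood": -0.016,
            "pets": -0.001,
            "boredom": -0.008,
            "other": -0.012,
        },
        trip_distance_logmean={
            "work": np.log(6.0),
            "sports": np.log(2.0),
            "friends": np.log(4.0),
            "medicine": np.log(2.0),
            "food": np.log(1.5),
            "nonfood": np.log(3.0),
            "pets": np.log(0.8),
            "boredom": np.log(1.0),
            "other": np.log(3.0),
        },
        trip_distance_logsd={c: 0.6 for c in ACTIVITY_CATEGORIES},
        trip_duration_mean={
            "work": 8.0,
            "sports": 1.5,
            "friends": 2.0,
            "medicine": 1.0,
            "food": 0.6,
            "nonfood": 1.0,
            "pets": 0.5,
            "boredom": 1.0,
            "other": 1.0,
        },
        seasonal_amplitude=0.15,
        noise_sd=0.10,
        age_multipliers={
            "14-29": {"sports": 1.4, "friends": 1.4, "boredom": 1.5, "work": 0.9},
            "60-74": {"medicine": 2.0, "sports": 0.7, "friends": 0.8, "boredom": 0.7},
        },
    )


def simulate_stays(
    persons: pd.DataFrame,
    model: LatentMobilityModel,
    stringency: pd.Series,
    dates: pd.DatetimeIndex,
    seed: int,
    regional_extra_stringency: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate daily stays for every person over ``dates``.

    Trip counts per person/day/category are Poisson with the log-linear
    rate; each trip gets a lognormal-distance destination (the workplace
    for 'work' trips of employed persons), a jittered duration and a
    sequential non-overlapping slot starting at the waking hour.  Residual
    home stays tile the rest of the 24 h day.

    ``regional_extra_stringency``, if given, is a DataFrame indexed by date
    with one column per region holding extra stringency points (a
    region-targeted lockdown); added to S(t) before clamping to [0, 100].

    The global seed is expanded into one substream per person, so results
    do not depend on iteration order.
    """
    model.validate()
    if len(dates) == 0:
        raise ValidationError("dates must be nonempty")
    S_base = stringency.reindex(dates)
    if S_base.isna().any():
        raise ValidationError("stringency series does not cover all simulation dates")

    cats = list(ACTIVITY_CATEGORIES)
    n_days = len(dates)
    doy = dates.dayofyear.to_numpy()
    seasonal = model.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - model.seasonal_peak_doy) / 365.0
    )
    coef = np.array([model.stringency_coef[c] for c in cats])
    log_dist_mu = np.array([model.trip_distance_logmean[c] for c in cats])
    log_dist_sd = np.array([model.trip_distance_logsd[c] for c in cats])
    dur_mean = np.array([model.trip_duration_mean[c] for c in cats])
    work_idx = cats.index("work")
    date_values = dates.to_numpy()

    extra_by_region: dict[str, np.ndarray] = {}
    if regional_extra_stringency is not None:
        aligned = regional_extra_stringency.reindex(dates).fillna(0.0)
        extra_by_region = {r: aligned[r].to_numpy() for r in aligned.columns}

    children = np.random.SeedSequence(seed).spawn(len(persons))
    out: list[dict[str, np.ndarray]] = []

    for i, person in enumerate(persons.itertuples(index=False)):
        rng = np.random.default_rng(children[i])
        base = np.array(
            [
                model.base_rate[c]
                * model.age_multipliers.get(person.age_group, {}).get(c, 1.0)
                for c in cats
            ]
        )
        if not person.employed:
            base = base.copy()
            base[work_idx] = 0.0
        S = S_base.to_numpy().copy()
        if person.region in extra_by_region:
            S = np.clip(S + extra_by_region[person.region], 0.0, 100.0)

        with np.errstate(divide="ignore"):
            log_lam = (
                np.log(base)[None, :]
                + coef[None, :] * S[:, None]
                + seasonal[:, None]
                + (
                    rng.normal(0.0, model.noise_sd, size=(n_days, len(cats)))
                    if model.noise_sd > 0
                    else 0.0
                )
            )
        lam = np.where(base[None, :] > 0, np.exp(log_lam), 0.0)
        counts = rng.poisson(lam)  # (n_days, n_cats)

        day_totals = counts.sum(axis=1)
        total_trips = int(day_totals.sum())

        if total_trips > 0:
            flat = counts.ravel()
            trip_day = np.repeat(np.arange(n_days * len(cats)) // len(cats), flat)
            trip_cat = np.repeat(np.arange(n_days * len(cats)) % len(cats), flat)
            dist = rng.lognormal(log_dist_mu[trip_cat], log_dist_sd[trip_cat])
            theta = rng.uniform(0.0, 2.0 * np.pi, total_trips)
            x = person.home_x_km + dist * np.cos(theta)
            y = person.home_y_km + dist * np.sin(theta)
            is_work = trip_cat == work_idx
            if person.employed and is_work.any():
                x = np.where(is_work, person.work_x_km, x)
                y = np.where(is_work, person.work_y_km, y)
            dur = dur_mean[trip_cat] * rng.uniform(0.7, 1.3, total_trips)
            # cap the active day; scale all of a day's trips if they overflow
            day_sum = np.bincount(trip_day, weights=dur, minlength=n_days)
            scale = np.where(
                day_sum > model.max_active_hours, model.max_active_hours / np.maximum(day_sum, 1e-12), 1.0
            )
            dur = dur * scale[trip_day]
            # sequential slots: start at waking hour, back to back within the day
            cum = np.cumsum(dur)
            day_offset = np.concatenate(([0.0], cum))[
                np.searchsorted(trip_day, np.arange(n_days), side="left")
            ]
            start_h = model.waking_start_h + cum - dur - day_offset[trip_day]
            trip_end = model.waking_start_h + cum - day_offset[trip_day]
        else:
            trip_day = np.empty(0, dtype=int)
            trip_cat = np.empty(0, dtype=int)
            x = y = dur = start_h = trip_end = np.empty(0)

        # home stays: full day when no trips; else before waking + after last trip
        active_days = np.flatnonzero(day_totals > 0)
        idle_days = np.flatnonzero(day_totals == 0)
        last_end = np.zeros(n_days)
        if total_trips > 0:
            np.maximum.at(last_end, trip_day, trip_end)

        n_home = len(idle_days) + 2 * len(active_days)
        home_day = np.concatenate(
            [idle_days, active_days, active_days]
        ) if n_home else np.empty(0, dtype=int)
        home_start = np.concatenate(
            [np.zeros(len(idle_days)), np.zeros(len(active_days)), last_end[active_days]]
        ) if n_home else np.empty(0)
        home_dur = np.concatenate(
            [
                np.full(len(idle_days), 24.0),
                np.full(len(active_days), model.waking_start_h),
                24.0 - last_end[active_days],
            ]
        ) if n_home else np.empty(0)

        n_rows = total_trips + n_home
        cat_arr = np.empty(n_rows, dtype=object)
        cat_arr[:total_trips] = np.array(cats, dtype=object)[trip_cat]
        cat_arr[total_trips:] = HOME_CATEGORY
        out.append(
            {
                "person_id": np.full(n_rows, person.person_id),
                "category": cat_arr,
                "x_km": np.concatenate([x, np.full(n_home, person.home_x_km)]),
                "y_km": np.concatenate([y, np.full(n_home, person.home_y_km)]),
                "day_index": np.concatenate([trip_day, home_day]),
                "start_h": np.concatenate([start_h, home_start]),
                "duration_h": np.concatenate([dur, home_dur]),
            }
        )

    stays = pd.DataFrame(
        {k: np.concatenate([p[k] for p in out]) for k in out[0]}
    )
    stays["date"] = date_values[stays.pop("day_index").to_numpy()]
    stays = stays.sort_values(
        ["person_id", "date", "start_h"], kind="mergesort", ignore_index=True
    )
    stays["start"] = stays["date"] + pd.to_timedelta(stays["start_h"], unit="h")
    return stays[
        ["person_id", "category", "x_km", "y_km", "date", "start", "start_h", "duration_h"]
    ]


def true_weekly_mobility(
    stays: pd.DataFrame, persons: pd.DataFrame, measure: str = "trip_count"
) -> pd.Series:
    """Ground-truth weekly population mean of a mobility measure.

    ``trip_count``: number of out-of-home stays per person per week.
    ``total_distance``: summed round-trip distance (2 x Euclidean distance
    from home to destination) per person per week, in km.  Used as the
    recovery target in tests; never observed by the channels.
    """
    if measure not in ("trip_count", "total_distance"):
        raise ValidationError(f"unknown measure '{measure}'")
    trips = stays[stays["category"] != HOME_CATEGORY].copy()
    week = pd.to_datetime(trips["date"]).dt.to_period("W-SUN").dt.start_time
    all_weeks = pd.to_datetime(stays["date"]).dt.to_period("W-SUN").dt.start_time.unique()
    n_persons = persons["person_id"].nunique()
    if measure == "trip_count":
        value = pd.Series(1.0, index=trips.index)
    else:
        home = persons.set_index("person_id")[["home_x_km", "home_y_km"]]
        hx = trips["person_id"].map(home["home_x_km"]).to_numpy()
        hy = trips["person_id"].map(home["home_y_km"]).to_numpy()
        value = pd.Series(
            2.0 * np.hypot(trips["x_km"].to_numpy() - hx, trips["y_km"].to_numpy() - hy),
            index=trips.index,
        )
    weekly = value.groupby(week).sum() / n_persons
    return weekly.reindex(sorted(all_weeks), fill_value=0.0).rename(measure)


def stays_to_csv(stays: pd.DataFrame, path) -> None:
    """One row per stay: person_id, category, x_km, y_km, start_iso8601, duration_h."""
    out = stays[["person_id", "category", "x_km", "y_km", "start", "duration_h"]].copy()
    out["start"] = pd.to_datetime(out["start"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.6f")


def stays_from_csv(path) -> pd.DataFrame:
    stays = pd.read_csv(path, parse_dates=["start"])
    stays["date"] = stays["start"].dt.normalize()
    stays["start_h"] = (stays["start"] - stays["date"]).dt.total_seconds() / 3600.0
    return stays[
        ["person_id", "category", "x_km", "y_km", "date", "start", "start_h", "duration_h"]
    ]
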