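"""End-to-end pipeline: simulate -> observe -> harmonize -> compare.

One seeded, configured run writes a directory of CSV outputs plus a log:

    persons.csv, stringency.csv, stays.csv            (simulate)
    gsm_events.csv, gsm_daily.csv, gps_daily.csv,
    cmr_synthetic.csv, survey_responses.csv           (observe)
    gsm_weekly.csv, aligned_panel.csv                 (harmonize)
    correlations.csv, fe_regression.csv, did.csv      (compare)

Stages read their inputs from the run directory, so each stage can be
re-run from cached intermediates.  All outputs are deterministic for a
fixed seed and config.

Subgroup labels in the aligned panel: ``population``, ``gender:<level>``,
``age:<level>``, ``region:<level>`` and the category comparisons
``cat:food_medicine``, ``cat:nonfood``, ``cat:work`` (survey subindices
matched to the grocery & pharmacy, retail & recreation and workplaces
place categories).
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, gps, gsm, harmonize, survey, synthetic, weighting
from .config import RunConfig
from .synthetic import ValidationError

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_observe",
    "stage_harmonize",
    "stage_compare",
]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

#: survey subindex -> matched place category
CATEGORY_PAIRS = {
    "food_medicine": "grocery_and_pharmacy",
    "nonfood": "retail_and_recreation",
    "work": "workplaces",
}


def _dates(cfg: RunConfig) -> pd.DatetimeIndex:
    return pd.date_range(cfg.start_date, cfg.end_date, freq="D")


def _seeds(cfg: RunConfig) -> dict[str, int]:
    """Stable per-stage substreams derived from the run seed."""
    root = np.random.SeedSequence(cfg.seed)
    names = ["population", "stays", "gsm", "gps", "survey"]
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, root.spawn(len(names)))
    }


# ---------------------------------------------------------------- simulate


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    cfg.validate()
    seeds = _seeds(cfg)
    dates = _dates(cfg)

    persons = synthetic.generate_population(
        cfg.population, seed=seeds["population"], mode=cfg.population_mode
    )
    stringency = synthetic.simulate_stringency(dates, cfg.stringency_breakpoints)

    extra = None
    if cfg.lockdown is not None:
        extra = pd.DataFrame(0.0, index=dates, columns=list(cfg.population.margins["region"]))
        window = (dates >= pd.Timestamp(cfg.lockdown.start)) & (
            dates <= pd.Timestamp(cfg.lockdown.end)
        )
        for region in cfg.lockdown.regions:
            extra.loc[window, region] = cfg.lockdown.extra_stringency

    stays = synthetic.simulate_stays(
        persons,
        cfg.latent_model,
        stringency,
        dates,
        seed=seeds["stays"],
        regional_extra_stringency=extra,
    )
    logger.info("simulate: %d persons, %d stays over %d days", len(persons), len(stays), len(dates))

    persons.to_csv(outdir / "persons.csv", index=False, float_format=FLOAT_FMT)
    stringency.rename_axis("date").reset_index().to_csv(
        outdir / "stringency.csv", index=False, float_format=FLOAT_FMT
    )
    synthetic.stays_to_csv(stays, outdir / "stays.csv")


# ----------------------------------------------------------------- observe


def stage_observe(cfg: RunConfig, outdir: Path) -> None:
    seeds = _seeds(cfg)
    persons = pd.read_csv(outdir / "persons.csv")
    stays = synthetic.stays_from_csv(outdir / "stays.csv")
    dates = _dates(cfg)

    # GSM channel
    grid = gsm.TowerGrid(spacing_km=cfg.gsm.tower_spacing_km)
    events = gsm.observe_gsm_events(
        stays,
        grid,
        event_rate_per_hour=cfg.gsm.event_rate_per_hour,
        coverage_prob=cfg.gsm.coverage_prob,
        seed=seeds["gsm"],
        tower_jitter_sd_km=cfg.gsm.tower_jitter_sd_km,
    )
    rogs = gsm.device_day_rog(events, min_events=cfg.gsm.min_events)
    gsm.events_to_csv(events, outdir / "gsm_events.csv")
    rogs.assign(date=lambda d: pd.to_datetime(d["date"]).dt.strftime("%Y-%m-%d")).to_csv(
        outdir / "gsm_daily.csv", index=False, float_format=FLOAT_FMT
    )
    logger.info("observe/gsm: %d events, %d device-days", len(events), len(rogs))

    # GPS channel: per-region daily category measures (region from the person)
    visits = gps.observe_place_visits(
        stays, optin_prob=cfg.gps.optin_prob, seed=seeds["gps"]
    )
    region_of = persons.set_index("person_id")["region"]
    visits["region"] = visits["device_id"].map(region_of)
    daily_frames = []
    for region, sub in itertools.chain(
        [("all", visits)], visits.groupby("region", sort=True)
    ):
        daily = gps.daily_category_measure(sub, alpha=cfg.gps.alpha, dates=dates)
        daily = daily.reset_index().assign(region=region)
        daily_frames.append(daily)
    gps_daily = pd.concat(daily_frames, ignore_index=True)
    gps_daily["date"] = pd.to_datetime(gps_daily["date"]).dt.strftime("%Y-%m-%d")
    gps_daily.to_csv(outdir / "gps_daily.csv", index=False, float_format=FLOAT_FMT)
    logger.info("observe/gps: %d visits from %d devices", len(visits), visits["device_id"].nunique())

    # CMR-dialect export of the country-level percent changes
    daily_all = gps.daily_category_measure(visits, alpha=cfg.gps.alpha, dates=dates)
    baseline = gps.compute_baseline(
        daily_all, cfg.gps.baseline_window_start, cfg.gps.baseline_window_end
    )
    pct = gps.percent_change_vs_baseline(daily_all, baseline)
    records = pct.reset_index().rename(
        columns={c: f"{c}_percent_change_from_baseline" for c in gps.PLACE_CATEGORIES}
    )
    records["country_region_code"] = "XX"
    records["country_region"] = "Synthetica"
    gps.write_cmr_csv(records, outdir / "cmr_synthetic.csv")

    # Survey channel
    schedule = survey.build_wave_schedule(cfg.first_wave_start)
    stringency = pd.read_csv(outdir / "stringency.csv", parse_dates=["date"]).set_index(
        "date"
    )["stringency"]
    responses = survey.administer_survey(
        persons, stays, schedule, cfg.survey, seed=seeds["survey"], stringency=stringency
    )
    responses.to_csv(outdir / "survey_responses.csv", index=False, float_format="%.0f")
    schedule.assign(
        start_date=lambda d: d["start_date"].dt.strftime("%Y-%m-%d"),
        end_date=lambda d: d["end_date"].dt.strftime("%Y-%m-%d"),
    ).to_csv(outdir / "wave_schedule.csv", index=False)


# --------------------------------------------------------------- harmonize


def _gsm_group_series(
    rogs: pd.DataFrame, persons: pd.DataFrame, targets: dict
) -> dict[str, pd.Series]:
    """Daily GSM level series per subgroup label.

    Subgroup daily medians are computed first; the population and
    marginal (gender / age) series are share-weighted combinations of the
    age x gender cell medians, with cell shares taken as the product of
    the target margins (the raking fixed point for independent margins).
    """
    cell = gsm.daily_median_rog(rogs, persons, grouping="age_group:gender")
    cell[["age", "gender"]] = cell["group"].str.split(":", expand=True)
    age_t, gender_t = targets["age_group"], targets["gender"]
    cell["share"] = cell["age"].map(age_t) * cell["gender"].map(gender_t)

    series: dict[str, pd.Series] = {}

    def combine(df: pd.DataFrame) -> pd.Series:
        num = (df["median_rog_km"] * df["share"]).groupby(df["date"]).sum()
        den = df["share"].groupby(df["date"]).sum()
        return num / den

    series["population"] = combine(cell)
    for g in gender_t:
        series[f"gender:{g}"] = combine(cell[cell["gender"] == g])
    for a in age_t:
        series[f"age:{a}"] = combine(cell[cell["age"] == a])
    region = gsm.daily_median_rog(rogs, persons, grouping="region")
    for r, sub in region.groupby("group"):
        series[f"region:{r}"] = sub.set_index("date")["median_rog_km"]
    return series


def _survey_wave_series(
    responses: pd.DataFrame, schedule: pd.DataFrame, targets: dict
) -> dict[str, pd.Series]:
    """Per-subgroup wave series of the weighted mean mobility (sub)index,
    indexed by the wave's field-week start."""
    filtered = survey.filter_sample(responses)
    idx = survey.mobility_index(filtered)
    data = filtered.join(idx[["index", "food_medicine", "nonfood", "work"]])
    week_of_wave = dict(
        zip(schedule["wave"], [harmonize.week_start(d) for d in schedule["start_date"]])
    )

    weights = pd.Series(np.nan, index=data.index)
    for wave, sub in data.groupby("wave"):
        rw = weighting.rake_weights(
            sub[["age_group", "gender", "region"]], targets
        )
        weights.loc[sub.index] = rw.weights
        logger.info(
            "raking wave %d: %d units, %d iterations, max margin error %.2e",
            wave, len(sub), rw.iterations, rw.max_margin_error,
        )
    data["weight"] = weights

    def wave_series(sub: pd.DataFrame, col: str) -> pd.Series:
        vals = {
            week_of_wave[wave]: weighting.weighted_aggregate(g[col], g["weight"])
            for wave, g in sub.groupby("wave")
        }
        return pd.Series(vals).sort_index()

    series = {"population": wave_series(data, "index")}
    for g, sub in data.groupby("gender"):
        series[f"gender:{g}"] = wave_series(sub, "index")
    for a, sub in data.groupby("age_group"):
        series[f"age:{a}"] = wave_series(sub, "index")
    for r, sub in data.groupby("region"):
        series[f"region:{r}"] = wave_series(sub, "index")
    for subindex in CATEGORY_PAIRS:
        series[f"cat:{subindex}"] = wave_series(data, subindex)
    return series


def _gps_level_series(
    gps_daily: pd.DataFrame, cfg: RunConfig
) -> dict[str, pd.Series]:
    """Daily GPS activity-level series per subgroup label.

    Per region (and overall), percent change from the day-of-week
    baseline is computed per category; the channel level is the mean over
    categories of (100 + pct_change), a positive activity index whose
    relative changes track the composite.  Categories with an undefined
    percent change (zero baseline cell, possible in sparse regions) drop
    out of that date's mean rather than poisoning it.  Category subgroups
    use (100 + pct_change) of the matched single category.
    """
    series: dict[str, pd.Series] = {}
    for region, sub in gps_daily.groupby("region"):
        daily = sub.set_index(pd.to_datetime(sub["date"]))[list(gps.PLACE_CATEGORIES)]
        baseline = gps.compute_baseline(
            daily, cfg.gps.baseline_window_start, cfg.gps.baseline_window_end
        )
        pct = gps.percent_change_vs_baseline(daily, baseline)
        level = (100.0 + pct).mean(axis=1, skipna=True)
        if region == "all":
            series["population"] = level
            for subindex, place in CATEGORY_PAIRS.items():
                series[f"cat:{subindex}"] = 100.0 + pct[place]
        else:
            series[f"region:{region}"] = level
    return series


def stage_harmonize(cfg: RunConfig, outdir: Path) -> None:
    persons = pd.read_csv(outdir / "persons.csv")
    rogs = pd.read_csv(outdir / "gsm_daily.csv", parse_dates=["date"])
    gps_daily = pd.read_csv(outdir / "gps_daily.csv", parse_dates=["date"])
    responses = pd.read_csv(outdir / "survey_responses.csv")
    schedule = pd.read_csv(
        outdir / "wave_schedule.csv", parse_dates=["start_date", "end_date"]
    )
    targets = cfg.targets()
    baseline_week = cfg.harmonize.baseline_week

    channel_series: dict[str, dict[str, pd.Series]] = {
        "gsm": _gsm_group_series(rogs, persons, targets),
        "gps": _gps_level_series(gps_daily, cfg),
        "survey": _survey_wave_series(responses, schedule, targets),
    }

    def build_panel(smooth: bool) -> tuple[pd.DataFrame, pd.DataFrame]:
        rows = []
        for channel, groups in channel_series.items():
            for label, daily in groups.items():
                if channel == "survey":
                    weekly = daily  # already one value per field week
                else:
                    if smooth:
                        daily = harmonize.moving_average(
                            daily, cfg.harmonize.moving_average_window
                        )
                    weekly = harmonize.weekly_aggregate(
                        daily, min_days=cfg.harmonize.min_days
                    )
                rel = harmonize.relative_change_from_baseline(
                    weekly, baseline_week, label=f"{channel}/{label}"
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "channel": channel,
                            "subgroup": label,
                            "week": weekly.index,
                            "level": weekly.to_numpy(),
                            "rel_change_pct": rel.to_numpy(),
                        }
                    )
                )
        weekly_panel = pd.concat(rows, ignore_index=True)
        return weekly_panel, harmonize.match_to_waves(weekly_panel, schedule)

    def write(df: pd.DataFrame, name: str, date_col: str = "week") -> None:
        df.assign(
            **{date_col: lambda d: pd.to_datetime(d[date_col]).dt.strftime("%Y-%m-%d")}
        ).to_csv(outdir / name, index=False, float_format=FLOAT_FMT)

    weekly_panel, panel = build_panel(smooth=False)
    write(weekly_panel[weekly_panel["channel"] == "gsm"], "gsm_weekly.csv")
    write(weekly_panel, "weekly_panel.csv")
    write(panel, "aligned_panel.csv", date_col="week_start")
    # robustness variant: smoothing adds *extra* outputs, raw levels untouched
    if cfg.harmonize.moving_average:
        weekly_sm, panel_sm = build_panel(smooth=True)
        write(weekly_sm, "weekly_panel_smoothed.csv")
        write(panel_sm, "aligned_panel_smoothed.csv", date_col="week_start")
    logger.info(
        "harmonize: %d weekly rows, %d wave-aligned rows", len(weekly_panel), len(panel)
    )


# ----------------------------------------------------------------- compare


def stage_compare(cfg: RunConfig, outdir: Path) -> None:
    panel = pd.read_csv(outdir / "aligned_panel.csv", parse_dates=["week_start"])

    # pairwise correlations per subgroup present in both channels
    corr_rows = []
    for a, b in (("survey", "gsm"), ("survey", "gps"), ("gsm", "gps")):
        pa = panel[panel["channel"] == a]
        pb = panel[panel["channel"] == b]
        for label in sorted(set(pa["subgroup"]) & set(pb["subgroup"])):
            merged = pa[pa["subgroup"] == label].merge(
                pb[pb["subgroup"] == label], on="wave", suffixes=("_a", "_b")
            )
            if len(merged) < 3:
                continue
            res = compare.pearson_correlation(
                merged["rel_change_pct_a"], merged["rel_change_pct_b"], label=label
            )
            trend = compare.trend_line(
                merged["rel_change_pct_a"], merged["rel_change_pct_b"]
            )
            corr_rows.append(
                {
                    "comparison": f"{a}_vs_{b}",
                    "label": label,
                    "r": res.r,
                    "n": res.n,
                    "p_value": res.p_value,
                    "slope": trend.slope,
                    "intercept": trend.intercept,
                }
            )
    pd.DataFrame(corr_rows).to_csv(
        outdir / "correlations.csv", index=False, float_format=FLOAT_FMT
    )

    # time-fixed-effects regression on the core subgroups
    core = panel[
        panel["subgroup"].isin(
            ["population"]
            + [s for s in panel["subgroup"].unique() if s.startswith(("gender:", "age:"))]
        )
    ]
    fit = compare.time_fe_regression(
        core, response_channel="survey", reference_channel="gsm"
    )
    fe = pd.DataFrame(
        {"term": fit.params.index, "estimate": fit.params.to_numpy(), "se": fit.bse.to_numpy()}
    )
    fe.to_csv(outdir / "fe_regression.csv", index=False, float_format=FLOAT_FMT)

    # difference-in-differences around the partial lockdown, per channel
    did_rows = []
    if cfg.lockdown is not None:
        ld = cfg.lockdown
        treated_labels = {f"region:{r}" for r in ld.regions}
        region_panel = panel[panel["subgroup"].str.startswith("region:")].copy()
        region_panel["group"] = np.where(
            region_panel["subgroup"].isin(treated_labels), "treated", "control"
        )
        pre_w = (region_panel["week_start"] >= pd.Timestamp(ld.pre_start)) & (
            region_panel["week_start"] < pd.Timestamp(ld.start)
        )
        post_w = (region_panel["week_start"] >= pd.Timestamp(ld.start)) & (
            region_panel["week_start"] <= pd.Timestamp(ld.end)
        )
        region_panel["period"] = np.where(pre_w, "pre", np.where(post_w, "post", "outside"))
        window = region_panel[region_panel["period"] != "outside"]
        for channel, sub in window.groupby("channel"):
            res = compare.did_estimate(
                sub.rename(columns={"rel_change_pct": "value"}),
                group_col="group",
                period_col="period",
                value_col="value",
            )
            did_rows.append(
                {"channel": channel, "effect": res.effect, "se": res.se, "n": res.n}
            )
    pd.DataFrame(did_rows, columns=["channel", "effect", "se", "n"]).to_csv(
        outdir / "did.csv", index=False, float_format=FLOAT_FMT
    )
    logger.info(
        "compare: %d correlations, %d FE terms, %d DiD rows",
        len(corr_rows), len(fe), len(did_rows),
    )


STAGES = {
    "simulate": stage_simulate,
    "observe": stage_observe,
    "harmonize": stage_harmonize,
    "compare": stage_compare,
}


def run_pipeline(
    cfg: RunConfig, outdir: str | Path, stages: list[str] | None = None
) -> Path:
    """Run the requested stages (default: all, in order) into ``outdir``.

    The effective config is copied into the run directory and a run.log
    records filter counts and weighting convergence.  Raises with the
    stage name on any stage failure.
    """
    cfg.validate()  # reject bad configs before touching the run directory
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .config import dump_config

    dump_config(cfg, outdir / "config.yaml")

    handler = logging.FileHandler(outdir / "run.log", mode="a")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    root = logging.getLogger("mobicompare")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        for name in stages or list(STAGES):
            if name not in STAGES:
                raise ValidationError(f"unknown stage '{name}'")
            try:
                STAGES[name](cfg, outdir)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
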