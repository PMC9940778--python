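"""Panel survey emulation: item coding, filters, index and aggregates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mobicompare.survey import (
    ITEM_COLUMNS,
    ResponseModel,
    administer_survey,
    build_wave_schedule,
    code_from_days,
    filter_sample,
    mobility_index,
    stay_home_measure,
)
from mobicompare.synthetic import ACTIVITY_CATEGORIES, ValidationError

from conftest import quiet_model
from mobicompare.synthetic import simulate_stays, simulate_stringency


def noiseless_model(**kw) -> ResponseModel:
    base = dict(
        panel_size=40,
        recall_noise_sd=0.0,
        desirability_shift=0.0,
        item_nonresponse_prob=0.0,
        attrition_prob=0.0,
    )
    base.update(kw)
    return ResponseModel(**base)


class TestSchedule:
    def test_cadence_and_baseline_week(self):
        sched = build_wave_schedule()
        assert len(sched) == 22
        assert sched.loc[0, "start_date"] == pd.Timestamp("2020-03-23")
        assert sched.loc[0, "end_date"] == pd.Timestamp("2020-03-29")
        gaps = sched["start_date"].diff().dt.days.dropna().tolist()
        assert gaps[:9] == [7] * 9          # waves 1-10 weekly
        assert gaps[9:13] == [14] * 4       # waves 11-14 bi-weekly
        assert gaps[13:] == [28] * 8        # waves 15-22 monthly
        # every field week is one ISO week
        assert ((sched["end_date"] - sched["start_date"]).dt.days == 6).all()

    def test_non_monday_start_rejected(self):
        with pytest.raises(ValidationError):
            build_wave_schedule("2020-03-24")


class TestItemCoding:
    @pytest.mark.parametrize(
        "days,code",
        [(0, 0), (1, 1), (2, 2), (3, 2), (4, 3), (5, 3), (6, 3), (7, 4)],
    )
    def test_threshold_map(self, days, code):
        assert code_from_days(np.array([days]))[0] == code


@pytest.fixture(scope="module")
def surveyed_world(small_persons_module):
    persons = small_persons_module
    sched = build_wave_schedule()
    dates = pd.date_range("2020-03-23", "2021-03-14", freq="D")
    S = simulate_stringency(dates, [("2020-03-23", 70.0), ("2020-06-01", 30.0)])
    model = quiet_model(food=0.6, sports=0.3, work=0.5)
    stays = simulate_stays(persons, model, S, dates, seed=31)
    return {"persons": persons, "schedule": sched, "stays": stays, "stringency": S}


@pytest.fixture(scope="module")
def small_persons_module():
    from mobicompare.synthetic import PopulationSpec, generate_population

    return generate_population(PopulationSpec(n_persons=40), seed=11)


class TestAdminister:
    def test_zero_noise_codes_reproduce_threshold_map(self, surveyed_world):
        responses = administer_survey(
            surveyed_world["persons"],
            surveyed_world["stays"],
            surveyed_world["schedule"],
            noiseless_model(),
            seed=1,
        )
        # oracle: recount active days per person/wave/category from stays
        stays = surveyed_world["stays"]
        trips = stays[stays["category"] != "home"]
        sched = surveyed_world["schedule"]
        checked = 0
        for resp in responses.sample(60, random_state=0).itertuples(index=False):
            row = sched[sched["wave"] == resp.wave].iloc[0]
            week = pd.date_range(row.start_date, row.end_date)
            mine = trips[
                (trips["person_id"] == resp.respondent_id) & trips["date"].isin(week)
            ]
            for cat in ("food", "sports", "work"):
                active_days = mine[mine["category"] == cat]["date"].nunique()
                expected = code_from_days(np.array([active_days]))[0]
                assert getattr(resp, f"item_{cat}") == expected
                checked += 1
        assert checked > 0

    def test_no_trips_is_all_zero_items(self, small_persons_module):
        sched = build_wave_schedule()
        dates = pd.date_range("2020-03-23", "2021-03-14", freq="D")
        S = simulate_stringency(dates, [("2020-03-23", 50.0)])
        stays = simulate_stays(small_persons_module, quiet_model(), S, dates, seed=2)
        responses = administer_survey(
            small_persons_module, stays, sched, noiseless_model(), seed=1
        )
        assert (responses[ITEM_COLUMNS] == 0).all().all()
        # everyone home all week reports the stay-home item as daily
        assert (responses["item_stayhome"] == 4).all()

    def test_daily_trips_code_four(self, small_persons_module):
        sched = build_wave_schedule()
        dates = pd.date_range("2020-03-23", "2021-03-14", freq="D")
        S = simulate_stringency(dates, [("2020-03-23", 0.0)])
        # rate 6/day: a trip on essentially every day
        stays = simulate_stays(small_persons_module, quiet_model(pets=6.0), S, dates, seed=3)
        responses = administer_survey(
            small_persons_module, stays, sched, noiseless_model(), seed=1
        )
        assert (responses["item_pets"] == 4).mean() > 0.97

    def test_schedule_outside_stays_rejected(self, surveyed_world):
        short = surveyed_world["stays"]
        short = short[short["date"] < "2020-06-01"]
        with pytest.raises(ValidationError, match="date range"):
            administer_survey(
                surveyed_world["persons"],
                short,
                surveyed_world["schedule"],
                noiseless_model(),
                seed=1,
            )

    def test_attrition_with_refreshment_holds_wave_size(self, surveyed_world):
        responses = administer_survey(
            surveyed_world["persons"],
            surveyed_world["stays"],
            surveyed_world["schedule"],
            noiseless_model(panel_size=10, attrition_prob=0.1),
            seed=7,
        )
        sizes = responses.groupby("wave").size()
        assert (sizes == 10).all()
        # refreshment brings in respondents beyond the initial panel
        assert responses["respondent_id"].nunique() > 10

    def test_desirability_shift_weakly_decreases_aggregates(self, surveyed_world):
        args = (
            surveyed_world["persons"],
            surveyed_world["stays"],
            surveyed_world["schedule"],
        )
        low = administer_survey(*args, noiseless_model(desirability_shift=0.0), seed=5)
        high = administer_survey(*args, noiseless_model(desirability_shift=0.3), seed=5)
        agg_low = mobility_index(filter_sample(low)).groupby("wave")["index"].mean()
        agg_high = mobility_index(filter_sample(high)).groupby("wave")["index"].mean()
        assert (agg_high <= agg_low + 1e-12).all()
        assert agg_high.sum() < agg_low.sum()

    def test_item_nonresponse_injects_missing(self, surveyed_world):
        responses = administer_survey(
            surveyed_world["persons"],
            surveyed_world["stays"],
            surveyed_world["schedule"],
            noiseless_model(item_nonresponse_prob=0.1),
            seed=5,
        )
        frac = responses[ITEM_COLUMNS].isna().to_numpy().mean()
        assert 0.05 < frac < 0.15


class TestFilterAndIndex:
    def _responses(self):
        rows = []
        for rid, age, items in [
            (1, "30-59", [1] * 9),
            (2, "30-59", [1] * 8 + [np.nan]),
            (3, "75+", [2] * 9),
        ]:
            rows.append(
                dict(
                    respondent_id=rid, wave=1, age_group=age, gender="f", region="east",
                    item_stayhome=2,
                    **dict(zip(ITEM_COLUMNS, items)),
                )
            )
        return pd.DataFrame(rows)

    def test_listwise_deletion_and_age_filter(self):
        out = filter_sample(self._responses())
        assert out["respondent_id"].tolist() == [1]

    def test_index_and_subindices(self):
        resp = self._responses().iloc[[0]].copy()
        resp[ITEM_COLUMNS] = 0
        resp["item_work"] = 2
        resp["item_food"] = 3
        resp["item_medicine"] = 1
        idx = mobility_index(resp)
        assert idx["index"].tolist() == [6]
        assert idx["food_medicine"].tolist() == [4]
        assert idx["work"].tolist() == [2]
        assert idx["nonfood"].tolist() == [0]

    def test_index_extremes(self):
        resp = self._responses().iloc[[0]].copy()
        resp[ITEM_COLUMNS] = 4
        idx = mobility_index(resp)
        assert idx["index"].tolist() == [36]
        assert idx["food_medicine"].tolist() == [8]
        resp[ITEM_COLUMNS] = 0
        idx = mobility_index(resp)
        assert idx["index"].tolist() == [0]

    def test_incomplete_response_rejected_by_index(self):
        with pytest.raises(ValidationError):
            mobility_index(self._responses().iloc[[1]])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=4), min_size=9, max_size=9))
    def test_index_bounds_on_fuzzed_items(self, items):
        resp = pd.DataFrame(
            [dict(respondent_id=0, wave=1, **dict(zip(ITEM_COLUMNS, items)))]
        )
        idx = mobility_index(resp)
        assert 0 <= idx.loc[0, "index"] <= 36
        assert idx.loc[0, "index"] == sum(items)
        assert 0 <= idx.loc[0, "food_medicine"] <= 8
        assert 0 <= idx.loc[0, "nonfood"] <= 4
        assert 0 <= idx.loc[0, "work"] <= 4


class TestStayHome:
    def test_uniform_code_aggregates_to_itself(self):
        resp = pd.DataFrame(
            {"wave": [1, 1], "item_stayhome": [4.0, 4.0]}
        )
        assert stay_home_measure(resp).loc[1] == 4.0

    def test_equal_weight_mean(self):
        resp = pd.DataFrame({"wave": [1, 1], "item_stayhome": [0.0, 4.0]})
        assert stay_home_measure(resp).loc[1] == 2.0

    def test_weighted_mean(self):
        resp = pd.DataFrame({"wave": [1, 1], "item_stayhome": [0.0, 4.0]})
        w = pd.Series([3.0, 1.0])
        assert stay_home_measure(resp, w).loc[1] == 1.0

    def test_empty_wave_missing(self):
        resp = pd.DataFrame({"wave": [1, 2], "item_stayhome": [2.0, np.nan]})
        out = stay_home_measure(resp)
        assert np.isnan(out.loc[2])
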