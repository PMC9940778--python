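"""Population generation and the latent stay process."""

import numpy as np
import pandas as pd
import pytest

from mobicompare.synthetic import (
    ACTIVITY_CATEGORIES,
    HOME_CATEGORY,
    LatentMobilityModel,
    PopulationSpec,
    ValidationError,
    generate_population,
    largest_remainder_counts,
    simulate_stays,
    simulate_stringency,
    stays_from_csv,
    stays_to_csv,
    true_weekly_mobility,
)

from conftest import make_stays, quiet_model


def lr_oracle(props, n):
    """Independent largest-remainder rounding: floors, then distribute the
    leftover seats to the largest fractional parts."""
    quotas = [p * n for p in props]
    counts = [int(np.floor(q)) for q in quotas]
    leftover = n - sum(counts)
    fracs = sorted(
        range(len(props)), key=lambda i: (-(quotas[i] - np.floor(quotas[i])), i)
    )
    for i in fracs[:leftover]:
        counts[i] += 1
    return counts


class TestPopulation:
    @pytest.mark.parametrize(
        "props,n,expected",
        [
            ([0.5, 0.5], 100, [50, 50]),
            ([0.3, 0.4, 0.3], 10, [3, 4, 3]),
            ([1 / 3, 1 / 3, 1 / 3], 10, None),  # oracle decides
        ],
    )
    def test_largest_remainder_known_cases(self, props, n, expected):
        got = list(largest_remainder_counts(np.array(props), n))
        assert got == (expected if expected is not None else lr_oracle(props, n))
        assert sum(got) == n

    def test_largest_remainder_matches_oracle_randomised(self, rng):
        for _ in range(50):
            k = rng.integers(2, 6)
            raw = rng.random(k) + 0.05
            props = raw / raw.sum()
            n = int(rng.integers(1, 500))
            assert list(largest_remainder_counts(props, n)) == lr_oracle(props, n)

    def test_quota_mode_margins_exact(self):
        spec = PopulationSpec(
            n_persons=100,
            margins={
                "age_group": {"14-29": 0.3, "30-59": 0.4, "60-74": 0.3},
                "gender": {"female": 0.5, "male": 0.5},
                "region": {"east": 0.45, "west": 0.55},
            },
        )
        persons = generate_population(spec, seed=0)
        assert persons["gender"].value_counts().to_dict() == {"female": 50, "male": 50}
        assert persons["age_group"].value_counts().to_dict() == {
            "14-29": 30, "30-59": 40, "60-74": 30,
        }
        assert len(persons) == 100
        assert persons["person_id"].is_unique

    def test_single_person_fully_populated(self):
        persons = generate_population(PopulationSpec(n_persons=1), seed=3)
        assert len(persons) == 1
        row = persons.iloc[0]
        assert pd.notna(row[["age_group", "gender", "region", "home_x_km", "home_y_km"]]).all()
        # employed iff workplace present
        assert row["employed"] == pd.notna(row["work_x_km"])

    def test_employed_iff_workplace_present(self, small_persons):
        assert (small_persons["employed"] == small_persons["work_x_km"].notna()).all()
        assert (small_persons["employed"] == small_persons["work_y_km"].notna()).all()

    def test_bad_margin_rejected(self):
        spec = PopulationSpec(
            n_persons=10,
            margins={
                "age_group": {"a": 0.5, "b": 0.6},
                "gender": {"f": 0.5, "m": 0.5},
                "region": {"r": 1.0},
            },
        )
        with pytest.raises(ValidationError, match="sums to"):
            generate_population(spec, seed=0)

    def test_probabilistic_margins_within_sampling_error(self):
        spec = PopulationSpec(n_persons=4000)
        persons = generate_population(spec, seed=9, mode="probabilistic")
        for var, margin in spec.margins.items():
            shares = persons[var].value_counts(normalize=True)
            for level, p in margin.items():
                tol = 4 * np.sqrt(p * (1 - p) / spec.n_persons)
                assert abs(shares.get(level, 0.0) - p) < tol

    def test_home_locations_inside_region_box(self):
        spec = PopulationSpec(
            n_persons=50,
            region_boxes={"east": (0, 0, 10, 10), "west": (100, 0, 110, 10)},
        )
        persons = generate_population(spec, seed=2)
        east = persons[persons["region"] == "east"]
        assert east["home_x_km"].between(0, 10).all()
        west = persons[persons["region"] == "west"]
        assert west["home_x_km"].between(100, 110).all()


class TestStringency:
    def test_single_breakpoint_constant(self):
        dates = pd.date_range("2020-01-01", periods=10)
        s = simulate_stringency(dates, [("2020-01-01", 80.0)])
        assert (s == 80.0).all()

    def test_piecewise_constant_switch(self):
        dates = pd.date_range("2020-01-01", periods=10)
        s = simulate_stringency(dates, [("2020-01-01", 80.0), ("2020-01-06", 30.0)])
        assert (s.iloc[:5] == 80.0).all()
        assert (s.iloc[5:] == 30.0).all()

    def test_level_outside_range_rejected(self):
        dates = pd.date_range("2020-01-01", periods=5)
        with pytest.raises(ValidationError):
            simulate_stringency(dates, [("2020-01-01", 120.0)])


class TestStays:
    def test_zero_rates_give_one_allday_home_stay(self, small_persons):
        dates = pd.date_range("2020-03-02", periods=5)
        S = simulate_stringency(dates, [("2020-03-02", 50.0)])
        stays = simulate_stays(small_persons, quiet_model(), S, dates, seed=1)
        assert (stays["category"] == HOME_CATEGORY).all()
        assert (stays["duration_h"] == 24.0).all()
        assert len(stays) == len(small_persons) * len(dates)

    def test_days_tile_24_hours_without_overlap(self, small_world):
        stays = small_world["stays"]
        per_day = stays.groupby(["person_id", "date"])
        assert np.allclose(per_day["duration_h"].sum(), 24.0)
        for _, g in list(per_day)[:50]:
            g = g.sort_values("start_h")
            ends = (g["start_h"] + g["duration_h"]).to_numpy()
            assert (g["start_h"].to_numpy()[1:] >= ends[:-1] - 1e-9).all()

    def test_poisson_mean_recovered(self, small_persons):
        r = 0.8
        dates = pd.date_range("2020-03-02", periods=150)
        S = simulate_stringency(dates, [("2020-03-02", 0.0)])
        stays = simulate_stays(small_persons, quiet_model(food=r), S, dates, seed=2)
        trips = stays[stays["category"] == "food"]
        n = len(small_persons) * len(dates)
        mean = len(trips) / n
        se = np.sqrt(r / n)
        assert abs(mean - r) < 3 * se

    def test_stringency_rate_ratio_closed_form(self, small_persons):
        # coef -0.02, S jumps 0 -> 100: multiplier e^-2
        model = quiet_model(food=1.0)
        model.stringency_coef["food"] = -0.02
        dates = pd.date_range("2020-03-02", periods=200)
        S = simulate_stringency(dates, [("2020-03-02", 0.0), ("2020-06-10", 100.0)])
        stays = simulate_stays(small_persons, model, S, dates, seed=3)
        trips = stays[stays["category"] == "food"]
        low = trips[trips["date"] < "2020-06-10"]
        high = trips[trips["date"] >= "2020-06-10"]
        n_low = len(small_persons) * int((dates < "2020-06-10").sum())
        n_high = len(small_persons) * int((dates >= "2020-06-10").sum())
        ratio = (len(high) / n_high) / (len(low) / n_low)
        expected = np.exp(-2.0)
        se = expected * np.sqrt(1 / max(len(high), 1) + 1 / len(low))
        assert abs(ratio - expected) < 3 * se

    def test_stringency_coefficient_recovered_by_regression(self):
        # log-linear model: regressing log mean counts on S(t) returns the coefficient
        spec = PopulationSpec(n_persons=200)
        persons = generate_population(spec, seed=21)
        coef = -0.015
        model = quiet_model(other=1.2)
        model.stringency_coef["other"] = coef
        dates = pd.date_range("2020-03-02", periods=90)
        S = simulate_stringency(
            dates,
            [("2020-03-02", 0.0), ("2020-03-30", 30.0), ("2020-04-27", 60.0), ("2020-05-25", 90.0)],
        )
        stays = simulate_stays(persons, model, S, dates, seed=22)
        trips = stays[stays["category"] == "other"]
        daily = trips.groupby("date").size().reindex(dates, fill_value=0) / len(persons)
        y = np.log(daily.to_numpy())
        x = S.to_numpy()
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(y) - 2
        se = np.sqrt(resid @ resid / dof / ((x - x.mean()) ** 2).sum())
        assert abs(beta[1] - coef) < 2 * se

    def test_work_trips_go_to_workplace(self, small_world):
        stays = small_world["stays"]
        persons = small_world["persons"].set_index("person_id")
        work = stays[stays["category"] == "work"]
        assert len(work) > 0
        wx = work["person_id"].map(persons["work_x_km"])
        assert np.allclose(work["x_km"], wx)

    def test_fixed_seed_bit_reproducible(self, small_persons):
        dates = pd.date_range("2020-03-02", periods=20)
        S = simulate_stringency(dates, [("2020-03-02", 40.0)])
        model = quiet_model(food=0.5, noise_sd=0.2)
        a = simulate_stays(small_persons, model, S, dates, seed=17)
        b = simulate_stays(small_persons, model, S, dates, seed=17)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_stays(small_persons, model, S, dates, seed=18)
        assert not a["x_km"].equals(c["x_km"])

    def test_stays_csv_round_trip(self, small_world, tmp_path):
        stays = small_world["stays"].head(200)
        path = tmp_path / "stays.csv"
        stays_to_csv(stays, path)
        back = stays_from_csv(path)
        assert len(back) == len(stays)
        assert np.allclose(back["duration_h"], stays["duration_h"], atol=1e-6)
        assert (back["category"].to_numpy() == stays["category"].to_numpy()).all()


class TestTrueWeeklyMobility:
    def test_zero_trips_is_zero_series(self, small_persons):
        dates = pd.date_range("2020-03-02", periods=14)
        S = simulate_stringency(dates, [("2020-03-02", 50.0)])
        stays = simulate_stays(small_persons, quiet_model(), S, dates, seed=1)
        weekly = true_weekly_mobility(stays, small_persons, "total_distance")
        assert (weekly == 0.0).all()

    def test_single_daily_round_trip_distance(self):
        # one person, one 4 km trip per day for a week: 2 * 4 * 7 = 56 km
        persons = pd.DataFrame(
            {
                "person_id": [0],
                "age_group": ["30-59"],
                "gender": ["f"],
                "region": ["east"],
                "home_x_km": [0.0],
                "home_y_km": [0.0],
                "employed": [False],
                "work_x_km": [np.nan],
                "work_y_km": [np.nan],
            }
        )
        rows = []
        for d in pd.date_range("2020-03-02", periods=7):
            rows.append((0, "food", 4.0, 0.0, d, 10.0, 1.0))
            rows.append((0, "home", 0.0, 0.0, d, 0.0, 10.0))
            rows.append((0, "home", 0.0, 0.0, d, 11.0, 13.0))
        stays = make_stays(rows)
        weekly = true_weekly_mobility(stays, persons, "total_distance")
        assert weekly.to_numpy() == pytest.approx([56.0])

    def test_trip_count_equals_non_home_stays(self, small_world):
        stays = small_world["stays"]
        persons = small_world["persons"]
        weekly = true_weekly_mobility(stays, persons, "trip_count")
        total = weekly.sum() * len(persons)
        assert total == pytest.approx((stays["category"] != HOME_CATEGORY).sum())

    def test_unknown_measure_rejected(self, small_world):
        with pytest.raises(ValidationError):
            true_weekly_mobility(small_world["stays"], small_world["persons"], "speed")


class TestModelValidation:
    def test_positive_stringency_coef_rejected(self):
        model = quiet_model(food=1.0)
        model.stringency_coef["food"] = 0.01
        with pytest.raises(ValidationError):
            model.validate()

    def test_missing_category_rejected(self):
        model = quiet_model()
        del model.base_rate["pets"]
        with pytest.raises(ValidationError, match="9 activity categories"):
            model.validate()
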