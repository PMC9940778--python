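import numpy as np
import pandas as pd
import pytest

from mobicompare.synthetic import (
    LatentMobilityModel,
    ACTIVITY_CATEGORIES,
    PopulationSpec,
    default_latent_model,
    generate_population,
    simulate_stays,
    simulate_stringency,
)


def quiet_model(**overrides) -> LatentMobilityModel:
    """Latent model with zero rates everywhere except explicit overrides.

    overrides maps category -> base_rate; optional kwargs prefixed with
    model fields set scalars (noise_sd=..., etc.).
    """
    model = default_latent_model()
    model.base_rate = {c: 0.0 for c in ACTIVITY_CATEGORIES}
    model.stringency_coef = {c: 0.0 for c in ACTIVITY_CATEGORIES}
    model.seasonal_amplitude = 0.0
    model.noise_sd = 0.0
    model.age_multipliers = {}
    for key, value in overrides.items():
        if key in ACTIVITY_CATEGORIES:
            model.base_rate[key] = value
        else:
            setattr(model, key, value)
    return model


@pytest.fixture(scope="session")
def small_spec():
    return PopulationSpec(n_persons=40)


@pytest.fixture(scope="session")
def small_persons(small_spec):
    return generate_population(small_spec, seed=11)


@pytest.fixture(scope="session")
def small_world(small_persons):
    """A compact simulated world: 40 persons, 10 weeks, mild dynamics."""
    dates = pd.date_range("2020-03-23", periods=70, freq="D")
    stringency = simulate_stringency(
        dates, [("2020-03-23", 75.0), ("2020-04-20", 40.0), ("2020-05-18", 20.0)]
    )
    model = default_latent_model()
    stays = simulate_stays(small_persons, model, stringency, dates, seed=5)
    return {
        "persons": small_persons,
        "dates": dates,
        "stringency": stringency,
        "model": model,
        "stays": stays,
    }


def make_stays(rows):
    """Build a stays frame from (person_id, category, x, y, date, start_h, dur_h)."""
    df = pd.DataFrame(
        rows,
        columns=["person_id", "category", "x_km", "y_km", "date", "start_h", "duration_h"],
    )
    df["date"] = pd.to_datetime(df["date"])
    df["start"] = df["date"] + pd.to_timedelta(df["start_h"], unit="h")
    return df[
        ["person_id", "category", "x_km", "y_km", "date", "start", "start_h", "duration_h"]
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
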