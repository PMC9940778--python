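"""GSM-style observation channel: localization events and radius of gyration.

A mobile network sees a device only when it communicates; each event is
located at the base station (tower) the device is attached to.  The
channel snaps each stay's true location to the nearest node of a regular
tower grid and draws event times from a Poisson process within the stay.

The per-device-day mobility statistic is the radius of gyration (ROG):
the time-weighted root-mean-square distance between each localization and
the time-weighted center of gravity.  The dwell weight of an event is the
forward inter-event time (the device "stays" at a tower until it is next
observed), truncated at midnight.  Daily medians over devices tame the
heavy right skew of the ROG distribution; weekly averages of the daily
medians feed the cross-channel comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ValidationError

__all__ = [
    "TowerGrid",
    "observe_gsm_events",
    "radius_of_gyration",
    "device_day_rog",
    "daily_median_rog",
    "share_rog_above",
    "events_to_csv",
    "events_from_csv",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class TowerGrid:
    """Square grid of GSM base stations with the given spacing in km."""

    spacing_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing_km <= 0:
            raise ValidationError("tower grid spacing must be > 0")

    def snap(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates of the nearest grid node."""
        ox, oy = self.origin
        sx = np.round((np.asarray(x, dtype=float) - ox) / self.spacing_km) * self.spacing_km + ox
        sy = np.round((np.asarray(y, dtype=float) - oy) / self.spacing_km) * self.spacing_km + oy
        return sx, sy


def observe_gsm_events(
    stays: pd.DataFrame,
    grid: TowerGrid,
    event_rate_per_hour: float = 0.4,
    coverage_prob: float = 0.8,
    seed: int = 0,
    tower_jitter_sd_km: float = 0.0,
) -> pd.DataFrame:
    """Observe stays through the mobile network.

    Each covered person becomes one device (device_id = person_id).
    Within every stay, event times follow a Poisson process at
    ``event_rate_per_hour``; each event is located at the tower nearest to
    the stay's true location.  The dwell weight of an event is the time
    until the device's next event that day, or until midnight for the last
    event.

    ``tower_jitter_sd_km`` adds isotropic Gaussian positional error to the
    true location before snapping, emulating the tower-oscillation of real
    networks (a stationary device hops among neighbouring base stations
    with load and signal conditions).  Default 0: exact nearest-node
    assignment.

    Returns a DataFrame with columns device_id, date, time_h (hours since
    midnight), tower_x_km, tower_y_km, dwell_h, sorted by device, date and
    time.
    """
    if event_rate_per_hour <= 0:
        raise ValidationError("event_rate_per_hour must be > 0")
    if not (0.0 < coverage_prob <= 1.0):
        raise ValidationError("coverage_prob must be in (0, 1]")

    person_ids = np.sort(stays["person_id"].unique())
    children = np.random.SeedSequence(seed).spawn(len(person_ids))

    frames: list[pd.DataFrame] = []
    stays_by_person = dict(tuple(stays.groupby("person_id", sort=True)))
    for child, pid in zip(children, person_ids):
        rng = np.random.default_rng(child)
        if rng.random() >= coverage_prob:
            continue
        ps = stays_by_person[pid]
        dur = ps["duration_h"].to_numpy()
        n_ev = rng.poisson(event_rate_per_hour * dur)
        total = int(n_ev.sum())
        if total == 0:
            continue
        idx = np.repeat(np.arange(len(ps)), n_ev)
        offsets = rng.uniform(0.0, dur[idx])
        ex = ps["x_km"].to_numpy()[idx]
        ey = ps["y_km"].to_numpy()[idx]
        if tower_jitter_sd_km > 0:
            ex = ex + rng.normal(0.0, tower_jitter_sd_km, total)
            ey = ey + rng.normal(0.0, tower_jitter_sd_km, total)
        sx, sy = grid.snap(ex, ey)
        frames.append(
            pd.DataFrame(
                {
                    "device_id": pid,
                    "date": ps["date"].to_numpy()[idx],
                    "time_h": ps["start_h"].to_numpy()[idx] + offsets,
                    "tower_x_km": sx,
                    "tower_y_km": sy,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["device_id", "date", "time_h", "tower_x_km", "tower_y_km", "dwell_h"]
        )
    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(
        ["device_id", "date", "time_h"], kind="mergesort", ignore_index=True
    )
    nxt = events.groupby(["device_id", "date"], sort=False)["time_h"].shift(-1)
    events["dwell_h"] = nxt.fillna(24.0) - events["time_h"]
    return events


def radius_of_gyration(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray, metric: str = "euclidean"
) -> float:
    """Time-weighted ROG of one device-day.

    Center c = sum(w_i x_i) / sum(w_i) coordinate-wise;
    ROG = sqrt( sum(w_i d(x_i, c)^2) / sum(w_i) ).

    ``metric`` is 'euclidean' for planar km inputs or 'haversine' for
    (lon, lat) degree inputs.  An empty event set yields NaN (undefined),
    never 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size == 0:
        return float("nan")
    if np.any(w <= 0):
        raise ValidationError("dwell weights must be > 0")
    # exact zero when every localization shares one tower
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 0.0
    W = w.sum()
    cx = (w * x).sum() / W
    cy = (w * y).sum() / W
    if metric == "euclidean":
        d2 = (x - cx) ** 2 + (y - cy) ** 2
    elif metric == "haversine":
        d = _haversine_km(x, y, cx, cy)
        d2 = d**2
    else:
        raise ValidationError(f"unknown metric '{metric}'")
    return float(np.sqrt((w * d2).sum() / W))


def _haversine_km(lon, lat, lon0, lat0):
    lon, lat, lon0, lat0 = map(np.radians, (lon, lat, lon0, lat0))
    a = (
        np.sin((lat - lat0) / 2.0) ** 2
        + np.cos(lat) * np.cos(lat0) * np.sin((lon - lon0) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def device_day_rog(events: pd.DataFrame, min_events: int = 1) -> pd.DataFrame:
    """Vectorised per-device-day ROG table.

    Device-days with fewer than ``min_events`` events are dropped (default
    keeps single-event days, which have ROG 0).

    Returns columns device_id, date, rog_km, n_events.
    """
    if events.empty:
        return pd.DataFrame(columns=["device_id", "date", "rog_km", "n_events"])
    df = events[["device_id", "date", "tower_x_km", "tower_y_km", "dwell_h"]].copy()
    df["wx"] = df["dwell_h"] * df["tower_x_km"]
    df["wy"] = df["dwell_h"] * df["tower_y_km"]
    g = df.groupby(["device_id", "date"], sort=True)
    agg = g.agg(
        W=("dwell_h", "sum"), wx=("wx", "sum"), wy=("wy", "sum"), n_events=("dwell_h", "size")
    )
    agg["cx"] = agg["wx"] / agg["W"]
    agg["cy"] = agg["wy"] / agg["W"]
    centers = agg[["cx", "cy"]].reindex(
        pd.MultiIndex.from_frame(df[["device_id", "date"]])
    )
    d2 = (df["tower_x_km"].to_numpy() - centers["cx"].to_numpy()) ** 2 + (
        df["tower_y_km"].to_numpy() - centers["cy"].to_numpy()
    ) ** 2
    df["wd2"] = df["dwell_h"].to_numpy() * d2
    agg["rog_km"] = np.sqrt(
        df.groupby(["device_id", "date"], sort=True)["wd2"].sum() / agg["W"]
    )
    out = agg.reset_index()[["device_id", "date", "rog_km", "n_events"]]
    return out[out["n_events"] >= min_events].reset_index(drop=True)


def daily_median_rog(
    rogs: pd.DataFrame,
    persons: pd.DataFrame | None = None,
    grouping: str = "population",
) -> pd.DataFrame:
    """Median device-day ROG per date, optionally within subgroups.

    ``grouping`` is 'population', 'age_group:gender' (cross of person
    attributes, requires ``persons``), or any single person attribute such
    as 'region'.  Even device counts take the mean of the two central
    order statistics (numpy convention).  Empty group-dates are simply
    absent (undefined), so they never enter weekly means.

    Returns columns: group, date, median_rog_km, n_devices.
    """
    df = rogs.copy()
    if grouping == "population":
        df["group"] = "population"
    else:
        if persons is None:
            raise ValidationError("subgroup medians require the persons table")
        attrs = grouping.split(":")
        lookup = persons.set_index("person_id")[attrs]
        for a in attrs:
            df[a] = df["device_id"].map(lookup[a])
        df["group"] = df[attrs[0]].astype(str)
        for a in attrs[1:]:
            df["group"] = df["group"] + ":" + df[a].astype(str)
    out = (
        df.groupby(["group", "date"], sort=True)["rog_km"]
        .agg(median_rog_km="median", n_devices="size")
        .reset_index()
    )
    return out


def share_rog_above(rogs: pd.DataFrame, threshold_km: float = 0.5) -> pd.DataFrame:
    """Per-date share of devices with ROG strictly above ``threshold_km``."""
    if threshold_km <= 0:
        raise ValidationError("threshold_km must be > 0")
    out = (
        rogs.groupby("date", sort=True)["rog_km"]
        .agg(share=lambda s: float((s > threshold_km).mean()), n_devices="size")
        .reset_index()
    )
    return out


def events_to_csv(events: pd.DataFrame, path) -> None:
    """device_id,timestamp_iso8601,x_km,y_km,dwell_h event log."""
    out = pd.DataFrame(
        {
            "device_id": events["device_id"],
            "timestamp": (
                pd.to_datetime(events["date"])
                + pd.to_timedelta(events["time_h"], unit="h")
            ).dt.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "x_km": events["tower_x_km"],
            "y_km": events["tower_y_km"],
            "dwell_h": events["dwell_h"],
        }
    )
    out.to_csv(path, index=False, float_format="%.6f")


def events_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    date = df["timestamp"].dt.normalize()
    return pd.DataFrame(
        {
            "device_id": df["device_id"],
            "date": date,
            "time_h": (df["timestamp"] - date).dt.total_seconds() / 3600.0,
            "tower_x_km": df["x_km"],
            "tower_y_km": df["y_km"],
            "dwell_h": df["dwell_h"],
        }
    )
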