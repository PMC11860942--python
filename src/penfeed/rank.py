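"""Social-ranking indicators derived from feeder logs.

Group-housed pigs share one feeder per pen, so the order of access, the
time of day an animal manages to eat, and its share of the pen's daily
resources are all proxies for its position in the social hierarchy:

Position       mean standardized entry order within pen feeding events
               (1/n for the first of n visits; low = priority access)
ratePrefTime   fraction of an animal's visits started inside preferred
               clock-time windows
rateNV/NM/FI/OT  day-averaged share of the pen's visits, meals, intake
               and feeder-occupation time
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: preferred-time window presets (clock hours, half-open [start, end))
WINDOW_A = ((8.0, 20.0),)
#: morning + afternoon peak windows as defined in the methods text
WINDOW_B_METHODS = ((8.0, 10.0), (15.0, 17.0))
#: wider variant printed in the trait table
WINDOW_B_TABLE = ((7.0, 11.0), (14.0, 18.0))

SHARE_TRAITS = {
    "rateNV": "TNV",
    "rateNM": "TNM",
    "rateFI": "FI_day_g",
    "rateOT": "OT_day_s",
}


def build_pen_events(visits: pd.DataFrame, threshold_min: float | dict) -> pd.DataFrame:
    """Segment each pen's visit stream into feeding events.

    A feeding event is a maximal run of pen visits in which every
    consecutive start-to-start gap is at most ``threshold_min`` minutes.
    ``threshold_min`` may be a single value or a per-pen mapping (the
    usual choice is the median meal criterion of the pen's members).

    Returns the visits with ``event_id`` (per pen) and ``event_n``
    (number of visits in the event) columns added.
    """
    df = visits.sort_values(["pen_id", "t_start"], kind="stable").copy()
    if isinstance(threshold_min, dict):
        thr = df["pen_id"].map(threshold_min).astype(float)
    else:
        thr = pd.Series(float(threshold_min), index=df.index)
    gap_min = df.groupby("pen_id")["t_start"].diff().dt.total_seconds() / 60.0
    new_event = gap_min.isna() | (gap_min > thr)
    df["event_id"] = new_event.groupby(df["pen_id"]).cumsum().astype(int)
    df["event_n"] = df.groupby(["pen_id", "event_id"])["t_start"].transform("size")
    return df


def compute_position(events: pd.DataFrame) -> pd.Series:
    """Mean standardized feeder-entry order per animal.

    Within an event of ``n`` visits the ``k``-th visit has order
    ``k / n``; an animal's per-event value is the mean over its visits
    in that event, and Position is the mean of per-event values over
    every event the animal appears in.
    """
    df = events.sort_values(["pen_id", "event_id", "t_start"], kind="stable").copy()
    df["k"] = df.groupby(["pen_id", "event_id"]).cumcount() + 1
    df["std_order"] = df["k"] / df["event_n"]
    per_event = df.groupby(["pen_id", "event_id", "animal_id"])["std_order"].mean()
    position = per_event.groupby("animal_id").mean()
    position.name = "Position"
    return position


def _in_windows(hours: pd.Series, windows) -> pd.Series:
    mask = pd.Series(False, index=hours.index)
    for start, end in windows:
        mask |= (hours >= start) & (hours < end)
    return mask


def compute_pref_time(
    visits: pd.DataFrame,
    windows_a=WINDOW_A,
    windows_b=WINDOW_B_METHODS,
) -> pd.DataFrame:
    """Fraction of each animal's visits starting inside preferred windows.

    Windows are unions of half-open clock-time intervals, so a visit at
    exactly the end bound is outside.
    """
    t = visits["t_start"]
    frac_hour = t.dt.hour + t.dt.minute / 60.0 + t.dt.second / 3600.0
    out = pd.DataFrame(
        {
            "animal_id": visits["animal_id"],
            "in_a": _in_windows(frac_hour, windows_a),
            "in_b": _in_windows(frac_hour, windows_b),
        }
    )
    res = out.groupby("animal_id").agg(
        ratePrefTime_a=("in_a", "mean"), ratePrefTime_b=("in_b", "mean")
    )
    return res.reset_index()


def compute_daily_shares(daily: pd.DataFrame) -> pd.DataFrame:
    """Day-averaged pen shares of visits, meals, intake and occupation.

    For each pen-day the share is the animal's value divided by the pen
    total (the focal animal included, so shares sum to one); the trait
    is the mean share over the animal's observed days.  Pen-days with a
    zero total for a trait are skipped for that trait.
    """
    df = daily.copy()
    out = {}
    for trait, col in SHARE_TRAITS.items():
        total = df.groupby(["pen_id", "day_index"])[col].transform("sum")
        share = df[col] / total.where(total > 0)
        out[trait] = share.groupby(df["animal_id"]).mean()
    res = pd.DataFrame(out)
    res.index.name = "animal_id"
    return res.reset_index()


def rank_traits(
    visits: pd.DataFrame,
    daily: pd.DataFrame,
    event_threshold_min: float | dict,
    windows_a=WINDOW_A,
    windows_b=WINDOW_B_METHODS,
) -> pd.DataFrame:
    """All social-ranking indicators in one per-animal table."""
    events = build_pen_events(visits, event_threshold_min)
    position = compute_position(events).reset_index()
    pref = compute_pref_time(visits, windows_a=windows_a, windows_b=windows_b)
    shares = compute_daily_shares(daily)
    out = position.merge(pref, on="animal_id", how="outer").merge(
        shares, on="animal_id", how="outer"
    )
    return out
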