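"""Merging feeder visits into meals and aggregating meal traits.

A meal is a maximal run of one animal's visits whose internal
end-to-start gaps are all strictly below that animal's meal criterion.
Meal-level traits follow the standard nomenclature:

NVM   visits per meal
OTM   occupation time (sum of visit durations, s)
TM    time to complete the meal (first start to last end, s)
FIM   intake in the meal (g)
FR    FIM / OTM (g/s)
FRM   FIM / TM (g/s)
IBM   start-to-start interval to the previous meal (s)

Daily values are sums over an animal-day; ratio traits at daily scale
are recomputed from the summed numerator and denominator.  Hourly values
are sums per clock hour divided by the number of observed days.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MEAL_COLUMNS = [
    "animal_id", "pen_id", "breed", "day_index", "hour", "t_start", "t_end",
    "NVM", "OTM_s", "TM_s", "FIM_g", "FR_gs", "FRM_gs", "IBM_s", "valid",
]


def build_meals(visits: pd.DataFrame, criteria: pd.DataFrame | dict) -> pd.DataFrame:
    """Merge cleaned visits into meals using per-animal criteria.

    Parameters
    ----------
    visits:
        cleaned visit table (must carry ``day_index``).
    criteria:
        mapping ``animal_id -> criterion_min`` or a frame with columns
        ``animal_id`` and ``criterion_min``.

    Consecutive visits merge when the end-to-start gap is strictly less
    than the criterion (a gap exactly equal to it starts a new meal).
    Zero-duration meals have undefined FR; they are kept in the table
    but flagged ``valid = False``.
    """
    if isinstance(criteria, pd.DataFrame):
        crit_map = criteria.set_index("animal_id")["criterion_min"].to_dict()
    else:
        crit_map = dict(criteria)
    missing = set(visits["animal_id"].unique()) - set(crit_map)
    if missing:
        raise ValueError(f"no meal criterion for animals: {sorted(missing)[:5]} ...")

    df = visits.sort_values(["animal_id", "t_start"], kind="stable").copy()
    df["t_end_v"] = df["t_start"] + pd.to_timedelta(df["duration_s"], unit="s")
    prev_end = df.groupby("animal_id")["t_end_v"].shift(1)
    gap_min = (df["t_start"] - prev_end).dt.total_seconds() / 60.0
    crit = df["animal_id"].map(crit_map).astype(float)
    new_meal = gap_min.isna() | (gap_min >= crit)
    df["meal_id"] = new_meal.groupby(df["animal_id"]).cumsum().astype(int)

    grp = df.groupby(["animal_id", "meal_id"], sort=False)
    meals = grp.agg(
        pen_id=("pen_id", "first"),
        breed=("breed", "first"),
        day_index=("day_index", "first"),
        t_start=("t_start", "first"),
        t_end=("t_end_v", "last"),
        NVM=("t_start", "size"),
        OTM_s=("duration_s", "sum"),
        FIM_g=("intake_g", "sum"),
    ).reset_index()
    meals["TM_s"] = (meals["t_end"] - meals["t_start"]).dt.total_seconds()
    with np.errstate(divide="ignore", invalid="ignore"):
        meals["FR_gs"] = np.where(meals["OTM_s"] > 0, meals["FIM_g"] / meals["OTM_s"], np.nan)
        meals["FRM_gs"] = np.where(meals["TM_s"] > 0, meals["FIM_g"] / meals["TM_s"], np.nan)
    meals["IBM_s"] = (
        meals.groupby("animal_id")["t_start"].diff().dt.total_seconds()
    )
    meals["valid"] = meals["OTM_s"] > 0
    meals["hour"] = meals["t_start"].dt.hour
    meals = meals.sort_values(["animal_id", "t_start"], kind="stable").reset_index(drop=True)
    return meals[MEAL_COLUMNS]


def aggregate_daily(meals: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily sums per animal plus the whole-period observation summary.

    A meal belongs to the calendar day of its start; days without meals
    produce no row.  Returns ``(daily, summary)`` where ``summary`` has
    one row per animal with ND (days observed), TFI and ADFI.
    """
    m = meals[meals["valid"]]
    grp = m.groupby(["animal_id", "day_index"], sort=True)
    daily = grp.agg(
        pen_id=("pen_id", "first"),
        breed=("breed", "first"),
        TNM=("NVM", "size"),
        TNV=("NVM", "sum"),
        OT_day_s=("OTM_s", "sum"),
        TM_day_s=("TM_s", "sum"),
        FI_day_g=("FIM_g", "sum"),
        mean_FIM_g=("FIM_g", "mean"),
        mean_IBM_s=("IBM_s", "mean"),
    ).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        daily["FR_day_gs"] = np.where(
            daily["OT_day_s"] > 0, daily["FI_day_g"] / daily["OT_day_s"], np.nan
        )
        daily["FRM_day_gs"] = np.where(
            daily["TM_day_s"] > 0, daily["FI_day_g"] / daily["TM_day_s"], np.nan
        )
    summary = daily.groupby("animal_id", sort=True).agg(
        pen_id=("pen_id", "first"),
        breed=("breed", "first"),
        ND=("day_index", "size"),
        TFI_g=("FI_day_g", "sum"),
    ).reset_index()
    summary["ADFI_gd"] = summary["TFI_g"] / summary["ND"]
    return daily, summary


def aggregate_hourly(meals: pd.DataFrame, summary: pd.DataFrame) -> pd.DataFrame:
    """Per-hour per-day averages: sums by clock hour divided by ND.

    Every animal gets all 24 hour rows; hours without meals are zero for
    additive traits.  FR/FRM per hour are recomputed from the hourly
    intake and time sums (NaN where the denominator is zero).
    """
    nd = summary.set_index("animal_id")["ND"]
    m = meals[meals["valid"]]
    grp = m.groupby(["animal_id", "hour"], sort=True)
    hourly = grp.agg(
        TNM=("NVM", "size"),
        TNV=("NVM", "sum"),
        OTM_s=("OTM_s", "sum"),
        TM_s=("TM_s", "sum"),
        FIM_g=("FIM_g", "sum"),
    ).reset_index()
    full = pd.MultiIndex.from_product(
        [nd.index, range(24)], names=["animal_id", "hour"]
    ).to_frame(index=False)
    hourly = full.merge(hourly, on=["animal_id", "hour"], how="left").fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        hourly["FR_gs"] = np.where(hourly["OTM_s"] > 0, hourly["FIM_g"] / hourly["OTM_s"], np.nan)
        hourly["FRM_gs"] = np.where(hourly["TM_s"] > 0, hourly["FIM_g"] / hourly["TM_s"], np.nan)
    nd_vec = hourly["animal_id"].map(nd).astype(float)
    for col in ("TNM", "TNV", "OTM_s", "TM_s", "FIM_g"):
        hourly[col] = hourly[col] / nd_vec
    return hourly
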