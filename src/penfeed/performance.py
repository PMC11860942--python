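"""Growth, carcass and feed-efficiency traits.

Growth is summarised by the OLS slope of body weight on age (ADGreg,
g/d) fitted to the feeder-scale readings of each animal.  Feed
efficiency combines the classical feed conversion ratio with the
residual traits:

RFI   residual of ADFI ~ ADGreg + MW + Lean%   (lower = more efficient)
RG    residual of ADGreg ~ ADFI + MW + Lean%   (higher = more efficient)
RIG   RG - RFI

where MW = ((BWs + SW) / 2) ** 0.75 in kg^0.75 is the metabolic
mid-weight.  Residual fits run separately per breed and, by OLS with an
intercept, have exactly zero mean within each fitting cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


def compute_adg_reg(age_days: np.ndarray, weight_g: np.ndarray) -> tuple[float, float]:
    """OLS slope (g/day) and intercept (g) of body weight on age.

    Any age origin works: the slope is translation invariant.
    """
    age = np.asarray(age_days, dtype=float)
    w = np.asarray(weight_g, dtype=float)
    if np.unique(age).size < 2:
        raise ValueError("ADGreg needs weight readings at two or more distinct ages")
    res = stats.linregress(age, w)
    return float(res.slope), float(res.intercept)


def growth_traits(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-animal growth summaries from feeder-scale readings.

    BWs and SW are the fitted regression values at the first and last
    observed age (robust to scale noise); BWG = SW - BWs and the
    metabolic weight uses the mid-period mean.  Weights in the visit log
    are grams; BWs/SW/BWG are reported in kg.
    """
    rows = []
    t0 = visits["t_start"].min()
    for animal_id, sub in visits.groupby("animal_id", sort=True):
        age = (sub["t_start"] - t0).dt.total_seconds() / 86400.0
        try:
            slope, intercept = compute_adg_reg(age.to_numpy(), sub["weight_g"].to_numpy())
        except ValueError:
            rows.append({"animal_id": animal_id, "ADGreg_gd": np.nan})
            continue
        bws_g = intercept + slope * age.min()
        sw_g = intercept + slope * age.max()
        bws, sw = bws_g / 1000.0, sw_g / 1000.0
        rows.append(
            {
                "animal_id": animal_id,
                "ADGreg_gd": slope,
                "BWs_kg": bws,
                "SW_kg": sw,
                "BWG_kg": sw - bws,
                "MW": ((bws + sw) / 2.0) ** 0.75,
            }
        )
    return pd.DataFrame(rows)


def compute_carcass(roster: pd.DataFrame) -> pd.DataFrame:
    """Carcass composition percentages from the cut weights.

    Ham%, Fat% and Loin% are cut weight over half-carcass weight, and
    Lean% = 25.08 + 0.73 Ham% + 0.87 Loin% - 1.23 Fat%.  Missing inputs
    propagate to missing percentages.
    """
    half = roster["half_carcass_weight_g"]
    out = pd.DataFrame({"animal_id": roster["animal_id"]})
    out["Ham_pct"] = 100.0 * roster["ham_weight_g"] / half
    out["Fat_pct"] = 100.0 * roster["back_fat_g"] / half
    out["Loin_pct"] = 100.0 * roster["loin_weight_g"] / half
    out["Lean_pct"] = (
        25.08 + 0.73 * out["Ham_pct"] + 0.87 * out["Loin_pct"] - 1.23 * out["Fat_pct"]
    )
    return out


def compute_fcr(adfi_gd, adg_gd, tfi_g=None, bwg_g=None):
    """Feed conversion ratio, primary (ADFI/ADGreg) and total-basis (TFI/BWG).

    Non-positive denominators give NaN.  Returns ``(fcr, fcr_tb)``;
    ``fcr_tb`` is NaN when totals are not supplied.
    """
    adfi = np.asarray(adfi_gd, dtype=float)
    adg = np.asarray(adg_gd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fcr = np.where(adg > 0, adfi / adg, np.nan)
        if tfi_g is not None and bwg_g is not None:
            bwg = np.asarray(bwg_g, dtype=float)
            fcr_tb = np.where(bwg > 0, np.asarray(tfi_g, dtype=float) / bwg, np.nan)
        else:
            fcr_tb = np.full_like(fcr, np.nan)
    return fcr, fcr_tb


def _residuals(df: pd.DataFrame, response: str, predictors: list[str]) -> pd.Series:
    X = sm.add_constant(df[predictors])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for {response} ~ {predictors}: "
            "one or more predictor columns are collinear"
        )
    fit = sm.OLS(df[response], X).fit()
    return fit.resid


def compute_residual_traits(cohort: pd.DataFrame, min_rows: int = 5) -> pd.DataFrame:
    """RFI, RG and RIG per animal, fitted separately within each breed.

    Rows with any missing input (ADFI, ADGreg, MW, Lean%) are excluded
    from the fit and get missing residual traits.  Cohorts smaller than
    ``min_rows`` complete rows are skipped entirely.
    """
    need = ["ADFI_gd", "ADGreg_gd", "MW", "Lean_pct"]
    out = cohort[["animal_id", "breed"]].copy()
    out["RFI"] = np.nan
    out["RG"] = np.nan
    for _, idx in cohort.groupby("breed").groups.items():
        sub = cohort.loc[idx].dropna(subset=need)
        if len(sub) < min_rows:
            continue
        rfi = _residuals(sub, "ADFI_gd", ["ADGreg_gd", "MW", "Lean_pct"])
        rg = _residuals(sub, "ADGreg_gd", ["ADFI_gd", "MW", "Lean_pct"])
        out.loc[sub.index, "RFI"] = rfi
        out.loc[sub.index, "RG"] = rg
    out["RIG"] = out["RG"] - out["RFI"]
    return out


def performance_table(
    visits: pd.DataFrame, roster: pd.DataFrame, summary: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the full per-animal performance table.

    Combines growth (from scale readings), intake totals (from the
    observation summary), carcass percentages (from the roster) and the
    per-breed residual efficiency traits.
    """
    growth = growth_traits(visits)
    carcass = compute_carcass(roster)
    df = (
        summary[["animal_id", "breed", "ND", "TFI_g", "ADFI_gd"]]
        .merge(growth, on="animal_id", how="left")
        .merge(carcass, on="animal_id", how="left")
    )
    fcr, fcr_tb = compute_fcr(
        df["ADFI_gd"], df["ADGreg_gd"], df["TFI_g"], df["BWG_kg"] * 1000.0
    )
    df["FCR"] = fcr
    df["FCR_tb"] = fcr_tb
    resid = compute_residual_traits(df)
    df = df.merge(resid[["animal_id", "RFI", "RG", "RIG"]], on="animal_id", how="left")
    return df
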