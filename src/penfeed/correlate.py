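"""Per-animal trait summaries and Pearson correlation matrices.

The unit of the correlation analysis is the animal: per-meal traits are
averaged over an animal's (post-filter) meals, daily traits over its
observed days, and ranking/performance traits are carried as-is.  The
correlation matrix uses pairwise-complete observations with a two-sided
t-test p-value per cell; cells with p below the significance level are
flagged.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats

MEAL_TRAITS = ["NVM", "TM_s", "OTM_s", "FIM_g", "FR_gs", "FRM_gs", "IBM_s"]
#: AnimalSummary columns entering the default correlation analysis
DEFAULT_TRAITS = [
    "TNM", "NVM", "TM_s", "OTM_s", "FIM_g", "FR_gs", "FRM_gs", "IBM_s",
    "SW_kg", "ADGreg_gd", "FCR", "RFI", "RG", "RIG",
    "Position", "ratePrefTime_a", "ratePrefTime_b",
    "rateNV", "rateNM", "rateFI", "rateOT",
]


def build_summary(
    meals: pd.DataFrame,
    daily: pd.DataFrame,
    rank: pd.DataFrame,
    performance: pd.DataFrame,
) -> pd.DataFrame:
    """One row per animal: trait means joined with rank and performance.

    Raises if any source table carries duplicate animal rows.
    """
    m = meals[meals["valid"]]
    meal_means = m.groupby("animal_id")[MEAL_TRAITS].mean().reset_index()
    tnm = (
        daily.groupby("animal_id")["TNM"].mean().rename("TNM").reset_index()
    )
    base = meals.drop_duplicates("animal_id")[["animal_id", "pen_id", "breed"]]
    out = base.merge(meal_means, on="animal_id", how="left").merge(
        tnm, on="animal_id", how="left"
    )
    for name, table in (("rank", rank), ("performance", performance)):
        if table["animal_id"].duplicated().any():
            raise ValueError(f"duplicate animal rows in {name} table")
        cols = [c for c in table.columns if c not in ("pen_id", "breed")]
        out = out.merge(table[cols], on="animal_id", how="left")
    return out


def pearson_matrix(
    summary: pd.DataFrame,
    traits: list[str] | None = None,
    by: str | None = None,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations with significance flags.

    Returns a long frame (``group``, ``trait_a``, ``trait_b``, ``r``,
    ``p``, ``n``, ``significant``); ``by`` splits the cohort (e.g. by
    breed).  Cells with fewer than 3 complete pairs or a zero-variance
    trait get ``r = NaN``.  ``bh_correct`` applies a Benjamini-Hochberg
    adjustment to the p-values before flagging (off by default).
    """
    if traits is None:
        traits = [c for c in DEFAULT_TRAITS if c in summary.columns]
    groups = summary.groupby(by) if by else [("all", summary)]
    rows = []
    for label, sub in groups:
        for a, b in combinations_with_replacement(traits, 2):
            if a == b:
                col = sub[a].dropna()
                n = len(col)
                var = col.var(ddof=1) if n > 1 else 0.0
                ok = np.isfinite(var) and var > 0
                r, p = (1.0, 0.0) if ok else (np.nan, np.nan)
                rows.append(
                    {"group": label, "trait_a": a, "trait_b": b, "r": r, "p": p, "n": n}
                )
                continue
            pair = sub[[a, b]].dropna()
            n = len(pair)
            if n < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(pair[a], pair[b])
            rows.append(
                {"group": label, "trait_a": a, "trait_b": b, "r": r, "p": p, "n": n}
            )
    out = pd.DataFrame(rows)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        ok = out["p"].notna() & (out["trait_a"] != out["trait_b"])
        adj = out["p"].copy()
        if ok.any():
            adj.loc[ok] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["p_adj"] = adj
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def get_r(matrix: pd.DataFrame, a: str, b: str, group=None) -> float:
    """Convenience lookup of one correlation from the long-format matrix."""
    m = matrix
    if group is not None:
        m = m[m["group"] == group]
    hit = m[((m["trait_a"] == a) & (m["trait_b"] == b)) | ((m["trait_a"] == b) & (m["trait_b"] == a))]
    if hit.empty:
        raise KeyError(f"no correlation cell for ({a}, {b})")
    return float(hit["r"].iloc[0])
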