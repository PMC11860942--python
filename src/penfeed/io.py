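"""Reading, validation and cleaning of electronic-feeder visit logs.

A visit record is one stay of one animal at its pen's single automatic
feeder: who, when, for how long, how much was eaten, and the body weight
read off the integrated scale.  Cleaning applies the record-exclusion
rules used throughout the package: pens that lost an animal are dropped
entirely, the (incomplete) first and last calendar day of each pen are
trimmed, and rows with missing values or unresolvable animal identities
are discarded.  Every removal is attributed to exactly one rule so the
counts in the :class:`CleaningReport` are conserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical visit-log columns (CSV headers can be remapped via ``dialect``)
VISIT_COLUMNS = ["pen_id", "animal_id", "breed", "t_start", "duration_s", "intake_g", "weight_g"]
ROSTER_COLUMNS = [
    "animal_id", "pen_id", "breed", "sex", "status",
    "ham_weight_g", "loin_weight_g", "back_fat_g", "half_carcass_weight_g",
]

#: removal rules, in the order they are applied (first match wins)
RULE_DEAD_PEN = "dead_or_culled_pen"
RULE_EDGE_DAYS = "incomplete_first_last_day"
RULE_MISSING = "missing_or_incorrect_identification"
RULE_ORDER = (RULE_DEAD_PEN, RULE_EDGE_DAYS, RULE_MISSING)


class ConfigError(ValueError):
    """Raised when an input file does not provide the required columns."""


@dataclass
class CleaningReport:
    """Bookkeeping of the cleaning pass: input size, per-rule removals, output size."""

    n_input: int
    n_removed_by_rule: dict[str, int] = field(default_factory=dict)
    n_output: int = 0
    n_overlap_truncated: int = 0

    @property
    def n_removed(self) -> int:
        return sum(self.n_removed_by_rule.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_by_rule": dict(self.n_removed_by_rule),
            "n_output": self.n_output,
            "n_overlap_truncated": self.n_overlap_truncated,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def read_visits(path: str | Path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a visit-log CSV into a typed frame.

    Parameters
    ----------
    path:
        CSV with one row per feeder visit.
    dialect:
        optional mapping from the file's column names to the canonical
        names in :data:`VISIT_COLUMNS`.

    Malformed timestamps or numeric fields become NaT/NaN and are later
    removed (and counted) by :func:`clean_visits`; they are never
    silently dropped here.
    """
    df = pd.read_csv(path, dtype=str)
    if dialect:
        df = df.rename(columns=dialect)
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"visit file {path} is missing required columns: {missing}")
    df = df[VISIT_COLUMNS].copy()
    df["t_start"] = pd.to_datetime(df["t_start"], errors="coerce", format="ISO8601")
    for col in ("duration_s", "intake_g", "weight_g"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    # empty identifier strings count as missing identification
    for col in ("pen_id", "animal_id"):
        df[col] = df[col].replace("", np.nan)
    return df


def read_roster(path: str | Path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read the pen/animal roster CSV (carcass columns optional)."""
    df = pd.read_csv(path, dtype=str)
    if dialect:
        df = df.rename(columns=dialect)
    required = ["animal_id", "pen_id", "breed", "sex", "status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"roster file {path} is missing required columns: {missing}")
    for col in ROSTER_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[ROSTER_COLUMNS].copy()
    for col in ("ham_weight_g", "loin_weight_g", "back_fat_g", "half_carcass_weight_g"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df["animal_id"].duplicated().any():
        dup = df.loc[df["animal_id"].duplicated(), "animal_id"].tolist()
        raise ConfigError(f"duplicate animal_id in roster: {dup}")
    return df


def t_end(visits: pd.DataFrame) -> pd.Series:
    """Visit end time: start plus duration."""
    return visits["t_start"] + pd.to_timedelta(visits["duration_s"], unit="s")


def _truncate_overlaps(visits: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Resolve physically impossible overlaps at a pen's single feeder.

    The later visit is truncated to start at the earlier visit's end
    (intake is preserved; duration shrinks, floored at zero).
    """
    out = []
    n_trunc = 0
    for _, pen in visits.groupby("pen_id", sort=False):
        pen = pen.sort_values("t_start", kind="stable").copy()
        starts = pen["t_start"].to_numpy()
        durs = pen["duration_s"].to_numpy(dtype=float)
        # iterate: truncation of one visit can cascade to the next
        prev_end = None
        new_starts = starts.copy()
        new_durs = durs.copy()
        for i in range(len(pen)):
            s = new_starts[i]
            e = s + np.timedelta64(int(round(new_durs[i])), "s")
            if prev_end is not None and s < prev_end:
                shift = (prev_end - s) / np.timedelta64(1, "s")
                new_starts[i] = prev_end
                new_durs[i] = max(0.0, new_durs[i] - shift)
                e = prev_end + np.timedelta64(int(round(new_durs[i])), "s")
                n_trunc += 1
            prev_end = e
        pen["t_start"] = new_starts
        pen["duration_s"] = new_durs
        out.append(pen)
    return pd.concat(out, ignore_index=True), n_trunc


def clean_visits(
    visits: pd.DataFrame, roster: pd.DataFrame
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the record-exclusion rules and annotate retained visits.

    Rules, in order (a row is attributed to the first rule that removes it):

    1. all visits of pens containing any dead or culled animal;
    2. for each remaining pen, all visits on the pen's first and last
       calendar day (those days are incomplete by construction);
    3. rows with missing values, or animal ids absent from the roster.

    The output gains ``day_index`` (0-based, per pen, from the first
    retained date) and is sorted by pen and start time.  Re-cleaning an
    already-cleaned frame is a no-op: edge days are identified from the
    raw log, and a frame carrying ``day_index`` is recognised as cleaned.

    Raises
    ------
    ValueError
        if ``visits`` is empty or nothing survives cleaning.
    """
    if len(visits) == 0:
        raise ValueError("no visits to clean")
    already_cleaned = "day_index" in visits.columns
    report = CleaningReport(n_input=len(visits))
    df = visits.copy()

    # rule (a): pens with dead/culled animals
    bad_pens = set(roster.loc[roster["status"].str.lower() != "alive", "pen_id"])
    mask_a = df["pen_id"].isin(bad_pens)
    report.n_removed_by_rule[RULE_DEAD_PEN] = int(mask_a.sum())
    df = df[~mask_a]

    # rule (b): first and last calendar day per pen (skip if already trimmed)
    if already_cleaned:
        report.n_removed_by_rule[RULE_EDGE_DAYS] = 0
    else:
        dates = df["t_start"].dt.normalize()
        first = dates.groupby(df["pen_id"]).transform("min")
        last = dates.groupby(df["pen_id"]).transform("max")
        # unparseable timestamps cannot be day-assigned; they fall through to rule (c)
        mask_b = ((dates == first) | (dates == last)) & ~dates.isna()
        report.n_removed_by_rule[RULE_EDGE_DAYS] = int(mask_b.sum())
        df = df[~mask_b]

    # rule (c): missing values / unknown animals
    known = set(roster["animal_id"])
    mask_c = (
        df[["pen_id", "animal_id", "t_start", "duration_s", "intake_g", "weight_g"]]
        .isna()
        .any(axis=1)
    ) | ~df["animal_id"].isin(known)
    report.n_removed_by_rule[RULE_MISSING] = int(mask_c.sum())
    df = df[~mask_c]

    if len(df) == 0:
        raise ValueError("empty after cleaning: all visit records removed")

    df, n_trunc = _truncate_overlaps(df)
    report.n_overlap_truncated = n_trunc

    # per-pen day index from the first retained date
    dates = df["t_start"].dt.normalize()
    first = dates.groupby(df["pen_id"]).transform("min")
    df["day_index"] = ((dates - first).dt.days).astype(int)

    df = df.sort_values(["pen_id", "t_start"], kind="stable").reset_index(drop=True)
    report.n_output = len(df)
    return df, report
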