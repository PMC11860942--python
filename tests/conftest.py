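"""Shared fixtures: a small simulated cohort run end-to-end once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from penfeed.pipeline import RunConfig, run_all
from penfeed.simulate import SimConfig


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_pens=3, n_days=20, seed=7)


@pytest.fixture(scope="session")
def small_run(small_cfg, tmp_path_factory):
    """Full pipeline results on a 3-pen, 20-day simulated cohort."""
    out = tmp_path_factory.mktemp("small_run")
    return run_all(RunConfig(simulation=small_cfg, seed=7), out)


def make_visits(rows: list[tuple]) -> pd.DataFrame:
    """Build a visit frame from (pen, animal, breed, iso_start, dur_s, intake_g, weight_g)."""
    df = pd.DataFrame(
        rows,
        columns=["pen_id", "animal_id", "breed", "t_start", "duration_s", "intake_g", "weight_g"],
    )
    df["t_start"] = pd.to_datetime(df["t_start"])
    return df


def make_roster(animals: list[tuple]) -> pd.DataFrame:
    """Build a roster from (animal, pen, breed, sex, status) tuples."""
    df = pd.DataFrame(animals, columns=["animal_id", "pen_id", "breed", "sex", "status"])
    for col in ("ham_weight_g", "loin_weight_g", "back_fat_g", "half_carcass_weight_g"):
        df[col] = float("nan")
    return df
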