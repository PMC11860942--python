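"""End-to-end pipeline: simulate/load -> clean -> criterion -> meals ->
outlier filter -> daily/hourly traits -> ranking -> performance -> correlations.

Every stage writes a plain CSV/JSON artifact into the run directory so
any stage can be inspected or rerun in isolation; a manifest records row
counts, checksums and the hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import correlate, criterion, io, meals as meals_mod, outliers, performance, rank
from .simulate import SimConfig, simulate


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (fully serialisable)."""

    visits_csv: str | None = None
    roster_csv: str | None = None
    simulation: SimConfig | None = None
    seed: int = 0

    criterion_t_max: int = 60
    criterion_window: int = 5
    criterion_min_gaps: int = 50
    event_threshold_min: float | None = None  # None -> per-pen median criterion
    windows_a: tuple = rank.WINDOW_A
    windows_b: tuple = rank.WINDOW_B_METHODS
    mcd_alpha: float = 0.75
    mcd_factor: float = 5.0
    mcd_level: float = 0.999
    filter_outliers: bool = True
    corr_alpha: float = 0.05
    corr_by_breed: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict() if self.simulation else None
        d["windows_a"] = [list(w) for w in self.windows_a]
        d["windows_b"] = [list(w) for w in self.windows_b]
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage in order, returning the in-memory results.

    Artifacts (visits, criteria, meals, traits, ranking, performance,
    correlations) land in ``outdir`` together with ``manifest.json``.
    Stage failures propagate with the stage named.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    artifacts: list[Path] = []
    cfg_dict = cfg.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "run_config.json").write_text(json.dumps(cfg_dict, indent=2, sort_keys=True))
    artifacts.append(out / "run_config.json")

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # --- input ---------------------------------------------------------
    if cfg.simulation is not None:
        sim_cfg = cfg.simulation
        visits_raw, roster, truth = stage("simulate", lambda: simulate(sim_cfg))
        results["truth"] = truth
        _write_csv(truth.animals, out / "truth_animals.csv")
        artifacts.append(out / "truth_animals.csv")
    else:
        if not cfg.visits_csv or not cfg.roster_csv:
            raise RuntimeError(
                "pipeline stage 'load' failed: need visits_csv and roster_csv "
                "when no simulation is configured"
            )
        visits_raw = stage("load", lambda: io.read_visits(cfg.visits_csv))
        roster = stage("load", lambda: io.read_roster(cfg.roster_csv))
    _write_csv(visits_raw, out / "visits_raw.csv")
    _write_csv(roster, out / "roster.csv")
    artifacts += [out / "visits_raw.csv", out / "roster.csv"]

    # --- clean ---------------------------------------------------------
    visits, report = stage("clean", lambda: io.clean_visits(visits_raw, roster))
    results["visits"] = visits
    results["cleaning_report"] = report
    _write_csv(visits, out / "visits_clean.csv")
    report.write_json(out / "cleaning_report.json")
    artifacts += [out / "visits_clean.csv", out / "cleaning_report.json"]

    # --- meal criterion ------------------------------------------------
    criteria = stage(
        "criterion",
        lambda: criterion.criteria_for_cohort(
            visits,
            t_max=cfg.criterion_t_max,
            window=cfg.criterion_window,
            min_gaps=cfg.criterion_min_gaps,
        ),
    )
    results["criteria"] = criteria
    _write_csv(criteria, out / "criteria.csv")
    artifacts.append(out / "criteria.csv")

    # --- meals ---------------------------------------------------------
    meals = stage("meals", lambda: meals_mod.build_meals(visits, criteria))
    if cfg.filter_outliers:
        meals_kept, flt_report = stage(
            "outliers",
            lambda: outliers.filter_meals(
                meals,
                alpha=cfg.mcd_alpha,
                level=cfg.mcd_level,
                factor=cfg.mcd_factor,
                seed=cfg.seed,
            ),
        )
        (out / "outlier_report.json").write_text(json.dumps(flt_report, indent=2))
        artifacts.append(out / "outlier_report.json")
    else:
        meals_kept, flt_report = meals, None
    results["meals"] = meals_kept
    results["outlier_report"] = flt_report
    _write_csv(meals_kept, out / "meals.csv")
    artifacts.append(out / "meals.csv")

    # --- aggregates ----------------------------------------------------
    daily, summary = stage("traits-daily", lambda: meals_mod.aggregate_daily(meals_kept))
    hourly = stage("traits-hourly", lambda: meals_mod.aggregate_hourly(meals_kept, summary))
    results["daily"], results["summary"], results["hourly"] = daily, summary, hourly
    for name, df in (("traits_daily", daily), ("summary", summary), ("traits_hourly", hourly)):
        _write_csv(df, out / f"{name}.csv")
        artifacts.append(out / f"{name}.csv")

    # --- social ranking ------------------------------------------------
    if cfg.event_threshold_min is None:
        pen_of = visits.drop_duplicates("animal_id").set_index("animal_id")["pen_id"]
        thr = (
            criteria.set_index("animal_id")["criterion_min"]
            .groupby(pen_of)
            .median()
            .to_dict()
        )
    else:
        thr = cfg.event_threshold_min
    rank_df = stage(
        "rank",
        lambda: rank.rank_traits(
            visits, daily, thr, windows_a=cfg.windows_a, windows_b=cfg.windows_b
        ),
    )
    results["rank"] = rank_df
    _write_csv(rank_df, out / "rank.csv")
    artifacts.append(out / "rank.csv")

    # --- performance ---------------------------------------------------
    perf = stage("performance", lambda: performance.performance_table(visits, roster, summary))
    results["performance"] = perf
    _write_csv(perf, out / "performance.csv")
    artifacts.append(out / "performance.csv")

    # --- correlations --------------------------------------------------
    summary_tbl = stage(
        "correlate", lambda: correlate.build_summary(meals_kept, daily, rank_df, perf)
    )
    corr = stage(
        "correlate",
        lambda: correlate.pearson_matrix(
            summary_tbl, by="breed" if cfg.corr_by_breed else None, alpha=cfg.corr_alpha
        ),
    )
    results["animal_summary"] = summary_tbl
    results["correlations"] = corr
    _write_csv(summary_tbl, out / "animal_summary.csv")
    _write_csv(corr, out / "correlations.csv")
    artifacts += [out / "animal_summary.csv", out / "correlations.csv"]

    manifest = {
        "config_hash": cfg_hash,
        "artifacts": {
            p.name: {
                "rows": sum(1 for _ in p.open()) - 1 if p.suffix == ".csv" else None,
                "sha256": _sha256(p),
            }
            for p in artifacts
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
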