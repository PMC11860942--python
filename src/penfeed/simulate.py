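"""Synthetic pen simulator for electronic-feeder visit logs.

Generates visit logs, rosters and latent truth with the statistical
structure the analysis pipeline assumes, so every stage can be tested
without external data:

* pens of ~14 pigs over ~100 days, one shared feeder per pen;
* bimodal circadian visit intensity (morning and afternoon peaks);
* two-timescale inter-visit gaps: seconds-scale pauses within meals and
  an hour-scale shifted log-normal between meals, calibrated so the
  combined per-minute start hazard bottoms out in the 9-10 min bin;
* an age trend in meals per day (early peak, late decline), intake and
  feeding rate;
* linear body-weight growth read off the feeder scale with noise;
* a latent dominance score that shifts meal frequency, eating speed,
  preferred-time access and queue priority at the feeder.

Feeder occupancy is resolved by a single-server priority queue per pen:
a visit that finds the feeder busy waits until it frees (dominant
animals are served first among the waiting), and is dropped if the wait
would exceed a cap.
"""

from __future__ import annotations

import heapq
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

MIN_PER_DAY = 1440.0


@dataclass
class SimConfig:
    """Generator parameters.  Defaults emulate a growing-finishing cohort.

    Times are minutes unless suffixed otherwise; intakes grams; rates g/s.
    """

    n_pens: int = 2
    animals_per_pen: int = 14
    n_days: int = 100
    start_date: str = "2018-03-01"
    breeds: tuple[str, ...] = ("B1", "B2", "B3")  # assigned to pens round-robin

    # circadian intensity: weighted von Mises peaks over a uniform floor
    circ_modes_h: tuple[float, ...] = (9.0, 17.0)
    circ_weights: tuple[float, ...] = (0.39, 0.39)
    circ_kappa: float = 2.2
    # crowding shortens meals: size scales with intensity^-exponent, so
    # busy hours see more but smaller meals and occupation stays feasible
    circ_size_exponent: float = 0.6

    # meals per day along the fattening period
    tnm_day0: float = 7.5
    tnm_peak: float = 8.8
    tnm_peak_day: float = 14.0
    tnm_min: float = 6.3
    tnm_min_day: float = 85.0

    # visits per meal: NVM = 1 + Poisson(nvm_extra_mean)
    nvm_extra_mean: float = 0.35

    # within-meal gap law: fast exponential pauses plus a slower
    # log-normal tail of displaced returns, truncated at wm_trunc_min
    wm_exp_mean_s: float = 45.0
    wm_slow_frac: float = 0.55
    wm_slow_median_min: float = 3.1
    wm_slow_sigma: float = 0.5
    wm_trunc_min: float = 20.0

    # between-meal gap law: bm_shift_min plus a two-part log-normal
    # mixture — a short "snack return" component and a long component
    # whose mean follows the daily meal budget (bm_mean_min pins the
    # long mean explicitly when set)
    bm_shift_min: float = 5.0
    bm_sigma: float = 1.0
    bm_mean_min: float | None = None
    bm_short_frac: float = 0.45
    bm_short_median_min: float = 13.8
    bm_short_sigma: float = 0.3

    # intake and feeding-rate trajectories
    intake_ramp: tuple[float, float] = (0.5, 1.5)  # relative daily intake day 0 -> last
    fr_day0: float = 0.35
    fr_dayN: float = 0.80
    fr_noise_sd: float = 0.10
    fim_noise_sd: float = 0.25

    # growth and intake-gain coupling
    adg_mean_gd: float = 950.0
    adg_sd_gd: float = 90.0
    bws_mean_kg: float = 23.0
    bws_sd_kg: float = 2.0
    scale_noise_sd_g: float = 500.0
    adfi_intercept_gd: float = 700.0
    adfi_slope: float = 1.7
    adfi_resid_sd_gd: float = 150.0

    # carcass composition (fractions of half-carcass weight)
    carcass_half_frac: float = 0.39      # half carcass as fraction of slaughter BW
    ham_frac_mean: float = 0.24
    ham_frac_sd: float = 0.012
    loin_frac_mean: float = 0.26
    loin_frac_sd: float = 0.015
    fat_frac_mean: float = 0.12
    fat_frac_sd: float = 0.015

    # dominance effects
    dom_tnm_effect: float = 0.10     # log-scale shift of meals/day per unit score
    dom_fr_effect: float = -0.08     # log-scale shift of feeding rate per unit score
    dom_pref_effect: float = 0.06    # shift of circadian peak mass per unit score
    dom_queue: bool = True           # dominant animals win ties at the feeder

    max_wait_min: float = 8.0
    frac_dead: float = 0.0           # fraction of animals marked dead (whole-pen removal)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = dict(d)
        for k in ("breeds", "circ_modes_h", "circ_weights", "intake_ramp"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SimTruth:
    """Latent quantities for recovery tests."""

    animals: pd.DataFrame          # per-animal z, ADG, BWs, ADFI, multipliers
    hazard_argmin_min: int         # trough of the configured gap hazard
    n_dropped_visits: int
    n_delayed_visits: int


@dataclass
class HazardOracle:
    t: np.ndarray
    hazard: np.ndarray
    argmin_min: int


# ---------------------------------------------------------------- trajectories

def tnm_target(cfg: SimConfig, day: np.ndarray | float) -> np.ndarray:
    """Cohort-level meals/day trajectory (piecewise linear)."""
    xs = [0.0, cfg.tnm_peak_day, cfg.tnm_min_day, max(cfg.n_days, cfg.tnm_min_day + 1)]
    ys = [cfg.tnm_day0, cfg.tnm_peak, cfg.tnm_min, cfg.tnm_min]
    return np.interp(day, xs, ys)


def intake_ramp(cfg: SimConfig, day: np.ndarray | float) -> np.ndarray:
    r0, r1 = cfg.intake_ramp
    span = max(cfg.n_days - 1, 1)
    raw = r0 + (r1 - r0) * np.asarray(day, dtype=float) / span
    return raw / ((r0 + r1) / 2.0)


def fr_target(cfg: SimConfig, day: np.ndarray | float) -> np.ndarray:
    span = max(cfg.n_days - 1, 1)
    return cfg.fr_day0 + (cfg.fr_dayN - cfg.fr_day0) * np.asarray(day, dtype=float) / span


def circadian_intensity(cfg: SimConfig, hour: np.ndarray | float,
                        peak_share: float | None = None) -> np.ndarray:
    """Relative visit intensity by clock hour, mean 1 over the day."""
    h = np.asarray(hour, dtype=float)
    w = np.asarray(cfg.circ_weights, dtype=float)
    base_share = w.sum()
    if peak_share is not None:
        w = w * (peak_share / base_share)
    floor = 1.0 - w.sum()
    dens = np.full_like(h, floor / 24.0)
    for mode, wj in zip(cfg.circ_modes_h, w):
        ang = 2.0 * np.pi * (h - mode) / 24.0
        dens = dens + wj * np.exp(cfg.circ_kappa * np.cos(ang)) / (24.0 * np.i0(cfg.circ_kappa))
    return 24.0 * dens


# ------------------------------------------------------------------- gap laws

def _within_cdf(cfg: SimConfig, t_min: np.ndarray) -> np.ndarray:
    """CDF of the within-meal gap mixture, truncated at wm_trunc_min."""
    t = np.asarray(t_min, dtype=float)
    scale = cfg.wm_exp_mean_s / 60.0
    T = cfg.wm_trunc_min
    f_exp = np.clip((1 - np.exp(-t / scale)) / (1 - np.exp(-T / scale)), 0, 1)
    mu = np.log(cfg.wm_slow_median_min)
    norm = stats.norm.cdf((np.log(T) - mu) / cfg.wm_slow_sigma)
    with np.errstate(divide="ignore"):
        f_ln = np.where(
            t > 0,
            stats.norm.cdf((np.log(np.maximum(t, 1e-12)) - mu) / cfg.wm_slow_sigma) / norm,
            0.0,
        )
    f_ln = np.clip(f_ln, 0, 1)
    f = (1 - cfg.wm_slow_frac) * f_exp + cfg.wm_slow_frac * f_ln
    return np.where(t >= T, 1.0, f)


def _between_short_mean(cfg: SimConfig) -> float:
    return cfg.bm_short_median_min * float(np.exp(cfg.bm_short_sigma ** 2 / 2.0))


def _between_lognorm_mean(
    cfg: SimConfig, day: float, meal_dur_min: float, tnm_mult: float = 1.0
) -> float:
    """Target mean of the long log-normal part from the daily meal budget."""
    if cfg.bm_mean_min is not None:
        return cfg.bm_mean_min
    nbar = float(tnm_target(cfg, day)) * tnm_mult
    e_total = MIN_PER_DAY / nbar - cfg.bm_shift_min - meal_dur_min
    q = cfg.bm_short_frac
    e_long = (e_total - q * _between_short_mean(cfg)) / (1.0 - q)
    return max(e_long, 10.0)


def _between_cdf(cfg: SimConfig, t_min: np.ndarray, e_long: float) -> np.ndarray:
    """CDF of the shifted between-meal mixture at the given long-part mean."""
    x = np.asarray(t_min, dtype=float) - cfg.bm_shift_min
    mu_l = np.log(e_long) - cfg.bm_sigma ** 2 / 2.0
    mu_s = np.log(cfg.bm_short_median_min)
    with np.errstate(divide="ignore"):
        lx = np.log(np.maximum(x, 1e-12))
        cdf_l = np.where(x > 0, stats.norm.cdf((lx - mu_l) / cfg.bm_sigma), 0.0)
        cdf_s = np.where(x > 0, stats.norm.cdf((lx - mu_s) / cfg.bm_short_sigma), 0.0)
    return (1.0 - cfg.bm_short_frac) * cdf_l + cfg.bm_short_frac * cdf_s


def _mean_meal_duration_min(cfg: SimConfig, day: float) -> float:
    """Expected meal span for an average animal on a given day."""
    adfi = cfg.adfi_intercept_gd + cfg.adfi_slope * cfg.adg_mean_gd
    fi_day = adfi * float(intake_ramp(cfg, day))
    nbar = float(tnm_target(cfg, day))
    occ_s = fi_day / nbar / float(fr_target(cfg, day))
    e_within = (
        (1 - cfg.wm_slow_frac) * cfg.wm_exp_mean_s / 60.0
        + cfg.wm_slow_frac
        * cfg.wm_slow_median_min * np.exp(cfg.wm_slow_sigma ** 2 / 2.0)
    )
    return occ_s / 60.0 + cfg.nvm_extra_mean * e_within


def theoretical_hazard(cfg: SimConfig, t_max: int = 60) -> HazardOracle:
    """Numeric per-minute start hazard of the configured gap mixture.

    The mixture weights within-meal and between-meal gaps by their
    expected counts (NVM - 1 within gaps and one between gap per meal);
    the between component averages the day-varying log-normal over the
    simulated period, weighted by the daily meal count.  The argmin bin
    is the trough the criterion estimator is expected to recover.
    """
    t = np.arange(t_max + 1, dtype=float)
    p_w = cfg.nvm_extra_mean / (1.0 + cfg.nvm_extra_mean)
    f_w = _within_cdf(cfg, t)
    days = np.arange(cfg.n_days, dtype=float)
    weights = tnm_target(cfg, days)
    weights = weights / weights.sum()
    f_b = np.zeros_like(t)
    for d, wt in zip(days, weights):
        e_ln = _between_lognorm_mean(cfg, d, _mean_meal_duration_min(cfg, d))
        f_b = f_b + wt * _between_cdf(cfg, t, e_ln)
    f_mix = p_w * f_w + (1 - p_w) * f_b
    surv = 1.0 - f_mix[:-1]
    hazard = np.where(surv > 0, (f_mix[1:] - f_mix[:-1]) / np.maximum(surv, 1e-300), np.nan)
    return HazardOracle(
        t=np.arange(t_max), hazard=hazard, argmin_min=int(np.nanargmin(hazard))
    )


# ------------------------------------------------------------------ sampling

def _sample_between_gap(cfg: SimConfig, rng: np.random.Generator, e_long: float) -> float:
    """Unshifted between-meal mixture draw (minutes)."""
    if rng.random() < cfg.bm_short_frac:
        mu = np.log(cfg.bm_short_median_min)
        return float(np.exp(mu + cfg.bm_short_sigma * rng.standard_normal()))
    mu = np.log(e_long) - cfg.bm_sigma ** 2 / 2.0
    return float(np.exp(mu + cfg.bm_sigma * rng.standard_normal()))


def _sample_within_gaps(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Within-meal gaps in minutes (mixture, truncated by resampling)."""
    if n == 0:
        return np.empty(0)
    out = np.empty(n)
    slow = rng.random(n) < cfg.wm_slow_frac
    n_slow = int(slow.sum())
    out[~slow] = rng.exponential(cfg.wm_exp_mean_s / 60.0, n - n_slow)
    out[slow] = np.exp(
        np.log(cfg.wm_slow_median_min) + cfg.wm_slow_sigma * rng.standard_normal(n_slow)
    )
    # truncation: resample the rare draws beyond the cap
    for _ in range(100):
        bad = out >= cfg.wm_trunc_min
        if not bad.any():
            break
        out[bad] = rng.exponential(cfg.wm_exp_mean_s / 60.0, int(bad.sum()))
    return out


def _feasibility_check(cfg: SimConfig) -> None:
    adfi = cfg.adfi_intercept_gd + cfg.adfi_slope * cfg.adg_mean_gd
    days = np.arange(cfg.n_days)
    demand_s = cfg.animals_per_pen * adfi * intake_ramp(cfg, days) / fr_target(cfg, days)
    if demand_s.max() > 0.95 * 86400.0:
        raise ValueError(
            "infeasible configuration: expected feeder occupation exceeds 95% of the day "
            f"(worst day {demand_s.max() / 864.0:.1f}%)"
        )


class _PenSimulator:
    """Event-driven single-feeder pen: animals schedule their next visit
    relative to the actual end of their previous one, so feeder
    contention only adds waiting time and never compresses the sampled
    gap structure.  Waiting animals are served in dominance order; an
    animal that would wait beyond the cap abandons the visit."""

    def __init__(self, cfg, anim_rngs, lam_tabs, fi_scale, tnm_scale, fr_scale, prio):
        self.cfg = cfg
        self.rngs = anim_rngs
        self.lam_tabs = lam_tabs
        self.fi_scale = fi_scale      # per-animal ADFI (g/d)
        self.tnm_scale = tnm_scale    # per-animal meals/day multiplier
        self.fr_scale = fr_scale      # per-animal feeding-rate multiplier
        self.prio = prio
        self.meal_rest: list[list] = [[] for _ in anim_rngs]
        self.records: list[tuple] = []  # (start_min, dur_min, intake_g, animal)
        self.n_dropped = 0
        self.n_delayed = 0

    def _advance_operational(self, a: int, t_min: float, op_amount: float) -> float:
        """Clock time reached after consuming ``op_amount`` units of
        operational time (the integral of the relative circadian intensity)
        starting at clock ``t_min`` — the time-rescaling construction of an
        inhomogeneous renewal process."""
        tab = self.lam_tabs[a]
        t = t_min
        remaining = op_amount
        while True:
            lam = max(float(tab[int((t % MIN_PER_DAY) / 15.0) % 96]), 1e-3)
            bin_end = (np.floor(t / 15.0) + 1.0) * 15.0
            cap = (bin_end - t) * lam
            if cap >= remaining:
                return t + remaining / lam
            remaining -= cap
            t = bin_end

    def _sample_meal(self, a: int, e_min: float):
        """Next meal after the animal's actual end time; returns the
        desired start and queues the meal's visits."""
        cfg, rng = self.cfg, self.rngs[a]
        d_ref = min(int(max(e_min, 0.0) // MIN_PER_DAY), cfg.n_days - 1)
        e_ln = _between_lognorm_mean(
            cfg, d_ref, _mean_meal_duration_min(cfg, d_ref), self.tnm_scale[a]
        )
        desired = self._advance_operational(
            a, e_min + cfg.bm_shift_min, _sample_between_gap(cfg, rng, e_ln)
        )
        d = min(int(desired // MIN_PER_DAY), cfg.n_days - 1)
        nvm = 1 + rng.poisson(cfg.nvm_extra_mean)
        fi_day = self.fi_scale[a] * float(intake_ramp(cfg, d))
        nbar = float(tnm_target(cfg, d)) * self.tnm_scale[a]
        lam_here = max(
            float(self.lam_tabs[a][int((desired % MIN_PER_DAY) / 15.0) % 96]), 1e-3
        )
        meal_intake = (
            fi_day / nbar
            * lam_here ** -cfg.circ_size_exponent
            * np.exp(-cfg.fim_noise_sd ** 2 / 2.0 + cfg.fim_noise_sd * rng.standard_normal())
        )
        fr_meal = float(fr_target(cfg, d)) * self.fr_scale[a] * np.exp(
            -cfg.fr_noise_sd ** 2 / 2.0 + cfg.fr_noise_sd * rng.standard_normal()
        )
        props = rng.dirichlet(np.full(nvm, 2.0)) if nvm > 1 else np.ones(1)
        intakes = meal_intake * props
        durs = intakes / fr_meal / 60.0
        gaps = _sample_within_gaps(cfg, rng, nvm - 1)
        self.meal_rest[a] = [
            (gaps[k - 1], durs[k], intakes[k]) for k in range(1, nvm)
        ]
        return desired, durs[0], intakes[0]

    def _next_arrival(self, a: int, e_min: float):
        if self.meal_rest[a]:
            gap, dur, intake = self.meal_rest[a].pop(0)
            return e_min + gap, dur, intake
        return self._sample_meal(a, e_min)

    def run(self, horizon_min: float) -> None:
        cfg = self.cfg
        arrivals: list = []   # (desired, seq, a, dur, intake)
        waiting: list = []    # (prio, desired, seq, a, dur, intake)
        seq = 0
        for a in range(len(self.rngs)):
            desired, dur, intake = self._sample_meal(a, 0.0)
            heapq.heappush(arrivals, (desired, seq, a, dur, intake))
            seq += 1
        free = 0.0
        while arrivals or waiting:
            while arrivals and arrivals[0][0] <= free:
                desired, s, a, dur, intake = heapq.heappop(arrivals)
                heapq.heappush(waiting, (self.prio[a], desired, s, a, dur, intake))
            if waiting:
                _, desired, _, a, dur, intake = heapq.heappop(waiting)
                wait = free - desired
                if wait > cfg.max_wait_min:
                    self.n_dropped += 1
                    end = desired + cfg.max_wait_min  # gave up at the cap
                else:
                    if wait > 0:
                        self.n_delayed += 1
                    self.records.append((free, dur, intake, a))
                    end = free + dur
                    free = end
            else:
                desired, _, a, dur, intake = heapq.heappop(arrivals)
                self.records.append((desired, dur, intake, a))
                end = desired + dur
                free = end
            nxt = self._next_arrival(a, end)
            if nxt[0] < horizon_min:
                heapq.heappush(arrivals, (nxt[0], seq, a, nxt[1], nxt[2]))
                seq += 1


def simulate(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (visit log, roster, truth) for one simulated cohort.

    Deterministic given ``cfg.seed``: pens and animals draw from
    deterministically spawned substreams, so a pen's log does not depend
    on how many other pens are simulated after it.
    """
    _feasibility_check(cfg)
    root = np.random.SeedSequence(cfg.seed)
    pen_seeds = root.spawn(cfg.n_pens + 1)
    rng_cohort = np.random.default_rng(pen_seeds[-1])

    n_animals = cfg.n_pens * cfg.animals_per_pen
    pen_ids = [f"P{p + 1:02d}" for p in range(cfg.n_pens)]
    animals = []
    for p, pen in enumerate(pen_ids):
        breed = cfg.breeds[p % len(cfg.breeds)]
        for a in range(cfg.animals_per_pen):
            animals.append((f"{pen}A{a + 1:02d}", pen, breed))
    adf = pd.DataFrame(animals, columns=["animal_id", "pen_id", "breed"])

    # latent per-animal quantities (cohort stream, fixed order)
    z = rng_cohort.standard_normal(n_animals)
    adg = cfg.adg_mean_gd + cfg.adg_sd_gd * rng_cohort.standard_normal(n_animals)
    bws_kg = cfg.bws_mean_kg + cfg.bws_sd_kg * rng_cohort.standard_normal(n_animals)
    adfi = (
        cfg.adfi_intercept_gd + cfg.adfi_slope * adg
        + cfg.adfi_resid_sd_gd * rng_cohort.standard_normal(n_animals)
    )
    tnm_mult = np.exp(cfg.dom_tnm_effect * z + 0.05 * rng_cohort.standard_normal(n_animals))
    fr_mult = np.exp(cfg.dom_fr_effect * z + 0.05 * rng_cohort.standard_normal(n_animals))
    base_share = float(np.sum(cfg.circ_weights))
    peak_share = np.clip(base_share + cfg.dom_pref_effect * z, 0.30, 0.95)

    visit_rows = []
    n_dropped = 0
    n_delayed = 0
    horizon_min = cfg.n_days * MIN_PER_DAY
    hours_grid = np.arange(0, 24, 0.25)

    for p, pen in enumerate(pen_ids):
        rng_pen = np.random.default_rng(pen_seeds[p])
        idx = np.arange(p * cfg.animals_per_pen, (p + 1) * cfg.animals_per_pen)
        anim_rngs = [
            np.random.default_rng(rng_pen.integers(0, 2 ** 31 - 1)) for _ in idx
        ]
        lam_tabs = [
            circadian_intensity(cfg, hours_grid, peak_share=float(peak_share[ai]))
            for ai in idx
        ]
        prio = -z[idx] if cfg.dom_queue else np.zeros(len(idx))
        sim = _PenSimulator(
            cfg, anim_rngs, lam_tabs,
            fi_scale=adfi[idx], tnm_scale=tnm_mult[idx], fr_scale=fr_mult[idx],
            prio=prio,
        )
        sim.run(horizon_min)
        n_delayed += sim.n_delayed
        n_dropped += sim.n_dropped

        start_min = np.array([r[0] for r in sim.records])
        dur_s = np.maximum(np.round([r[1] * 60.0 for r in sim.records]), 1).astype(np.int64)
        intake = np.array([r[2] for r in sim.records])
        local = np.array([r[3] for r in sim.records], dtype=int)
        start_s = np.round(start_min * 60.0).astype(np.int64)
        # rounding to whole seconds can reintroduce sub-second overlaps
        order = np.argsort(start_s, kind="stable")
        prev_end = -1
        for k in order:
            if start_s[k] < prev_end:
                start_s[k] = prev_end
            prev_end = start_s[k] + dur_s[k]
        # body weight read at the (actual) visit time
        rng_w = np.random.default_rng(rng_pen.integers(0, 2 ** 31 - 1))
        age_days = start_s / 86400.0
        weight = (
            bws_kg[idx][local] * 1000.0
            + adg[idx][local] * age_days
            + cfg.scale_noise_sd_g * rng_w.standard_normal(len(local))
        )
        for k in range(len(local)):
            ai = idx[local[k]]
            visit_rows.append(
                (
                    pen,
                    adf["animal_id"].iloc[ai],
                    adf["breed"].iloc[ai],
                    int(start_s[k]),
                    int(dur_s[k]),
                    float(intake[k]),
                    float(weight[k]),
                )
            )

    t0 = pd.Timestamp(cfg.start_date)
    visits = pd.DataFrame(
        visit_rows,
        columns=["pen_id", "animal_id", "breed", "start_s", "duration_s", "intake_g", "weight_g"],
    )
    visits["t_start"] = t0 + pd.to_timedelta(visits["start_s"], unit="s")
    visits = visits.drop(columns="start_s")
    visits = visits[
        ["pen_id", "animal_id", "breed", "t_start", "duration_s", "intake_g", "weight_g"]
    ].sort_values(["pen_id", "t_start"], kind="stable").reset_index(drop=True)
    visits["duration_s"] = visits["duration_s"].astype(float)
    visits["intake_g"] = visits["intake_g"].round(1)
    visits["weight_g"] = visits["weight_g"].round(0)

    # roster with carcass composition at slaughter
    sw_kg = bws_kg + adg * cfg.n_days / 1000.0
    half_g = cfg.carcass_half_frac * sw_kg * 1000.0
    ham = half_g * np.clip(
        rng_cohort.normal(cfg.ham_frac_mean, cfg.ham_frac_sd, n_animals), 0.05, None
    )
    loin = half_g * np.clip(
        rng_cohort.normal(cfg.loin_frac_mean, cfg.loin_frac_sd, n_animals), 0.05, None
    )
    fat = half_g * np.clip(
        rng_cohort.normal(cfg.fat_frac_mean, cfg.fat_frac_sd, n_animals), 0.02, None
    )
    status = np.array(["alive"] * n_animals, dtype=object)
    if cfg.frac_dead > 0:
        n_dead = int(round(cfg.frac_dead * n_animals))
        dead_idx = rng_cohort.choice(n_animals, size=n_dead, replace=False)
        status[dead_idx] = "dead"
    roster = adf.copy()
    roster["sex"] = np.where(roster["breed"] == cfg.breeds[0], "M", "F")
    roster["status"] = status
    roster["ham_weight_g"] = ham.round(0)
    roster["loin_weight_g"] = loin.round(0)
    roster["back_fat_g"] = fat.round(0)
    roster["half_carcass_weight_g"] = half_g.round(0)
    roster = roster[
        ["animal_id", "pen_id", "breed", "sex", "status",
         "ham_weight_g", "loin_weight_g", "back_fat_g", "half_carcass_weight_g"]
    ]

    truth_animals = adf.copy()
    truth_animals["dominance"] = z
    truth_animals["ADG_gd"] = adg
    truth_animals["BWs_kg"] = bws_kg
    truth_animals["ADFI_gd"] = adfi
    truth_animals["tnm_mult"] = tnm_mult
    truth_animals["fr_mult"] = fr_mult
    oracle = theoretical_hazard(cfg)
    truth = SimTruth(
        animals=truth_animals,
        hazard_argmin_min=oracle.argmin_min,
        n_dropped_visits=n_dropped,
        n_delayed_visits=n_delayed,
    )
    return visits, roster, truth
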