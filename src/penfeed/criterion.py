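"""Meal-criterion estimation from inter-visit intervals.

Feeder visits cluster into meals: the gaps between consecutive visits of
one animal are a mixture of short within-meal pauses (seconds to a few
minutes) and long between-meal intervals (tens of minutes to hours).
The meal criterion is the gap duration that separates the two regimes.

It is located on the discrete hazard of starting a new visit, ``Pstart``:
for each whole minute ``t``, the fraction of intervals that end in
``[t, t+1)`` among those still running at ``t``.  The hazard falls while
the within-meal component empties out, reaches a minimum, and rises
again as the between-meal component becomes due; after a 5-minute
rolling average the minute where the change in ``Pstart`` turns from
negative to positive is taken as the animal's criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

DEFAULT_T_MAX = 60
DEFAULT_WINDOW = 5
DEFAULT_MIN_GAPS = 50

SOURCE_INDIVIDUAL = "individual"
SOURCE_POOLED = "pooled-fallback"
METHOD_SIGN_CHANGE = "sign-change"
METHOD_ARGMIN = "argmin-fallback"


@dataclass
class PstartCurve:
    """Per-minute start hazard: at-risk counts, raw ratios and optional smoothing.

    ``raw[t]`` is NaN where no interval was still running (``n_at_risk == 0``).
    """

    t: np.ndarray
    n_at_risk: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray | None = None


@dataclass
class MealCriterion:
    animal_id: str
    criterion_min: int
    source: str  # individual | pooled-fallback
    method: str  # sign-change | argmin-fallback
    n_gaps: int


def compute_gaps(visits: pd.DataFrame) -> pd.DataFrame:
    """End-of-visit to start-of-next gaps, per animal, in minutes.

    The gap is the feeder-free time between consecutive visits of the
    same animal (occupation time is not part of the interval).  Animals
    with fewer than two visits contribute no gaps.

    Returns a frame with columns ``animal_id``, ``breed``, ``gap_min``.
    """
    df = visits.sort_values(["animal_id", "t_start"], kind="stable")
    end = df["t_start"] + pd.to_timedelta(df["duration_s"], unit="s")
    next_start = df.groupby("animal_id")["t_start"].shift(-1)
    gap_min = (next_start - end).dt.total_seconds() / 60.0
    out = pd.DataFrame(
        {"animal_id": df["animal_id"], "breed": df["breed"], "gap_min": gap_min}
    ).dropna(subset=["gap_min"])
    # overlap truncation guarantees non-negative gaps; clip defensively
    out["gap_min"] = out["gap_min"].clip(lower=0.0)
    return out.reset_index(drop=True)


def estimate_pstart(gaps: np.ndarray | pd.Series, t_max: int = DEFAULT_T_MAX) -> PstartCurve:
    """Raw per-minute start hazard of a gap sample.

    ``raw[t] = #{gaps in [t, t+1)} / #{gaps >= t}``.  Gaps of ``t_max``
    minutes or more are censored: they stay in every bin's at-risk count
    but enter no bin's numerator.
    """
    g = np.asarray(gaps, dtype=float)
    if g.size == 0:
        raise ValueError("no intervals: cannot estimate Pstart from an empty gap sample")
    if np.any(g < 0) or not np.all(np.isfinite(g)):
        raise ValueError("gaps must be finite and non-negative")
    t = np.arange(t_max)
    starts = np.bincount(np.floor(g[g < t_max]).astype(int), minlength=t_max)[:t_max]
    # n_at_risk[t] = number of gaps >= t
    n_at_risk = g.size - np.cumsum(np.concatenate(([0], starts)))[:t_max]
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(n_at_risk > 0, starts / np.maximum(n_at_risk, 1), np.nan)
    return PstartCurve(t=t, n_at_risk=n_at_risk.astype(int), raw=raw)


def smooth_curve(curve: PstartCurve, window: int = DEFAULT_WINDOW) -> PstartCurve:
    """Centred rolling mean over ``window`` minutes (edge windows truncate).

    Undefined raw bins are ignored inside the window; a bin stays
    undefined only if its whole window is undefined.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    half = window // 2
    raw = curve.raw
    n = raw.size
    smoothed = np.full(n, np.nan)
    for i in range(n):
        seg = raw[max(0, i - half): min(n, i + half + 1)]
        if np.any(~np.isnan(seg)):
            smoothed[i] = np.nanmean(seg)
    return replace(curve, smoothed=smoothed)


def find_criterion(curve: PstartCurve) -> tuple[int, str]:
    """Locate the minute where the smoothed hazard turns from falling to rising.

    Scanning successive differences from ``t = 0``, the scan ends at the
    first strictly positive difference that follows at least one
    negative one; runs of zero differences inside the descent do not end
    it.  The criterion is the first bin of the minimum-value plateau at
    that turning point.  If the curve never turns, the argmin of the
    smoothed curve is returned with a fallback flag.

    Returns ``(criterion_minutes, method)`` where method is
    :data:`METHOD_SIGN_CHANGE` or :data:`METHOD_ARGMIN`.
    """
    if curve.smoothed is None:
        raise ValueError("curve must be smoothed before locating the criterion")
    s = curve.smoothed
    defined = ~np.isnan(s)
    if defined.sum() < 3:
        raise ValueError("too few defined bins to locate a criterion")
    # defined bins form a prefix (at-risk counts are non-increasing)
    last = int(np.max(np.nonzero(defined)[0]))
    s = s[: last + 1]
    seen_negative = False
    for i in range(len(s) - 1):
        d = s[i + 1] - s[i]
        if d < 0:
            seen_negative = True
        elif d > 0 and seen_negative:
            # walk back over the plateau of equal minimum values
            j = i
            while j > 0 and s[j - 1] == s[i]:
                j -= 1
            return max(int(j), 1), METHOD_SIGN_CHANGE
    return max(int(np.argmin(s)), 1), METHOD_ARGMIN


def estimate_criterion(
    gaps: np.ndarray | pd.Series,
    t_max: int = DEFAULT_T_MAX,
    window: int = DEFAULT_WINDOW,
) -> tuple[int, str]:
    """Full per-sample pipeline: hazard, smoothing, turning-point scan."""
    curve = smooth_curve(estimate_pstart(gaps, t_max=t_max), window=window)
    return find_criterion(curve)


def criteria_for_cohort(
    visits: pd.DataFrame,
    t_max: int = DEFAULT_T_MAX,
    window: int = DEFAULT_WINDOW,
    min_gaps: int = DEFAULT_MIN_GAPS,
) -> pd.DataFrame:
    """Per-animal meal criteria, with a pooled per-breed fallback.

    Animals with at least ``min_gaps`` inter-visit gaps get an
    individual estimate; the rest inherit the criterion estimated from
    all gaps of their breed pooled together.

    Returns a frame with columns ``animal_id``, ``criterion_min``,
    ``source``, ``method``, ``n_gaps``.
    """
    gaps = compute_gaps(visits)
    if len(gaps) == 0:
        raise ValueError("cohort has no inter-visit gaps")
    pooled: dict[str, tuple[int, str]] = {}
    for breed, sub in gaps.groupby("breed"):
        pooled[breed] = estimate_criterion(sub["gap_min"], t_max=t_max, window=window)
    breed_of = visits.drop_duplicates("animal_id").set_index("animal_id")["breed"]
    rows = []
    counts = gaps.groupby("animal_id").size()
    for animal_id in visits["animal_id"].unique():
        n = int(counts.get(animal_id, 0))
        if n >= min_gaps:
            sub = gaps.loc[gaps["animal_id"] == animal_id, "gap_min"]
            try:
                crit, method = estimate_criterion(sub, t_max=t_max, window=window)
                source = SOURCE_INDIVIDUAL
            except ValueError:
                crit, method = pooled[breed_of[animal_id]]
                source = SOURCE_POOLED
        else:
            crit, method = pooled[breed_of[animal_id]]
            source = SOURCE_POOLED
        rows.append(
            MealCriterion(
                animal_id=animal_id, criterion_min=crit, source=source, method=method, n_gaps=n
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
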