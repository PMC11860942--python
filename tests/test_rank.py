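"""Social-ranking indicators: feeding events, Position, preferred time, shares."""

import numpy as np
import pandas as pd
import pytest

from penfeed import rank
from conftest import make_visits


def pen_visits_from_gaps(gaps_min, animals=None):
    """Build a single-pen visit stream with the given start-to-start gaps."""
    n = len(gaps_min) + 1
    animals = animals or [f"A{i}" for i in range(n)]
    t = pd.Timestamp("2018-03-01T08:00:00")
    rows = [("P1", animals[0], "B1", t.isoformat(), 30, 10, 23000)]
    for g, a in zip(gaps_min, animals[1:]):
        t = t + pd.Timedelta(minutes=g)
        rows.append(("P1", a, "B1", t.isoformat(), 30, 10, 23000))
    return make_visits(rows)


class TestPenEvents:
    def test_run_segmentation(self):
        v = pen_visits_from_gaps([1, 2, 30, 1])
        ev = rank.build_pen_events(v, threshold_min=10)
        sizes = sorted(ev.groupby("event_id").size().tolist())
        assert sizes == [2, 3]

    def test_all_gaps_large_gives_singletons(self):
        v = pen_visits_from_gaps([20, 25, 30])
        ev = rank.build_pen_events(v, threshold_min=10)
        assert (ev["event_n"] == 1).all()

    def test_all_gaps_small_gives_one_event(self):
        v = pen_visits_from_gaps([1, 2, 3])
        ev = rank.build_pen_events(v, threshold_min=10)
        assert ev["event_id"].nunique() == 1
        assert (ev["event_n"] == 4).all()

    def test_per_pen_threshold_mapping(self):
        v1 = pen_visits_from_gaps([5, 5])
        v2 = pen_visits_from_gaps([5, 5]).assign(pen_id="P2")
        v = pd.concat([v1, v2], ignore_index=True)
        ev = rank.build_pen_events(v, {"P1": 10.0, "P2": 2.0})
        assert ev.loc[ev["pen_id"] == "P1", "event_n"].iloc[0] == 3
        assert (ev.loc[ev["pen_id"] == "P2", "event_n"] == 1).all()


class TestPosition:
    def test_standardized_order_example(self):
        v = pen_visits_from_gaps([1, 1], animals=["A", "B", "B"])
        ev = rank.build_pen_events(v, threshold_min=10)
        pos = rank.compute_position(ev)
        assert pos["A"] == pytest.approx(1 / 3)
        assert pos["B"] == pytest.approx((2 / 3 + 3 / 3) / 2)

    def test_single_visit_event(self):
        v = pen_visits_from_gaps([])
        ev = rank.build_pen_events(v, threshold_min=10)
        assert rank.compute_position(ev)["A0"] == pytest.approx(1.0)

    def test_always_first_in_full_events(self):
        # animal X enters first in every event of 14 visits
        frames = []
        for k in range(5):
            animals = ["X"] + [f"A{i}" for i in range(13)]
            v = pen_visits_from_gaps([1] * 13, animals=animals)
            v["t_start"] = v["t_start"] + pd.Timedelta(hours=3 * k)
            frames.append(v)
        v = pd.concat(frames, ignore_index=True)
        ev = rank.build_pen_events(v, threshold_min=10)
        assert rank.compute_position(ev)["X"] == pytest.approx(1 / 14)

    def test_random_order_expectation(self):
        """Uniformly random queue order: E[Position] = (n+1)/(2n) per event."""
        rng = np.random.default_rng(42)
        n = 10
        frames = []
        for k in range(300):
            animals = list(rng.permutation([f"A{i}" for i in range(n)]))
            v = pen_visits_from_gaps([1] * (n - 1), animals=animals)
            v["t_start"] = v["t_start"] + pd.Timedelta(hours=2 * k)
            frames.append(v)
        v = pd.concat(frames, ignore_index=True)
        ev = rank.build_pen_events(v, threshold_min=5)
        pos = rank.compute_position(ev)
        assert pos.mean() == pytest.approx((n + 1) / (2 * n), abs=0.02)


class TestPrefTime:
    def test_window_fraction(self):
        rows = [
            ("P1", "A1", "B1", "2018-03-01T07:30:00", 30, 10, 23000),
            ("P1", "A1", "B1", "2018-03-01T09:00:00", 30, 10, 23000),
            ("P1", "A1", "B1", "2018-03-01T21:00:00", 30, 10, 23000),
        ]
        out = rank.compute_pref_time(make_visits(rows)).set_index("animal_id")
        assert out.loc["A1", "ratePrefTime_a"] == pytest.approx(1 / 3)

    def test_half_open_boundary_excludes_end(self):
        rows = [("P1", "A1", "B1", "2018-03-01T20:00:00", 30, 10, 23000)]
        out = rank.compute_pref_time(make_visits(rows)).set_index("animal_id")
        assert out.loc["A1", "ratePrefTime_a"] == 0.0

    def test_saturation_and_presets(self):
        rows = [
            ("P1", "A1", "B1", "2018-03-01T09:00:00", 30, 10, 23000),
            ("P1", "A1", "B1", "2018-03-01T16:00:00", 30, 10, 23000),
        ]
        out = rank.compute_pref_time(
            make_visits(rows), windows_b=rank.WINDOW_B_TABLE
        ).set_index("animal_id")
        assert out.loc["A1", "ratePrefTime_a"] == 1.0
        assert out.loc["A1", "ratePrefTime_b"] == 1.0


class TestDailyShares:
    def make_daily(self, values, trait="FI_day_g"):
        rows = []
        for day, vals in enumerate(values):
            for i, v in enumerate(vals):
                rows.append(
                    {"animal_id": f"A{i}", "pen_id": "P1", "day_index": day,
                     "TNV": 1.0, "TNM": 1.0, "FI_day_g": 1.0, "OT_day_s": 1.0}
                )
                rows[-1][trait] = v
        return pd.DataFrame(rows)

    def test_share_ratio(self):
        daily = self.make_daily([[1000, 2000, 1000]])
        out = rank.compute_daily_shares(daily).set_index("animal_id")
        assert out["rateFI"].tolist() == pytest.approx([0.25, 0.5, 0.25])

    def test_mean_over_days(self):
        daily = self.make_daily([[200, 800], [400, 600]])
        out = rank.compute_daily_shares(daily).set_index("animal_id")
        assert out.loc["A0", "rateFI"] == pytest.approx((0.2 + 0.4) / 2)

    def test_identical_animals_get_equal_shares(self):
        daily = self.make_daily([[5, 5, 5, 5]])
        out = rank.compute_daily_shares(daily)
        assert np.allclose(out["rateFI"], 0.25)

    def test_zero_total_day_skipped(self):
        daily = self.make_daily([[0, 0], [300, 700]])
        out = rank.compute_daily_shares(daily).set_index("animal_id")
        assert out.loc["A0", "rateFI"] == pytest.approx(0.3)

    def test_pen_day_shares_sum_to_one(self, small_run):
        daily = small_run["daily"]
        for col in rank.SHARE_TRAITS.values():
            total = daily.groupby(["pen_id", "day_index"])[col].transform("sum")
            share = daily[col] / total
            sums = share.groupby([daily["pen_id"], daily["day_index"]]).sum()
            assert np.allclose(sums, 1.0)
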