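"""Pstart hazard estimation and meal-criterion location."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from penfeed import criterion as crit
from conftest import make_visits


class TestEstimatePstart:
    def test_hand_enumerated_curve(self):
        # gaps {0.5, 1.5, 2.5, 11, 14}: ratio of starts in [t,t+1) to gaps >= t
        c = crit.estimate_pstart([0.5, 1.5, 2.5, 11.0, 14.0], t_max=16)
        assert c.raw[0] == pytest.approx(1 / 5)
        assert c.raw[1] == pytest.approx(1 / 4)
        assert c.raw[2] == pytest.approx(1 / 3)
        assert np.all(c.raw[3:11] == 0)
        assert c.raw[11] == pytest.approx(1 / 2)
        assert c.raw[12] == 0 and c.raw[13] == 0
        assert c.raw[14] == pytest.approx(1.0)

    def test_single_bin_case(self):
        c = crit.estimate_pstart([0.1, 0.5, 0.9], t_max=5)
        assert c.raw[0] == 1.0
        assert np.isnan(c.raw[1:]).all()

    def test_two_gaps_same_bin(self):
        c = crit.estimate_pstart([5.2, 5.9], t_max=8)
        assert np.all(c.raw[:5] == 0)
        assert (c.n_at_risk[:6] == 2).all()
        assert c.raw[5] == pytest.approx(1.0)

    def test_censoring_beyond_t_max(self):
        # the 100-min gap counts at risk everywhere but never starts
        c = crit.estimate_pstart([2.5, 100.0], t_max=10)
        assert c.n_at_risk[9] == 1
        assert c.raw[2] == pytest.approx(1 / 2)
        assert np.nansum(c.raw[3:]) == 0

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="no intervals"):
            crit.estimate_pstart([])

    @given(
        st.lists(st.floats(min_value=0, max_value=200, allow_nan=False), min_size=1, max_size=200)
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_hazard_definition_invariants(self, gaps):
        c = crit.estimate_pstart(gaps, t_max=60)
        defined = ~np.isnan(c.raw)
        assert np.all((c.raw[defined] >= 0) & (c.raw[defined] <= 1))
        assert np.all(np.diff(c.n_at_risk) <= 0)
        # numerators over all bins account for every uncensored gap
        starts = c.raw * c.n_at_risk
        assert np.nansum(starts) == pytest.approx(np.sum(np.array(gaps) < 60))


class TestSmoothing:
    def test_centered_window_mean(self):
        c = crit.PstartCurve(
            t=np.arange(6), n_at_risk=np.full(6, 10),
            raw=np.array([0.5, 0.4, 0.3, 0.1, 0.05, 0.2]),
        )
        s = crit.smooth_curve(c, window=5)
        assert s.smoothed[2] == pytest.approx(np.mean([0.5, 0.4, 0.3, 0.1, 0.05]))
        # edges truncate to the available bins
        assert s.smoothed[0] == pytest.approx(np.mean([0.5, 0.4, 0.3]))

    def test_constant_curve_invariant(self):
        c = crit.PstartCurve(
            t=np.arange(10), n_at_risk=np.full(10, 5), raw=np.full(10, 0.2)
        )
        s = crit.smooth_curve(c)
        assert np.allclose(s.smoothed, 0.2)

    def test_even_window_rejected(self):
        c = crit.PstartCurve(t=np.arange(3), n_at_risk=np.ones(3), raw=np.ones(3))
        with pytest.raises(ValueError):
            crit.smooth_curve(c, window=4)


def _curve_from_smoothed(values):
    n = len(values)
    return crit.PstartCurve(
        t=np.arange(n), n_at_risk=np.full(n, 100),
        raw=np.asarray(values, dtype=float), smoothed=np.asarray(values, dtype=float),
    )


class TestFindCriterion:
    def test_sign_change_scan(self):
        c = _curve_from_smoothed([0.30, 0.20, 0.12, 0.08, 0.07, 0.09, 0.15])
        assert crit.find_criterion(c) == (4, crit.METHOD_SIGN_CHANGE)

    def test_monotone_decreasing_falls_back_to_argmin(self):
        c = _curve_from_smoothed([0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        t, method = crit.find_criterion(c)
        assert method == crit.METHOD_ARGMIN
        assert t == 5

    def test_v_shape_minimum_found(self):
        vals = list(np.linspace(0.5, 0.05, 10)) + list(np.linspace(0.07, 0.3, 8))
        c = _curve_from_smoothed(vals)
        assert crit.find_criterion(c) == (9, crit.METHOD_SIGN_CHANGE)

    def test_zero_plateau_does_not_end_scan(self):
        c = _curve_from_smoothed([0.3, 0.2, 0.1, 0.1, 0.1, 0.15, 0.2])
        # plateau of zeros inside the descent; criterion is its first bin
        assert crit.find_criterion(c) == (2, crit.METHOD_SIGN_CHANGE)

    def test_exact_exponential_hazard_triggers_fallback(self):
        # discrete hazard of an exponential is constant: no interior minimum
        t = np.arange(60)
        p = 1 - np.exp(-1 / 20.0)
        c = crit.PstartCurve(t=t, n_at_risk=np.full(60, 1000), raw=np.full(60, p))
        s = crit.smooth_curve(c)
        _, method = crit.find_criterion(s)
        assert method == crit.METHOD_ARGMIN

    def test_too_few_bins_raises(self):
        c = _curve_from_smoothed([0.3, 0.2])
        with pytest.raises(ValueError):
            crit.find_criterion(c)


class TestMixtureRecovery:
    def test_criterion_converges_to_theoretical_hazard_minimum(self):
        """Two-timescale gap mixture: the estimated criterion approaches the
        argmin of the closed-form per-minute hazard as the sample grows."""
        rng = np.random.default_rng(123)
        n = 60_000
        w = 0.30
        fast = rng.exponential(0.9, n)
        slow = 6.0 + rng.lognormal(np.log(30.0), 0.7, n)
        gaps = np.where(rng.random(n) < w, fast, slow)
        # closed-form discrete hazard of the same mixture
        t = np.arange(61, dtype=float)
        cdf = w * (1 - np.exp(-t / 0.9)) + (1 - w) * np.where(
            t > 6.0, stats.norm.cdf((np.log(np.maximum(t - 6.0, 1e-12)) - np.log(30.0)) / 0.7), 0.0
        )
        hazard = (cdf[1:] - cdf[:-1]) / (1 - cdf[:-1])
        expected = int(np.argmin(hazard))
        est, method = crit.estimate_criterion(gaps)
        assert method == crit.METHOD_SIGN_CHANGE
        assert abs(est - expected) <= 1


@pytest.fixture(scope="module")
def cohort_visits():
    """Two animals: one with plenty of visits, one with only a handful."""
    rng = np.random.default_rng(5)
    rows = []
    t = pd.Timestamp("2018-03-01")
    for _ in range(400):
        gap_min = rng.exponential(0.8) if rng.random() < 0.35 else 8 + rng.lognormal(np.log(40), 0.8)
        t = (t + pd.Timedelta(minutes=float(gap_min) + 1.0)).floor("s")
        rows.append(("P1", "A1", "B1", t.isoformat(), 60, 50, 30000))
    t2 = pd.Timestamp("2018-03-01T06:00:00")
    for _ in range(10):
        t2 = t2 + pd.Timedelta(minutes=200)
        rows.append(("P1", "A2", "B1", t2.isoformat(), 60, 50, 30000))
    return make_visits(rows)


class TestCohortCriteria:
    def test_individual_vs_pooled_fallback(self, cohort_visits):
        out = crit.criteria_for_cohort(cohort_visits, min_gaps=50)
        src = out.set_index("animal_id")["source"]
        assert src["A1"] == crit.SOURCE_INDIVIDUAL
        assert src["A2"] == crit.SOURCE_POOLED

    def test_zero_gap_cohort_raises(self):
        v = make_visits([("P1", "A1", "B1", "2018-03-01T08:00:00", 60, 50, 30000)])
        with pytest.raises(ValueError, match="no inter-visit gaps"):
            crit.criteria_for_cohort(v)

    def test_gap_is_end_to_start(self):
        v = make_visits(
            [
                ("P1", "A1", "B1", "2018-03-01T08:00:00", 120, 50, 30000),
                ("P1", "A1", "B1", "2018-03-01T08:04:00", 60, 50, 30000),
                ("P1", "A1", "B1", "2018-03-01T08:05:00", 60, 50, 30000),
            ]
        )
        g = crit.compute_gaps(v)
        assert g["gap_min"].tolist() == [2.0, 0.0]
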