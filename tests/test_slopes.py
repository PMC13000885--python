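"""Slope estimators (two-point, OLS, mixed model) and error classification."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gfrmon import (EquationId, VisitRecord, classify_error, elapsed_years,
                    mixed_model_slopes, ols_slope, two_point_slope)

EQ = EquationId.CKDEPI_CR_2009


def _visit(pid, date, measured=None, est=None):
    return VisitRecord(participant_id=pid, visit_date=date,
                       measured_gfr=measured,
                       estimates={EQ: est} if est is not None else {})


class TestElapsedYears:
    def test_same_date_is_zero(self):
        assert elapsed_years("2015-01-01", "2015-01-01") == 0.0

    def test_half_year(self):
        # 182 calendar days
        assert elapsed_years("2014-01-01", "2014-07-02") == pytest.approx(
            182 / 365.25, abs=1e-10)
        assert elapsed_years("2014-01-01", "2014-07-02") == pytest.approx(0.4983, abs=5e-5)

    def test_three_years_across_leap_day(self):
        # 1096 calendar days (2016 is a leap year)
        assert elapsed_years("2014-04-01", "2017-04-01") == pytest.approx(
            1096 / 365.25, abs=1e-10)

    def test_reversed_dates_raise(self):
        with pytest.raises(ValueError):
            elapsed_years("2015-01-02", "2015-01-01")


class TestTwoPoint:
    def test_cohort_median_pair(self):
        """48.1 -> 43.6 over exactly three years is -1.5 per year."""
        b = _visit("p", "2014-01-01", measured=48.1)
        f = _visit("p", pd.Timestamp("2014-01-01") + pd.Timedelta(days=3 * 365.25),
                   measured=43.6)
        est = two_point_slope(b, f)
        assert est.slope == pytest.approx(-1.5)
        assert est.baseline_value == 48.1

    def test_percent_slope_uses_observed_baseline(self):
        b = _visit("p", "2014-01-01", measured=50.0)
        f = _visit("p", pd.Timestamp("2014-01-01") + pd.Timedelta(days=3 * 365.25),
                   measured=35.0)
        est = two_point_slope(b, f)
        assert est.slope == pytest.approx(-5.0)
        assert est.percent_slope == pytest.approx(-10.0)

    def test_no_change_is_zero(self):
        b = _visit("p", "2014-01-01", measured=48.0)
        f = _visit("p", "2016-05-20", measured=48.0)
        assert two_point_slope(b, f).slope == 0.0

    def test_same_day_raises(self):
        with pytest.raises(ValueError):
            two_point_slope(_visit("p", "2014-01-01", measured=48.0),
                            _visit("p", "2014-01-01", measured=40.0))

    @settings(max_examples=100, derandomize=True)
    @given(v1=st.floats(10, 120), v2=st.floats(10, 120), days=st.integers(30, 2000))
    def test_antisymmetry(self, v1, v2, days):
        d0 = pd.Timestamp("2014-06-01")
        a = _visit("p", d0, measured=v1)
        b = _visit("p", d0 + pd.Timedelta(days=days), measured=v2)
        forward = two_point_slope(a, b).slope
        # swapping the roles of the values negates the rate of change
        a2 = _visit("p", d0, measured=v2)
        b2 = _visit("p", d0 + pd.Timedelta(days=days), measured=v1)
        assert two_point_slope(a2, b2).slope == pytest.approx(-forward, rel=1e-12)


class TestOLS:
    def _series(self, values, years, pid="p"):
        d0 = pd.Timestamp("2014-01-01")
        return [_visit(pid, d0 + pd.Timedelta(days=t * 365.25), measured=v)
                for v, t in zip(values, years)]

    def test_two_visits_equals_two_point(self):
        vs = self._series([52.0, 44.0], [0, 2.7])
        assert ols_slope(vs).slope == pytest.approx(
            two_point_slope(vs[0], vs[1]).slope, rel=1e-12)

    def test_exact_linear_data(self):
        t = np.arange(0, 3.5, 0.5)
        vs = self._series(50 - 2 * t, t)
        assert ols_slope(vs).slope == pytest.approx(-2.0, abs=1e-9)

    def test_closed_form_example(self):
        # Sxy/Sxx with y = 48,47,49,44 at t = 0,1,2,3: -5/5 = -1.0
        vs = self._series([48, 47, 49, 44], [0, 1, 2, 3])
        assert ols_slope(vs).slope == pytest.approx(-1.0, abs=1e-9)

    def test_insufficient_visits_raise(self):
        with pytest.raises(ValueError):
            ols_slope(self._series([48.0], [0]))


class TestClassifyError:
    def _pair(self, est_slope, meas_slope):
        """Exact-valued slope estimates (baseline 50 so percent = 2 × slope)."""
        from gfrmon import SlopeEstimate
        est = SlopeEstimate("p", EQ, est_slope, 100 * est_slope / 50.0,
                            "two_point", 50.0)
        meas = SlopeEstimate("p", "measured", meas_slope, 100 * meas_slope / 50.0,
                             "two_point", 50.0)
        return est, meas

    def test_small_error_not_flagged(self):
        err = classify_error(*self._pair(-1.0, -1.5))
        assert err.error == pytest.approx(0.5)
        assert not err.large_abs

    def test_abs_boundary_is_inclusive(self):
        err = classify_error(*self._pair(-1.0, -4.0))
        assert err.error == pytest.approx(3.0)
        assert err.large_abs

    def test_pct_boundary_is_exclusive(self):
        est, meas = self._pair(-2.0, -4.55)
        err = classify_error(est, meas)
        # baselines are both 50 so percent error = 2*error
        assert err.percent_error == pytest.approx(5.1)
        assert err.large_pct
        est, meas = self._pair(-2.0, -4.5)
        assert not classify_error(est, meas).large_pct

    def test_identical_slopes_never_flagged(self):
        est, meas = self._pair(-2.3, -2.3)
        err = classify_error(est, meas)
        assert not err.large_abs and not err.large_pct
        assert err.error == pytest.approx(0.0)

    def test_participant_mismatch_raises(self):
        d0, d1 = pd.Timestamp("2014-01-01"), pd.Timestamp("2017-01-01")
        est = two_point_slope(_visit("a", d0, est=50.0), _visit("a", d1, est=45.0), EQ)
        meas = two_point_slope(_visit("b", d0, measured=50.0),
                               _visit("b", d1, measured=45.0))
        with pytest.raises(ValueError):
            classify_error(est, meas)


class TestMixedModel:
    def _cohort(self, slopes, n_visits=4, noise_sd=0.0, rng=None, intercept=50.0):
        d0 = pd.Timestamp("2014-01-01")
        visits = []
        for i, s in enumerate(slopes):
            for j in range(n_visits):
                t = j * 36 / (n_visits - 1) / 12 if n_visits > 1 else 0.0
                y = intercept + s * t
                if noise_sd and rng is not None:
                    y += rng.normal(0, noise_sd)
                visits.append(_visit(f"p{i}", d0 + pd.Timedelta(days=t * 365.25),
                                     measured=max(y, 1.0)))
        return visits

    def test_identical_linear_trajectories(self):
        res = mixed_model_slopes(self._cohort([-2.0] * 12))
        assert res.population_slope == pytest.approx(-2.0, abs=5e-3)
        for est in res.slopes.values():
            assert est.slope == pytest.approx(-2.0, abs=1e-2)

    def test_zero_random_slope_variance_returns_pooled_slope(self):
        """All-equal true slopes: everyone gets the pooled OLS slope."""
        visits = self._cohort([-1.5] * 10)
        res = mixed_model_slopes(visits)
        t, y = [], []
        d0 = pd.Timestamp("2014-01-01")
        for v in visits:
            t.append((v.visit_date - d0).days / 365.25)
            y.append(v.measured_gfr)
        pooled = np.polyfit(t, y, 1)[0]
        for est in res.slopes.values():
            assert est.slope == pytest.approx(pooled, abs=1e-2)

    def test_shrinkage_toward_population_mean(self, rng):
        true = rng.normal(-1.5, 1.0, size=200)
        visits = self._cohort(true, n_visits=4, noise_sd=4.0, rng=rng)
        res = mixed_model_slopes(visits)
        assert res.converged
        mixed = np.array([res.slopes[f"p{i}"].slope for i in range(200)])
        groups = {}
        for v in visits:
            groups.setdefault(v.participant_id, []).append(v)
        ols = np.array([ols_slope(groups[f"p{i}"]).slope for i in range(200)])
        assert np.var(mixed) < np.var(ols)
        assert res.population_slope == pytest.approx(-1.5, abs=3 * res.population_slope_se)

    def test_single_visit_participant_shrinks_to_population_slope(self, rng):
        """One visit carries no direct slope information: the BLUP stays
        within the random-slope spread of the population slope (it is not
        exactly the population slope because the random intercept and slope
        covary, and one observation does inform the intercept)."""
        true_sd = 0.5
        visits = self._cohort(rng.normal(-2.0, true_sd, 30), noise_sd=2.0, rng=rng)
        visits.append(_visit("lonely", "2014-06-01", measured=48.0))
        res = mixed_model_slopes(visits)
        assert res.slopes["lonely"].n_visits == 1
        assert abs(res.slopes["lonely"].slope - res.population_slope) < 2 * true_sd

    def test_requires_two_participants(self):
        with pytest.raises(ValueError):
            mixed_model_slopes(self._cohort([-2.0]))
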