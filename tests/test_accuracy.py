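"""Exact binomial inference, McNemar, diagnostic metrics, P30, bias."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gfrmon import (ConfusionMatrix, EquationId, SlopeEstimate,
                    agreement_summary, change_summary, classify_error,
                    diagnostic_metrics, exact_binomial_ci, mcnemar_paired,
                    median_bias, p30, paired_difference)


def cp_bisection_oracle(k, n, level=0.95):
    """Clopper–Pearson bounds by inverting binomial tails with bisection."""
    alpha = 1 - level

    def solve(f, lo, hi):
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    low = 0.0 if k == 0 else solve(
        lambda p: stats.binom.sf(k - 1, n, p) - alpha / 2, 0.0, 1.0)
    high = 1.0 if k == n else solve(
        lambda p: alpha / 2 - stats.binom.cdf(k, n, p), 0.0, 1.0)
    return low, high


class TestExactBinomialCI:
    def test_matches_bisection_oracle_small_n(self):
        for n in range(1, 51):
            for k in range(n + 1):
                ci = exact_binomial_ci(k, n)
                lo, hi = cp_bisection_oracle(k, n)
                assert ci.ci_low == pytest.approx(lo, abs=1e-9)
                assert ci.ci_high == pytest.approx(hi, abs=1e-9)
                assert ci.proportion == k / n

    def test_zero_successes_lower_bound_is_zero(self):
        ci = exact_binomial_ci(0, 10)
        assert ci.ci_low == 0.0 and ci.ci_high > 0

    @pytest.mark.parametrize("k, n, formatted", [
        (640, 875, "73.1 (70.1 to 76.1)"),
        (702, 875, "80.2 (77.4 to 82.8)"),
        (609, 875, "69.6 (66.4 to 72.6)"),
    ])
    def test_printed_agreement_rows(self, k, n, formatted):
        assert exact_binomial_ci(k, n).formatted() == formatted

    def test_invalid_counts_raise(self):
        for k, n in ((-1, 10), (11, 10), (0, 0)):
            with pytest.raises(ValueError):
                exact_binomial_ci(k, n)


def _errors(large_abs_flags):
    return [
        type("E", (), {"large_abs": f, "large_pct": f})() for f in large_abs_flags]


class TestAgreementSummary:
    def test_all_zero_errors_give_full_agreement(self):
        assert agreement_summary(_errors([False] * 20)).proportion == 1.0

    def test_numerator_plus_large_equals_denominator(self, rng):
        flags = rng.random(200) < 0.3
        ci = agreement_summary(_errors(flags))
        assert ci.numerator + flags.sum() == ci.denominator == 200

    def test_single_flagged_participant(self):
        ci = agreement_summary(_errors([True]))
        assert (ci.numerator, ci.denominator) == (0, 1)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            agreement_summary([])


def mcnemar_enumeration_oracle(b, c):
    """Two-sided exact p by full enumeration of the discordant binomial."""
    n = b + c
    if n == 0:
        return 1.0
    pmf = [stats.binom.pmf(x, n, 0.5) for x in range(n + 1)]
    p_obs = pmf[b]
    return min(1.0, sum(p for p in pmf if p <= p_obs * (1 + 1e-12)))


class TestMcNemar:
    def test_identical_vectors(self):
        flags = [True, False, True] * 5
        assert mcnemar_paired(flags, flags).p_value == 1.0

    def test_one_sided_discordance(self):
        # 10 discordant pairs all in one direction: p = 2 * 0.5^10
        a = [True] * 10 + [False] * 5
        b = [False] * 10 + [False] * 5
        res = mcnemar_paired(a, b)
        assert res.p_exact == pytest.approx(2 * 0.5 ** 10, rel=1e-12)
        assert (res.b, res.c) == (10, 0)

    def test_symmetric_discordance(self):
        a = [True] * 5 + [False] * 5
        b = [False] * 5 + [True] * 5
        assert mcnemar_paired(a, b).p_exact == pytest.approx(1.0)

    def test_exact_matches_enumeration_small_totals(self):
        for total in range(1, 21):
            for b in range(total + 1):
                c = total - b
                flags_a = [True] * b + [False] * c
                flags_b = [False] * b + [True] * c
                res = mcnemar_paired(flags_a, flags_b)
                assert res.p_exact == pytest.approx(
                    mcnemar_enumeration_oracle(b, c), rel=1e-9), (b, c)

    def test_large_totals_use_chisquare(self):
        a = [True] * 40 + [False] * 20 + [True] * 100
        b = [False] * 40 + [True] * 20 + [True] * 100
        res = mcnemar_paired(a, b)
        assert res.statistic == pytest.approx((40 - 20) ** 2 / 60)
        assert res.p_value == res.p_chi2

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mcnemar_paired([True], [True, False])


class TestPairedDifference:
    def test_identical_is_zero(self):
        flags = [True, False] * 10
        assert paired_difference(flags, flags).difference_pct == 0.0

    def test_printed_agreement_difference(self):
        # 640/875 agree under the reference, 702/875 under the comparator,
        # overlapping maximally: the point difference is 62/875
        a = [True] * 640 + [False] * 235
        b = [True] * 702 + [False] * 173
        d = paired_difference(a, b)
        assert d.difference_pct == pytest.approx(100 * 62 / 875)
        assert round(d.difference_pct, 1) == 7.1
        assert d.ci_low_pct < d.difference_pct < d.ci_high_pct

    def test_complete_flip(self):
        assert paired_difference([False] * 4, [True] * 4).difference_pct == 100.0


TABLE4 = [
    # tp, fn, fp, tn, sens, spec, ppv, npv (printed to 1 dp)
    (75, 64, 63, 673, 54.0, 91.4, 54.3, 91.3),
    (71, 68, 68, 668, 51.1, 90.8, 51.1, 90.8),
    (72, 67, 67, 669, 51.8, 90.9, 51.8, 90.9),
    (71, 68, 70, 666, 51.1, 90.5, 50.4, 90.7),
    (75, 64, 65, 671, 54.0, 91.2, 53.6, 91.3),
    (69, 70, 63, 673, 49.6, 91.4, 52.3, 90.6),
    (63, 76, 51, 685, 45.3, 93.1, 55.3, 90.0),
    (69, 70, 44, 692, 49.6, 94.0, 61.1, 90.8),
]


class TestDiagnosticMetrics:
    @pytest.mark.parametrize("tp, fn, fp, tn, sens, spec, ppv, npv", TABLE4)
    def test_published_confusion_rows(self, tp, fn, fp, tn, sens, spec, ppv, npv):
        dm = diagnostic_metrics(ConfusionMatrix(tp, fn, fp, tn))
        assert round(dm.sensitivity.percent, 1) == sens
        assert round(dm.specificity.percent, 1) == spec
        assert round(dm.ppv.percent, 1) == ppv
        assert round(dm.npv.percent, 1) == npv

    def test_perfect_classifier(self):
        dm = diagnostic_metrics(ConfusionMatrix(1, 0, 0, 1))
        for m in (dm.sensitivity, dm.specificity, dm.ppv, dm.npv):
            assert m.percent == 100.0

    def test_reversed_labels_swap_sens_and_spec(self, rng):
        ref = rng.random(100) < 0.3
        idx = rng.random(100) < 0.35
        dm = diagnostic_metrics(ConfusionMatrix.from_calls(ref, idx))
        dm_rev = diagnostic_metrics(ConfusionMatrix.from_calls(~ref, ~idx))
        assert dm.sensitivity.proportion == pytest.approx(dm_rev.specificity.proportion)
        assert dm.specificity.proportion == pytest.approx(dm_rev.sensitivity.proportion)

    def test_ppv_equals_sens_when_fp_equals_fn(self):
        dm = diagnostic_metrics(ConfusionMatrix(30, 12, 12, 100))
        assert dm.ppv.proportion == pytest.approx(dm.sensitivity.proportion)

    def test_zero_denominator_is_missing(self):
        dm = diagnostic_metrics(ConfusionMatrix(0, 0, 5, 95))
        assert dm.sensitivity is None
        assert dm.specificity is not None


class TestP30:
    def test_perfect_estimates(self):
        meas = np.array([40.0, 55.0, 70.0])
        assert p30(meas, meas).proportion == 1.0

    def test_boundary_is_inclusive(self):
        assert p30([70.0], [100.0]).proportion == 1.0
        assert p30([130.0], [100.0]).proportion == 1.0

    def test_just_outside(self):
        ci = p30([129.0, 131.0], [100.0, 100.0])
        assert (ci.numerator, ci.denominator) == (1, 2)

    @settings(max_examples=100, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_scale_invariance(self, scale):
        est = np.array([50.0, 80.0, 20.0, 45.0])
        meas = np.array([60.0, 70.0, 30.0, 44.0])
        assert (p30(est * scale, meas * scale).proportion
                == p30(est, meas).proportion)


class TestBias:
    def test_identical_series_have_zero_bias(self):
        x = np.array([40.0, 50.0, 60.0])
        assert median_bias(x, x) == 0.0

    def test_symmetric_pairs_cancel(self):
        assert median_bias([40.0, 60.0], [50.0, 50.0]) == 0.0

    def test_change_summary_median_iqr(self):
        base = np.array([50.0, 48.0, 46.0, 52.0])
        fol = base + np.array([-16.0, -17.0, -16.4, -15.0])
        ch = change_summary(base, fol)
        assert ch["median"] == pytest.approx(-16.2)
        assert ch["q1"] <= ch["median"] <= ch["q3"]
        assert ch["n"] == 4
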