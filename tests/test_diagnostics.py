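"""Confusion matrix, interval methods and lead-time summaries.

Expected interval values are cross-checked against independent oracles:
binomial tail-probability bisection for the exact interval, statsmodels for
the same, and direct formula recomputation for the report statistics.
"""

from __future__ import annotations

import math
import random

import numpy as np
import pytest
from scipy.stats import binom

from sepsalert.diagnostics import (
    ConfusionMatrix,
    Undefined,
    UndefinedStatisticError,
    build_confusion,
    clopper_pearson,
    diagnostic_report,
    lead_time_summary,
    likelihood_ratios,
    wilson_score_cc,
)

TABLE_COUNTS = ConfusionMatrix(tp=205, fp=772, fn=15, tn=48846)


class TestBuildConfusion:
    def test_reference_strata(self):
        status, labels = {}, {}
        spec_pairs = [(True, True, 205), (True, False, 772),
                      (False, True, 15), (False, False, 48846)]
        i = 0
        for pos, lab, count in spec_pairs:
            for _ in range(count):
                status[f"x{i}"] = pos
                labels[f"x{i}"] = lab
                i += 1
        cm = build_confusion(status, labels)
        assert cm == TABLE_COUNTS and cm.n == 49838

    def test_all_negative(self):
        status = {f"p{i}": False for i in range(10)}
        cm = build_confusion(status, dict(status))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 0, 10)

    def test_matches_nested_loop_recount(self):
        rng = random.Random(11)
        ids = [f"p{i}" for i in range(200)]
        status = {i: rng.random() < 0.3 for i in ids}
        labels = {i: rng.random() < 0.5 for i in ids}
        tp = sum(status[i] and labels[i] for i in ids)
        fp = sum(status[i] and not labels[i] for i in ids)
        fn = sum(not status[i] and labels[i] for i in ids)
        tn = sum(not status[i] and not labels[i] for i in ids)
        assert build_confusion(status, labels) == ConfusionMatrix(tp, fp, fn, tn)

    def test_mismatched_ids_listed(self):
        with pytest.raises(ValueError, match="only_in_status"):
            build_confusion({"a": True, "only_in_status": False}, {"a": True})

    def test_relabeling_invariance(self):
        rng = random.Random(5)
        ids = [f"p{i}" for i in range(80)]
        status = {i: rng.random() < 0.4 for i in ids}
        labels = {i: rng.random() < 0.2 for i in ids}
        renamed = {f"z-{i}": v for i, v in status.items()}
        renamed_labels = {f"z-{i}": v for i, v in labels.items()}
        assert build_confusion(status, labels) == build_confusion(renamed, renamed_labels)


def cp_by_tail_bisection(k, n, alpha=0.05, tol=1e-10):
    """Independent exact-interval oracle: invert binomial tail probabilities."""
    def bisect(f, lo, hi):
        for _ in range(80):
            mid = (lo + hi) / 2
            if f(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2
    lower = 0.0 if k == 0 else bisect(lambda p: binom.sf(k - 1, n, p) < alpha / 2, 0, 1)
    upper = 1.0 if k == n else bisect(lambda p: binom.cdf(k, n, p) >= alpha / 2, 0, 1)
    return lower, upper


class TestClopperPearson:
    def test_reference_sensitivity_counts(self):
        ci = clopper_pearson(205, 220)
        assert ci.estimate == pytest.approx(0.93182, abs=5e-6)
        assert ci.lower == pytest.approx(0.89004, abs=5e-6)
        assert ci.upper == pytest.approx(0.96134, abs=5e-6)

    def test_zero_successes_pins_lower(self):
        ci = clopper_pearson(0, 10)
        assert ci.lower == 0.0 and ci.estimate == 0.0 and ci.upper < 0.35

    def test_all_successes_pins_upper(self):
        assert clopper_pearson(10, 10).upper == 1.0

    @pytest.mark.parametrize("k,n", [(7, 19), (1, 50), (49, 50), (100, 220)])
    def test_matches_tail_inversion_oracle(self, k, n):
        ci = clopper_pearson(k, n)
        lo, hi = cp_by_tail_bisection(k, n)
        assert ci.lower == pytest.approx(lo, abs=1e-8)
        assert ci.upper == pytest.approx(hi, abs=1e-8)

    def test_matches_statsmodels(self):
        smp = pytest.importorskip("statsmodels.stats.proportion")
        lo, hi = smp.proportion_confint(160, 400, 0.05, method="beta")
        ci = clopper_pearson(160, 400)
        assert (ci.lower, ci.upper) == pytest.approx((lo, hi), abs=1e-12)

    @pytest.mark.parametrize("k,n,alpha", [(-1, 10, 0.05), (11, 10, 0.05),
                                           (5, 0, 0.05), (5, 10, 0.0), (5, 10, 1.0)])
    def test_invalid_inputs(self, k, n, alpha):
        with pytest.raises(ValueError):
            clopper_pearson(k, n, alpha)

    def test_coverage_is_conservative(self):
        """Exact intervals cover the true p in at least 95% of draws."""
        p, n, draws = 0.93, 220, 2000
        rng = np.random.default_rng(1234)
        ks = rng.binomial(n, p, size=draws)
        from scipy.stats import beta as beta_dist
        lowers = np.where(ks == 0, 0.0, beta_dist.ppf(0.025, ks, n - ks + 1))
        uppers = np.where(ks == n, 1.0, beta_dist.ppf(0.975, ks + 1, n - ks))
        coverage = np.mean((lowers <= p) & (p <= uppers))
        assert coverage >= 0.95


class TestWilsonCC:
    def test_reproduces_published_bounds(self):
        # the interval method identified by reproducing the printed CIs
        ci = wilson_score_cc(205, 220)
        assert (round(ci.lower * 100, 2), round(ci.upper * 100, 2)) == (88.78, 96.00)

    def test_edge_counts(self):
        assert wilson_score_cc(0, 10).lower == 0.0
        assert wilson_score_cc(10, 10).upper == 1.0


class TestLikelihoodRatios:
    def test_reference_values(self):
        lr_pos, lr_neg = likelihood_ratios(TABLE_COUNTS)
        assert lr_pos.estimate == pytest.approx(59.89, abs=0.005)
        assert (round(lr_pos.lower, 2), round(lr_pos.upper, 2)) == (55.36, 64.79)
        assert lr_neg.estimate == pytest.approx(0.0693, abs=5e-5)
        assert lr_neg.lower == pytest.approx(0.0425, abs=5e-4)
        assert lr_neg.upper == pytest.approx(0.1129, abs=5e-4)

    def test_zero_cells_raise(self):
        with pytest.raises(UndefinedStatisticError):
            likelihood_ratios(ConfusionMatrix(10, 0, 2, 50))  # perfect specificity
        with pytest.raises(UndefinedStatisticError):
            likelihood_ratios(ConfusionMatrix(10, 5, 0, 50))  # perfect sensitivity

    def test_identity_with_sens_spec(self):
        rng = random.Random(3)
        for _ in range(200):
            cm = ConfusionMatrix(*(rng.randint(1, 400) for _ in range(4)))
            lr_pos, lr_neg = likelihood_ratios(cm)
            sens = cm.tp / (cm.tp + cm.fn)
            spec = cm.tn / (cm.fp + cm.tn)
            assert abs(lr_pos.estimate * (1 - spec) - sens) < 1e-12
            assert abs(lr_neg.estimate * spec - (1 - sens)) < 1e-12


class TestDiagnosticReport:
    def test_reference_counts_summary(self):
        rep = diagnostic_report(TABLE_COUNTS)
        assert round(rep.sensitivity.estimate * 100, 2) == 93.18
        assert round(rep.specificity.estimate * 100, 2) == 98.44
        assert round(rep.ppv.estimate * 100, 2) == 20.98
        assert round(rep.npv.estimate * 100, 2) == 99.97
        assert rep.prevalence == pytest.approx(220 / 49838)
        assert rep.n == 49838

    def test_symmetric_matrix_sens_equals_spec(self):
        rep = diagnostic_report(ConfusionMatrix(40, 10, 10, 40))
        assert rep.sensitivity.estimate == rep.specificity.estimate

    def test_matches_direct_formulas(self):
        rng = random.Random(17)
        for _ in range(500):
            tp, fp, fn, tn = (rng.randint(1, 60) for _ in range(4))
            rep = diagnostic_report(ConfusionMatrix(tp, fp, fn, tn))
            assert rep.sensitivity.estimate == pytest.approx(tp / (tp + fn))
            assert rep.specificity.estimate == pytest.approx(tn / (fp + tn))
            assert rep.ppv.estimate == pytest.approx(tp / (tp + fp))
            assert rep.npv.estimate == pytest.approx(tn / (fn + tn))
            assert rep.lr_pos.estimate == pytest.approx(
                rep.sensitivity.estimate / (1 - rep.specificity.estimate))
            assert rep.lr_neg.estimate == pytest.approx(
                (1 - rep.sensitivity.estimate) / rep.specificity.estimate)

    def test_zero_prevalence_yields_markers_not_crash(self):
        rep = diagnostic_report(ConfusionMatrix(0, 5, 0, 95))
        assert isinstance(rep.sensitivity, Undefined)
        assert isinstance(rep.lr_pos, Undefined)
        assert not isinstance(rep.specificity, Undefined)


class TestLeadTimeSummary:
    def test_singleton(self):
        s = lead_time_summary([4.02])
        assert (s.median, s.q1, s.q3, s.n) == (4.02, 4.02, 4.02, 1)

    def test_even_length_interpolation(self):
        s = lead_time_summary([1, 2, 3, 4])
        assert s.median == 2.5 and s.q1 == 1.75 and s.q3 == 3.25

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(77)
        x = rng.lognormal(mean=1.4, sigma=1.1, size=200)
        s = lead_time_summary(list(x))

        def quantile(sorted_x, q):
            pos = q * (len(sorted_x) - 1)
            lo, frac = int(math.floor(pos)), pos - math.floor(pos)
            hi = min(lo + 1, len(sorted_x) - 1)
            return sorted_x[lo] * (1 - frac) + sorted_x[hi] * frac

        xs = sorted(x)
        assert s.q1 == pytest.approx(quantile(xs, 0.25))
        assert s.median == pytest.approx(quantile(xs, 0.50))
        assert s.q3 == pytest.approx(quantile(xs, 0.75))
        assert s.q1 <= s.median <= s.q3

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            lead_time_summary([])
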