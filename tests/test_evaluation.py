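"""Wilson intervals, confusion metrics, kappa, entity P/R/F1 and sample size.

Independent oracles: statsmodels' Wilson implementation, a numeric inversion
of the binomial score test (scipy brentq), sklearn's kappa, and hand
enumeration for the small confusion tables.
"""

import math

import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.proportion import proportion_confint

from radphen.corpus_io import StandoffEntity
from radphen.evaluation import (
    ConfusionCounts,
    UndefinedMetricError,
    cohens_kappa,
    confusion_counts,
    entity_prf,
    f1_score,
    min_sample_size,
    report_metrics,
    wilson_ci,
    wilson_width,
)
from radphen.phenotype_labelling import LabelledReport, Phenotype
from radphen.types import Span


def _score_test_inversion(k, n, confidence=0.95):
    """Oracle: the Wilson interval is the set of p where the score test
    does not reject; find the boundary roots numerically."""
    z = norm.ppf(1 - (1 - confidence) / 2)
    phat = k / n

    def g(p):
        return (phat - p) ** 2 - z * z * p * (1 - p) / n

    # bracket the non-trivial root away from endpoints where g(phat) = 0
    lo = 0.0 if k == 0 else brentq(g, 1e-12, min(phat, 1 - 1e-9))
    hi = 1.0 if k == n else brentq(g, max(phat, 1e-9), 1 - 1e-12)
    return lo, hi


class TestWilson:
    @pytest.mark.parametrize("k,n,lo,hi", [
        (159, 164, 0.93, 0.99),
        (39, 41, 0.84, 0.99),
        (24, 26, 0.76, 0.98),
    ])
    def test_published_cells_at_2dp(self, k, n, lo, hi):
        got_lo, got_hi = wilson_ci(k, n)
        assert round(got_lo, 2) == lo and round(got_hi, 2) == hi

    def test_degenerate_bounds(self):
        lo, hi = wilson_ci(145, 145)
        assert round(lo, 2) == 0.97 and hi == 1.0
        lo, _ = wilson_ci(0, 10)
        assert lo == 0.0

    def test_symmetric_at_half(self):
        lo, hi = wilson_ci(50, 100)
        assert math.isclose(0.5 - lo, hi - 0.5, rel_tol=1e-9)

    def test_zero_trials_undefined(self):
        with pytest.raises(UndefinedMetricError):
            wilson_ci(0, 0)

    def test_matches_statsmodels(self):
        for k, n in [(0, 7), (3, 9), (159, 164), (145, 145), (1, 1000)]:
            lo, hi = wilson_ci(k, n)
            slo, shi = proportion_confint(k, n, method="wilson")
            assert math.isclose(lo, slo, abs_tol=1e-10)
            assert math.isclose(hi, shi, abs_tol=1e-10)

    @given(st.integers(1, 500), st.data())
    def test_matches_score_test_inversion(self, n, data):
        k = data.draw(st.integers(0, n))
        lo, hi = wilson_ci(k, n)
        olo, ohi = _score_test_inversion(k, n)
        assert math.isclose(lo, olo, abs_tol=1e-8)
        assert math.isclose(hi, ohi, abs_tol=1e-8)

    @given(st.integers(1, 1000), st.data())
    def test_interval_contains_phat_and_width_shrinks(self, n, data):
        k = data.draw(st.integers(0, n))
        lo, hi = wilson_ci(k, n)
        assert lo <= k / n <= hi
        assert wilson_width(k / n, n + 1) < wilson_width(k / n, n)

    def test_wald_equivalence_at_large_n(self):
        n = 100_000
        lo, hi = wilson_ci(n // 2, n)
        z = norm.ppf(0.975)
        wald = z * math.sqrt(0.25 / n)
        assert abs(lo - (0.5 - wald)) < 1e-3 and abs(hi - (0.5 + wald)) < 1e-3


class TestConfusion:
    def _reports(self, gold_sets, pred_sets):
        gold = [LabelledReport(str(i), s) for i, s in enumerate(gold_sets)]
        pred = [LabelledReport(str(i), s) for i, s in enumerate(pred_sets)]
        return pred, gold

    def test_hand_enumerated_counts(self):
        A = Phenotype.ATROPHY
        pred, gold = self._reports([{A}, {A}, set()], [{A}, set(), {A}])
        c = confusion_counts(pred, gold, A)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 0)

    def test_identical_sets_no_errors(self):
        A = Phenotype.ATROPHY
        pred, gold = self._reports([{A}, set()], [{A}, set()])
        c = confusion_counts(pred, gold, A)
        assert c.fp == c.fn == 0 and c.total == 2

    def test_disjoint_report_ids_rejected(self):
        A = Phenotype.ATROPHY
        pred = [LabelledReport("a", {A})]
        gold = [LabelledReport("b", {A})]
        with pytest.raises(ValueError, match="a"):
            confusion_counts(pred, gold, A)

    def test_aggregate_any_of_counts_union(self):
        isch = [Phenotype.ISCHAEMIC_DEEP_OLD, Phenotype.ISCHAEMIC_CORTICAL_RECENT]
        pred, gold = self._reports(
            [{isch[0]}, set(), {isch[0]}],
            [{isch[1]}, set(), set()],
        )
        c = confusion_counts(pred, gold, isch)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 1, 1)


class TestReportMetrics:
    def test_published_row_deep_old(self):
        sens, spec, ppv, f1 = report_metrics(ConfusionCounts(tp=39, fp=2, fn=2, tn=657))
        assert round(sens.estimate, 2) == 0.95
        assert (round(sens.ci_low, 2), round(sens.ci_high, 2)) == (0.84, 0.99)
        assert round(ppv.estimate, 2) == 0.95
        assert (round(ppv.ci_low, 2), round(ppv.ci_high, 2)) == (0.84, 0.99)
        assert round(spec.estimate, 2) == 1.00

    def test_zero_denominator_undefined_not_zero(self):
        sens, spec, ppv, f1 = report_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert sens.estimate is None and ppv.estimate is None
        assert f1.estimate is None
        assert spec.estimate == 1.0

    def test_perfect_prediction_all_ones(self):
        sens, spec, ppv, f1 = report_metrics(ConfusionCounts(tp=4, fp=0, fn=0, tn=6))
        assert sens.estimate == ppv.estimate == spec.estimate == f1.estimate == 1.0

    def test_f1_harmonic_mean(self):
        assert round(f1_score(0.89, 0.85), 2) == 0.87


class TestKappa:
    def test_identical_vectors(self):
        assert cohens_kappa([1, 0, 1], [1, 0, 1]) == 1.0
        assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0  # degenerate marginals

    def test_hand_computed_two_by_two(self):
        # po = 0.5; marginals 1.0 / 0.5 -> pe = 0.5; kappa = 0
        assert cohens_kappa([1, 1, 1, 1], [1, 1, 0, 0]) == 0.0

    @given(st.lists(st.booleans(), min_size=1, max_size=40), st.data())
    def test_symmetry_and_bound(self, a, data):
        b = data.draw(st.lists(st.booleans(), min_size=len(a), max_size=len(a)))
        k1, k2 = cohens_kappa(a, b), cohens_kappa(b, a)
        assert math.isclose(k1, k2, abs_tol=1e-12)
        assert k1 <= 1.0 + 1e-12

    @given(st.lists(st.booleans(), min_size=2, max_size=60), st.data())
    def test_matches_sklearn_on_mixed_vectors(self, a, data):
        b = data.draw(st.lists(st.booleans(), min_size=len(a), max_size=len(a)))
        if len(set(a)) < 2 and len(set(b)) < 2:
            return  # sklearn yields nan for doubly-degenerate tables
        ours = cohens_kappa(a, b)
        ref = cohen_kappa_score(a, b)
        if math.isnan(ref):
            return
        assert math.isclose(ours, ref, abs_tol=1e-12)


def _se(i, type_, start, end):
    return StandoffEntity(f"T{i}", type_, Span(start, end), "x" * (end - start))


class TestEntityPRF:
    def test_perfect_agreement(self):
        gold = [_se(1, "atrophy", 0, 5), _se(2, "time_old", 10, 13)]
        assert entity_prf(gold, gold) == (1.0, 1.0, 1.0)

    def test_one_spurious_prediction(self):
        gold = [_se(i, "atrophy", 10 * i, 10 * i + 4) for i in range(4)]
        pred = gold + [_se(9, "microbleed", 90, 95)]
        p, r, f = entity_prf(gold, pred)
        assert (p, r) == (0.8, 1.0)

    def test_empty_pred_undefined_precision(self):
        gold = [_se(1, "atrophy", 0, 5)]
        p, r, f = entity_prf(gold, [])
        assert p is None and r == 0.0 and f is None

    def test_overlap_mode_tolerates_boundary_shift(self):
        gold = [_se(1, "atrophy", 0, 7)]
        pred = [_se(2, "atrophy", 2, 9)]
        assert entity_prf(gold, pred, "exact")[2] == 0.0
        assert entity_prf(gold, pred, "overlap") == (1.0, 1.0, 1.0)

    def test_type_mismatch_never_matches(self):
        gold = [_se(1, "atrophy", 0, 5)]
        pred = [_se(2, "microbleed", 0, 5)]
        p, r, f = entity_prf(gold, pred)
        assert p == 0.0 and r == 0.0

    def test_each_gold_matched_at_most_once(self):
        gold = [_se(1, "atrophy", 0, 5)]
        pred = [_se(2, "atrophy", 0, 5), _se(3, "atrophy", 0, 5)]
        p, r, f = entity_prf(gold, pred)
        assert (p, r) == (0.5, 1.0)


class TestSampleSize:
    def _oracle(self, p, prevalence, max_width, round_to=None):
        m = 1
        while wilson_width(p, m) > max_width:
            m += 1
        n = math.ceil(m / prevalence)
        if round_to:
            n = math.ceil(n / round_to) * round_to
        return n

    @pytest.mark.parametrize("args,expected", [
        ((0.95, 0.12, 0.10, 100), 700),
        ((0.95, 0.12, 0.10, None), 692),
        ((0.5, 1.0, 0.2, None), 93),
    ])
    def test_planner_values(self, args, expected):
        p, prev, w, r = args
        assert min_sample_size(p, prev, w, round_to=r) == expected
        assert self._oracle(p, prev, w, r) == expected

    def test_matches_linear_search_oracle_on_grid(self):
        for p in (0.5, 0.8, 0.95):
            for w in (0.08, 0.15, 0.3):
                assert min_sample_size(p, 0.4, w) == self._oracle(p, 0.4, w)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            min_sample_size(0.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            min_sample_size(0.95, 0.0, 0.1)
        with pytest.raises(ValueError):
            min_sample_size(0.95, 0.12, 0.1, max_cases=5)
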