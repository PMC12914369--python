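"""Diagnostic-accuracy metrics against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from uactrials.acss_model import SymptomVariant
from uactrials.dx_metrics import (
    ConfusionMatrix,
    build_confusion,
    metric_ci,
    metric_report,
    rule_sweep,
    score_auc,
)
from uactrials.eligibility import DiagnosticRule
from uactrials.microbiology import UrineResult
from uactrials.records import DiagnosticCohort

from conftest import make_response


def brute_force_auc(scores, labels):
    """All-pairs oracle: P(case outscores control), ties counted half."""
    cases = [s for s, y in zip(scores, labels) if y]
    ctrls = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for c in cases:
        for k in ctrls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(ctrls))


class TestBuildConfusion:
    def test_cross_tabulation(self):
        cm = build_confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)

    def test_perfect_classifier(self):
        cm = build_confusion([1] * 10 + [0] * 10, [1] * 10 + [0] * 10)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 10, 0, 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_confusion([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_confusion([1, 0], [1])


class TestMetricReport:
    def test_pyuria_like_operating_point(self):
        rep = metric_report(ConfusionMatrix(tp=85, fn=15, tn=72, fp=28))
        assert rep.sensitivity == pytest.approx(0.85)
        assert rep.specificity == pytest.approx(0.72)

    def test_perfect_classifier_dor_undefined_without_correction(self):
        rep = metric_report(ConfusionMatrix(tp=50, fn=0, tn=40, fp=0))
        assert rep.youden == pytest.approx(1.0)
        assert rep.dor is None
        corrected = metric_report(ConfusionMatrix(tp=50, fn=0, tn=40, fp=0),
                                  correction="haldane_half")
        assert corrected.dor is not None and corrected.dor > 1

    def test_chance_classifier(self):
        rep = metric_report(ConfusionMatrix(tp=25, fp=25, fn=25, tn=25))
        assert rep.sensitivity == rep.specificity == 0.5
        assert rep.youden == pytest.approx(0.0)
        assert rep.phi == pytest.approx(0.0)

    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_metric_identities(self, cells):
        tp, fp, fn, tn = cells
        if tp + fp + fn + tn == 0:
            return
        rep = metric_report(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        if rep.youden is not None:
            assert rep.youden == pytest.approx(rep.sensitivity + rep.specificity - 1)
            assert rep.auc == pytest.approx((rep.sensitivity + rep.specificity) / 2)
            if rep.youden >= 0:
                assert 0.5 <= rep.auc <= 1.0
        if rep.dor is not None and rep.lr_pos is not None and rep.lr_neg is not None:
            assert rep.dor == pytest.approx(rep.lr_pos / rep.lr_neg)

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_phi_symmetric_under_joint_label_swap(self, cells):
        tp, fp, fn, tn = cells
        if tp + fp + fn + tn == 0:
            return
        a = metric_report(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)).phi
        # swapping both rule and reference labels maps tp<->tn, fp<->fn
        b = metric_report(ConfusionMatrix(tp=tn, fp=fn, fn=fp, tn=tp)).phi
        if a is not None and b is not None:
            assert a == pytest.approx(b)


class TestScoreAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([3, 4, 1, 2], [1, 1, 0, 0], 1.0),
            ([1, 2, 1, 2], [1, 1, 0, 0], 0.5),
            # all-pairs oracle: (1 + 0 + 1 + 0.5 + 1 + 0.5) / 6 = 2/3
            ([2, 3, 3, 1, 3], [1, 1, 1, 0, 0], 2 / 3),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert score_auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            score_auc([1, 2], [1, 1])

    def test_agrees_with_all_pairs_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 200))
            scores = rng.integers(0, 19, size=n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert score_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )


class TestMetricCi:
    def test_interval_contains_point_estimate(self):
        cm = ConfusionMatrix(tp=10, fn=10, tn=20, fp=5)
        lo, hi = metric_ci(cm, "sensitivity")
        assert lo < 0.5 < hi

    def test_wilson_boundary(self):
        cm = ConfusionMatrix(tp=100, fn=0, tn=1, fp=1)
        lo, hi = metric_ci(cm, "sensitivity")
        assert hi == pytest.approx(1.0)
        assert lo < 1.0

    def test_dor_interval_contains_point(self):
        cm = ConfusionMatrix(tp=85, fn=15, tn=72, fp=28)
        point = (85 * 72) / (28 * 15)
        lo, hi = metric_ci(cm, "dor")
        assert lo < point < hi

    def test_undefined_metric_raises(self):
        cm = ConfusionMatrix(tp=10, fn=0, tn=10, fp=0)
        with pytest.raises(ValueError):
            metric_ci(cm, "dor")
        with pytest.raises(ValueError):
            metric_ci(cm, "nonsense")


def _toy_cohort(vectors, wbcs, labels):
    responses = [
        make_response(v, patient_id=f"p{i}") for i, v in enumerate(vectors)
    ]
    urines = [
        UrineResult(patient_id=f"p{i}", visit_day=0, wbc=w)
        for i, w in enumerate(wbcs)
    ]
    return DiagnosticCohort(responses=responses, urines=urines,
                            labels=np.array(labels, dtype=bool))


class TestRuleSweep:
    def _cohort(self, rng, n=40):
        vectors = [tuple(int(x) for x in rng.integers(0, 4, size=6)) for _ in range(n)]
        wbcs = rng.integers(0, 100, size=n).astype(float)
        labels = rng.random(n) < 0.5
        labels[0], labels[1] = True, False  # ensure both classes
        return _toy_cohort(vectors, wbcs, labels)

    def test_duplicate_rules_give_identical_rows(self, rng):
        cohort = self._cohort(rng)
        rule = DiagnosticRule(variant=SymptomVariant.ACSS6, min_summary=6)
        df = rule_sweep(cohort, [rule, rule])
        assert df.iloc[0].drop("rule").equals(df.iloc[1].drop("rule"))

    def test_always_positive_rule(self, rng):
        cohort = self._cohort(rng)
        rule = DiagnosticRule(variant=SymptomVariant.ACSS6, min_summary=0,
                              require_more_than_mild=False)
        df = rule_sweep(cohort, [rule])
        assert df.loc[0, "sensitivity"] == 1.0
        assert df.loc[0, "specificity"] == 0.0
        assert df.loc[0, "youden"] == pytest.approx(0.0)

    def test_dominating_rule_flagged_best(self, rng):
        cohort = self._cohort(rng)
        loose = DiagnosticRule(name="loose", variant=SymptomVariant.ACSS6,
                               min_summary=0, require_more_than_mild=False)
        informative = DiagnosticRule(name="informative", variant=SymptomVariant.ACSS6,
                                     min_summary=6)
        df = rule_sweep(cohort, [loose, informative]).set_index("rule")
        assert df.loc["informative", "youden"] >= df.loc["loose", "youden"]
        assert df.loc["informative", "best"]

    def test_empty_rule_list_rejected(self, rng):
        with pytest.raises(ValueError):
            rule_sweep(self._cohort(rng), [])

    def test_pyuria_conjunction_property(self, rng):
        """Adding the pyuria requirement can only lower (or hold)
        sensitivity and raise (or hold) specificity."""
        for _ in range(10):
            cohort = self._cohort(rng)
            base = DiagnosticRule(variant=SymptomVariant.ACSS6, min_summary=6)
            with_pyuria = base.model_copy(update={"require_pyuria": True})
            df = rule_sweep(cohort, [base, with_pyuria])
            assert df.loc[1, "sensitivity"] <= df.loc[0, "sensitivity"]
            assert df.loc[1, "specificity"] >= df.loc[0, "specificity"]
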