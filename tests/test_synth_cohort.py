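"""Synthetic-cohort generator: determinism, calibration, recovery."""

import filecmp

import numpy as np
import pytest
from scipy.stats import chisquare

from uactrials.acss_model import SymptomVariant
from uactrials.dx_metrics import rule_sweep
from uactrials.eligibility import DiagnosticRule
from uactrials.outcome import WINDOW_LABELS
from uactrials.synth_cohort import (
    CohortParams,
    TrialParams,
    cohort_preset,
    generate_diagnostic_cohort,
    generate_trial,
    recovery_harness,
    trial_preset,
)

DEGENERATE_RESOLVED = tuple([(1.0, 0.0, 0.0, 0.0)] * 6)
FORCED_FAILURE = tuple([(0.0, 0.0, 1.0, 0.0)] * 5 + [(1.0, 0.0, 0.0, 0.0)])


def flat_success(p):
    return {arm: {w: p for w in WINDOW_LABELS} for arm in ("nonantibiotic", "antibiotic")}


class TestDiagnosticCohort:
    def test_preset_counts(self):
        cohort = generate_diagnostic_cohort(cohort_preset("study2019"))
        assert len(cohort) == 517
        assert cohort.n_cases == 285
        assert cohort.n_controls == 232

    def test_all_control_cohort(self):
        cohort = generate_diagnostic_cohort(CohortParams(n_cases=0, n_controls=10))
        assert len(cohort) == 10 and cohort.n_cases == 0

    def test_same_seed_reproduces(self):
        a = generate_diagnostic_cohort(CohortParams(n_cases=30, n_controls=30), seed=7)
        b = generate_diagnostic_cohort(CohortParams(n_cases=30, n_controls=30), seed=7)
        assert a.responses == b.responses
        assert a.urines == b.urines

    def test_invalid_distribution_rejected(self):
        bad = tuple([(0.5, 0.5, 0.5, 0.0)] + [(0.25,) * 4] * 5)
        with pytest.raises(ValueError, match="sum to 1"):
            CohortParams(case_typical=bad)

    def test_severity_marginals_calibrated(self):
        """Empirical per-item severity frequencies match the specified
        categorical distributions (chi-square GOF, alpha=0.01)."""
        params = CohortParams(n_cases=10000, n_controls=0)
        cohort = generate_diagnostic_cohort(params, seed=11)
        severities = np.array([r.typical for r in cohort.responses])
        for item in range(6):
            observed = np.bincount(severities[:, item], minlength=4)
            expected = np.array(params.case_typical[item]) * len(cohort)
            _, p = chisquare(observed, expected)
            assert p > 0.01, f"item {item} miscalibrated (p={p:.4g})"

    def test_pyuria_conjunct_ordering_of_operating_points(self):
        """On the default presets, requiring pyuria lowers sensitivity and
        raises specificity of the six-symptom rule."""
        cohort = generate_diagnostic_cohort(cohort_preset("study2019"), seed=5)
        base = DiagnosticRule(variant=SymptomVariant.ACSS6, min_summary=6)
        df = rule_sweep(cohort, [base, base.model_copy(update={"require_pyuria": True})])
        assert df.loc[1, "sensitivity"] < df.loc[0, "sensitivity"]
        assert df.loc[1, "specificity"] > df.loc[0, "specificity"]


class TestTrialGeneration:
    def test_preset_enrolls_134(self):
        trial = generate_trial(trial_preset("outcome2023"), seed=1)
        assert len(trial) == 134
        assert trial.funnel["enrolled"] == 134
        assert trial.funnel["screened"] >= trial.funnel["symptom_eligible"] >= 134

    def test_forced_success(self):
        params = TrialParams(
            n_per_arm=20,
            visit_success_prob=flat_success(1.0),
            rescue_prob={"nonantibiotic": 0.0, "antibiotic": 0.0},
            relapse_prob={a: {"abu": 0.0, "no_abu": 0.0}
                          for a in ("nonantibiotic", "antibiotic")},
            resolved_typical=DEGENERATE_RESOLVED,
            resolved_qol=(1.0, 0.0, 0.0, 0.0),
            never_dosed_prob=0.0,
        )
        df = recovery_harness(params, replicates=1, seed=3)
        assert (df["estimate"] == 1.0).all()

    def test_forced_failure_via_rescue(self):
        params = TrialParams(
            n_per_arm=20,
            visit_success_prob=flat_success(0.0),
            rescue_prob={"nonantibiotic": 1.0, "antibiotic": 1.0},
            never_dosed_prob=0.0,
        )
        df = recovery_harness(params, replicates=1, seed=3)
        assert (df["estimate"] == 0.0).all()

    def test_same_seed_byte_identical_files(self, tmp_path):
        params = TrialParams(n_per_arm=10)
        for sub in ("a", "b"):
            generate_trial(params, seed=9).write(tmp_path / sub)
        for fname in ("responses.csv", "cultures.csv", "patients.csv", "rescue.csv"):
            assert filecmp.cmp(tmp_path / "a" / fname, tmp_path / "b" / fname,
                               shallow=False), fname

    def test_rescue_forces_downstream_unresolved_state(self):
        params = TrialParams(
            n_per_arm=15,
            visit_success_prob={
                arm: {"early": 0.0, "end_of_treatment": 1.0, "toc": 1.0, "late_fu": 1.0}
                for arm in ("nonantibiotic", "antibiotic")
            },
            rescue_prob={"nonantibiotic": 1.0, "antibiotic": 1.0},
            never_dosed_prob=0.0,
        )
        trial = generate_trial(params, seed=2)
        for rec in trial.records:
            for window in WINDOW_LABELS:
                assert rec.visits[window].rescue_taken


class TestRecoveryHarness:
    def test_recovers_latent_success_probability(self):
        params = TrialParams(
            n_per_arm=50,
            visit_success_prob=flat_success(0.8),
            rescue_prob={"nonantibiotic": 0.0, "antibiotic": 0.0},
            relapse_prob={a: {"abu": 0.2, "no_abu": 0.2}
                          for a in ("nonantibiotic", "antibiotic")},
            resolved_typical=DEGENERATE_RESOLVED,
            resolved_qol=(1.0, 0.0, 0.0, 0.0),
            unresolved_typical=FORCED_FAILURE,
            never_dosed_prob=0.0,
        )
        df = recovery_harness(params, replicates=60, seed=17)
        for row in df.itertuples():
            assert abs(row.estimate - row.truth) <= 3 * row.mc_se + 1e-12, row

    def test_single_replicate_table_shape(self):
        df = recovery_harness(TrialParams(n_per_arm=5), replicates=1, seed=0)
        assert len(df) == 2 * len(WINDOW_LABELS)
        assert set(df["window"]) == set(WINDOW_LABELS)

    def test_two_seeds_differ_but_agree_statistically(self):
        params = TrialParams(n_per_arm=30, visit_success_prob=flat_success(0.8),
                             resolved_typical=DEGENERATE_RESOLVED,
                             resolved_qol=(1.0, 0.0, 0.0, 0.0),
                             unresolved_typical=FORCED_FAILURE,
                             rescue_prob={"nonantibiotic": 0.0, "antibiotic": 0.0},
                             relapse_prob={a: {"abu": 0.2, "no_abu": 0.2}
                                           for a in ("nonantibiotic", "antibiotic")},
                             never_dosed_prob=0.0)
        a = recovery_harness(params, replicates=25, seed=1)
        b = recovery_harness(params, replicates=25, seed=2)
        assert not np.allclose(a["estimate"], b["estimate"])
        pooled_se = np.sqrt(a["mc_se"] ** 2 + b["mc_se"] ** 2)
        assert (np.abs(a["estimate"] - b["estimate"]) <= 4 * pooled_se + 1e-12).all()
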