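"""End-to-end orchestration: funnel, determinism, sub-analyses."""

import numpy as np
import pandas as pd
import pytest

from uactrials.acss_model import AcssResponse
from uactrials.microbiology import Isolate, UrineResult
from uactrials.records import TrialRecord, Visit
from uactrials.synth_cohort import TrialParams
from uactrials.trial_engine import (
    TrialConfig,
    crosstab_micro_clinical,
    load_trial_records,
    run_trial,
)

from conftest import make_response


def small_config(seed=0, **overrides):
    params = TrialParams(n_per_arm=25)
    return TrialConfig(trial_params=params, seed=seed, **overrides)


class TestRunTrial:
    def test_funnel_monotone(self):
        report = run_trial(small_config(seed=4))
        f = report.funnel
        assert (
            f["screened"] >= f["symptom_eligible"] >= f["enrolled"]
            >= f["randomized"] >= f["dosed"]
        )

    def test_determinism(self):
        a = run_trial(small_config(seed=12)).to_json()
        b = run_trial(small_config(seed=12)).to_json()
        assert a == b

    def test_randomization_balance(self):
        report = run_trial(small_config(seed=6))
        sizes = {a.arm: a.n for a in report.arm_summaries}
        assert abs(sizes["nonantibiotic"] - sizes["antibiotic"]) <= 4

    def test_rescue_everywhere_gives_zero_success(self):
        params = TrialParams(
            n_per_arm=15,
            visit_success_prob={
                arm: {"early": 0.0, "end_of_treatment": 0.5, "toc": 0.5, "late_fu": 0.5}
                for arm in ("nonantibiotic", "antibiotic")
            },
            rescue_prob={"nonantibiotic": 1.0, "antibiotic": 1.0},
            never_dosed_prob=0.0,
        )
        report = run_trial(TrialConfig(trial_params=params, seed=2))
        toc = report.success_tables.query("window == 'toc' and threshold == 'ACSS5'")
        assert (toc["n_success"] == 0).all()
        assert report.ni.risk_difference == 0.0

    def test_success_tables_cover_all_thresholds_and_windows(self):
        report = run_trial(small_config(seed=1))
        assert set(report.success_tables["threshold"]) == {
            "ACSS5", "FDA4", "EMA3", "ACSS5_QOL", "DYNAMICS_ONLY"
        }
        assert set(report.success_tables["window"]) == {
            "early", "end_of_treatment", "toc", "late_fu"
        }

    def test_abu_table_counts_are_consistent(self):
        report = run_trial(small_config(seed=8))
        toc = report.success_tables.query("window == 'toc' and threshold == 'ACSS5'")
        n_toc_success = int(toc["n_success"].iloc[0])
        assert int(report.abu_table["n_toc_success"].sum()) == n_toc_success

    def test_report_round_trips_to_disk(self, tmp_path):
        report = run_trial(small_config(seed=3))
        report.write(tmp_path)
        for fname in ("report.json", "success_tables.csv", "abu_relapse.csv",
                      "micro_clinical_crosstab.csv", "adjudications.csv"):
            assert (tmp_path / fname).exists()


class TestConfigValidation:
    def test_nonnegative_margin_rejected(self):
        with pytest.raises(ValueError):
            small_config(margin=0.10)

    def test_primary_threshold_cannot_repeat(self):
        with pytest.raises(ValueError):
            small_config(descriptive_thresholds=("ACSS5",))

    def test_micro_itt_without_culture_file_rejected(self, tmp_path):
        # write only the questionnaire/patient files, no cultures.csv
        (tmp_path / "responses.csv").write_text("x")
        (tmp_path / "patients.csv").write_text("x")
        with pytest.raises(ValueError, match="cultures.csv"):
            small_config(population="micro_itt", input_dir=str(tmp_path))


def test_simulated_files_reanalyze_identically(tmp_path):
    """Writing the trial to CSV and re-analyzing from files reproduces the
    in-memory primary analysis."""
    from uactrials.synth_cohort import generate_trial

    params = TrialParams(n_per_arm=20)
    trial = generate_trial(params, seed=5)
    trial.write(tmp_path)
    in_memory = run_trial(TrialConfig(trial_params=params, seed=5))
    from_files = run_trial(
        TrialConfig(trial_params=params, input_dir=str(tmp_path), seed=5)
    )
    assert from_files.ni.risk_difference == pytest.approx(in_memory.ni.risk_difference)
    assert from_files.ni.ci == pytest.approx(in_memory.ni.ci)
    pd.testing.assert_frame_equal(
        from_files.success_tables.sort_values(["threshold", "window"]).reset_index(drop=True),
        in_memory.success_tables.sort_values(["threshold", "window"]).reset_index(drop=True),
    )


# --- hand-enumerated micro/clinical cross-table -----------------------------

E_COLI = "Escherichia coli"


def _trial_record(pid, toc_typical, toc_species, toc_cfu, rescue=False):
    baseline_urine = UrineResult(
        patient_id=pid, visit_day=0, wbc=40.0,
        isolates=(Isolate(species=E_COLI, cfu=1e6),),
    )
    isolates = () if toc_species is None else (Isolate(species=toc_species, cfu=toc_cfu),)
    toc_urine = UrineResult(patient_id=pid, visit_day=11, wbc=5.0, isolates=isolates)
    toc_resp = make_response(toc_typical, part="B", patient_id=pid, visit_day=11,
                             dynamics=0)
    return TrialRecord(
        patient_id=pid, arm="test", dosed=True,
        baseline=make_response((2, 2, 2, 1, 1, 0), patient_id=pid),
        baseline_urine=baseline_urine, baseline_eligible=True,
        visits={"toc": Visit(window="toc", response=toc_resp, urine=toc_urine,
                             rescue_taken=rescue)},
    )


def test_crosstab_matches_hand_enumeration():
    """Ten constructed patients with known clinical and culture outcomes."""
    cured, sick = (0, 0, 1, 0, 0, 0), (2, 3, 2, 1, 0, 0)
    records = [
        _trial_record("p0", cured, None, None),          # success/eradication
        _trial_record("p1", cured, None, None),          # success/eradication
        _trial_record("p2", cured, E_COLI, 1e6),         # success/persistence (ABU)
        _trial_record("p3", cured, "Klebsiella pneumoniae", 1e6),  # success/new
        _trial_record("p4", sick, E_COLI, 1e7),          # failure/persistence
        _trial_record("p5", sick, E_COLI, 1e6),          # failure/persistence
        _trial_record("p6", sick, None, None),           # failure/eradication
        _trial_record("p7", cured, None, None, rescue=True),  # failure (rescue)/erad.
        _trial_record("p8", cured, None, None),          # success/eradication
        _trial_record("p9", sick, "Proteus mirabilis", 1e6),  # failure/new
    ]
    table = crosstab_micro_clinical(records, "general_1e5", "ACSS5", windows=("toc",))
    counts = {(r.clinical, r.micro): r.n for r in table.itertuples()}
    assert counts == {
        ("success", "eradication"): 3,
        ("success", "persistence"): 1,
        ("success", "new_infection"): 1,
        ("failure", "persistence"): 2,
        ("failure", "eradication"): 2,
        ("failure", "new_infection"): 1,
    }
    assert table["n"].sum() == 10  # margins equal the micro ITT size


def test_crosstab_empty_population_warns(caplog):
    table = crosstab_micro_clinical([], "general_1e5")
    assert table.empty


def test_crosstab_margins_on_random_trial():
    report = run_trial(small_config(seed=21))
    config = small_config(seed=21)
    from uactrials.synth_cohort import generate_trial
    from uactrials.microbiology import significant_bacteriuria, get_policy

    trial = generate_trial(config.trial_params, seed=21, rule=config.rule)
    pol = get_policy("s3_species_aware")
    micro_n = sum(
        1 for r in trial.records
        if r.dosed and r.baseline_urine is not None
        and significant_bacteriuria(r.baseline_urine, pol)[0]
    )
    toc_total = report.crosstab.query("window == 'toc'")["n"].sum()
    assert toc_total == micro_n
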