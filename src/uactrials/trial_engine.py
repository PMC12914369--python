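"""End-to-end trial orchestration: screen → enroll → randomize → visits →
adjudicate → analyze.

:func:`run_trial` drives the whole decision tree of a prospective,
randomized, double-blind comparison of a non-antibiotic against an
antibiotic agent: baseline eligibility screening, permuted-block
randomization, per-visit adjudication under every configured
cure/failure threshold, the primary non-inferiority analysis at test of
cure, the asymptomatic-bacteriuria relapse sub-analysis at late
follow-up, and the cross-tabulation of microbiological against clinical
outcome.  Every stage is logged with counts, and the whole run is
reproducible from a single seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, model_validator

from .acss_model import read_responses
from .eligibility import DEFAULT_RULE, DiagnosticRule
from .microbiology import (
    SignificancePolicy,
    get_policy,
    micro_outcome,
    read_cultures,
    significant_bacteriuria,
)
from .ni_analysis import (
    ArmSummary,
    NiResult,
    noninferiority_conclusion,
    population_filter,
    risk_difference_ci,
    wilson_interval,
)
from .outcome import (
    adjudicate,
    standard_threshold,
    success_table,
)
from .records import TrialRecord, Visit
from .synth_cohort import TrialParams, generate_trial

logger = logging.getLogger("uactrials")

__all__ = ["TrialConfig", "TrialReport", "run_trial", "crosstab_micro_clinical",
           "adjudication_frame", "load_trial_records"]


class TrialConfig(BaseModel):
    """Configuration of one end-to-end run."""

    model_config = {"frozen": True, "arbitrary_types_allowed": True}

    rule: DiagnosticRule = DEFAULT_RULE
    policy: str = "s3_species_aware"
    primary_threshold: str = "ACSS5"
    descriptive_thresholds: tuple[str, ...] = ("FDA4", "EMA3", "ACSS5_QOL", "DYNAMICS_ONLY")
    population: str = "clinical_itt"
    margin: float = -0.10
    ci_method: str = "newcombe"
    level: float = 0.95
    trial_params: TrialParams = TrialParams()
    input_dir: Optional[str] = None  # read records from files instead of generating
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TrialConfig":
        if self.margin >= 0:
            raise ValueError("non-inferiority margin must be negative")
        if self.primary_threshold in self.descriptive_thresholds:
            raise ValueError("primary threshold repeated among descriptive thresholds")
        standard_threshold(self.primary_threshold)
        for name in self.descriptive_thresholds:
            standard_threshold(name)
        get_policy(self.policy)
        if self.population not in ("itt", "clinical_itt", "micro_itt"):
            raise ValueError(f"unknown population {self.population!r}")
        if self.input_dir is not None:
            base = Path(self.input_dir)
            needed = ["responses.csv", "patients.csv"]
            if self.population == "micro_itt":
                needed.append("cultures.csv")
            for fname in needed:
                if not (base / fname).exists():
                    raise ValueError(
                        f"population/config requires {fname} in {self.input_dir}"
                    )
        return self


@dataclass
class TrialReport:
    """Everything one run produces."""

    funnel: dict[str, int]
    success_tables: pd.DataFrame
    ni: NiResult
    arm_summaries: tuple[ArmSummary, ArmSummary]
    abu_table: pd.DataFrame
    crosstab: pd.DataFrame
    adjudications: pd.DataFrame = field(repr=False, default=None)

    def to_json(self) -> str:
        payload = {
            "funnel": self.funnel,
            "success_tables": self.success_tables.to_dict(orient="records"),
            "primary_analysis": {
                "arms": [
                    {"arm": a.arm, "n": a.n, "successes": a.successes}
                    for a in self.arm_summaries
                ],
                "risk_difference": self.ni.risk_difference,
                "ci": list(self.ni.ci),
                "level": self.ni.level,
                "method": self.ni.method,
                "margin": self.ni.margin,
                "conclusion": self.ni.conclusion,
            },
            "abu_relapse": self.abu_table.to_dict(orient="records"),
            "micro_clinical_crosstab": self.crosstab.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, default=float)

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json(), encoding="utf-8")
        self.success_tables.to_csv(out / "success_tables.csv", index=False)
        self.abu_table.to_csv(out / "abu_relapse.csv", index=False)
        self.crosstab.to_csv(out / "micro_clinical_crosstab.csv", index=False)
        if self.adjudications is not None:
            adj = self.adjudications.copy()
            adj.to_csv(out / "adjudications.csv", index=False)


def adjudication_frame(
    records: Sequence[TrialRecord], thresholds: Sequence[str]
) -> pd.DataFrame:
    """Adjudicate every dosed patient's visits under every threshold."""
    rows = []
    for rec in records:
        if not rec.dosed:
            continue
        for window, visit in rec.visits.items():
            if visit.response is None:
                continue
            for name in thresholds:
                adj = adjudicate(visit.response, name, rescue_taken=visit.rescue_taken)
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "arm": rec.arm,
                        "visit_day": visit.response.visit_day,
                        "window": window,
                        "threshold": name,
                        "status": adj.status,
                        "hematuria_flag": adj.hematuria_flag,
                        "reasons": "; ".join(adj.reasons),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "arm", "visit_day", "window", "threshold",
                 "status", "hematuria_flag", "reasons"],
    )


def _toc_success_map(adj: pd.DataFrame, threshold: str) -> dict[str, bool]:
    sub = adj[(adj["window"] == "toc") & (adj["threshold"] == threshold)]
    return dict(zip(sub["patient_id"], sub["status"] == "success"))


def _primary_analysis(
    records: Sequence[TrialRecord],
    adj: pd.DataFrame,
    config: TrialConfig,
) -> tuple[tuple[ArmSummary, ArmSummary], NiResult]:
    pop = population_filter(records, config.population, config.policy)
    success = _toc_success_map(adj, config.primary_threshold)
    test_arm, ref_arm = config.trial_params.arms
    summaries = []
    for arm in (test_arm, ref_arm):
        members = [r for r in pop if r.arm == arm]
        # members without a TOC adjudication count as failures (conservative)
        k = sum(1 for r in members if success.get(r.patient_id, False))
        summaries.append(ArmSummary(arm=arm, n=len(members), successes=k))
    ni = risk_difference_ci(summaries[0], summaries[1], config.level, config.ci_method)
    ni = noninferiority_conclusion(ni, config.margin)
    return (summaries[0], summaries[1]), ni


def _abu_relapse_table(
    records: Sequence[TrialRecord],
    adj: pd.DataFrame,
    config: TrialConfig,
) -> pd.DataFrame:
    """Relapse at late follow-up among TOC successes, by ABU status and arm."""
    policy = get_policy(config.policy)
    toc_success = _toc_success_map(adj, config.primary_threshold)
    late = adj[(adj["window"] == "late_fu") & (adj["threshold"] == config.primary_threshold)]
    late_failure = dict(zip(late["patient_id"], late["status"] == "failure"))

    rows = []
    for arm in config.trial_params.arms:
        strata: dict[bool, list[str]] = {True: [], False: []}
        for rec in records:
            if rec.arm != arm or not toc_success.get(rec.patient_id, False):
                continue
            toc_visit = rec.visits.get("toc")
            urine = toc_visit.urine if toc_visit else None
            has_abu = urine is not None and significant_bacteriuria(urine, policy)[0]
            strata[has_abu].append(rec.patient_id)
        for abu_status, pids in strata.items():
            evaluable = [p for p in pids if p in late_failure]
            n_relapse = sum(late_failure[p] for p in evaluable)
            n = len(evaluable)
            lo, hi = wilson_interval(n_relapse, n, config.level) if n else (float("nan"),) * 2
            rows.append(
                {
                    "arm": arm,
                    "abu_at_toc": abu_status,
                    "n_toc_success": len(pids),
                    "n_evaluable": n,
                    "n_relapse": n_relapse,
                    "relapse_proportion": n_relapse / n if n else float("nan"),
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)


def crosstab_micro_clinical(
    records: Sequence[TrialRecord],
    policy: Union[str, SignificancePolicy],
    threshold: str = "ACSS5",
    windows: Sequence[str] = ("toc", "late_fu"),
) -> pd.DataFrame:
    """Cross-tabulate clinical against microbiological outcome.

    Restricted to the microbiological ITT population (significant
    baseline bacteriuria).  For each requested window the clinical
    adjudication (success/failure) is crossed with the microbiological
    outcome relative to baseline (eradication / persistence /
    new_infection / indeterminate); per-window margins equal the
    population size among patients with a visit in that window.
    """
    pol = get_policy(policy)
    micro_pop = [
        r for r in records
        if r.dosed and r.baseline_urine is not None
        and significant_bacteriuria(r.baseline_urine, pol)[0]
    ]
    if not micro_pop:
        logger.warning("microbiological ITT population is empty")
        return pd.DataFrame(
            columns=["window", "clinical", "micro", "n"]
        )
    counts: dict[tuple[str, str, str], int] = {}
    for rec in micro_pop:
        for window in windows:
            visit = rec.visits.get(window)
            if visit is None or visit.response is None:
                continue
            adj = adjudicate(visit.response, threshold, rescue_taken=visit.rescue_taken)
            mo = micro_outcome(rec.baseline_urine, visit.urine, pol)
            key = (window, adj.status, mo.value)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"window": w, "clinical": c, "micro": m, "n": n}
        for (w, c, m), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["window", "clinical", "micro", "n"])


def load_trial_records(
    input_dir: Union[str, Path], treatment_end_day: int = 5
) -> list[TrialRecord]:
    """Reconstruct trial records from the CSV file set written by
    :meth:`uactrials.synth_cohort.SyntheticTrial.write`."""
    base = Path(input_dir)
    responses = read_responses(base / "responses.csv")
    cultures = (
        read_cultures(base / "cultures.csv") if (base / "cultures.csv").exists() else []
    )
    patients = pd.read_csv(base / "patients.csv", dtype={"patient_id": str})
    rescue_path = base / "rescue.csv"
    rescue: set[tuple[str, int]] = set()
    if rescue_path.exists():
        rdf = pd.read_csv(rescue_path, dtype={"patient_id": str})
        rescue = {(row.patient_id, int(row.visit_day)) for row in rdf.itertuples()}

    resp_by_patient: dict[str, list] = {}
    for r in responses:
        resp_by_patient.setdefault(r.patient_id, []).append(r)
    cult_by_key = {(c.patient_id, c.visit_day): c for c in cultures}

    records = []
    for row in patients.itertuples():
        pid = row.patient_id
        mine = resp_by_patient.get(pid, [])
        baseline = next((r for r in mine if r.part == "A"), None)
        if baseline is None:
            raise ValueError(f"patient {pid} has no baseline Part A record")
        visits: dict[str, Visit] = {}
        rescued = False
        followups = sorted((r for r in mine if r.part == "B"), key=lambda r: r.visit_day)
        for r in followups:
            window = _window_of(r.visit_day, treatment_end_day)
            if window == "unscheduled":
                continue
            rescued = rescued or (pid, r.visit_day) in rescue
            visits[window] = Visit(
                window=window,
                response=r,
                urine=cult_by_key.get((pid, r.visit_day)),
                rescue_taken=rescued,
            )
        records.append(
            TrialRecord(
                patient_id=pid,
                arm=str(row.arm),
                dosed=bool(row.dosed),
                baseline=baseline,
                baseline_urine=cult_by_key.get((pid, baseline.visit_day)),
                baseline_eligible=bool(row.baseline_eligible),
                visits=visits,
            )
        )
    return records


def _window_of(day: int, treatment_end_day: int = 5) -> str:
    from .outcome import classify_visit

    return classify_visit(day, treatment_end_day)


def run_trial(config: TrialConfig) -> TrialReport:
    """Execute the full decision tree and return the assembled report."""
    if config.input_dir is not None:
        records = load_trial_records(
            config.input_dir, config.trial_params.treatment_end_day
        )
        funnel = {
            "screened": len(records),
            "symptom_eligible": sum(r.baseline_eligible for r in records),
            "enrolled": len(records),
            "randomized": len(records),
            "dosed": sum(r.dosed for r in records),
        }
        logger.info("loaded %d trial records from %s", len(records), config.input_dir)
    else:
        trial = generate_trial(config.trial_params, seed=config.seed, rule=config.rule)
        records, funnel = trial.records, trial.funnel
        logger.info(
            "generated trial: screened %d, symptom-eligible %d, enrolled %d, dosed %d",
            funnel["screened"], funnel["symptom_eligible"], funnel["enrolled"],
            funnel["dosed"],
        )

    thresholds = (config.primary_threshold,) + config.descriptive_thresholds
    adj = adjudication_frame(records, thresholds)
    logger.info("adjudicated %d visit-threshold combinations", len(adj))

    tables = success_table(adj[["patient_id", "window", "threshold", "status"]])
    summaries, ni = _primary_analysis(records, adj, config)
    logger.info(
        "primary NI analysis (%s, %s at TOC): rd=%.3f, ci=(%.3f, %.3f), %s",
        config.population, config.primary_threshold, ni.risk_difference,
        ni.ci[0], ni.ci[1], ni.conclusion,
    )
    abu = _abu_relapse_table(records, adj, config)
    crosstab = crosstab_micro_clinical(records, config.policy, config.primary_threshold)

    return TrialReport(
        funnel=funnel,
        success_tables=tables,
        ni=ni,
        arm_summaries=summaries,
        abu_table=abu,
        crosstab=crosstab,
        adjudications=adj,
    )
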