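"""Synthetic cohorts and trials for exercising the full analysis pipeline.

The questionnaire datasets this methodology was developed on (a
517-subject diagnostic case/control study and a 134-patient longitudinal
outcome study) are not publicly deposited, so this module generates
synthetic stand-ins with the same design:

* :func:`generate_diagnostic_cohort` — a cross-sectional case/control
  cohort with per-item ordinal severity distributions, status-specific
  log-normal white-cell (pyuria) distributions, and mixed-species
  bacteriuria with log-spread colony counts.  The ``study2019`` preset
  emits 285 cases and 232 controls.
* :func:`generate_trial` — a two-arm randomized trial: screening against
  an inclusion rule, permuted-block randomization, latent per-visit
  resolved/unresolved states per arm, rescue-therapy events that force
  failure downstream, asymptomatic bacteriuria at test of cure, and
  relapse at late follow-up.  The ``outcome2023`` preset enrolls 134
  patients.
* :func:`recovery_harness` — Monte-Carlo check that adjudicated success
  proportions recover the latent per-visit success probabilities.

All generation is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .acss_model import AcssResponse, write_responses
from .eligibility import DEFAULT_RULE, DiagnosticRule, assess_symptoms, enroll
from .microbiology import Isolate, UrineResult, write_cultures
from .outcome import WINDOW_LABELS, adjudicate, standard_threshold
from .records import DiagnosticCohort, TrialRecord, Visit

__all__ = [
    "CohortParams",
    "TrialParams",
    "cohort_preset",
    "trial_preset",
    "generate_diagnostic_cohort",
    "generate_trial",
    "SyntheticTrial",
    "recovery_harness",
]

Dist = tuple[float, float, float, float]

# --- default ordinal severity profiles (per item, P over severities 0-3) ---
# Cases: moderate/severe typical symptoms dominate; visible blood is the
# exception — present in a minority, mostly mild.
_CASE_TYPICAL: tuple[Dist, ...] = (
    (0.10, 0.20, 0.35, 0.35),
    (0.10, 0.20, 0.35, 0.35),
    (0.08, 0.17, 0.35, 0.40),
    (0.20, 0.30, 0.30, 0.20),
    (0.25, 0.30, 0.28, 0.17),
    (0.55, 0.25, 0.12, 0.08),  # visible blood
)
# Controls: symptoms mostly absent or mild; visible blood is rare at any
# severity, which is what makes even mild hematuria discriminative.
_CTRL_TYPICAL: tuple[Dist, ...] = (
    (0.55, 0.30, 0.11, 0.04),
    (0.55, 0.30, 0.11, 0.04),
    (0.65, 0.25, 0.08, 0.02),
    (0.60, 0.28, 0.09, 0.03),
    (0.60, 0.28, 0.09, 0.03),
    (0.92, 0.06, 0.015, 0.005),
)
_CASE_DIFFERENTIAL: Dist = (0.70, 0.20, 0.08, 0.02)
_CTRL_DIFFERENTIAL: Dist = (0.75, 0.18, 0.05, 0.02)
_CASE_QOL: Dist = (0.15, 0.30, 0.35, 0.20)
_CTRL_QOL: Dist = (0.70, 0.20, 0.08, 0.02)

# Log-normal WBC/mm3: cases centred near 35 cells with wide spread
# (pyuria-positive ~85% at the 10/mm3 cut); controls near 4 cells
# (pyuria-positive ~28%).
_CASE_WBC = (3.55, 1.2)
_CTRL_WBC = (1.43, 1.5)

_CASE_SPECIES = (
    ("Escherichia coli", 0.70),
    ("Staphylococcus saprophyticus", 0.10),
    ("Klebsiella pneumoniae", 0.08),
    ("Proteus mirabilis", 0.05),
    ("Enterococcus faecalis", 0.05),
    ("Streptococcus agalactiae", 0.02),
)
_CTRL_SPECIES = (
    ("Escherichia coli", 0.35),
    ("Enterococcus faecalis", 0.25),
    ("Streptococcus agalactiae", 0.15),
    ("Staphylococcus saprophyticus", 0.10),
    ("Klebsiella pneumoniae", 0.15),
)


def _check_dist(dist: Sequence[float], name: str, k: int = 4) -> tuple[float, ...]:
    d = tuple(float(x) for x in dist)
    if len(d) != k:
        raise ValueError(f"{name} must have {k} probabilities")
    if any(x < 0 for x in d):
        raise ValueError(f"{name} has negative probability")
    if abs(sum(d) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {sum(d)})")
    return d


class CohortParams(BaseModel):
    """Parameters of the case/control diagnostic cohort generator."""

    model_config = {"frozen": True}

    n_cases: int = 285
    n_controls: int = 232
    case_typical: tuple[Dist, ...] = _CASE_TYPICAL
    control_typical: tuple[Dist, ...] = _CTRL_TYPICAL
    case_differential: Dist = _CASE_DIFFERENTIAL
    control_differential: Dist = _CTRL_DIFFERENTIAL
    case_qol: Dist = _CASE_QOL
    control_qol: Dist = _CTRL_QOL
    case_wbc_lognorm: tuple[float, float] = _CASE_WBC
    control_wbc_lognorm: tuple[float, float] = _CTRL_WBC
    case_sterile_prob: float = 0.20
    control_sterile_prob: float = 0.70
    cfu_log10_range: tuple[float, float] = (1.0, 8.0)
    control_cfu_log10_range: tuple[float, float] = (1.0, 4.0)
    additional_flag_prob: float = 0.05
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "CohortParams":
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        for label, mat in (("case_typical", self.case_typical),
                           ("control_typical", self.control_typical)):
            if len(mat) != 6:
                raise ValueError(f"{label} must have 6 per-item distributions")
            for i, d in enumerate(mat):
                _check_dist(d, f"{label}[{i}]")
        _check_dist(self.case_differential, "case_differential")
        _check_dist(self.control_differential, "control_differential")
        _check_dist(self.case_qol, "case_qol")
        _check_dist(self.control_qol, "control_qol")
        for p in (self.case_sterile_prob, self.control_sterile_prob,
                  self.additional_flag_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        return self


def cohort_preset(name: str, **overrides) -> CohortParams:
    """Named cohort presets; ``study2019`` is 285 cases / 232 controls."""
    if name == "study2019":
        return CohortParams(**overrides)
    raise ValueError(f"unknown cohort preset {name!r}")


def _sample_cat(rng: np.random.Generator, dist: Sequence[float], size: int) -> np.ndarray:
    cum = np.cumsum(dist)
    return np.searchsorted(cum, rng.random(size), side="right").astype(int)


def _sample_species(rng: np.random.Generator, table) -> str:
    names = [t[0] for t in table]
    probs = np.array([t[1] for t in table])
    probs = probs / probs.sum()
    return names[int(rng.choice(len(names), p=probs))]


def _make_urine(
    rng: np.random.Generator,
    patient_id: str,
    visit_day: int,
    wbc: float,
    sterile_prob: float,
    species_table,
    cfu_log10_range: tuple[float, float],
) -> UrineResult:
    isolates: tuple[Isolate, ...] = ()
    if rng.random() >= sterile_prob:
        species = _sample_species(rng, species_table)
        lo, hi = cfu_log10_range
        cfu = 10.0 ** rng.uniform(lo, hi)
        isolates = (Isolate(species=species, cfu=cfu),)
    return UrineResult(patient_id=patient_id, visit_day=visit_day, wbc=wbc,
                       isolates=isolates)


def _draw_response(
    rng: np.random.Generator,
    patient_id: str,
    part: str,
    visit_day: int,
    typical_dists: Sequence[Dist],
    differential_dist: Dist,
    qol_dist: Dist,
    additional_flag_prob: float,
    dynamics_dist: Optional[dict[int, float]] = None,
) -> AcssResponse:
    typical = tuple(int(_sample_cat(rng, d, 1)[0]) for d in typical_dists)
    differential = tuple(_sample_cat(rng, differential_dist, 4).tolist())
    qol = tuple(_sample_cat(rng, qol_dist, 3).tolist())
    additional = tuple((rng.random(5) < additional_flag_prob).tolist())
    dynamics = None
    if dynamics_dist is not None:
        levels = sorted(dynamics_dist)
        probs = np.array([dynamics_dist[l] for l in levels])
        dynamics = int(rng.choice(levels, p=probs / probs.sum()))
    return AcssResponse(
        patient_id=patient_id, part=part, visit_day=visit_day,
        typical=typical, differential=differential, qol=qol,
        additional=additional, dynamics=dynamics,
    )


def generate_diagnostic_cohort(
    params: CohortParams, seed: Optional[int] = None
) -> DiagnosticCohort:
    """Generate a labeled case/control cohort (responses, urines, labels)."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    responses, urines, labels = [], [], []
    for i in range(params.n_cases + params.n_controls):
        is_case = i < params.n_cases
        pid = f"{'P' if is_case else 'C'}{i + 1:04d}"
        if is_case:
            typ, diff, qol = params.case_typical, params.case_differential, params.case_qol
            mu, sigma = params.case_wbc_lognorm
            sterile_p, species, cfu_rng = (
                params.case_sterile_prob, _CASE_SPECIES, params.cfu_log10_range
            )
        else:
            typ, diff, qol = (
                params.control_typical, params.control_differential, params.control_qol
            )
            mu, sigma = params.control_wbc_lognorm
            sterile_p, species, cfu_rng = (
                params.control_sterile_prob, _CTRL_SPECIES, params.control_cfu_log10_range
            )
        responses.append(
            _draw_response(rng, pid, "A", 0, typ, diff, qol, params.additional_flag_prob)
        )
        wbc = float(np.round(np.exp(rng.normal(mu, sigma)), 1))
        urines.append(_make_urine(rng, pid, 0, wbc, sterile_p, species, cfu_rng))
        labels.append(is_case)
    return DiagnosticCohort(responses=responses, urines=urines,
                            labels=np.array(labels, dtype=bool))


# ---------------------------------------------------------------------------
# Two-arm trial generator
# ---------------------------------------------------------------------------

_RESOLVED_TYPICAL: tuple[Dist, ...] = tuple(
    [(0.75, 0.25, 0.0, 0.0)] * 5 + [(1.0, 0.0, 0.0, 0.0)]
)
_UNRESOLVED_TYPICAL: tuple[Dist, ...] = tuple(
    [(0.05, 0.25, 0.45, 0.25)] * 5 + [(0.80, 0.12, 0.05, 0.03)]
)
_RESOLVED_QOL: Dist = (0.70, 0.30, 0.0, 0.0)
_UNRESOLVED_QOL: Dist = (0.10, 0.30, 0.40, 0.20)
_TRIAL_DIFFERENTIAL: Dist = (0.80, 0.15, 0.04, 0.01)
_RESOLVED_DYNAMICS = {0: 0.7, 1: 0.3}
_UNRESOLVED_DYNAMICS = {2: 0.4, 3: 0.4, 4: 0.2}

_DEFAULT_SUCCESS = {
    "nonantibiotic": {"early": 0.45, "end_of_treatment": 0.72, "toc": 0.78, "late_fu": 0.75},
    "antibiotic": {"early": 0.55, "end_of_treatment": 0.80, "toc": 0.85, "late_fu": 0.80},
}
_DEFAULT_RESCUE = {"nonantibiotic": 0.10, "antibiotic": 0.04}
# Asymptomatic bacteriuria may protect against recurrence, so relapse is
# set lower with ABU than without.
_DEFAULT_RELAPSE = {
    "nonantibiotic": {"abu": 0.08, "no_abu": 0.18},
    "antibiotic": {"abu": 0.10, "no_abu": 0.20},
}


class TrialParams(BaseModel):
    """Parameters of the two-arm longitudinal trial generator."""

    model_config = {"frozen": True}

    n_per_arm: int = 67
    arms: tuple[str, str] = ("nonantibiotic", "antibiotic")
    treatment_end_day: int = 5
    visit_days: dict[str, int] = {
        "early": 3, "end_of_treatment": 7, "toc": 11, "late_fu": 28,
    }
    visit_success_prob: dict[str, dict[str, float]] = _DEFAULT_SUCCESS
    rescue_prob: dict[str, float] = _DEFAULT_RESCUE
    abu_prob_given_success: float = 0.25
    relapse_prob: dict[str, dict[str, float]] = _DEFAULT_RELAPSE
    persistence_prob_given_failure: float = 0.70
    new_species_prob: float = 0.15
    baseline_sterile_prob: float = 0.20
    never_dosed_prob: float = 0.02
    block_size: int = 4
    resolved_typical: tuple[Dist, ...] = _RESOLVED_TYPICAL
    unresolved_typical: tuple[Dist, ...] = _UNRESOLVED_TYPICAL
    resolved_qol: Dist = _RESOLVED_QOL
    unresolved_qol: Dist = _UNRESOLVED_QOL
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "TrialParams":
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if len(set(self.arms)) != 2:
            raise ValueError("exactly two distinct arms required")
        for arm in self.arms:
            probs = self.visit_success_prob.get(arm)
            if probs is None:
                raise ValueError(f"visit_success_prob missing arm {arm!r}")
            for w in WINDOW_LABELS:
                p = probs.get(w)
                if p is None or not 0 <= p <= 1:
                    raise ValueError(f"visit_success_prob[{arm!r}][{w!r}] invalid")
            if not 0 <= self.rescue_prob.get(arm, -1) <= 1:
                raise ValueError(f"rescue_prob[{arm!r}] invalid")
            for key in ("abu", "no_abu"):
                if not 0 <= self.relapse_prob.get(arm, {}).get(key, -1) <= 1:
                    raise ValueError(f"relapse_prob[{arm!r}][{key!r}] invalid")
        for p in (self.abu_prob_given_success, self.persistence_prob_given_failure,
                  self.new_species_prob, self.baseline_sterile_prob,
                  self.never_dosed_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for label, mat in (("resolved_typical", self.resolved_typical),
                           ("unresolved_typical", self.unresolved_typical)):
            if len(mat) != 6:
                raise ValueError(f"{label} must have 6 per-item distributions")
            for i, d in enumerate(mat):
                _check_dist(d, f"{label}[{i}]")
        _check_dist(self.resolved_qol, "resolved_qol")
        _check_dist(self.unresolved_qol, "unresolved_qol")
        if self.block_size < 2 or self.block_size % 2:
            raise ValueError("block_size must be a positive even number")
        return self


def trial_preset(name: str, **overrides) -> TrialParams:
    """Named trial presets; ``outcome2023`` enrolls 134 patients (67/arm)."""
    if name == "outcome2023":
        return TrialParams(**overrides)
    raise ValueError(f"unknown trial preset {name!r}")


@dataclass
class SyntheticTrial:
    """A generated trial: enrolled records plus the screening funnel."""

    records: list[TrialRecord]
    funnel: dict[str, int]
    params: TrialParams

    def __len__(self) -> int:
        return len(self.records)

    def write(self, out_dir: Union[str, Path]) -> None:
        """Emit the CSV files consumed by the analysis stages."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        responses, cultures, patients, rescue_rows = [], [], [], []
        for rec in self.records:
            responses.append(rec.baseline)
            if rec.baseline_urine is not None:
                cultures.append(rec.baseline_urine)
            patients.append(
                {"patient_id": rec.patient_id, "arm": rec.arm,
                 "dosed": int(rec.dosed), "baseline_eligible": int(rec.baseline_eligible)}
            )
            for window in WINDOW_LABELS:
                visit = rec.visits.get(window)
                if visit is None:
                    continue
                if visit.response is not None:
                    responses.append(visit.response)
                if visit.urine is not None:
                    cultures.append(visit.urine)
                if visit.rescue_taken:
                    rescue_rows.append(
                        {"patient_id": rec.patient_id,
                         "visit_day": visit.response.visit_day}
                    )
        write_responses(responses, out / "responses.csv")
        write_cultures(cultures, out / "cultures.csv")
        pd.DataFrame(patients).to_csv(out / "patients.csv", index=False)
        pd.DataFrame(rescue_rows, columns=["patient_id", "visit_day"]).to_csv(
            out / "rescue.csv", index=False
        )


def _permuted_block_arms(
    rng: np.random.Generator, n_total: int, arms: tuple[str, str], block_size: int
) -> list[str]:
    per_arm = block_size // 2
    assignment: list[str] = []
    while len(assignment) < n_total:
        block = [arms[0]] * per_arm + [arms[1]] * per_arm
        rng.shuffle(block)
        assignment.extend(block)
    return assignment[:n_total]


def generate_trial(
    params: TrialParams,
    seed: Optional[int] = None,
    rule: DiagnosticRule = DEFAULT_RULE,
    screening: Optional[CohortParams] = None,
) -> SyntheticTrial:
    """Screen, randomize and follow a synthetic two-arm trial.

    Candidates are drawn from the case profile of ``screening`` (default
    ``study2019``) and screened against ``rule`` until 2 × ``n_per_arm``
    are enrolled; the screening funnel counts are recorded.  Enrolled
    patients are randomized by permuted blocks.  Each dosed patient then
    follows a latent resolved/unresolved trajectory: the state at each
    scheduled window is Bernoulli in the arm's per-window success
    probability; an unresolved early visit can trigger rescue therapy,
    which forces the unresolved state (and failure) at all later visits.
    Cultures are generated at baseline, test of cure and late follow-up,
    including asymptomatic bacteriuria among clinical successes and its
    effect on relapse.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    scr = screening if screening is not None else CohortParams()

    n_total = 2 * params.n_per_arm
    screened = symptom_eligible = 0
    enrolled: list[tuple[AcssResponse, UrineResult]] = []
    max_attempts = 1000 * n_total + 1000
    while len(enrolled) < n_total:
        if screened >= max_attempts:
            raise RuntimeError("screening failure rate too high for requested n")
        screened += 1
        pid = f"T{len(enrolled) + 1:04d}"
        response = _draw_response(
            rng, pid, "A", 0, scr.case_typical, scr.case_differential,
            scr.case_qol, scr.additional_flag_prob,
        )
        mu, sigma = scr.case_wbc_lognorm
        wbc = float(np.round(np.exp(rng.normal(mu, sigma)), 1))
        urine = _make_urine(
            rng, pid, 0, wbc, params.baseline_sterile_prob, _CASE_SPECIES,
            scr.cfu_log10_range,
        )
        if not assess_symptoms(response, rule).eligible:
            continue
        symptom_eligible += 1
        if not enroll(response, urine, rule).eligible:
            continue
        enrolled.append((response, urine))

    arms = _permuted_block_arms(rng, n_total, params.arms, params.block_size)
    records: list[TrialRecord] = []
    n_dosed = 0
    for (baseline, baseline_urine), arm in zip(enrolled, arms):
        pid = baseline.patient_id
        dosed = bool(rng.random() >= params.never_dosed_prob)
        rec = TrialRecord(
            patient_id=pid, arm=arm, dosed=dosed, baseline=baseline,
            baseline_urine=baseline_urine, baseline_eligible=True,
        )
        if dosed:
            n_dosed += 1
            rec.visits = _simulate_visits(rng, params, pid, arm, baseline_urine)
        records.append(rec)

    funnel = {
        "screened": screened,
        "symptom_eligible": symptom_eligible,
        "enrolled": n_total,
        "randomized": n_total,
        "dosed": n_dosed,
    }
    return SyntheticTrial(records=records, funnel=funnel, params=params)


def _simulate_visits(
    rng: np.random.Generator,
    params: TrialParams,
    pid: str,
    arm: str,
    baseline_urine: Optional[UrineResult],
) -> dict[str, Visit]:
    success_p = params.visit_success_prob[arm]
    baseline_species = None
    if baseline_urine is not None and baseline_urine.isolates:
        baseline_species = baseline_urine.isolates[0].species

    visits: dict[str, Visit] = {}
    rescued = False
    abu = False
    resolved_at_toc = False
    for window in WINDOW_LABELS:
        day = params.visit_days[window]
        if rescued:
            resolved = False
        elif window == "late_fu" and resolved_at_toc:
            relapse_key = "abu" if abu else "no_abu"
            resolved = bool(rng.random() >= params.relapse_prob[arm][relapse_key])
        else:
            resolved = bool(rng.random() < success_p[window])

        if window == "early" and not resolved and not rescued:
            if rng.random() < params.rescue_prob[arm]:
                rescued = True

        state_typical = params.resolved_typical if resolved else params.unresolved_typical
        state_qol = params.resolved_qol if resolved else params.unresolved_qol
        dynamics = _RESOLVED_DYNAMICS if resolved else _UNRESOLVED_DYNAMICS
        response = _draw_response(
            rng, pid, "B", day, state_typical, _TRIAL_DIFFERENTIAL, state_qol,
            0.0, dynamics_dist=dynamics,
        )

        urine = None
        if window in ("toc", "late_fu"):
            urine = _followup_culture(
                rng, params, pid, day, resolved, abu, baseline_species, window
            )
            if window == "toc":
                resolved_at_toc = resolved
                sig = urine is not None and bool(urine.isolates)
                abu = resolved and sig

        visits[window] = Visit(window=window, response=response, urine=urine,
                               rescue_taken=rescued)
    return visits


def _followup_culture(
    rng: np.random.Generator,
    params: TrialParams,
    pid: str,
    day: int,
    resolved: bool,
    abu: bool,
    baseline_species: Optional[str],
    window: str,
) -> UrineResult:
    wbc_mu, wbc_sigma = (1.2, 1.0) if resolved else (3.0, 1.0)
    wbc = float(np.round(np.exp(rng.normal(wbc_mu, wbc_sigma)), 1))
    if resolved:
        if window == "toc":
            bacteriuric = rng.random() < params.abu_prob_given_success
        else:  # late_fu: ABU tends to persist
            bacteriuric = rng.random() < (0.5 if abu else 0.05)
    else:
        bacteriuric = rng.random() < params.persistence_prob_given_failure
    isolates: tuple[Isolate, ...] = ()
    if bacteriuric:
        if baseline_species is not None and rng.random() >= params.new_species_prob:
            species = baseline_species
        else:
            species = _sample_species(rng, _CASE_SPECIES)
        cfu = 10.0 ** rng.uniform(3.0, 8.0)
        isolates = (Isolate(species=species, cfu=cfu),)
    return UrineResult(patient_id=pid, visit_day=day, wbc=wbc, isolates=isolates)


def recovery_harness(
    params: TrialParams,
    replicates: int,
    seed: int = 0,
    threshold: str = "ACSS5",
) -> pd.DataFrame:
    """Estimate per-arm, per-window adjudicated success proportions.

    Runs ``replicates`` independent trials, adjudicates every dosed
    patient's visit under ``threshold`` and compares the mean success
    proportion with the generator's latent ``visit_success_prob``.
    Returns one row per (arm, window) with the truth, the Monte-Carlo
    estimate and its standard error across replicates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    thr = standard_threshold(threshold)
    seed_rng = np.random.default_rng(seed)
    child_seeds = seed_rng.integers(0, 2**31 - 1, size=replicates)

    props: dict[tuple[str, str], list[float]] = {
        (arm, w): [] for arm in params.arms for w in WINDOW_LABELS
    }
    for rep_seed in child_seeds:
        trial = generate_trial(params, seed=int(rep_seed))
        counts: dict[tuple[str, str], list[int]] = {k: [0, 0] for k in props}
        for rec in trial.records:
            if not rec.dosed:
                continue
            for window, visit in rec.visits.items():
                adj = adjudicate(visit.response, thr, rescue_taken=visit.rescue_taken)
                cell = counts[(rec.arm, window)]
                cell[0] += adj.success
                cell[1] += 1
        for key, (k, n) in counts.items():
            if n:
                props[key].append(k / n)

    rows = []
    for (arm, window), values in props.items():
        vals = np.asarray(values)
        rows.append(
            {
                "arm": arm,
                "window": window,
                "truth": params.visit_success_prob[arm][window],
                "estimate": float(vals.mean()),
                "mc_se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
                "replicates": len(vals),
                "n_per_replicate": 2 * params.n_per_arm,
            }
        )
    return pd.DataFrame(rows)
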