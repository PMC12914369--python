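"""Visit scheduling and cure/failure adjudication from follow-up ACSS records.

A treated patient is evaluated at up to four scheduled visits relative to
the start of treatment: an *early* visit (days 2–4), *end of treatment*
(days 5–9), *test of cure* (TOC, 5–7 days after the end of treatment) and
*late follow-up* (days 24–33).  At each visit the follow-up questionnaire
(Part B) is adjudicated against a named cure/failure threshold.

The favoured threshold (``ACSS5``) declares clinical cure when the
summary score of the five typical symptoms is ≤ 5 with no single symptom
worse than mild and no visible blood in urine; its complement — summary
score ≥ 6 or any symptom of severity ≥ 2 — is clinical failure.
Analogous per-item-cap thresholds exist for the four-symptom (``FDA4``,
cure ≤ 4 / failure ≥ 5) and three-symptom (``EMA3``, cure ≤ 3 / failure
≥ 4) symptom sets, plus a variant adding a quality-of-life cap
(``ACSS5_QOL``) and a patient-global-assessment-only measure
(``DYNAMICS_ONLY``).  Switching to (another) antibiotic — rescue therapy
— is always adjudicated as failure.

Visible blood is handled by a separate hematuria flag: persistent
visible hematuria raises the suspicion of a source other than the
infection and calls for differential-diagnostic work-up, so the flag is
reported at every visit independently of the cure/failure status.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel

from .acss_model import AcssResponse, SymptomVariant, max_severity, variant_score

__all__ = [
    "VISIT_WINDOWS",
    "WINDOW_LABELS",
    "classify_visit",
    "OutcomeThreshold",
    "standard_threshold",
    "STANDARD_THRESHOLD_NAMES",
    "Adjudication",
    "adjudicate",
    "success_table",
    "write_adjudications",
]

#: Scheduled evaluation windows, as day intervals.  ``early`` and
#: ``end_of_treatment`` and ``late_fu`` are relative to treatment start;
#: ``toc`` is relative to the end of treatment.
VISIT_WINDOWS = {
    "early": (2, 4),
    "end_of_treatment": (5, 9),
    "toc": (5, 7),  # days after end of treatment
    "late_fu": (24, 33),
}

#: Windows in chronological/analysis order (later windows take priority
#: when intervals overlap, since later visits are analytically primary).
WINDOW_LABELS = ("early", "end_of_treatment", "toc", "late_fu")


def classify_visit(day: int, treatment_end_day: int) -> str:
    """Map a visit day (days since treatment start) to its window label.

    Returns one of :data:`WINDOW_LABELS` or ``"unscheduled"``.
    """
    if day < 0:
        raise ValueError(f"visit day cannot be negative: {day}")
    if treatment_end_day < 1:
        raise ValueError(f"treatment_end_day must be >= 1, got {treatment_end_day}")

    lo, hi = VISIT_WINDOWS["late_fu"]
    if lo <= day <= hi:
        return "late_fu"
    lo, hi = VISIT_WINDOWS["toc"]
    if treatment_end_day + lo <= day <= treatment_end_day + hi:
        return "toc"
    lo, hi = VISIT_WINDOWS["end_of_treatment"]
    if lo <= day <= hi:
        return "end_of_treatment"
    lo, hi = VISIT_WINDOWS["early"]
    if lo <= day <= hi:
        return "early"
    return "unscheduled"


class OutcomeThreshold(BaseModel):
    """One cure/failure definition applied at a follow-up visit.

    ``variant`` with ``max_summary``/``max_item`` caps defines a
    symptom-score criterion; ``forbid_visible_blood`` additionally
    requires absent visible blood; ``qol_max_item`` caps every
    quality-of-life item; ``dynamics_success_levels`` defines success for
    the patient-global-assessment-only measure.
    """

    model_config = {"frozen": True}

    name: str
    variant: Optional[SymptomVariant] = None
    max_summary: Optional[int] = None
    max_item: Optional[int] = None
    forbid_visible_blood: bool = False
    qol_max_item: Optional[int] = None
    dynamics_success_levels: Optional[frozenset[int]] = None


_STANDARD_THRESHOLDS = {
    "ACSS5": OutcomeThreshold(
        name="ACSS5", variant=SymptomVariant.ACSS5, max_summary=5, max_item=1,
        forbid_visible_blood=True,
    ),
    "FDA4": OutcomeThreshold(
        name="FDA4", variant=SymptomVariant.FDA4, max_summary=4, max_item=1,
        forbid_visible_blood=True,
    ),
    "EMA3": OutcomeThreshold(
        name="EMA3", variant=SymptomVariant.EMA3, max_summary=3, max_item=1,
        forbid_visible_blood=True,
    ),
    # QoL criterion: every QoL item at most mild.  The exact cut used in
    # published summaries is not stated, so it is a configurable value.
    "ACSS5_QOL": OutcomeThreshold(
        name="ACSS5_QOL", variant=SymptomVariant.ACSS5, max_summary=5, max_item=1,
        forbid_visible_blood=True, qol_max_item=1,
    ),
    # Patient's overall assessment alone; kept for comparability although
    # it is not sensitive enough to be a recommended endpoint.
    "DYNAMICS_ONLY": OutcomeThreshold(
        name="DYNAMICS_ONLY", dynamics_success_levels=frozenset({0}),
    ),
}

STANDARD_THRESHOLD_NAMES = tuple(_STANDARD_THRESHOLDS)


def standard_threshold(name: Union[str, OutcomeThreshold]) -> OutcomeThreshold:
    if isinstance(name, OutcomeThreshold):
        return name
    try:
        return _STANDARD_THRESHOLDS[name]
    except KeyError:
        raise ValueError(
            f"unknown threshold {name!r}; known: {STANDARD_THRESHOLD_NAMES}"
        ) from None


@dataclass(frozen=True)
class Adjudication:
    """Cure/failure status of one visit, with reasons and hematuria flag."""

    status: str  # "success" | "failure"
    hematuria_flag: bool
    reasons: tuple[str, ...] = ()

    @property
    def success(self) -> bool:
        return self.status == "success"


def adjudicate(
    response: AcssResponse,
    threshold: Union[str, OutcomeThreshold],
    rescue_taken: bool = False,
) -> Adjudication:
    """Adjudicate a Part B response under one outcome threshold.

    Rescue therapy forces failure.  Otherwise failure occurs when the
    variant summary score exceeds ``max_summary``, any variant item
    exceeds ``max_item``, visible blood is present while forbidden, any
    QoL item exceeds ``qol_max_item``, or (for the dynamics-only
    measure) the patient's overall assessment is outside the success
    levels.  The hematuria flag is set whenever visible blood of any
    severity is reported, independently of the status.
    """
    if response.part != "B":
        raise ValueError("outcome is adjudicated on follow-up Part B records")
    thr = standard_threshold(threshold)

    hematuria = response.visible_blood >= 1
    reasons: list[str] = []
    failed = False

    if rescue_taken:
        reasons.append("FAIL: rescue antibiotic therapy taken")
        failed = True
    else:
        if thr.variant is not None:
            score = variant_score(response, thr.variant)
            worst = max_severity(response, thr.variant)
            if thr.max_summary is not None and score > thr.max_summary:
                reasons.append(
                    f"FAIL: {thr.variant.name} summary score {score} > {thr.max_summary}"
                )
                failed = True
            if thr.max_item is not None and worst > thr.max_item:
                reasons.append(f"FAIL: symptom severity {worst} > {thr.max_item}")
                failed = True
        if thr.forbid_visible_blood and response.visible_blood >= 1:
            reasons.append("FAIL: visible blood in urine present")
            failed = True
        if thr.qol_max_item is not None and max(response.qol) > thr.qol_max_item:
            reasons.append(f"FAIL: QoL item severity {max(response.qol)} > {thr.qol_max_item}")
            failed = True
        if thr.dynamics_success_levels is not None:
            if response.dynamics is None:
                raise ValueError("dynamics-based threshold requires the dynamics item")
            if response.dynamics not in thr.dynamics_success_levels:
                reasons.append(
                    f"FAIL: dynamics level {response.dynamics} not in success levels"
                )
                failed = True

    if not failed:
        reasons.append("PASS: all cure criteria met")
    return Adjudication(
        status="failure" if failed else "success",
        hematuria_flag=hematuria,
        reasons=tuple(reasons),
    )


def success_table(
    adjudications: Union[pd.DataFrame, Iterable[dict]],
    thresholds: Optional[Sequence[str]] = None,
    windows: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Tabulate success counts and proportions per threshold × window.

    ``adjudications`` carries one record per patient, window and
    threshold with columns ``patient_id``, ``window``, ``threshold``,
    ``status``.  Duplicate (patient, window, threshold) entries raise.
    """
    df = adjudications if isinstance(adjudications, pd.DataFrame) else pd.DataFrame(
        list(adjudications)
    )
    if df.empty:
        return pd.DataFrame(
            columns=["threshold", "window", "n_success", "n_total", "proportion"]
        )
    required = {"patient_id", "window", "threshold", "status"}
    if not required <= set(df.columns):
        raise ValueError(f"adjudication table needs columns {sorted(required)}")
    if df.duplicated(["patient_id", "window", "threshold"]).any():
        raise ValueError("duplicate patient-window-threshold adjudications")

    if thresholds is not None:
        df = df[df["threshold"].isin(thresholds)]
    if windows is not None:
        df = df[df["window"].isin(windows)]

    grouped = (
        df.assign(success=(df["status"] == "success").astype(int))
        .groupby(["threshold", "window"], sort=False)
        .agg(n_success=("success", "sum"), n_total=("success", "size"))
        .reset_index()
    )
    grouped["proportion"] = grouped["n_success"] / grouped["n_total"]
    return grouped


def write_adjudications(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write per-visit adjudications to CSV (reasons semicolon-joined)."""
    out = df.copy()
    if "reasons" in out.columns:
        out["reasons"] = out["reasons"].map(
            lambda r: "; ".join(r) if isinstance(r, (list, tuple)) else r
        )
    out.to_csv(path, index=False, encoding="utf-8")
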