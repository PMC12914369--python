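"""Shared patient-record containers for cohorts and trials."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .acss_model import AcssResponse
from .microbiology import UrineResult

__all__ = ["DiagnosticCohort", "Visit", "TrialRecord"]


@dataclass
class DiagnosticCohort:
    """A labeled cross-sectional cohort for diagnostic-rule evaluation.

    ``responses`` (baseline Part A), ``urines`` and boolean reference
    ``labels`` (True = physician-diagnosed cystitis) are index-aligned.
    """

    responses: list[AcssResponse]
    urines: list[UrineResult]
    labels: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.responses) == len(self.urines) == len(self.labels)):
            raise ValueError("responses, urines and labels must be aligned")
        self.labels = np.asarray(self.labels, dtype=bool)

    def __len__(self) -> int:
        return len(self.responses)

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.labels).sum())

    def label_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.responses],
                "case": self.labels.astype(int),
            }
        )


@dataclass(frozen=True)
class Visit:
    """One scheduled follow-up contact."""

    window: str
    response: Optional[AcssResponse] = None
    urine: Optional[UrineResult] = None
    rescue_taken: bool = False


@dataclass
class TrialRecord:
    """One randomized patient: arm, baseline, and visit-indexed follow-up."""

    patient_id: str
    arm: str
    dosed: bool
    baseline: AcssResponse
    baseline_urine: Optional[UrineResult]
    baseline_eligible: bool
    visits: dict[str, Visit] = field(default_factory=dict)

    def visit(self, window: str) -> Optional[Visit]:
        return self.visits.get(window)
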