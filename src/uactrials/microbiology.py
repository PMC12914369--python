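"""Bacteriuria-significance policies and microbiological outcome.

What colony count makes a urine culture "significant" is contested for
acute cystitis.  The classical ≥10⁵ CFU/mL criterion was derived for
pyelonephritis and is highly specific but insensitive for cystitis;
lower cut-offs (≥10² CFU/mL, or 10¹–10² for *Escherichia coli* and
*Staphylococcus saprophyticus*) are far more sensitive in symptomatic
women.  Species-aware guidance treats *E. coli* as predictive at any
count while regarding enterococci and group B streptococci as
non-predictive.  This module encodes those alternatives as named,
deterministic :class:`SignificancePolicy` objects and classifies
microbiological outcome (eradication / persistence / new infection)
between a baseline and a follow-up culture.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, field_validator

__all__ = [
    "Isolate",
    "UrineResult",
    "SpeciesClass",
    "classify_species",
    "SignificancePolicy",
    "get_policy",
    "POLICY_NAMES",
    "significant_bacteriuria",
    "MicroOutcome",
    "micro_outcome",
    "abu_flag",
    "read_cultures",
    "write_cultures",
    "CULTURE_COLUMNS",
]


class Isolate(BaseModel):
    """One cultured organism with its colony count (CFU/mL)."""

    model_config = {"frozen": True}

    species: str
    cfu: float

    @field_validator("species")
    @classmethod
    def _species_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("species label must be non-empty")
        return v

    @field_validator("cfu")
    @classmethod
    def _cfu_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError(f"CFU count must be positive, got {v}")
        return v


class UrineResult(BaseModel):
    """Urinalysis and culture observations for one patient visit."""

    model_config = {"frozen": True}

    patient_id: str = ""
    visit_day: int = 0
    wbc: float = 0.0
    isolates: tuple[Isolate, ...] = ()

    @field_validator("wbc")
    @classmethod
    def _wbc_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"WBC count cannot be negative: {v}")
        return v

    @property
    def sterile(self) -> bool:
        return len(self.isolates) == 0


class SpeciesClass(str, enum.Enum):
    E_COLI = "e_coli"
    S_SAPROPHYTICUS = "s_saprophyticus"
    ENTEROCOCCUS = "enterococcus"
    GROUP_B_STREP = "group_b_strep"
    OTHER = "other"


def classify_species(label: str) -> SpeciesClass:
    """Map a free-text species label to a policy species class."""
    s = label.strip().lower()
    if "escherichia coli" in s or s in ("e. coli", "e coli", "ecoli"):
        return SpeciesClass.E_COLI
    if "saprophyticus" in s:
        return SpeciesClass.S_SAPROPHYTICUS
    if "enterococcus" in s or "enterococci" in s:
        return SpeciesClass.ENTEROCOCCUS
    if "agalactiae" in s or "group b strep" in s:
        return SpeciesClass.GROUP_B_STREP
    return SpeciesClass.OTHER


@dataclass(frozen=True)
class SignificancePolicy:
    """Deterministic mapping from (species, CFU/mL) to significance.

    ``thresholds`` maps a species class to its minimum significant count;
    ``None`` means the species is never significant.  Species classes not
    listed fall back to ``default_threshold``.
    """

    name: str
    thresholds: dict[SpeciesClass, Optional[float]]
    default_threshold: float

    def isolate_significant(self, isolate: Isolate) -> bool:
        cut = self.thresholds.get(classify_species(isolate.species), self.default_threshold)
        if cut is None:
            return False
        return isolate.cfu >= cut


# Non-E. coli primary-pathogen threshold under the species-aware policy is
# configuration, not biology: no enumeration exists in guidance text.
S3_DEFAULT_OTHER_THRESHOLD = 1e3

_POLICIES = {
    # Classical definition of significant bacteriuria (≥10^5 CFU/mL).
    "general_1e5": SignificancePolicy("general_1e5", {}, 1e5),
    # Low count criterion for acute cystitis (≥10^2 CFU/mL).
    "stamm_1e2": SignificancePolicy("stamm_1e2", {}, 1e2),
    # Most sensitive of the set: E. coli / S. saprophyticus at 10^1.
    "hooton_low": SignificancePolicy(
        "hooton_low",
        {SpeciesClass.E_COLI: 1e1, SpeciesClass.S_SAPROPHYTICUS: 1e1},
        1e2,
    ),
    # Species-aware rule: E. coli predictive at any count; enterococci and
    # group B streptococci never predictive; other uropathogens at 10^3.
    "s3_species_aware": SignificancePolicy(
        "s3_species_aware",
        {
            SpeciesClass.E_COLI: 1.0,
            SpeciesClass.ENTEROCOCCUS: None,
            SpeciesClass.GROUP_B_STREP: None,
        },
        S3_DEFAULT_OTHER_THRESHOLD,
    ),
}

POLICY_NAMES = tuple(_POLICIES)


def get_policy(name: Union[str, SignificancePolicy]) -> SignificancePolicy:
    """Look up a named policy; pass a policy object through unchanged."""
    if isinstance(name, SignificancePolicy):
        return name
    try:
        return _POLICIES[name]
    except KeyError:
        raise ValueError(f"unknown significance policy {name!r}; known: {POLICY_NAMES}") from None


def significant_bacteriuria(
    result: UrineResult, policy: Union[str, SignificancePolicy]
) -> tuple[bool, list[Isolate]]:
    """Whether the culture shows significant bacteriuria, and which isolates."""
    pol = get_policy(policy)
    hits = [iso for iso in result.isolates if pol.isolate_significant(iso)]
    return bool(hits), hits


class MicroOutcome(str, enum.Enum):
    ERADICATION = "eradication"
    PERSISTENCE = "persistence"
    NEW_INFECTION = "new_infection"
    INDETERMINATE = "indeterminate"


def _norm_species(label: str) -> str:
    return " ".join(label.strip().lower().split())


def micro_outcome(
    baseline: UrineResult,
    followup: Optional[UrineResult],
    policy: Union[str, SignificancePolicy],
) -> MicroOutcome:
    """Classify microbiological outcome between baseline and follow-up.

    The baseline must itself show significant bacteriuria (otherwise the
    patient is not in the microbiological ITT population and a
    ``ValueError`` is raised).  A missing follow-up culture is
    *indeterminate*.  Species are matched by normalised label; no strain
    typing is attempted.
    """
    pol = get_policy(policy)
    base_sig, base_hits = significant_bacteriuria(baseline, pol)
    if not base_sig:
        raise ValueError(
            "baseline culture shows no significant bacteriuria; "
            "patient is outside the microbiological ITT population"
        )
    if followup is None:
        return MicroOutcome.INDETERMINATE

    baseline_species = {_norm_species(iso.species) for iso in base_hits}
    _, fu_hits = significant_bacteriuria(followup, pol)
    fu_species = {_norm_species(iso.species) for iso in fu_hits}

    if fu_species & baseline_species:
        return MicroOutcome.PERSISTENCE
    if fu_species:
        return MicroOutcome.NEW_INFECTION
    return MicroOutcome.ERADICATION


def abu_flag(
    clinical_success: bool,
    followup: Optional[UrineResult],
    policy: Union[str, SignificancePolicy],
) -> bool:
    """Asymptomatic bacteriuria: clinical success with significant bacteriuria.

    Marks patients for the relapse sub-analysis at late follow-up, where
    residual bacteriuria without symptoms may even protect against
    recurrence.
    """
    if not clinical_success or followup is None:
        return False
    sig, _ = significant_bacteriuria(followup, policy)
    return sig


# ---------------------------------------------------------------------------
# CSV dialect: one isolate per row; a sterile culture is a single row with
# empty species and cfu 0.
# ---------------------------------------------------------------------------

CULTURE_COLUMNS = ["patient_id", "visit_day", "wbc_mm3", "species", "cfu_per_ml"]


def write_cultures(results: Sequence[UrineResult], path: Union[str, Path]) -> None:
    rows = []
    for res in results:
        if res.sterile:
            rows.append(
                {"patient_id": res.patient_id, "visit_day": res.visit_day,
                 "wbc_mm3": res.wbc, "species": "", "cfu_per_ml": 0.0}
            )
        else:
            for iso in res.isolates:
                rows.append(
                    {"patient_id": res.patient_id, "visit_day": res.visit_day,
                     "wbc_mm3": res.wbc, "species": iso.species, "cfu_per_ml": iso.cfu}
                )
    pd.DataFrame(rows, columns=CULTURE_COLUMNS).to_csv(path, index=False, encoding="utf-8")


def read_cultures(path: Union[str, Path]) -> list[UrineResult]:
    df = pd.read_csv(path, dtype={"patient_id": str, "species": str}, keep_default_na=False)
    missing = set(CULTURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out: list[UrineResult] = []
    for (pid, day), group in df.groupby(["patient_id", "visit_day"], sort=False):
        isolates = [
            Isolate(species=row.species, cfu=float(row.cfu_per_ml))
            for row in group.itertuples()
            if str(row.species).strip()
        ]
        out.append(
            UrineResult(
                patient_id=str(pid),
                visit_day=int(day),
                wbc=float(group["wbc_mm3"].iloc[0]),
                isolates=tuple(isolates),
            )
        )
    return out
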