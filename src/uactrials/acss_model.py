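"""Data model and scoring for the Acute Cystitis Symptom Score (ACSS).

The ACSS is an 18-item patient self-reporting questionnaire for
uncomplicated acute cystitis (uAC) in women.  It exists in two forms:
diagnostic Part A (baseline) and follow-up Part B.  Items are allocated to
four domains:

* **Typical** — six typical cystitis symptoms, in the fixed order
  frequency, urgency, dysuria, suprapubic pain, sense of incomplete
  bladder emptying, visible blood in urine;
* **Differential** — four items for differential diagnosis;
* **QoL** — three quality-of-life items;
* **Additional** — five dichotomous yes/no condition flags.

Typical, Differential and QoL items are scored on a 4-point ordinal scale
from 0 (absent) to 3 (severe).  Part B adds a single "Dynamics" item
describing the overall evolution of symptoms, encoded here as an ordinal
0 (fully recovered) … 4 (worse).

Regulatory guidance differs in how many typical symptoms define the
syndrome, which this module captures as nested symptom-set variants:
EMA3 (frequency, urgency, dysuria) ⊂ FDA4 (+ suprapubic pain) ⊂
ACSS5 (+ incomplete emptying) ⊂ ACSS6 (+ visible blood).
"""

from __future__ import annotations

import enum
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

__all__ = [
    "TYPICAL_ITEMS",
    "VISIBLE_BLOOD_INDEX",
    "SymptomVariant",
    "AcssResponse",
    "score_domain",
    "variant_score",
    "max_severity",
    "validate_response",
    "read_responses",
    "write_responses",
    "RESPONSE_COLUMNS",
]

#: Fixed item order of the Typical domain.
TYPICAL_ITEMS = (
    "frequency",
    "urgency",
    "dysuria",
    "suprapubic_pain",
    "incomplete_emptying",
    "visible_blood",
)

#: Position of "visible blood in urine" within the Typical domain.
VISIBLE_BLOOD_INDEX = 5

SEVERITY_MIN, SEVERITY_MAX = 0, 3
DYNAMICS_MIN, DYNAMICS_MAX = 0, 4


class SymptomVariant(enum.Enum):
    """Nested typical-symptom subsets used by different guidelines.

    The enum value is the ordered tuple of Typical-domain indices the
    variant scores over.
    """

    EMA3 = (0, 1, 2)
    FDA4 = (0, 1, 2, 3)
    ACSS5 = (0, 1, 2, 3, 4)
    ACSS6 = (0, 1, 2, 3, 4, 5)

    @property
    def indices(self) -> tuple[int, ...]:
        return self.value

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(TYPICAL_ITEMS[i] for i in self.value)

    def __len__(self) -> int:
        return len(self.value)


class AcssResponse(BaseModel):
    """One administration of the ACSS questionnaire.

    Parameters
    ----------
    patient_id
        Subject identifier; empty string when anonymous.
    part
        ``"A"`` for the diagnostic baseline form, ``"B"`` for follow-up.
    visit_day
        Days since treatment start (0 or negative for baseline).
    typical, differential, qol
        Ordinal severities (0–3) for the respective domains, with exactly
        6, 4 and 3 entries.
    additional
        Five yes/no condition flags; stored but never scored.
    dynamics
        Overall symptom evolution (0 recovered … 4 worse); Part B only.
    """

    model_config = {"frozen": True}

    patient_id: str = ""
    part: Literal["A", "B"]
    visit_day: int = 0
    typical: tuple[int, int, int, int, int, int]
    differential: tuple[int, int, int, int]
    qol: tuple[int, int, int]
    additional: tuple[bool, bool, bool, bool, bool] = (False,) * 5
    dynamics: Optional[int] = None

    @field_validator("typical", "differential", "qol")
    @classmethod
    def _severities_in_range(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        for s in v:
            if not SEVERITY_MIN <= s <= SEVERITY_MAX:
                raise ValueError(f"severity {s} out of range {SEVERITY_MIN}-{SEVERITY_MAX}")
        return v

    @field_validator("dynamics")
    @classmethod
    def _dynamics_in_range(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and not DYNAMICS_MIN <= v <= DYNAMICS_MAX:
            raise ValueError(f"dynamics {v} out of range {DYNAMICS_MIN}-{DYNAMICS_MAX}")
        return v

    @model_validator(mode="after")
    def _dynamics_only_part_b(self) -> "AcssResponse":
        if self.dynamics is not None and self.part != "B":
            raise ValueError("dynamics item is only defined for Part B")
        return self

    @property
    def visible_blood(self) -> int:
        return self.typical[VISIBLE_BLOOD_INDEX]


def score_domain(response: AcssResponse, domain: str) -> int:
    """Summary score (sum of ordinal severities) of a scored domain.

    ``domain`` is one of ``"typical"``, ``"differential"``, ``"qol"``.
    """
    if domain not in ("typical", "differential", "qol"):
        raise ValueError(f"unknown domain {domain!r}")
    return int(sum(getattr(response, domain)))


def variant_score(response: AcssResponse, variant: SymptomVariant) -> int:
    """Summary score over the typical-symptom subset of ``variant``."""
    return int(sum(response.typical[i] for i in variant.indices))


def max_severity(response: AcssResponse, variant: SymptomVariant) -> int:
    """Maximum single-item severity over the typical-symptom subset."""
    return int(max(response.typical[i] for i in variant.indices))


# ---------------------------------------------------------------------------
# Raw-record validation and delimited-text I/O
# ---------------------------------------------------------------------------

#: Canonical column set of the questionnaire CSV dialect, one row per
#: administration.
RESPONSE_COLUMNS = (
    ["patient_id", "part", "visit_day"]
    + [f"t{i}" for i in range(1, 7)]
    + [f"d{i}" for i in range(1, 5)]
    + [f"q{i}" for i in range(1, 4)]
    + [f"a{i}" for i in range(1, 6)]
    + ["dyn"]
)

_DOMAIN_KEYS = {
    "typical": [f"t{i}" for i in range(1, 7)],
    "differential": [f"d{i}" for i in range(1, 5)],
    "qol": [f"q{i}" for i in range(1, 4)],
}


def _missing(value) -> bool:
    return value is None or (isinstance(value, str) and value.strip() == "") or (
        isinstance(value, float) and pd.isna(value)
    )


def validate_response(record: Mapping) -> Union[AcssResponse, list[str]]:
    """Translate a raw key-value record into a validated response.

    Returns an :class:`AcssResponse` when the record is fully valid, or a
    complete list of human-readable constraint violations otherwise.
    Never raises on bad content.
    """
    violations: list[str] = []

    part = record.get("part")
    if part not in ("A", "B"):
        violations.append(f"part must be 'A' or 'B', got {part!r}")

    try:
        visit_day = int(record.get("visit_day", 0))
    except (TypeError, ValueError):
        violations.append(f"visit_day not an integer: {record.get('visit_day')!r}")
        visit_day = 0

    severities: dict[str, tuple[int, ...]] = {}
    for domain, keys in _DOMAIN_KEYS.items():
        vals = []
        for key in keys:
            raw = record.get(key)
            if _missing(raw):
                violations.append(f"missing item {key}")
                continue
            try:
                v = int(raw)
            except (TypeError, ValueError):
                violations.append(f"item {key} not an integer: {raw!r}")
                continue
            if not SEVERITY_MIN <= v <= SEVERITY_MAX:
                violations.append(f"item {key} severity out of range: {v}")
                continue
            vals.append(v)
        severities[domain] = tuple(vals)

    additional = []
    for key in (f"a{i}" for i in range(1, 6)):
        raw = record.get(key)
        if _missing(raw):
            violations.append(f"missing item {key}")
            continue
        try:
            additional.append(bool(int(raw)))
        except (TypeError, ValueError):
            violations.append(f"item {key} not boolean (0/1): {raw!r}")

    dynamics: Optional[int] = None
    raw_dyn = record.get("dyn")
    if not _missing(raw_dyn):
        try:
            dynamics = int(raw_dyn)
        except (TypeError, ValueError):
            violations.append(f"dyn not an integer: {raw_dyn!r}")
        else:
            if not DYNAMICS_MIN <= dynamics <= DYNAMICS_MAX:
                violations.append(f"dyn out of range: {dynamics}")
            if part == "A":
                violations.append("dynamics item present on Part A record")

    if violations:
        return violations
    return AcssResponse(
        patient_id=str(record.get("patient_id", "")),
        part=part,
        visit_day=visit_day,
        typical=severities["typical"],
        differential=severities["differential"],
        qol=severities["qol"],
        additional=tuple(additional),
        dynamics=dynamics,
    )


def response_to_row(response: AcssResponse) -> dict:
    """Flatten a response into one CSV row (dict keyed by RESPONSE_COLUMNS)."""
    row: dict = {
        "patient_id": response.patient_id,
        "part": response.part,
        "visit_day": response.visit_day,
    }
    for i, v in enumerate(response.typical, 1):
        row[f"t{i}"] = v
    for i, v in enumerate(response.differential, 1):
        row[f"d{i}"] = v
    for i, v in enumerate(response.qol, 1):
        row[f"q{i}"] = v
    for i, v in enumerate(response.additional, 1):
        row[f"a{i}"] = int(v)
    row["dyn"] = "" if response.dynamics is None else response.dynamics
    return row


def write_responses(responses: Sequence[AcssResponse], path: Union[str, Path]) -> None:
    """Write questionnaire administrations to a UTF-8 CSV with header."""
    df = pd.DataFrame([response_to_row(r) for r in responses], columns=RESPONSE_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_responses(path: Union[str, Path]) -> list[AcssResponse]:
    """Read questionnaire administrations from CSV; raise on invalid rows."""
    df = pd.read_csv(path, dtype={"patient_id": str, "part": str}, keep_default_na=False)
    missing_cols = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    out: list[AcssResponse] = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        result = validate_response(row)
        if isinstance(result, list):
            raise ValueError(f"invalid record at row {idx}: {'; '.join(result)}")
        out.append(result)
    return out
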