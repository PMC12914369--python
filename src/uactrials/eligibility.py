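"""Patient-selection rules combining symptom scores and pyuria.

Enrollment into a cystitis trial should maximise the probability that a
patient truly has uncomplicated acute cystitis before culture results are
available.  A :class:`DiagnosticRule` therefore combines

* a typical-symptom subset (:class:`~uactrials.acss_model.SymptomVariant`)
  with a minimum summary score,
* optionally the requirement that at least one symptom is *more than
  mild* (severity ≥ 2), and
* optionally documented pyuria (white blood cells in mid-stream urine at
  or above a threshold, conventionally 10 WBC/mm³).

All threshold comparisons are inclusive (≥).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

from pydantic import BaseModel, model_validator

from .acss_model import AcssResponse, SymptomVariant, max_severity, variant_score
from .microbiology import UrineResult

__all__ = [
    "DiagnosticRule",
    "EligibilityDecision",
    "assess_pyuria",
    "assess_symptoms",
    "enroll",
    "rule_from_config",
    "DEFAULT_RULE",
]


class DiagnosticRule(BaseModel):
    """A candidate inclusion rule.

    Attributes
    ----------
    variant
        Typical-symptom subset the summary score is computed over.
    min_summary
        Minimum summary score (inclusive).
    require_more_than_mild
        Require at least one scored symptom with severity ≥ 2.
    require_pyuria
        Require WBC ≥ ``pyuria_threshold`` in mid-stream urine.
    pyuria_threshold
        WBC per mm³ cut-off, inclusive.
    mild_blood_qualifies
        If set, mild visible blood (severity ≥ 1) also satisfies the
        more-than-mild requirement.  Off by default: visible blood
        discriminates cases from controls even when mild, but it is not a
        stated inclusion criterion.
    exclude_differential
        If set, any differential-domain item ≥ 2 blocks eligibility.
    """

    model_config = {"frozen": True}

    name: str = ""
    variant: SymptomVariant = SymptomVariant.ACSS6
    min_summary: int = 6
    require_more_than_mild: bool = True
    require_pyuria: bool = False
    pyuria_threshold: float = 10.0
    mild_blood_qualifies: bool = False
    exclude_differential: bool = False

    @model_validator(mode="after")
    def _check(self) -> "DiagnosticRule":
        if not 0 <= self.min_summary <= 3 * len(self.variant):
            raise ValueError(
                f"min_summary {self.min_summary} outside [0, {3 * len(self.variant)}]"
            )
        if self.require_pyuria and self.pyuria_threshold <= 0:
            raise ValueError("pyuria_threshold must be positive when pyuria is required")
        return self


#: The recommended default: all six ACSS typical symptoms, summary score
#: ≥ 6, at least one more-than-mild symptom, documented pyuria.
DEFAULT_RULE = DiagnosticRule(
    name="acss6_pyuria",
    variant=SymptomVariant.ACSS6,
    min_summary=6,
    require_more_than_mild=True,
    require_pyuria=True,
    pyuria_threshold=10.0,
)


@dataclass(frozen=True)
class EligibilityDecision:
    """Outcome of applying a rule, with per-criterion reasons."""

    eligible: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.eligible


def assess_pyuria(wbc: float, threshold: float = 10.0) -> bool:
    """True iff the WBC density meets the pyuria threshold (inclusive)."""
    if wbc < 0:
        raise ValueError(f"WBC count cannot be negative: {wbc}")
    return wbc >= threshold


def assess_symptoms(response: AcssResponse, rule: DiagnosticRule) -> EligibilityDecision:
    """Apply the symptom-score part of a rule to a baseline Part A record."""
    if response.part != "A":
        raise ValueError("symptom eligibility is assessed on baseline Part A records")

    reasons: list[str] = []
    ok = True

    score = variant_score(response, rule.variant)
    if score >= rule.min_summary:
        reasons.append(f"PASS: {rule.variant.name} summary score {score} >= {rule.min_summary}")
    else:
        reasons.append(f"FAIL: {rule.variant.name} summary score {score} < {rule.min_summary}")
        ok = False

    if rule.require_more_than_mild:
        worst = max_severity(response, rule.variant)
        qualifies = worst >= 2 or (rule.mild_blood_qualifies and response.visible_blood >= 1)
        if qualifies:
            reasons.append(f"PASS: at least one symptom more than mild (max severity {worst})")
        else:
            reasons.append(f"FAIL: no symptom more than mild (max severity {worst})")
            ok = False

    if rule.exclude_differential and max(response.differential) >= 2:
        reasons.append("FAIL: differential-domain item of severity >= 2 present")
        ok = False

    return EligibilityDecision(eligible=ok, reasons=tuple(reasons))


def enroll(
    response: AcssResponse, urine: Optional[UrineResult], rule: DiagnosticRule
) -> EligibilityDecision:
    """Full enrollment decision: symptoms plus (optionally) pyuria."""
    if urine is not None and response.patient_id and urine.patient_id:
        if response.patient_id != urine.patient_id:
            raise ValueError(
                f"patient id mismatch: {response.patient_id!r} vs {urine.patient_id!r}"
            )

    symptom_decision = assess_symptoms(response, rule)
    reasons = list(symptom_decision.reasons)
    ok = symptom_decision.eligible

    if rule.require_pyuria:
        if urine is None:
            reasons.append("FAIL: pyuria required but no urinalysis available")
            ok = False
        elif assess_pyuria(urine.wbc, rule.pyuria_threshold):
            reasons.append(f"PASS: pyuria (WBC {urine.wbc:g} >= {rule.pyuria_threshold:g}/mm3)")
        else:
            reasons.append(f"FAIL: no pyuria (WBC {urine.wbc:g} < {rule.pyuria_threshold:g}/mm3)")
            ok = False

    return EligibilityDecision(eligible=ok, reasons=tuple(reasons))


def rule_from_config(source: Union[str, Path, Mapping]) -> DiagnosticRule:
    """Build a rule from a ``key = value`` plain-text config or mapping."""
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        raw = {}
        for line in Path(source).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()

    kwargs: dict = {}
    if "name" in raw:
        kwargs["name"] = str(raw["name"])
    if "variant" in raw:
        v = raw["variant"]
        kwargs["variant"] = v if isinstance(v, SymptomVariant) else SymptomVariant[str(v)]
    if "min_summary" in raw:
        kwargs["min_summary"] = int(raw["min_summary"])
    for flag in ("require_more_than_mild", "require_pyuria", "mild_blood_qualifies",
                 "exclude_differential"):
        if flag in raw:
            val = raw[flag]
            kwargs[flag] = val if isinstance(val, bool) else str(val).lower() in ("1", "true", "yes")
    if "pyuria_threshold" in raw:
        kwargs["pyuria_threshold"] = float(raw["pyuria_threshold"])
    return DiagnosticRule(**kwargs)
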