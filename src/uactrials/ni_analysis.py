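"""Non-inferiority analysis of success proportions between trial arms.

The primary endpoint of a comparative cystitis trial is the clinical
success proportion at the test-of-cure visit, compared between the test
(non-antibiotic) and reference (antibiotic) arm as a risk difference
p_test − p_ref with a two-sided confidence interval.  Non-inferiority is
concluded when the lower confidence bound lies strictly above the
margin, by default −10 percentage points.

The default interval is the Newcombe hybrid Wilson-score interval, which
behaves well for proportions near the boundary; a Wald interval and the
Miettinen-Nurminen-type score interval are selectable for comparability.

Analysis populations are nested: the intention-to-treat population (all
randomized), the clinical ITT population (randomized, received at least
one dose, symptomatically eligible at baseline) and the microbiological
ITT population (clinical ITT with significant baseline bacteriuria under
a chosen policy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .microbiology import SignificancePolicy, significant_bacteriuria
from .records import TrialRecord

__all__ = [
    "ArmSummary",
    "NiResult",
    "POPULATIONS",
    "population_filter",
    "wilson_interval",
    "risk_difference_ci",
    "noninferiority_conclusion",
]


@dataclass(frozen=True)
class ArmSummary:
    """Success count out of n for one arm."""

    arm: str
    n: int
    successes: int

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.n:
            raise ValueError(f"successes {self.successes} outside [0, n={self.n}]")

    @property
    def proportion(self) -> float:
        return self.successes / self.n if self.n else float("nan")


@dataclass(frozen=True)
class NiResult:
    """Risk difference (test − reference) with CI and NI conclusion."""

    risk_difference: float
    ci: tuple[float, float]
    level: float
    method: str
    margin: Optional[float] = None
    conclusion: Optional[str] = None  # "non_inferior" | "inconclusive"


POPULATIONS = ("itt", "clinical_itt", "micro_itt")


def population_filter(
    records: Sequence[TrialRecord],
    population: str,
    policy: Optional[Union[str, SignificancePolicy]] = None,
) -> list[TrialRecord]:
    """Select the analysis population from randomized trial records.

    * ``itt`` — everyone randomized;
    * ``clinical_itt`` — randomized, at least one dose, baseline
      symptomatic eligibility;
    * ``micro_itt`` — clinical ITT with significant baseline bacteriuria
      under ``policy`` (required; note this can exclude a large share of
      genuinely symptomatic patients under a strict count threshold).
    """
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}; known: {POPULATIONS}")
    if population == "itt":
        return list(records)
    clinical = [r for r in records if r.dosed and r.baseline_eligible]
    if population == "clinical_itt":
        return clinical
    if policy is None:
        raise ValueError("micro_itt population requires a significance policy")
    out = []
    for r in clinical:
        if r.baseline_urine is not None and significant_bacteriuria(r.baseline_urine, policy)[0]:
            out.append(r)
    return out


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a single proportion."""
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def risk_difference_ci(
    test: ArmSummary,
    ref: ArmSummary,
    level: float = 0.95,
    method: str = "newcombe",
) -> NiResult:
    """Two-sided CI for the difference in success proportions.

    ``newcombe`` (default) squares-and-adds the distances from each
    arm's Wilson bounds to its point estimate; ``wald`` is the textbook
    normal interval; ``score`` delegates to the statsmodels score
    interval for two independent proportions.
    """
    if test.n == 0 or ref.n == 0:
        raise ValueError("both arms must have n > 0")
    p1, p2 = test.proportion, ref.proportion
    d = p1 - p2

    if method == "newcombe":
        l1, u1 = wilson_interval(test.successes, test.n, level)
        l2, u2 = wilson_interval(ref.successes, ref.n, level)
        lo = d - math.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
        hi = d + math.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    elif method == "wald":
        z = norm.ppf(0.5 + level / 2)
        se = math.sqrt(p1 * (1 - p1) / test.n + p2 * (1 - p2) / ref.n)
        lo, hi = d - z * se, d + z * se
    elif method == "score":
        from statsmodels.stats.proportion import confint_proportions_2indep

        lo, hi = confint_proportions_2indep(
            test.successes, test.n, ref.successes, ref.n,
            method="score", compare="diff", alpha=1 - level,
        )
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return NiResult(
        risk_difference=d, ci=(float(lo), float(hi)), level=level, method=method
    )


def noninferiority_conclusion(ni: NiResult, margin: float = -0.10) -> NiResult:
    """Attach the NI conclusion: lower CI bound strictly above the margin.

    Margins are negative by convention (largest acceptable deficit in
    the test arm); a bound exactly at the margin is inconclusive.
    """
    if margin >= 0:
        raise ValueError("non-inferiority margin must be negative")
    conclusion = "non_inferior" if ni.ci[0] > margin else "inconclusive"
    return replace(ni, margin=margin, conclusion=conclusion)
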