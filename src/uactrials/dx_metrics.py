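"""Diagnostic-accuracy battery for candidate inclusion rules.

Candidate symptom/pyuria rules are evaluated against the treating
physician's diagnosis as reference standard.  For each rule the module
reports sensitivity, specificity, predictive values, likelihood ratios,
the diagnostic odds ratio (DOR), Youden's index J = sens + spec − 1, an
ROC area, and the phi coefficient as the correlation between the rule's
decision and a positive diagnosis.  The rule maximising Youden's index
(equivalently, for binary rules, the one-point ROC area) offers the best
balance between sensitivity and specificity.

For score-valued classifiers (e.g. a symptom summary score over all
cut-offs) the ROC area is computed by the Mann-Whitney rank formulation:
the probability that a random case outscores a random control, ties
counted one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

from .eligibility import DiagnosticRule, enroll

__all__ = [
    "ConfusionMatrix",
    "build_confusion",
    "MetricReport",
    "metric_report",
    "score_auc",
    "metric_ci",
    "rule_sweep",
    "write_metric_table",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 table of rule decision against reference diagnosis."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def has_zero_cell(self) -> bool:
        return min(self.tp, self.fp, self.fn, self.tn) == 0


def build_confusion(
    decisions: Sequence[Union[bool, int]], reference: Sequence[Union[bool, int]]
) -> ConfusionMatrix:
    """Cross-tabulate paired boolean rule decisions and reference labels."""
    d = np.asarray(decisions, dtype=bool)
    r = np.asarray(reference, dtype=bool)
    if d.shape != r.shape or d.ndim != 1:
        raise ValueError("decisions and reference must be equal-length 1-d vectors")
    if d.size == 0:
        raise ValueError("empty input")
    return ConfusionMatrix(
        tp=int(np.sum(d & r)),
        fp=int(np.sum(d & ~r)),
        fn=int(np.sum(~d & r)),
        tn=int(np.sum(~d & ~r)),
    )


@dataclass(frozen=True)
class MetricReport:
    """Diagnostic metrics for one rule; undefined metrics are ``None``."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    lr_pos: Optional[float]
    lr_neg: Optional[float]
    dor: Optional[float]
    youden: Optional[float]
    auc: Optional[float]
    phi: Optional[float]
    correction: str = "none"


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def metric_report(cm: ConfusionMatrix, correction: str = "none") -> MetricReport:
    """Compute the full metric battery from a confusion matrix.

    ``correction="haldane_half"`` adds 0.5 to every cell before computing
    the ratio metrics (likelihood ratios, DOR) when any cell is zero;
    proportion metrics always use the raw counts.  Metrics with a zero
    denominator and no correction are reported as ``None`` rather than
    raising.
    """
    if correction not in ("none", "haldane_half"):
        raise ValueError(f"unknown correction {correction!r}")

    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)

    if correction == "haldane_half" and cm.has_zero_cell:
        a, b, c, d = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
    else:
        a, b, c, d = float(tp), float(fp), float(fn), float(tn)
    r_sens = _ratio(a, a + c)
    r_spec = _ratio(d, d + b)
    lr_pos = None
    lr_neg = None
    dor = None
    if r_sens is not None and r_spec is not None:
        lr_pos = _ratio(r_sens, 1 - r_spec)
        lr_neg = _ratio(1 - r_sens, r_spec)
        if b * c > 0:
            dor = (a * d) / (b * c)

    youden = sens + spec - 1 if sens is not None and spec is not None else None
    auc = (sens + spec) / 2 if sens is not None and spec is not None else None

    phi = None
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom > 0:
        phi = (tp * tn - fp * fn) / math.sqrt(denom)

    return MetricReport(
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        lr_pos=lr_pos, lr_neg=lr_neg, dor=dor, youden=youden, auc=auc, phi=phi,
        correction=correction,
    )


def score_auc(scores: Sequence[float], reference: Sequence[Union[bool, int]]) -> float:
    """ROC area for a score-valued classifier (rank / Mann-Whitney form).

    Equals the probability that a randomly drawn case has a higher score
    than a randomly drawn control, with ties counted one half; this is
    also the trapezoidal area under the empirical ROC curve over all
    thresholds.
    """
    s = np.asarray(scores, dtype=float)
    r = np.asarray(reference, dtype=bool)
    if s.shape != r.shape or s.ndim != 1:
        raise ValueError("scores and reference must be equal-length 1-d vectors")
    n_case = int(r.sum())
    n_ctrl = int((~r).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("AUC needs at least one case and one control")
    ranks = rankdata(s)  # midranks handle ties
    u = ranks[r].sum() - n_case * (n_case + 1) / 2
    return float(u / (n_case * n_ctrl))


_PROPORTION_METRICS = {
    "sensitivity": lambda cm: (cm.tp, cm.tp + cm.fn),
    "specificity": lambda cm: (cm.tn, cm.tn + cm.fp),
    "ppv": lambda cm: (cm.tp, cm.tp + cm.fp),
    "npv": lambda cm: (cm.tn, cm.tn + cm.fn),
}


def metric_ci(
    cm: ConfusionMatrix, metric: str, level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval for one metric.

    Proportion metrics use the Wilson score interval; likelihood ratios
    and the DOR use the normal interval on the log scale.  Raises when
    the metric is undefined on ``cm``.
    """
    if metric in _PROPORTION_METRICS:
        k, n = _PROPORTION_METRICS[metric](cm)
        if n == 0:
            raise ValueError(f"{metric} undefined: zero denominator")
        lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
        return float(lo), float(hi)

    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    z = norm.ppf(0.5 + level / 2)
    if metric == "lr_pos":
        if tp == 0 or fp == 0 or tn + fp == 0 or tp + fn == 0:
            raise ValueError("lr_pos interval undefined with zero cells")
        est = (tp / (tp + fn)) / (fp / (fp + tn))
        se = math.sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
    elif metric == "lr_neg":
        if fn == 0 or tn == 0:
            raise ValueError("lr_neg interval undefined with zero cells")
        est = (fn / (tp + fn)) / (tn / (fp + tn))
        se = math.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
    elif metric == "dor":
        if min(tp, fp, fn, tn) == 0:
            raise ValueError("dor interval undefined with zero cells")
        est = (tp * tn) / (fp * fn)
        se = math.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return float(est * math.exp(-z * se)), float(est * math.exp(z * se))


def rule_sweep(cohort, rules: Sequence[DiagnosticRule], level: float = 0.95) -> pd.DataFrame:
    """Evaluate candidate rules on a labeled diagnostic cohort.

    ``cohort`` exposes ``responses``, ``urines`` and boolean ``labels``
    (reference diagnosis), index-aligned.  Returns one row per rule with
    the full metric battery plus Wilson CIs for sensitivity/specificity;
    the rule(s) with the highest Youden's index are flagged ``best``.
    """
    if len(rules) == 0:
        raise ValueError("empty rule list")
    labels = np.asarray(cohort.labels, dtype=bool)
    rows = []
    for rule in rules:
        decisions = [
            enroll(resp, urine, rule).eligible
            for resp, urine in zip(cohort.responses, cohort.urines)
        ]
        cm = build_confusion(decisions, labels)
        rep = metric_report(cm, correction="haldane_half")
        sens_ci = metric_ci(cm, "sensitivity", level)
        spec_ci = metric_ci(cm, "specificity", level)
        rows.append(
            {
                "rule": rule.name or f"{rule.variant.name}>={rule.min_summary}"
                + ("+pyuria" if rule.require_pyuria else ""),
                "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
                "sensitivity": rep.sensitivity,
                "sens_ci_low": sens_ci[0], "sens_ci_high": sens_ci[1],
                "specificity": rep.specificity,
                "spec_ci_low": spec_ci[0], "spec_ci_high": spec_ci[1],
                "ppv": rep.ppv, "npv": rep.npv,
                "lr_pos": rep.lr_pos, "lr_neg": rep.lr_neg, "dor": rep.dor,
                "youden": rep.youden, "auc": rep.auc, "phi": rep.phi,
            }
        )
    df = pd.DataFrame(rows)
    best = df["youden"].max()
    df["best"] = df["youden"] == best
    return df


def write_metric_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False, encoding="utf-8")
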