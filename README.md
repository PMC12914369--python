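# uactrials

A design and simulation toolkit for clinical trials comparing
**non-antibiotic against antibiotic treatment of uncomplicated acute
cystitis (uAC)** in women. It is aimed at trial statisticians and
methodologists who need to pre-specify, stress-test and simulate the
whole analysis pipeline of such a trial before any patient is enrolled:
questionnaire-based eligibility, bacteriuria-significance policies,
visit-scheduled cure/failure adjudication, diagnostic-rule evaluation
and the primary non-inferiority analysis.

## What it implements

**ACSS scoring.** The Acute Cystitis Symptom Score (ACSS) is an 18-item
patient self-reporting questionnaire. Its *Typical* domain scores six
symptoms — frequency, urgency, dysuria, suprapubic pain, sense of
incomplete bladder emptying, visible blood in urine — each on an ordinal
0 (absent) … 3 (severe) scale. Regulatory guidance differs in which
symptoms define the syndrome, giving nested variants
EMA3 ⊂ FDA4 ⊂ ACSS5 ⊂ ACSS6.

**Eligibility.** A patient enters the trial when the summary score
S = Σᵢ sᵢ over the chosen symptom set satisfies S ≥ 6 (for ACSS6), at
least one symptom is more than mild (sᵢ ≥ 2), and documented pyuria
(≥ 10 WBC/mm³ in mid-stream urine) is present.

**Bacteriuria significance.** Four selectable policies: the classical
≥ 10⁵ CFU/mL rule, the ≥ 10² CFU/mL cystitis criterion, a low-count
10¹ CFU/mL rule for *E. coli* / *S. saprophyticus*, and a species-aware
rule under which *E. coli* is significant at any count while enterococci
and group B streptococci never are.

**Outcome adjudication.** At each scheduled visit (early: days 2–4; end
of treatment: days 5–9; test of cure: 5–7 days after end of treatment;
late follow-up: days 24–33), clinical cure under the favoured five-symptom
threshold means S₅ ≤ 5 with no single symptom above mild and no visible
blood; the complement — S₅ ≥ 6 or any symptom ≥ 2 — is clinical failure,
as is any switch to (another) antibiotic. Four-symptom and
three-symptom analogues use cure cuts of ≤ 4 and ≤ 3.

**Diagnostic metrics.** For candidate inclusion rules against the
physician's diagnosis: sensitivity, specificity, PPV/NPV, likelihood
ratios, diagnostic odds ratio, Youden's index J = se + sp − 1, ROC area
(Mann-Whitney rank form for score-valued rules) and the phi coefficient,
with Wilson or log-normal confidence intervals.

**Non-inferiority.** The primary analysis is the risk difference in
clinical success at test of cure, test arm minus reference arm, with a
Newcombe hybrid Wilson-score interval; non-inferiority is concluded when
the lower 95% bound lies strictly above the −10 percentage-point margin.

**Synthetic cohorts.** Because the source datasets are not deposited,
`synth_cohort` generates stand-ins with the same design: a 517-subject
case/control diagnostic cohort (285 cases, 232 controls) and a
134-patient two-arm longitudinal trial, both reproducible from a seed.

## Worked example

Simulate and analyze a complete trial (67 patients per arm):

```python
from uactrials.trial_engine import TrialConfig, run_trial

report = run_trial(TrialConfig(seed=1))
print(report.funnel)
print(report.success_tables.query("window == 'toc'"))
print(report.ni)
```

which prints

```
{'screened': 165, 'symptom_eligible': 157, 'enrolled': 134, 'randomized': 134, 'dosed': 132}
    threshold window  n_success  n_total  proportion
        ACSS5    toc        106      132    0.803030
         FDA4    toc        106      132    0.803030
         EMA3    toc        106      132    0.803030
    ACSS5_QOL    toc        106      132    0.803030
DYNAMICS_ONLY    toc         77      132    0.583333
NiResult(risk_difference=-0.0546..., ci=(-0.1888..., 0.0824...), level=0.95,
         method='newcombe', margin=-0.1, conclusion='inconclusive')
```

165 candidates were screened to enroll 134; at test of cure 106 of 132
dosed patients (80.3%) were clinical successes under the five-symptom
threshold, while the patient-global-assessment-only measure is visibly
less sensitive. The non-antibiotic arm had 52/67 successes against
54/65 in the antibiotic arm: a risk difference of −5.5 percentage points
whose lower confidence bound (−18.9%) crosses the −10% margin, so at
this sample size the trial is inconclusive — exactly the kind of
power insight the simulator is for.

The same pipeline is scriptable from the shell:

```bash
uactrials simulate --preset outcome2023 --seed 1 --out-dir sim/
uactrials analyze sim/ --out-dir analysis/
uactrials evaluate-rules --seed 1 --out rule_metrics.csv
```

## Layout

```
src/uactrials/
  acss_model.py    questionnaire model, scoring, CSV I/O
  eligibility.py   symptom + pyuria inclusion rules
  microbiology.py  bacteriuria policies, micro outcome, ABU flag
  outcome.py       visit windows, cure/failure thresholds
  dx_metrics.py    diagnostic-accuracy battery
  ni_analysis.py   risk-difference CIs, NI conclusion, populations
  synth_cohort.py  synthetic diagnostic cohorts and trials
  trial_engine.py  end-to-end orchestration and reporting
  cli.py           command-line verbs
```

See `docs/methods.md` for the modelling assumptions and numerical
choices.
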