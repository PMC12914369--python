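# Methods

This note documents the models, rules and numerical choices behind
`uactrials`, and what the synthetic-data generator does and does not
emulate.

## Questionnaire model

Each ACSS administration stores the six Typical, four Differential and
three QoL items as ordinal severities in {0, 1, 2, 3}, five dichotomous
Additional flags, and — on the follow-up form (Part B) only — a Dynamics
item describing the overall evolution of symptoms. The Dynamics scale is
not fixed by the published description of the instrument; we encode it
as an ordinal 0 (fully recovered) … 4 (worse), isolated in one place so
a different anchoring can be swapped in. Item order within the Typical
domain is fixed (frequency, urgency, dysuria, suprapubic pain,
incomplete emptying, visible blood) and the CSV dialect carries explicit
column names so order mistakes are detectable.

Missing scored items are not imputed: eligibility and outcome thresholds
are defined on complete summary scores, so a record with any missing
scored item is invalid for scoring and `validate_response` returns the
full list of violations instead of raising.

## Eligibility

The default inclusion rule is: ACSS6 summary score ≥ 6, at least one
symptom more than mild (severity ≥ 2), and pyuria ≥ 10 WBC/mm³. All
threshold comparisons are inclusive. Two deliberately optional switches:

* `mild_blood_qualifies` (default off) lets mild visible blood satisfy
  the more-than-mild requirement. Mild hematuria does discriminate
  cases from controls, but it is reported as evidence, not as a stated
  inclusion criterion, so the default rule excludes it.
* `exclude_differential` (default off) blocks eligibility when any
  differential-domain item is ≥ 2; no published cut-off exists, so the
  domain is carried but not acted on by default.

## Outcome thresholds and visit windows

Cure under the five-symptom threshold is: summary ≤ 5, every item ≤ 1,
no visible blood. Note the summary clause is mathematically implied by
the per-item cap (five items ≤ 1 sum to ≤ 5); the tests verify this
redundancy exhaustively for the 3-, 4- and 5-item variants, and the
clause is kept for fidelity to the stated definition. Rescue therapy is
always failure. A response that meets all symptom criteria but shows
visible blood is adjudicated *not* cured **and** raises a separate
per-visit hematuria flag: persistent visible blood may have a source
other than the infection, so the flag routes the patient to
differential-diagnostic follow-up regardless of status. The QoL-augmented
threshold requires additionally every QoL item ≤ 1 (the published cut is
not stated; this is a config value), and the dynamics-only measure
counts only the top recovery level as success — included for
comparability, not recommended.

Visit windows: early = days 2–4 and end of treatment = days 5–9 after
treatment start; test of cure = 5–7 days after end of treatment; late
follow-up = days 24–33 after start. With very short treatment courses
the windows can overlap; a day matching several windows resolves to the
later-stage label because later visits are analytically primary.

## Microbiology

Significance policies are total functions from (species, CFU/mL) to a
boolean, monotone in CFU for every species. The species-aware policy
takes *E. coli* at any count, never counts enterococci or group B
streptococci, and applies 10³ CFU/mL to other recognized uropathogens —
that last threshold is configuration, since no enumeration of "other"
pathogens with counts is published. The low-count policy uses the lower
bound (10¹ CFU/mL) of the published 10¹–10² range for *E. coli* and
*S. saprophyticus* so that it is the most sensitive policy of the set.
Species matching for persistence/new-infection classification is at the
normalised species-label level; no strain typing is modelled.

## Diagnostic metrics

For a binary rule the ROC "curve" has one interior operating point, so
AUC = (sens + spec)/2; for score-valued rules the Mann-Whitney rank
estimator (ties half) is used, verified against an all-pairs brute-force
oracle to 10⁻¹². "Correlation with positive outcome" is implemented as
the phi coefficient, which for binary-binary data equals the
point-biserial/Pearson correlation. Likelihood ratios and DOR optionally
use a Haldane 0.5-per-cell correction when any cell is zero; proportion
metrics always use raw counts, and metrics with empty denominators are
reported as undefined (`None`) rather than raising. CIs: Wilson score
for proportions, log-scale normal for LR/DOR.

## Non-inferiority analysis

The risk difference (test − reference) at test of cure is interval-
estimated with the Newcombe hybrid Wilson-score method by default
(well-behaved near boundary proportions); Wald and the score method are
selectable. Non-inferiority requires the lower bound strictly above the
margin (default −0.10); a bound exactly at the margin is inconclusive —
the conservative reading. The five outcome thresholds are not
multiplicity-adjusted: one threshold (ACSS5) is pre-specified primary
and the rest are descriptive. Population members without a
test-of-cure adjudication are counted as failures in the primary
analysis (ITT-conservative); the generator rarely produces such
patients, but file-based inputs can.

Analysis populations are nested: ITT (all randomized) ⊇ clinical ITT
(dosed and baseline-symptomatic) ⊇ microbiological ITT (additionally
culture-positive under the chosen policy). Making the last filter
explicit lets users *count* how many symptomatic patients a strict
10⁵ CFU/mL policy would discard.

## Synthetic-data generator

The generator emulates two study designs, not their data (the source
datasets are unavailable; published summary tables exist only as figure
images, so no cell values are targeted).

**Diagnostic cohort** (preset `study2019`: 285 cases, 232 controls).
Severities are drawn independently per item from status-specific
categorical distributions: cases skew moderate/severe on the first five
symptoms while visible blood is present in a minority and mostly mild;
controls skew absent/mild with visible blood rare at any severity. WBC
is log-normal — cases exp(N(3.55, 1.2²)), median ≈ 35 cells/mm³,
pyuria-positive ≈ 0.85 at the 10/mm³ cut; controls exp(N(1.43, 1.5²)),
median ≈ 4, pyuria-positive ≈ 0.28 — chosen once so that pyuria alone
operates near the sensitivity-high / specificity-modest regime reported
for real cohorts, and so that adding the pyuria conjunct to a symptom
rule trades sensitivity for specificity as observed. Cultures are
mixed-species (E. coli-dominant in cases) with log-uniform CFU over
10¹–10⁸; 20% of cases and 70% of controls are culture-sterile.

**Trial** (preset `outcome2023`: 134 enrolled, 67 per arm). Candidates
are drawn from the case profile, screened against the default inclusion
rule (the screening funnel is recorded), and randomized by permuted
blocks of 4. Each dosed patient carries a latent resolved/unresolved
state per window, Bernoulli in the arm's per-window success probability.
Defaults are plausible mid-range values — antibiotic arm
0.55/0.80/0.85/0.80 across early/EOT/TOC/late, non-antibiotic arm
0.45/0.72/0.78/0.75, rescue probabilities 0.04/0.10 — deliberately *not*
presented as estimates of any published trial. Unresolved patients at
the early visit may take rescue therapy, which forces the unresolved
state (and failure) at all later visits. At TOC, clinical successes
carry significant bacteriuria (ABU) with probability 0.25; relapse at
late follow-up is stratified by ABU status with ABU set mildly
protective (0.08–0.10 with ABU vs 0.18–0.20 without), reflecting the
hypothesis the sub-analysis exists to test. Severity vectors are drawn
from state-specific distributions; with the default separation the
resolved state is always cure-compatible and the unresolved state is
almost always failure-compatible, so adjudicated success proportions
track the latent probabilities closely, and exactly when degenerate
distributions are used (as the recovery harness does).

**What the generator does not emulate.** Item severities are independent
within a response (no symptom correlation structure; an optional latent
mixing would be needed to stress-test that), visit attendance is
complete, cultures are single-isolate, and species do not change
within a patient except through the explicit new-infection channel.
Passing tests therefore demonstrate that the *pipeline* — scoring,
rules, adjudication, intervals — behaves correctly under controlled
conditions, not that any particular real-world success rate is
reproduced.

## Problem sizes and tolerances

Exhaustive enumerations run over 4⁵/4⁴/4³ = 1024/256/64 severity
vectors. The interval-coverage check uses 2,000 simulated trials of
200 patients per arm at a true success probability of 0.8 in both arms
(nominal 95% coverage accepted within 93–97%). The parameter-recovery
check uses 500 replicates of 100-patient trials and requires agreement
within 3 Monte-Carlo standard errors. Severity-marginal calibration is
tested by χ² goodness-of-fit at α = 0.01 on a 10,000-subject cohort
(one expected false alarm per hundred runs; the test is seeded). The
AUC estimator must agree with the brute-force oracle to 10⁻¹²; metric
identities (J = se + sp − 1, DOR = LR⁺/LR⁻) are exact whenever defined.
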