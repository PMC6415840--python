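# Methods

## Scoring model

The instrument is scored from dual-rater responses in four stages.

**Reconciliation.** For each of the 28 Section A questions the parent and
investigator responses (yes/no/unsure) are resolved to one final response:
agreement keeps the shared value; *unsure* is recorded only when both raters
are unsure; when exactly one rater is unsure the definite answer stands
without invoking precedence (precedence is defined for discrepancies between
two definite answers, and a lone *unsure* is not a discrepancy in that
sense); a definite yes-versus-no conflict is settled by the rater named in
the question's `precedence` field. Enumerating the nine rater-pair states
shows *unsure* survives reconciliation exactly once (the both-unsure cell);
the test suite asserts this for both precedence settings.

**Abnormality.** Each question carries a polarity (`abnormal_response`,
either yes or no). A final response is abnormal iff it equals the polarity;
*unsure* is never abnormal and contributes 0 to the total score. This is
the conservative reading: abnormality is defined only for definite
responses, so residual uncertainty cannot inflate a child's score.

**Subdomain flags and diagnosis.** A subdomain is abnormal when at least
`abnormal_min_count` of its questions are abnormal; the default is 1 for
every subdomain (any abnormal question flags it). The published description
fixes the question counts (8/4/3/7/1/1/4) but not within-subdomain
thresholds; the single-question subdomains A2b and A2c force a threshold of
1, and a uniform default is the least surprising extension. The threshold
is stored per subdomain in the instrument definition so holders of the full
printed form can set the true rules. The diagnosis is structural: ASD
positive ⟺ all three A1 subdomains abnormal ∧ at least 2 of the 4 A2
subdomains abnormal ∧ both mandatory Section B items. The companion count
of criteria met (abnormal subdomains plus satisfied B items, 0–9) is
reported but is not the decision variable: "7 of 9 criteria" is implied by
a positive structural call, but not every 7-subset satisfies the structural
rule, so the structural rule is primary. Exhaustive enumeration of all
2⁷ × 2² combinations in the tests confirms both the equivalence with the
structural rule and the ≥7 implication.

**Severity.** The 0–28 total score is banded at the three published
cutoffs, each read as score ≥ cutoff: ≥10 ASD, ≥11 moderate, ≥14 severe
(the ≥14 cutoff corresponds to CARS > 36.5). The band *labels*
(`below_threshold` / `asd_mild` / `asd_moderate` / `asd_severe`) are a
reporting convention of this package: the source analyses give three
overlapping cutoffs but never name non-overlapping bands, and a per-child
report needs a partition. Cutoffs are overridable (`SeverityCutoffs`,
`--cutoffs`). The band is a function of the total score alone; the
structural diagnosis is reported beside it rather than folded into it,
since score cutoffs and the structural rule are two distinct
operationalizations that can disagree for individual children.

**Missing data.** A child with a missing or duplicate answer, or without a
Section B record, is a hard error naming the child and question ids. The
instrument is administered in full; partial records indicate a data-entry
fault, and silent imputation would bias the score downward.

## Default instrument definition

The shipped YAML carries placeholder prompts and uniform per-question
polarity (`abnormal_response: no`) and precedence (`investigator`). The
published main text does not disclose item-level polarity or precedence
(they live on the printed form), so an explicit, visible, user-editable
default was preferred to a silent guess. Scoring depends only on
structure, polarity and precedence, never on prompt text.

## Validation statistics

- **Accuracy measures.** Sensitivity TP/(TP+FN), specificity TN/(TN+FP),
  PPV TP/(TP+FP), NPV TN/(TN+FN), each with an exact Clopper–Pearson
  interval from beta quantiles: lower = B(α/2; x, n−x+1) (0 when x = 0),
  upper = B(1−α/2; x+1, n−x) (1 when x = n). The exact method reproduces
  all eight published interval bounds for the validation 2×2 at two
  decimals, which identifies it as the method behind those tables. Display
  rounding is half-up: two decimals for accuracy percentages, one decimal
  for cross-tab row percentages, matching the printed precision.
- **ROC.** Positivity is score ≥ cutoff (every published cutoff is phrased
  as ≥). One operating point per distinct observed score plus a sentinel
  above the maximum; AUC by the trapezoidal rule, which equals the
  tie-corrected pairwise concordance probability (asserted against an
  O(n²) oracle in the tests). The Youden cutoff maximizes J = TPR − FPR
  with ties broken toward the smallest cutoff, which favours sensitivity —
  the appropriate bias for a case-finding instrument.
- **CARS banding.** <30 non-autistic, 30–36.5 mild-moderate, >36.5 severe;
  scores outside the plausible 15–60 instrument range are banded with a
  warning rather than rejected. Severity-ROC comparisons (e.g. ≥14 versus
  CARS > 36.5) are caller-composable from `roc_curve` with any reference
  labelling, since the published comparison population for the moderate and
  severe analyses is not stated.
- **Reliability.** Cohen's κ is unweighted (the pilot agreement outcome is
  binary, so weighting is moot) and undefined when both raters are constant
  (chance agreement 1). Cronbach's α uses sample (ddof = 1) variances and
  reports per-item leave-one-out alphas. Pearson's r delegates to
  scipy.stats.

## Synthetic cohort generative model

Each child draws, from its own deterministic substream of the root seed
(`numpy` `SeedSequence.spawn`, so a child's content is independent of cohort
size and iteration order):

1. latent ASD class ~ Bernoulli(prevalence), default 0.569 (128/225);
2. CARS band ~ class-conditional categorical — (0.086, 0.289, 0.625) within
   the ASD class, (0.979, 0.021, 0) outside — with the score uniform inside
   the band's range (non-autistic [15, 30), mild-moderate [30, 36.5],
   severe (36.5, 60]); uniform-within-band is the minimal assumption
   consistent with reporting only band counts;
3. per-question latent abnormality ~ Bernoulli with one probability per
   subdomain per class (defaults 0.55 within the ASD class and 0.12
   outside, giving mean total scores near 15 and 3 — consistent with the
   instrument's 10/11/14 cutoff geometry — while leaving class overlap so
   validation statistics are non-trivial), optionally logit-shifted by
   `severity_slope × (CARS − 36.5)` within the ASD class (slope 0 by
   default: the true score–severity coupling is not identifiable from the
   published marginals and is only needed when exercising severity-cutoff
   behaviour);
4. the latent abnormality maps through the question's polarity to a true
   response; each rater independently reports it, replaced by *unsure* with
   probability 0.03 or flipped with probability 0.05 (plausible magnitudes
   for a piloted structured interview with trained raters; the pilot κ of
   0.95 bounds disagreement as rare);
5. Section B items ~ class-conditional Bernoulli (defaults 0.98/0.98 within
   the ASD class; 0.60/0.50 outside, reflecting that most non-ASD children
   in a referred cohort are developmentally delayed);
6. a developmental-quotient band ~ the full-cohort categorical
   (0.511, 0.284, 0.147, 0.036, 0.009, 0.013), generated for report parity
   only — scoring never reads it.

**What the simulator does and does not emulate.** It reproduces the study's
marginal structure (size, prevalence, band mixtures, DQ mix) and the
mechanics of dual-rater item response, so it can exercise every pipeline
stage and support parameter-recovery tests: with noise off, the
class-conditional probability of a positive call factorises over subdomains
and is computed exactly by enumeration (`analytic_call_probability`), and
simulated cohorts recover it within binomial error. It is *not* a clinical
model of autism symptomatology: items are conditionally independent given
class (no question-level correlation beyond class and optional severity
coupling), there are no age or sex effects and no missing data, and the
default parameters are not calibrated to reproduce the real cohort's
measured accuracy, AUC, κ, α or score–CARS correlation — those were
measured on real children and cannot be pinned down from published
marginals. Passing tests therefore demonstrate correctness of the scoring
and statistical machinery, not field performance of the instrument.

## Numerical choices

- Exact interval bounds via `scipy.special.betaincinv`; cross-checked in
  tests against statsmodels' beta-method interval and a direct
  binomial-tail root search.
- Half-up decimal rounding (`floor(x·10^d + 0.5)/10^d`) for displayed
  percentages, avoiding banker's-rounding surprises at .5 boundaries.
- Degenerate inputs raise typed errors rather than returning NaN: empty
  2×2, zero denominators, single-class ROC labels, constant raters, zero
  total-score variance, out-of-range total scores.
- Empty CARS bands render NaN percentages and are written blank in CSV;
  children without a CARS score are excluded from the cross-tab with a
  logged count.

## Test problem sizes

Simulation-backed tests use cohorts of 120–225 children for pipeline
checks, 5,000 for parameter recovery against the enumerated call
probability (3-SE binomial bands), and 20,000 for marginal recovery;
interval coverage uses 2,000 replicates per (p, n) cell. These sizes put
Monte-Carlo error well inside the asserted tolerances while keeping the
default suite fast.

## Known limitations

- Item-level polarity, precedence and within-subdomain thresholds ship as
  uniform defaults; faithful scoring of real records requires editing the
  instrument YAML from the printed form.
- The replication path for the study's deposited per-child spreadsheet is
  limited to the documented CSV interface: export the sheet to the
  response/Section-B/covariates layout and run `score`/`validate`.
- Cronbach's α here treats item scores as continuous; no IRT or
  tetrachoric refinement is attempted.
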