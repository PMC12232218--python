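# Methods

## The measurement procedure

`gccm` measures goal-concordant care (GCC) at the level of *epochs*:
intervals between consecutive documented goals-of-care (GOC) discussions.
The procedure assumes

1. a closed four-category taxonomy (comfort-focused, maintain/improve
   function, life extension, unclear) shared by goals and care received;
2. day-granularity calendar dates — discussions, admissions and deaths
   are dated but not timed;
3. dual independent review of care received per epoch, reconciled by
   consensus and, failing that, adjudication;
4. epochs treated as independent units in the association analyses (no
   within-patient correlation adjustment), a deliberate replication of
   common practice in chart-review studies; the limitation is noted below.

### Interval conventions

All intervals are half-open `[start, end)`. A discussion takes effect the
day it is documented: it ends the previous epoch and opens the next one
on its own date. Follow-up ends at `min(admission + followup_days,
death + 1 day)`, so the death day itself belongs to the final epoch and
"care at the time of death" is the final epoch's concordance class.
"Six months" is fixed at 180 days for both follow-up and baseline
lookback; calendar-month arithmetic would make epoch lengths depend on
the admission month. Both windows are configurable (`FollowupWindow`).

Degenerate cases are resolved to keep the no-zero-length-epoch invariant:

- a discussion dated exactly on admission governs epoch 0 (source
  `DISCUSSION`) rather than opening a zero-length epoch;
- a discussion dated on the follow-up end is ignored;
- several discussions on one date collapse to a single boundary whose
  label is the last *clear* category of that day, else unclear — the
  "most recent governs" convention extended to ties;
- a discussion documented on the day of death still opens the final
  (1-day) epoch, because the window extends one day past death.

Patients lost to follow-up are carried to 180 days by default
(`censor_at_ltfu=False`); censoring at last contact is available as a
flag because either handling is defensible and neither changes the other
conventions.

### Concordance classification

With a discussion present, concordance is a pure function of the two
labels: equal clear labels → concordant; unequal clear labels →
discordant; either label unclear → uncertain, recording `GOC_UNCLEAR`
and/or `CARE_UNCLEAR` non-exclusively. An epoch with no governing
discussion (source `NONE`) is uncertain with reason `NO_GOC_DISCUSSION`
regardless of the care label; this includes a first epoch whose baseline
lookback found nothing even when later discussions exist. Reasons are
non-exclusive because an epoch can be unclear on both axes at once;
reason counts may therefore exceed the number of uncertain epochs.

### Reliability

Interrater reliability pools all reviewer pairs into one 4×4 confusion
matrix (reviewer roles fixed lexicographically by reviewer id, which
makes the matrix orientation deterministic; κ is transpose-invariant
anyway). κ is unweighted; its standard error uses the asymptotic
(non-null) variance of Fleiss, Cohen & Everitt (1969) and the Wald
interval is truncated to [−1, 1]. The variance estimator was chosen for
being the standard large-sample form; other estimators would give
slightly different interval widths without changing κ itself.
Confidence-band analyses assign an epoch to the low band when the
*minimum* of its two reviewers' confidences is ≤ 2 (a conservative rule;
mean-based banding is available). A band that is empty — or whose pairs
all fall in one category for both reviewers, leaving κ undefined — is
reported as absent.

### Association statistics

- **Pearson χ²** on 2×2 tables, expected counts from marginal products,
  **no continuity correction** (a Yates-corrected variant exists behind a
  flag), p from the upper tail of χ²(1). Tables with a zero marginal
  raise and are routed to the Fisher test.
- **Fisher exact**, two-sided by the small-p summation rule: the sum of
  hypergeometric probabilities no larger than the observed table's. The
  enumeration runs on exact integer numerators, so ties are decided
  exactly rather than with a floating-point fudge factor.
- **Bivariable logistic regression** via maximum likelihood
  (statsmodels `Logit`); for a binary predictor the fitted odds ratio
  equals ad/bc, which the tests assert as a closed-form consistency
  check. A zero cell is reported as non-estimable with a separation flag
  rather than as a numerical blow-up.
- p-values are reported unadjusted at α = 0.05 per test; the report
  output says so explicitly. Journal-style formatting (3 dp, `<.001`)
  applies to the printed report only, never to stored values.

## The synthetic-cohort generator

`SimConfig`/`simulate_cohort` emulate a seriously ill inpatient cohort:
admissions spread over a four-month enrollment window, two mortality-risk
strata, death for a configurable fraction during follow-up, GOC
discussions arriving at heavy-tailed intervals, and two blinded reviewers
reading each epoch. Defaults are calibrated to published cohort-level
marginal statistics:

| parameter | default | calibration target |
|---|---|---|
| `n_patients` | 109 | cohort size |
| `p_very_high_risk` | 0.5 | even stratification across risk strata |
| `p_any_discussion` | 0.76 | 76% of patients with ≥1 documented discussion |
| `p_baseline_discussion` | 0.45 | 45% with a prehospital baseline discussion |
| `p_death` | 0.46 | 46% died during follow-up |
| discussion count | 1 + NegBin(r=3.0, p=0.30) | epochs/patient median 3 (IQR 2–5) |
| inter-discussion gap | log-normal, median 7 d, σ=3.0 | epoch duration median 7 d |
| `care_category_probs` | 0.18/0.32/0.46/0.04 | care mix ≈ 18/32/46/4% (comfort/function/life-extension/unclear) |
| `reviewer_confusion` | 0.975 diagonal | expected raw agreement ≈ 0.95, κ ≈ 0.92 |
| `confidence_probs` | median 4 | reviewer confidence median 4 (IQR 3–5) |
| `concordance_coupling` | 0.55 | ≈50% of epochs concordant |

Calibration notes made once and not revisited:

- The published epoch-duration IQR (2–115 d) is strongly asymmetric
  around its median of 7 d on the log scale, so no log-normal can match
  the median and both quartiles simultaneously; σ = 3.0 reproduces the
  quartile *ratio*. Sub-day draws are rounded up to 1 day.
- The realized epochs-per-patient lower quartile is 1 rather than 2
  because the ~24% of patients with no discussion contribute single
  epochs; the median (3) and upper quartile (5) match.
- The care label copies the governing goals label with probability
  `concordance_coupling` *only when the goals label is clear*; epochs
  with unclear or absent goals draw care from `care_category_probs`
  directly. Coupling to an unclear goals label would copy "unclear" into
  the care labels and push the unclear-care share far above its
  calibrated 4%.
- Death times follow a truncated log-normal (median 45 d, σ = 1.0) over
  (0, 180]; the source material reports no death-time distribution, so
  this is a generic right-skewed choice.
- Reviewer confidence is independent of correctness by default;
  `confidence_error_coupling=True` ties wrong labels to confidences 1–2
  for exercising the per-band reliability analysis.

Each patient draws from `default_rng([seed, patient_index])`, so growing
the cohort never perturbs earlier patients, and identical seeds give
bit-identical cohorts. Disagreeing reviewer pairs get a consensus label
(the true label) with probability 0.9, else an adjudicator label,
emitted in a `resolutions` table the pipeline consumes.

**What passing tests do and do not show.** The generator reproduces the
marginal structure the pipeline relies on (category mixes, agreement
rates, interval geometry) but none of the clinical correlation structure
of real chart-review data: no association between palliative-care
consultation and discussion frequency, no link between nearing death and
comfort-focused goals, no documentation gaps or reviewer drift. Tests
passing on synthetic cohorts validate the measurement machinery, not any
clinical claim about real cohorts.

## Analytic oracles used in testing

For a true-label mix π and row-stochastic reviewer confusion matrix M,
two independent reviewers agree with probability Σ_c π_c Σ_k M[c,k]²,
and the population κ follows from the expected joint table
P(i,j) = Σ_c π_c M[c,i] M[c,j]. Parameter-recovery tests compare realized
statistics on a 2,000-patient cohort against these closed forms within
three Monte-Carlo standard errors (binomial SEs for proportions, the
Fleiss–Cohen–Everitt SE for κ). The Fisher implementation is checked
against a full `Fraction`-arithmetic enumeration over every 2×2 table
with n ≤ 30, and κ against a first-principles p_o/p_e computation and
statsmodels.

## Problem sizes

Unit tests run on cohorts of ≤ 80 patients; the tiling property uses
1,000 simulated patients and parameter recovery 2,000 — sizes at which
the binomial standard errors are small enough for 3-SE bands to be
informative while the whole suite stays fast.

## Known limitations

- Epochs are treated as independent in χ²/Fisher/logistic analyses,
  replicating the measurement framework's own convention; clustered
  standard errors are future work.
- No person-day weighting: concordance proportions count epochs, not
  days, so a 2-day and a 115-day epoch weigh equally.
- Single-goal concordance only; concurrent or contingent goals (e.g.
  function *and* longevity) are collapsed to one label upstream.
- No weighted κ and no >2-rater generalization (Fleiss κ).
- Readmissions do not open epochs; only documented GOC discussions do.
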