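# Methods

## Problem

Health-maintenance-organisation claims record *what was dispensed or
infused on which day*, not "the patient started second-line FOLFIRI".
To study treatment patterns and outcomes in metastatic colorectal cancer
(mCRC) patients receiving first-line bevacizumab, the package reconstructs
per-patient therapy timelines from six claims tables, applies the study's
eligibility rules, and runs standard survival analyses.  Because real
claims are private, a synthetic-cohort generator with known ground truth
stands in for source data everywhere in testing.

## Timeline reconstruction

**Exposure intervals.**  Every record contributes a nominal coverage
window: 1 day per infusion, 30 days per oral dispense (a monthly refill is
the usual pharmacy cadence; actual days-supplied is not in the data, so
the 30-day window is a modelling choice that cannot be verified against
any source field).  Within one patient and agent class, windows whose
uncovered gap is at most `gap_days` (default 30 — the conventional reading
of "a gap of up to a month is tolerated") are merged into half-open
intervals.

**Regimen states.**  The treated span is cut at every interval boundary
and each slice is classified: the chemotherapy backbone is FP when only a
fluoropyrimidine is active, FP-O when oxaliplatin is active, FP-I when
irinotecan (without oxaliplatin) is active; the biologic set is whichever
of bevacizumab/cetuximab/panitumumab are active.  Two degenerate inputs
get deterministic tie-breaks with data-quality warnings: oxaliplatin or
irinotecan without any fluoropyrimidine is classified by the non-FP agent,
and a simultaneous triplet (FP + oxaliplatin + irinotecan) is classified
FP-O.

**Line segmentation.**  A new therapy line starts exactly when

1. a biologic is **omitted or replaced** (the defining set loses a
   member), or
2. the backbone **changes**, except de-escalation — FP-O→FP or FP-I→FP
   with no biologic loss — which stays in the current line, or
3. a treatment-free gap longer than `short_gap_days` (default 30)
   separates two states; if the composition is unchanged across such a gap
   the new line is flagged `resumption` and excluded from
   change-of-therapy semantics.

Design choices where the rules were genuinely open, all encoded in the
transition truth table of the test-suite:

* **Additions never split**: adding a biologic (to an empty or non-empty
  set) extends the line's defining set; "omitting or replacing" are the
  change triggers, and symmetric treatment of additions would make
  FP→FP+bev at line start a spurious change.
* **Chemo-free maintenance continues the line**: backbone dropping to
  `none` under a continuing biologic (e.g. bevacizumab maintenance) is a
  de-escalation, not a change.
* **Re-escalation splits**: FP→FP-O/FP-I starts a new line; the exception
  covers *terminating* agents, not adding them.  Returning to the line's
  own defining backbone after a tolerated gap continues the line.

A brute-force day-resolution implementation of the same rules
(`carelines.oracle`) — per-agent day grids, literal gap filling, a
day-by-day walk — is shipped as an independent cross-check; interval and
day implementations agree on 100% of randomized event histories
(1,000 sets in the validation script).

## Cohort and covariates

Eligibility: bevacizumab in line 1; index date = first bevacizumab
administration, inside the accrual window (2006-09-01..2012-12-31,
configurable); patients alive at the cutoff (2013-12-31) need ≥ 12 months
of follow-up from the index.  Exclusions carry reason codes.

* **Surgery group**: first qualifying claim (liver/lung metastasectomy or
  definitive radiotherapy) on/after the index date; earlier claims are
  ignored with a warning.
* **Regular medication use**: ≥ 4 *distinct calendar months* with a
  purchase of the category inside some window of 12 consecutive calendar
  months, starting no earlier than one year pre-index and ending no later
  than last follow-up ("last follow-up" is read as
  min(death, cutoff, last activity)).  Distinct months, not dispense
  counts — four purchases in one month do not qualify.  The implementation
  is checked against literal enumeration of every 12-month window.
* **Baseline labs**: most recent value per test in the half-open 183-day
  window before the index.
* **Review flag**: alive at last follow-up, no liver-resection billing,
  and a ≥ 15-calendar-month therapy-free gap (after the last line or
  between lines).  The flag is advisory — it never excludes anyone,
  mirroring the manual-review step such studies use.
* **Anti-EGFR exposure**: cetuximab/panitumumab in any line ≥ 2, with a
  companion flag for whether any later line starts after 2008-12-01 (when
  wild-type-KRAS confirmation became mandatory for these agents).

Calendar months are used for eligibility/review thresholds, days for gap
merging; durations convert to months at a fixed 30.44 days/month.

## Endpoints

* **OS**: index date to death; censored at the cutoff, or at last contact
  if earlier.  Death before the index is a data error.
* **DOT**: index date to the earliest of first-line end, surgery date
  (Surgery patients count the pre-surgery portion only), and the cutoff;
  censored only when the cutoff truncates an ongoing line.  The interval
  is additionally capped at the observation end (death or last contact)
  because a trailing oral-dispense coverage window can nominally outlast
  the record; this enforces DOT ≤ OS for every patient.

## Statistics

Kaplan-Meier curves via the product-limit estimator; the median is the
earliest time with survival ≤ 0.5 ("not reached" when the curve stays
above it) and its 95% CI comes from the log-log-transformed curve bounds —
the common convention when no method is stated.  Group comparison by the
log-rank test.  Cox proportional-hazards models use the Efron tie
correction (day-resolution data tie heavily).  Covariate screening fits
one model per covariate adjusted for age and sex — not a joint model —
and refits each stratified by first-line backbone; results are ranked by
p-value.  Subgroup characteristics use one-way ANOVA with Bonferroni
correction (`min(1, p × m)`).  Model fitting is delegated to lifelines and
scipy; this package fixes the conventions and containers.

Lab dichotomisation thresholds (e.g. platelets > 400) live in
`carelines.synthetic_data.LAB_PROFILES`-style config rather than code
constants, since no canonical cut-offs are given for this setting.

## Synthetic cohort: what it emulates, and what it does not

Per patient: independent Bernoulli covariates (medication categories,
comorbidity registries), Gaussian age, exponential OS (Weibull optional)
with the group baseline median scaled by exp(Σ planted log-HRs), an
independent exponential first-line-duration draw (its own log-HRs)
truncated at survival, and a line plan — bevacizumab plus backbone in
line 1 (backbone mix ≈ 0.70/0.30 FP-O/FP-I in the Surgery group and
0.34/0.59/0.07 FP-O/FP-I/FP otherwise), optional bevacizumab-only
maintenance, later lines with switched backbone and optionally an
anti-EGFR biologic, surgery mid-course for ~15% with a post-operative
resumption after a >30-day pause.  Events are emitted on a 14-day infusion
cadence and 30-day oral/non-oncology dispense cadence, truncated at
death/dropout/cutoff.  All draws come from one seeded generator in fixed
patient order, so output is byte-reproducible.

Emission respects three realism constraints that are also what makes the
ground truth recoverable: line ends sit on the infusion grid (treatment
ends with the last administered cycle); an oral refill is only purchased
if its supplied days fit before the stop date; and a biologic *switch*
follows a >month pause (re-staging and KRAS testing precede anti-EGFR
therapy), while backbone switches under a continuing biologic follow a
short, bridgeable gap.  Without these, nominal coverage windows straddle
transitions and create compositions that never clinically happened.

The generator does **not** emulate: dose reductions or schedule density,
realistic code vocabularies, lab time-series dynamics, correlated
covariates (age/comorbidity effects default to zero so planted-HR
recovery is unconfounded), or misclassified/missing records — a separate
`corrupt` operation injects duplicates and post-death events at
controlled rates to exercise the validators.  Passing the recovery tests
therefore shows the rules are implemented and invertible under faithful
claims, not that the pipeline is robust to arbitrarily messy real data.

Note one deliberate asymmetry: the configured `dot_median_months` (11.4)
is the baseline *treatment-stop* hazard's median.  The observed DOT median
in a simulated cohort is substantially lower because death competes and
truncates treatment; in outcome-level simulations used for estimator
checks, death-truncation is treated as independent censoring so the
planted hazard is identifiable.

## Validation problem sizes

The validation script (`scripts/acceptance.py`) uses 1,000 random event
histories for oracle agreement, a 2,000-patient cohort for end-to-end
recovery, 50 replicates of n = 2,000 for Cox CI coverage, 40 replicates of
n = 1,000 (5 null covariates) for the screen's type-I error, n = 5,000
exponential draws for the KM median, and 1,000 random dispense histories
for the regular-use flag — sizes at which the binomial/Monte-Carlo noise
of each check is comfortably below its acceptance margin.

## Known limitations

* Oral supply duration is assumed (30 days), not observed.
* A >1-month gap followed by the same regimen is a flagged resumption
  line; other conventions (continuing the line) exist and would change
  line counts.
* DOT is a treatment-duration proxy; progression-free survival is not
  computable from claims.
* The covariate screen is associational; planted-HR recovery in
  simulation says nothing about confounding in real cohorts (e.g.
  narcotic use proxying performance status).
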