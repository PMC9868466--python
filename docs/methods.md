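# Methods

This note documents the statistical conventions, the generative model
behind the synthetic data, and the design decisions taken where the
underlying protocol left room for interpretation.  All concentrations are
ng/mL; all CVs and biases are percentages.

## Measurement model and censoring

An automated immunoassay reports concentrations only inside its calibrated
range; outside it the analyzer emits `<lower` or `>upper` markers.
`p4valid` keeps such cells as censored measurements and applies an explicit
resolution policy before any statistic is computed:

* `substitute_limit` (default): replace a `<0.2` cell by 0.2.  The
  unspiked matrix pools in this application sit right at the reporting
  limit (daily means 0.2–0.35 ng/mL), so substituting the limit is
  conservative and keeps the control-mean arithmetic close to what a
  laboratory would do by hand when averaging day means that include
  below-limit days.
* `substitute_half_limit`: replace by half the limit (a common convention
  for left-censored environmental data).
* `drop`: remove the cells; a (level, day) group emptied this way is
  recorded as a warning and excluded from day means.

The policy is recorded in the table metadata and in the report, because no
single convention is defensible in all settings.

## Precision

* Within-run CV of a level = unweighted mean over days of 100·s/x̄ of that
  day's replicates.  Averaging over all available days uses all the data;
  a `day` filter reproduces a single-run (day-1-only) protocol.  Days with
  fewer than two uncensored replicates, or a nonpositive mean, are
  excluded with a warning.
* Between-run CV = 100·s/x̄ over the daily means.
* Sample SD (n−1 denominator) everywhere.
* Overall CVs are unweighted means of the per-level CVs over spiked
  levels; the unspiked control is excluded so that the overall value
  describes the reportable range.
* CV trendlines are ordinary least squares of CV% on log10(concentration)
  (`linlog`) or on (c, c²) (`quadratic`), fitted against the spiked
  amounts.  R² is reported; no weighting is applied.

## Recovery

Recovery% = 100·(x̄_level − x̄_control)/spiked and SRB% = Recovery% − 100.
The control mean is the grand mean of the spiked-0 level pooled over all
days (after censoring resolution): the protocol subtracts a single control
value without per-day matching, and pooling is the lowest-variance reading
of that. SRB ≡ Recovery − 100 is asserted as an invariant on every result.

## Detection limits

LOB = x̄_blank + 1.65·s_blank, LOD = x̄_control + 1.65·s_control,
LOQ(level) = x̄_level + 2·s_level.  All means and SDs are taken over the
daily-mean series (between-run dispersion), and each LOQ is reported with
its level's between-run CV.  The 1.65 and 2 multipliers are the protocol's
fixed constants; this is deliberately not the CLSI EP17 percentile
machinery, and no probit fitting or outlier rejection is applied.  A
series with fewer than two usable daily values invalidates only its own
limit.  The LOQ definition (mean + 2 SD rather than a CV-target search) is
unconventional but implemented as specified by the protocol.

## Linearity

OLS of measured level means (y) on spiked concentrations (x), control
excluded.  Constant bias ⇔ intercept p < α; proportional bias ⇔ the 95% CI
of the slope excludes 1 (the slope-vs-0 test is reported but a slope
significantly ≠ 0 says nothing about proportionality).  A paired t-test of
(measured − spiked) against zero is reported without an interpretive
label.  Because regression direction is a recurring ambiguity in method
validation, the reverse fit (spiked on measured) is also reported.
Degenerate exact fits (zero residual variance) yield p = 0 for nonzero
estimates and p = 1 otherwise rather than NaN.

## Passing–Bablok regression

Implemented from the original shifted-median procedure, regressing lab B
(y) on lab A (x):

* pairwise slopes S_ij = (y_j − y_i)/(x_j − x_i), i < j; slopes with
  x_i = x_j (undefined) and slopes exactly −1 are excluded before ranking;
* K = #{S_ij < −1}; slope = the K-offset median of the sorted slopes
  (mean of the two middle offset entries for an even count);
* CI: w = z_{1−α/2}·√(n(n−1)(2n+5)/18), M1 = round-half-up((N − w)/2),
  M2 = N − M1 + 1, bounds at ranks M1+K and M2+K.  The round-half-up
  convention for M1 is stated because implementations differ here;
* intercept = median(y − slope·x), CI endpoints from the slope CI bounds
  (upper slope bound gives the lower intercept endpoint);
* constant bias ⇔ 0 outside the intercept CI; proportional bias ⇔ 1
  outside the slope CI.

At n ≤ 4 and α = 0.05 the CI ranks fall outside 1..N; the default is a
hard error advising more pairs, `require_ci=False` returns the point
estimates with CIs/flags set to None.  The estimator is validated against
an independent pure-Python exhaustive-enumeration oracle for all n ≤ 8.

## Bland–Altman agreement

Differences are lab A minus lab B (A is the minuend), absolute or as a
percentage of the pair mean — the pair mean, not the reference laboratory,
is the denominator, matching the standard percentage-difference plot.
LoA = d̄ ± 1.96·s_d exactly (the protocol's formula), while the CIs use
finite-sample t quantiles: d̄ ± t_{0.975,n−1}·s_d/√n for the mean and
LoA ± t_{0.975,n−1}·s_d·√(3/n) for each limit.  Mixing the fixed 1.96
LoA factor with t-based CIs is intentional: it reproduces the protocol's
printed limits yet gives honest interval estimates.  The
proportional-error slope is the OLS slope of d on the pair means with its
two-sided p-value.

## Concentration bins and the range-based bias

Samples are sorted by pair mean (ties broken by sample id) and split into
contiguous, equal-as-possible bins, larger bins first (40 samples, 5 bins
→ 5×8).  Each bin's range-based bias is the mean of its members'
percentage differences.  A spiking level takes the bias of the bin whose
pair-mean range contains its spiked amount; if none does, the bin with the
nearest range midpoint.  The published group ranges this emulates overlap
in print (and carry an inconsistent unit label); the implementation uses
strictly contiguous sorted bins instead.

## Observed total error

TEo% = 2·CV% + |bias%|.  Signs of biases are preserved in all tables for
directional reporting; the absolute value is taken only inside the TEo
formula.  TEo_SR and TEo_RB pair each level's within-run CV with the
spiking-recovery and range-based bias respectively; TEo_AB applies the
overall Bland–Altman mean percentage bias at every level.  (In the
published table the average-based column follows the stated formula only
at the lowest level; rows above it equal 2·CV alone.  The implementation
follows the stated formula throughout.)  For QC materials TEo uses the
between-run CV with bias = 100·|x̄ − nominal|/nominal, since day-to-day
stability is what QC monitors — this convention, not the within-run one,
reproduces the published QC total errors.  No allowable-total-error (TEa)
verdicts are produced: no TEa consensus exists for veterinary
endocrinology, so TEo is reported as a guide only.

## Synthetic-data generator

`simulate_spike_panel` draws

  measured(level, day, rep) = truth · g_day · (1 + e),
  truth = (baseline + spiked) · r(baseline + spiked),

with one shared mean-one lognormal day effect g_day per day (relative SD
`sd_between_day`), replicate noise e ~ N(0, (CV%(truth)/100)²), and
censored emission outside the reporting range [0.2, 40].  Noise is
multiplicative because the instrument's dispersion is CV-parameterized;
additive noise would make CV% rise with concentration, the wrong
direction.  Day effects are shared across levels within a day because
between-run variation is a run-level shift.

Default parameters (the plasma study conditions):

| parameter | default | meaning |
|---|---|---|
| baseline_mean | 0.30 | endogenous matrix P4 (daily pool means 0.28–0.35) |
| baseline_sd | 0.03 | pool-to-pool spread, one draw per panel |
| cv_intercept, cv_slope | 8.9, −1.7 | CV% = 8.9 − 1.7·log10 c (fitted plasma trendline) |
| cv_min | 0.5 | floor keeping CV positive at high c |
| srb_intercept, srb_slope | −20.7, 3.3 | SRB% = −20.7 + 3.3·log10 c, so r(c) = 1 + SRB/100 |
| sd_between_day | 0.05 | chosen so the between-run CV of 5-replicate day means, √(5²+CV²_w/5), tracks the fitted between-run plasma trendline (7.5 − 1.5·log10 c) at mid-range concentrations |
| reporting limits | 0.2 / 40 | the assay's calibrated range |

A level whose true concentration is exactly zero (blank-like) is emitted
fully censored rather than erroring; negative truths, nonpositive recovery
factors and nonpositive drawn baselines are hard errors.

`simulate_paired_comparison` draws truths from a log-uniform law on
0.3–28 ng/mL (the biological range of the comparison samples), lab A
measures the truth with proportional noise, lab B applies the systematic
line b = intercept + slope·a before its noise (defaults slope 1.09,
intercept 0.05, 5% CV per lab).  Passing–Bablok regresses B on A, so the
injected slope is what the fit recovers.

`simulate_qc_panel` applies the same noise structure to the nominal QC
targets but, by default, not the matrix recovery loss: commercial QC
materials are assay-matched, and imposing the plasma recovery profile
would fabricate a ~20% bias where real QC panels show a few percent.
`apply_recovery=True` restores the matrix behaviour.

What the generator does **not** emulate: antibody cross-reactivity,
hemolysis/lipemia interference, carry-over, calibration drift within a
lot, and heteroscedastic day effects.  Passing tests on synthetic panels
therefore demonstrate that the statistics recover the parameters of this
error model under the study design (5 days × 5 replicates, n = 40 pairs),
not that the physical instrument meets any specification.

## Numerical choices and degenerate inputs

* Report rounding is half-to-even (banker's) at 1 decimal by default,
  applied via decimal arithmetic on the shortest float representation.
* Zero-variance inputs are exact: identical replicates give CV = 0; an
  identical paired series gives bias 0 with LoA (0, 0) and a
  proportional-error p of 1.
* Monte-Carlo test tolerances (±1.5 CV points over 200 panels, ±0.03 on
  the median Passing–Bablok slope over 500 datasets of n = 40) allow for
  the small-sample bias of the sample CV (E[s] ≈ 0.94·σ at n = 5); problem
  sizes were chosen as the smallest that hold those tolerances stably
  across seeds.

## Known limitations

* Passing–Bablok CIs use the analytic rank approximation only (no
  bootstrap), and no Deming regression is offered.
* The linearity stage fits level means, not individual replicates, so its
  p-values inherit the 5-point design's low power.
* Left-censored statistics are substitution-based; no maximum-likelihood
  censored estimators are provided.
* Plot output is diagnostic, not publication-grade.
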