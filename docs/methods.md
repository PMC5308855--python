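# Methods

## The analysis

`pvscreen` implements the standard disproportionality workflow for
spontaneous adverse-event reporting databases of the JADER/FAERS family.
The raw material is three linked tables — demographics (one row per case),
drugs (one row per reported drug, with the reporter-assigned involvement
category *suspected / concomitant / interaction* and the administration
route) and reactions (one row per reported adverse-event term).  The
pipeline:

1. drops exact duplicate rows from each table (a duplicate is a row
   identical on **all** fields of its table; a key subset is configurable),
2. inner-joins the tables on the case identifier into the *all-data table*
   (one record per case x drug x event combination; drug or event rows with
   no demographics entry are orphans, dropped with a logged count by
   default),
3. optionally maps route-specific registered drug names to canonical generic
   names via a user-supplied synonym table, and
4. restricts to records whose involvement is *suspected* — the conventional
   denominator of a disproportionality screen.

For one exposure E (a drug, a sex, a route) and one event V, units of the
table are cross-tabulated as a = E&V, b = E&not-V, c = not-E&V,
d = not-E&not-V, and summarized by

* the **reporting odds ratio** ROR = ad/bc,
* its **Woolf (log-normal) 95% interval**
  exp(ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d)) — the standard ROR interval
  in pharmacovigilance; undefined when any cell is zero unless the optional
  Haldane–Anscombe +0.5 correction is enabled (off by default, since screens
  conventionally report only exposures with events),
* the **two-sided Fisher exact test** under the minimum-likelihood
  definition: the sum of hypergeometric probabilities, over tables sharing
  the observed margins, that do not exceed the observed table's probability
  (relative tolerance 1 + 1e-7).  A zero margin makes the observed table the
  only table, so P = 1.  `scipy.stats.fisher_exact` implements exactly this
  definition; the test suite verifies it against an independent
  integer-arithmetic enumeration oracle on every 2x2 table with total <= 60.

An exposure is a **signal** when the lower 95% confidence limit of its ROR
strictly exceeds 1.  Screens are plotted as volcanoes, x = ln ROR and
y = −log10 P, with the red baseline at y = −log10 0.05 ≈ 1.301 and point
colour encoding the number of event reports.  The ROR measures
disproportionate *reporting*, not risk; it approximates an odds ratio of the
event process only insofar as the reporting process is exposure-neutral, and
it is numerically close to a rate ratio only for events that are rare among
reports.

By default the drug screen counts **records** of the suspected-medicine
table (matching the convention in which the table size, not the case count,
is the denominator N); case-level counting — a case is exposed if *any* of
its records names the drug — is available via `unit="case"` and is the
better-defined estimand when cases carry several drugs.  Raw P values are
reported with a 0.05 significance line and no multiplicity adjustment, the
field's convention for these screens; Benjamini–Hochberg adjusted columns
are available as a clearly marked extension.

## Patient background and trend

Sex is compared between event and non-event units with the Fisher exact
test.  Age/height/weight arrive as decade or range codes ("50s",
"160-169"); they are decoded to numbers by the leading integer (the range's
lower bound, matching the treat-codes-as-absolute-numbers convention; a
midpoint option exists) and compared with a two-sided t test.  **Welch's
unequal-variance test is the default** — group spreads of the two groups
differ materially in this kind of data and the pooled test is available as
an option.  All comparisons use only non-missing values and report the n
actually analyzed.

The yearly trend is the Spearman rank correlation between reporting year and
the event's yearly share of reports (raw counts optional), with the
t-approximation P value (average ranks for ties); an exact permutation P is
available for up to 10 years.  An all-tied series is reported as rho = 0,
P = 1 rather than undefined.

## Multivariate adjustment

Drugs passing the univariate screen (Fisher P < 0.05 **and** more than
`min_reports = 3` event reports) enter, with the four patient covariates
(male indicator, decoded age/height/weight), a multiple logistic regression
on complete cases (listwise deletion).  The default analysis unit is one row
per **case** — demographics are case-level, and drug indicators aggregate
over the case's suspected records; record-level rows are available via
config.  Before fitting, every predictor pair is screened with
pairwise-complete Spearman rho²; pairs above 0.9 are flagged as internally
correlated.

The fit is authored in-package: iteratively reweighted least squares with
step halving, so the log-likelihood is non-decreasing across iterations;
convergence at relative log-likelihood change < 1e-8 (100 iterations max,
non-convergence raises).  Inference is Wald — z-based two-sided P values and
confidence intervals on the log-odds scale, exponentiated to odds ratios.
Wald intervals become very wide under near-separation (rare events with
sparse indicators); that behaviour is expected, and a Firth bias-reduced
penalized fit is available behind a flag.  Complete separation is detected
before the fit (a binary column that perfectly predicts the response) and
quasi-complete separation during it (a diverging coefficient of a binary
column with a zero event cell); both raise an error naming the separating
term rather than returning silently absurd estimates.  The implementation is
cross-checked against `statsmodels.Logit` in the test suite, and the
single-binary-covariate fit reproduces ad/bc to 1e-6 relative.

## Stratified analyses

**Routes.**  For each administration route of a target drug, the 2x2 is the
drug's records given by that route against the *remainder of the whole
suspected-medicine table*, tested with the two-sided Fisher exact test.
This construction keeps every route's comparator identical, makes per-route
counts additive to the drug's total row, and is the construction under which
published route tables of this design reproduce exactly.

**Co-treatment.**  Among unique event cases (deduplicated by case identifier
alone), each case is classified by (any record of the target drug?) x (any
record of a configurable drug-class list?).  This uses the **all-data**
table — suspected, concomitant and interaction records alike — because
co-medications are mostly recorded as concomitant and a suspected-only table
systematically misses them (a property the test suite demonstrates).
Summary percentages are rounded half-up to whole percent.

## The synthetic generator

`SyntheticSpec` draws databases with the structural features the pipeline
must survive: one-to-many case links, involvement labels, routes, exact-copy
duplicated rows (a fraction of drug/event rows re-emitted), MCAR missing
demographics, and a rare target event.  The event indicator follows a
logistic model

    logit P(event) = logit(background_rate) + Σ_j 1[drug_j]·ln(multiplier_j)
                     + 1[male]·male_log_odds + (height−160)·height_log_odds_per_cm

so each drug's `event_odds_multiplier` is a planted conditional odds ratio.

Default conditions (chosen once, as the study conditions of the test-bed):
50,000 cases; background event rate 0.01 — large enough that a desk-scale
database yields a usable event count, while preserving the rare-event regime
in which ROR ≈ OR; male fraction 0.5 with male_log_odds = ln 4 (emulating
the strong male dominance of intractable-hiccup reporting); missingness
fractions sex 0.02, age 0.04, height 0.53, weight 0.45 (the magnitudes seen
in real suspected-medicine tables of this family); reporting years
2004–2015; duplicate fraction 0.05.  Planted signal drugs default to
all-suspected involvement — when a drug actually drives the event, the
reporter marks it suspected — while null drugs in the demo spec carry mixed
involvement distributions.

What the generator does **not** emulate: correlated co-prescription
structure, notoriety/competition reporting biases, informative missingness,
within-case repeated reports over time.  Passing recovery tests therefore
show the estimators are correct under exposure-neutral reporting, not that
real-database signals are unconfounded.

**Non-collapsibility.**  The marginal ROR of a drug equals its planted
conditional multiplier only when no other strong risk factors vary in the
population.  Recovery and null-calibration experiments therefore plant
male_log_odds = 0, so the screen's estimand is the planted value itself;
when a sex effect is planted, the covariate-adjusted logistic fit is the
estimator that recovers the multiplier, and the marginal screen is
(correctly) attenuated.  This is a property of odds ratios, not an
implementation artifact.

## Numerical choices and degenerate inputs

* Fisher P with a zero margin: 1 by convention (the table is modal).
* ROR with a = 0: 0.  ROR with b = 0 or c = 0: undefined (NaN), never an
  exception; undefined CI ⇒ never a signal.
* Screen result ordering: (P, −ROR, label), so repeated runs are
  byte-identical.
* Percent rounding: half away from zero to whole percent.
* IRLS: start at the empirical-logit intercept, at most 40 step halvings per
  iteration, Wald covariance from the observed information at the optimum.
* Exact Spearman permutation enumeration is batched (200k permutations per
  block) and limited to 10 points.

## Problem sizes used in the checks

Published-table replays run at their printed sizes (972,220 records).
Property suites run at: 635,375 tables for the exhaustive Fisher-oracle
sweep (every 2x2 with total ≤ 60); 1,500 simulated tables for Woolf
coverage; 500 simulated datasets of n = 2,000 for logistic Wald coverage;
20 synthetic databases of 50,000 cases for planted-multiplier recovery; 100
databases of 10,000 cases for null calibration.
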