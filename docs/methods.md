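# Methods

`registrend` implements the inferential chain used for histology- and
stage-specific cancer-incidence trend analysis on population-based registry
data: restricted multiple imputation of incompletely coded histology and
stage, direct age standardization with gamma confidence intervals, Rubin
pooling across imputations, joinpoint (segmented log-linear) trend
selection with permutation tests, female-to-male incidence-rate-ratio
series, and a survival-based diagnostic for the imputation itself.  Because
registry extracts of this kind are not publicly deposited, the package
ships a synthetic-registry generator whose statistical structure matches
what the analysis assumes; every downstream stage is tested against that
generator's known truth.

## Synthetic registry

The generator covers 3 prefectures x 23 diagnosis years (1993-2015) x
2 sexes x 18 five-year age bands (0-4 ... 85+; the band scheme is a
configuration default following common Japanese vital-statistics practice).
Stratum case counts are Poisson with mean `rate x person-years / 1e5`,
which matches the Poisson variance model used for the standardized rates
downstream.  The rate surface factorizes into a per-sex age schedule
(lung-cancer-like: negligible under 40, rising to ~650/100,000 at 85+ for
men, female rates ~42% of male), a per-sex histology mixture that is
softmax-linear in calendar year, and optional piecewise log-linear trend
multipliers per (sex, histology) used to inject known joinpoints
(`inject_joinpoint_trend`; slopes are APC-like percentages, b = ln(1 +
APC/100)).

Each case carries a true histology group — small-cell (SMC), squamous
(SQC), adenocarcinoma (ADC), large-cell (LAC), other non-small-cell, or
other/unspecified — and a true SEER summary stage
(localized/regional/distant) drawn from a softmax model with
histology-specific intercepts, a calendar-time stage-shift term (localized
rising, regional falling) and a linear age term.  Survival is exponential
with stage x histology hazards (defaults 0.08/0.35/1.2 per year for
localized/regional/distant, scaled by histology), administratively censored
in 2017; a small declining fraction of cases are death-certificate-only
registrations with zero follow-up.  Prefecture-year quality covariates
(DCN%, DCO%, MV%) are the empirical flag rates; the Gini coefficient is a
fixed per-prefecture value with a slight drift, a stand-in for an external
socioeconomic series.

**Missingness.**  Two logistic missing-at-random models mask histology and
stage.  Stage masking depends on sex, age 80+, prefecture, calendar year
(declining, echoing improving registration), and treatment; masked stages
are labelled "unknown" or "missing" with a 0.57/0.43 split and pooled as
one absent state for imputation.  Histology masking replaces the morphology
code with a nonspecific code — 8010 (carcinoma NOS; candidate set = the
five specific-carcinoma groups) or 8046 (non-small-cell carcinoma;
additionally excludes SMC) with a 0.88/0.12 split.  The intended code is
drawn *first* and masking only goes through when the true group lies in
that code's candidate set.  This ordering matters: it makes the observed
code uninformative about the true group beyond the candidate restriction
("MAR given the restriction"), which is exactly the assumption under which
the restricted imputer below is unbiased.  If instead the code were chosen
after masking (with true-SMC cases forced to 8010), the code would carry
extra information and recovery would be systematically biased by ~0.1pp.
Model intercepts are solved numerically so the expected masking fractions
equal the calibration targets — 11.0% nonspecific histology and 23.6%
unconfirmed stage, the shares observed in the motivating registry data.

A truth table with the pre-masking values is returned separately from the
registry files so downstream code cannot accidentally peek.

**What the generator does not emulate**: real ICD-O code frequencies beyond
the six-group resolution, within-band population age structure, migration
or population change over time, non-exponential survival, and any
missingness depending on unobserved clinical severity.  Passing tests
therefore demonstrate correctness of the *method* under its stated
assumptions, not robustness to every violation real data may present.

## Recoding and tabulation

Morphology codes map to the six histology groups via an editable CSV
lookup; 8010/8046 carry candidate sets instead of a group.  Only these two
codes are treated as missing histology.  Raw stage strings normalize to
localized/regional/distant; "Unknown" and empty fields become absent with
their kind retained for tabulation.  Tabulations count cases by sex x
diagnosis period (defaults 1993-1999, 2000-2004, 2005-2009, 2010-2015,
closed on both ends) with row percentages computed on exact counts and
rounded to one decimal for display only.  A packaged fixture of
published-style counts (62,870 cases) exercises the arithmetic end to end.

## Restricted multiple imputation

Fully conditional specification with two chained conditionals: baseline-
category multinomial logistic models for stage given covariates + current
histology, and histology given covariates + current stage.  Covariates:
prefecture, diagnosis year (linear by default; categorical periods
switchable), age (linear, plus an 80+ indicator because masking is elevated
there), sex, screening, four treatment flags, log observation time, vital
status, DCN%, DCO%, MV%, Gini.  Absent values initialize from observed
marginal frequencies (restricted), then `n_cycles` sweeps (default 10;
scaled runs in the tests use 2, which already forgets the initialization
in this generator) refit each conditional on its originally-observed rows
and redraw the absent values.  The default m is 20 imputations from
independent named RNG substreams.

**The restriction amendment** zeroes the predicted probabilities of
disallowed categories and renormalizes before drawing, so a draw outside
the candidate set is impossible by construction.  The alternative reading —
refitting a separate conditional per candidate set — is available as
`restriction_mode="refit"`; both modes give indistinguishable marginal
recovery on the default scenario, so the simpler renormalization (which
uses all observed rows for estimation) is the default.

Draws come from the fitted predictive distribution without posterior
perturbation of the coefficients.  This is a deliberate simplification of
proper multiple imputation: with ~50,000 observed rows the coefficient
uncertainty is negligible next to the categorical draw noise, and the
package's guarantees target point-estimate recovery and the pooling
algebra.  It understates between-imputation variance very slightly; noted
as a limitation.

Model fitting uses scikit-learn's unpenalized multinomial
`LogisticRegression` (lbfgs, tol 1e-4, warm-started across sweeps and
imputations — warm starts change only the convergence path of a convex
MLE).  An intercept-only specification returns exact observed frequencies.
A statsmodels `MNLogit` fit serves as an independent cross-check in the
test suite.

**Rubin's rules** (`rubin_pool`): point estimate = arithmetic mean of the m
estimates; total variance T = W + (1 + 1/m)B with W the mean
within-imputation variance and B the between-imputation sample variance;
degrees of freedom (m-1)(1 + W/((1+1/m)B))^2, infinite (and flagged) when
B = 0.

## Rates

The age-standardized incidence rate is `1e5 * sum_a w_a d_a / n_a` per
100,000 person-years with Poisson variance `1e10 * sum_a w_a^2 d_a /
n_a^2`; weights come from a standard population (the bundled table is the
smooth 1985 Japanese model population over 18 bands; any CSV of band
weights can be substituted, and the math is weight-agnostic).  Confidence
intervals use the gamma method: the lower bound matches the rate's first
two moments to a gamma quantile; the upper bound adds a continuity
adjustment to both moments — the *mean* of the per-band w_a/n_a ratios
(Tiwari's modification, the default) or the *maximum* (the original
construction), behind a flag.  Zero-case strata contribute zero to rate and
variance and pin the lower bound at 0.

Per-year rates are computed on each completed dataset, pooled with Rubin's
rules, and the gamma interval is then applied with the pooled total
variance T in place of the single-sample variance — the only composition
that uses both the pooling and the gamma interval.  A complete-case series
(records with the stratifying variables observed) is always emitted
alongside for sensitivity comparison; imputation only adds cases, so the
pooled series dominates the complete-case series pointwise.

Female-to-male incidence rate ratios are pooled-rate ratios with log-scale
delta-method intervals, `exp(ln IRR +/- z sqrt(T_f/R_f^2 + T_m/R_m^2))`,
computed after pooling (the alternative — per-imputation ratios pooled
afterwards — differs only at second order and is not implemented).

## Joinpoint regression

Annual rate series are fitted on the log scale with a continuous piecewise-
linear basis, weighted least squares with weights 1/SE(ln rate)^2 (SE(ln r)
= SE(r)/r), errors treated as uncorrelated.  Joinpoint locations are found
by exhaustive grid search over data years with at least three observations
from any joinpoint to either end of the series and between consecutive
joinpoints; SSE ties break toward the earliest location vector.  Years with
zero rates are offset by half the smallest positive rate before logging and
flagged.

The number of joinpoints is selected sequentially: H0: k = k0 vs H1:
k = k_max, permuting the standardized (weighted-scale) residuals of the H0
fit, refitting both models per permutation (grid search included) and
comparing F ratios; p = (1 + #{F* >= F}) / (1 + n_perm), each test at level
alpha/(k_max - k0).  The reference Monte Carlo size is 4,500 permutations;
the test suite and acceptance script use 999, and k_max defaults to 1 for
23-point series (fitted registry models of this kind show at most one
joinpoint; 3 is supported).

APC_i = 100(e^{b_i} - 1) with t-based intervals on the residual degrees of
freedom.  The AAPC over a period is the segment-length-weighted slope
average transformed the same way; its variance comes from the WLS
covariance of the slopes with joinpoint locations treated as fixed (the
interval therefore ignores location uncertainty, as is conventional), and
normal quantiles are used because the composite spans segments with
differing df.  For a 0-joinpoint fit AAPC equals APC exactly.

## Validation diagnostics

Within strata of diagnosis period x sex x stage x histology, the follow-up
of fully observed cases is compared against cases imputed into the stratum
using the Kaplan-Meier log-rank test (lifelines).  A case joins the imputed
arm if any analysis value was masked; its stratum labels are the
majority-vote completion across the m imputations (a per-imputation pooled
variant would also be defensible; majority vote is stable and
reproducible).  Strata with fewer than 10 cases in either arm are skipped
and counted.  The summary statistic is the fraction of tested strata with
p < 0.05; raw p-values are reported alongside Benjamini-Hochberg-adjusted
ones.

Calibration of this diagnostic requires care: even under covariate-driven
masking, cases imputed *into* a stratum are a mixture over true categories,
so if survival depends on the imputed variable the arms differ slightly and
the rejection fraction sits above the nominal level.  The package's null
calibration scenario therefore uses masking independent of survival *and*
hazards that do not depend on stage or histology, under which the rejection
fraction is nominal (~5%).  A misuse scenario whose stage masking depends
on the true stage itself (missing not at random) pushes the rejection
fraction well above 20%, demonstrating that the diagnostic detects invalid
imputation.  A second, smaller source of excess rejection is intrinsic to
the diagnostic: the imputation model uses follow-up time and vital status
as predictors (as it should), so assignment *into* a stratum is mildly
correlated with survival, and the imputed arm can differ slightly from the
observed arm even under a correct model.  At the scales used here this
adds a few points above the nominal level at moderate n; it shrinks as the
conditional model concentrates.

Missingness screening uses Pearson chi-square tests for categorical
covariates (with a Fisher fallback for sparse 2x2 tables) and
Kruskal-Wallis rank-sum tests for continuous ones, against each missingness
indicator.

## Problem sizes and numerical choices

Scaled study sizes used by the tests and the acceptance script: ~50,000
cases for imputation-scale checks (m = 20, 2 sweeps), ~30,000 for the
acceptance pipeline run, 10,000 Poisson replicates for gamma-interval
coverage, 999 permutations and k_max = 1 for joinpoint selection, m = 5 for
the survival-validation scenarios.  All randomness flows from a single seed
through named substreams (`_rng.substream`), so reruns are byte-identical
and changing one stage's settings does not perturb another's draws.

Known limitations: no posterior draws in the imputer (slightly understated
B); no imputation of covariates; no autocorrelated-error or
jump joinpoint variants; FM-IRR intervals pooled-first only; the survival
diagnostic's majority-vote arm assignment is one of several defensible
conventions.
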