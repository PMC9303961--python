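# registrend

Histology- and stage-specific cancer-incidence trend analysis for
population-based registries whose records carry incompletely coded
histology (nonspecific ICD-O morphology codes 8010 and 8046) and
unknown/missing SEER summary stage.  The package is aimed at cancer
epidemiologists and registry statisticians who need the full inferential
chain — not just one piece of it — reproducible from a single seed:

1. **Restricted multiple imputation** (`registrend.imputation`): fully
   conditional specification with multinomial logistic conditionals for
   stage and histology.  The nonspecific codes restrict the imputable
   categories (8010: the five specific carcinoma groups; 8046: the four
   non-small-cell groups); the imputer zeroes disallowed categories'
   predicted probabilities and renormalizes before drawing, so a draw
   outside the candidate set is impossible.  Default m = 20 imputations.
2. **Age-standardized incidence rates** (`registrend.rates`):
   ASIR = 10^5 Σ_a w_a d_a / n_a per 100,000 person-years with Poisson
   variance 10^10 Σ_a w_a² d_a / n_a², pooled across imputations by
   Rubin's rules (point = mean; total variance T = W + (1 + 1/m)B) and
   wrapped in gamma confidence intervals (Fay–Feuer construction with
   Tiwari's mean-adjustment upper bound).
3. **Joinpoint regression** (`registrend.joinpoint`): continuous piecewise
   log-linear fits by exhaustive 1-year grid search under the 3-3-3 rule,
   Monte Carlo permutation tests to choose the number of joinpoints,
   APC_i = 100(e^{b_i} − 1) per segment and the segment-length-weighted
   AAPC with delta-method intervals.
4. **Female-to-male incidence rate ratios** with log-scale intervals, and
   **survival-based imputation validation**: stratified Kaplan–Meier
   log-rank comparison of observed vs imputed cases plus χ²/Kruskal–Wallis
   missingness screening (`registrend.validation`).

Real registry extracts of this kind are not publicly deposited, so
`registrend.synthetic` generates a registry with the same statistical
skeleton — 3 prefectures × 1993–2015 × 2 sexes × 18 age bands, Poisson
case counts, MAR masking calibrated to ~11% nonspecific histology and
~23.6% unconfirmed stage, injectable joinpoint trends, exponential
survival — and returns a separate truth table so every stage of the
pipeline is testable against known ground truth.  `registrend.fixtures`
additionally packages a published-style descriptive count table (62,870
cases) for checking the tabulation arithmetic exactly.

## Worked example

The numbered drivers under `analysis/` run a scaled study (~30,000 cases,
m = 20) end to end:

```bash
python analysis/01_simulate.py
python analysis/02_tabulate.py
python analysis/03_impute.py
python analysis/04_rates.py
python analysis/05_trends.py
python analysis/06_validate.py
```

Output from a run with the default seed:

```
generated 29740 cases over 2484 strata
  nonspecific histology: 11.2%
  unconfirmed stage:     23.9%
...
imputed 3339 histology and 7111 stage values x 20 imputations; restriction violations: 0
  histology_group: worst pooled-marginal error 0.09pp vs truth
  stage: worst pooled-marginal error 0.22pp vs truth
...
male localized                 AAPC 3.2 (2.8 to 3.7)  (k=0)
male regional                  AAPC -2.8 (-3.3 to -2.3)  (k=0)
male ADC                       AAPC 1.5 (1.1 to 1.9)  (k=1)
female localized               AAPC 2.6 (1.9 to 3.3)  (k=0)
```

Reading this: the imputer filled every masked value without ever leaving a
record's candidate set, and the pooled category shares land within a
quarter of a percentage point of the generator's truth.  The joinpoint
stage reads the injected stage shift back out of the pooled rates — the
localized series grows at about 3% per year while the regional series
declines, and the male adenocarcinoma series is the one stratum where a
joinpoint is selected (k=1).  The AAPC strings are printed as
"x.x (lo to hi)", the display convention used for trend tables;
full-precision CSVs land in `results/analysis/`.

A `registrend` console command exposes the same stages as subcommands
(`generate`, `recode`, `tabulate`, `impute`, `trends`, `run-all`,
`fixtures`) for shell use.

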