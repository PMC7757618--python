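# Methods

## Scope and data flow

The package estimates the burden of clinical iodine deficiency
disorders (IDDs) and the benefit of universal salt iodization by
comparing a goiter-survey-era baseline (nominally 1993) with a
urinary-iodine-era endpoint (nominally 2019). Input is country-level:
demographics (population and live births, thousands), iodine indicators
(total goiter rate TGR in %, and/or median urinary iodine concentration
MUIC in µg/L), and economic covariates (GNI per capita in USD, wage
share, labor-force participation, healthy life expectancy HALE).
Country products flow upward to the six WHO regions and the globe.

No external database ships with the package. Users supply CSVs (UTF-8,
comma-separated, mandatory header; invalid rows are reported with row
number and reason, never silently dropped), or use the synthetic
generator. Region membership is configuration (a YAML mapping), since
published regional summaries state only counts per region. A small set
of regional summary rows for both eras is bundled in
`iddburden.datasets` and used as fixed inputs for the global headline
accounting; see "Limitations" for why those cells cannot be recomputed
from first principles.

## Dose–response model

TGR = α · MUIC^β, estimated by unweighted ordinary least squares of
ln TGR on ln MUIC. Unweighted, because paired national survey points
carry no usable size information; no confidence band is placed on the
conversion. Diagnostics are reported on the log scale, where the model
is linear: R², the residual standard error with n − 2 degrees of
freedom, and the standard error of β. At n = 2 the line interpolates
exactly and the diagnostics are set to their exact values (R² = 1,
residual SD = 0) rather than the indeterminate 0/0 forms.

The packaged reference model is α = 11 049, β = −1.63, estimated from
24 countries with contemporaneous school-age TGR and MUIC surveys.
Predictions are clipped to [0, 100] because TGR is a prevalence; below
the cap the curve is strictly decreasing in MUIC for β < 0. Population
iodine status is classified from MUIC as deficient (< 100 µg/L),
optimal (100–299 µg/L) or above optimal (> 299 µg/L); thresholds are
configurable.

## Burden accounting

Cases (thousands) = denominator (thousands) × TGR / 100, computed at
country level at full precision and rounded only for display. Aggregate
rates are recomputed as 100 · Σcases / Σdenominator — never by
averaging or by multiplying a rounded regional rate back out, which
gives visibly different numbers (the aggregation-order effect).

The *doing-nothing* counterfactual pairs baseline goiter rates with a
later-era denominator. Because baseline and endpoint surveillance cover
different country sets, three join policies are implemented and logged:

* `endpoint-denominators` (default for population): baseline TGR ×
  endpoint population per matched country; unmatched baseline countries
  fall back to their baseline denominator and are flagged;
* `baseline-denominators` (default for births): the counterfactual is
  evaluated over the baseline country set with baseline-era cohorts —
  the convention implied by published newborn accounting, whose
  counterfactual birth cohort exceeds the endpoint cohort;
* `strict`: intersection only; an empty intersection is an error.

When a record carries both indicators, the endpoint burden uses the
modeled (MUIC-derived) TGR by default so both eras sit on one
comparable scale; `prefer_measured_tgr` switches this. Negative
prevented cases (a country that worsened) are reported, never clipped.

## Economics

NPV loss ('000 USD) = newborns ('000) × participation × annual income ×
deficit × annuity factor. Annual income is GNI per capita × wage share.
The deficit fraction defaults to the published chain value 0.0612; the
literal product of its three coefficients (8.18 × 1.18 × 0.64) / 100 =
0.0618 is exposed via `derive_deficit_fraction` for sensitivity
analysis. Participation applies as a single scalar on the cohort, not
year by year.

Discounting is discrete annual at rate r (default 0.03). A cohort born
in the reference year (2019) enters work `delay` = 11 years later and
works W = HALE − 15 years, so the annuity factor is
Σ_{t=delay}^{delay+⌈W⌉−1} (1+r)^{−t} with a fractional final year
prorated; equivalently (1/r)·((1+r)^{−(delay−1)} − (1+r)^{−(delay−1+W)})
for whole W. Losses accrue at the end of each working year by default;
a payments-at-start variant (one year earlier throughout) is available
on `EconParams`. At r = 0 the factor equals W exactly; it is strictly
decreasing in r and delay and increasing in W.

## Synthetic data generator

The generator emulates what the analysis assumes and nothing more:

* survey points: MUIC ~ log-normal(µ, σ); TGR = α·MUIC^β·exp(ε),
  ε ~ N(0, sd²) with sd = 0.3 by default (n = 24 points, matching the
  size of the reference fitting set);
* baseline tables: goiter rates ~ N(13, 5²) clipped to [0.5, 60] %
  (the clip moves the mean by < 0.05 points), era-scaled denominators;
* endpoint tables: log-normal MUIC plus uniform economic covariates.
  Covariates are independent uniforms — the analysis treats them as
  exogenous constants, so no correlation structure is claimed.

Streams are seeded per table (survey / countries / baseline /
endpoint), so regenerating or resizing one table never perturbs
another's draws. Two packaged calibrations exist. `paper_like_config`
places the endpoint MUIC at median ≈ 172 µg/L with log-sd 0.4 so the
*expected* modeled endpoint prevalence is ≈ 3.1% against a 13%
baseline, i.e. a construction prevented-case fraction of
1 − E[TGR_end]/E[TGR_base] ≈ 0.76 (the log-normal mean correction
exp(β²σ²/2) is included; see `expected_prevented_fraction`).
`status_survey_config` places the median at ≈ 154 µg/L so ≈ 14% of
countries fall below the 100 µg/L deficiency threshold, the proportion
seen in current global scorecards. A single log-normal cannot satisfy
both calibrations at once — matching the deficient-country share drags
the heavy-tailed mean prevalence above 3% — hence two named configs
rather than one compromise.

What passing tests on synthetic data do *not* show: real country tables
have correlated covariates, regionally clustered iodine status,
survey-timing heterogeneity, and goiter of non-iodine etiology; none of
these are modeled, so synthetic recovery demonstrates the correctness
of the estimation chain, not the accuracy of any real-world figure.

Default problem sizes (139 countries, 24 survey points, 100 replicate
fits for coverage checks) mirror the surveillance setting the package
addresses and keep every example and test interactive.

## Numerical choices

* Validation is fail-fast per stage: each operation declares the fields
  it needs and errors with the offending record and stage name.
* CSV writes use `%.10g` formatting, lossless for values with ≤ 6
  significant digits; row order is (region, country_id), so identical
  tables produce byte-identical files.
* Zero denominators yield a 0% aggregate rate rather than NaN.
* Prevalence reductions are defined as 0 when the counterfactual burden
  is 0.

## Limitations

* The bundled regional rows are rounded to the nearest thousand; totals
  recomputed from them can differ from published totals by a few
  thousand cases (e.g. prevented cases 720 185 vs 720 186), and the
  recomputed global reduction is 76.2% where the published table rounds
  its own path to 75.9%.
* The per-region NPV rows are carried as inputs: the implied
  deficit × annuity per region spans more than a factor of two, so no
  single discounting convention reproduces them from their printed
  columns — the per-region work-life inputs behind them are not public.
* The published deficit chain (6.12%) differs from the literal product
  of its stated coefficients (6.18%); the default keeps the published
  value so totals line up, and the derivation is exposed.
* All goiter is attributed to iodine deficiency; no age/sex
  stratification, no program-cost side, no uncertainty intervals.
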