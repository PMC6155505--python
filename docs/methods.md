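# Methods

## The measure

`mvindex` implements the Alkire–Foster (AF) dual cut-off counting
methodology for a multidimensional *vulnerability* index over female
sex worker (FSW) survey data. The measure is the adjusted headcount
ratio (the M0 member of the AF family):

1. **First cut-off (per indicator).** Each of 16 survey-derived
   conditions is dichotomised so that 1 marks the vulnerable state
   (e.g. age < 25, street solicitation, more than two dependents on the
   respondent's income, no insurance, no ration card, no membership in
   a community organization). The indicators sit in four dimensions —
   personal attributes (4), financial security (5), social protection
   (4), social support & network (3).
2. **Weights.** Equal nested weighting: each dimension carries 1/4 and
   splits it evenly among its indicators, so w_j ∈ {1/16, 1/20, 1/12}.
   Weights are exact rationals and sum to 1.
3. **Second cut-off (across indicators).** The weighted deprivation
   score c_i = Σ_j w_j x_ij identifies respondent i as
   multidimensionally vulnerable when c_i ≥ k, default k = 1/3;
   c_i ≥ 1/2 marks severe vulnerability.
4. **Aggregation.** H = q/n is the vulnerable headcount ratio, A the
   mean score among the identified, and MVI = H·A. Censoring zeroes
   the scores (and deprivations) of the non-identified, which gives
   the two identities the implementation and its tests lean on:
   MVI = H·A = Σ_j w_j·CH_j, where CH_j is the censored headcount —
   the share of the *whole* population both identified and deprived
   in j. Indicator contributions are φ_j = w_j·CH_j / MVI (summing to
   1); dimension contributions sum the member φ_j.

Only the adjusted-headcount member is implemented; poverty-gap style
extensions (M1/M2) need cardinal data the binary indicators cannot
supply and are out of scope.

### Numerical choices

- **Exact identification.** With rational weights, ties between c_i
  and k are real, not pathological: e.g. the whole personal-attributes
  block plus one network indicator gives c = 4/16 + 1/12 = 1/3 exactly.
  Scores are therefore accumulated as integers over the common
  denominator of the weights and cut-offs (240 for the default tree
  with k = 1/3) and identification is an integer comparison. The
  comparison is ≥ by default and configurable to >; the severe rule is
  fixed at ≥ ("50% or more"). The published text says "above" the
  threshold for k but defines severe with "or more"; ≥ everywhere is
  the internally consistent reading and matches common AF practice.
- **q = 0.** When nobody is identified, A is defined as 0 so that
  MVI = 0 (the natural limit) instead of 0/0. Contributions are then
  undefined and reported as empty with a log note.
- **Rounding.** All arithmetic is full double precision; rounding
  (3 decimals for index values, 1 for percentages, half away from
  zero) happens only in the reporting layer. The printed identities of
  the source tables hold only to ~1 unit in the last printed digit
  because their inputs are themselves rounded; the engine's internal
  identities hold to 1e-12.
- **Two headcount normalisations.** Published decomposition tables are
  ambiguous between CH_j (share of everyone) and CH_j/H (share of the
  identified); arithmetically the printed columns behave as CH_j
  (they reproduce the index under Σ w_j·CH_j). Both quantities are
  computed and labelled unambiguously (`censored_headcount_pct` vs
  `pct_deprived_among_vulnerable`), leaving no room for the confusion.

## Indicator derivation

`indicators.derive_indicators` maps raw survey fields to the 16
indicators; `derive_outcomes` maps response items to 8 binary
HIV-related risk outcomes (inconsistent condom use — anything short of
"always" with both regular and occasional clients; inability to
negotiate condom use; anal sex; any of three STI symptoms; current
alcohol use; no STI check-up; fewer than three HIV tests in two years;
no family planning method). Literal readings adopted where the source
wording leaves room:

- "More than two dependents" → `n_dependents > 2`, the respondent not
  counted among her own dependents.
- The mobility indicator is the OR of high mobility (frequency levels
  declared high in config; default `monthly_or_more`) and not being a
  native of the district of work.
- Missing raw fields propagate to missing indicator values under
  Kleene (three-valued) logic, so a composite already determined by a
  non-missing operand stays determined. The default downstream policy
  is complete-case: rows missing any indicator input are excluded from
  aggregation (the count is logged), and each regression is
  complete-case for its own outcome. A configurable alternative
  recodes missing indicator inputs as non-vulnerable.

## Threshold robustness

`robustness.mvi_by_threshold` reruns the full aggregation per stratum
over a k-grid (default {0.25, 0.33, 0.40, 0.50}) and compares stratum
rankings across grid points with the Kendall tau-b rank correlation
(tie-corrected; computed on the metric values directly, so no arbitrary
rank-assignment convention is needed). A constant value list makes
tau-b undefined; such cells are reported missing. The qualitative
notion of a "consistent pattern" is operationalised as every pairwise
tau-b ≥ 0.9 (configurable) — a reproducible rule standing in for a
judgment call.

## Association analysis

For each outcome, a maximum-likelihood logistic regression (statsmodels
`Logit`, Newton iterations, convergence at max coefficient change
< 1e-8 within 100 iterations) with vulnerability status as exposure,
adjusted for duration in sex work (continuous, untransformed),
education (reference: no formal education), marital status (reference:
currently married) and state (reference: first level alphabetically);
references are configurable. AOR = exp(β) with Wald 95% CI
exp(β ± 1.96·SE) — the standard epidemiological presentation. No survey
weights or clustering adjustments are applied; the analysis is
unweighted throughout. Rank-deficient designs, perfect separation and
non-convergence raise a `FitFailure` with a diagnostic rather than
returning a number.

## Synthetic data generator

The real microdata are not deposited, so `simulate` generates
populations with the statistical structure the analysis assumes:

- **Scale and strata.** n = 4098 respondents, four strata (Andhra
  Pradesh & Telangana counted as one sampling domain, Karnataka, Tamil
  Nadu, Maharashtra) at equal shares by largest-remainder
  apportionment — the per-state sample sizes were not published.
- **Indicators.** Latent Gaussian threshold (Gaussian copula) model:
  z ~ N(0, R), x_j = 1 iff z_j > Φ⁻¹(1 − p_j). The copula decouples
  the marginals p_j (the 16 published national prevalences, applied to
  every stratum because state-specific ones were not published) from
  the dependence R (exchangeable: 0.3 within a dimension, 0.1
  between — a plausible placeholder, not an estimate; the true
  indicator correlations are unpublished). Non-PSD configurations are
  rejected with a pointer to the nearest-PSD fix.
- **Back-construction.** Raw survey fields are reconstructed from each
  drawn indicator (age uniform on 18–24 vs 25–50; one of the three
  true mobility/native combinations chosen uniformly when the
  composite is deprived; etc.), so `derive_indicators` recovers the
  drawn matrix *exactly* — the round-trip contract that makes the
  derivation stage testable end-to-end. Fields not pinned by an
  indicator follow documented defaults (duration ~ Gamma(2, 3.5),
  mean 7 years; 58% formal education; 62%/15%/23% currently/never/
  formerly married), chosen to match the published sample description.
- **Outcomes.** Given vulnerability status at the definition's k, each
  outcome is Bernoulli(expit(α + β·status + γ·covariates)) with
  β = log(OR) from config (defaults: the published adjusted odds
  ratios, 1.17–2.69), small fixed covariate effects, and α set so the
  expected prevalence among the non-vulnerable matches the published
  baseline (mean covariate contribution absorbed into α). Outcome
  response fields (condom-use ordinals, symptom items, test counts) are
  back-constructed the same way.
- **Seeding.** One master seed; per-stage substreams are spawned
  deterministically (`SeedSequence.spawn`), so the same seed yields
  byte-identical records and stages can be regenerated independently.

**What passing tests do and do not show.** The generator reproduces the
marginal prevalences, a plausible dependence structure, the strata and
a logistic outcome layer — not the real joint distribution, real
state-level contrasts (every stratum is drawn from the same law, so
stratum rankings in the synthetic robustness analysis are sampling
noise by construction), item non-response patterns, or any
survey-design effects. Tests passing on synthetic data validate the
machinery (derivation rules, AF identities, decompositions, regression
plumbing) and its statistical calibration, not substantive estimates
for the real population. The published aggregate identities are
checked directly from the printed numbers instead.

## Problem sizes used in the test suite

Unit and property tests run on populations of a few hundred (n = 600
fixture) and on brute-force-checkable micro-problems (n ≤ 8, J ≤ 4).
Calibration and parameter-recovery checks run at the study scale,
n = 4098: 20 seeds for marginal calibration, 200 replicates for
odds-ratio recovery — sizes at which binomial and Wald error bounds
are tight enough to be informative while the suite stays fast.

## Known limitations

- The three-stage sampling design and any design weights are not
  modelled; like the published analysis, everything is unweighted.
- Stratum-specific marginals, real indicator correlations, and the
  published state-level index values cannot be reproduced without the
  microdata; they are out of scope by design.
- Wald intervals can misbehave near separation; such fits are refused
  rather than patched (no Firth correction is provided).
- The robustness verdict threshold (0.9) and the latent correlation
  defaults are normative settings, exposed in config.
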