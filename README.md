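# mvindex

Multidimensional vulnerability analysis for female sex worker (FSW)
survey data, built on the Alkire–Foster (AF) dual cut-off counting
method.

HIV-prevention programs need to know not just *how many* sex workers
are vulnerable but *how intensely* and *through which channels* —
financial insecurity, weak social protection, thin community networks,
or disempowering personal circumstances. `mvindex` turns individual
survey records into a Multidimensional Vulnerability Index (MVI) and
connects vulnerability status to HIV-related risk behaviors. It is
aimed at epidemiologists and program analysts working with
cross-sectional FSW (or similar key-population) survey microdata.

## The measure

Sixteen binary deprivation indicators x_ij sit in four dimensions
(personal attributes, financial security, social protection, social
support & network) with equal nested weights w_j — each dimension
carries 1/4, split evenly inside, so w_j ∈ {1/16, 1/20, 1/12}. With
the weighted deprivation score c_i = Σ_j w_j x_ij and identification
cut-off k (default 1/3):

- **H** = q/n, the share identified as multidimensionally vulnerable
  (c_i ≥ k),
- **A** = mean c_i among the identified (intensity),
- **MVI** = H · A = Σ_j w_j · CH_j, the adjusted headcount, where
  CH_j is the censored headcount (share of everyone both identified
  and deprived in j),
- **φ_j** = w_j · CH_j / MVI, indicator j's contribution to the index.

The pipeline also recomputes the MVI over a grid of thresholds
k ∈ {0.25, 0.33, 0.40, 0.50} and checks ranking stability with the
Kendall tau-b rank correlation, and fits per-outcome logistic
regressions (adjusted odds ratios with 95% Wald CIs) of eight risk
behaviors on vulnerability status, adjusted for duration in sex work,
education, marital status and state.

Because the original microdata are not deposited, the package ships a
Gaussian-copula synthetic survey generator that reproduces the
published national indicator prevalences, the four state strata and a
logistic outcome layer, with raw fields back-constructed so the
derivation stage round-trips exactly. See `docs/methods.md` for the
model details and what synthetic results do and do not show.

## Worked example

Generate a synthetic survey of 4,098 respondents and compute the index
(or equivalently run `python analysis/03_index.py 1`):

```python
from mvindex import IndexDefinition, SyntheticConfig, aggregate, build_matrix, generate_survey

definition = IndexDefinition()                # 4 dimensions, 16 indicators, k = 1/3
survey = generate_survey(SyntheticConfig(seed=1))
matrix = build_matrix(survey.records, definition)
clean, subgroup, dropped = matrix.complete_case_indicators()
result = aggregate(clean, definition, subgroup)
s = result.overall
print(f"H = {s.headcount:.3f}  A = {s.intensity:.3f}  MVI = {s.mvi:.3f}  severe = {s.severe_headcount:.3f}")
```

prints

```
H = 0.542  A = 0.474  MVI = 0.257  severe = 0.190
```

i.e. 54.2% of the synthetic respondents are multidimensionally
vulnerable, those identified are deprived in 47.4% of the weighted
indicators on average, the adjusted headcount is 0.257, and 19.0% are
severely vulnerable (score ≥ 1/2). The decomposition
(`result.overall.dimension_contribution`) attributes 31.6% of the
index to financial security, 25.2% to social support & network, 24.8%
to personal attributes and 18.5% to social protection — financial
insecurity dominating, as its five indicators combine high prevalence
with censored headcounts up to ~51%.

The numbered scripts under `analysis/` run the full narrative
(simulate → derive → index → robustness → associations), writing
tables under `results/`; `mvindex all --simulate --seed 1 --outdir out`
does the same from the shell.

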