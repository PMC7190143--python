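# geoses

A composite **socioeconomic index of geographic context** for health and
social research, built from census-style small-area tabulations.  Health
outcomes track the socioeconomic context of the places people live in;
epidemiologists therefore need a single, comparable per-area measure of
that context.  `geoses` constructs one from count tabulations covering
seven dimensions — education, mobility, poverty, wealth, income,
residential segregation, and material deprivation / access to services —
and ships the validation and spatial diagnostics needed to judge whether
the index is fit for a given study.

## Method

Inputs are per-unit processed variables: expansion-weighted percentages
(e.g. % of people without schooling), weighted means (e.g. mean
household income), and the **Index of Concentration at the Extremes**
for segregation,

```
ICE_i = (P_i − D_i) / T_i ∈ [−1, 1]
```

where `P_i` / `D_i` count people of unit *i* above the 80th / below the
20th percentile of the pooled reference distribution and `T_i` is the
unit's reference population.

The index itself is a staged principal-component construction on the
**correlation matrix** throughout:

1. within each dimension, a PCA keeps the smallest number of components
   reaching ≥ 75 % cumulative explained variance and selects the top
   absolute-loading variable of each;
2. a second PCA pools all selections; its first component brings the
   dimensions together;
3. variables whose |loading| falls below the mean |loading| are pruned
   and the PCA is re-fit once — the refit's first component defines the
   index;
4. unit scores are the projections of z-scored values on those loadings;
5. scores are standardized linearly to [−1, 1], so −1 marks the worst
   and +1 the best socioeconomic context *in the analysed scope*
   (scores are relative: only differences between areas are meaningful).

A +10 shift is applied to all values before analysis for numerical
hygiene; correlation-matrix PCA makes it provably inert, and the test
suite verifies final scores are identical for shifts 0, 10 and 1000.
An explicit orientation step fixes the PCA sign ambiguity so that an
advantage-positive (by default income-type) variable loads positively.

Around the core sit: **Cronbach's alpha** over the retained items
(internal consistency), a correlation matrix against an external
benchmark index plus per-dimension representative variables (construct
validation and interpretation), and an applicability layer — indirect
standardization of stratified event counts into relative risks, OLS of
risk on the index, and **Moran's I** with permutation p-values on the
residuals under Queen-contiguity weights.

A fully seeded synthetic-census generator (one latent SES factor →
binomial counts, lognormal incomes, multinomial extreme-tail counts,
lattice geography, Poisson outcomes) makes every stage testable offline
against known ground truth.

## Worked example

```sh
python examples/01_build_index.py
```

```
step-1 selections per dimension:
  education    -> ['education_v2']
  mobility     -> ['mobility_v1']
  poverty      -> ['poverty_v1']
  wealth       -> ['wealth_v1']
  income       -> ['income_v1']
  segregation  -> ['segregation_v1']
  deprivation  -> ['deprivation_v1']
retained after pruning: ['education_v2', 'segregation_v1']
final loadings:
education_v2      0.707
segregation_v1    0.707
score range: [-1.000, 1.000]
Pearson r(scores, latent SES) = 0.961
```

One variable per dimension survives step 1 (the dimensions are
internally one-dimensional here), pruning keeps the two variables that
load above the mean, and the resulting scores span exactly [−1, 1] while
correlating 0.96 with the latent factor the data were generated from.
`examples/02–04` demonstrate ICE, the validation report (alpha ≈ 0.97 on
this data) and the spatial applicability check (negative risk slope,
non-significant residual Moran's I).

The same workflow is scriptable from a shell:

```sh
geoses simulate --out-dir demo --seed 3
geoses fit --table demo/variables.csv --registry demo/dimensions.yaml \
           --out demo/scores.csv --log-json demo/decisions.json
geoses eval --table demo/variables.csv --registry demo/dimensions.yaml \
            --out demo/report.json
geoses spatial --scores demo/scores.csv --outcome demo/outcome.csv \
               --weights demo/units.gal --seed 7 --out demo/spatial.json
```

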