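# Methods

## The index

The package builds an area-level composite socioeconomic index as the
first principal component of a pruned set of census variables,
standardized to [−1, 1].  The construction assumes that a single latent
dimension of socioeconomic context dominates the shared variance of the
input variables; the staged selection exists to (a) keep each of the
seven themed dimensions represented by its most informative variables
and (b) drop variables that contribute little to the pooled first
component, so the final index needs fewer inputs without changing its
meaning.

All PCAs operate on the correlation matrix, computed explicitly and
eigendecomposed with a direct symmetric solver (`numpy.linalg.eigh`).
This makes every stage deterministic, scale-free (multiplying a variable
by a positive constant cannot change anything downstream) and
location-free (adding a constant to a variable is inert).  The +10
preprocessing shift is therefore mathematically a no-op; it is kept for
fidelity to the published procedure and covered by an invariance test
(shifts 0 / 10 / 1000 give identical scores to 1e-10).

### Stages and their parameters

| parameter | default | meaning |
|---|---|---|
| `shift_constant` | 10 | additive preprocessing shift (inert) |
| `variance_threshold` | 0.75 | per-dimension cumulative explained-variance target |
| `prune_rule` | `below_mean_abs` | prune variables with \|loading\| below the mean \|loading\| |
| `iterate_prune` | false | single prune/refit pass |
| `orientation_reference` | `auto` | variable forced to load positively |

*Step 1.* Within a dimension, `k` is the smallest number of components
whose cumulative explained-variance ratio reaches the threshold; the
variable with the largest absolute loading on each of the `k` components
is selected (set semantics: a variable topping two components counts
once).  Single-variable dimensions pass through.

*Step 3 pruning.* The implemented reading removes variables whose
absolute first-component loading is below the mean of absolute loadings,
then re-fits once.  A signed-mean alternative (`below_mean_signed`)
exists because the rule's published phrasing admits both readings; the
absolute reading matches the intent of the stepwise-PCA literature the
procedure descends from.  An optional iterated variant repeats the
prune/refit cycle to convergence; the default is one pass.

*Orientation.* Eigenvector signs are arbitrary, so the pipeline fixes
them explicitly: the reference variable's loading is made positive.
`auto` prefers an advantage-positive (+1 polarity) income-dimension
variable among the retained set, then any +1-polarity variable in
registry order.  Polarity metadata is *never* used to pre-flip data
columns — variables enter as measured, which is why disadvantage-coded
representatives legitimately show negative correlations with the index.

*Scores.* Raw score = Σ loading_v · z_v per unit, using the final PCA's
means and standard deviations; standardized score = affine map of raw
scores with min → −1, max → +1.  Scores are relative to the analysed
scope by construction.

### Numerical choices

- The correlation matrix is explicitly symmetrized and given an exact
  unit diagonal before eigendecomposition, so float summation order
  cannot perturb downstream decisions.
- Selection and pruning comparisons carry a 1e-9 snap: loadings within
  1e-9 of the per-component maximum count as tied (broken by registry
  order), and pruning requires falling 1e-9 below the mean.  This
  matters because a dimension holding two correlated variables has an
  *analytically symmetric* first eigenvector — which variable "wins" is
  a true tie that float noise must not decide.
- Degenerate inputs are hard errors, never silently repaired: constant
  columns, fewer than 3 units or 2 variables, all-equal raw scores,
  pruning that would leave fewer than 2 variables.

## ICE and percentile thresholds

ICE_i = (privileged_i − deprived_i) / total_i.  Units with an empty
reference population raise rather than scoring 0 (0 means "balanced",
not "no data").  Thresholds for the extreme groups are the weighted
20th/80th percentiles of the *pooled* reference population (scope-wide,
the default; per-unit extremes would measure something else).  The
pinned percentile definition is the Weibull plotting position: the k-th
order statistic sits at probability k/(n+1), with linear interpolation
between order statistics; under general weights the position is the
cumulative weight share rescaled by n/(n+1), which is invariant to
positive rescaling of weights.  Four segregation flavours (income,
education, ethnicity-stratified income) are registry entries sharing
the same formula.

## Tabulation

The weighted percentage of a unit aggregating sub-records is
100 · Σw·count / Σw·total; the weighted mean is Σw·x / Σw.  The same two
operations serve record→area and area→municipality aggregation via a
grouping key.  Missing values are rejected with the offending units
named — no imputation, because silently imputed values would shift
loadings.  CSV dialect is comma/dot/UTF-8 by default with a `br`
(semicolon/comma-decimal) ingest option.

## Evaluation

Cronbach's alpha is computed on z-scored items with polarity-aligned
signs (mixed-direction items would spuriously deflate alpha), over the
retained item set by default (`alpha_items="all"` gives the pre-pruning
alternative).  Construct validation is a plain Pearson correlation
matrix over {scores, dimension representatives, external benchmark
columns}.  Each dimension's representative is its variable with the
largest |correlation| with the final scores, reported in original units
so non-specialists can compare areas on, say, "% without schooling";
dimensions whose variables were all constant are skipped with a warning.

## Spatial applicability

Indirect standardization applies per-stratum reference rates to each
unit's stratum populations (`expected_i = Σ_s rate_s · pop_is`;
RR = observed/expected).  The internal reference pools rates from the
data, which forces Σ expected = Σ observed exactly — an identity the
tests assert.  No small-count smoothing is applied; units whose expected
events fall below a configurable floor (default 5) trigger a warning
instead, because smoothing would trade transparency for stability.

OLS of relative risk on the index (via statsmodels) supplies residuals
for Moran's I, computed as (n/S0)·(Σ w_ij z_i z_j)/(Σ z_i²) on binary
Queen-contiguity weights with a permutation p-value (999 random
relabelings by default, seeded; one-sided "greater", significance read
at p < 0.05).  Permutation was chosen over the analytic normal
approximation because it is assumption-free and matches common GIS
practice.  Geographically weighted regression — the natural next step
when residual spatial dependence *is* found — is deliberately out of
scope: it is an established external method available in GIS tooling,
and this package's job ends at detecting that it is needed.  Weights
come from GAL files (GeoDa dialect) or the synthetic lattice; polygon
contiguity extraction belongs to GIS tooling.

## The synthetic census

The generator emulates decennial-census sample-area tabulations with a
single latent SES factor s_i ~ N(0,1):

- percentage variables: proportion logistic(a_v + polarity_v·(s_i +
  eps_iv)), eps ~ N(0, noise_sd); counts Binomial(total_i, p).  Baseline
  logits a_v spread over [−1.5, 0.5] so prevalences differ across
  variables; slope 1.0 on the latent scale.
- income variables: lognormal unit means exp(2.3 + 0.3j + 0.6·signal).
- ICE inputs: multinomial (privileged, deprived, rest) with tail shares
  0.45·logistic(−1.5 ± signal), so extreme concentration tracks SES.
- geography: Queen contiguity on a near-square lattice (the factor pair
  of n closest to square; corner degree 3, edge 5, interior 8).
- outcome: events_is ~ Poisson(pop_is · base_rate · factor_s ·
  exp(beta·z_i)) over 6 strata (2 sexes × 3 age bands) with fixed
  population shares and rate multipliers.

Defaults: 200 units, 15 variables (3 education, 2 each elsewhere),
noise_sd 0.3, populations 500–2000, expansion weights lognormal(0, 0.2),
base_rate 0.01 per person-period (a multi-year cumulative mortality
scale, keeping per-unit expected events ≈ 10–30 so relative risks are
stable), outcome_beta −0.5.  These sizes keep the full test suite and
the acceptance script in seconds while leaving comfortable statistical
margins.

What the generator does **not** emulate — hence what passing tests do
not show about real data: multi-factor socioeconomic structure (real
dimensions are not perfectly one-dimensional, so real step-1 selections
retain more variables), spatially autocorrelated confounding beyond
SES, informative missingness, measurement error correlated across
variables, and real questionnaire schemas or microdata volumes.
Recovery of the latent factor (|r| ≥ 0.9 at n = 200, noise_sd ≤ 0.3, a
threshold frozen after a single calibration run) certifies the
pipeline's mechanics, not the substantive validity of any real-world
index.

## Known limitations

- With few, highly homogeneous selected variables the mean-|loading|
  prune rule can be aggressive (roughly half the variables sit below the
  mean when loadings are near-equal); the decision log records exactly
  what was pruned, and `iterate_prune`/`prune_rule` expose the
  alternatives.
- Unit weights enter tabulation only; the PCA itself is unweighted by
  design.
- Scores are scope-relative: comparing scores across separately fitted
  scopes (e.g. two different states) is not meaningful.
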