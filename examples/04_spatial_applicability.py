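"""Check the index's explanatory power for a health outcome.

Indirectly standardizes stratified synthetic event counts into relative
risks, regresses risk on the index with OLS, and tests the residuals for
spatial autocorrelation with Moran's I under Queen lattice weights.
"""

from geoses import SimConfig, generate_census, run_pipeline, spatial_diagnostics

census = generate_census(SimConfig(n_units=200, outcome_beta=-0.5, seed=1))
result = run_pipeline(census.variable_table(), census.registry())

diag = spatial_diagnostics(
    result.scores, census.outcome, census.adjacency,
    n_permutations=999, seed=7,
)

fit = diag["ols"]
print(f"OLS: RR = {fit.intercept:.3f} + {fit.slope:.3f} * score")
print(f"     adjusted R^2 = {fit.adj_r_squared:.3f}, AIC = {fit.aic:.1f}")
print(f"residual Moran's I = {diag['morans_i']:.4f} (p = {diag['morans_p']:.3f})")
print("residual spatial dependence:", diag["residual_spatial_dependence"])
print(
    "\nThe negative slope says risk falls as socioeconomic context improves"
    "\n(the generator used outcome_beta = -0.5).  A non-significant Moran's I"
    "\n(p >= 0.05) means the index absorbed the spatial pattern: nothing"
    "\nspatial is left in the residuals, as expected when SES is the only"
    "\nspatially structured driver."
)
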