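"""Build the composite socioeconomic index on a synthetic census.

Generates a 200-unit census-style table (15 variables over seven
dimensions), runs the five-step staged-PCA pipeline, and compares the
resulting [-1, 1] scores with the generator's known latent SES factor.
"""

import numpy as np

from geoses import SimConfig, generate_census, run_pipeline

census = generate_census(SimConfig(n_units=200, noise_sd=0.3, seed=1))
table = census.variable_table()
registry = census.registry()

result = run_pipeline(table, registry)

print("step-1 selections per dimension:")
for dim, sel in result.step1_selection.items():
    print(f"  {dim:12s} -> {sel}")
print("retained after pruning:", result.retained_variables)
print("final loadings:")
print(result.loadings.round(3).to_string())
print(f"score range: [{result.scores.min():.3f}, {result.scores.max():.3f}]")

r = np.corrcoef(result.scores, census.latent_ses)[0, 1]
print(f"Pearson r(scores, latent SES) = {r:.3f}")
print(
    "\nScores span exactly [-1, 1]: -1 is the most deprived unit in this run,"
    "\n+1 the most advantaged; r near 1 means the index recovered the single"
    "\nlatent factor that generated all variables."
)
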