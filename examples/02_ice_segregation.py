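"""Residential segregation via the Index of Concentration at the Extremes.

Builds person-level incomes for three areas, pools them to find the
20th/80th percentile thresholds, and computes each area's ICE.
"""

import numpy as np

from geoses import extreme_thresholds, ice_from_values

rng = np.random.default_rng(0)

# three areas: poor (low incomes), mixed, rich (high incomes)
incomes = np.concatenate(
    [
        rng.lognormal(6.0, 0.4, 300),  # area P
        rng.lognormal(7.0, 0.8, 300),  # area M
        rng.lognormal(8.0, 0.4, 300),  # area R
    ]
)
areas = ["P"] * 300 + ["M"] * 300 + ["R"] * 300

p20, p80 = extreme_thresholds(incomes)
print(f"pooled thresholds: p20 = {p20:.0f}, p80 = {p80:.0f}")

ice = ice_from_values(incomes, None, areas)
print(ice.round(3).to_string())
print(
    "\nICE = (privileged - deprived) / total per area: near -1 the area is"
    "\ndominated by the deprived extreme (P), near +1 by the privileged"
    "\nextreme (R); the mixed area sits near 0."
)
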