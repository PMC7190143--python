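"""Synthetic census-style small-area data with a known latent SES factor.

Real inputs to the index are decennial-census sample tabulations: per
small area, counts of people or households with some attribute, expansion
weights restoring representativity, mean incomes, and counts in the
extreme tails of the income distribution.  This module emulates exactly
that shape from a single latent socioeconomic factor per unit, so every
downstream stage — tabulation, ICE, staged PCA, validation, spatial
diagnostics — can be exercised and checked against the stored ground
truth without any external download.

Generative model (one latent factor, per the empirical finding that a
single first principal component summarizes the context):

* latent SES ``s_i ~ N(0, 1)`` per unit;
* percentage-type variables: proportion
  ``p_iv = logistic(a_v + polarity_v * (s_i + eps_iv))`` with unit-level
  disturbance ``eps_iv ~ N(0, noise_sd)``, counts Binomial(total_i, p_iv);
* income-type variables: lognormal unit means
  ``exp(mu_v + slope_v * (s_i + eps_iv))``;
* segregation (ICE) inputs: privileged/deprived extreme counts drawn
  multinomially with tail shares rising/falling logistically in latent
  SES;
* geography: Queen contiguity on a rectangular lattice;
* health outcome: per unit and stratum,
  ``events ~ Poisson(pop * base_rate * stratum_factor * exp(outcome_beta * z(s)))``.

Everything is driven by one integer seed; identical configs reproduce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dimensions import DIMENSIONS, DimensionRegistry, ExtremeCounts, compute_ice
from .errors import ConfigurationError, DataError
from .io import VariableTable, weighted_percentage, write_variable_table
from .spatial import SpatialWeights, queen_lattice, write_gal

#: default direction of each dimension's variables w.r.t. advantage:
#: e.g. poverty and deprivation variables measure lack, commute-time
#: mobility variables measure burden.
_DIM_POLARITY = {
    "education": +1,
    "mobility": -1,
    "poverty": -1,
    "wealth": +1,
    "income": +1,
    "segregation": +1,
    "deprivation": -1,
}

#: 2 sexes x 3 age bands; shares of unit population and rate multipliers
_STRATA = ("F_young", "F_mid", "F_old", "M_young", "M_mid", "M_old")
_STRATUM_SHARE = np.array([0.20, 0.18, 0.12, 0.20, 0.18, 0.12])
_STRATUM_FACTOR = np.array([0.5, 1.0, 3.0, 0.7, 1.4, 4.0])


def _default_vars_per_dimension() -> dict[str, int]:
    return {
        "education": 3,
        "mobility": 2,
        "poverty": 2,
        "wealth": 2,
        "income": 2,
        "segregation": 2,
        "deprivation": 2,
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic census generator."""

    n_units: int = 200
    n_vars_per_dimension: dict[str, int] = field(
        default_factory=_default_vars_per_dimension
    )
    polarity: dict[str, int] = field(default_factory=dict)
    noise_sd: float = 0.3
    population_range: tuple[int, int] = (500, 2000)
    outcome_beta: float = -0.5
    base_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ConfigurationError("n_units must be positive")
        missing = [d for d in DIMENSIONS if d not in self.n_vars_per_dimension]
        if missing:
            raise ConfigurationError(f"missing dimension(s): {missing}")
        if any(k <= 0 for k in self.n_vars_per_dimension.values()):
            raise ConfigurationError("n_vars_per_dimension values must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        lo, hi = self.population_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("population_range must satisfy 1 <= lo <= hi")
        if self.base_rate < 0:
            raise ConfigurationError("base_rate must be nonnegative")

    def variable_names(self) -> dict[str, list[str]]:
        return {
            dim: [f"{dim}_v{k + 1}" for k in range(self.n_vars_per_dimension[dim])]
            for dim in DIMENSIONS
        }

    def variable_polarity(self) -> dict[str, int]:
        out = {}
        for dim, names in self.variable_names().items():
            for v in names:
                out[v] = self.polarity.get(v, _DIM_POLARITY[dim])
        return out

    def registry(self) -> DimensionRegistry:
        names = self.variable_names()
        pol = self.variable_polarity()
        kind = {}
        for dim, vs in names.items():
            for v in vs:
                kind[v] = {"income": "mean", "segregation": "ice"}.get(dim, "percentage")
        return DimensionRegistry(dict(names), pol, kind)


@dataclass
class SyntheticCensus:
    """Generated tabulations plus the ground truth they were drawn from."""

    config: SimConfig
    counts: pd.DataFrame  # percentage-var counts and ICE extreme counts
    totals: pd.Series  # per-unit reference population
    income_values: pd.DataFrame  # lognormal unit means (kind "mean")
    weights: pd.Series  # expansion weights
    latent_ses: pd.Series
    adjacency: SpatialWeights
    grid_shape: tuple[int, int]
    outcome: pd.DataFrame  # tidy: unit_id, stratum, population, events

    def variable_table(self) -> VariableTable:
        """Tabulate raw counts into the processed per-unit variable table
        (the "second step": percentages, means, ICE)."""
        reg = self.config.registry()
        cols: dict[str, pd.Series] = {}
        for dim, names in self.config.variable_names().items():
            for v in names:
                if dim == "income":
                    cols[v] = self.income_values[v]
                elif dim == "segregation":
                    cols[v] = compute_ice(
                        ExtremeCounts(
                            self.counts[f"{v}_privileged"],
                            self.counts[f"{v}_deprived"],
                            self.totals,
                        )
                    )
                else:
                    cols[v] = weighted_percentage(self.counts[v], self.totals)
        values = pd.DataFrame(cols, index=self.totals.index)
        return VariableTable(values, self.weights, reg.variable_meta())

    def registry(self) -> DimensionRegistry:
        return self.config.registry()

    def write_dir(self, out_dir) -> dict[str, Path]:
        """Write the CSV/YAML/GAL artifact set the CLI consumes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "table": out / "variables.csv",
            "registry": out / "dimensions.yaml",
            "adjacency": out / "units.gal",
            "outcome": out / "outcome.csv",
            "truth": out / "latent_ses.csv",
        }
        write_variable_table(paths["table"], self.variable_table())
        self.registry().to_yaml(paths["registry"])
        write_gal(paths["adjacency"], self.adjacency)
        self.outcome.to_csv(paths["outcome"], index=False)
        self.latent_ses.rename("latent_ses").to_csv(paths["truth"], index_label="unit_id")
        return paths


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _grid_shape(n: int) -> tuple[int, int]:
    r = int(np.sqrt(n))
    while r > 1 and n % r:
        r -= 1
    return r, n // r


def generate_census(config: SimConfig) -> SyntheticCensus:
    """Draw a full synthetic census from the one-factor model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_units
    unit_ids = pd.Index([f"u{i:04d}" for i in range(n)], name="unit_id")

    latent = pd.Series(rng.standard_normal(n), index=unit_ids, name="latent_ses")
    lo, hi = config.population_range
    totals = pd.Series(rng.integers(lo, hi + 1, size=n), index=unit_ids, name="total")
    weights = pd.Series(
        np.exp(rng.normal(0.0, 0.2, size=n)), index=unit_ids, name="weight"
    )

    pol = config.variable_polarity()
    names = config.variable_names()
    counts: dict[str, np.ndarray] = {}
    income: dict[str, np.ndarray] = {}
    for dim in DIMENSIONS:
        for j, v in enumerate(names[dim]):
            eps = rng.normal(0.0, config.noise_sd, size=n)
            signal = pol[v] * (latent.to_numpy() + eps)
            if dim == "income":
                # lognormal unit mean income; baseline ~ exp(2.3) = 10 units
                income[v] = np.exp(2.3 + 0.3 * j + 0.6 * signal)
            elif dim == "segregation":
                # extreme-tail shares rise/fall logistically with SES
                q_priv = 0.45 * _logistic(-1.5 + signal)
                q_depr = 0.45 * _logistic(-1.5 - signal)
                draws = np.array(
                    [
                        rng.multinomial(t, [qp, qd, 1.0 - qp - qd])
                        for t, qp, qd in zip(totals, q_priv, q_depr)
                    ]
                )
                counts[f"{v}_privileged"] = draws[:, 0]
                counts[f"{v}_deprived"] = draws[:, 1]
            else:
                # baseline logits spread over [-1.5, 0.5] across a
                # dimension's variables so prevalences differ
                a = -1.5 + 2.0 * (j / max(len(names[dim]) - 1, 1)) - 0.5
                p = _logistic(a + signal)
                counts[v] = rng.binomial(totals.to_numpy(), p)

    n_rows, n_cols = _grid_shape(n)
    adjacency = queen_lattice(n_rows, n_cols, ids=list(unit_ids))

    outcome = generate_outcome(latent, config, populations=totals, rng=rng)

    return SyntheticCensus(
        config=config,
        counts=pd.DataFrame(counts, index=unit_ids),
        totals=totals,
        income_values=pd.DataFrame(income, index=unit_ids),
        weights=weights,
        latent_ses=latent,
        adjacency=adjacency,
        grid_shape=(n_rows, n_cols),
        outcome=outcome,
    )


def generate_outcome(
    latent_ses: pd.Series,
    config: SimConfig,
    populations: pd.Series | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Stratified Poisson event counts whose log-rate is linear in SES.

    Per unit i and stratum s:
    ``events_is ~ Poisson(pop_is * base_rate * factor_s * exp(beta * z_i))``
    with ``z`` the standardized latent SES, so ``beta < 0`` means worse
    outcomes in disadvantaged areas.
    """
    latent = pd.Series(latent_ses)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if populations is None:
        lo, hi = config.population_range
        populations = pd.Series(
            rng.integers(lo, hi + 1, size=len(latent)), index=latent.index
        )
    else:
        populations = pd.Series(populations).reindex(latent.index)
    if (populations < 0).any():
        raise DataError("negative populations")

    z = (latent - latent.mean()) / latent.std(ddof=1) if latent.std(ddof=1) > 0 else latent * 0.0
    rows = []
    for uid in latent.index:
        pop = float(populations.loc[uid])
        rr = float(np.exp(config.outcome_beta * z.loc[uid]))
        for s, share, factor in zip(_STRATA, _STRATUM_SHARE, _STRATUM_FACTOR):
            pop_s = np.floor(pop * share)
            mean = pop_s * config.base_rate * factor * rr
            rows.append(
                {
                    "unit_id": uid,
                    "stratum": s,
                    "population": int(pop_s),
                    "events": int(rng.poisson(mean)) if mean > 0 else 0,
                }
            )
    return pd.DataFrame(rows)
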