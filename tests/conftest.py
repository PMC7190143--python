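import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from geoses import SimConfig, generate_census, run_pipeline

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def census():
    """Moderate-noise synthetic census shared across read-only tests."""
    return generate_census(SimConfig(n_units=200, noise_sd=0.3, seed=1))


@pytest.fixture(scope="session")
def table(census):
    return census.variable_table()


@pytest.fixture(scope="session")
def registry(census):
    return census.registry()


@pytest.fixture(scope="session")
def fitted(table, registry):
    return run_pipeline(table, registry)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_table(rng, n_units=50, n_vars=5, prefix="v"):
    """Unstructured random table for PCA oracle checks."""
    from geoses import VariableTable

    values = pd.DataFrame(
        rng.normal(size=(n_units, n_vars)),
        columns=[f"{prefix}{j}" for j in range(n_vars)],
        index=pd.Index([f"u{i}" for i in range(n_units)], name="unit_id"),
    )
    weights = pd.Series(1.0, index=values.index)
    return VariableTable(values, weights, {})
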