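import numpy as np
import pandas as pd
import pytest

from geoses import (
    DimensionRegistry,
    VariableTable,
    correlation_matrix,
    cronbach_alpha,
    dimension_contribution,
    validation_report,
)
from geoses.errors import DegenerateInputError


def make_table(df):
    return VariableTable(df, pd.Series(1.0, index=df.index), {})


class TestCronbachAlpha:
    def test_duplicated_item_gives_one(self, rng):
        x = rng.normal(size=50)
        t = make_table(pd.DataFrame({"a": x, "b": x.copy()}))
        assert cronbach_alpha(t) == pytest.approx(1.0, abs=1e-12)

    def test_independent_items_give_near_zero(self, rng):
        n = 20000
        t = make_table(
            pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        )
        assert cronbach_alpha(t) == pytest.approx(0.0, abs=0.05)

    def test_equicorrelated_closed_form(self, rng):
        # k=3 items with pairwise rho=0.5: Spearman-Brown gives
        # alpha = k*rho / (1 + (k-1)*rho) = 1.5/2 = 0.75
        n, rho = 30000, 0.5
        common = rng.normal(size=n)
        df = pd.DataFrame(
            {f"x{j}": np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.normal(size=n)
             for j in range(3)}
        )
        assert cronbach_alpha(make_table(df)) == pytest.approx(0.75, abs=0.02)

    def test_polarity_alignment_restores_alpha(self, rng):
        x = rng.normal(size=100)
        noisy = x + 0.3 * rng.normal(size=100)
        t = make_table(pd.DataFrame({"up": x, "down": -noisy}))
        deflated = cronbach_alpha(t)
        aligned = cronbach_alpha(t, polarity={"up": 1, "down": -1})
        assert aligned > 0.8 > 0 > deflated

    def test_affine_rescaling_invariant(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        base = cronbach_alpha(make_table(df))
        df2 = df.copy()
        df2["a"] = 100 * df2["a"] - 7
        assert cronbach_alpha(make_table(df2)) == pytest.approx(base, abs=1e-12)

    def test_single_item_rejected(self, rng):
        t = make_table(pd.DataFrame({"a": rng.normal(size=10)}))
        with pytest.raises(DegenerateInputError):
            cronbach_alpha(t)


class TestCorrelationMatrix:
    def test_self_correlation_and_antithesis(self, rng):
        x = rng.normal(size=20)
        out = correlation_matrix(pd.DataFrame({"x": x, "neg": -x}))
        assert out.loc["x", "x"] == 1.0
        assert out.loc["x", "neg"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_two_pass_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        out = correlation_matrix(df)
        # textbook oracle: explicit centered cross-products
        X = df.to_numpy()
        Xc = X - X.mean(0)
        C = Xc.T @ Xc
        denom = np.sqrt(np.outer(np.diag(C), np.diag(C)))
        assert np.allclose(out.to_numpy(), C / denom, atol=1e-12)
        assert np.allclose(out, out.T)

    def test_constant_column_named(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=10), "flat": np.ones(10)})
        with pytest.raises(DegenerateInputError, match="flat"):
            correlation_matrix(df)


class TestDimensionContribution:
    def test_single_variable_dimension_is_its_own_representative(
        self, fitted, table, registry
    ):
        reps = dimension_contribution(fitted, table, registry)
        for dim, rep in reps.items():
            assert rep.variable in registry.dimensions[dim]

    def test_brute_force_max_abs_correlation(self, fitted, table, registry):
        reps = dimension_contribution(fitted, table, registry)
        s = fitted.scores.to_numpy()
        for dim, rep in reps.items():
            best = max(
                registry.dimensions[dim],
                key=lambda v: abs(np.corrcoef(table.values[v], s)[0, 1]),
            )
            assert rep.variable == best
            assert rep.correlation == pytest.approx(
                np.corrcoef(table.values[best], s)[0, 1], abs=1e-12
            )

    def test_planted_high_signal_variable_wins(self, rng):
        n = 200
        sig = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "edu_strong": sig + 0.05 * rng.normal(size=n),
                "edu_weak": sig + 2.0 * rng.normal(size=n),
            }
        )
        t = make_table(df)
        reg = DimensionRegistry(
            dimensions={"education": ["edu_strong", "edu_weak"]},
            polarity={"edu_strong": 1, "edu_weak": 1},
        )

        class FakeResult:
            scores = pd.Series(sig, index=df.index)

        reps = dimension_contribution(FakeResult(), t, reg)
        assert reps["education"].variable == "edu_strong"

    def test_representatives_follow_polarity_direction(
        self, fitted, table, registry, census
    ):
        # with a positively oriented index, each representative's
        # correlation sign should match its polarity
        reps = dimension_contribution(fitted, table, registry)
        for dim, rep in reps.items():
            assert np.sign(rep.correlation) == registry.polarity[rep.variable]


class TestValidationReport:
    def test_report_shape_and_bounds(self, fitted, table, registry):
        rep = validation_report(fitted, table, registry)
        C = rep.correlations
        assert (C.to_numpy() <= 1 + 1e-12).all() and (C.to_numpy() >= -1 - 1e-12).all()
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C, C.T)
        assert rep.cronbach_alpha <= 1.0
        assert "geoses" in C.columns

    def test_external_benchmark_included(self, fitted, table, registry, census):
        # a noisy monotone transform of latent SES stands in for an
        # external development index
        rng = np.random.default_rng(0)
        ext = pd.DataFrame(
            {"hdi": 0.5 + 0.1 * census.latent_ses + 0.02 * rng.normal(size=len(census.latent_ses))}
        )
        rep = validation_report(fitted, table, registry, external=ext)
        assert rep.correlations.loc["geoses", "hdi"] > 0.85

    def test_alpha_item_sets_differ(self, fitted, table, registry):
        a_ret = validation_report(fitted, table, registry, alpha_items="retained")
        a_all = validation_report(fitted, table, registry, alpha_items="all")
        assert a_ret.cronbach_alpha != a_all.cronbach_alpha
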