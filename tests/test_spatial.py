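import numpy as np
import pandas as pd
import pytest

from geoses import (
    SpatialWeights,
    indirect_standardize,
    morans_i,
    ols_fit,
    queen_lattice,
    read_gal,
    rook_lattice,
    spatial_diagnostics,
    write_gal,
)
from geoses.errors import DataError, DegenerateInputError, WeightsError


class TestSpatialWeights:
    def test_self_neighbor_rejected(self):
        with pytest.raises(WeightsError):
            SpatialWeights({1: {1, 2}, 2: {1}})

    def test_island_rejected(self):
        with pytest.raises(WeightsError):
            SpatialWeights({1: {2}, 2: {1}, 3: set()})

    def test_asymmetry_rejected(self):
        with pytest.raises(WeightsError):
            SpatialWeights({1: {2}, 2: {1, 3}, 3: {1}})

    def test_row_standardized_rows_sum_to_one(self):
        w = queen_lattice(3, 3)
        W = w.matrix(row_standardized=True)
        assert np.allclose(W.sum(axis=1), 1.0)


class TestGAL:
    def test_three_unit_chain(self, tmp_path):
        p = tmp_path / "chain.gal"
        p.write_text("3\n1 1\n2\n2 2\n1 3\n3 1\n2\n")
        w = read_gal(p)
        assert w.neighbors == {"1": {"2"}, "2": {"1", "3"}, "3": {"2"}}

    def test_round_trip(self, tmp_path):
        w = queen_lattice(4, 5)
        p = tmp_path / "lattice.gal"
        write_gal(p, w)
        back = read_gal(p)
        assert back.neighbors == {
            str(k): {str(x) for x in v} for k, v in w.neighbors.items()
        }

    def test_asymmetric_file_rejected(self, tmp_path):
        p = tmp_path / "bad.gal"
        p.write_text("2\n1 1\n2\n2 0\n\n")
        with pytest.raises(DataError):
            read_gal(p)

    def test_unknown_id_rejected(self, tmp_path):
        p = tmp_path / "bad.gal"
        p.write_text("2\n1 1\n9\n2 1\n1\n")
        with pytest.raises(DataError):
            read_gal(p)


class TestIndirectStandardization:
    def _tidy(self, units, strata, pops, events):
        rows = []
        for i, u in enumerate(units):
            for j, s in enumerate(strata):
                rows.append(
                    {"unit_id": u, "stratum": s,
                     "population": pops[i][j], "events": events[i][j]}
                )
        return pd.DataFrame(rows)

    def test_two_unit_worked_example(self):
        # external rates (0.01, 0.02); unit A has 100 people in stratum 1,
        # B 100 in stratum 2; observed (2, 1) -> expected (1, 2),
        # RR_A = 2.0, RR_B = 0.5
        df = self._tidy(["A", "B"], ["s1", "s2"],
                        [[100, 0], [0, 100]], [[2, 0], [0, 1]])
        rates = pd.Series({"s1": 0.01, "s2": 0.02})
        out = indirect_standardize(df, reference=rates, min_expected_warn=0)
        assert out.relative_risk.loc["A"] == pytest.approx(2.0)
        assert out.relative_risk.loc["B"] == pytest.approx(0.5)

    def test_internal_reference_conserves_totals(self, census):
        out = indirect_standardize(census.outcome, min_expected_warn=0)
        assert out.expected.sum() == pytest.approx(out.observed.sum(), rel=1e-12)

    def test_uniform_rates_equal_stratum_mix_ranks_by_crude_rate(self):
        df = self._tidy(["A", "B"], ["s1", "s2"],
                        [[100, 100], [100, 100]], [[4, 4], [1, 1]])
        out = indirect_standardize(df, min_expected_warn=0)
        crude = out.observed / 200.0
        assert np.allclose(
            out.relative_risk / out.relative_risk.sum(), crude / crude.sum()
        )

    def test_events_without_population_rejected(self):
        df = self._tidy(["A"], ["s1"], [[0]], [[3]])
        with pytest.raises(DataError):
            indirect_standardize(df)

    def test_low_expected_triggers_warning(self):
        df = self._tidy(["A", "B"], ["s1"], [[50], [50]], [[1], [2]])
        with pytest.warns(UserWarning, match="unstable"):
            indirect_standardize(df, min_expected_warn=5.0)


class TestOLS:
    def test_exact_line_recovered(self):
        x = pd.Series(np.arange(10, dtype=float))
        y = 2.0 * x + 1.0
        fit = ols_fit(y, x)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.adj_r_squared == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_null_slope_within_two_se(self, rng):
        x = pd.Series(rng.normal(size=500))
        y = pd.Series(rng.normal(size=500))
        fit = ols_fit(y, x)
        assert abs(fit.slope) <= 2 * fit.slope_se

    def test_matches_normal_equation_oracle(self, rng):
        x = pd.Series(rng.normal(size=40))
        y = pd.Series(rng.normal(size=40))
        fit = ols_fit(y, x)
        X = np.column_stack([np.ones(40), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_residuals_orthogonal_to_x_and_centered(self, rng):
        x = pd.Series(rng.normal(size=60))
        y = pd.Series(3 * x + rng.normal(size=60))
        fit = ols_fit(y, x)
        assert abs(fit.residuals.sum()) < 1e-9
        assert abs(fit.residuals @ x) < 1e-9

    def test_constant_regressor_rejected(self):
        with pytest.raises(DegenerateInputError):
            ols_fit(pd.Series([1.0, 2, 3]), pd.Series([5.0, 5, 5]))


class TestMoransI:
    def test_checkerboard_is_negative(self):
        w = rook_lattice(4, 4)
        vals = pd.Series(
            [(-1.0) ** (i // 4 + i % 4) for i in range(16)], index=range(16)
        )
        I, _ = morans_i(vals, w, n_permutations=0)
        assert I < 0

    def test_block_pattern_positive_and_significant(self):
        w = queen_lattice(6, 6)
        vals = pd.Series(
            [1.0 if i % 6 < 3 else -1.0 for i in range(36)], index=range(36)
        )
        I, p = morans_i(vals, w, n_permutations=999, seed=1)
        assert I > 0
        assert p <= 0.05

    def test_matches_double_sum_oracle(self, rng):
        w = queen_lattice(5, 6)
        vals = pd.Series(rng.normal(size=30), index=range(30))
        I, _ = morans_i(vals, w, n_permutations=0)
        z = vals.to_numpy() - vals.mean()
        num = 0.0
        s0 = 0
        for i in range(30):
            for j in w.neighbors[i]:
                num += z[i] * z[j]
                s0 += 1
        oracle = (30 / s0) * num / (z @ z)
        assert I == pytest.approx(oracle, abs=1e-12)

    def test_permutation_null_mean_is_minus_one_over_n_minus_1(self, rng):
        w = queen_lattice(6, 6)
        vals = pd.Series(rng.normal(size=36), index=range(36))
        _, _, null = morans_i(vals, w, n_permutations=999, seed=2, return_null=True)
        expected = -1.0 / 35
        assert null.mean() == pytest.approx(expected, abs=3 * null.std() / np.sqrt(999))

    def test_seed_reproducible(self, rng):
        w = queen_lattice(4, 4)
        vals = pd.Series(rng.normal(size=16), index=range(16))
        assert morans_i(vals, w, seed=5) == morans_i(vals, w, seed=5)

    def test_constant_values_rejected(self):
        w = queen_lattice(3, 3)
        with pytest.raises(DegenerateInputError):
            morans_i(pd.Series(np.ones(9), index=range(9)), w, seed=0)


class TestDiagnosticsEndToEnd:
    def test_negative_beta_yields_negative_slope_no_residual_structure(
        self, census, fitted
    ):
        # generator ties outcome to SES only, with no extra spatial field:
        # risk falls with the index and residuals carry no autocorrelation
        diag = spatial_diagnostics(
            fitted.scores, census.outcome, census.adjacency,
            n_permutations=499, seed=11,
        )
        assert diag["ols"].slope < 0
        assert diag["morans_p"] > 0.05
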