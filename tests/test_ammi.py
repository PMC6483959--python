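"""AMMI decomposition, ANOVA partition, axis tests and biplots.

Oracles: an alternating-least-squares successive rank-1 fit (independent of
the SVD route), a numeric Jacobian-rank count of free parameters for the
Gollob degrees of freedom, and statsmodels OLS for the replicate-level
ANOVA.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ammistab import (
    AMMI,
    GEMatrix,
    ReplicateTable,
    anova_from_means,
    anova_two_way,
    biplot_coordinates,
    center_interaction,
    gollob_axis_tests,
)
from ammistab.ammi import gollob_df
from ammistab.simulate import AMMISimSpec, random_interaction_scores, simulate_ammi_trial


def _ge(values, r=1):
    values = np.asarray(values, dtype=float)
    G, E = values.shape
    return GEMatrix(values, tuple(f"g{i}" for i in range(G)),
                    tuple(f"e{j}" for j in range(E)), replicates=r)


# ---------------------------------------------------------------------------
# double centering

class TestCenterInteraction:
    def test_constant_matrix_gives_zero(self):
        Z = center_interaction(_ge(np.full((4, 5), 7.3)))
        np.testing.assert_allclose(Z, 0.0, atol=1e-12)

    def test_purely_additive_table_gives_zero(self, rng):
        alpha = rng.normal(size=6)
        beta = rng.normal(size=4)
        Y = 10.0 + alpha[:, None] + beta[None, :]
        np.testing.assert_allclose(center_interaction(_ge(Y)), 0.0, atol=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(
        arrays(
            float,
            st.tuples(st.integers(3, 8), st.integers(3, 8)),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_row_and_column_sums_vanish(self, values):
        Z = center_interaction(_ge(values))
        np.testing.assert_allclose(Z.sum(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.sum(axis=1), 0.0, atol=1e-9)

    def test_barley_interaction_ss(self, barley_ge):
        Z = center_interaction(barley_ge)
        ss_ge = 3 * (Z**2).sum()
        assert ss_ge == pytest.approx(10057, rel=0.002)


# ---------------------------------------------------------------------------
# decomposition identities

class TestDecompositionIdentities:
    def test_exact_reconstruction(self, barley_model, barley_ge):
        np.testing.assert_allclose(
            barley_model.fitted_values(), barley_ge.values, atol=1e-8
        )

    def test_axis_ss_sums_to_interaction_ss(self, barley_model, barley_ge):
        Z = center_interaction(barley_ge)
        ss_ge = barley_ge.replicates * (Z**2).sum()
        assert barley_model.axis_ss_.sum() == pytest.approx(ss_ge, rel=1e-6)

    def test_symmetric_scaling_identity(self, barley_model):
        for n, lam in enumerate(barley_model.singular_values_):
            assert (barley_model.genotype_scores_[:, n] ** 2).sum() == pytest.approx(lam, rel=1e-9)
            assert (barley_model.environment_scores_[:, n] ** 2).sum() == pytest.approx(lam, rel=1e-9)

    def test_score_columns_orthogonal(self, barley_model):
        crossg = barley_model.genotype_scores_.T @ barley_model.genotype_scores_
        crosse = barley_model.environment_scores_.T @ barley_model.environment_scores_
        for cross in (crossg, crosse):
            off = cross - np.diag(np.diag(cross))
            np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_main_effects_sum_to_zero(self, barley_model):
        assert barley_model.genotype_effects_.sum() == pytest.approx(0.0, abs=1e-9)
        assert barley_model.environment_effects_.sum() == pytest.approx(0.0, abs=1e-9)

    def test_transform_recovers_training_scores(self, barley_model, barley_ge):
        scores = barley_model.transform(barley_ge.values)
        np.testing.assert_allclose(scores, barley_model.genotype_scores_, atol=1e-8)


class TestPlantedRank1Recovery:
    def test_recovers_singular_value_and_scores(self, rng):
        G, E, lam = 10, 6, 8.0
        gamma = random_interaction_scores(G, 1, rng)[:, 0]
        delta = random_interaction_scores(E, 1, rng)[:, 0]
        alpha = rng.normal(size=G)
        beta = rng.normal(size=E)
        Y = 50.0 + (alpha - alpha.mean())[:, None] + (beta - beta.mean())[None, :]
        Y = Y + lam * np.outer(gamma, delta)
        model = AMMI().fit(_ge(Y))
        assert model.singular_values_[0] == pytest.approx(lam, rel=1e-10)
        assert model.singular_values_[1] == pytest.approx(0.0, abs=1e-8)
        got = model.genotype_scores_[:, 0]
        want = np.sqrt(lam) * gamma
        sign = np.sign(got @ want)
        np.testing.assert_allclose(got, sign * want, atol=1e-8)
        np.testing.assert_allclose(
            model.environment_scores_[:, 0],
            sign * np.sqrt(lam) * delta,
            atol=1e-8,
        )


def _successive_rank1_ss(Z, n_axes, n_iter=2000):
    """Brute-force axis SS by alternating-least-squares rank-1 fits."""
    Z = Z.copy()
    out = []
    for _ in range(n_axes):
        v = Z[np.argmax((Z**2).sum(axis=1))].copy()
        for _ in range(n_iter):
            u = Z @ v / (v @ v)
            v = Z.T @ u / (u @ u)
        fit = np.outer(u, v)
        out.append((fit**2).sum())
        Z = Z - fit
    return np.array(out)


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_axis_ss_matches_alternating_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        Y = rng.normal(50, 5, size=(4, 4))
        ge = _ge(Y, r=2)
        model = AMMI().fit(ge)
        brute = 2 * _successive_rank1_ss(center_interaction(ge), 3)
        np.testing.assert_allclose(model.axis_ss_, brute, rtol=1e-6)


def _bilinear_model_dim(G, E, n, rng):
    """Numeric dimension of the doubly-centered rank<=n bilinear family.

    Rank of the Jacobian of (A, B) -> P_G A B' P_E at a generic point,
    where P are the centering projectors.
    """
    if n == 0:
        return 0
    PG = np.eye(G) - 1.0 / G
    PE = np.eye(E) - 1.0 / E
    A = rng.standard_normal((G, n))
    B = rng.standard_normal((E, n))
    cols = []
    for i in range(G):
        for j in range(n):
            dA = np.zeros((G, n)); dA[i, j] = 1.0
            cols.append((PG @ dA @ B.T @ PE).ravel())
    for i in range(E):
        for j in range(n):
            dB = np.zeros((E, n)); dB[i, j] = 1.0
            cols.append((PG @ A @ dB.T @ PE).ravel())
    return np.linalg.matrix_rank(np.column_stack(cols))


class TestGollobDegreesOfFreedom:
    @pytest.mark.parametrize("G, E, n", [(6, 5, 1), (6, 5, 2), (8, 4, 1), (8, 4, 3), (32, 6, 1)])
    def test_df_equals_free_parameter_count(self, G, E, n, rng):
        added = _bilinear_model_dim(G, E, n, rng) - _bilinear_model_dim(G, E, n - 1, rng)
        assert gollob_df(G, E, n) == added

    def test_barley_axis_df(self, barley_model):
        np.testing.assert_array_equal(barley_model.axis_df_, [35, 33, 31, 29, 27])


# ---------------------------------------------------------------------------
# ANOVA tables

class TestAnovaFromMeans:
    def test_barley_main_effect_ss(self, barley_ge):
        table = anova_from_means(barley_ge).set_index("source")
        assert table.loc["Genotypes", "ss"] == pytest.approx(13210, rel=0.002)
        assert table.loc["Environments", "ss"] == pytest.approx(6920, rel=0.002)
        assert table.loc["Interactions", "ss"] == pytest.approx(10057, rel=0.002)
        assert table.loc["Genotypes", "df"] == 31
        assert table.loc["Environments", "df"] == 5
        assert table.loc["Interactions", "df"] == 155

    def test_constant_matrix_all_zero(self):
        table = anova_from_means(_ge(np.full((4, 4), 3.0)))
        assert (table["ss"] == 0).all()

    def test_error_term_enables_f_tests(self, barley_ge):
        table = anova_from_means(barley_ge, error_ms=26.4, error_df=372).set_index("source")
        assert table.loc["Genotypes", "f_statistic"] == pytest.approx(16.16, rel=0.005)
        assert table.loc["Genotypes", "p_value"] < 1e-10


class TestAnovaTwoWay:
    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rep = simulate_ammi_trial(AMMISimSpec(G=5, E=4, r=3, lambdas=(6.0, 3.0), seed=7))
        table = anova_two_way(rep).set_index("source")
        df = rep.records
        fit = smf.ols("value ~ C(genotype) * C(environment)", data=df).fit()
        oracle = sm.stats.anova_lm(fit, typ=2)
        assert table.loc["Genotypes", "ss"] == pytest.approx(oracle.loc["C(genotype)", "sum_sq"], rel=1e-9)
        assert table.loc["Environments", "ss"] == pytest.approx(oracle.loc["C(environment)", "sum_sq"], rel=1e-9)
        assert table.loc["Interactions", "ss"] == pytest.approx(
            oracle.loc["C(genotype):C(environment)", "sum_sq"], rel=1e-9
        )
        assert table.loc["Error", "ss"] == pytest.approx(oracle.loc["Residual", "sum_sq"], rel=1e-9)
        assert table.loc["Genotypes", "f_statistic"] == pytest.approx(
            oracle.loc["C(genotype)", "F"], rel=1e-9
        )

    def test_single_replicate_refused(self):
        rep = simulate_ammi_trial(AMMISimSpec(G=4, E=4, r=1, lambdas=(), seed=0))
        with pytest.raises(ValueError, match="anova_from_means"):
            anova_two_way(rep)

    def test_null_genotype_f_averages_one(self):
        fs = []
        for seed in range(200):
            rep = simulate_ammi_trial(
                AMMISimSpec(G=6, E=4, r=3, genotype_sd=0, environment_sd=0,
                            lambdas=(), error_sd=1.0, seed=seed)
            )
            table = anova_two_way(rep).set_index("source")
            fs.append(table.loc["Genotypes", "f_statistic"])
        # E[F] = d2/(d2-2) = 48/46 for the null distribution here
        assert np.mean(fs) == pytest.approx(48 / 46, abs=0.12)

    def test_huge_effects_zero_noise_limit(self):
        rep = simulate_ammi_trial(
            AMMISimSpec(G=5, E=4, r=3, genotype_sd=50.0, lambdas=(),
                        error_sd=1e-6, seed=3)
        )
        table = anova_two_way(rep).set_index("source")
        assert table.loc["Genotypes", "p_value"] < 1e-200


class TestGollobAxisTests:
    def test_barley_axis_rows(self, barley_model):
        table = gollob_axis_tests(barley_model, error_ms=26.4, error_df=372, n_axes=3)
        table = table.set_index("source")
        assert table.loc["IPCA1", "df"] == 35
        assert table.loc["IPCA1", "ss"] == pytest.approx(4640, rel=0.002)
        assert table.loc["IPCA1", "f_statistic"] == pytest.approx(5.03, rel=0.01)
        assert table.loc["IPCA1", "p_value"] < 0.001
        assert table.loc["IPCA3", "df"] == 31
        assert table.loc["Residuals", "df"] == 56
        assert table.loc["Residuals", "f_statistic"] == pytest.approx(1.01, abs=0.02)

    def test_requesting_too_many_axes(self, barley_model):
        with pytest.raises(ValueError, match="n_axes"):
            gollob_axis_tests(barley_model, 26.4, 372, n_axes=6)

    def test_auto_axis_selection_uses_gollob(self, barley_ge):
        model = AMMI(n_components="auto", error_ms=26.4, error_df=372).fit(barley_ge)
        assert model.n_components_ == 3  # three significant axes at alpha=0.05


# ---------------------------------------------------------------------------
# biplots

class TestBiplotCoordinates:
    def test_ammi2_genotype_point(self, barley_model, barley_ge):
        coords = biplot_coordinates(barley_model, barley_ge, kind="ammi2")
        row = coords[coords["label"] == "R63N/1"].iloc[0]
        assert abs(row["x"]) == pytest.approx(0.281, abs=0.02)
        assert abs(row["y"]) == pytest.approx(0.328, abs=0.02)

    def test_ammi1_environment_point(self, barley_model, barley_ge):
        coords = biplot_coordinates(barley_model, barley_ge, kind="ammi1")
        row = coords[coords["label"] == "2012"].iloc[0]
        assert row["entity_type"] == "environment"
        assert row["x"] == pytest.approx(45.54, abs=0.005)
        assert abs(row["y"]) == pytest.approx(3.868, abs=0.02)
        assert coords.attrs["grand_mean"] == pytest.approx(44.80, abs=0.005)

    def test_zero_interaction_flat_ammi1(self, rng):
        alpha = rng.normal(size=5)
        beta = rng.normal(size=4)
        Y = 20.0 + alpha[:, None] + beta[None, :]
        with pytest.warns(RuntimeWarning, match="interaction sum of squares"):
            model = AMMI().fit(_ge(Y))
        coords = biplot_coordinates(model, _ge(Y), kind="ammi1")
        np.testing.assert_allclose(coords["y"], 0.0, atol=1e-8)
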