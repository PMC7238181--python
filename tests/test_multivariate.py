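"""Feature-table assembly, PCA with correlation loadings, flux regressions."""

import numpy as np
import pandas as pd
import pytest

from filadose import datasets
from filadose.multivariate import (
    DESCRIPTOR_COLUMNS,
    FEATURE_COLUMNS,
    FluxRegression,
    assemble_feature_table,
    fit_flux_model,
    run_pca,
)


class TestAssembly:
    def test_reference_study_gives_eight_rows_six_columns(self, feature_table):
        assert feature_table.shape == (8, 6)
        assert tuple(feature_table.columns) == FEATURE_COLUMNS
        assert not feature_table.isna().any().any()

    def test_single_solvent_subset(self, screen_results):
        flux = datasets.reference_flux_table()
        table = assemble_feature_table(
            screen_results,
            datasets.reference_mechanics_table(),
            flux[flux["solvent"] == "ethanol"],
            datasets.SATURATION_SOLUBILITY,
        )
        assert len(table) == 4

    def test_row_order_of_inputs_is_irrelevant(self, screen_results, feature_table):
        flux = datasets.reference_flux_table().iloc[::-1].reset_index(drop=True)
        mech = datasets.reference_mechanics_table().iloc[::-1].reset_index(drop=True)
        permuted = assemble_feature_table(
            screen_results, mech, flux, datasets.SATURATION_SOLUBILITY
        )
        pd.testing.assert_frame_equal(permuted, feature_table)

    def test_missing_combination_named_in_error(self, screen_results):
        flux = datasets.reference_flux_table()
        flux.loc[len(flux)] = ["acetone", "PVA", 0.1]
        with pytest.raises(KeyError, match="acetone"):
            assemble_feature_table(
                screen_results,
                datasets.reference_mechanics_table(),
                flux,
                {**datasets.SATURATION_SOLUBILITY, "acetone": 10.0},
            )

    def test_permeability_column_is_flux_over_csat(self, feature_table):
        for (solvent, _), row in feature_table.iterrows():
            assert row["permeability"] == pytest.approx(
                row["jss"] / datasets.SATURATION_SOLUBILITY[solvent], rel=1e-12
            )


class TestPca:
    def test_rank_one_table_explained_by_first_component(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        table = pd.DataFrame({"a": x, "b": 2 * x + 1})
        res = run_pca(table)
        assert res.explained_variance[0] == pytest.approx(1.0, abs=1e-12)

    def test_scores_centred_with_diagonal_covariance(self, feature_table):
        res = run_pca(feature_table)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)
        cov = np.cov(res.scores.to_numpy().T)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-10

    def test_loadings_match_eigendecomposition_oracle(self, feature_table):
        res = run_pca(feature_table)
        # independent oracle: eigenvectors of the correlation matrix
        x = feature_table.to_numpy(float)
        xs = (x - x.mean(0)) / x.std(0, ddof=1)
        corr = xs.T @ xs / (len(xs) - 1)
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        for j in range(res.loadings.shape[1]):
            v, w = res.loadings.iloc[:, j].to_numpy(), evecs[:, order[j]]
            assert min(np.max(np.abs(v - w)), np.max(np.abs(v + w))) < 1e-8

    def test_flux_loads_opposite_to_distance_and_stiffness(self, feature_table):
        res = run_pca(feature_table)
        pc1 = res.correlation_loadings["PC1"]
        flux_sign = np.sign(pc1["jss"])
        assert np.sign(pc1["permeability"]) == flux_sign
        for var in ("ra_solvent_filament", "toughness", "bending_modulus"):
            assert np.sign(pc1[var]) == -flux_sign

    def test_correlation_loadings_bounded(self, feature_table):
        cl = run_pca(feature_table).correlation_loadings.to_numpy()
        assert np.all(np.abs(cl) <= 1.0 + 1e-12)

    def test_zero_variance_column_named(self, feature_table):
        table = feature_table.copy()
        table["toughness"] = 1.0
        with pytest.raises(ValueError, match="toughness"):
            run_pca(table)


class TestRegression:
    def test_mlr_identifies_exact_linear_target(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(8, 4))
        table = pd.DataFrame(x, columns=DESCRIPTOR_COLUMNS)
        table["jss"] = x @ np.array([0.5, -1.0, 2.0, 0.1]) + 3.0
        res = fit_flux_model(table, "mlr")
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.rmse == pytest.approx(0.0, abs=1e-9)

    def test_svm_predictions_match_kernel_expansion_oracle(self, feature_table):
        res = fit_flux_model(feature_table, "svm_rbf")
        est = res._estimator
        x = feature_table[list(DESCRIPTOR_COLUMNS)].to_numpy(float)
        x_mean, x_sd, y_mean, y_sd = res._scaling
        xs = (x - x_mean) / x_sd
        gamma = est._gamma if hasattr(est, "_gamma") else est.gamma
        sv, alpha, b = est.support_vectors_, est.dual_coef_[0], est.intercept_[0]
        manual = np.array(
            [
                sum(
                    a * np.exp(-gamma * np.sum((xi - svj) ** 2))
                    for a, svj in zip(alpha, sv)
                )
                + b
                for xi in xs
            ]
        )
        direct = manual * y_sd + y_mean
        assert np.max(np.abs(direct - res.predictions.to_numpy())) < 1e-8

    def test_constant_target_predicts_the_constant(self):
        table = pd.DataFrame(
            np.random.default_rng(1).normal(size=(6, 4)), columns=DESCRIPTOR_COLUMNS
        )
        table["jss"] = 0.2
        res = fit_flux_model(table, "svm_rbf")
        assert np.allclose(res.predictions, 0.2, atol=1e-6)

    def test_training_row_prediction_within_epsilon_tube(self, feature_table):
        res = fit_flux_model(feature_table, "svm_rbf")
        y = feature_table["jss"].to_numpy()
        y_sd = y.std()
        eps = res.hyperparameters["epsilon"]
        assert np.all(np.abs(res.predictions.to_numpy() - y) <= 2 * eps * y_sd + 1e-8)

    def test_out_of_schema_descriptors_rejected(self, feature_table):
        res = fit_flux_model(feature_table, "svm_rbf")
        with pytest.raises(KeyError, match="bending_modulus"):
            res.predict({"ra_solvent_filament": 10.0})

    def test_affine_rescaling_of_an_input_column_is_invisible(self, feature_table):
        base = fit_flux_model(feature_table, "svm_rbf")
        rescaled_table = feature_table.copy()
        rescaled_table["toughness"] = rescaled_table["toughness"] * 1000.0
        rescaled = fit_flux_model(rescaled_table, "svm_rbf")
        assert np.max(
            np.abs(base.predictions.to_numpy() - rescaled.predictions.to_numpy())
        ) < 1e-8

    def test_svm_not_worse_than_mlr_on_reference_table(self, feature_table):
        svm = fit_flux_model(feature_table, "svm_rbf")
        mlr = fit_flux_model(feature_table, "mlr")
        assert svm.r_squared >= mlr.r_squared

    def test_pls_components_bounded_by_rows(self, feature_table):
        with pytest.raises(ValueError):
            FluxRegression(feature_table.iloc[:3], "pls", pls_components=5)

    def test_loo_tuning_mode_runs(self, feature_table):
        res = FluxRegression(feature_table, "svm_rbf", svm_tune="loo").fit()
        assert res.loo_r_squared is not None
        assert res.rmse >= 0
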