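import numpy as np
import pandas as pd
import pytest

from phaseomics.benchmark import (ALPHA_GRID, FeatureTable, ModelSpec,
                                  build_supervised_table, fit_scaler,
                                  rank_models, run_loocv)
from phaseomics.simulate import SimulationConfig, simulate_dataset

import oracles
from conftest import make_matrix


def tiny_table(y_values, x_values=None):
    """Hand-built FeatureTable with one feature and one target."""
    n = len(y_values)
    idx = [f"WT_r{i + 1}" for i in range(n)]
    x = x_values if x_values is not None else list(range(n))
    X = pd.DataFrame({"metab_t0|M1": np.asarray(x, float)}, index=idx)
    Y = pd.DataFrame({"P1": np.asarray(y_values, float)}, index=idx)
    meta = pd.DataFrame({"strain": ["WT"] * n, "replicate": range(1, n + 1)},
                        index=idx)
    return FeatureTable(X=X, Y=Y, row_meta=meta,
                        col_modality={"metab_t0|M1": "metabolomics",
                                      "P1": "proteomics"},
                        dropped={})


@pytest.fixture(scope="module")
def sim_table():
    cfg = SimulationConfig(n_metabolites=10, n_proteins=4, n_pathways=2,
                           frac_affected=0.5, noise_sd_log2=0.1,
                           protein_noise_sd_log2=0.02, seed=31,
                           phases=("OD0.6", "OD2.0"))
    _, metab, prot = simulate_dataset(cfg, censor=False)
    return build_supervised_table(metab["OD0.6"], metab["OD2.0"],
                                  prot["OD0.6"], prot["OD2.0"])


class TestBuildTable:
    def test_eight_rows_from_four_replicates(self, sim_table):
        assert sim_table.X.shape[0] == 8
        assert sim_table.Y.shape[0] == 8

    def test_missing_feature_dropped_and_logged(self):
        cfg = SimulationConfig(n_metabolites=8, n_proteins=3, n_pathways=2,
                               seed=5, phases=("OD0.6", "OD2.0"))
        _, metab, prot = simulate_dataset(cfg, censor=False)
        m0 = metab["OD0.6"]
        data = m0.data.copy()
        data.iloc[0, 0] = np.nan
        m0 = m0.with_data(data)
        t = build_supervised_table(m0, metab["OD2.0"], prot["OD0.6"],
                                   prot["OD2.0"])
        fid = data.index[0]
        assert f"metab_t0|{fid}" not in t.X.columns
        assert fid in t.dropped["metab_t0"]
        assert f"metab_t1|{fid}" in t.X.columns

    def test_mismatched_replicates_error(self):
        cfg = SimulationConfig(n_metabolites=6, n_proteins=2, n_pathways=2,
                               seed=6, phases=("OD0.6", "OD2.0"))
        _, metab, prot = simulate_dataset(cfg, censor=False)
        short = prot["OD2.0"].subset_samples(prot["OD2.0"].sample_ids[:-1])
        with pytest.raises(ValueError, match="does not match"):
            build_supervised_table(metab["OD0.6"], metab["OD2.0"],
                                   prot["OD0.6"], short)


class TestMeanBaselineClosedForm:
    def test_two_row_closed_form(self):
        # train-mean predictor on targets [0, 2]: predictions [2, 0], MSE 4
        res = run_loocv(tiny_table([0.0, 2.0]), ModelSpec("Mean"),
                        scale_within_fold=False)
        assert list(res.predictions["P1"]) == [2.0, 0.0]
        assert res.mse == 4.0

    def test_four_row_closed_form(self):
        y = [1.0, 3.0, 5.0, 9.0]
        res = run_loocv(tiny_table(y), ModelSpec("Mean"),
                        scale_within_fold=False)
        assert res.mse == pytest.approx(oracles.mean_baseline_loocv_mse(y),
                                        abs=1e-14)


class TestRunLOOCV:
    def test_ridge_interpolates_noiseless_linear(self):
        # y = 2x exactly; tiny regularization floor -> near-zero LOOCV error
        y = [0.0, 2.0, 4.0, 6.0, 8.0, 10.0]
        spec = ModelSpec("Ridge", hyperparameters={"alpha_grid": [1e-8]})
        res = run_loocv(tiny_table(y), spec, scale_within_fold=False)
        assert res.mse < 1e-6

    def test_row_permutation_invariant_for_deterministic_families(self, sim_table):
        rng = np.random.default_rng(0)
        perm = rng.permutation(sim_table.X.index)
        shuffled = FeatureTable(X=sim_table.X.loc[perm],
                                Y=sim_table.Y.loc[perm],
                                row_meta=sim_table.row_meta.loc[perm],
                                col_modality=sim_table.col_modality,
                                dropped=sim_table.dropped)
        for fam in ("Ridge", "Lasso", "PLS"):
            a = run_loocv(sim_table, ModelSpec(fam))
            b = run_loocv(shuffled, ModelSpec(fam))
            assert a.mse == pytest.approx(b.mse, rel=1e-9)

    def test_tree_families_bit_stable_under_seed(self, sim_table):
        for fam in ("RandomForest", "GBT"):
            a = run_loocv(sim_table, ModelSpec(fam, seed=7))
            b = run_loocv(sim_table, ModelSpec(fam, seed=7))
            assert a.mse == b.mse
            pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_fold_scalers_estimated_on_training_rows_only(self, sim_table):
        res = run_loocv(sim_table, ModelSpec("Ridge"))
        for held_out, scalers in zip(res.fold_assignment, res.fold_scalers):
            train = sim_table.X.loc[sim_table.X.index != held_out]
            expected = fit_scaler(train, sim_table.col_modality)
            for col, got in scalers["X"].items():
                assert got == pytest.approx(expected[col])

    def test_constant_target_skipped_with_warning(self):
        t = tiny_table([1.0, 1.0, 1.0, 1.0])
        with pytest.warns(RuntimeWarning, match="constant"):
            res = run_loocv(t, ModelSpec("Ridge"), scale_within_fold=False)
        assert res.skipped_targets == ["P1"]

    def test_pure_noise_feature_changes_mse_under_10pct(self, sim_table):
        base = run_loocv(sim_table, ModelSpec("Ridge"))
        rng = np.random.default_rng(99)
        X2 = sim_table.X.copy()
        X2["metab_t0|NOISE"] = rng.normal(size=len(X2))
        mod = dict(sim_table.col_modality)
        mod["metab_t0|NOISE"] = "metabolomics"
        noisy = FeatureTable(X=X2, Y=sim_table.Y, row_meta=sim_table.row_meta,
                             col_modality=mod, dropped=sim_table.dropped)
        res = run_loocv(noisy, ModelSpec("Ridge"))
        assert abs(res.mse - base.mse) / base.mse < 0.10


class TestRankModels:
    def test_orders_by_mse(self, sim_table):
        a = run_loocv(sim_table, ModelSpec("Ridge"))
        b = run_loocv(sim_table, ModelSpec("Mean"))
        ranking = rank_models([a, b])
        assert list(ranking["mse"]) == sorted(ranking["mse"])

    def test_alphabetical_tiebreak(self, sim_table):
        a = run_loocv(sim_table, ModelSpec("Ridge"))
        b = run_loocv(sim_table, ModelSpec("Ridge"))
        b.family = "Aardvark"
        ranking = rank_models([a, b])
        assert list(ranking["family"]) == ["Aardvark", "Ridge"]

    def test_single_result_errors(self, sim_table):
        with pytest.raises(ValueError, match="at least 2"):
            rank_models([run_loocv(sim_table, ModelSpec("Mean"))])

    def test_different_tables_error(self, sim_table):
        other = tiny_table([0.0, 1.0, 2.0])
        a = run_loocv(sim_table, ModelSpec("Mean"))
        b = run_loocv(other, ModelSpec("Mean"), scale_within_fold=False)
        with pytest.raises(ValueError, match="different tables"):
            rank_models([a, b])


class TestRidgeOracle:
    def test_closed_form_agreement(self):
        # sklearn Ridge (no intercept fitting quirks) vs normal equations
        rng = np.random.default_rng(55)
        from sklearn.linear_model import Ridge
        for _ in range(50):
            n, d = int(rng.integers(5, 12)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, d))
            y = rng.normal(size=n)
            alpha = float(rng.choice(ALPHA_GRID))
            est = Ridge(alpha=alpha).fit(X, y)
            beta, b0 = oracles.ridge_closed_form(X, y, alpha)
            np.testing.assert_allclose(est.coef_, beta, atol=1e-8)
            np.testing.assert_allclose(est.intercept_, b0, atol=1e-8)
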