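import numpy as np
import pandas as pd
import pytest

from phaseomics.datamodel import PathwayAnnotation
from phaseomics.gat import (GATConfig, GATModel, OmicsGraph, TrainingSchedule,
                            assemble_node_features, attention_coefficients,
                            build_graph, eligible_proteins, gat_loocv,
                            predict_protein_abundance, train_gat)
from phaseomics.benchmark import build_supervised_table
from phaseomics.simulate import SimulationConfig, simulate_dataset


def small_graph():
    ann = PathwayAnnotation.from_pairs([
        ("M1", "Glycolysis"), ("M2", "Glycolysis"), ("M3", "PPP"),
        ("P1", "Glycolysis"), ("P2", "PPP"), ("P3", "Quorum"),
    ])
    return build_graph(ann, ["M1", "M2", "M3"], ["P1", "P2", "P3"])


class TestBuildGraph:
    def test_shared_pathway_edge(self):
        g = small_graph()
        i, j = g.index_of("M1"), g.index_of("P1")
        assert tuple(sorted((i, j))) in set(g.edges)

    def test_no_shared_pathway_no_edge(self):
        g = small_graph()
        i, j = sorted((g.index_of("M3"), g.index_of("P1")))
        assert (i, j) not in set(g.edges)

    def test_double_shared_pathway_single_edge(self):
        ann = PathwayAnnotation.from_pairs([
            ("M1", "Glycolysis"), ("M1", "PPP"),
            ("P1", "Glycolysis"), ("P1", "PPP")])
        g = build_graph(ann, ["M1"], ["P1"])
        assert len(g.edges) == 1
        assert g.provenance[g.edges[0]] == frozenset({"Glycolysis", "PPP"})

    def test_id_in_both_lists_errors(self):
        ann = PathwayAnnotation.from_pairs([("X", "PW")])
        with pytest.raises(ValueError, match="both lists"):
            build_graph(ann, ["X"], ["X"])

    def test_deterministic_node_order(self):
        g = small_graph()
        assert g.node_ids == ["M1", "M2", "M3", "P1", "P2", "P3"]


class TestEligibleProteins:
    def test_isolated_protein_excluded(self):
        g = small_graph()
        assert "P3" not in eligible_proteins(g)

    def test_connected_protein_included(self):
        assert set(eligible_proteins(small_graph())) == {"P1", "P2"}

    def test_empty_edges_empty_list(self):
        ann = PathwayAnnotation.from_pairs([("M1", "A"), ("P1", "B")])
        g = build_graph(ann, ["M1"], ["P1"])
        assert eligible_proteins(g) == []


class TestAttention:
    def _model(self, cfg=None):
        g = small_graph()
        return g, GATModel(g, in_dim=3, cfg=cfg or GATConfig(hidden_dim=8,
                                                             heads=2,
                                                             dropout=0.0),
                           seed=1)

    def test_rows_sum_to_one(self):
        g, model = self._model()
        X = np.random.default_rng(0).normal(size=(2, g.n_nodes, 3))
        alpha, src, dst = attention_coefficients(
            X, model.params["W1_0"], model.params["ar1_0"],
            model.params["as1_0"], model.src, model.dst, 0.2)
        sums = np.zeros((2, g.n_nodes))
        np.add.at(sums, (np.arange(2)[:, None], dst), alpha)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_isolated_node_self_attention_only(self):
        g, model = self._model()
        iso = g.index_of("P3")  # no neighbours -> only self loop
        X = np.random.default_rng(1).normal(size=(1, g.n_nodes, 3))
        alpha, src, dst = attention_coefficients(
            X, model.params["W1_0"], model.params["ar1_0"],
            model.params["as1_0"], model.src, model.dst, 0.2)
        sel = dst == iso
        assert sel.sum() == 1
        assert src[sel][0] == iso
        np.testing.assert_allclose(alpha[:, sel], 1.0, atol=1e-12)

    def test_identical_z_uniform_attention(self):
        g, model = self._model()
        X = np.ones((1, g.n_nodes, 3))  # all z identical -> uniform alpha
        alpha, src, dst = attention_coefficients(
            X, model.params["W1_0"], model.params["ar1_0"],
            model.params["as1_0"], model.src, model.dst, 0.2)
        deg = np.bincount(dst, minlength=g.n_nodes)
        np.testing.assert_allclose(alpha[0], 1.0 / deg[dst], atol=1e-12)


class TestSchedule:
    def test_lr_at_epoch_250(self):
        sched = TrainingSchedule()
        assert sched.lr_at(250) == pytest.approx(0.00025)

    def test_final_lr_after_300_epochs(self):
        sched = TrainingSchedule()
        assert sched.lr_at(299) == pytest.approx(0.001 * 0.5 ** 2)

    def test_invalid(self):
        with pytest.raises(ValueError):
            TrainingSchedule(epochs=0)
        with pytest.raises(ValueError):
            TrainingSchedule(gamma=1.5)


class TestGradients:
    def test_finite_difference_check(self):
        # 6-node fixture; 5%+ of parameters sampled per tensor
        g = small_graph()
        cfg = GATConfig(hidden_dim=8, heads=2, dropout=0.0)
        model = GATModel(g, in_dim=3, cfg=cfg, seed=3)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2, g.n_nodes, 3))
        elig = eligible_proteins(g)
        tn = np.array([g.index_of(p) for p in elig])
        Y = rng.normal(size=(2, len(tn)))
        _, grads = model.loss_and_grads(X, Y, tn, train=True)
        eps = 1e-5
        for k, p in model.params.items():
            flat = p.ravel()
            n_check = max(1, flat.size // 20)
            for i in rng.choice(flat.size, size=n_check, replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = model.loss_and_grads(X, Y, tn, train=True)
                flat[i] = orig - eps
                lm, _ = model.loss_and_grads(X, Y, tn, train=True)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[k].ravel()[i]
                denom = max(abs(num), abs(ana), 1e-8)
                assert abs(num - ana) / denom < 1e-4, (k, i)


class TestEquivariance:
    def test_node_permutation(self):
        g = small_graph()
        cfg = GATConfig(hidden_dim=8, heads=2, dropout=0.0)
        model = GATModel(g, in_dim=3, cfg=cfg, seed=5)
        rng = np.random.default_rng(7)
        X = rng.normal(size=(2, g.n_nodes, 3))
        out = model.predict(X)

        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        g2 = OmicsGraph(
            node_ids=[g.node_ids[i] for i in perm],
            kinds=[g.kinds[i] for i in perm],
            edges=[tuple(sorted((int(inv[i]), int(inv[j]))))
                   for i, j in g.edges],
            provenance={})
        model2 = GATModel(g2, in_dim=3, cfg=cfg, seed=5)
        model2.params = {k: v.copy() for k, v in model.params.items()}
        model2.bn_mean, model2.bn_var = model.bn_mean, model.bn_var
        out2 = model2.predict(X[:, perm, :])
        np.testing.assert_allclose(out2, out[:, perm], atol=1e-10)


class TestTraining:
    def _dataset(self, noise=0.0, pnoise=0.0, seed=2):
        cfg = SimulationConfig(n_metabolites=8, n_proteins=4, n_pathways=2,
                               frac_affected=0.5, noise_sd_log2=noise,
                               protein_noise_sd_log2=pnoise, seed=seed,
                               phases=("OD0.6", "OD2.0"))
        truth, metab, prot = simulate_dataset(cfg, censor=False)
        table = build_supervised_table(metab["OD0.6"], metab["OD2.0"],
                                       prot["OD0.6"], prot["OD2.0"])
        g = build_graph(truth.pathway_assignment,
                        metab["OD0.6"].feature_ids, prot["OD0.6"].feature_ids)
        return truth, table, g

    def _train(self, table, g, epochs=200, seed=0, dropout=0.3):
        from phaseomics.benchmark import apply_scaler, fit_scaler
        elig = [p for p in eligible_proteins(g) if p in table.Y.columns]
        tn = np.array([g.index_of(p) for p in elig])
        xs = fit_scaler(table.X, table.col_modality)
        ys = fit_scaler(table.Y[elig], table.col_modality)
        X = assemble_node_features(g, apply_scaler(table.X, xs))
        Y = apply_scaler(table.Y[elig], ys).to_numpy()
        cfg = GATConfig(dropout=dropout)
        model = GATModel(g, in_dim=3, cfg=cfg, seed=seed)
        sched = TrainingSchedule(epochs=epochs, seed=seed)
        return train_gat(model, X, Y, tn, sched), X, Y, tn, elig

    def test_noiseless_training_converges(self):
        _, table, g = self._dataset()
        trained, X, Y, tn, _ = self._train(table, g, epochs=300, dropout=0.0)
        final_mse = trained.loss_trajectory[-1]
        assert final_mse <= 1e-2 * np.var(Y) + 1e-3

    def test_same_seed_identical_trajectory(self):
        _, table, g = self._dataset(noise=0.1)
        a, *_ = self._train(table, g, epochs=30, seed=4)
        b, *_ = self._train(table, g, epochs=30, seed=4)
        assert a.loss_trajectory == b.loss_trajectory

    def test_inference_deterministic_and_dropout_off(self):
        _, table, g = self._dataset()
        trained, X, *_ = self._train(table, g, epochs=30)
        p1 = trained.model.predict(X)
        p2 = trained.model.predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_ineligible_protein_prediction_errors(self):
        ann = PathwayAnnotation.from_pairs(
            [("M1", "A"), ("P1", "A"), ("P2", "B")])
        g = build_graph(ann, ["M1"], ["P1", "P2"])
        cfg = GATConfig(hidden_dim=8, heads=2, dropout=0.0)
        model = GATModel(g, in_dim=3, cfg=cfg, seed=0)
        X = np.zeros((1, g.n_nodes, 3))
        trained = train_gat(model, X, np.zeros((1, 1)),
                            np.array([g.index_of("P1")]),
                            TrainingSchedule(epochs=2))
        with pytest.raises(ValueError, match="not eligible"):
            predict_protein_abundance(trained, X, ["P2"])

    def test_feature_layout_mismatch_errors(self):
        g = small_graph()
        model = GATModel(g, in_dim=3,
                         cfg=GATConfig(hidden_dim=8, heads=2, dropout=0.0),
                         seed=0)
        with pytest.raises(ValueError, match="layout"):
            model.predict(np.zeros((1, g.n_nodes + 1, 3)))

    def test_loocv_deterministic(self):
        _, table, g = self._dataset(noise=0.1, pnoise=0.05)
        sched = TrainingSchedule(epochs=25, seed=9)
        a = gat_loocv(g, table, GATConfig(), sched)
        b = gat_loocv(g, table, GATConfig(), sched)
        pd.testing.assert_frame_equal(a.predictions, b.predictions)
        assert a.mse == b.mse


class TestConfigValidation:
    def test_hidden_not_divisible_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            GATConfig(hidden_dim=10, heads=4)

    def test_per_head_width(self):
        assert GATConfig().per_head == 32
        assert GATConfig(hidden_dim=16, heads=4,
                         hidden_is_total=False).per_head == 16
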