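"""Sparse layers, batch normalisation, losses, and the training loop."""

import numpy as np
import pytest

from annonet.annotations import AnnotationError
from annonet.simulate import SimulationConfig, simulate_dataset
from annonet.sparsenet import (
    Adadelta,
    Adam,
    BatchNorm,
    EarlyStopper,
    NetworkSpec,
    SparseLayer,
    TrainConfig,
    all_to_one,
    assemble,
    batchnorm_plain,
    class_weights_from_labels,
    hyperparameter_grid,
    l1_term,
    select_best,
    sparse_forward,
    train,
    weighted_bce,
)

from conftest import dense_mask_and_weights, random_connectivity_matrix


class TestSparseForward:
    def test_zero_weights_give_zero_output(self, rng, four_variant_cm):
        layer = SparseLayer(four_variant_cm, "tanh")
        out = sparse_forward(layer, rng.standard_normal((8, 4)))
        assert np.all(out == 0)

    def test_identity_connectivity_is_identity(self, rng):
        n = 5
        cm = random_connectivity_matrix(rng, n, n, n * n, "full")
        # use a diagonal instead: build explicitly
        from annonet.annotations import ConnectivityMatrix
        cm = ConnectivityMatrix(tuple(f"i{k}" for k in range(n)),
                                tuple(f"o{k}" for k in range(n)),
                                np.arange(n), np.arange(n), "diag")
        layer = SparseLayer(cm, "linear")
        layer.w = np.ones(n)
        x = rng.standard_normal((6, n))
        assert np.allclose(sparse_forward(layer, x), x)

    def test_matches_masked_dense_matmul(self, rng):
        cm = random_connectivity_matrix(rng, 6, 3, 10)
        layer = SparseLayer(cm, "tanh")
        layer.initialize(rng)
        layer.b = rng.standard_normal(3)
        x = rng.standard_normal((16, 6))
        _, dense = dense_mask_and_weights(layer)
        expected = np.tanh(x @ dense + layer.b)
        assert np.abs(sparse_forward(layer, x) - expected).max() < 1e-6

    def test_shape_mismatch_raises(self, rng, four_variant_cm):
        layer = SparseLayer(four_variant_cm)
        with pytest.raises(ValueError, match="width"):
            layer.forward(rng.standard_normal((4, 5)))

    def test_gradients_match_finite_differences(self, rng):
        cm = random_connectivity_matrix(rng, 8, 4, 14)
        layer = SparseLayer(cm, "tanh")
        layer.initialize(rng)
        x = rng.standard_normal((5, 8))
        out, cache = layer.forward(x, capture=True)
        _, dw, db = layer.backward(np.ones_like(out), cache)
        eps = 1e-6
        for k in range(layer.w.size):
            layer.w[k] += eps
            up = layer.forward(x).sum()
            layer.w[k] -= 2 * eps
            dn = layer.forward(x).sum()
            layer.w[k] += eps
            assert abs((up - dn) / (2 * eps) - dw[k]) < 1e-5


class TestBatchNorm:
    def test_standardized_input_passes_through(self, rng):
        x = rng.standard_normal((200, 4))
        x = (x - x.mean(0)) / x.std(0)
        out = batchnorm_plain(x)
        assert np.abs(out - x).max() < 0.01  # eps shrinks slightly

    def test_constant_column_maps_to_zero_not_nan(self):
        x = np.full((10, 2), 3.0)
        out = batchnorm_plain(x)
        assert np.all(np.isfinite(out)) and np.abs(out).max() < 1e-9

    def test_hand_computed_column(self):
        out = batchnorm_plain(np.array([[1.0], [2.0], [3.0]]))
        expected = np.array([-1.2247, 0.0, 1.2247])
        assert np.abs(out.ravel() - expected).max() < 1e-3  # eps=1e-3 effect

    def test_inference_uses_running_moments(self, rng):
        bn = BatchNorm(3, momentum=0.0)  # running moments = last batch
        x = rng.standard_normal((50, 3)) * 2 + 1
        bn.forward(x, training=True)
        out, _ = bn.forward(x, training=False)
        assert np.abs(out.mean(0)).max() < 1e-9

    def test_backward_matches_finite_differences(self, rng):
        x = rng.standard_normal((7, 3))
        bn = BatchNorm(3)
        _, cache = bn.forward(x, training=True)
        r = rng.standard_normal((7, 3))
        dx = BatchNorm.backward(r, cache)
        eps = 1e-6
        for i in range(7):
            for j in range(3):
                xp = x.copy(); xp[i, j] += eps
                xm = x.copy(); xm[i, j] -= eps
                fp = (BatchNorm(3).forward(xp, True)[0] * r).sum()
                fm = (BatchNorm(3).forward(xm, True)[0] * r).sum()
                assert abs((fp - fm) / (2 * eps) - dx[i, j]) < 1e-5


class TestLosses:
    def test_confident_correct_prediction_has_near_zero_loss(self):
        assert weighted_bce(np.ones(4), np.full(4, 1 - 1e-9)) < 1e-5

    def test_uninformative_prediction_is_ln2(self):
        assert weighted_bce(np.ones(3), np.full(3, 0.5)) == pytest.approx(np.log(2))

    def test_balanced_labels_give_unit_weights(self):
        w0, w1 = class_weights_from_labels(np.array([0, 1, 0, 1]))
        assert w0 == 1.0 and w1 == 1.0

    def test_imbalanced_weights_proportional_to_inverse_frequency(self):
        w0, w1 = class_weights_from_labels(np.array([0, 0, 0, 1]))
        assert w0 == pytest.approx(4 / 6) and w1 == pytest.approx(4 / 2)

    def test_single_class_dataset_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            class_weights_from_labels(np.ones(5))

    def test_l1_term_closed_forms(self, four_variant_cm):
        net = NetworkSpec(layers=[SparseLayer(all_to_one(["a", "b"]), "sigmoid")])
        net.layers[0].w = np.array([0.5, -0.5])
        net.l1_penalty = 0.1
        assert l1_term(net) == pytest.approx(0.1)
        net.l1_penalty = 0.0
        assert l1_term(net) == 0.0


class TestAssemble:
    def _stack(self):
        from annonet.annotations import AnnotationTable, build_pathway_stack, \
            build_snp_gene_matrix
        snp_gene = AnnotationTable.from_pairs(
            [(f"v{i}", f"g{i // 2}") for i in range(12)])
        cm, _ = build_snp_gene_matrix(snp_gene, [f"v{i}" for i in range(12)])
        tables = [
            AnnotationTable.from_pairs([(f"g{i}", f"loc{i // 2}") for i in range(6)],
                                       "gene_pathway_level"),
            AnnotationTable.from_pairs([("loc0", "mid0"), ("loc1", "mid0"),
                                        ("loc2", "mid1")], "gene_pathway_level"),
            AnnotationTable.from_pairs([("mid0", "glob0"), ("mid1", "glob1")],
                                       "gene_pathway_level"),
        ]
        stack, _ = build_pathway_stack(tables)
        return [cm] + stack

    def test_single_matrix_becomes_two_layer_net(self, four_variant_cm):
        net = assemble([four_variant_cm])
        assert len(net.layers) == 2
        assert net.layers[0].activation == "tanh"
        assert net.layers[1].activation == "sigmoid"
        assert net.layers[1].n_out == 1

    def test_pathway_stack_becomes_five_layer_net(self):
        net = assemble(self._stack())
        assert len(net.layers) == 5
        assert net.layers[-1].n_out == 1

    def test_regression_uses_relu_hidden_and_linear_output(self, four_variant_cm):
        net = assemble([four_variant_cm], task="regression")
        assert net.layers[0].activation == "relu"
        assert net.layers[-1].activation == "linear"

    def test_unchained_stack_rejected(self, four_variant_cm):
        from annonet.annotations import ConnectivityMatrix
        bad = ConnectivityMatrix(("gB", "gA"), ("p",),
                                 np.array([0, 1]), np.array([0, 0]))
        with pytest.raises(AnnotationError):
            assemble([four_variant_cm, bad])

    def test_parameter_count_is_links_plus_biases(self):
        matrices = self._stack()
        net = assemble(matrices)
        expected = sum(m.n_links for m in matrices) + matrices[-1].n_outputs  # final layer
        expected += sum(m.n_outputs for m in matrices) + 1  # biases incl output
        assert net.n_params == expected
        dense = sum(l.n_in * l.n_out + l.n_out for l in net.layers)
        assert dense > net.n_params


class TestEarlyStopping:
    def test_stops_patience_epochs_after_best(self):
        stopper = EarlyStopper(patience=10)
        losses = [1.0, 0.8, 0.6] + [0.6 + 0.01 * k for k in range(1, 30)]
        stopped_at = None
        for epoch, loss in enumerate(losses):
            stopper.update(epoch, loss)
            if stopper.stop:
                stopped_at = epoch
                break
        assert stopper.best_epoch == 2
        assert stopped_at == 12  # 10 epochs after the best

    def test_improvement_resets_patience(self):
        stopper = EarlyStopper(patience=3)
        for epoch, loss in enumerate([1.0, 0.9, 0.95, 0.85, 0.9, 0.95, 0.96]):
            stopper.update(epoch, loss)
        assert stopper.stop and stopper.best_epoch == 3


def _toy_training_data(seed=0, n=1200, h2=0.99):
    cfg = SimulationConfig(n_samples=n, n_variants=40, n_genes=8,
                           variants_per_gene=5, h2=h2, polygenicity=0.25,
                           seed=seed)
    data = simulate_dataset(cfg)
    X = data.genotypes.astype(float)
    y = data.labels.astype(float)
    k = int(0.7 * n)
    return data, (X[:k], y[:k], X[k:], y[k:])


class TestTrain:
    def test_high_heritability_signal_is_learned(self):
        data, (Xtr, ytr, Xva, yva) = _toy_training_data()
        from annonet.annotations import build_snp_gene_matrix
        cm, _ = build_snp_gene_matrix(data.annotation, data.variant_ids)
        net = assemble([cm])
        cfg = TrainConfig(learning_rate=0.01, max_epochs=50, seed=1)
        result = train(net, Xtr, ytr, Xva, yva, cfg)
        assert result.history["val_auc"].max() > 0.95

    def test_determinism_identical_history_for_identical_seed(self):
        data, (Xtr, ytr, Xva, yva) = _toy_training_data()
        from annonet.annotations import build_snp_gene_matrix
        cm, _ = build_snp_gene_matrix(data.annotation, data.variant_ids)
        cfg = TrainConfig(learning_rate=0.01, max_epochs=8, seed=7)
        h1 = train(assemble([cm]), Xtr, ytr, Xva, yva, cfg).history
        h2 = train(assemble([cm]), Xtr, ytr, Xva, yva, cfg).history
        assert h1.equals(h2)

    def test_l1_drives_weights_to_zero_on_pure_noise(self, rng):
        n, m = 400, 20
        X = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        net = assemble([all_to_one([f"v{i}" for i in range(m)], "g")])
        cfg = TrainConfig(learning_rate=1e-3, l1_penalty=0.1, max_epochs=2000,
                          patience_epochs=2000, seed=0)
        train(net, X[:300], y[:300], X[300:], y[300:], cfg)
        assert max(np.abs(l.w).max() for l in net.layers) < 1e-3

    def test_restores_best_epoch_weights(self):
        data, (Xtr, ytr, Xva, yva) = _toy_training_data(seed=3)
        from annonet.annotations import build_snp_gene_matrix
        cm, _ = build_snp_gene_matrix(data.annotation, data.variant_ids)
        net = assemble([cm])
        cfg = TrainConfig(learning_rate=0.05, max_epochs=40, seed=2)
        result = train(net, Xtr, ytr, Xva, yva, cfg)
        from annonet.sparsenet import weighted_bce as bce
        restored_loss = bce(yva, net.predict(Xva),
                            class_weights_from_labels(ytr)) + l1_term(net)
        assert restored_loss == pytest.approx(
            result.history["val_loss"].min(), abs=1e-9)


class TestHyperparameterGrid:
    def test_grid_is_cartesian_product_of_sixteen(self):
        grid = hyperparameter_grid()
        assert len(grid) == 16
        assert len({(c.optimizer, c.learning_rate, c.l1_penalty) for c in grid}) == 16
        assert {c.l1_penalty for c in grid} == {0.1, 0.001, 0.00001, 0.0}
        assert sum(c.optimizer == "adadelta" for c in grid) == 4

    def test_selection_argmax_with_low_penalty_tie_break(self):
        grid = hyperparameter_grid()
        aucs = [0.5] * len(grid)
        aucs[3] = 0.9
        assert select_best(grid, aucs) is grid[3]
        aucs = [0.7] * len(grid)  # full tie -> lowest penalty wins
        assert select_best(grid, aucs).l1_penalty == 0.0


class TestOptimizers:
    @pytest.mark.parametrize("opt", [Adam(lr=0.05), Adadelta(lr=1.0)])
    def test_minimizes_quadratic(self, opt):
        p = np.array([5.0, -3.0])
        for _ in range(3000):
            opt.step([p], [2 * p])
        assert np.abs(p).max() < 0.05
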