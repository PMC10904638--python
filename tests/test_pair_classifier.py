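import math

import numpy as np
import pytest

from ddifusion.graph_views import InteractionDataset
from ddifusion.pair_classifier import (
    PRESETS,
    DualViewModel,
    FoldSpec,
    TrainConfig,
    binary_loss,
    combine_pair,
    combine_pairs,
    dnn_forward,
    multiclass_loss,
    train,
)

from _oracles import binary_loss_oracle, multiclass_loss_oracle, random_graph
from conftest import TINY_TRAIN


class TestCombinePair:
    def test_concatenation_doubles_length(self, rng):
        e_i, e_j = rng.random(7), rng.random(7)
        out = combine_pair(e_i, e_j, "concatenation")
        assert out.shape == (14,)
        np.testing.assert_array_equal(out[:7], e_i)

    def test_average_of_identical_is_identity(self, rng):
        e = rng.random(5)
        np.testing.assert_allclose(combine_pair(e, e, "average"), e)

    def test_hadamard_annihilated_by_zero(self, rng):
        np.testing.assert_array_equal(
            combine_pair(rng.random(5), np.zeros(5), "hadamard"), np.zeros(5)
        )

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            combine_pair(np.ones(2), np.ones(2), "sum")

    def test_batch_combination_canonicalizes_pair_order(self, rng):
        emb = rng.random((6, 4))
        for method in ("concatenation", "average", "hadamard"):
            fwd = combine_pairs(emb, np.array([[1, 4]]), method)
            rev = combine_pairs(emb, np.array([[4, 1]]), method)
            np.testing.assert_array_equal(fwd, rev)


class TestLosses:
    def test_closed_forms(self):
        assert binary_loss([1], [0.5]) == pytest.approx(math.log(2), abs=1e-12)
        assert binary_loss([1, 0], [1.0, 0.0]) == pytest.approx(0.0, abs=1e-5)
        r = 7
        uniform = np.full((3, r), 1.0 / r)
        onehot = np.eye(r)[[0, 3, 6]]
        assert multiclass_loss(onehot, uniform) == pytest.approx(3 * math.log(r), rel=1e-9)
        assert multiclass_loss(onehot, onehot) == pytest.approx(0.0, abs=1e-5)

    def test_match_elementwise_oracles(self, rng):
        y = rng.integers(0, 2, size=50)
        p = rng.random(50)
        assert binary_loss(y, p) == pytest.approx(binary_loss_oracle(y, p), rel=1e-10)
        onehot = np.eye(6)[rng.integers(0, 6, size=40)]
        scores = rng.random((40, 6))
        scores /= scores.sum(axis=1, keepdims=True)
        assert multiclass_loss(onehot, scores) == pytest.approx(
            multiclass_loss_oracle(onehot, scores), rel=1e-10
        )

    def test_nonnegative_and_zero_only_at_perfect(self, rng):
        y = rng.integers(0, 2, size=30)
        p = np.clip(rng.random(30), 0.01, 0.99)
        assert binary_loss(y, p) > 0
        assert binary_loss(y, y.astype(float)) < 1e-4

    def test_mean_reduction_for_logging(self):
        assert binary_loss([1, 1], [0.5, 0.5], reduction="mean") == pytest.approx(math.log(2))


def _toy_model(task="binary", n=10, seed=3, dropout=0.0, n_outputs=None, method="hadamard"):
    rng = np.random.default_rng(seed)
    cfg = TrainConfig(
        task=task,
        method=method,
        gcn_dims=(5, 4, 3),
        dnn_hidden=(6, 5),
        dropout=dropout,
        seed=seed,
        k=3,
    )
    n_out = n_outputs or (1 if task == "binary" else 4)
    x = rng.random((n, 8))
    from ddifusion.graph_views import GraphView

    topo = GraphView("topology", random_graph(rng, n))
    knn = GraphView("feature", random_graph(rng, n))
    model = DualViewModel(cfg, n_features=8, n_outputs=n_out, rng=rng)
    model.attach(topo, knn, x)
    return model, rng


class TestDnnForward:
    def test_binary_outputs_in_unit_interval(self, rng):
        model, _ = _toy_model("binary")
        preds = model.predict(np.array([[0, 1], [2, 5], [3, 9]]))
        assert preds.shape == (3,)
        assert ((preds > 0) & (preds < 1)).all()

    def test_multiclass_rows_normalized(self):
        model, _ = _toy_model("multiclass")
        preds = model.predict(np.array([[0, 1], [2, 5]]))
        assert preds.shape == (2, 4)
        assert (preds > 0).all()
        np.testing.assert_allclose(preds.sum(axis=1), 1.0, atol=1e-9)

    def test_event_type_head_width_65(self):
        model, _ = _toy_model("multiclass", n_outputs=65)
        preds = model.predict(np.array([[0, 1]]))
        assert preds.shape == (1, 65)

    def test_head_rejects_width_mismatch(self, rng):
        model, _ = _toy_model("binary")
        with pytest.raises(ValueError, match="width"):
            dnn_forward(model, rng.random((2, model.head.input_dim + 1)))

    def test_head_scores_precombined_vectors(self, rng):
        model, _ = _toy_model("binary")
        out = dnn_forward(model, rng.random((4, model.head.input_dim)))
        assert out.shape == (4,)
        assert ((out > 0) & (out < 1)).all()


class TestGradients:
    @pytest.mark.parametrize("task", ["binary", "multiclass"])
    def test_analytic_gradients_match_finite_differences(self, task):
        """Spot-check d(loss)/d(theta) on a 10-drug toy problem."""
        model, rng = _toy_model(task, dropout=0.0, seed=11)
        pairs = np.array([[0, 1], [2, 5], [3, 9], [4, 7]])
        if task == "binary":
            labels = np.array([1.0, 0.0, 1.0, 1.0])
            loss_of = lambda: __import__("ddifusion.pair_classifier", fromlist=["x"])._binary_loss_t(
                labels, model.forward_t(pairs, training=True, rng=None)
            )
        else:
            onehot = np.eye(4)[[0, 1, 2, 3]]
            loss_of = lambda: __import__("ddifusion.pair_classifier", fromlist=["x"])._multiclass_loss_t(
                onehot, model.forward_t(pairs, training=True, rng=None)
            )
        loss = loss_of()
        for p in model.params.values():
            p.zero_grad()
        loss.backward()
        analytic = {k: None if p.grad is None else p.grad.copy() for k, p in model.params.items()}
        check_rng = np.random.default_rng(0)
        names = check_rng.choice(sorted(model.params), size=6, replace=False)
        h = 1e-6
        for name in names:
            p = model.params[name]
            flat_idx = int(check_rng.integers(p.value.size))
            idx = np.unravel_index(flat_idx, p.value.shape)
            orig = p.value[idx]
            p.value[idx] = orig + h
            f_plus = float(loss_of().value)
            p.value[idx] = orig - h
            f_minus = float(loss_of().value)
            p.value[idx] = orig
            numeric = (f_plus - f_minus) / (2 * h)
            got = analytic[name][idx]
            assert got == pytest.approx(numeric, rel=1e-4, abs=1e-7), name


class TestTrainingLoop:
    def _fold(self, synth):
        pairs = synth.interactions.pairs
        labels = synth.interactions.labels
        cut = int(0.8 * len(pairs))
        return FoldSpec(pairs[:cut], labels[:cut], pairs[cut:], labels[cut:])

    def test_loss_decreases_on_learnable_data(self, small_synth, small_features, tiny_multiclass_cfg):
        fold = self._fold(small_synth)
        _model, history = train(small_synth.interactions, small_features, tiny_multiclass_cfg, fold)
        assert history[-1] < history[0]

    def test_identical_seed_gives_bit_identical_history(
        self, small_synth, small_features, tiny_multiclass_cfg
    ):
        fold = self._fold(small_synth)
        m1, h1 = train(small_synth.interactions, small_features, tiny_multiclass_cfg, fold)
        m2, h2 = train(small_synth.interactions, small_features, tiny_multiclass_cfg, fold)
        assert h1 == h2
        np.testing.assert_array_equal(m1.predict(fold.test_pairs), m2.predict(fold.test_pairs))

    def test_empty_training_set_rejected(self, small_synth, small_features, tiny_multiclass_cfg):
        pairs = small_synth.interactions.pairs
        fold = FoldSpec(pairs[:0], np.array([], dtype=int), pairs, small_synth.interactions.labels)
        with pytest.raises(ValueError, match="empty"):
            train(small_synth.interactions, small_features, tiny_multiclass_cfg, fold)

    def test_prediction_invariant_to_pair_orientation(
        self, small_synth, small_features, tiny_binary_cfg
    ):
        pairs = small_synth.interactions.pairs
        labels = np.ones(len(pairs), dtype=int)
        fold = FoldSpec(pairs, labels, pairs[:0], labels[:0])
        for method in ("concatenation", "average", "hadamard"):
            cfg = TrainConfig(**{**TINY_TRAIN, "epochs": 2, "method": method, "task": "binary", "seed": 5, "k": 5})
            model, _ = train(small_synth.interactions, small_features, cfg, fold)
            probe = pairs[:10]
            np.testing.assert_array_equal(model.predict(probe), model.predict(probe[:, ::-1]))


class TestPresets:
    @pytest.mark.parametrize(
        "name, batch, epochs, lr, task",
        [
            ("ddimdl-multiclass", 1000, 100, 1e-3, "multiclass"),
            ("deepddi-multiclass", 512, 50, 1e-3, "multiclass"),
            ("ddimdl-binary", 1000, 50, 1e-4, "binary"),
            ("deepddi-binary", 1000, 50, 1e-4, "binary"),
        ],
    )
    def test_published_protocol_values(self, name, batch, epochs, lr, task):
        cfg = TrainConfig.from_preset(name)
        assert (cfg.batch_size, cfg.epochs, cfg.learning_rate, cfg.task) == (batch, epochs, lr, task)

    def test_default_layer_dims_truncate_to_depth(self):
        assert TrainConfig(n_layers=3).gcn_dims == (256, 128, 64)
        assert TrainConfig(n_layers=5).gcn_dims == (256, 128, 64, 32, 16)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            TrainConfig.from_preset("nope")

    def test_presets_all_constructible(self):
        for name in PRESETS:
            TrainConfig.from_preset(name)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, small_synth, small_features, tiny_binary_cfg):
        pairs = small_synth.interactions.pairs
        labels = np.ones(len(pairs), dtype=int)
        fold = FoldSpec(pairs, labels, pairs[:0], labels[:0])
        model, _ = train(small_synth.interactions, small_features, tiny_binary_cfg, fold)
        path = tmp_path / "model.npz"
        model.save(path)
        restored = DualViewModel.load(path)
        topo = model.views["topology"]
        restored.attach(topo, model.views["feature"], small_features.values)
        np.testing.assert_array_equal(model.predict(pairs[:8]), restored.predict(pairs[:8]))
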