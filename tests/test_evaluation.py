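import numpy as np
import pytest

from ddifusion.evaluation import (
    compute_metrics,
    cross_validate,
    make_folds,
    mean_report,
    run_ablation,
    sample_negatives,
)
from ddifusion.graph_views import InteractionDataset
from ddifusion.pair_classifier import FoldSpec, TrainConfig, train

from _oracles import macro_f1_oracle
from conftest import TINY_TRAIN


class TestMakeFolds:
    def test_exact_division(self):
        plan = make_folds(10, 5, seed=0)
        assert sorted(len(f) for f in plan.folds) == [2] * 5

    def test_partition_property(self):
        plan = make_folds(23, 5, seed=3)
        all_idx = np.concatenate(plan.folds)
        assert sorted(all_idx.tolist()) == list(range(23))
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_stratification_within_one_sample(self):
        labels = np.array([0] * 80 + [1] * 20)
        plan = make_folds(100, 5, seed=1, labels=labels)
        for fold in plan.folds:
            # global fractions are 16/4 per fold of 20
            assert abs((labels[fold] == 1).sum() - 4) <= 1
            assert len(fold) == 20

    def test_split_returns_disjoint_complement(self):
        plan = make_folds(20, 4, seed=2)
        tr, te = plan.split(1)
        assert set(tr) | set(te) == set(range(20))
        assert not set(tr) & set(te)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            make_folds(3, 5, seed=0)
        with pytest.raises(ValueError):
            make_folds(10, 1, seed=0)


class TestSampleNegatives:
    def test_one_to_one_ratio_and_disjointness(self):
        positives = np.array([[0, 1], [1, 2], [2, 3], [0, 4]])
        negs = sample_negatives(positives, n_drugs=10, ratio=1.0, seed=4)
        assert len(negs) == len(positives)
        pos_set = {tuple(p) for p in positives}
        for i, j in negs:
            assert i < j
            assert (i, j) not in pos_set
        assert len({tuple(p) for p in negs}) == len(negs)

    def test_seed_reproducible(self):
        positives = np.array([[0, 1], [2, 3]])
        a = sample_negatives(positives, 8, seed=9)
        b = sample_negatives(positives, 8, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_insufficient_candidates_rejected(self):
        # complete graph on 4 drugs: no unconnected pairs remain
        positives = np.array([[i, j] for i in range(4) for j in range(i + 1, 4)])
        with pytest.raises(ValueError, match="unconnected"):
            sample_negatives(positives, 4, ratio=1.0, seed=0)


class TestComputeMetrics:
    def test_perfect_binary_predictions(self):
        y = np.array([0, 1, 1, 0])
        rep = compute_metrics(y, np.array([0.1, 0.9, 0.8, 0.2]), "binary")
        assert rep.overall == {"ACC": 1.0, "AUC": 1.0, "AUCPR": 1.0}

    def test_single_class_auc_undefined_marker(self):
        rep = compute_metrics(np.ones(5), np.linspace(0.2, 0.9, 5), "binary")
        assert rep.overall["AUC"] is None
        assert rep.overall["AUCPR"] is None
        assert rep.overall["ACC"] is not None

    def test_random_scores_near_half_auc(self):
        rng = np.random.default_rng(42)
        y = rng.integers(0, 2, size=10_000)
        rep = compute_metrics(y, rng.random(10_000), "binary")
        assert rep.overall["AUC"] == pytest.approx(0.5, abs=0.05)

    def test_micro_average_identity(self, rng):
        """Micro P = micro R = micro F1 = accuracy in single-label
        multi-class prediction."""
        for _ in range(20):
            r = int(rng.integers(3, 8))
            m = int(rng.integers(20, 60))
            y = rng.integers(0, r, size=m)
            scores = rng.random((m, r))
            scores /= scores.sum(axis=1, keepdims=True)
            rep = compute_metrics(y, scores, "multiclass")
            acc = rep.overall["ACC"]
            assert rep.overall["Pre_micro"] == pytest.approx(acc, abs=1e-12)
            assert rep.overall["Recall_micro"] == pytest.approx(acc, abs=1e-12)
            assert rep.overall["F1_micro"] == pytest.approx(acc, abs=1e-12)

    def test_macro_f1_matches_manual_confusion_oracle(self):
        # hand-enumerable 3-class toy problem
        y = np.array([0, 0, 0, 1, 1, 2, 2, 2, 2])
        pred = np.array([0, 0, 1, 1, 2, 2, 2, 0, 2])
        scores = np.full((9, 3), 0.05)
        scores[np.arange(9), pred] = 0.9
        scores /= scores.sum(axis=1, keepdims=True)
        rep = compute_metrics(y, scores, "multiclass")
        assert rep.overall["F1_macro"] == pytest.approx(
            macro_f1_oracle(y, pred, [0, 1, 2]), rel=1e-10
        )
        assert set(rep.per_class) == {0, 1, 2}
        assert rep.per_class[0]["support"] == 3

    def test_all_metrics_in_unit_interval(self, rng):
        y = rng.integers(0, 4, size=200)
        scores = rng.random((200, 4))
        scores /= scores.sum(axis=1, keepdims=True)
        rep = compute_metrics(y, scores, "multiclass")
        for key, value in rep.overall.items():
            if value is not None:
                assert 0.0 <= value <= 1.0, key

    def test_unnormalized_multiclass_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="normalized"):
            compute_metrics(np.array([0, 1]), rng.random((2, 3)) + 1.0, "multiclass")


class TestCrossValidation:
    def test_fold_bookkeeping_and_mean(self, small_synth, small_features, tiny_multiclass_cfg):
        report = cross_validate(small_synth.interactions, small_features, tiny_multiclass_cfg, n_folds=3)
        assert len(report.folds) == 3
        for key, value in report.overall.items():
            vals = [f.overall[key] for f in report.folds if f.overall[key] is not None]
            if vals:
                assert value == pytest.approx(float(np.mean(vals)), rel=1e-12)

    def test_full_variant_identical_to_cross_validate(
        self, small_synth, small_features, tiny_multiclass_cfg
    ):
        a = cross_validate(small_synth.interactions, small_features, tiny_multiclass_cfg, n_folds=2)
        b = run_ablation("full", small_synth.interactions, small_features, tiny_multiclass_cfg, n_folds=2)
        assert a.overall == b.overall

    def test_unknown_variant_rejected(self, small_synth, small_features, tiny_multiclass_cfg):
        with pytest.raises(ValueError, match="variant"):
            run_ablation("no_such_thing", small_synth.interactions, small_features, tiny_multiclass_cfg)

    def test_feature_only_variant_ignores_interaction_edges(self, small_synth, small_features):
        """Without the topology view, predictions cannot depend on which
        edges feed message passing."""
        cfg = TrainConfig(
            task="binary", seed=5, k=5, variant="without_topology_view", **TINY_TRAIN
        )
        ds = small_synth.interactions
        pairs = ds.pairs
        labels = np.ones(len(pairs), dtype=int)
        fold = FoldSpec(pairs, labels, pairs[:0], labels[:0])
        model_a, _ = train(ds, small_features, cfg, fold)
        # same drugs and samples, entirely different interaction edges
        rng = np.random.default_rng(0)
        n = ds.n_drugs
        other = np.array(sorted({(int(a), int(b)) for a, b in
                                 np.sort(rng.integers(0, n, (len(pairs) * 2, 2)), axis=1)
                                 if a != b})[: len(pairs)])
        ds_b = InteractionDataset(ds.drug_ids, other)
        model_b, _ = train(ds_b, small_features, cfg, fold)
        probe = pairs[:20]
        np.testing.assert_allclose(model_a.predict(probe), model_b.predict(probe), atol=1e-12)

    def test_scale_only_variant_narrows_embedding(self, small_synth, small_features):
        cfg = TrainConfig(task="binary", seed=5, k=5, variant="scale_only_1", **{**TINY_TRAIN, "epochs": 1})
        pairs = small_synth.interactions.pairs
        labels = np.ones(len(pairs), dtype=int)
        fold = FoldSpec(pairs, labels, pairs[:0], labels[:0])
        model, _ = train(small_synth.interactions, small_features, cfg, fold)
        assert model.embeddings().values.shape[1] == cfg.gcn_dims[0]

    def test_learnable_signal_beats_feature_free_baseline(self, small_synth, small_features):
        """High-signal synthetic data must be separable well above chance."""
        cfg = TrainConfig(task="binary", seed=5, k=5, **{**TINY_TRAIN, "epochs": 20})
        report = cross_validate(small_synth.interactions, small_features, cfg, n_folds=2)
        assert report.overall["AUC"] > 0.8


def test_mean_report_requires_folds():
    with pytest.raises(ValueError):
        mean_report([])
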