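"""Training protocol: folds, early stopping, determinism, CV, resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corenup import (
    ModelConfig, SimulationConfig, TrainConfig, build_corenup,
    cross_validate, make_folds, resample_evaluate, simulate_dataset, train,
)
from corenup.models import predict as model_predict
from corenup.training import (CrossValidationResults, FoldPlan,
                              ResampleResults, scaled_builder)

from conftest import make_dataset


class FakeNetwork:
    """A frozen 'model' whose score is the first channel of position 0.

    On datasets where positives start with A and negatives with C this
    is a perfect classifier; it has no trainable parameters, so the
    training loop's loss plateaus immediately.
    """

    name = "fake"

    def __init__(self, input_length):
        self.config = ModelConfig(input_length=input_length)

    def forward(self, x, training=False, rng=None):
        return x[:, 0, 0:1] * 0.98 + 0.01

    def backward(self, grad, skip_last_activation=False):
        return None

    def parameters(self):
        return []

    def l2_penalty(self):
        return 0.0

    def predict(self, batch, batch_size=256):
        return model_predict(self, batch, batch_size=batch_size)


def separable_dataset(n=40, length=8):
    pos = ["A" + "G" * (length - 1)] * n
    neg = ["C" + "G" * (length - 1)] * n
    return make_dataset(pos + neg, [1] * n + [0] * n)


class TestMakeFolds:
    def test_even_partition_200_by_20(self):
        labels = np.array([1, 0] * 100)
        plan = make_folds(labels, k=20, seed=0)
        assert list(plan.fold_sizes()) == [10] * 20

    def test_benchmark_cardinality_4573(self):
        """A 4573-item set (2273 positives / 2300 negatives) splits into
        13 folds of 229 and 7 of 228, each item tested exactly once."""
        labels = np.array([1] * 2273 + [0] * 2300)
        plan = make_folds(labels, k=20, seed=1)
        sizes = sorted(plan.fold_sizes())
        assert sizes == [228] * 7 + [229] * 13
        seen = np.concatenate([plan.test_indices(f) for f in range(20)])
        assert sorted(seen) == list(range(4573))

    def test_stratified_balanced_100_100(self):
        labels = np.array([1] * 100 + [0] * 100)
        plan = make_folds(labels, k=20, stratified=True, seed=2)
        for f in range(20):
            fold_labels = labels[plan.test_indices(f)]
            assert (fold_labels == 1).sum() == 5
            assert (fold_labels == 0).sum() == 5

    def test_deterministic_from_seed(self):
        labels = np.array([1, 0] * 50)
        a = make_folds(labels, k=5, seed=3).assignments
        b = make_folds(labels, k=5, seed=3).assignments
        np.testing.assert_array_equal(a, b)

    def test_k_larger_than_dataset_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array([1, 0, 1]), k=5)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array([1] + [0] * 30), k=5, stratified=True)

    @given(st.integers(2, 12), st.integers(30, 120), st.integers(0, 1000),
           st.booleans())
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_partition_invariants(self, k, n, seed, stratified):
        rng = np.random.default_rng(seed)
        labels = np.concatenate([np.ones(n // 2 + k), np.zeros(n // 2 + k)])
        rng.shuffle(labels)
        plan = make_folds(labels, k=k, stratified=stratified, seed=seed)
        sizes = plan.fold_sizes()
        assert sizes.sum() == labels.size
        assert sizes.max() - sizes.min() <= 1
        if stratified:
            pos_per_fold = np.array([
                labels[plan.test_indices(f)].sum() for f in range(k)])
            assert pos_per_fold.max() - pos_per_fold.min() <= 1


class TestTrain:
    def test_signal_recovery_on_separable_data(self, tiny_config):
        cfg = SimulationConfig(n_per_class=80, length=20,
                               periodic_strength=1.0, motif_prob=1.0,
                               seed=1)
        ds = simulate_dataset(cfg)
        # a higher learning rate and no dropout suit this very small run
        net, _ = build_corenup(tiny_config.scaled(dropout_rate=0.0),
                               init_seed=0)
        res = train(net, ds, TrainConfig(seed=0, max_epochs=60,
                                         learning_rate=3e-3))
        scores = res.predict(ds.encode())
        train_acc = ((scores >= 0.5).astype(int) == ds.labels).mean()
        assert train_acc > 0.95

    def test_plateau_triggers_early_stop(self, tiny_config, tiny_dataset):
        net, _ = build_corenup(tiny_config, init_seed=0)
        cfg = TrainConfig(seed=0, learning_rate=0.0, max_epochs=50,
                          early_stop_patience=5)
        res = train(net, tiny_dataset, cfg)
        assert res.stopped_early
        assert res.stopping_epoch <= cfg.early_stop_patience + 1
        # the recorded loss series is consistent with the stopping rule
        losses = [e["val_loss"] for e in res.history]
        best_before_tail = min(losses[:-cfg.early_stop_patience] or losses)
        assert all(l >= best_before_tail
                   for l in losses[-cfg.early_stop_patience:])

    def test_never_exceeds_max_epochs(self, tiny_config, null_dataset):
        net, _ = build_corenup(tiny_config, init_seed=0)
        res = train(net, null_dataset, TrainConfig(seed=0, max_epochs=3))
        assert res.stopping_epoch <= 3
        assert len(res.history) == res.stopping_epoch

    def test_same_seed_reproduces_final_loss(self, tiny_config,
                                             tiny_dataset):
        vals = []
        for _ in range(2):
            net, _ = build_corenup(tiny_config, init_seed=0)
            res = train(net, tiny_dataset, TrainConfig(seed=4, max_epochs=3))
            vals.append(res.history[-1]["val_loss"])
        assert vals[0] == vals[1]

    def test_single_class_rejected(self, tiny_config):
        ds = make_dataset(["ACGT" * 5] * 10, [1] * 10)
        net, _ = build_corenup(tiny_config, init_seed=0)
        with pytest.raises(ValueError, match="single class"):
            train(net, ds, TrainConfig(seed=0))

    def test_length_mismatch_rejected(self, tiny_config):
        ds = make_dataset(["ACGT"] * 4, [1, 0, 1, 0])
        net, _ = build_corenup(tiny_config, init_seed=0)
        with pytest.raises(ValueError, match="length"):
            train(net, ds, TrainConfig(seed=0))

    def test_invalid_train_config(self):
        with pytest.raises(ValueError):
            TrainConfig(validation_fraction=0.0)
        with pytest.raises(ValueError):
            TrainConfig(early_stop_patience=0)


class TestCrossValidate:
    def test_bookkeeping_two_folds(self):
        ds = separable_dataset(n=20)
        results = cross_validate(
            ds, lambda seed: FakeNetwork(ds.length),
            TrainConfig(seed=0, max_epochs=2), k=2)
        assert len(results.fold_metrics) == 2
        assert set(results.mean) == {"ACC", "SENS", "SPEC", "MCC", "AUC"}

    def test_perfect_classifier_scores_one_everywhere(self):
        ds = separable_dataset(n=20)
        results = cross_validate(
            ds, lambda seed: FakeNetwork(ds.length),
            TrainConfig(seed=0, max_epochs=2), k=4)
        for fold in results.fold_metrics:
            for metric, value in fold.items():
                assert value == pytest.approx(1.0), metric

    def test_aggregate_is_arithmetic_mean_of_folds(self):
        fm = [dict(ACC=0.8, SENS=0.7, SPEC=0.9, MCC=0.6, AUC=0.85),
              dict(ACC=0.6, SENS=0.5, SPEC=0.7, MCC=0.2, AUC=0.65)]
        results = CrossValidationResults(fm)
        assert results.mean["ACC"] == pytest.approx(0.7)
        assert results.std["AUC"] == pytest.approx(0.1)
        df = results.to_frame_with_aggregates()
        assert list(df["fold"])[-2:] == ["mean", "std"]

    def test_real_model_two_folds(self, tiny_config, tiny_dataset):
        results = cross_validate(
            tiny_dataset, scaled_builder("corenup", tiny_config),
            TrainConfig(seed=0, max_epochs=2), k=2)
        assert len(results.fold_metrics) == 2
        assert all(0 <= f["AUC"] <= 1 for f in results.fold_metrics)


class TestResampleEvaluate:
    def test_perfect_pool_all_aucs_one(self):
        pool = separable_dataset(n=30)
        net = FakeNetwork(pool.length)
        res = resample_evaluate(net, pool, n_samples=10, sample_size=20,
                                seed=0)
        assert res.aucs == [1.0] * 10
        assert res.mean_auc == 1.0

    def test_deterministic_from_seed(self):
        pool = separable_dataset(n=30)
        net = FakeNetwork(pool.length)
        a = resample_evaluate(net, pool, n_samples=20, sample_size=10, seed=5)
        b = resample_evaluate(net, pool, n_samples=20, sample_size=10, seed=5)
        assert a.aucs == b.aucs

    def test_single_class_draws_redrawn(self):
        strings = (["A" + "G" * 7] * 2 + ["C" + "G" * 7] * 98)
        pool = make_dataset(strings, [1] * 2 + [0] * 98)
        net = FakeNetwork(pool.length)
        res = resample_evaluate(net, pool, n_samples=15, sample_size=4,
                                seed=1)
        assert len(res.aucs) == 15
        assert res.n_redrawn > 0

    def test_train_test_overlap_rejected(self):
        pool = separable_dataset(n=30)
        net = FakeNetwork(pool.length)
        with pytest.raises(ValueError, match="overlap"):
            resample_evaluate(net, pool, n_samples=5, sample_size=10,
                              seed=0, train_ids=[pool.ids[0]])

    def test_pool_smaller_than_sample_rejected(self):
        pool = separable_dataset(n=3)
        with pytest.raises(ValueError, match="pool"):
            resample_evaluate(FakeNetwork(pool.length), pool,
                              n_samples=2, sample_size=100, seed=0)

    def test_summary_mentions_mean(self):
        res = ResampleResults([0.9, 1.0], n_redrawn=1, sample_size=10)
        assert "0.950" in res.summary()
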