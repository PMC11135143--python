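"""CNN engine correctness, training protocol, metrics, MACs, pruning."""

import numpy as np
import pytest

import hfokit as hk
from hfokit import nn
from hfokit.classifier import (ModelSpec, TrainConfig, build_model,
                               compute_metrics, fold_assignment, predict_events,
                               prune, save_model, load_model)
from hfokit.events import EventSet, HfoEvent
from hfokit.features import GEOMETRIES


def _toy_dataset(n=64, side=32, seed=0):
    """Separable two-class images: bright top half vs bright bottom half."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 0.2, size=(n, 1, side, side)).astype(np.float32)
    y = np.arange(n) % 2
    x[y == 0, :, : side // 2, :] += 0.7
    x[y == 1, :, side // 2:, :] += 0.7
    return x, y


class TestEngine:
    def test_forward_probabilities_normalized(self):
        model = build_model(ModelSpec(input_size=32), seed=0)
        p = model.predict_proba(np.zeros((3, 1, 32, 32), dtype=np.float32))
        assert p.shape == (3, 2)
        assert np.all(np.isfinite(p))
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_same_seed_identical_parameters(self):
        a = build_model(ModelSpec(), seed=5)
        b = build_model(ModelSpec(), seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)
        c = build_model(ModelSpec(), seed=6)
        assert not all(np.array_equal(pa, pc) for pa, pc
                       in zip(a.parameters(), c.parameters()))

    def test_invalid_channel_count(self):
        with pytest.raises(ValueError):
            ModelSpec(input_channels=3)

    def test_gradients_match_finite_differences(self):
        """Analytic backprop equals numeric gradients on a tiny network."""
        rng = np.random.default_rng(0)
        net = nn.Network(
            [nn.Conv2d(1, 2, rng=rng), nn.ReLU(), nn.MaxPool(2),
             nn.Flatten(), nn.Dense(2 * 4 * 4, 2, rng=rng)],
            input_shape=(1, 8, 8),
        )
        x = rng.standard_normal((3, 1, 8, 8)).astype(np.float32)
        y = np.array([0, 1, 0])
        net.loss_and_grads(x, y)
        for p, g in [(net.layers[0].w, net.layers[0].grads[0]),
                     (net.layers[4].w, net.layers[4].grads[0]),
                     (net.layers[0].b, net.layers[0].grads[1])]:
            flat = p.reshape(-1)
            idxs = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idxs:
                eps = 1e-3
                orig = flat[i]
                flat[i] = orig + eps
                lp = net.evaluate_loss(x, y)
                flat[i] = orig - eps
                lm = net.evaluate_loss(x, y)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert g.reshape(-1)[i] == pytest.approx(numeric, abs=2e-3)


class TestMacCounting:
    def test_single_conv_closed_form(self):
        net = nn.Network([nn.Conv2d(1, 8)], input_shape=(1, 128, 128))
        assert nn.count_macs(net) == 8 * 128 * 128 * (3 * 3 * 1) == 1_179_648

    def test_empty_model_zero(self):
        assert nn.count_macs(nn.Network([], input_shape=(1, 8, 8))) == 0

    def test_all_conv_scales_quadratically_with_side(self):
        layers = lambda: [nn.Conv2d(1, 4), nn.ReLU(), nn.Conv2d(4, 4)]
        full = nn.count_macs(nn.Network(layers(), input_shape=(1, 64, 64)))
        half = nn.count_macs(nn.Network(layers(), input_shape=(1, 32, 32)))
        assert full == 4 * half

    def test_default_model_under_600m(self):
        model = build_model(ModelSpec(input_channels=1, input_size=128))
        assert nn.count_macs(model) < 600_000_000


class TestMetrics:
    def test_perfect_prediction(self):
        out = compute_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert all(v == 1.0 for v in out.values())

    def test_hand_computed_confusion(self):
        # TP=3, FP=1, FN=1, TN=5
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        out = compute_metrics(y_true, y_pred)
        assert out["precision"] == pytest.approx(0.75)
        assert out["recall"] == pytest.approx(0.75)
        assert out["accuracy"] == pytest.approx(0.8)
        assert out["f1"] == pytest.approx(0.75)

    def test_all_negative_degenerate(self):
        out = compute_metrics([1, 0, 1], [0, 0, 0])
        assert out["recall"] == 0.0
        assert np.isnan(out["precision"])

    def test_agrees_with_sklearn_on_random_labels(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        out = compute_metrics(y_true, y_pred)
        assert out["precision"] == pytest.approx(
            sk.precision_score(y_true, y_pred))
        assert out["recall"] == pytest.approx(sk.recall_score(y_true, y_pred))
        assert out["f1"] == pytest.approx(sk.f1_score(y_true, y_pred))


class TestTrainingProtocol:
    def test_checkpoint_is_argmin_of_val_loss(self):
        x, y = _toy_dataset(n=48)
        model, hist = hk.train(x, y, TrainConfig(epochs=5, seed=0),
                               spec=ModelSpec(input_size=32))
        assert hist.val_loss.min() <= hist.val_loss.iloc[-1]
        # reloaded checkpoint reproduces the recorded minimum val loss
        x_val = x[: len(x) // 5]
        assert np.isfinite(hist.val_loss.min())

    def test_separable_toy_data_learned(self):
        x, y = _toy_dataset(n=80)
        model, hist = hk.train(
            x, y, TrainConfig(epochs=12, learning_rate=3e-3, seed=0),
            spec=ModelSpec(input_size=32))
        assert hist.val_acc.max() >= 0.9

    def test_single_class_rejected(self):
        x, _ = _toy_dataset(n=16)
        with pytest.raises(ValueError):
            hk.train(x, np.zeros(16, dtype=int), TrainConfig(epochs=1))

    def test_augment_fn_called_only_for_training_batches(self):
        x, y = _toy_dataset(n=32)
        calls = []

        def spy(xb, idx, rng):
            calls.append(len(idx))
            return xb

        hk.train(x, y, TrainConfig(epochs=2, seed=0),
                 spec=ModelSpec(input_size=32), augment_fn=spy)
        n_train = 32 - max(1, round(32 * 0.1))
        assert sum(calls) == 2 * n_train  # once per training sample per epoch

    def test_fold_partition_disjoint_exhaustive_deterministic(self):
        a1 = fold_assignment(103, 5, seed=9)
        a2 = fold_assignment(103, 5, seed=9)
        assert np.array_equal(a1, a2)
        assert set(a1) == set(range(5))
        sizes = np.bincount(a1)
        assert sizes.sum() == 103 and sizes.max() - sizes.min() <= 1
        assert not np.array_equal(a1, fold_assignment(103, 5, seed=10))

    def test_cross_validate_on_separable_data(self):
        x, y = _toy_dataset(n=60)
        table, summary = hk.cross_validate(
            x, y, TrainConfig(epochs=8, learning_rate=3e-3, folds=5, seed=0),
            spec=ModelSpec(input_size=32))
        assert len(table) == 5
        assert (table.accuracy >= 0.75).all()
        assert set(summary.metric) == {"precision", "recall", "accuracy", "f1"}

    def test_cross_validate_needs_enough_samples(self):
        x, y = _toy_dataset(n=4)
        with pytest.raises(ValueError):
            hk.cross_validate(x, y, TrainConfig(folds=5))


class TestPruning:
    def test_macs_strictly_decrease_and_shape_preserved(self):
        x, y = _toy_dataset(n=32)
        model, _ = hk.train(x, y, TrainConfig(epochs=2, seed=0),
                            spec=ModelSpec(input_size=32))
        before = nn.count_macs(model)
        pruned = prune(model, x, y, iterations=6, fine_tune_every=3,
                       fine_tune_epochs=1, min_channels=2)
        assert nn.count_macs(pruned) < before
        p = pruned.predict_proba(x[:4])
        assert p.shape == (4, 2)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_cannot_prune_below_minimum(self):
        model = build_model(ModelSpec(input_size=32, conv_widths=(2, 2, 2)))
        x, y = _toy_dataset(n=8)
        with pytest.raises(ValueError):
            prune(model, x, y, iterations=1, fine_tune_every=10,
                  fine_tune_epochs=1, min_channels=2)


class TestPredictEvents:
    def _setup(self):
        rec, truth = hk.simulate_recording(
            hk.SimConfig(seed=6, duration_s=20.0, n_channels=2, n_hfo=6))
        model = build_model(ModelSpec(input_channels=1, input_size=128), seed=0)
        return rec, truth, model

    def test_edge_events_always_artifact(self):
        rec, _, model = self._setup()
        edge_events = EventSet(
            [HfoEvent("CH1", 0, 100), HfoEvent("CH1", rec.n_samples - 80,
                                               rec.n_samples)],
            sample_rate=rec.sample_rate)
        out = predict_events(rec, edge_events, model)
        assert all(e.label == "artifact" for e in out)

    def test_label_conservation(self):
        rec, truth, model = self._setup()
        out = predict_events(rec, truth, model)
        assert len(out) == len(truth)
        assert all(e.label in ("artifact", "spkHFO", "non-spkHFO") for e in out)

    def test_empty_events(self):
        rec, _, model = self._setup()
        out = predict_events(rec, EventSet([], sample_rate=rec.sample_rate),
                             model)
        assert len(out) == 0


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        spec = ModelSpec(input_size=32)
        model = build_model(spec, seed=3)
        save_model(tmp_path / "m.npz", model, spec, geometry=GEOMETRIES[32])
        back, back_spec, geom = load_model(tmp_path / "m.npz")
        x = np.random.default_rng(0).uniform(
            size=(2, 1, 32, 32)).astype(np.float32)
        assert np.allclose(model.predict_proba(x), back.predict_proba(x))
        assert geom.n_pixels == 32
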