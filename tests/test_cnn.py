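"""Network architecture, gradients, training behaviour and determinism."""

import numpy as np
import pytest

import amycnn as a
from amycnn.cnn import (_bce, _sigmoid, BatchNorm, Conv2D, Dense, Dropout,
                        GlobalAveragePool, MaxPool2, ReLU)
from conftest import make_stack

EXPECTED_SEQUENCE = [
    "Conv2D", "ReLU", "Conv2D", "ReLU", "MaxPool2", "BatchNorm", "Dropout",
    "Conv2D", "ReLU", "Conv2D", "ReLU", "MaxPool2", "BatchNorm", "Dropout",
    "GlobalAveragePool", "Dense",
]


def small_config(**kw):
    defaults = dict(conv_filters=(4, 4, 8, 8), epochs=5, rng_seed=0)
    defaults.update(kw)
    return a.CNNConfig(**defaults)


class TestArchitecture:
    def test_layer_sequence(self):
        model = a.build_model((32, 32, 8), small_config(
            conv_filters=(8, 8, 16, 16)))
        assert model.layer_sequence() == EXPECTED_SEQUENCE

    def test_dense_head_size_matches_final_filters(self):
        model = a.build_model((32, 32, 8), small_config(
            conv_filters=(8, 8, 16, 16), kernel_size=3))
        w, b = model.gap_dense_weights
        assert w.shape == (16,)
        dense = model.layers[-1]
        assert sum(p.size for p in dense.params.values()) == 16 + 1

    def test_parameter_count_formula(self):
        f = (8, 8, 16, 16)
        k, c_in = 3, 8
        model = a.build_model((32, 32, c_in), small_config(
            conv_filters=f, kernel_size=k))
        conv = (k * k * c_in * f[0] + f[0]) + (k * k * f[0] * f[1] + f[1]) \
            + (k * k * f[1] * f[2] + f[2]) + (k * k * f[2] * f[3] + f[3])
        bn = 2 * (f[1] + f[3])  # one batch norm per block, after the pool
        dense = f[3] + 1
        assert model.n_params() == conv + bn + dense

    def test_zero_dropout_architecture_identical(self):
        m0 = a.build_model((16, 16, 4), small_config(dropout_rate=0.0))
        m6 = a.build_model((16, 16, 4), small_config(dropout_rate=0.6))
        assert m0.layer_sequence() == m6.layer_sequence()

    def test_4x4_input_boundary_valid(self):
        model = a.build_model((4, 4, 2), small_config())
        x = np.random.default_rng(0).random((2, 4, 4, 2))
        assert model.feature_maps(x).shape[1:3] == (1, 1)

    def test_too_small_input_raises(self):
        with pytest.raises(ValueError, match="too small"):
            a.build_model((3, 4, 2), small_config())


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Central-difference oracle on every parameter tensor of a tiny
        model. The bias of each block's second conv reaches batch norm
        through pooling only, so its true gradient is zero; those are
        checked for smallness instead of ratio."""
        cfg = small_config(conv_filters=(2, 2, 3, 3), dropout_rate=0.0)
        model = a.build_model((6, 6, 2), cfg)
        rng = np.random.default_rng(1)
        x = rng.random((4, 6, 6, 2)).astype(np.float32)
        y = np.array([0.0, 1.0, 1.0, 0.0])

        def loss():
            return _bce(_sigmoid(model.forward_logits(x, training=True)), y)

        p = _sigmoid(model.forward_logits(x, training=True))
        g = ((p - y) / len(y)).astype(np.float32)[:, None]
        for lyr in reversed(model.layers):
            g = lyr.backward(g)

        eps = 1e-3
        bn_nulled = {2, 9}  # second conv of each block
        for li, lyr in enumerate(model.layers):
            for name, P in lyr.params.items():
                for _ in range(3):
                    idx = tuple(rng.integers(0, s) for s in P.shape)
                    orig = P[idx]
                    P[idx] = orig + eps
                    lp = loss()
                    P[idx] = orig - eps
                    lm = loss()
                    P[idx] = orig
                    num = (lp - lm) / (2 * eps)
                    ana = lyr.grads[name][idx]
                    if isinstance(lyr, Conv2D) and name == "b" \
                            and li in bn_nulled:
                        assert abs(ana) < 1e-5  # nulled by batch norm
                    else:
                        assert ana == pytest.approx(num, rel=2e-2, abs=2e-4)


class TestTraining:
    def test_zero_epochs_returns_initialized_model(self, tiny_separable_dataset):
        cfg = small_config(epochs=0)
        m = a.build_model((16, 12, 16), cfg)
        w0, b0 = m.gap_dense_weights
        a.train(m, tiny_separable_dataset, None, cfg)
        w1, b1 = m.gap_dense_weights
        np.testing.assert_array_equal(w0, w1)
        assert b0 == b1 and m.history["loss"] == []

    def test_training_deterministic(self, tiny_separable_dataset):
        losses = []
        for _ in range(2):
            cfg = small_config(epochs=8, rng_seed=13)
            m = a.build_model((16, 12, 16), cfg)
            a.train(m, tiny_separable_dataset, None, cfg)
            losses.append(m.history["loss"])
        assert losses[0] == losses[1]

    def test_separable_cohort_reaches_perfect_training_accuracy(self):
        """300 full-batch epochs on a clearly separable cohort drive the
        training-set accuracy (inference mode) to 100%."""
        spec = a.PhantomSpec(grid_shape=(16, 16, 12), noise_cv=0.05,
                             between_subject_sd=0.0)
        scans = a.generate_cohort(spec, 8, 8, seed=31)
        ds = a.scans_to_suvr_datasets(scans, ("sagittal",))["sagittal"]
        cfg = small_config(epochs=300, rng_seed=2)
        m = a.build_model((16, 12, 16), cfg)
        a.train(m, ds, None, cfg)
        x, y = a.dataset_to_arrays(ds)
        acc = np.mean((m.predict_proba(x) >= 0.5) == (y == 1))
        assert acc == 1.0

    def test_loss_non_increasing_on_clean_separable_data(self):
        """With inert dropout and no noise the full-batch loss decreases
        monotonically (tiny tolerance for float32 plateaus)."""
        spec = a.PhantomSpec(grid_shape=(16, 16, 12), noise_cv=0.0,
                             between_subject_sd=0.0)
        scans = a.generate_cohort(spec, 4, 4, seed=17)
        ds = a.scans_to_suvr_datasets(scans, ("sagittal",))["sagittal"]
        cfg = small_config(epochs=120, dropout_rate=0.0, rng_seed=1)
        m = a.build_model((16, 12, 16), cfg)
        a.train(m, ds, None, cfg)
        loss = np.array(m.history["loss"])
        assert np.all(np.diff(loss) < 1e-4)

    def test_validation_history_recorded(self, tiny_separable_dataset):
        cfg = small_config(epochs=4)
        m = a.build_model((16, 12, 16), cfg)
        a.train(m, tiny_separable_dataset, tiny_separable_dataset, cfg)
        assert len(m.history["val_accuracy"]) == 4

    def test_mini_batch_mode_runs(self, tiny_separable_dataset):
        cfg = small_config(epochs=3, batch_mode="mini_batch",
                           mini_batch_size=4)
        m = a.build_model((16, 12, 16), cfg)
        a.train(m, tiny_separable_dataset, None, cfg)
        assert len(m.history["loss"]) == 3


class TestPredict:
    def test_probability_in_unit_interval(self, tiny_trained_model,
                                          tiny_separable_dataset):
        for stack, _ in tiny_separable_dataset.items:
            p = a.predict(tiny_trained_model, stack)
            assert 0.0 <= p <= 1.0

    def test_zero_dense_weights_give_half(self, tiny_trained_model,
                                          tiny_separable_dataset):
        import copy
        model = copy.deepcopy(tiny_trained_model)
        dense = model.layers[-1]
        dense.params["W"][:] = 0.0
        dense.params["b"][:] = 0.0
        p = a.predict(model, tiny_separable_dataset.items[0][0])
        assert p == 0.5

    def test_forward_decomposes_as_gap_dense(self, tiny_trained_model,
                                             tiny_separable_dataset):
        """predict == sigmoid(sum_n W_n * mean(f_n) + b) recomputed from
        the extracted feature maps."""
        stack = tiny_separable_dataset.items[0][0]
        x = np.moveaxis(stack.planes, 0, -1)
        fmaps = tiny_trained_model.feature_maps(x)[0]
        w, b = tiny_trained_model.gap_dense_weights
        logit = float(fmaps.mean(axis=(0, 1)) @ w + b)
        expected = 1.0 / (1.0 + np.exp(-logit))
        assert a.predict(tiny_trained_model, stack) \
            == pytest.approx(expected, abs=1e-5)

    def test_shape_mismatch_raises(self, tiny_trained_model):
        with pytest.raises(ValueError, match="shape"):
            a.predict(tiny_trained_model, make_stack(np.zeros((3, 5, 5))))

    def test_dropout_inactive_at_inference(self, tiny_trained_model,
                                           tiny_separable_dataset):
        stack = tiny_separable_dataset.items[0][0]
        p1 = a.predict(tiny_trained_model, stack)
        p2 = a.predict(tiny_trained_model, stack)
        assert p1 == p2


def test_save_load_roundtrip(tmp_path, tiny_trained_model,
                             tiny_separable_dataset):
    a.save_model(tiny_trained_model, tmp_path / "m")
    loaded = a.load_model(tmp_path / "m")
    x, _ = a.dataset_to_arrays(tiny_separable_dataset)
    np.testing.assert_allclose(loaded.predict_proba(x),
                               tiny_trained_model.predict_proba(x),
                               rtol=1e-6)
    assert loaded.axis == tiny_trained_model.axis
    assert loaded.history == tiny_trained_model.history
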