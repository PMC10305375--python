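import numpy as np
import pytest

from lipocomplex.cnn import (CNNArchitecture, CNNClassifier,
                             ClassifierTrainConfig, _backward_batch,
                             _forward_batch, build_cnn, forward, predict,
                             train_classifier)
from lipocomplex.table import DescriptorTable


class TestArchitecture:
    def test_default_sequence_trace(self):
        arch = CNNArchitecture()
        assert arch.sequence_trace() == [10, 10, 10, 10, 5, 5, 2]
        assert arch.flatten_dim == 64

    def test_unit_kernel_preserves_length(self):
        arch = CNNArchitecture(input_length=17)
        assert arch.sequence_trace()[:4] == [17, 17, 17, 17]

    def test_default_parameter_count_matches_hand_trace(self):
        _, count = build_cnn(CNNArchitecture(), seed=0)
        # (1*8+8) + (8*16+16) + (16*32+32) + (40*32+32) + (64*1+1)
        assert count == 2081

    def test_parameter_count_is_data_independent(self):
        _, a = build_cnn(CNNArchitecture(), seed=0)
        _, b = build_cnn(CNNArchitecture(), seed=99)
        assert a == b

    def test_non_increasing_channels_rejected(self):
        with pytest.raises(ValueError):
            CNNArchitecture(conv_channels=(8, 8, 32))

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            CNNArchitecture(input_length=3)

    def test_mismatched_skip_lengths_rejected(self):
        # kernel > 1 shrinks every conv, so conv-1 and conv-3 outputs
        # cannot be concatenated
        with pytest.raises(ValueError):
            CNNArchitecture(input_length=12, kernel_size=2)

    def test_deterministic_init_per_seed(self):
        a, _ = build_cnn(CNNArchitecture(), seed=3)
        b, _ = build_cnn(CNNArchitecture(), seed=3)
        assert all(np.array_equal(a.params[k], b.params[k])
                   for k in a.params)
        for name, p in a.params.items():
            if name.endswith("b"):
                assert np.all(p == 0.0)


class TestForward:
    def test_output_in_open_unit_interval(self, rng):
        model, _ = build_cnn(CNNArchitecture(), seed=0)
        p = forward(model, rng.standard_normal(10))
        assert 0.0 < p < 1.0

    def test_zero_weight_model_outputs_half(self):
        model, _ = build_cnn(CNNArchitecture(), seed=0)
        for k in model.params:
            model.params[k] = np.zeros_like(model.params[k])
        assert forward(model, np.ones(10)) == pytest.approx(0.5)

    def test_batched_equals_per_row(self, rng):
        model, _ = build_cnn(CNNArchitecture(), seed=1)
        X = rng.standard_normal((12, 10))
        batched = forward(model, X)
        single = np.array([forward(model, x) for x in X])
        assert np.allclose(batched, single, atol=1e-6)

    def test_permutation_equivariant_over_rows(self, rng):
        model, _ = build_cnn(CNNArchitecture(), seed=1)
        X = rng.standard_normal((15, 10))
        perm = rng.permutation(15)
        assert np.allclose(forward(model, X)[perm], forward(model, X[perm]))

    def test_dimension_mismatch_rejected(self, rng):
        model, _ = build_cnn(CNNArchitecture(), seed=0)
        with pytest.raises(ValueError):
            forward(model, rng.standard_normal(7))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        model, _ = build_cnn(CNNArchitecture(), seed=2)
        X = rng.standard_normal((6, 10))
        y = rng.integers(0, 2, 6).astype(float)
        probs, caches = _forward_batch(model, X, cache=True)
        grads = _backward_batch(model, probs, caches, y)

        def loss():
            p = np.clip(_forward_batch(model, X), 1e-12, 1 - 1e-12)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        h = 1e-6
        for name, g in grads.items():
            P = model.params[name]
            flat_idx = rng.choice(P.size, size=min(4, P.size),
                                  replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, P.shape)
                old = P[idx]
                P[idx] = old + h
                lp = loss()
                P[idx] = old - h
                lm = loss()
                P[idx] = old
                num = (lp - lm) / (2 * h)
                assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-8), name


class TestTraining:
    def test_loss_descends_on_average(self, rng):
        X = np.vstack([rng.normal(-1, 0.3, (40, 10)),
                       rng.normal(1, 0.3, (40, 10))])
        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        model, _ = build_cnn(CNNArchitecture(), seed=0)
        _, hist = train_classifier(
            model, (X, y), ClassifierTrainConfig(iterations=600, seed=0))
        assert hist["loss"][-100:].mean() < hist["loss"][:100].mean()

    def test_bit_reproducible_runs(self, rng):
        X = rng.standard_normal((30, 10))
        y = rng.integers(0, 2, 30)
        cfg = ClassifierTrainConfig(iterations=120, seed=5)
        m1, h1 = train_classifier(build_cnn(CNNArchitecture(), 5)[0],
                                  (X, y), cfg)
        m2, h2 = train_classifier(build_cnn(CNNArchitecture(), 5)[0],
                                  (X, y), cfg)
        assert np.array_equal(h1["loss"], h2["loss"])
        assert all(np.array_equal(m1.params[k], m2.params[k])
                   for k in m1.params)

    def test_non_binary_labels_rejected(self, rng):
        model, _ = build_cnn(CNNArchitecture(), seed=0)
        with pytest.raises(ValueError):
            train_classifier(model, (rng.standard_normal((4, 10)),
                                     np.array([0, 1, 2, 1])),
                             ClassifierTrainConfig(iterations=1))

    def test_learns_separable_synthetic_data(self, rng):
        """Training accuracy approaches the (high) achievable level on
        strongly separated clusters."""
        X = np.vstack([rng.normal(-1, 0.3, (60, 10)),
                       rng.normal(1, 0.3, (60, 10))])
        y = np.r_[np.zeros(60, int), np.ones(60, int)]
        clf = CNNClassifier(iterations=800, random_state=0).fit(X, y)
        assert np.mean(clf.predict(X) == y) >= 0.95


class TestPredict:
    def test_threshold_rule_with_ge(self):
        table = DescriptorTable(np.zeros((3, 10)), [0, 1, 1],
                                [f"f{i}" for i in range(10)])
        model, _ = build_cnn(CNNArchitecture(), seed=0)
        labels, probs = predict(model, table, threshold=0.5)
        assert np.array_equal(labels, (probs >= 0.5).astype(int))

    def test_extreme_thresholds(self, rng):
        model, _ = build_cnn(CNNArchitecture(), seed=0)
        X = rng.standard_normal((8, 10))
        labels_lo, _ = predict(model, X, threshold=1e-12)
        labels_hi, _ = predict(model, X, threshold=1 - 1e-12)
        assert np.all(labels_lo == 1)
        assert np.all(labels_hi == 0)
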