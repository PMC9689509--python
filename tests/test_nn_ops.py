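"""Autograd ops, attention blocks and segmentation metrics against
brute-force oracles and numerical gradients."""

import numpy as np
import pytest

from girthvision.nn import (
    CBAM,
    ChannelAttention,
    SpatialAttention,
    Tensor,
    channel_attention,
    confusion_matrix,
    segmentation_metrics,
    spatial_attention,
)
from girthvision.nn.training import softmax_cross_entropy


def numerical_grad(fn, x, eps=1e-3):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = fn()
        x[i] = orig - eps
        fm = fn()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def check_op_gradient(build, shape, seed=0, tol=5e-2):
    """Compare autograd input-gradient of sum(op(x)) with central differences."""
    rng = np.random.default_rng(seed)
    data = rng.normal(size=shape).astype(np.float32)
    x = Tensor(data, requires_grad=True)
    out = build(x)
    loss = out.sum() if not np.isscalar(out.data) and out.data.size > 1 else out
    loss.backward(np.ones_like(loss.data))
    analytic = x.grad.astype(np.float64)

    def value():
        return float(build(Tensor(data)).data.sum())

    numeric = numerical_grad(value, data)
    denom = np.maximum(np.abs(numeric), 1.0)
    assert np.max(np.abs(analytic - numeric) / denom) < tol


class TestAutogradOps:
    def test_conv2d_matches_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 4, 7, 7)).astype(np.float32)
        w = rng.normal(size=(6, 2, 3, 3)).astype(np.float32)  # groups=2
        out = Tensor(x).conv2d(Tensor(w), stride=2, padding=1, groups=2).data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        ho = wo = (7 + 2 - 3) // 2 + 1
        ref = np.zeros((2, 6, ho, wo), np.float32)
        for n in range(2):
            for o in range(6):
                g = o // 3
                for i in range(ho):
                    for j in range(wo):
                        patch = xp[n, 2 * g:2 * g + 2, 2 * i:2 * i + 3,
                                   2 * j:2 * j + 3]
                        ref[n, o, i, j] = np.sum(patch * w[o])
        assert np.allclose(out, ref, atol=1e-5)

    def test_grouped_conv_equals_block_diagonal_full_conv(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
        wg = rng.normal(size=(4, 2, 3, 3)).astype(np.float32)
        grouped = Tensor(x).conv2d(Tensor(wg), padding=1, groups=2).data
        wf = np.zeros((4, 4, 3, 3), np.float32)
        wf[:2, :2] = wg[:2]
        wf[2:, 2:] = wg[2:]
        full = Tensor(x).conv2d(Tensor(wf), padding=1).data
        assert np.allclose(grouped, full, atol=1e-5)

    @pytest.mark.parametrize(
        "name,build,shape",
        [
            ("relu", lambda x: x.relu(), (2, 3, 4, 4)),
            ("sigmoid", lambda x: x.sigmoid(), (2, 3, 4, 4)),
            ("maxpool", lambda x: x.maxpool2d(3, 2, 1), (1, 2, 7, 7)),
            ("adaptive_pool", lambda x: x.adaptive_avg_pool2d((3, 3)), (1, 2, 7, 7)),
            ("upsample", lambda x: x.upsample_bilinear((9, 9)), (1, 2, 4, 4)),
            ("max_over", lambda x: x.max_over(1, keepdims=True), (2, 4, 3, 3)),
            ("mean_axes", lambda x: x.mean(axis=(0, 2, 3)), (2, 3, 4, 4)),
        ],
    )
    def test_op_gradients_match_finite_differences(self, name, build, shape):
        check_op_gradient(build, shape, seed=hash(name) % 100)

    def test_conv_weight_and_input_gradients(self):
        rng = np.random.default_rng(3)
        wdata = rng.normal(size=(4, 2, 3, 3)).astype(np.float32)

        def build(x):
            return x.conv2d(Tensor(wdata), stride=1, padding=1, groups=2)

        check_op_gradient(build, (2, 4, 5, 5), seed=3)

        xdata = rng.normal(size=(2, 4, 5, 5)).astype(np.float32)
        w = Tensor(wdata, requires_grad=True)
        out = Tensor(xdata).conv2d(w, padding=1, groups=2)
        out.sum().backward(np.ones(1))
        analytic = w.grad.astype(np.float64)

        def value():
            return float(Tensor(xdata).conv2d(Tensor(wdata), padding=1, groups=2).data.sum())

        numeric = numerical_grad(value, wdata)
        assert np.max(np.abs(analytic - numeric) / np.maximum(np.abs(numeric), 1.0)) < 5e-2

    def test_batch_norm_training_gradient(self):
        rng = np.random.default_rng(4)
        gamma = rng.normal(size=3).astype(np.float32) + 1.0
        beta = rng.normal(size=3).astype(np.float32)

        def build(x):
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            return x.batch_norm(Tensor(gamma), Tensor(beta), mu, var,
                                batch_stats=True)

        check_op_gradient(build, (2, 3, 4, 4), seed=4)

    def test_softmax_cross_entropy_value_and_gradient(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        targets = rng.integers(0, 3, size=(2, 4, 4))
        t = Tensor(scores, requires_grad=True)
        loss = softmax_cross_entropy(t, targets)
        # oracle value: -log p[target] averaged over pixels
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        p = e / e.sum(axis=1, keepdims=True)
        ref = 0.0
        for n in range(2):
            for i in range(4):
                for j in range(4):
                    ref -= np.log(p[n, targets[n, i, j], i, j])
        ref /= targets.size
        assert np.isclose(float(loss.data), ref, atol=1e-5)
        loss.backward()

        def value():
            return float(softmax_cross_entropy(Tensor(scores), targets).data)

        numeric = numerical_grad(value, scores)
        assert np.max(np.abs(t.grad - numeric)) < 1e-3


class TestChannelAttention:
    def test_output_shape_matches_input(self):
        x = np.random.default_rng(0).normal(size=(4, 16, 6, 6)).astype(np.float32)
        a, fc = channel_attention(x, reduction=4)
        assert fc.shape == x.shape
        assert a.shape == (4, 16)

    def test_zero_input_is_gated_to_zero(self):
        a, fc = channel_attention(np.zeros((8, 5, 5), np.float32), reduction=4)
        assert np.allclose(fc, 0.0)
        assert np.all((a > 0) & (a < 1))

    def test_hand_set_identity_perceptron_on_two_channel_input(self):
        # 2 channels, 1x1 spatial: avg pool == max pool == the value itself,
        # identity perceptron -> attention = sigmoid(2 * relu(v))
        mod = ChannelAttention(2, reduction=1)
        mod.mlp.layers[0].weight.data = np.eye(2, dtype=np.float32)
        mod.mlp.layers[2].weight.data = np.eye(2, dtype=np.float32)
        v = np.array([0.7, -1.3], np.float32)
        x = v.reshape(1, 2, 1, 1)
        a, fc = channel_attention(x, module=mod)
        expected_a = 1 / (1 + np.exp(-2 * np.maximum(v, 0)))
        assert np.allclose(a.reshape(2), expected_a, atol=1e-6)
        assert np.allclose(fc.reshape(2), v * expected_a, atol=1e-6)

    def test_indivisible_reduction_raises(self):
        with pytest.raises(ValueError, match="invalid reduction"):
            ChannelAttention(10, reduction=4)

    def test_attention_strictly_inside_unit_interval(self):
        x = np.random.default_rng(1).normal(size=(2, 8, 5, 5)).astype(np.float32) * 5
        a, _ = channel_attention(x, reduction=2)
        assert np.all(a > 0) and np.all(a < 1)


class TestSpatialAttention:
    def test_output_shape_matches_input(self):
        x = np.random.default_rng(0).normal(size=(3, 7, 9, 9)).astype(np.float32)
        a, fcs = spatial_attention(x)
        assert fcs.shape == x.shape
        assert a.shape == (3, 1, 9, 9)

    def test_zero_kernel_gives_uniform_half_attention(self):
        mod = SpatialAttention()
        mod.conv.weight.data = np.zeros_like(mod.conv.weight.data)
        x = np.full((4, 6, 6), 3.0, np.float32)
        a, fcs = spatial_attention(x, module=mod)
        assert np.allclose(a, 0.5)
        assert np.allclose(fcs, 0.5 * x)

    def test_hand_rolled_convolution_oracle(self):
        rng = np.random.default_rng(2)
        mod = SpatialAttention()
        k = rng.normal(size=(1, 2, 7, 7)).astype(np.float32)
        mod.conv.weight.data = k
        x = rng.normal(size=(1, 1, 3, 3)).astype(np.float32)
        a, fcs = spatial_attention(x, module=mod)
        # single channel: mean map == max map == x
        maps = np.concatenate([x, x], axis=1)[0]
        padded = np.pad(maps, ((0, 0), (3, 3), (3, 3)))
        ref = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                ref[i, j] = np.sum(padded[:, i:i + 7, j:j + 7] * k[0])
        ref = 1 / (1 + np.exp(-ref))
        assert np.allclose(a[0, 0], ref, atol=1e-5)
        assert np.allclose(fcs[0, 0], x[0, 0] * ref, atol=1e-5)

    def test_cbam_composition_preserves_shape_and_differentiates(self):
        mod = CBAM(8, reduction=4)
        x = Tensor(
            np.random.default_rng(3).normal(size=(2, 8, 6, 6)).astype(np.float32),
            requires_grad=True,
        )
        out = mod(x)
        assert out.shape == x.shape
        out.sum().backward(np.ones(1))
        assert x.grad is not None and np.any(x.grad != 0)
        assert all(p.grad is not None for p in mod.parameters())


class TestSegmentationMetrics:
    def test_perfect_prediction_scores_hundreds(self):
        m = np.array([[0, 1], [2, 1]])
        assert segmentation_metrics(m, m, 3) == (100.0, 100.0, 100.0)

    def test_fully_swapped_binary_masks_zero_accuracy(self):
        truth = np.array([[0, 0], [1, 1]])
        pa, mpa, miou = segmentation_metrics(1 - truth, truth, 2)
        assert pa == 0.0 and mpa == 0.0 and miou == 0.0

    def test_reference_toy_example(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, 1, 1, 1])
        pa, mpa, miou = segmentation_metrics(pred, truth, 2)
        assert pa == pytest.approx(75.0)
        assert mpa == pytest.approx(75.0)  # mean of 50 and 100
        assert miou == pytest.approx(100 * (0.5 + 2 / 3) / 2, abs=0.01)  # 58.33

    def test_classes_absent_from_both_masks_are_excluded(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, 0, 1, 1])
        pa, mpa, miou = segmentation_metrics(pred, truth, 5)
        assert (pa, mpa, miou) == (100.0, 100.0, 100.0)

    def test_matches_brute_force_confusion_oracle_on_random_masks(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            k = int(rng.integers(2, 5))
            truth = rng.integers(0, k, size=(13, 11))
            pred = rng.integers(0, k, size=(13, 11))
            pa, mpa, miou = segmentation_metrics(pred, truth, k)
            accs, ious = [], []
            for c in range(k):
                tp = np.sum((pred == c) & (truth == c))
                fn = np.sum((pred != c) & (truth == c))
                fp = np.sum((pred == c) & (truth != c))
                if tp + fn + fp == 0:
                    continue
                accs.append(tp / (tp + fn) if tp + fn else 0.0)
                ious.append(tp / (tp + fn + fp))
            assert pa == pytest.approx(100 * np.mean(pred == truth))
            assert mpa == pytest.approx(100 * np.mean(accs))
            assert miou == pytest.approx(100 * np.mean(ious))

    def test_shape_mismatch_and_bad_values_raise(self):
        with pytest.raises(ValueError, match="incompatible"):
            segmentation_metrics(np.zeros((2, 2)), np.zeros((2, 3)), 2)
        with pytest.raises(ValueError):
            segmentation_metrics(np.array([5]), np.array([0]), 2)

    def test_confusion_matrix_counts(self):
        cm = confusion_matrix(np.array([0, 1, 1]), np.array([0, 0, 1]), 2)
        assert cm.tolist() == [[1, 1], [0, 1]]
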