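import numpy as np
import pytest

import sleepradar.nn as nn
from sleepradar.model import ModelConfig, build_restcn, build_variant
from sleepradar.nn.network import _make_tcn
from sleepradar.nn.optim import AdamW


def numeric_gradient(layer, x, grad_out, param_handle, eps=1e-2):
    """Central-difference gradient of sum(out * grad_out) w.r.t. one weight."""
    mod, name = param_handle
    flat = mod.params[name].ravel()
    out = np.zeros_like(flat, dtype=np.float64)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = float((layer.forward(x) * grad_out).sum())
        flat[i] = orig - eps
        lo = float((layer.forward(x) * grad_out).sum())
        flat[i] = orig
        out[i] = (hi - lo) / (2 * eps)
    return out.reshape(mod.params[name].shape)


class TestGradients:
    """Analytic backward passes agree with central differences."""

    @pytest.mark.parametrize("stride", [(1, 1), (2, 1)])
    def test_conv2d(self, stride):
        rng = np.random.default_rng(0)
        layer = nn.Conv2d(2, 3, 3, stride, rng=rng, bias=True)
        x = rng.normal(size=(2, 2, 6, 7)).astype(np.float32)
        g = rng.normal(size=layer.forward(x).shape).astype(np.float32)
        layer.forward(x)
        gx = layer.backward(g)
        for handle in layer.parameters():
            num = numeric_gradient(layer, x, g, handle)
            assert np.allclose(handle[0].grads[handle[1]], num, rtol=0.05, atol=0.02)
        # input gradient via perturbation of one element
        i = (0, 1, 2, 3)
        eps = 1e-2
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        num = ((layer.forward(xp) - layer.forward(xm)) * g).sum() / (2 * eps)
        assert gx[i] == pytest.approx(num, rel=0.05, abs=0.02)

    @pytest.mark.parametrize("dilation", [1, 2])
    def test_causal_conv1d(self, dilation):
        rng = np.random.default_rng(1)
        layer = nn.CausalConv1d(3, 4, 3, dilation, rng=rng)
        x = rng.normal(size=(2, 3, 9)).astype(np.float32)
        g = rng.normal(size=(2, 4, 9)).astype(np.float32)
        layer.forward(x)
        layer.backward(g)
        for handle in layer.parameters():
            num = numeric_gradient(layer, x, g, handle)
            assert np.allclose(handle[0].grads[handle[1]], num, rtol=0.05, atol=0.02)

    def test_batchnorm_and_linear(self):
        rng = np.random.default_rng(2)
        bn = nn.BatchNorm(3)
        x = rng.normal(size=(8, 3, 5)).astype(np.float32)
        g = rng.normal(size=(8, 3, 5)).astype(np.float32)
        bn.forward(x)
        bn.backward(g)
        for handle in bn.parameters():
            num = numeric_gradient(bn, x, g, handle)
            assert np.allclose(handle[0].grads[handle[1]], num, rtol=0.05, atol=0.02)

        lin = nn.Linear(4, 2, rng=rng)
        x = rng.normal(size=(6, 4)).astype(np.float32)
        g = rng.normal(size=(6, 2)).astype(np.float32)
        lin.forward(x)
        lin.backward(g)
        for handle in lin.parameters():
            num = numeric_gradient(lin, x, g, handle)
            assert np.allclose(handle[0].grads[handle[1]], num, rtol=0.05, atol=0.02)


class TestLoss:
    def test_perfect_onehot_prediction_is_zero(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        assert nn.cross_entropy_loss(probs, probs) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_costs_ln3(self):
        probs = np.full((4, 3), 1 / 3)
        labels = np.eye(3)[[0, 1, 2, 0]]
        assert nn.cross_entropy_loss(probs, labels) == pytest.approx(np.log(3), rel=1e-6)

    def test_mixup_label_self_prediction_costs_ln2(self):
        p = np.array([[0.5, 0.0, 0.5]])
        assert nn.cross_entropy_loss(p, p) == pytest.approx(np.log(2), rel=1e-6)

    def test_nonfinite_probabilities_rejected(self):
        with pytest.raises(ValueError):
            nn.cross_entropy_loss(np.array([[np.nan, 0.5, 0.5]]), np.eye(3)[[0]])

    def test_softmax_grad_direction(self):
        logits = np.zeros((2, 3))
        labels = np.eye(3)[[0, 1]]
        loss, probs, grad = nn.softmax_cross_entropy(logits, labels)
        assert loss == pytest.approx(np.log(3))
        assert np.allclose(grad.sum(axis=1), 0, atol=1e-7)
        assert grad[0, 0] < 0 < grad[0, 1]


class TestNetworks:
    def test_output_shape_and_probability_contract(self):
        net = build_restcn(ModelConfig(seed=0))
        net.set_training(False)
        x = np.random.default_rng(0).random((5, 40, 60)).astype(np.float32)
        probs = nn.softmax(net.forward(x))
        assert probs.shape == (5, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_same_seed_same_initial_weights(self):
        a = build_restcn(ModelConfig(seed=11))
        b = build_restcn(ModelConfig(seed=11))
        for (ma, na), (mb, nb) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(ma.params[na], mb.params[nb])

    def test_repeat_forward_identical_in_eval_mode(self):
        net = build_restcn(ModelConfig(seed=3))
        net.set_training(False)
        x = np.random.default_rng(1).random((4, 40, 60)).astype(np.float32)
        assert np.array_equal(net.forward(x), net.forward(x))

    def test_batch_permutation_equivariance(self):
        net = build_restcn(ModelConfig(seed=4))
        net.set_training(False)
        x = np.random.default_rng(2).random((6, 40, 60)).astype(np.float32)
        perm = np.array([3, 1, 5, 0, 2, 4])
        out = net.forward(x)
        assert np.allclose(net.forward(x[perm]), out[perm], atol=1e-5)

    def test_embedding_dimension_is_1024(self):
        """The backbone emits 1024-dim per-step feature vectors."""
        from sleepradar.nn.layers import CausalConv1d
        net = build_restcn(ModelConfig())
        projections = [m for m, _ in ((m, n) for m, n in net.parameters())
                       if isinstance(m, CausalConv1d) and m.c_out == 1024]
        assert projections, "1024-dim embedding projection missing"

    @pytest.mark.parametrize("variant", ["resnet_only", "tcn_only"])
    def test_variants_emit_three_logits(self, variant):
        net = build_variant(variant, ModelConfig(seed=0))
        net.set_training(False)
        x = np.random.default_rng(3).random((2, 40, 60)).astype(np.float32)
        assert net.forward(x).shape == (2, 3)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_variant("lstm", ModelConfig())

    def test_resnet_only_is_strictly_smaller_than_restcn(self):
        full = build_restcn(ModelConfig(seed=0)).n_parameters()
        resnet = build_variant("resnet_only", ModelConfig(seed=0)).n_parameters()
        assert resnet < full

    def test_tcn_causality(self):
        """Zeroing the last k input steps leaves earlier outputs unchanged."""
        rng = np.random.default_rng(5)
        drop_rng = np.random.default_rng(6)
        tcn = _make_tcn(8, (16, 16), 3, (1, 2), 0.0, rng, drop_rng)
        tcn.set_training(False)
        x = rng.normal(size=(1, 8, 20)).astype(np.float32)
        k = 5
        x2 = x.copy()
        x2[:, :, -k:] = 0.0
        out, out2 = tcn.forward(x.copy()), tcn.forward(x2)
        assert np.allclose(out[:, :, : 20 - k], out2[:, :, : 20 - k], atol=1e-6)

    def test_gradient_reaches_every_parameter(self):
        net = build_restcn(ModelConfig(seed=7, dropout=0.0))
        net.set_training(True)
        rng = np.random.default_rng(8)
        x = rng.random((8, 40, 60)).astype(np.float32)
        y = np.eye(3)[rng.integers(0, 3, 8)]
        _, _, g = nn.softmax_cross_entropy(net.forward(x), y)
        net.backward(g)
        for mod, name in net.parameters():
            assert np.any(mod.grads[name] != 0), f"dead gradient in {type(mod).__name__}.{name}"

    def test_overfits_eight_images(self):
        """Capacity check: the full model memorizes 8 images within 200 steps."""
        rng = np.random.default_rng(9)
        x = rng.random((8, 40, 60)).astype(np.float32)
        y = np.eye(3)[np.array([0, 1, 2, 0, 1, 2, 0, 1])]
        net = build_restcn(ModelConfig(seed=10, dropout=0.0))
        opt = AdamW(net.parameters(), lr=0.002, weight_decay=0.0)
        done = False
        for step in range(200):
            net.set_training(True)
            logits = net.forward(x)
            _, _, g = nn.softmax_cross_entropy(logits, y)
            net.backward(g)
            opt.step()
            if step % 20 == 19:  # training accuracy, measured in eval mode
                net.set_training(False)
                probs = nn.softmax(net.forward(x))
                if (probs.argmax(1) == y.argmax(1)).all():
                    done = True
                    break
        assert done
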