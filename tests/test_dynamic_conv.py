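"""Expert-kernel convolution: routing, fusion, batched-vs-oracle equivalence,
and the parameter budget of the layer and its CSP blocks."""

import numpy as np
import pytest

from teayolo.nn.autograd import Tensor
from teayolo.nn import functional as F
from teayolo.dynamic_conv import (
    pool_descriptor, route, fuse_kernels, dynamic_conv_forward,
    DynamicConv, DynamicConvC3k2,
)


class TestPoolDescriptor:
    def test_constant_map(self):
        x = np.full((1, 3, 4, 4), 2.0)
        np.testing.assert_allclose(pool_descriptor(x).data, 2.0)

    def test_small_map_mean(self):
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 2, 2)
        assert pool_descriptor(x).data[0, 0] == pytest.approx(2.5)

    def test_matches_bruteforce_sum(self, rng):
        x = rng.normal(size=(2, 3, 5, 5))
        # independent oracle: explicit elementwise accumulation / 25
        expected = np.zeros((2, 3))
        for b in range(2):
            for c in range(3):
                acc = 0.0
                for i in range(5):
                    for j in range(5):
                        acc += x[b, c, i, j]
                expected[b, c] = acc / 25
        np.testing.assert_allclose(pool_descriptor(x).data, expected, atol=1e-12)


class TestRoute:
    def test_equal_logits_uniform(self):
        v = np.ones((1, 4))
        w = np.zeros((3, 4))
        b = np.zeros(3)
        np.testing.assert_allclose(route(v, w, b).data, 1 / 3, atol=1e-12)

    def test_closed_form_two_experts(self):
        # logits (ln 3, ln 1) -> alpha (0.75, 0.25)
        v = np.ones((1, 1))
        w = np.array([[np.log(3.0)], [0.0]])
        b = np.zeros(2)
        np.testing.assert_allclose(route(v, w, b).data[0], [0.75, 0.25], atol=1e-12)

    def test_matches_exp_normalize_oracle(self, rng):
        v = rng.normal(size=(3, 5))
        w = rng.normal(size=(4, 5))
        b = rng.normal(size=4)
        logits = v @ w.T + b
        expected = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(route(v, w, b).data, expected, atol=1e-6)

    def test_simplex_invariant(self, rng):
        alpha = route(rng.normal(size=(6, 8)), rng.normal(size=(5, 8)),
                      rng.normal(size=5)).data
        assert np.all(alpha >= 0) and np.all(alpha <= 1)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="does not match"):
            route(np.ones((1, 3)), np.ones((2, 4)), np.zeros(2))


class TestFuseKernels:
    def test_one_hot_selects_expert(self, rng):
        bank = rng.normal(size=(3, 4, 2, 3, 3))
        alpha = np.array([[0.0, 1.0, 0.0]])
        np.testing.assert_allclose(fuse_kernels(bank, alpha).data[0], bank[1])

    def test_midpoint_of_two_experts(self):
        bank = np.stack([np.ones((2, 2, 3, 3)), 3 * np.ones((2, 2, 3, 3))])
        fused = fuse_kernels(bank, np.array([0.5, 0.5]))
        np.testing.assert_allclose(fused.data, 2.0)

    def test_matches_loop_oracle(self, rng):
        bank = rng.normal(size=(4, 3, 2, 3, 3))
        alpha = rng.dirichlet(np.ones(4), size=2)
        expected = np.zeros((2, 3, 2, 3, 3))
        for b in range(2):
            for m in range(4):
                expected[b] += alpha[b, m] * bank[m]
        np.testing.assert_allclose(fuse_kernels(bank, alpha).data, expected, atol=1e-12)

    def test_wrong_coefficient_count_rejected(self, rng):
        with pytest.raises(ValueError, match="experts"):
            fuse_kernels(rng.normal(size=(3, 2, 2, 3, 3)), np.ones((1, 4)) / 4)


class TestDynamicForward:
    def test_one_hot_reduces_to_static_conv(self, rng):
        bank = rng.normal(size=(3, 4, 2, 3, 3)).astype(np.float32)
        x = rng.normal(size=(1, 2, 6, 6)).astype(np.float32)
        # router forcing expert 2: huge bias on that logit
        w = np.zeros((3, 2), dtype=np.float32)
        b = np.array([-1e4, -1e4, 0.0], dtype=np.float32)
        out = dynamic_conv_forward(x, Tensor(bank), Tensor(w), Tensor(b))
        ref = F.conv2d(Tensor(x), Tensor(bank[2]), padding=1)
        np.testing.assert_allclose(out.data, ref.data, atol=1e-5)

    def test_batched_equals_per_sample_oracle(self, rng):
        bank = Tensor(rng.normal(size=(4, 5, 3, 3, 3)).astype(np.float32))
        w = Tensor(rng.normal(size=(4, 3)).astype(np.float32))
        b = Tensor(rng.normal(size=4).astype(np.float32))
        x = rng.normal(size=(3, 3, 8, 8)).astype(np.float32)
        out = dynamic_conv_forward(x, bank, w, b, stride=2)
        for i in range(3):
            xi = x[i:i + 1]
            alpha = route(pool_descriptor(xi), w, b).data[0]
            fused = np.einsum("m,moikl->oikl", alpha, bank.data)
            ref = F.conv2d(Tensor(xi), Tensor(fused), stride=2, padding=1)
            np.testing.assert_allclose(out.data[i], ref.data[0], atol=1e-5)

    def test_identical_experts_alpha_independent(self, rng):
        kernel = rng.normal(size=(4, 2, 3, 3)).astype(np.float32)
        bank = Tensor(np.stack([kernel] * 5))
        x = rng.normal(size=(2, 2, 6, 6)).astype(np.float32)
        w1 = Tensor(rng.normal(size=(5, 2)).astype(np.float32))
        w2 = Tensor(rng.normal(size=(5, 2)).astype(np.float32))
        b0 = Tensor(np.zeros(5, dtype=np.float32))
        out1 = dynamic_conv_forward(x, bank, w1, b0)
        out2 = dynamic_conv_forward(x, bank, w2, b0)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-5)

    def test_gradients_reach_every_expert(self, rng):
        layer = DynamicConv(2, 3, 3, 1, num_experts=4)
        x = Tensor(rng.normal(size=(2, 2, 4, 4)).astype(np.float32))
        (layer(x) ** 2).sum().backward()
        g = layer.experts.grad
        assert g is not None
        for m in range(4):
            assert np.abs(g[m]).max() > 0, f"expert {m} received no gradient"
        assert layer.router_weight.grad is not None
        assert np.abs(layer.router_weight.grad).max() > 0


class TestParameterBudget:
    @pytest.mark.parametrize("cin,cout,expected", [(128, 128, 590_596),
                                                   (128, 256, 1_180_676)])
    def test_layer_counts_match_table(self, cin, cout, expected):
        layer = DynamicConv(cin, cout, 3, 2)
        assert layer.num_params() == expected

    def test_count_formula(self):
        m, cin, cout, k = 4, 32, 48, 3
        layer = DynamicConv(cin, cout, k, 1, num_experts=m)
        assert layer.num_params() == m * cout * cin * k ** 2 + (cin * m + m) + 2 * cout

    @pytest.mark.parametrize("args,expected", [
        ((32, 64, 1, False, 0.25), 15_940),
        ((384, 128, 1, True), 175_368),
    ])
    def test_c3k2_counts_match_table(self, args, expected):
        assert DynamicConvC3k2(*args).num_params() == expected

    def test_c3k2_shape_contract(self, rng):
        block = DynamicConvC3k2(8, 16, 1, False, 0.5)
        x = Tensor(rng.normal(size=(2, 8, 6, 6)).astype(np.float32))
        out = block(x)
        assert out.shape == (2, 16, 6, 6)

    def test_c3k2_rejects_bad_expansion(self):
        with pytest.raises(ValueError, match="expansion"):
            DynamicConvC3k2(8, 16, 1, False, 0.0)
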