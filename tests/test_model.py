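"""Network tests: shape conformance, hand-computed oracles, gradients."""

import numpy as np
import pytest

from forcemi.nn import (ChannelAttention, ModelConfig, MSTCNAMNetwork,
                        count_parameters, cross_entropy, softmax)
from forcemi.nn.network import EPS_PROB


@pytest.fixture(scope="module")
def tiny_cfg():
    return ModelConfig(n_electrodes=4, n_timepoints=32,
                       branch_kernel_widths=(3, 5), branch_filters=2,
                       spatial_filters=6, pool_width=8, dropout_p=0.0,
                       attention_reduction=3)


class TestShapes:
    @pytest.mark.parametrize("N,M", [(30, 768), (16, 256)])
    def test_stage_shapes_follow_architecture_table(self, N, M):
        cfg = ModelConfig(n_electrodes=N, n_timepoints=M)
        net = MSTCNAMNetwork(cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((2, N, M))
        inter = net.forward_intermediates(x)
        assert inter["input"].shape == (2, 1, N, M)
        assert inter["concat"].shape == (2, 24, N, M)
        assert inter["spatial"].shape == (2, 48, 1, M // 64)
        assert inter["attended"].shape == (2, 48, 1, M // 64)
        assert inter["probs"].shape == (2, 3)
        np.testing.assert_allclose(inter["probs"].sum(axis=1), 1, atol=1e-6)

    def test_flattened_feature_count(self):
        cfg = ModelConfig(n_electrodes=30, n_timepoints=768)
        assert cfg.n_features == 576  # 48 * 768/64

    def test_branch_stacking_equals_concat(self, tiny_cfg):
        net = MSTCNAMNetwork(tiny_cfg, np.random.default_rng(0))
        x = np.random.default_rng(2).standard_normal(
            (3, 1, 4, 32)).astype(np.float32)
        together = net.mstcn.forward(x, train=False)
        separate = np.concatenate(
            [b.forward(x, train=False) for b in net.mstcn.branches], axis=1)
        np.testing.assert_allclose(together, separate)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(n_electrodes=4, n_timepoints=100, pool_width=64)
        with pytest.raises(ValueError, match="reduction"):
            ModelConfig(n_electrodes=4, n_timepoints=64,
                        spatial_filters=48, attention_reduction=7)
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(n_electrodes=4, n_timepoints=64,
                        branch_kernel_widths=(2, 4, 6))


class TestZeroWeightOracles:
    def test_zero_temporal_weights_zero_output(self, tiny_cfg):
        net = MSTCNAMNetwork(tiny_cfg, np.random.default_rng(0))
        for branch in net.mstcn.branches:
            conv, bn = branch.layers
            conv.params["W"][:] = 0
            conv.params["b"][:] = 0
        x = np.random.default_rng(0).standard_normal((2, 1, 4, 32))
        out = net.mstcn.forward(x.astype(np.float32), train=False)
        np.testing.assert_allclose(out, 0, atol=1e-6)

    def test_constant_block_average_pools_to_itself(self):
        from forcemi.nn import AvgPoolWidth
        pool = AvgPoolWidth(8)
        x = np.full((1, 2, 1, 16), 3.5)
        np.testing.assert_allclose(pool.forward(x), 3.5)

    def test_pool_error_names_k(self):
        from forcemi.nn import AvgPoolWidth
        with pytest.raises(ValueError, match="K=64"):
            AvgPoolWidth(64).forward(np.zeros((1, 1, 1, 100)))


class TestAttention:
    def test_zero_mlp_gives_half_weights(self):
        att = ChannelAttention(4, 2, np.random.default_rng(0))
        att.params["W0"][:] = 0
        att.params["W1"][:] = 0
        x = np.random.default_rng(1).standard_normal((2, 4, 1, 6))
        out = att.forward(x)
        np.testing.assert_allclose(out, 0.5 * x)
        np.testing.assert_allclose(att._a, 0.5)

    def test_weights_in_open_unit_interval(self):
        att = ChannelAttention(6, 3, np.random.default_rng(2))
        x = 3 * np.random.default_rng(3).standard_normal((4, 6, 1, 5))
        a = att.attention_weights(x)
        assert np.all(a > 0) and np.all(a < 1)

    def test_hand_computed_two_channel_case(self):
        att = ChannelAttention(2, 1, np.random.default_rng(0))
        W0 = np.array([[1.0, -1.0], [0.5, 2.0]])
        W1 = np.array([[1.0, 0.0], [-1.0, 1.0]])
        att.params["W0"] = W0
        att.params["W1"] = W1
        x = np.array([[[[1.0, 3.0]], [[2.0, -2.0]]]])  # (1, 2, 1, 2)
        p_avg = np.array([2.0, 0.0])
        p_max = np.array([3.0, 2.0])
        z = W1 @ np.maximum(W0 @ p_avg, 0) + W1 @ np.maximum(W0 @ p_max, 0)
        expected = 1 / (1 + np.exp(-z))
        np.testing.assert_allclose(att.attention_weights(x)[0], expected)

    def test_channel_permutation_equivariance(self):
        att = ChannelAttention(6, 1, np.random.default_rng(4))
        # per-channel-symmetric MLP: permuting channels permutes weights
        att.params["W0"] = np.eye(6)
        att.params["W1"] = 0.7 * np.eye(6)
        x = np.random.default_rng(5).standard_normal((3, 6, 1, 4))
        perm = np.array([2, 0, 5, 1, 4, 3])
        a = att.attention_weights(x)
        a_perm = att.attention_weights(x[:, perm])
        np.testing.assert_allclose(a_perm, a[:, perm], atol=1e-12)

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ChannelAttention(5, 2, np.random.default_rng(0))


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.array([[1.0, 0.0, 0.0]])
        assert cross_entropy(probs, [0]) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_three_class_is_ln3(self):
        probs = np.full((4, 3), 1 / 3)
        assert cross_entropy(probs, [0, 1, 2, 0]) == pytest.approx(
            np.log(3.0), rel=1e-12)

    def test_hand_computed_batch(self):
        probs = np.array([[0.5, 0.25, 0.25], [0.25, 0.25, 0.5]])
        expected = (np.log(2) + np.log(4)) / 2
        assert cross_entropy(probs, [0, 0]) == pytest.approx(expected)

    def test_zero_probability_clamped_with_warning(self):
        probs = np.array([[0.0, 1.0]])
        with pytest.warns(UserWarning, match="clamp"):
            loss = cross_entropy(probs, [0])
        assert loss == pytest.approx(-np.log(EPS_PROB))


class TestForwardContract:
    def test_eval_mode_deterministic(self, tiny_cfg):
        net = MSTCNAMNetwork(tiny_cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((4, 4, 32))
        x = (x - x.mean()) / x.std()
        np.testing.assert_array_equal(net.predict_proba(x),
                                      net.predict_proba(x))

    def test_nonfinite_and_unnormalized_rejected(self, tiny_cfg):
        net = MSTCNAMNetwork(tiny_cfg, np.random.default_rng(0))
        bad = np.full((1, 4, 32), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            net.predict_proba(bad)
        huge = 1e6 * np.ones((1, 4, 32))
        with pytest.raises(ValueError, match="normalize"):
            net.predict_proba(huge)


class TestParameterCount:
    def test_analytic_count_matches_actual(self, tiny_cfg):
        for cfg in (tiny_cfg, ModelConfig(n_electrodes=30, n_timepoints=768)):
            net = MSTCNAMNetwork(cfg, np.random.default_rng(0))
            assert count_parameters(cfg) == net.n_parameters()

    def test_doubling_branch_filters_scales_spatial_conv(self):
        base = ModelConfig(n_electrodes=8, n_timepoints=64, branch_filters=8)
        doubled = ModelConfig(n_electrodes=8, n_timepoints=64,
                              branch_filters=16)
        spatial_base = 48 * base.concat_channels * 8
        spatial_doubled = 48 * doubled.concat_channels * 8
        assert spatial_doubled == 2 * spatial_base
        delta = count_parameters(doubled) - count_parameters(base)
        extra_branch = sum(8 * (s + 3) for s in (3, 5, 7))  # conv + bias + BN
        assert delta == (spatial_doubled - spatial_base) + extra_branch


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_cfg):
        """Analytic gradients agree with central differences everywhere."""
        from forcemi.nn.network import cross_entropy, softmax
        net = MSTCNAMNetwork(tiny_cfg, np.random.default_rng(0),
                             dtype=np.float64)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 4, 32))
        y = np.array([0, 1, 2])

        def loss_at():
            logits = net._stages.forward(net._as_input(x), True)
            return cross_entropy(softmax(logits), y)

        net.train_step(x, y)
        eps = 1e-6
        for layer, name in net.parameters():
            g = layer.grads[name]
            p = layer.params[name]
            for idx in [tuple(rng.integers(0, s) for s in p.shape)
                        for _ in range(4)]:
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss_at()
                p[idx] = orig - eps
                lm = loss_at()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) < 1e-6 * (1 + abs(num)), \
                    f"{type(layer).__name__}.{name}[{idx}]"

    def test_gradients_finite_on_random_batch(self):
        cfg = ModelConfig(n_electrodes=6, n_timepoints=64, pool_width=16,
                          attention_reduction=8)
        net = MSTCNAMNetwork(cfg, np.random.default_rng(3))
        x = np.random.default_rng(4).standard_normal((8, 6, 64))
        net.train_step(x, np.arange(8) % 3)
        for layer, name in net.parameters():
            assert np.all(np.isfinite(layer.grads[name]))


class TestOverfitCapacity:
    def test_memorizes_12_random_trials(self):
        """Capacity check: training accuracy reaches 100% on random data."""
        from forcemi.estimator import MSTCNAMClassifier
        rng = np.random.default_rng(0)
        X = rng.standard_normal((12, 6, 64)).astype(np.float32)
        X = (X - X.mean(axis=(1, 2), keepdims=True)) / X.std(
            axis=(1, 2), keepdims=True)
        y = np.arange(12) % 3
        clf = MSTCNAMClassifier(pool_width=16, n_epochs=200, batch_size=12,
                                random_state=0)
        clf.fit(X, y)
        assert clf.score(X, y) == 1.0
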