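"""SE block, convolution, loss and the assembled network against
independent scalar-loop oracles; gradient and structural checks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sparnet import ArchitectureSpec, SparNet, cross_entropy, se_forward, softmax
from sparnet.network import Conv1d, Dense, SEBlock


def se_oracle(u, W1, W2):
    """Scalar-loop squeeze/excitation/scale."""
    C, L = u.shape
    z = np.array([sum(u[k, i] for i in range(L)) / L for k in range(C)])
    hidden = [max(0.0, sum(W1[h, k] * z[k] for k in range(C)))
              for h in range(W1.shape[0])]
    s = np.array([
        1.0 / (1.0 + np.exp(-sum(W2[k, h] * hidden[h] for h in range(len(hidden)))))
        for k in range(C)
    ])
    return u * s[:, None], s


class TestSEBlock:
    def test_constant_channel_squeeze_exact(self, rng):
        blk = SEBlock(3, 2, rng)
        u = np.zeros((1, 3, 7))
        u[0, 1] = 4.5
        blk.forward(u)
        z = u.mean(axis=2)
        assert z[0, 1] == 4.5

    def test_zero_w2_gives_half_gates(self, rng):
        blk = SEBlock(4, 2, rng)
        blk.params["W2"][:] = 0.0
        u = rng.normal(size=(2, 4, 6))
        out = blk.forward(u)
        np.testing.assert_allclose(blk.last_gates, 0.5)
        np.testing.assert_allclose(out, 0.5 * u)

    def test_matches_scalar_loop_oracle(self, rng):
        u = rng.normal(size=(4, 6))
        blk = SEBlock(4, 2, rng)
        out, s = se_forward(u, blk.params["W1"], blk.params["W2"])
        oracle_out, oracle_s = se_oracle(u, blk.params["W1"], blk.params["W2"])
        np.testing.assert_allclose(out, oracle_out, atol=1e-8)
        np.testing.assert_allclose(s, oracle_s, atol=1e-8)
        assert np.all((s > 0) & (s < 1))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            SEBlock(4, 2, rng).forward(rng.normal(size=(1, 5, 6)))


class TestConv:
    def test_matches_nested_loop_oracle(self, rng):
        x = rng.normal(size=(1, 3, 8))
        conv = Conv1d(3, 5, 1, rng)
        out = conv.forward(x)
        W, b = conv.params["W"], conv.params["b"]
        for l in range(4):
            acc = b[0]
            for c in range(3):
                for k in range(5):
                    acc += W[0, c, k] * x[0, c, l + k]
            assert out[0, 0, l] == pytest.approx(acc, abs=1e-12)

    @pytest.mark.parametrize("C", [12, 25])
    def test_branch_output_length_18(self, C, rng):
        arch = ArchitectureSpec(region_channels=(C,) * 5)
        net = SparNet(arch, seed=0)
        x = rng.normal(size=(2, C, 40))
        br = net.branches[0]
        h = br["pool"].forward(br["relu"].forward(br["conv"].forward(br["se"].forward(x))))
        assert h.shape == (2, 1, 18)

    def test_zero_input_zero_output(self, rng):
        conv = Conv1d(3, 5, 1, rng)
        conv.params["b"][:] = 0.0
        assert np.all(conv.forward(np.zeros((1, 3, 10))) == 0.0)


class TestLossAndSoftmax:
    def test_exact_prediction_zero_loss(self):
        p = np.eye(2)[[0, 1, 1]]
        assert cross_entropy(p, p) == 0.0

    def test_uniform_prediction_closed_form(self):
        T = 7
        p = np.full((T, 2), 0.5)
        onehot = np.eye(2)[np.zeros(T, dtype=int)]
        assert cross_entropy(p, onehot) == pytest.approx(T * np.log(2), abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        p = rng.dirichlet([1, 1], size=9)
        labels = rng.integers(0, 2, size=9)
        onehot = np.eye(2)[labels]
        oracle = -sum(
            onehot[i, j] * np.log(p[i, j]) for i in range(9) for j in range(2)
        )
        assert cross_entropy(p, onehot) == pytest.approx(oracle, abs=1e-10)

    def test_zero_probability_clamped_with_warning(self):
        p = np.array([[0.0, 1.0]])
        onehot = np.array([[1.0, 0.0]])
        with pytest.warns(UserWarning, match="clamping"):
            loss = cross_entropy(p, onehot)
        assert np.isfinite(loss)

    @given(st.integers(0, 1000))
    def test_softmax_rows_sum_to_one(self, seed):
        logits = np.random.default_rng(seed).normal(scale=20.0, size=(5, 2))
        p = softmax(logits)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= 0)


def default_batch(rng, B=2, arch=None):
    arch = arch or ArchitectureSpec()
    return [rng.normal(size=(B, C, 40)) for C in arch.region_channels]


class TestSparNet:
    def test_probabilities_normalized(self, rng):
        net = SparNet(seed=3)
        p = net.forward(default_batch(rng))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_forward_deterministic(self, rng):
        X = default_batch(rng)
        a = SparNet(seed=5).forward(X)
        b = SparNet(seed=5).forward(X)
        np.testing.assert_array_equal(a, b)

    def test_no_senet_equals_unit_gates(self, rng):
        """Disabling SE must equal the plain conv pipeline (gates == 1)."""
        arch = ArchitectureSpec(use_senet=False)
        net = SparNet(arch, seed=2)
        X = default_batch(rng)
        # independent manual pipeline from the same weights
        feats = []
        for br, x in zip(net.branches, X):
            h = br["conv"].forward(x)
            h = np.maximum(h, 0.0)
            h = h[:, :, : 36 // 2 * 2].reshape(h.shape[0], 1, 18, 2).max(axis=3)
            feats.append(h)
        m = np.concatenate(feats, axis=1)
        h = net.global_conv.forward(m)
        h = np.maximum(h, 0.0)
        h = h[:, :, :16].reshape(h.shape[0], 1, 8, 2).max(axis=3)
        logits = net.dense.forward(h.reshape(h.shape[0], -1))
        expect = np.exp(logits - logits.max(axis=1, keepdims=True))
        expect /= expect.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(net.forward(X), expect, atol=1e-12)

    def test_gradients_match_finite_differences(self, rng):
        net = SparNet(seed=7)
        X = default_batch(rng, B=2)
        onehot = np.eye(2)[[0, 1]]
        _, grads = net.loss_and_grads(X, onehot)
        eps = 1e-6
        for key in ["dense.W", "global.conv.W", "global.se.W1",
                    "branch1.conv.W", "branch1.se.W2", "branch0.conv.b"]:
            lname, pname = key.rsplit(".", 1)
            arr = net._layer_index[lname].params[pname].reshape(-1)
            for idx in (0, arr.size // 2, arr.size - 1):
                old = arr[idx]
                arr[idx] = old + eps
                lp, _ = net.loss_and_grads(X, onehot)
                arr[idx] = old - eps
                lm, _ = net.loss_and_grads(X, onehot)
                arr[idx] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[key].reshape(-1)[idx]
                assert abs(num - ana) <= 1e-4 * max(abs(num), abs(ana), 1e-3)

    def test_channel_permutation_with_permuted_weights_invariant(self, rng):
        net = SparNet(seed=9)
        X = default_batch(rng)
        base = net.forward(X)
        perm = rng.permutation(12)
        # permute channels of region C (index 0) and the matching weight slices
        X2 = [x.copy() for x in X]
        X2[0] = X2[0][:, perm, :]
        net.branches[0]["conv"].params["W"] = net.branches[0]["conv"].params["W"][:, perm, :]
        net.branches[0]["se"].params["W1"] = net.branches[0]["se"].params["W1"][:, perm]
        net.branches[0]["se"].params["W2"] = net.branches[0]["se"].params["W2"][perm, :]
        np.testing.assert_array_equal(net.forward(X2), base)

    def test_wrong_region_count_rejected(self, rng):
        with pytest.raises(ValueError, match="region tensors"):
            SparNet(seed=0).forward(default_batch(rng)[:4])


class TestParamCount:
    def test_se_block_count(self):
        assert SEBlock(12, 2).count_params() == 2 * 12 * 6  # 144

    def test_dense_count(self):
        assert Dense(8, 2).count_params() == 8 * 2 + 2  # 18

    def test_full_network_counts(self):
        with_se, per_layer = SparNet(ArchitectureSpec(), 0).count_params(breakdown=True)
        without = SparNet(ArchitectureSpec(use_senet=False), 0).count_params()
        assert without < with_se
        assert sum(per_layer.values()) == with_se
        # attention carries most of the weight budget
        se_total = sum(v for k, v in per_layer.items() if k.endswith(".se"))
        assert se_total > with_se / 2
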