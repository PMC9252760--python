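"""Gradient and behaviour checks for the autodiff engine and layers.

Every custom vector-Jacobian product (dense ops, conv1d, the LSTM scan,
attention) is compared against central finite differences on small inputs.
"""

import numpy as np
import pytest

from resprop.nn import (
    Adam,
    Conv1d,
    Dropout,
    LayerNorm,
    LSTM,
    MaskedBatchNorm1d,
    Module,
    MultiheadSelfAttention,
    Parameter,
    Tensor,
    TransformerEncoderLayer,
    concatenate,
    gather_rows,
    log_softmax,
    softmax,
)
from resprop.nn.layers import _lstm_primitive, _reverse_index, sinusoidal_positions


def numeric_grad(fn, param: Tensor, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar-valued fn wrt param.data."""
    grad = np.zeros_like(param.data)
    flat = param.data.ravel()
    gflat = grad.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        f_plus = fn().item()
        flat[i] = orig - eps
        f_minus = fn().item()
        flat[i] = orig
        gflat[i] = (f_plus - f_minus) / (2 * eps)
    return grad


def check_grads(fn, params: list[Tensor], tol: float = 1e-6):
    out = fn()
    for p in params:
        p.grad = None
    out.backward()
    for p in params:
        num = numeric_grad(fn, p)
        np.testing.assert_allclose(p.grad, num, rtol=tol, atol=tol)


@pytest.fixture
def prng():
    return np.random.default_rng(42)


class TestTensorOps:
    def test_arithmetic_chain_gradient(self, prng):
        a = Parameter(prng.normal(size=(3, 4)))
        b = Parameter(prng.normal(size=(4,)))  # broadcast

        def fn():
            return (((a * 2.0 + b) ** 2 / (a.exp() + 3.0)).tanh()).sum()

        check_grads(fn, [a, b])

    def test_matmul_and_reductions(self, prng):
        a = Parameter(prng.normal(size=(3, 4)))
        b = Parameter(prng.normal(size=(4, 5)))

        def fn():
            return ((a @ b).relu().mean(axis=0)).sum()

        check_grads(fn, [a, b])

    def test_batched_matmul(self, prng):
        a = Parameter(prng.normal(size=(2, 3, 4)))
        b = Parameter(prng.normal(size=(2, 4, 3)))

        def fn():
            return ((a @ b).sigmoid()).sum()

        check_grads(fn, [a, b])

    def test_slicing_concat_transpose(self, prng):
        a = Parameter(prng.normal(size=(4, 6)))

        def fn():
            left = a[:, :3]
            right = a[:, 3:]
            joined = concatenate([left * 2.0, right.transpose(1, 0).transpose(1, 0)], axis=1)
            return (joined.reshape(2, 12).swapaxes(0, 1) ** 2).sum()

        check_grads(fn, [a])

    def test_log_softmax_rows_normalise(self, prng):
        x = Tensor(prng.normal(size=(5, 7)) * 30.0)  # large logits: stability
        probs = softmax(x, axis=-1).data
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.isfinite(log_softmax(x, axis=-1).data).all()

    def test_log_softmax_gradient(self, prng):
        a = Parameter(prng.normal(size=(3, 5)))
        w = prng.normal(size=(3, 5))

        def fn():
            return (log_softmax(a, axis=-1) * Tensor(w)).sum()

        check_grads(fn, [a])

    def test_gather_rows_gradient(self, prng):
        a = Parameter(prng.normal(size=(2, 5, 3)))
        idx = _reverse_index(np.array([3, 5]), 5)

        def fn():
            return (gather_rows(a, idx) ** 2).sum()

        check_grads(fn, [a])

    def test_repeated_use_accumulates(self, prng):
        a = Parameter(np.array([2.0]))
        out = (a * a + a).sum()
        out.backward()
        np.testing.assert_allclose(a.grad, [5.0])


class TestConv1d:
    def test_gradients(self, prng):
        conv = Conv1d(3, 2, 5, 2, prng)
        x = Parameter(prng.normal(size=(2, 7, 3)))

        def fn():
            return (conv(x).tanh()).sum()

        check_grads(fn, [x, conv.weight, conv.bias])

    def test_matches_direct_correlation(self, prng):
        conv = Conv1d(1, 1, 3, 1, prng)
        x = prng.normal(size=(1, 6, 1))
        out = conv(Tensor(x)).data[0, :, 0]
        xp = np.pad(x[0, :, 0], 1)
        expected = [
            (xp[i:i + 3] * conv.weight.data[:, 0, 0]).sum() + conv.bias.data[0]
            for i in range(6)
        ]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_length_violating_padding_rejected(self, prng):
        with pytest.raises(ValueError, match="preserve"):
            Conv1d(3, 2, 4, 2, prng)


class TestLSTM:
    def test_primitive_gradients(self, prng):
        H, C = 4, 3
        w_ih = Parameter(prng.normal(size=(4 * H, C)) * 0.5)
        w_hh = Parameter(prng.normal(size=(4 * H, H)) * 0.5)
        b = Parameter(prng.normal(size=4 * H) * 0.5)
        x = Parameter(prng.normal(size=(2, 5, C)))

        def fn():
            return (_lstm_primitive(x, w_ih, w_hh, b) ** 2).sum()

        check_grads(fn, [x, w_ih, w_hh, b], tol=1e-5)

    def test_primitive_matches_stepwise_recurrence(self, prng):
        """Forward scan equals an independent per-step evaluation."""
        H, C, L = 3, 2, 4
        w_ih = prng.normal(size=(4 * H, C))
        w_hh = prng.normal(size=(4 * H, H))
        b = prng.normal(size=4 * H)
        x = prng.normal(size=(1, L, C))
        out = _lstm_primitive(Tensor(x), Parameter(w_ih), Parameter(w_hh),
                              Parameter(b)).data[0]

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        h = np.zeros(H)
        c = np.zeros(H)
        for t in range(L):
            a = w_ih @ x[0, t] + w_hh @ h + b
            i, f, g, o = sig(a[:H]), sig(a[H:2 * H]), np.tanh(a[2 * H:3 * H]), sig(a[3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            np.testing.assert_allclose(out[t], h, atol=1e-12)

    def test_bidirectional_ignores_trailing_padding(self, prng):
        lstm = LSTM(3, 4, 2, prng, bidirectional=True)
        x = prng.normal(size=(1, 6, 3))
        full = lstm(Tensor(x), np.array([6]))
        padded = np.concatenate([x, np.zeros((1, 3, 3))], axis=1)
        trimmed = lstm(Tensor(padded), np.array([6]))
        np.testing.assert_allclose(trimmed.data[0, :6], full.data[0], atol=1e-12)

    def test_layers_gradients(self, prng):
        lstm = LSTM(2, 3, 2, prng, bidirectional=True)
        x = Parameter(prng.normal(size=(2, 4, 2)))
        lengths = np.array([4, 3])

        def fn():
            return (lstm(x, lengths) ** 2).sum()

        check_grads(fn, [x] + lstm.parameters(), tol=1e-5)


class TestNormalisation:
    def test_masked_batchnorm_stats_ignore_padding(self, prng):
        bn = MaskedBatchNorm1d(3)
        x = prng.normal(size=(2, 5, 3))
        mask = np.array([[1, 1, 1, 1, 1], [1, 1, 1, 0, 0]], dtype=bool)
        out = bn(Tensor(x), mask)
        sel = x[mask]
        np.testing.assert_allclose(
            (out.data[mask]).mean(axis=0), 0.0, atol=1e-10)
        expected = (sel - sel.mean(0)) / np.sqrt(sel.var(0) + bn.eps)
        np.testing.assert_allclose(out.data[mask], expected, atol=1e-10)

    def test_batchnorm_gradient(self, prng):
        bn = MaskedBatchNorm1d(2)
        x = Parameter(prng.normal(size=(2, 4, 2)))
        mask = np.ones((2, 4), dtype=bool)

        def fn():
            return (bn(x, mask).tanh()).sum()

        check_grads(fn, [x, bn.gamma, bn.beta], tol=1e-5)

    def test_layernorm_gradient(self, prng):
        ln = LayerNorm(5)
        x = Parameter(prng.normal(size=(2, 3, 5)))

        def fn():
            return (ln(x) ** 2).sum()

        check_grads(fn, [x, ln.gamma, ln.beta], tol=1e-5)


class TestAttention:
    def test_gradients(self, prng):
        attn = MultiheadSelfAttention(6, 2, prng)
        x = Parameter(prng.normal(size=(2, 4, 6)))
        mask = np.array([[1, 1, 1, 1], [1, 1, 1, 0]], dtype=bool)

        def fn():
            return (attn(x, mask) ** 2).sum()

        check_grads(fn, [x] + attn.parameters(), tol=1e-5)

    def test_padded_keys_get_no_weight(self, prng):
        attn = MultiheadSelfAttention(4, 2, prng)
        x = prng.normal(size=(1, 5, 4))
        mask = np.array([[1, 1, 1, 0, 0]], dtype=bool)
        out_masked = attn(Tensor(x), mask).data
        x2 = x.copy()
        x2[0, 3:] = 99.0  # perturb only padded positions
        out_perturbed = attn(Tensor(x2), mask).data
        np.testing.assert_allclose(out_masked[0, :3], out_perturbed[0, :3],
                                   atol=1e-9)

    def test_encoder_layer_gradients(self, prng):
        layer = TransformerEncoderLayer(4, 2, 8, 0.0, prng)
        x = Parameter(prng.normal(size=(1, 3, 4)))
        mask = np.ones((1, 3), dtype=bool)

        def fn():
            return (layer(x, mask) ** 2).sum()

        check_grads(fn, [x] + layer.parameters(), tol=1e-4)


class TestDropoutAndOptim:
    def test_dropout_eval_is_identity(self, prng):
        drop = Dropout(0.5, prng)
        drop.training = False
        x = Tensor(prng.normal(size=(3, 3)))
        assert (drop(x).data == x.data).all()

    def test_dropout_preserves_expectation(self, prng):
        drop = Dropout(0.25, prng)
        x = Tensor(np.ones((200, 200)))
        out = drop(x).data
        assert abs(out.mean() - 1.0) < 0.01
        assert set(np.round(np.unique(out), 8)) <= {0.0, np.round(1 / 0.75, 8)}

    def test_adam_minimises_quadratic(self):
        p = Parameter(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            loss = (p ** 2).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        np.testing.assert_allclose(p.data, 0.0, atol=1e-3)

    def test_module_state_dict_round_trip(self, prng):
        lstm = LSTM(2, 3, 1, prng)
        state = lstm.state_dict()
        lstm2 = LSTM(2, 3, 1, np.random.default_rng(99))
        lstm2.load_state_dict(state)
        x = Tensor(prng.normal(size=(1, 4, 2)))
        np.testing.assert_array_equal(
            lstm(x, np.array([4])).data, lstm2(x, np.array([4])).data)


def test_sinusoidal_positions_shape_and_range():
    enc = sinusoidal_positions(10, 8)
    assert enc.shape == (10, 8)
    assert (np.abs(enc) <= 1.0).all()
    assert not np.allclose(enc[0], enc[5])
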