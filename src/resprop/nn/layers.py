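"""Neural-network building blocks on top of the autodiff engine.

Layers follow the (batch, length, channels) layout throughout.  Sequence
batches carry a boolean mask of real (non-padded) positions; layers that mix
information across positions (batch norm statistics, the backward LSTM
direction, attention) consult the mask so that appending padding to a batch
never changes the outputs at real positions.

Conv1d and LSTM are implemented as single tape primitives with hand-written
vector-Jacobian products rather than being composed step by step on the
tape; this keeps the graph small and the training loop fast.  Their
gradients are checked against finite differences in the test suite.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, as_tensor, concatenate, gather_rows, softmax


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Base class providing parameter traversal and train/eval switching."""

    def __init__(self) -> None:
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Parameter):
                        yield f"{name}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        for m_name, m in self._named_modules():
            for b_name, buf in getattr(m, "_buffers", {}).items():
                state[f"{m_name}{b_name}"] = np.asarray(buf).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.named_parameters():
            v.data = np.asarray(state[k], dtype=np.float64).copy()
        for m_name, m in self._named_modules():
            for b_name in getattr(m, "_buffers", {}):
                m._buffers[b_name] = np.asarray(state[f"{m_name}{b_name}"]).copy()

    def _named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._named_modules(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{k}.{i}.")


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class Conv1d(Module):
    """1-D convolution over the length axis of (B, L, C_in) input.

    Odd kernel with padding (k-1)//2, preserving length ('same').  Padding
    is with zeros, which coincides with how padded batch positions are
    encoded, so convolution output at real positions is unaffected by
    trailing batch padding.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 != 1 or padding != (kernel_size - 1) // 2:
            raise ValueError(
                f"kernel {kernel_size} with padding {padding} does not "
                "preserve sequence length"
            )
        self.kernel_size = kernel_size
        self.padding = padding
        bound = 1.0 / np.sqrt(in_channels * kernel_size)
        self.weight = Parameter(
            rng.uniform(-bound, bound, (kernel_size, in_channels, out_channels))
        )
        self.bias = Parameter(np.zeros(out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        w, b = self.weight, self.bias
        B, L, Cin = x.shape
        K, p = self.kernel_size, self.padding
        xp = np.pad(x.data, ((0, 0), (p, p), (0, 0)))
        out = np.empty((B, L, w.shape[2]))
        out[:] = b.data
        for k in range(K):
            out += xp[:, k:k + L, :] @ w.data[k]

        def vjp(g):
            gw = np.empty_like(w.data)
            gxp = np.zeros_like(xp)
            for k in range(K):
                seg = xp[:, k:k + L, :]
                gw[k] = np.tensordot(seg, g, axes=([0, 1], [0, 1]))
                gxp[:, k:k + L, :] += g @ w.data[k].T
            gx = gxp[:, p:p + L, :] if p else gxp
            gb = g.sum(axis=(0, 1))
            return (gx, gw, gb)

        return Tensor._make(out, (x, w, b), vjp)


def _lstm_primitive(x: Tensor, w_ih: Parameter, w_hh: Parameter,
                    bias: Parameter) -> Tensor:
    """Unidirectional LSTM scan as one tape primitive.

    Gate layout along the 4H axis: input, forget, cell, output.  Initial
    hidden and cell states are zero.  The backward pass replays the scan in
    reverse with the standard LSTM gradient recurrences.
    """
    xd = x.data
    B, L, _ = xd.shape
    H = w_hh.data.shape[1]
    pre = xd @ w_ih.data.T + bias.data  # (B, L, 4H)
    I = np.empty((B, L, H)); F = np.empty((B, L, H))
    G = np.empty((B, L, H)); O = np.empty((B, L, H))
    C = np.empty((B, L, H)); TC = np.empty((B, L, H))
    Hs = np.empty((B, L, H))
    h = np.zeros((B, H)); c = np.zeros((B, H))
    for t in range(L):
        a = pre[:, t] + h @ w_hh.data.T
        i = 1.0 / (1.0 + np.exp(-a[:, :H]))
        f = 1.0 / (1.0 + np.exp(-a[:, H:2 * H]))
        g_ = np.tanh(a[:, 2 * H:3 * H])
        o = 1.0 / (1.0 + np.exp(-a[:, 3 * H:]))
        c = f * c + i * g_
        tc = np.tanh(c)
        h = o * tc
        I[:, t], F[:, t], G[:, t], O[:, t] = i, f, g_, o
        C[:, t], TC[:, t], Hs[:, t] = c, tc, h

    def vjp(gy):
        dpre = np.empty((B, L, 4 * H))
        dw_hh = np.zeros_like(w_hh.data)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(L - 1, -1, -1):
            dh = gy[:, t] + dh_next
            i, f, g_, o = I[:, t], F[:, t], G[:, t], O[:, t]
            tc = TC[:, t]
            c_prev = C[:, t - 1] if t > 0 else np.zeros((B, H))
            h_prev = Hs[:, t - 1] if t > 0 else np.zeros((B, H))
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            di = dc * g_
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate(
                [di * i * (1.0 - i), df * f * (1.0 - f),
                 dg * (1.0 - g_**2), do * o * (1.0 - o)], axis=1
            )
            dpre[:, t] = da
            dh_next = da @ w_hh.data
            dw_hh += da.T @ h_prev
        gx = dpre @ w_ih.data
        gw_ih = np.tensordot(dpre, xd, axes=([0, 1], [0, 1]))
        gb = dpre.sum(axis=(0, 1))
        return (gx, gw_ih, dw_hh, gb)

    return Tensor._make(Hs, (x, w_ih, w_hh, bias), vjp)


def _reverse_index(lengths: np.ndarray, L: int) -> np.ndarray:
    """Per-sequence time-reversal index: reverses the first ``lengths[b]``
    positions of row b and leaves padding positions in place (an
    involution)."""
    t = np.arange(L)[None, :]
    lens = np.asarray(lengths)[:, None]
    return np.where(t < lens, lens - 1 - t, t)


class LSTM(Module):
    """(Optionally bidirectional) multi-layer LSTM with inter-layer dropout.

    For the backward direction each sequence is reversed within its true
    length, so trailing batch padding never leaks into the reverse scan.
    """

    def __init__(self, input_size: int, hidden_size: int, num_layers: int,
                 rng: np.random.Generator, bidirectional: bool = True,
                 dropout_p: float = 0.0):
        super().__init__()
        self.hidden_size = hidden_size
        self.num_layers = num_layers
        self.bidirectional = bidirectional
        self.dropout = Dropout(dropout_p, rng)
        ndir = 2 if bidirectional else 1
        bound = 1.0 / np.sqrt(hidden_size)

        def make(n_in):
            return (Parameter(rng.uniform(-bound, bound, (4 * hidden_size, n_in))),
                    Parameter(rng.uniform(-bound, bound, (4 * hidden_size, hidden_size))),
                    Parameter(rng.uniform(-bound, bound, 4 * hidden_size)))

        self.weights: list[Parameter] = []
        self._cells = []
        for layer in range(num_layers):
            n_in = input_size if layer == 0 else hidden_size * ndir
            dirs = [make(n_in) for _ in range(ndir)]
            self._cells.append(dirs)
            for trio in dirs:
                self.weights.extend(trio)

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        L = x.shape[1]
        rev = _reverse_index(lengths, L) if self.bidirectional else None
        out = x
        for layer, dirs in enumerate(self._cells):
            if layer > 0:
                out = self.dropout(out)
            fwd = _lstm_primitive(out, *dirs[0])
            if self.bidirectional:
                bwd = gather_rows(
                    _lstm_primitive(gather_rows(out, rev), *dirs[1]), rev
                )
                out = concatenate([fwd, bwd], axis=2)
            else:
                out = fwd
        return out


class MaskedBatchNorm1d(Module):
    """Batch normalisation over channels, statistics from real positions only.

    Running statistics (exponential moving average, momentum 0.1) are used in
    eval mode, matching the usual train/inference convention.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self._buffers = {
            "running_mean": np.zeros(num_features),
            "running_var": np.ones(num_features),
        }

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        m = Tensor(mask[:, :, None].astype(np.float64))
        n = float(mask.sum())
        if self.training:
            mean = (x * m).sum(axis=(0, 1)) * (1.0 / n)
            centred = x - mean
            var = ((centred * m) * centred).sum(axis=(0, 1)) * (1.0 / n)
            mom = self.momentum
            self._buffers["running_mean"] = (
                (1 - mom) * self._buffers["running_mean"] + mom * mean.data
            )
            self._buffers["running_var"] = (
                (1 - mom) * self._buffers["running_var"] + mom * var.data
            )
        else:
            mean = Tensor(self._buffers["running_mean"])
            var = Tensor(self._buffers["running_var"])
            centred = x - mean
        inv = (var + self.eps) ** -0.5
        return centred * inv * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, num_features: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))

    def __call__(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        centred = x - mean
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred * (var + self.eps) ** -0.5 * self.gamma + self.beta


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention; padded keys are masked out."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError(f"d_model {d_model} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.proj = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L, D = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv(x)  # (B, L, 3D)

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, L, h, dh).transpose(0, 2, 1, 3).reshape(B * h, L, dh)

        q = heads(qkv[:, :, :D])
        k = heads(qkv[:, :, D:2 * D])
        v = heads(qkv[:, :, 2 * D:])
        scores = (q @ k.swapaxes(1, 2)) * (1.0 / np.sqrt(dh))  # (B*h, L, L)
        key_bias = np.where(mask[:, None, :], 0.0, -1e9)  # (B, 1, L)
        key_bias = np.repeat(key_bias, h, axis=0)  # (B*h, 1, L)
        attn = softmax(scores + Tensor(key_bias), axis=-1)
        ctx = attn @ v  # (B*h, L, dh)
        ctx = ctx.reshape(B, h, L, dh).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.proj(ctx)


class TransformerEncoderLayer(Module):
    """Post-norm encoder block: self-attention and position-wise FFN, each
    with residual connection, dropout and layer normalisation."""

    def __init__(self, d_model: int, n_heads: int, ffn_dim: int,
                 dropout_p: float, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.ffn1 = Linear(d_model, ffn_dim, rng)
        self.ffn2 = Linear(ffn_dim, d_model, rng)
        self.drop = Dropout(dropout_p, rng)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x, mask)))
        x = self.norm2(x + self.drop(self.ffn2(self.ffn1(x).relu())))
        return x


def sinusoidal_positions(L: int, d_model: int) -> np.ndarray:
    """Standard sinusoidal positional encoding matrix of shape (L, d_model)."""
    pos = np.arange(L)[:, None]
    dim = np.arange((d_model + 1) // 2)[None, :]
    angles = pos / (10000.0 ** (2 * dim / d_model))
    enc = np.zeros((L, d_model))
    enc[:, 0::2] = np.sin(angles)[:, : (d_model + 1) // 2]
    enc[:, 1::2] = np.cos(angles)[:, : d_model // 2]
    return enc
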