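"""Layer objects over the autodiff primitives.

Parameter initialization mirrors the common uniform(-1/sqrt(fan_in),
1/sqrt(fan_in)) convention.  Layers are seeded explicitly through the
numpy Generator handed to their constructor, so a build is a pure function
of (hyperparameters, seed).
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

_DTYPE = np.float32


class Module:
    """Minimal parameter container with train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        out = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def parameters(self) -> list[Tensor]:
        params = []
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat state for checkpoints and best-epoch snapshots ---------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = []
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Tensor):
                    arrays.append(v.data)
                elif isinstance(v, np.ndarray):
                    arrays.append(v)
        return arrays

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]):
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError(f"state length {len(state)} != expected {len(arrays)}")
        for dst, src in zip(arrays, state):
            dst[...] = src


def _param(rng: np.random.Generator, shape, k: float) -> Tensor:
    return Tensor(rng.uniform(-k, k, size=shape).astype(_DTYPE), requires_grad=True)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        k = 1.0 / np.sqrt(in_features)
        self.w = _param(rng, (in_features, out_features), k)
        self.b = _param(rng, (out_features,), k)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.w), self.b)


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, pad: int = 0):
        super().__init__()
        self.pad = pad
        k = 1.0 / np.sqrt(in_channels * kernel)
        self.w = _param(rng, (out_channels, in_channels, kernel), k)
        self.b = _param(rng, (out_channels,), k)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.w, self.b, pad=self.pad)


class MaxPool1d(Module):
    def __init__(self, kernel: int, stride: int = 1, pad: int = 0):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return ag.maxpool1d(x, self.kernel, self.stride, self.pad)


class BatchNorm(Module):
    """Batch normalization over the given axes with running statistics.

    axes=(0, 2) normalizes (B, C, T) per channel; axes=(0,) normalizes (B, F)
    per feature.
    """

    def __init__(self, num_features: int, axes: tuple = (0, 2), momentum: float = 0.1):
        super().__init__()
        self.axes = tuple(axes)
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features, dtype=_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=_DTYPE), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=_DTYPE)
        self.running_var = np.ones(num_features, dtype=_DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = ag.batchnorm_train(x, self.gamma, self.beta, self.axes)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu
            self.running_var[...] = (1 - m) * self.running_var + m * var
            return out
        return ag.batchnorm_eval(x, self.gamma, self.beta,
                                 self.running_mean, self.running_var, self.axes)


class LSTMLayer(Module):
    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        k = 1.0 / np.sqrt(hidden_size)
        self.w = _param(rng, (input_size, 4 * hidden_size), k)
        self.u = _param(rng, (hidden_size, 4 * hidden_size), k)
        self.b = _param(rng, (4 * hidden_size,), k)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.lstm(x, self.w, self.u, self.b)


class GRULayer(Module):
    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        k = 1.0 / np.sqrt(hidden_size)
        self.w = _param(rng, (input_size, 3 * hidden_size), k)
        self.u = _param(rng, (hidden_size, 3 * hidden_size), k)
        self.bx = _param(rng, (3 * hidden_size,), k)
        self.bh = _param(rng, (3 * hidden_size,), k)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.gru(x, self.w, self.u, self.bx, self.bh)


class BiLSTMLayer(Module):
    """One bidirectional LSTM layer; output concatenates both directions."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTMLayer(input_size, hidden_size, rng)
        self.bwd = LSTMLayer(input_size, hidden_size, rng)

    def __call__(self, x: Tensor, lengths) -> Tensor:
        h_f = self.fwd(x)
        x_rev = ag.reverse_time(x, lengths)
        h_b_rev = self.bwd(x_rev)
        h_b = ag.reverse_time(h_b_rev, lengths)
        return ag.concat([h_f, h_b], axis=2)


class MultiHeadAttention(Module):
    """Scaled dot-product self-attention with `n_heads` heads over (B, T, D)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.n_heads = dim, n_heads
        self.head_dim = dim // n_heads
        self.wq = Dense(dim, dim, rng)
        self.wk = Dense(dim, dim, rng)
        self.wv = Dense(dim, dim, rng)
        self.wo = Dense(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, d = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:  # (B, T, D) -> (B, h, T, d)
            return ag.transpose(ag.reshape(t, (B, T, h, d)), (0, 2, 1, 3))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = ag.scale(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(d))
        attn = ag.softmax(scores, axis=-1)
        ctx = ag.matmul(attn, v)  # (B, h, T, d)
        ctx = ag.reshape(ag.transpose(ctx, (0, 2, 1, 3)), (B, T, D))
        return self.wo(ctx)
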