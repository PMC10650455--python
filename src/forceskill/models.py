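"""The six sequence classifiers: LSTM, Bi-LSTM, GRU, CLDNN, TCN, Transformer.

Every architecture maps a (channels x T) force sequence to a single
Expert-probability through a sigmoid head.  Hyperparameters are fixed
constants of each architecture (they are what the benchmark compares):

* lstm / gru:   4 recurrent layers, hidden size 64, readout at the last
                non-padded step, affine 64 -> 1.
* bilstm:       4 bidirectional layers, hidden 64 per direction; readout
                concatenates the final forward and final backward states
                (128) before the affine head.
* cldnn:        two Conv1d-ReLU-MaxPool blocks (64 then 128 channels, each
                pool halving T), 4 LSTM layers hidden 64, affine 64 -> 64
                with ReLU, affine 64 -> 1.
* tcn:          four length-preserving blocks Conv1d(k=25, pad 12) ->
                BatchNorm -> ReLU -> MaxPool(k=3, stride 1, pad 1) with
                channels 64, 32, 16, 16; temporal average; affine 16 -> 1.
* transformer:  pointwise Conv1d to width 16, one 8-head self-attention
                block (no positional encoding), BatchNorm, temporal
                average, affine 16 -> 16 + ReLU, BatchNorm, affine 16 -> 1.

Intermediate feature maps are captured on request (``capture=True``) under
the names f1, f2, ... as used by the saliency overlay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .force_data import ScalerState

ARCHITECTURES = ("lstm", "bilstm", "gru", "cldnn", "tcn", "transformer")

HIDDEN = 64
N_RECURRENT_LAYERS = 4
TCN_CHANNELS = (64, 32, 16, 16)
TCN_KERNEL = 25
TCN_POOL = 3
TRANSFORMER_WIDTH = 16
TRANSFORMER_HEADS = 8


@dataclass(frozen=True)
class ModelSpec:
    arch: str
    in_channels: int = 1
    init_seed: int = 0

    def __post_init__(self):
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown arch {self.arch!r}; expected one of {ARCHITECTURES}")
        if self.in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 (raw) or 3 (rfft-stacked)")


# ---------------------------------------------------------------------------
# network bodies
# ---------------------------------------------------------------------------

class _RNNNet(nn.Module):
    def __init__(self, kind: str, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.kind = kind
        layers = []
        if kind == "bilstm":
            in_dim = in_channels
            for _ in range(N_RECURRENT_LAYERS):
                layers.append(nn.BiLSTMLayer(in_dim, HIDDEN, rng))
                in_dim = 2 * HIDDEN
            self.head = nn.Dense(2 * HIDDEN, 1, rng)
        else:
            cls = nn.LSTMLayer if kind == "lstm" else nn.GRULayer
            in_dim = in_channels
            for _ in range(N_RECURRENT_LAYERS):
                layers.append(cls(in_dim, HIDDEN, rng))
                in_dim = HIDDEN
            self.head = nn.Dense(HIDDEN, 1, rng)
        self.layers = layers

    def __call__(self, x: Tensor, lengths: np.ndarray, features: dict | None = None):
        # x: (B, C, T) -> (B, T, C)
        h = ag.transpose(x, (0, 2, 1))
        for i, layer in enumerate(self.layers):
            h = layer(h, lengths) if self.kind == "bilstm" else layer(h)
            if features is not None:
                features[f"h{i + 1}"] = h.data
        last = np.asarray(lengths, dtype=np.intp) - 1
        if self.kind == "bilstm":
            fwd = ag.gather_time(ag.slice_lastdim(h, 0, HIDDEN), last)
            bwd = ag.gather_time(ag.slice_lastdim(h, HIDDEN, 2 * HIDDEN),
                                 np.zeros_like(last))
            readout = ag.concat([fwd, bwd], axis=1)
        else:
            readout = ag.gather_time(h, last)
        if features is not None:
            features["readout"] = readout.data
        return self.head(readout)  # (B, 1) logits


class _CLDNNNet(nn.Module):
    MIN_T = 4

    def __init__(self, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv1d(in_channels, 64, 5, rng, pad=2)
        self.pool1 = nn.MaxPool1d(2, stride=2)
        self.conv2 = nn.Conv1d(64, 128, 5, rng, pad=2)
        self.pool2 = nn.MaxPool1d(2, stride=2)
        self.lstms = [nn.LSTMLayer(128 if i == 0 else HIDDEN, HIDDEN, rng)
                      for i in range(N_RECURRENT_LAYERS)]
        self.fc1 = nn.Dense(HIDDEN, HIDDEN, rng)
        self.fc2 = nn.Dense(HIDDEN, 1, rng)

    def __call__(self, x: Tensor, lengths: np.ndarray, features: dict | None = None):
        T = x.shape[2]
        if T < self.MIN_T:
            raise ValueError(f"cldnn requires T >= {self.MIN_T}, got {T}")
        f1 = ag.relu(self.conv1(x))
        p1 = self.pool1(f1)          # (B, 64, T/2)
        f2 = ag.relu(self.conv2(p1))
        p2 = self.pool2(f2)          # (B, 128, T/4)
        h = ag.transpose(p2, (0, 2, 1))  # (B, T/4, 128)
        T4 = h.shape[1]
        if features is not None:
            features["f1"] = p1.data
            features["f2"] = p2.data
        for i, layer in enumerate(self.lstms):
            h = layer(h)
            if features is not None:
                features[f"f{i + 3}"] = h.data  # f3..f6, each (B, T/4, 64)
        # last valid pooled step of each sequence
        last4 = np.clip((np.asarray(lengths, dtype=np.intp) + 3) // 4, 1, T4) - 1
        readout = ag.gather_time(h, last4)
        f7 = ag.relu(self.fc1(readout))
        if features is not None:
            features["f7"] = f7.data
            features["recurrent_seq"] = h.data  # saliency source (B, T/4, 64)
        return self.fc2(f7)


class _TCNNet(nn.Module):
    MIN_T = TCN_KERNEL

    def __init__(self, in_channels: int, rng: np.random.Generator):
        super().__init__()
        chans = (in_channels,) + TCN_CHANNELS
        self.convs = [nn.Conv1d(chans[i], chans[i + 1], TCN_KERNEL, rng,
                                pad=TCN_KERNEL // 2)
                      for i in range(len(TCN_CHANNELS))]
        self.norms = [nn.BatchNorm(c, axes=(0, 2)) for c in TCN_CHANNELS]
        self.pools = [nn.MaxPool1d(TCN_POOL, stride=1, pad=TCN_POOL // 2)
                      for _ in TCN_CHANNELS]
        self.head = nn.Dense(TCN_CHANNELS[-1], 1, rng)

    def __call__(self, x: Tensor, lengths: np.ndarray, features: dict | None = None):
        T = x.shape[2]
        if T < self.MIN_T:
            raise ValueError(f"tcn requires T >= {self.MIN_T}, got {T}")
        h = x
        for i, (conv, norm, pool) in enumerate(zip(self.convs, self.norms, self.pools)):
            h = pool(ag.relu(norm(conv(h))))
            if features is not None:
                features[f"F{i + 1}"] = h.data  # (B, C_i, T); F4 is the saliency source
        pooled = ag.mean(h, axis=2)  # temporal average -> (B, 16)
        if features is not None:
            features["pooled"] = pooled.data
        return self.head(pooled)


class _TransformerNet(nn.Module):
    MIN_T = 1

    def __init__(self, in_channels: int, rng: np.random.Generator):
        super().__init__()
        self.embed = nn.Conv1d(in_channels, TRANSFORMER_WIDTH, 1, rng)
        self.attn = nn.MultiHeadAttention(TRANSFORMER_WIDTH, TRANSFORMER_HEADS, rng)
        self.norm1 = nn.BatchNorm(TRANSFORMER_WIDTH, axes=(0, 1))  # (B, T, D) per feature
        self.fc1 = nn.Dense(TRANSFORMER_WIDTH, TRANSFORMER_WIDTH, rng)
        self.norm2 = nn.BatchNorm(TRANSFORMER_WIDTH, axes=(0,))
        self.fc2 = nn.Dense(TRANSFORMER_WIDTH, 1, rng)

    def __call__(self, x: Tensor, lengths: np.ndarray, features: dict | None = None):
        f1 = self.embed(x)  # (B, 16, T)
        if features is not None:
            features["f1"] = f1.data
        tokens = ag.transpose(f1, (0, 2, 1))  # (B, T, 16)
        attended = self.norm1(self.attn(tokens))
        f2 = ag.mean(attended, axis=1)  # (B, 16)
        if features is not None:
            features["f2"] = f2.data
        h = self.norm2(ag.relu(self.fc1(f2)))
        return self.fc2(h)


_NET_BUILDERS = {
    "lstm": lambda spec, rng: _RNNNet("lstm", spec.in_channels, rng),
    "bilstm": lambda spec, rng: _RNNNet("bilstm", spec.in_channels, rng),
    "gru": lambda spec, rng: _RNNNet("gru", spec.in_channels, rng),
    "cldnn": lambda spec, rng: _CLDNNNet(spec.in_channels, rng),
    "tcn": lambda spec, rng: _TCNNet(spec.in_channels, rng),
    "transformer": lambda spec, rng: _TransformerNet(spec.in_channels, rng),
}


class FittedModel:
    """An architecture plus its (possibly trained) parameters.

    `forward` maps a batch of (channels x T) arrays to Expert probabilities;
    at evaluation time variable T is accepted (items are processed
    individually when lengths differ) and normalization layers use their
    accumulated running statistics.
    """

    def __init__(self, spec: ModelSpec, net: nn.Module,
                 scaler: ScalerState | None = None,
                 input_transform: str | None = None):
        self.spec = spec
        self.net = net
        self.scaler = scaler
        self.input_transform = input_transform  # "fft" or None
        self.features: dict[str, np.ndarray] = {}

    def forward_logits(self, batch: np.ndarray, lengths=None,
                       capture: bool = False) -> Tensor:
        """Training-path forward on an already-stacked (B, C, T) batch."""
        batch = np.asarray(batch, dtype=np.float32)
        if batch.ndim != 3 or batch.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected batch of shape (B, {self.spec.in_channels}, T), "
                f"got {batch.shape}")
        if lengths is None:
            lengths = np.full(batch.shape[0], batch.shape[2], dtype=np.intp)
        features = {} if capture else None
        logits = self.net(Tensor(batch), np.asarray(lengths, dtype=np.intp), features)
        if capture:
            self.features = features
        return logits

    def forward(self, inputs, lengths=None, capture: bool = False) -> np.ndarray:
        """Evaluation-mode probabilities for a batch of (C, T) or (T,) arrays."""
        arrays = [np.atleast_2d(np.asarray(a, dtype=np.float32)) for a in inputs]
        for a in arrays:
            if a.shape[0] != self.spec.in_channels:
                raise ValueError(
                    f"input has {a.shape[0]} channels, model expects "
                    f"{self.spec.in_channels}")
        self.net.eval()
        try:
            if len({a.shape[1] for a in arrays}) == 1:
                batch = np.stack(arrays)
                logits = self.forward_logits(batch, lengths, capture=capture)
                probs = _sigmoid(logits.data[:, 0])
            else:
                probs = np.empty(len(arrays))
                for i, a in enumerate(arrays):
                    li = None if lengths is None else [lengths[i]]
                    logit = self.forward_logits(a[None], li, capture=capture)
                    probs[i] = _sigmoid(logit.data[0, 0])
        finally:
            self.net.train()
        return probs


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def build_model(spec: ModelSpec) -> FittedModel:
    """Build an untrained model; a pure function of (spec, init_seed)."""
    rng = np.random.default_rng(spec.init_seed)
    return FittedModel(spec, _NET_BUILDERS[spec.arch](spec, rng))


def build_lstm(spec: ModelSpec) -> FittedModel:
    assert spec.arch == "lstm"
    return build_model(spec)


def build_bilstm(spec: ModelSpec) -> FittedModel:
    assert spec.arch == "bilstm"
    return build_model(spec)


def build_gru(spec: ModelSpec) -> FittedModel:
    assert spec.arch == "gru"
    return build_model(spec)


def build_cldnn(spec: ModelSpec) -> FittedModel:
    assert spec.arch == "cldnn"
    return build_model(spec)


def build_tcn(spec: ModelSpec) -> FittedModel:
    assert spec.arch == "tcn"
    return build_model(spec)


def build_transformer(spec: ModelSpec) -> FittedModel:
    assert spec.arch == "transformer"
    return build_model(spec)


def parameter_count(model: FittedModel) -> int:
    return sum(p.data.size for p in model.net.parameters())


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: FittedModel, path: str | Path):
    """Single-archive checkpoint: spec JSON plus all parameter/state arrays."""
    meta = {
        "arch": model.spec.arch,
        "in_channels": model.spec.in_channels,
        "init_seed": model.spec.init_seed,
        "input_transform": model.input_transform,
        "scaler": None if model.scaler is None
                  else {"mean": model.scaler.mean, "std": model.scaler.std},
    }
    state = model.net.get_state()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **{f"arr_{i}": a for i, a in enumerate(state)})


def load_checkpoint(path: str | Path) -> FittedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    spec = ModelSpec(arch=meta["arch"], in_channels=meta["in_channels"],
                     init_seed=meta["init_seed"])
    model = build_model(spec)
    model.net.set_state(state)
    model.input_transform = meta["input_transform"]
    if meta["scaler"] is not None:
        model.scaler = ScalerState(**meta["scaler"])
    return model
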