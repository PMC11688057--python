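"""The CBA-BiLSTM classifier: convolution front-end, BiLSTM, bottleneck attention.

Architecture, in execution order:

1. three conv + max-pool groups over the raw (L, C_in) sequence;
2. a bidirectional LSTM whose per-timestep forward/backward states are
   concatenated, giving an L' x 2H output;
3. a bottleneck attention block: the BiLSTM output is viewed as a feature
   map with C = 2H channels over an N x M = L' x 1 grid; a channel branch
   (global average pooling, reduce/expand fully connected layers, batch
   norm) and a spatial branch (1x1 reduce, two dilated 3x3 convolutions,
   1x1 collapse, batch norm) produce maps that are broadcast-added, squashed
   by a sigmoid and applied residually: F' = F + F * M;
4. a softmax head over the flattened attended features.

Because the BiLSTM output already concatenates the two directions along the
channel axis, a single reduce/expand pair over C = 2H covers both attention
streams jointly.  All math runs on :mod:`gaitfreeze.autodiff` tensors so the
same code serves inference and training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .signal_io import ValidationError, apply_sequence_norm

DEFAULT_CONV_GROUPS = ((16, 3, 2), (32, 3, 2), (64, 3, 2))


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return ad.parameter(rng.uniform(-limit, limit, size=shape))


@dataclass
class LstmParams:
    """Gate weights over the concatenated [x_t, h_{t-1}] input, plus biases."""

    w_i: Tensor
    w_o: Tensor
    w_f: Tensor
    w_c: Tensor
    b_i: Tensor
    b_o: Tensor
    b_f: Tensor
    b_c: Tensor

    @property
    def hidden_size(self) -> int:
        return self.w_i.shape[1]

    @property
    def input_size(self) -> int:
        return self.w_i.shape[0] - self.hidden_size

    def tensors(self) -> list[Tensor]:
        return [self.w_i, self.w_o, self.w_f, self.w_c,
                self.b_i, self.b_o, self.b_f, self.b_c]


def make_lstm_params(input_size: int, hidden_size: int, rng: np.random.Generator) -> LstmParams:
    d = input_size + hidden_size
    ws = {g: _glorot(rng, (d, hidden_size), d, hidden_size) for g in "iofc"}
    bs = {g: ad.parameter(np.zeros(hidden_size)) for g in "iofc"}
    bs["f"].value[:] = 1.0  # forget-gate bias at 1: standard stability choice
    return LstmParams(w_i=ws["i"], w_o=ws["o"], w_f=ws["f"], w_c=ws["c"],
                      b_i=bs["i"], b_o=bs["o"], b_f=bs["f"], b_c=bs["c"])


class BatchNorm:
    """Batch normalization over all axes except the last (feature) axis.

    Training mode normalizes with batch statistics and updates running
    statistics; inference mode uses the running statistics, which makes
    outputs independent of batch composition.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = ad.parameter(np.ones(n_features))
        self.beta = ad.parameter(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            n = x.size // x.shape[-1]
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.value.ravel()
            unbiased = var.value.ravel() * (n / max(n - 1, 1))
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) / ad.sqrt(var + self.eps)
        return xhat * self.gamma + self.beta

    def tensors(self) -> list[Tensor]:
        return [self.gamma, self.beta]


@dataclass
class AttentionParams:
    """Weights of the bottleneck attention block for a C-channel feature map."""

    w1: Tensor  # channel reduce, (C, C/r)
    w2: Tensor  # channel expand, (C/r, C)
    bn_channel: BatchNorm
    conv_reduce: Tensor  # 1x1, (C, C/r)
    conv_dil1: Tensor  # 3x3 dilated, (3, 3, C/r, C/r)
    conv_dil2: Tensor
    conv_collapse: Tensor  # 1x1, (C/r, 1)
    bn_spatial: BatchNorm
    reduction_ratio: int
    dilation: int

    @property
    def n_channels(self) -> int:
        return self.w1.shape[0]

    def tensors(self) -> list[Tensor]:
        return [self.w1, self.w2, self.conv_reduce, self.conv_dil1,
                self.conv_dil2, self.conv_collapse,
                *self.bn_channel.tensors(), *self.bn_spatial.tensors()]


def make_attention_params(
    n_channels: int,
    reduction_ratio: int = 16,
    dilation: int = 4,
    rng: np.random.Generator | None = None,
    allow_padding: bool = True,
) -> AttentionParams:
    """Initialize attention weights; C/r is rounded up when r does not divide C."""
    if dilation < 1:
        raise ValidationError("dilation must be >= 1")
    if reduction_ratio > n_channels and not allow_padding:
        raise ValidationError(
            f"reduction_ratio {reduction_ratio} exceeds channel count {n_channels}"
        )
    rng = rng or np.random.default_rng(0)
    cr = max(1, -(-n_channels // reduction_ratio))  # ceil division
    return AttentionParams(
        w1=_glorot(rng, (n_channels, cr), n_channels, cr),
        w2=_glorot(rng, (cr, n_channels), cr, n_channels),
        bn_channel=BatchNorm(n_channels),
        conv_reduce=_glorot(rng, (n_channels, cr), n_channels, cr),
        conv_dil1=_glorot(rng, (3, 3, cr, cr), 9 * cr, cr),
        conv_dil2=_glorot(rng, (3, 3, cr, cr), 9 * cr, cr),
        conv_collapse=_glorot(rng, (cr, 1), cr, 1),
        bn_spatial=BatchNorm(1),
        reduction_ratio=reduction_ratio,
        dilation=dilation,
    )


# ---------------------------------------------------------------------------
# Core computations (autodiff tensors, batch-first, channels-last)
# ---------------------------------------------------------------------------

def _lstm_step_t(x: Tensor, h: Tensor, c: Tensor, p: LstmParams) -> tuple[Tensor, Tensor]:
    xh = ad.concatenate([x, h], axis=-1)
    i = ad.sigmoid(xh @ p.w_i + p.b_i)
    o = ad.sigmoid(xh @ p.w_o + p.b_o)
    f = ad.sigmoid(xh @ p.w_f + p.b_f)
    cand = ad.tanh(xh @ p.w_c + p.b_c)
    c_t = f * c + i * cand
    h_t = o * ad.tanh(c_t)
    return h_t, c_t


def _bilstm_t(x: Tensor, fwd: LstmParams, bwd: LstmParams) -> Tensor:
    """(B, L, D) -> (B, L, 2H), per-timestep [forward; backward] concat."""
    b, length, _ = x.shape
    h_dim = fwd.hidden_size
    zeros = Tensor(np.zeros((b, h_dim)))
    h, c = zeros, zeros
    hf = []
    for t in range(length):
        h, c = _lstm_step_t(x[:, t, :], h, c, fwd)
        hf.append(h)
    h, c = zeros, zeros
    hb: list[Tensor] = [None] * length  # type: ignore[list-item]
    for t in range(length - 1, -1, -1):
        h, c = _lstm_step_t(x[:, t, :], h, c, bwd)
        hb[t] = h
    steps = [
        ad.reshape(ad.concatenate([hf[t], hb[t]], axis=1), (b, 1, 2 * h_dim))
        for t in range(length)
    ]
    return ad.concatenate(steps, axis=1)


def _conv1d_same(x: Tensor, kernel: Tensor, bias: Tensor) -> Tensor:
    """'same' 1-D convolution; x (B, L, Cin), kernel (K, Cin, Cout)."""
    k = kernel.shape[0]
    left, right = (k - 1) // 2, k // 2
    xp = ad.pad(x, ((0, 0), (left, right), (0, 0)))
    length = x.shape[1]
    out = None
    for tap in range(k):
        term = xp[:, tap : tap + length, :] @ kernel[tap]
        out = term if out is None else out + term
    return out + bias


def _maxpool1d(x: Tensor, pool: int) -> Tensor:
    length = (x.shape[1] // pool) * pool
    out = x[:, 0:length:pool, :]
    for off in range(1, pool):
        out = ad.maximum(out, x[:, off:length:pool, :])
    return out


def _dilated_conv2d_same(x: Tensor, kernel: Tensor, dilation: int) -> Tensor:
    """'same' 3x3 dilated convolution; x (B, N, M, C), kernel (3, 3, C, C')."""
    d = dilation
    n, m = x.shape[1], x.shape[2]
    xp = ad.pad(x, ((0, 0), (d, d), (d, d), (0, 0)))
    out = None
    for i in range(3):
        for j in range(3):
            term = xp[:, i * d : i * d + n, j * d : j * d + m, :] @ kernel[i, j]
            out = term if out is None else out + term
    return out


def _channel_attention_t(f: Tensor, p: AttentionParams, training: bool) -> Tensor:
    """(B, N, M, C) -> (B, C): GAP, FC reduce (ReLU), FC expand, batch norm."""
    gap = f.mean(axis=(1, 2))
    z = ad.relu(gap @ p.w1)
    s = z @ p.w2
    return p.bn_channel(s, training)


def _spatial_attention_t(f: Tensor, p: AttentionParams, training: bool) -> Tensor:
    """(B, N, M, C) -> (B, N, M, 1): 1x1 reduce, two dilated 3x3, 1x1, BN."""
    t = ad.relu(f @ p.conv_reduce)
    t = ad.relu(_dilated_conv2d_same(t, p.conv_dil1, p.dilation))
    t = ad.relu(_dilated_conv2d_same(t, p.conv_dil2, p.dilation))
    v = t @ p.conv_collapse
    return p.bn_spatial(v, training)


def _fuse_t(mc: Tensor, ms: Tensor, mode: str = "sum") -> Tensor:
    """Broadcast (B, C) and (B, N, M, 1) maps to (B, N, M, C) and squash."""
    b, c = mc.shape
    mc4 = ad.reshape(mc, (b, 1, 1, c))
    if mode == "sum":
        return ad.sigmoid(mc4 + ms)
    if mode == "product":
        return ad.sigmoid(mc4 * ms)
    raise ValidationError(f"unknown fusion mode {mode!r}")


def _apply_attention_t(f: Tensor, m: Tensor) -> Tensor:
    return f + f * m


# ---------------------------------------------------------------------------
# Public functional operations (NumPy in, NumPy out; channels-first maps)
# ---------------------------------------------------------------------------

def lstm_step(x_t, h_prev, c_prev, params: LstmParams):
    """One LSTM cell update on plain arrays; returns (h_t, c_t).

    Accepts single vectors (D,)/(H,) or batches (B, D)/(B, H).
    """
    x = np.atleast_2d(np.asarray(x_t, dtype=np.float64))
    h = np.atleast_2d(np.asarray(h_prev, dtype=np.float64))
    c = np.atleast_2d(np.asarray(c_prev, dtype=np.float64))
    if x.shape[1] != params.input_size or h.shape[1] != params.hidden_size:
        raise ValidationError(
            f"lstm_step shapes {x.shape}/{h.shape} inconsistent with params "
            f"(D={params.input_size}, H={params.hidden_size})"
        )
    if h.shape != c.shape:
        raise ValidationError("h_prev and c_prev must have identical shapes")
    h_t, c_t = _lstm_step_t(Tensor(x), Tensor(h), Tensor(c), params)
    squeeze = np.asarray(x_t).ndim == 1
    return (h_t.value[0], c_t.value[0]) if squeeze else (h_t.value, c_t.value)


def bilstm_sequence(seq, forward_params: LstmParams, backward_params: LstmParams):
    """(L, D) sequence -> (L, 2H) output, [forward; backward] per timestep."""
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValidationError("seq must be a nonempty (L, D) array")
    out = _bilstm_t(Tensor(seq[None]), forward_params, backward_params)
    return out.value[0]


def global_average_pool(feature_map):
    """(C, N, M) -> (C,): per-channel mean over the spatial grid."""
    f = _check_map(feature_map)
    return f.mean(axis=(1, 2))


def _check_map(feature_map) -> np.ndarray:
    f = np.asarray(feature_map, dtype=np.float64)
    if f.ndim != 3:
        raise ValidationError("feature map must be (C, N, M)")
    return f


def channel_attention(feature_map, params: AttentionParams, training: bool = False):
    """(C, N, M) feature map -> channel attention map Mc of shape (C, 1, 1)."""
    f = _check_map(feature_map)
    if f.shape[0] != params.n_channels:
        raise ValidationError("feature map channels do not match params")
    x = Tensor(np.transpose(f, (1, 2, 0))[None])  # (1, N, M, C)
    mc = _channel_attention_t(x, params, training)
    return mc.value[0].reshape(-1, 1, 1)


def spatial_attention(feature_map, params: AttentionParams, training: bool = False):
    """(C, N, M) feature map -> spatial attention map Ms of shape (1, N, M)."""
    f = _check_map(feature_map)
    if f.shape[0] != params.n_channels:
        raise ValidationError("feature map channels do not match params")
    d = params.dilation
    x = Tensor(np.transpose(f, (1, 2, 0))[None])
    ms = _spatial_attention_t(x, params, training)
    return np.transpose(ms.value[0], (2, 0, 1))  # (1, N, M)


def fuse_attention(mc, ms, mode: str = "sum"):
    """Broadcast Mc (C, 1, 1) and Ms (1, N, M) to (C, N, M); sigmoid of sum."""
    mc = np.asarray(mc, dtype=np.float64).reshape(-1, 1, 1)
    ms = np.asarray(ms, dtype=np.float64)
    if ms.ndim != 3 or ms.shape[0] != 1:
        raise ValidationError("Ms must have shape (1, N, M)")
    combined = mc + ms if mode == "sum" else mc * ms
    return 1.0 / (1.0 + np.exp(-combined))


def apply_attention(feature_map, fused_map):
    """Residual application F' = F + F * M, elementwise."""
    f = _check_map(feature_map)
    m = np.asarray(fused_map, dtype=np.float64)
    if m.shape != f.shape:
        raise ValidationError(f"attention map shape {m.shape} != feature map {f.shape}")
    return f + f * m


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

@dataclass
class CbaBilstmConfig:
    """Architecture hyperparameters.

    ``conv_groups`` lists (filters, kernel, pool) for the three front-end
    groups; ``reduction_ratio`` and ``dilation`` parameterize the attention
    bottleneck; ``fusion`` selects additive or multiplicative map merging.
    """

    n_channels: int = 9
    sequence_length: int = 128
    conv_groups: tuple[tuple[int, int, int], ...] = DEFAULT_CONV_GROUPS
    bilstm_units: int = 64
    reduction_ratio: int = 16
    dilation: int = 4
    n_classes: int = 2
    fusion: str = "sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.sequence_length < 1:
            raise ValidationError("n_channels and sequence_length must be >= 1")
        if self.bilstm_units < 1 or self.n_classes < 2:
            raise ValidationError("bilstm_units >= 1 and n_classes >= 2 required")
        length = self.sequence_length
        for _, _, pool in self.conv_groups:
            length //= pool
            if length < 1:
                raise ValidationError(
                    f"sequence_length {self.sequence_length} too short for the "
                    f"pooling stages {[g[2] for g in self.conv_groups]}"
                )

    @property
    def reduced_length(self) -> int:
        length = self.sequence_length
        for _, _, pool in self.conv_groups:
            length //= pool
        return length

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "sequence_length": self.sequence_length,
            "conv_groups": [list(g) for g in self.conv_groups],
            "bilstm_units": self.bilstm_units,
            "reduction_ratio": self.reduction_ratio,
            "dilation": self.dilation,
            "n_classes": self.n_classes,
            "fusion": self.fusion,
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "CbaBilstmConfig":
        d = dict(d)
        d["conv_groups"] = tuple(tuple(g) for g in d["conv_groups"])
        return CbaBilstmConfig(**d)


class CbaBilstm:
    """The assembled network; see the module docstring for the data flow."""

    def __init__(self, config: CbaBilstmConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.conv_kernels: list[Tensor] = []
        self.conv_biases: list[Tensor] = []
        c_in = config.n_channels
        for filters, kernel, _pool in config.conv_groups:
            self.conv_kernels.append(
                _glorot(rng, (kernel, c_in, filters), kernel * c_in, filters)
            )
            self.conv_biases.append(ad.parameter(np.zeros(filters)))
            c_in = filters
        h = config.bilstm_units
        self.lstm_fwd = make_lstm_params(c_in, h, rng)
        self.lstm_bwd = make_lstm_params(c_in, h, rng)
        self.attention = make_attention_params(
            2 * h, config.reduction_ratio, config.dilation, rng
        )
        feat = 2 * h * config.reduced_length
        self.head_w = _glorot(rng, (feat, config.n_classes), feat, config.n_classes)
        self.head_b = ad.parameter(np.zeros(config.n_classes))
        # training-fit per-channel (min, max) applied at inference; None until
        # the training harness sets it
        self.input_norm: tuple[np.ndarray, np.ndarray] | None = None

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return [
            *self.conv_kernels,
            *self.conv_biases,
            *self.lstm_fwd.tensors(),
            *self.lstm_bwd.tensors(),
            *self.attention.tensors(),
            self.head_w,
            self.head_b,
        ]

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward ------------------------------------------------------------
    def forward(self, batch, training: bool = False) -> Tensor:
        """(B, L, C) batch -> (B, n_classes) class probabilities."""
        x = batch if isinstance(batch, Tensor) else Tensor(np.asarray(batch, dtype=np.float64))
        cfg = self.config
        if x.ndim != 3 or x.shape[1] != cfg.sequence_length or x.shape[2] != cfg.n_channels:
            raise ValidationError(
                f"batch shape {x.shape} does not match (B, {cfg.sequence_length}, "
                f"{cfg.n_channels})"
            )
        for kernel, bias, (_f, _k, pool) in zip(
            self.conv_kernels, self.conv_biases, cfg.conv_groups
        ):
            x = ad.relu(_conv1d_same(x, kernel, bias))
            x = _maxpool1d(x, pool)
        out = _bilstm_t(x, self.lstm_fwd, self.lstm_bwd)  # (B, L', 2H)
        b = out.shape[0]
        fmap = ad.reshape(out, (b, cfg.reduced_length, 1, 2 * cfg.bilstm_units))
        mc = _channel_attention_t(fmap, self.attention, training)
        ms = _spatial_attention_t(fmap, self.attention, training)
        fused = _fuse_t(mc, ms, cfg.fusion)
        attended = _apply_attention_t(fmap, fused)
        flat = ad.reshape(attended, (b, -1))
        logits = flat @ self.head_w + self.head_b
        return ad.softmax(logits, axis=-1)

    def predict_proba(self, batch) -> np.ndarray:
        """Inference-mode probabilities; applies the stored input
        normalization (if any) so raw sequences can be scored directly."""
        batch = np.asarray(batch, dtype=np.float64)
        if self.input_norm is not None:
            batch = apply_sequence_norm(batch, *self.input_norm)
        return self.forward(batch, training=False).value

    def predict(self, batch) -> np.ndarray:
        return self.predict_proba(batch).argmax(axis=1)


def build_model(config: CbaBilstmConfig) -> CbaBilstm:
    """Construct the network; ``model.parameter_count`` reports its size."""
    return CbaBilstm(config)


def forward(model: CbaBilstm, batch) -> np.ndarray:
    """Inference-mode class probabilities for a batch of sequences."""
    return model.predict_proba(batch)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def _named_state(model: CbaBilstm) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    for i, (k, b) in enumerate(zip(model.conv_kernels, model.conv_biases)):
        state[f"conv{i}/kernel"] = k.value
        state[f"conv{i}/bias"] = b.value
    for name, p in (("fwd", model.lstm_fwd), ("bwd", model.lstm_bwd)):
        for g in "iofc":
            state[f"lstm_{name}/w_{g}"] = getattr(p, f"w_{g}").value
            state[f"lstm_{name}/b_{g}"] = getattr(p, f"b_{g}").value
    att = model.attention
    state["att/w1"] = att.w1.value
    state["att/w2"] = att.w2.value
    state["att/conv_reduce"] = att.conv_reduce.value
    state["att/conv_dil1"] = att.conv_dil1.value
    state["att/conv_dil2"] = att.conv_dil2.value
    state["att/conv_collapse"] = att.conv_collapse.value
    for bn_name, bn in (("bn_channel", att.bn_channel), ("bn_spatial", att.bn_spatial)):
        state[f"att/{bn_name}/gamma"] = bn.gamma.value
        state[f"att/{bn_name}/beta"] = bn.beta.value
        state[f"att/{bn_name}/running_mean"] = bn.running_mean
        state[f"att/{bn_name}/running_var"] = bn.running_var
    state["head/w"] = model.head_w.value
    state["head/b"] = model.head_b.value
    return state


def save_model(model: CbaBilstm, path) -> None:
    """Write weights, batch-norm statistics and the config to an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(model.config.to_dict())
        for name, arr in _named_state(model).items():
            f.create_dataset(name, data=arr)
        if model.input_norm is not None:
            f.create_dataset("input_norm/lo", data=model.input_norm[0])
            f.create_dataset("input_norm/hi", data=model.input_norm[1])


def load_model(path) -> CbaBilstm:
    with h5py.File(path, "r") as f:
        config = CbaBilstmConfig.from_dict(json.loads(f.attrs["config"]))
        model = CbaBilstm(config)
        for name, arr in _named_state(model).items():
            arr[...] = f[name][()]
        if "input_norm" in f:
            model.input_norm = (f["input_norm/lo"][()], f["input_norm/hi"][()])
    return model
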