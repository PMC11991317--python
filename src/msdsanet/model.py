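"""MSDSANet: multimodal emotion-recognition network.

The model fuses three feature streams:

* an EEG *temporal* stream — per-electrode temporal convolution, a
  cross-channel convolution collapsing the electrode axis, then two 3x3
  convolutions (BN + ReLU after each, dropout last);
* an EEG *spatial* stream — the 1-s window mapped onto a 2-D electrode grid
  (time samples as input channels) fed to a multi-scale attention residual
  block (MSARB): a 3x3 stem, parallel 7x7/5x5/3x3 convolutions, channel
  concatenation, a 1x1 bottleneck, efficient channel attention (ECA) and a
  residual connection back to the stem;
* a peripheral stream (DSANet) — two conv-LSTM branches over the EOG/ECG
  channels, a long-kernel branch (1x50 -> 1x10 -> LSTM) for slow components
  and a short-kernel branch (1x5 -> 1x3 -> LSTM) for transients, concatenated
  and reweighted by ECA.

The streams are adapted to a common HxW plane, concatenated along feature
channels and passed through CBAM (channel attention then spatial attention)
before a flatten/dropout/dense softmax classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .autodiff import Tensor, concat, conv2d, cross_entropy_logits, softmax
from .layers import LSTM, BatchNorm, Conv2d, Dense, Dropout, Module, _uniform

ABLATION_NAMES = ("Model1", "Model2", "Model3", "Model4", "Model5", "Model6", "full")


@dataclass(frozen=True)
class ECAConfig:
    """Adaptive-kernel constants for efficient channel attention."""
    t0: int = 2
    b1: int = 1

    def __post_init__(self):
        if self.t0 < 1:
            raise ValueError("t0 must be >= 1")


def eca_kernel_size(n_channels: int, cfg: ECAConfig = ECAConfig()) -> int:
    """Adaptive 1-D convolution kernel size for ECA.

    k = floor(|log2(C)/t0 + b1/t0|), bumped to the next integer if even,
    and never below 1 — so k is always odd and the attention window grows
    logarithmically with the channel count.
    """
    if n_channels < 1:
        raise ValueError(f"channel count must be >= 1, got {n_channels}")
    k = int(abs(np.log2(n_channels) / cfg.t0 + cfg.b1 / cfg.t0))
    if k % 2 == 0:
        k += 1
    return max(k, 1)


@dataclass
class ModelConfig:
    """Every architectural hyperparameter, with defaults for unstated values.

    `n_eeg`, `n_periph` and `window_samples` describe the input; stream
    toggles implement the ablation variants. The reduced() preset shrinks
    every width for fast experiments on synthetic data.
    """

    n_eeg: int = 32
    n_periph: int = 2
    window_samples: int = 128
    grid_h: int = 9
    grid_w: int = 9
    # EEG spatial stream (MSARB)
    f0: int = 64                 # stem / bottleneck channels
    f_ms: int = 64               # channels per multi-scale branch
    # EEG temporal stream
    temporal_kernel: int = 5     # per-electrode 1-D kernel length
    temporal_filters: int = 64
    cross_channel_filters: int = 64
    eeg_conv_filters: tuple = (64, 32)
    # peripheral stream (DSANet)
    dsanet_filters: tuple = (32, 64)
    long_kernels: tuple = (50, 10)
    short_kernels: tuple = (5, 3)
    lstm_long: int = 768
    lstm_short: int = 384
    # fusion + head
    f_e: int = 16                # peripheral projection channels
    cbam_reduction: int = 8
    cbam_spatial_kernel: int = 7
    dropout: float = 0.5
    n_classes: int = 2
    # stream toggles (ablations)
    use_temporal_stream: bool = True
    use_grid_stream: bool = True
    use_dsanet: bool = True
    dsanet_long: bool = True
    dsanet_short: bool = True
    eca: ECAConfig = field(default_factory=ECAConfig)
    seed: int = 0

    def __post_init__(self):
        for name in ("temporal_kernel", "cbam_spatial_kernel"):
            if getattr(self, name) % 2 == 0:
                raise ValueError(f"{name} must be odd for a centred receptive field")
        for name in ("f0", "f_ms", "temporal_filters", "lstm_long", "lstm_short",
                     "f_e", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (self.use_temporal_stream or self.use_grid_stream or self.use_dsanet):
            raise ValueError("at least one stream must be enabled")
        if self.use_dsanet and not (self.dsanet_long or self.dsanet_short):
            raise ValueError("DSANet enabled but both branches disabled")

    @classmethod
    def reduced(cls, n_eeg: int, n_periph: int = 2, window_samples: int = 128,
                seed: int = 0, **kw) -> "ModelConfig":
        """Small widths for synthetic-data experiments and gradient checks."""
        defaults = dict(f0=8, f_ms=8, temporal_filters=8, cross_channel_filters=8,
                        eeg_conv_filters=(16, 8), dsanet_filters=(8, 16),
                        lstm_long=32, lstm_short=16, f_e=4, cbam_reduction=4)
        defaults.update(kw)
        return cls(n_eeg=n_eeg, n_periph=n_periph, window_samples=window_samples,
                   seed=seed, **defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("eeg_conv_filters", "dsanet_filters", "long_kernels", "short_kernels"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if isinstance(d.get("eca"), dict):
            d["eca"] = ECAConfig(**d["eca"])
        for k in ("eeg_conv_filters", "dsanet_filters", "long_kernels", "short_kernels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def ablation_config(name: str, base: ModelConfig) -> ModelConfig:
    """Stream-removal variants used in the ablation study.

    Model1: EEG only (both EEG streams, no peripheral branch).
    Model2: peripheral only.  Model3: no spatial-grid stream.
    Model4: no raw time-series stream.  Model5: long peripheral branch only.
    Model6: short peripheral branch only.  "full": everything on.
    """
    variants = {
        "full": {},
        "Model1": dict(use_dsanet=False),
        "Model2": dict(use_temporal_stream=False, use_grid_stream=False),
        "Model3": dict(use_grid_stream=False),
        "Model4": dict(use_temporal_stream=False),
        "Model5": dict(dsanet_short=False),
        "Model6": dict(dsanet_long=False),
    }
    if name not in variants:
        raise ValueError(
            f"unknown ablation {name!r}; valid names: {', '.join(ABLATION_NAMES)}")
    return replace(base, **variants[name])


# --------------------------------------------------------------------- blocks
class ECA(Module):
    """Efficient channel attention.

    Global-average-pool each channel, slide a 1-D convolution of adaptive odd
    kernel size over the channel descriptor, squash with a sigmoid and rescale
    the input channels by the resulting (0, 1) weights. Shape-preserving.
    """

    def __init__(self, n_channels: int, rng: np.random.Generator,
                 cfg: ECAConfig = ECAConfig()):
        self.k = eca_kernel_size(n_channels, cfg)
        self.weight = _uniform(rng, (1, 1, 1, self.k), self.k)

    def attention(self, x: Tensor) -> Tensor:
        """Per-channel weights in (0,1); x is [N, C] or [N, C, H, W]."""
        g = x if x.ndim == 2 else x.mean(axis=(2, 3))        # [N, C]
        n, c = g.shape
        y = conv2d(g.reshape(n, 1, 1, c), self.weight, None, padding="same")
        return y.reshape(n, c).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        w = self.attention(x)
        if x.ndim == 4:
            w = w.reshape(*w.shape, 1, 1)
        return x * w


class ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, padding="same"):
        self.conv = Conv2d(in_ch, out_ch, kernel, rng, padding=padding)
        self.bn = BatchNorm(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class MSARB(Module):
    """Multi-scale attention residual block over the electrode grid.

    Input is the spatial form of a window: time samples act as input channels
    over the HxW electrode plane, so the 3x3/5x5/7x7 kernels span growing
    electrode neighbourhoods. All convolutions are same-padded; the ECA output
    is added back to the stem (residual connection).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.stem = ConvBNReLU(cfg.window_samples, cfg.f0, 3, rng)
        self.branches = [ConvBNReLU(cfg.f0, cfg.f_ms, k, rng) for k in (7, 5, 3)]
        self.bottleneck = ConvBNReLU(3 * cfg.f_ms, cfg.f0, 1, rng)
        self.eca = ECA(cfg.f0, rng, cfg.eca)

    def __call__(self, x: Tensor) -> Tensor:
        h0 = self.stem(x)
        hcat = concat([b(h0) for b in self.branches], axis=1)
        hcat1 = self.bottleneck(hcat)
        return self.eca(hcat1) + h0


class EEGTemporalStream(Module):
    """Raw EEG time-series stream.

    A temporal convolution applied to each electrode independently, a
    cross-channel convolution spanning the whole electrode axis, then two
    3x3 convolutions with 64 and 32 feature maps at full width; each
    convolution is followed by BN + ReLU, with dropout after the last
    activation. Output is [N, F, 1, T].
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.k_t = cfg.temporal_kernel
        self.temporal = ConvBNReLU(1, cfg.temporal_filters, (1, cfg.temporal_kernel), rng)
        self.cross = ConvBNReLU(cfg.temporal_filters, cfg.cross_channel_filters,
                                (cfg.n_eeg, 1), rng, padding="valid")
        f1, f2 = cfg.eeg_conv_filters
        self.conv1 = ConvBNReLU(cfg.cross_channel_filters, f1, 3, rng)
        self.conv2 = ConvBNReLU(f1, f2, 3, rng)
        self.drop = Dropout(cfg.dropout, rng)
        self.out_channels = f2

    def __call__(self, eeg: Tensor) -> Tensor:
        n, c, t = eeg.shape
        if t < self.k_t:
            raise ValueError(f"window length {t} shorter than temporal kernel {self.k_t}")
        h = self.temporal(eeg.reshape(n, 1, c, t))
        h = self.cross(h)                     # collapses the electrode axis -> H=1
        h = self.conv2(self.conv1(h))
        return self.drop(h)


class DSANetBranch(Module):
    def __init__(self, in_ch, kernels, filters, lstm_units, rng):
        k1, k2 = kernels
        f1, f2 = filters
        self.min_t = k1 + k2 - 1
        self.conv1 = Conv2d(1, f1, (1, k1), rng, padding="valid")
        self.conv2 = Conv2d(f1, f2, (1, k2), rng, padding="valid")
        self.lstm = LSTM(f2 * in_ch, lstm_units, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # x: [N, 1, P, T] -> conv features [N, F, P, L] -> L steps of F*P dims
        h = self.conv2(self.conv1(x).relu()).relu()
        n, f, p, length = h.shape
        seq = h.transpose(0, 3, 1, 2).reshape(n, length, f * p)
        return self.lstm(seq)


class DSANet(Module):
    """Dual-scale peripheral-signal extractor.

    Long branch (1x50 -> 1x10 -> LSTM) and short branch (1x5 -> 1x3 -> LSTM)
    over the EOG/ECG channels; final hidden states are concatenated and
    reweighted by ECA over the concatenated units.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.long = None
        self.short = None
        self.out_channels = 0
        if cfg.dsanet_long:
            self.long = DSANetBranch(cfg.n_periph, cfg.long_kernels,
                                     cfg.dsanet_filters, cfg.lstm_long, rng)
            self.out_channels += cfg.lstm_long
        if cfg.dsanet_short:
            self.short = DSANetBranch(cfg.n_periph, cfg.short_kernels,
                                      cfg.dsanet_filters, cfg.lstm_short, rng)
            self.out_channels += cfg.lstm_short
        self.min_t = max(b.min_t for b in (self.long, self.short) if b is not None)
        self.eca = ECA(self.out_channels, rng, ECAConfig(t0=cfg.eca.t0, b1=cfg.eca.b1))

    def __call__(self, periph: Tensor) -> Tensor:
        n, p, t = periph.shape
        if t < self.min_t:
            raise ValueError(
                f"peripheral window length {t} too short; the enabled DSANet "
                f"branches need at least {self.min_t} samples")
        x = periph.reshape(n, 1, p, t)
        feats = [b(x) for b in (self.long, self.short) if b is not None]
        h = feats[0] if len(feats) == 1 else concat(feats, axis=1)
        return self.eca(h)


class CBAM(Module):
    """Convolutional block attention: channel attention then spatial attention.

    Channel attention: shared 2-layer MLP (reduction r) applied to spatially
    average- and max-pooled descriptors, summed, sigmoid. Spatial attention:
    7x7 convolution over the channelwise average- and max-pooled maps,
    sigmoid. Both are shape-preserving multiplicative gates in (0, 1).
    """

    def __init__(self, n_channels: int, cfg: ModelConfig, rng: np.random.Generator):
        hidden = max(n_channels // cfg.cbam_reduction, 1)
        self.mlp1 = Dense(n_channels, hidden, rng)
        self.mlp2 = Dense(hidden, n_channels, rng)
        self.spatial = Conv2d(2, 1, cfg.cbam_spatial_kernel, rng, padding="same")

    def channel_attention(self, x: Tensor) -> Tensor:
        avg = self.mlp2(self.mlp1(x.mean(axis=(2, 3))).relu())
        mx = self.mlp2(self.mlp1(x.max(axis=(2, 3))).relu())
        return (avg + mx).sigmoid()                    # [N, C]

    def spatial_attention(self, x: Tensor) -> Tensor:
        pooled = concat([x.mean(axis=1, keepdims=True),
                         x.max(axis=1, keepdims=True)], axis=1)
        return self.spatial(pooled).sigmoid()          # [N, 1, H, W]

    def __call__(self, x: Tensor) -> Tensor:
        w = self.channel_attention(x)
        h_ca = x * w.reshape(*w.shape, 1, 1)
        return h_ca * self.spatial_attention(h_ca)


def _pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Adaptive average-pooling weights [n_out, n_in] (replicates if n_out > n_in)."""
    m = np.zeros((n_out, n_in))
    for i in range(n_out):
        a = (i * n_in) // n_out
        b = max(-(-((i + 1) * n_in) // n_out), a + 1)  # ceil, at least one cell
        m[i, a:b] = 1.0 / (b - a)
    return m


class MSDSANet(Module):
    """The assembled multimodal network.

    forward() takes a batch of windows — EEG [N, C, T], spatial grid
    [N, H, W, T], peripheral [N, P, T] — and returns class logits; inputs of
    disabled streams are never read. Stream outputs are adapted to the HxW
    electrode plane (temporal stream by adaptive average pooling, peripheral
    vector by a learned projection), concatenated along feature channels,
    gated by CBAM and classified by flatten -> dropout -> dense -> softmax.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.rng = rng
        h, w = cfg.grid_h, cfg.grid_w
        fused_ch = 0
        if cfg.use_temporal_stream:
            self.temporal_stream = EEGTemporalStream(cfg, rng)
            self._pool_h = _pool_matrix(1, h).T          # [1, H] via matmul
            self._pool_w = _pool_matrix(cfg.window_samples, w).T
            fused_ch += self.temporal_stream.out_channels
        if cfg.use_grid_stream:
            self.msarb = MSARB(cfg, rng)
            fused_ch += cfg.f0
        if cfg.use_dsanet:
            self.dsanet = DSANet(cfg, rng)
            self.periph_proj = Dense(self.dsanet.out_channels, cfg.f_e * h * w, rng)
            fused_ch += cfg.f_e
        self.cbam = CBAM(fused_ch, cfg, rng)
        self.head_drop = Dropout(cfg.dropout, rng)
        self.head = Dense(fused_ch * h * w, cfg.n_classes, rng)
        self.fused_channels = fused_ch

    # ------------------------------------------------------------- forward
    def forward(self, eeg=None, grid=None, periph=None) -> Tensor:
        cfg = self.cfg
        h, w = cfg.grid_h, cfg.grid_w
        feats = []
        n = None
        if cfg.use_temporal_stream:
            if eeg is None:
                raise ValueError("temporal stream enabled but no EEG input given")
            eeg = Tensor._lift(eeg)
            n = eeg.shape[0]
            f = self.temporal_stream(eeg)                # [N, F, 1, T]
            f = Tensor(self._pool_h.T) @ f @ Tensor(self._pool_w)  # -> [N, F, H, W]
            feats.append(f)
        if cfg.use_grid_stream:
            if grid is None:
                raise ValueError("grid stream enabled but no grid input given")
            grid = Tensor._lift(grid)
            n = grid.shape[0]
            feats.append(self.msarb(grid.transpose(0, 3, 1, 2)))   # time as channels
        if cfg.use_dsanet:
            if periph is None:
                raise ValueError("DSANet enabled but no peripheral input given")
            periph = Tensor._lift(periph)
            n = periph.shape[0]
            v = self.periph_proj(self.dsanet(periph))
            feats.append(v.reshape(n, cfg.f_e, h, w))
        fused = feats[0] if len(feats) == 1 else concat(feats, axis=1)
        fused = self.cbam(fused)
        flat = fused.reshape(n, self.fused_channels * h * w)
        self._last_features = flat.data
        return self.head(self.head_drop(flat))

    __call__ = forward

    def extract_features(self, eeg=None, grid=None, periph=None) -> np.ndarray:
        """Flattened post-fusion (CBAM) features, eval mode — for embedding plots."""
        was_training = self.training
        self.eval()
        try:
            self.forward(eeg=eeg, grid=grid, periph=periph)
            return self._last_features
        finally:
            self.train(was_training)

    def predict_proba(self, eeg=None, grid=None, periph=None) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            return softmax(self.forward(eeg=eeg, grid=grid, periph=periph)).data
        finally:
            self.train(was_training)

    def predict(self, eeg=None, grid=None, periph=None) -> np.ndarray:
        return self.predict_proba(eeg=eeg, grid=grid, periph=periph).argmax(axis=1)

    def loss(self, onehot: np.ndarray, eeg=None, grid=None, periph=None) -> Tensor:
        return cross_entropy_logits(self.forward(eeg=eeg, grid=grid, periph=periph),
                                    onehot)


def cross_entropy(y_true: np.ndarray, y_prob: np.ndarray, eps: float = 1e-12) -> float:
    """Mean cross-entropy of predicted probabilities against one-hot targets."""
    y_true = np.asarray(y_true, dtype=float)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_prob.shape}")
    return float(-(y_true * np.log(np.clip(y_prob, eps, 1.0))).sum() / y_true.shape[0])


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(model: MSDSANet, path) -> None:
    """Single-file checkpoint: weights + embedded config."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8).copy()
    with open(path, "wb") as fh:
        np.savez(fh, **state)


def load_checkpoint(path) -> MSDSANet:
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"].tobytes()).decode()))
        model = MSDSANet(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
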