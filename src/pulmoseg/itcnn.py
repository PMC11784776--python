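"""Improved Transformer-based CNN (ITCNN) lesion segmenter.

Two parallel encoder branches process the preprocessed image:

* a transformer branch of improved Swin-transformer (IST) blocks —
  windowed multi-head self-attention (W-MSA, and the shifted SW-MSA
  variant that rolls the token grid by half a window), layer norm and
  a GELU MLP, augmented with batch normalisation and average pooling;
* a CNN branch of mobile inverted bottleneck (MBConv) blocks with
  squeeze-and-excitation gating and Swish activations.

At each of the four stages a fusion module (STCF) merges the two
branches with spatial attention, concurrent spatial/channel
squeeze-and-excitation (scSE) recalibration, and a Hadamard-product
bridge, and the fused maps feed a convolutional decoder with skip
connections that produces a sigmoid lesion-probability map.

The attention logits support two modes. In ``improved`` mode the
query-key product is squared elementwise before scaling,
``softmax(σ·((qkᵀ ⊙ qkᵀ)/√D + B))``, with σ a learnable positive
scalar and B a relative-position bias gathered from a
(2p−1)×(2p+1) table; ``standard`` mode uses the usual
``softmax(qkᵀ/√D + B)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .nn import (
    Adam, BatchNorm2d, Conv2d, DepthwiseConv2d, LayerNorm, Linear, Module,
    Parameter, Tensor, concat, refresh_bn_stats,
)

__all__ = [
    "AttentionParams", "SegConfig", "SegTrainConfig", "SegModel",
    "improved_self_attention", "relative_position_bias",
    "WindowAttention", "ISTBlock", "MBConv", "STCF",
    "segment", "train_segmenter", "apply_mask", "save_model", "load_model",
]


# ---------------------------------------------------------------------------
# attention primitive
# ---------------------------------------------------------------------------

@dataclass
class AttentionParams:
    """Parameters of the windowed self-attention operator."""

    window_p: int
    dim_D: int
    n_heads: int = 1
    bias_table: np.ndarray | None = None     # (2p-1, 2p+1)
    logit_scale: float = 1.0
    mode: str = "improved"                   # improved | standard

    def __post_init__(self):
        if self.bias_table is None:
            self.bias_table = np.zeros(
                (2 * self.window_p - 1, 2 * self.window_p + 1))
        if self.logit_scale <= 0:
            raise ValueError("logit_scale must be positive")
        if self.mode not in ("improved", "standard"):
            raise ValueError(f"unknown attention mode: {self.mode}")


def _relative_index(p: int) -> np.ndarray:
    """Flat (p², p²) index into the (2p−1)×(2p+1) bias table."""
    coords = np.stack(np.mgrid[0:p, 0:p], 0).reshape(2, -1)
    dr = coords[0][:, None] - coords[0][None, :]
    dc = coords[1][:, None] - coords[1][None, :]
    return (dr + p - 1) * (2 * p + 1) + (dc + p)


def relative_position_bias(table: np.ndarray, p: int) -> np.ndarray:
    """Gather the (p², p²) bias matrix B from the table B̂."""
    return table.reshape(-1)[_relative_index(p)]


def improved_self_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                            params: AttentionParams) -> np.ndarray:
    """Single-window self-attention on (tokens × D) arrays.

    ``improved`` mode squares the query-key logits elementwise before
    the √D scaling; every softmax row sums to one.
    """
    q, k, v = (np.asarray(a, dtype=float) for a in (q, k, v))
    if q.shape != k.shape or q.shape[0] != v.shape[0]:
        raise ValueError("q, k, v must share token count; q, k share dim")
    if q.shape[1] != params.dim_D:
        raise ValueError("q/k dimension must equal params.dim_D")
    n = q.shape[0]
    if n == params.window_p**2:
        bias = relative_position_bias(params.bias_table, params.window_p)
    else:
        bias = np.zeros((n, n))
    s = q @ k.T
    if params.mode == "improved":
        logits = params.logit_scale * ((s * s) / np.sqrt(params.dim_D) + bias)
    else:
        logits = s / np.sqrt(params.dim_D) + bias
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    attn = e / e.sum(axis=1, keepdims=True)
    return attn @ v


# ---------------------------------------------------------------------------
# transformer branch
# ---------------------------------------------------------------------------

class WindowAttention(Module):
    """Multi-head windowed self-attention over (B, H, W, C) token maps."""

    def __init__(self, dim: int, window: int, heads: int,
                 rng: np.random.Generator, mode: str = "improved"):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.window, self.heads, self.mode = dim, window, heads, mode
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)
        p = window
        self.bias_table = Parameter(np.zeros((2 * p - 1) * (2 * p + 1)))
        self.log_scale = Parameter(np.zeros(1))
        self._rel = _relative_index(p)

    def __call__(self, x: Tensor, shift: bool = False) -> Tensor:
        b, h, w, c = x.shape
        p = self.window
        ph = (p - h % p) % p
        pw = (p - w % p) % p
        if ph or pw:  # pad token grid to window multiples
            x = x.transpose(0, 3, 1, 2)
            data_pad = [(0, 0), (0, 0), (0, ph), (0, pw)]
            xpad = Tensor(np.pad(x.data, data_pad))
            if x.requires_grad:
                xpad.requires_grad = True
                xpad._prev = (x,)
                xpad._backward = lambda g, _x=x: _x._acc(
                    g[:, :, : h, : w])
            x = xpad.transpose(0, 2, 3, 1)
        hp, wp = h + ph, w + pw
        if shift:
            x = x.roll((-(p // 2), -(p // 2)), axis=(1, 2))
        nwh, nww = hp // p, wp // p
        xw = (x.reshape(b, nwh, p, nww, p, c)
               .transpose(0, 1, 3, 2, 4, 5)
               .reshape(b * nwh * nww, p * p, c))
        d = c // self.heads

        def heads_of(t):
            return (t.reshape(b * nwh * nww, p * p, self.heads, d)
                     .transpose(0, 2, 1, 3))

        q, k, v = heads_of(self.q(xw)), heads_of(self.k(xw)), heads_of(self.v(xw))
        s = q @ k.transpose(0, 1, 3, 2)
        bias = self.bias_table.take(self._rel)
        if self.mode == "improved":
            scale = self.log_scale.exp().reshape(1)
            logits = (s * s * (1.0 / np.sqrt(d)) + bias) * scale
        else:
            logits = s * (1.0 / np.sqrt(d)) + bias
        attn = logits.softmax(axis=-1)
        out = attn @ v
        out = (out.transpose(0, 2, 1, 3).reshape(b * nwh * nww, p * p, c))
        out = self.proj(out)
        x = (out.reshape(b, nwh, nww, p, p, c)
                .transpose(0, 1, 3, 2, 4, 5)
                .reshape(b, hp, wp, c))
        if shift:
            x = x.roll((p // 2, p // 2), axis=(1, 2))
        if ph or pw:
            x = x[:, :h, :w, :]
        return x


class ISTBlock(Module):
    """Improved Swin-transformer block: pre-norm residual attention and
    MLP, plus the two added layers (batch norm; optional 2×2 average
    pooling as the between-stage downsampler)."""

    def __init__(self, dim: int, window: int, heads: int,
                 rng: np.random.Generator, shift: bool = False,
                 mlp_ratio: float = 2.0, mode: str = "improved",
                 use_batchnorm: bool = True, pool: str = "none"):
        super().__init__()
        self.shift = shift
        self.pool = pool
        self.ln1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, window, heads, rng, mode)
        self.ln2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)
        self.bn = BatchNorm2d(dim) if use_batchnorm else None

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, H, W, C) token map."""
        u = x + self.attn(self.ln1(x), shift=self.shift)
        u = u + self.fc2(self.fc1(self.ln2(u)).gelu())
        if self.bn is not None:
            u = self.bn(u.transpose(0, 3, 1, 2)).transpose(0, 2, 3, 1)
        if self.pool == "avg2":
            u = u.transpose(0, 3, 1, 2).avg_pool2d(2).transpose(0, 2, 3, 1)
        return u


# ---------------------------------------------------------------------------
# CNN branch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MBConvConfig:
    expansion: int = 2
    kernel: int = 3
    se_ratio: float = 0.25
    dropout: float = 0.0

    def __post_init__(self):
        if not 0 < self.se_ratio <= 1:
            raise ValueError("se_ratio must lie in (0, 1]")
        if self.kernel not in (3, 5):
            raise ValueError("kernel must be 3 or 5")


class MBConv(Module):
    """Mobile inverted bottleneck: expand → depthwise → SE → project."""

    def __init__(self, ch: int, rng: np.random.Generator,
                 cfg: MBConvConfig = MBConvConfig()):
        super().__init__()
        e = ch * cfg.expansion
        self.cfg = cfg
        self.expand = Conv2d(ch, e, 1, rng, padding=0)
        self.bn1 = BatchNorm2d(e)
        self.dw = DepthwiseConv2d(e, cfg.kernel, rng)
        self.bn2 = BatchNorm2d(e)
        squeeze = max(1, int(e * cfg.se_ratio))
        self.se_reduce = Linear(e, squeeze, rng)
        self.se_expand = Linear(squeeze, e, rng)
        self.project = Conv2d(e, ch, 1, rng, padding=0)
        self.bn3 = BatchNorm2d(ch)
        self._rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        y = self.bn1(self.expand(x)).swish()
        y = self.bn2(self.dw(y)).swish()
        # squeeze-and-excitation gate
        n, c = y.shape[0], y.shape[1]
        pooled = y.mean(axis=(2, 3))
        gate = self.se_expand(self.se_reduce(pooled).swish()).sigmoid()
        y = y * gate.reshape(n, c, 1, 1)
        y = self.bn3(self.project(y))
        if self.cfg.dropout > 0 and self.training:
            keep = 1.0 - self.cfg.dropout
            m = self._rng.random(y.shape) < keep
            y = y * Tensor(m / keep)
        if y.shape == x.shape:
            y = y + x
        return y


# ---------------------------------------------------------------------------
# fusion module
# ---------------------------------------------------------------------------

class SpatialAttention(Module):
    """CBAM-style gate: sigmoid(7×7 conv over channelwise [max, mean])."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(2, 1, 7, rng)

    def __call__(self, x: Tensor) -> Tensor:
        stats = concat([x.max(axis=1, keepdims=True),
                        x.mean(axis=1, keepdims=True)], axis=1)
        gate = self.conv(stats).sigmoid()
        return x * gate


class SCSE(Module):
    """Concurrent spatial & channel squeeze-and-excitation (additive)."""

    def __init__(self, ch: int, rng: np.random.Generator, reduction: int = 2):
        super().__init__()
        squeeze = max(1, ch // reduction)
        self.c_reduce = Linear(ch, squeeze, rng)
        self.c_expand = Linear(squeeze, ch, rng)
        self.s_conv = Conv2d(ch, 1, 1, rng, padding=0)

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        cgate = self.c_expand(self.c_reduce(x.mean(axis=(2, 3))).relu()).sigmoid()
        sgate = self.s_conv(x).sigmoid()
        return x * cgate.reshape(n, c, 1, 1) + x * sgate


class STCF(Module):
    """Swin-Transformer-and-CNN Fusion at one encoder stage.

    Tr₁ = SA(Tr), CNN₁ = SA(CNN); T̂r = scSE([CNN₁, Tr]),
    ĈNN = scSE([Tr₁, CNN]); b̂ = conv₃ₓ₃((Tr·w₁) ⊙ (CNN·w₂));
    f̂ = re([T̂r, ĈNN, b̂]) with re a 3×3 conv + BN + ReLU.
    """

    def __init__(self, ch: int, rng: np.random.Generator):
        super().__init__()
        self.sa = SpatialAttention(rng)
        self.scse = SCSE(2 * ch, rng)
        self.w1 = Conv2d(ch, ch, 1, rng, padding=0, bias=False)
        self.w2 = Conv2d(ch, ch, 1, rng, padding=0, bias=False)
        self.fuse_conv = Conv2d(ch, ch, 3, rng)
        self.re_conv = Conv2d(5 * ch, ch, 3, rng)
        self.re_bn = BatchNorm2d(ch)

    def __call__(self, tr: Tensor, cnn: Tensor) -> Tensor:
        if tr.shape[2:] != cnn.shape[2:]:
            raise ValueError("STCF inputs must be spatially aligned")
        tr1 = self.sa(tr)
        cnn1 = self.sa(cnn)
        tr_hat = self.scse(concat([cnn1, tr], axis=1))
        cnn_hat = self.scse(concat([tr1, cnn], axis=1))
        bridge = self.fuse_conv(self.w1(tr) * self.w2(cnn))
        fused = concat([tr_hat, cnn_hat, bridge], axis=1)
        return self.re_bn(self.re_conv(fused)).relu()


# ---------------------------------------------------------------------------
# full segmenter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegConfig:
    input_side: int = 64
    patch: int = 4
    dims: tuple[int, ...] = (16, 32, 64, 128)
    window: int = 4
    heads: int = 2
    mlp_ratio: float = 2.0
    attention_mode: str = "improved"
    use_batchnorm: bool = True
    threshold: float = 0.5


@dataclass(frozen=True)
class SegTrainConfig:
    epochs: int = 5
    lr: float = 3e-3
    batch_size: int = 8


class _ConvBNReLU(Module):
    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv = Conv2d(cin, cout, 3, rng)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x):
        return self.bn(self.conv(x)).relu()


class SegModel(Module):
    """Four paired IST/MBConv stages, per-stage STCF fusion, and a
    decoder with skip connections ending in a 1×1 conv + sigmoid."""

    def __init__(self, config: SegConfig = SegConfig(), seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.dims
        self.patch_embed = Conv2d(1, d[0], config.patch, rng,
                                  stride=config.patch, padding=0)
        self.cnn_stem = Conv2d(1, d[0], config.patch, rng,
                               stride=config.patch, padding=0)
        self.ist_blocks = []
        self.mbconvs = []
        self.stcfs = []
        self.tr_down = []
        self.cnn_down = []
        for x in range(4):
            blocks = [
                ISTBlock(d[x], config.window, config.heads, rng, shift=False,
                         mlp_ratio=config.mlp_ratio, mode=config.attention_mode,
                         use_batchnorm=config.use_batchnorm),
                ISTBlock(d[x], config.window, config.heads, rng, shift=True,
                         mlp_ratio=config.mlp_ratio, mode=config.attention_mode,
                         use_batchnorm=config.use_batchnorm),
            ]
            self.ist_blocks.append(blocks)
            self.mbconvs.append(MBConv(d[x], rng))
            self.stcfs.append(STCF(d[x], rng))
            if x < 3:
                self.tr_down.append(Conv2d(d[x], d[x + 1], 1, rng, padding=0))
                self.cnn_down.append(Conv2d(d[x], d[x + 1], 1, rng, padding=0))
        self.ist_blocks = [b for pair in self.ist_blocks for b in pair]
        self.dec2 = _ConvBNReLU(d[3] + d[2], d[2], rng)
        self.dec1 = _ConvBNReLU(d[2] + d[1], d[1], rng)
        self.dec0 = _ConvBNReLU(d[1] + d[0], d[0], rng)
        self.head_conv = Conv2d(d[0], 8, 3, rng)
        self.head_out = Conv2d(8, 1, 1, rng, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, 1, S, S) in [0,1] → (N, 1, S, S) lesion probabilities."""
        tr = self.patch_embed(x).transpose(0, 2, 3, 1)  # tokens (B,H,W,C)
        cnn = self.cnn_stem(x)
        fused = []
        for stage in range(4):
            tr = self.ist_blocks[2 * stage](tr)
            tr = self.ist_blocks[2 * stage + 1](tr)
            cnn = self.mbconvs[stage](cnn)
            fused.append(self.stcfs[stage](tr.transpose(0, 3, 1, 2), cnn))
            if stage < 3:
                tr = self.tr_down[stage](
                    tr.transpose(0, 3, 1, 2).avg_pool2d(2)).transpose(0, 2, 3, 1)
                cnn = self.cnn_down[stage](cnn.avg_pool2d(2))
        d = fused[3].upsample_nearest(2)
        d = self.dec2(concat([d, fused[2]], axis=1)).upsample_nearest(2)
        d = self.dec1(concat([d, fused[1]], axis=1)).upsample_nearest(2)
        d = self.dec0(concat([d, fused[0]], axis=1))
        d = d.upsample_nearest(self.config.patch)
        return self.head_out(self.head_conv(d).relu()).sigmoid()


def _resize_to(img: np.ndarray, side: int, order: int = 1) -> np.ndarray:
    if img.shape == (side, side):
        return img.astype(float)
    return resize(img.astype(float), (side, side), order=order,
                  anti_aliasing=order > 0, preserve_range=True)


def segment(image: np.ndarray, model: SegModel,
            threshold: float | None = None) -> np.ndarray:
    """Binary lesion mask for one image, same shape as the input."""
    threshold = model.config.threshold if threshold is None else threshold
    probs = segment_probs(image[None], model)[0]
    return (probs >= threshold).astype(np.uint8)


def segment_probs(images: np.ndarray, model: SegModel) -> np.ndarray:
    """Lesion-probability maps at the original resolution (batched)."""
    side = model.config.input_side
    orig_shape = images.shape[1:]
    x = np.stack([_resize_to(im, side) for im in images])[:, None]
    model.eval()
    probs = model.forward(Tensor(x)).data[:, 0]
    if orig_shape != (side, side):
        probs = np.stack([
            resize(p, orig_shape, order=1, preserve_range=True) for p in probs])
    return probs


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Masked (segmented) image S = image ⊙ mask."""
    return np.asarray(image, dtype=float) * (np.asarray(mask) > 0)


def train_segmenter(images: list[np.ndarray], masks: list[np.ndarray],
                    config: SegConfig = SegConfig(),
                    train_config: SegTrainConfig = SegTrainConfig(),
                    seed: int = 0) -> tuple[SegModel, list[float]]:
    """Train with binary cross-entropy + (1 − soft Dice), Adam.

    Returns the model and the per-epoch mean loss history.
    """
    if len(images) == 0:
        raise ValueError("empty training set")
    side = config.input_side
    x = np.stack([_resize_to(im, side) for im in images])[:, None]
    m = np.stack([_resize_to(mk.astype(float), side, order=0) for mk in masks]
                 )[:, None]
    model = SegModel(config, seed=seed)
    model.train()
    opt = Adam(model.parameters(), lr=train_config.lr)
    rng = np.random.default_rng(seed + 1)
    n = len(x)
    history = []
    eps = 1e-7
    for _ in range(train_config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            xb, mb = Tensor(x[idx]), Tensor(m[idx])
            p = model.forward(xb)
            bce = -(mb * (p + eps).log()
                    + (1.0 - mb) * (1.0 - p + eps).log()).mean()
            inter = (p * mb).sum()
            soft_dice = (2.0 * inter + 1.0) / (p.sum() + mb.sum() + 1.0)
            loss = bce + (1.0 - soft_dice)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history.append(float(np.mean(epoch_losses)))
    perm = rng.permutation(n)
    batches = [x[perm[i:i + train_config.batch_size]]
               for i in range(0, n, train_config.batch_size)]
    refresh_bn_stats(model, lambda b: model.forward(Tensor(b)), batches)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: SegModel, path: str | Path):
    state = model.state_dict()
    cfg = json.dumps(model.config.__dict__ | {"dims": list(model.config.dims)})
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **state)


def load_model(path: str | Path) -> SegModel:
    data = np.load(path)
    cfg = json.loads(bytes(data["__config__"]).decode())
    cfg["dims"] = tuple(cfg["dims"])
    model = SegModel(SegConfig(**cfg))
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    model.eval()
    return model
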