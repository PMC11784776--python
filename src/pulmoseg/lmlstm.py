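"""Hybrid L-MLSTM classifier.

Two branches, trained independently and fused by probability
averaging:

* **LinkNet head** — four conv-BN-ReLU encoder blocks (filters 32, 64,
  128, 256, 3×3 kernels, 2×2 max-pooling), global average pooling and
  a dense softmax; it consumes the masked segmented image.
* **MLSTM** — an LSTM cell whose gate and candidate nonlinearities are
  the ScReLU activation instead of sigmoid/tanh; it consumes the
  concatenated feature vector F, zero-padded and chunked into T
  timesteps.

ScReLU is piecewise: identity for x ≥ 0; sigmoid(x) + sinh(βx) +
comb-term(βx) for −1 ≤ x < 0; and a leaky-linear αx (α = 0.01) below
−1. The comb term defaults to arcsinh(βx), which keeps the middle
branch bounded; a literal 1/sinh(βx) mode is retained (with |sinh|
floored at 1e−6), and is discontinuous as x → 0⁻.

Because ScReLU is unbounded above, MLSTM "gates" are not confined to
[0, 1] and the cell state can grow; this literal behaviour is kept
(a clamp is available via ``ScReLUParams``-aware training configs
choosing small initialisations instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .nn import (
    Adam, BatchNorm2d, Conv2d, Linear, Module, Tensor, clip_grad_norm,
    concat, cross_entropy, refresh_bn_stats,
)

__all__ = [
    "ScReLUParams", "screlu", "screlu_t",
    "MLSTMWeights", "mlstm_step", "MLSTMClassifier", "train_mlstm",
    "LinkNetHeadConfig", "LinkNetHead", "train_linknet", "linknet_classify",
    "fuse_predictions", "LMLSTM", "train_classifier", "TrainConfig",
]


# ---------------------------------------------------------------------------
# ScReLU activation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScReLUParams:
    alpha: float = 0.01          # leaky slope below -1
    beta: float = 1.0            # comb-H-sine scale
    comb_mode: str = "arcsinh"   # arcsinh | reciprocal

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.comb_mode not in ("arcsinh", "reciprocal"):
            raise ValueError(f"unknown comb_mode: {self.comb_mode}")


def screlu(x, params: ScReLUParams = ScReLUParams()):
    """Elementwise ScReLU on scalars or arrays (numpy path)."""
    arr = np.asarray(x, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    out = np.empty_like(arr)
    pos = arr >= 0
    neg = arr < -1
    mid = ~pos & ~neg
    out[pos] = arr[pos]
    out[neg] = params.alpha * arr[neg]
    xm = arr[mid]
    bx = params.beta * xm
    if params.comb_mode == "arcsinh":
        comb = np.arcsinh(bx)
    else:
        s = np.sinh(bx)
        s = np.where(np.abs(s) < 1e-6, np.where(s > 0, 1e-6, -1e-6), s)
        comb = 1.0 / s
    out[mid] = 1.0 / (1.0 + np.exp(-xm)) + np.sinh(bx) + comb
    return float(out[0]) if scalar else out.reshape(np.asarray(x).shape)


def screlu_t(x: Tensor, params: ScReLUParams = ScReLUParams()) -> Tensor:
    """ScReLU on autodiff tensors (used inside the MLSTM cell)."""
    d = x.data
    pos = (d >= 0).astype(float)
    neg = (d < -1).astype(float)
    mid = 1.0 - pos - neg
    mpos, mmid, mneg = Tensor(pos), Tensor(mid), Tensor(neg)
    xm = x * mmid                      # zero outside the middle region
    b = params.beta
    sig = xm.sigmoid()
    e1 = (xm * b).exp()
    e2 = (xm * (-b)).exp()
    sinh = (e1 - e2) * 0.5
    if params.comb_mode == "arcsinh":
        bx = xm * b
        comb = (bx + (bx * bx + 1.0).sqrt()).log()
    else:
        ok = (np.abs(sinh.data) >= 1e-6).astype(float)
        fallback = np.where(ok > 0, 0.0, -1e-6)  # middle region is negative
        comb = Tensor(np.ones_like(d)) / (sinh * Tensor(ok) + Tensor(fallback))
    mid_val = (sig + sinh + comb) * mmid
    return x * mpos + mid_val + x * mneg * params.alpha


# ---------------------------------------------------------------------------
# MLSTM cell
# ---------------------------------------------------------------------------

@dataclass
class MLSTMWeights:
    """Gate weights over the concatenated [input, previous hidden]."""

    w_i: np.ndarray
    w_f: np.ndarray
    w_o: np.ndarray
    w_c: np.ndarray
    bi_i: np.ndarray
    bi_f: np.ndarray
    bi_o: np.ndarray
    bi_c: np.ndarray

    @property
    def hidden(self) -> int:
        return self.w_i.shape[1]

    @staticmethod
    def zeros(input_len: int, hidden: int) -> "MLSTMWeights":
        z = np.zeros((input_len + hidden, hidden))
        b = np.zeros(hidden)
        return MLSTMWeights(z.copy(), z.copy(), z.copy(), z.copy(),
                            b.copy(), b.copy(), b.copy(), b.copy())


def mlstm_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
               w: MLSTMWeights, act: ScReLUParams = ScReLUParams()):
    """One MLSTM update: gates and candidate through ScReLU,
    c = f⊙c_prev + i⊙c', h = o⊙ScReLU(c). Gates are not clamped.
    """
    x_t, h_prev, c_prev = (np.asarray(a, dtype=float)
                           for a in (x_t, h_prev, c_prev))
    z = np.concatenate([x_t, h_prev])
    if z.shape[0] != w.w_i.shape[0]:
        raise ValueError("input/hidden dimensions inconsistent with weights")
    i = screlu(z @ w.w_i + w.bi_i, act)
    f = screlu(z @ w.w_f + w.bi_f, act)
    o = screlu(z @ w.w_o + w.bi_o, act)
    cand = screlu(z @ w.w_c + w.bi_c, act)
    c = f * c_prev + i * cand
    h = o * screlu(c, act)
    return h, c


class MLSTMClassifier(Module):
    """MLSTM over chunked feature vectors, final hidden → dense softmax."""

    def __init__(self, input_len: int, n_classes: int, hidden: int = 128,
                 seq_len: int = 16, act: ScReLUParams = ScReLUParams(),
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.input_len = input_len
        self.n_classes = n_classes
        self.hidden = hidden
        self.seq_len = seq_len
        self.act = act
        self.chunk = int(np.ceil(input_len / seq_len))
        zdim = self.chunk + hidden
        self.wi = Linear(zdim, hidden, rng)
        self.wf = Linear(zdim, hidden, rng)
        self.wo = Linear(zdim, hidden, rng)
        self.wc = Linear(zdim, hidden, rng)
        # small gate weights keep the unbounded ScReLU gates stable early on
        for lin in (self.wi, self.wf, self.wo, self.wc):
            lin.w.data *= 0.3
        self.head = Linear(hidden, n_classes, rng)
        self.mu = np.zeros(input_len)
        self.sd = np.ones(input_len)

    def set_scaler(self, features: np.ndarray):
        self.mu = features.mean(axis=0)
        self.sd = np.where(features.std(axis=0) < 1e-9, 1.0,
                           features.std(axis=0))

    def forward(self, features: np.ndarray) -> Tensor:
        x = (np.asarray(features, dtype=float) - self.mu) / self.sd
        n = x.shape[0]
        padded = np.zeros((n, self.chunk * self.seq_len))
        padded[:, : self.input_len] = x
        seq = padded.reshape(n, self.seq_len, self.chunk)
        h = Tensor(np.zeros((n, self.hidden)))
        c = Tensor(np.zeros((n, self.hidden)))
        for t in range(self.seq_len):
            z = concat([Tensor(seq[:, t]), h], axis=1)
            i = screlu_t(self.wi(z), self.act)
            f = screlu_t(self.wf(z), self.act)
            o = screlu_t(self.wo(z), self.act)
            cand = screlu_t(self.wc(z), self.act)
            c = f * c + i * cand
            h = o * screlu_t(c, self.act)
        return self.head(h)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        logits = self.forward(np.atleast_2d(features)).data
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


def mlstm_classify(features: np.ndarray, model: MLSTMClassifier) -> np.ndarray:
    """Per-class probabilities for one feature vector."""
    return model.predict_proba(np.atleast_2d(features))[0]


def train_mlstm(features: np.ndarray, labels: np.ndarray, n_classes: int,
                epochs: int = 25, batch_size: int = 50, lr: float = 2e-3,
                hidden: int = 128, seq_len: int = 16,
                act: ScReLUParams = ScReLUParams(), clip_norm: float = 1.0,
                seed: int = 0) -> tuple[MLSTMClassifier, list[float]]:
    """Adam training with global-norm gradient clipping (the unbounded
    ScReLU gates make the recurrence prone to exploding gradients)."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    model = MLSTMClassifier(features.shape[1], n_classes, hidden=hidden,
                            seq_len=seq_len, act=act, seed=seed)
    model.set_scaler(features)
    params = list(model.parameters())
    opt = Adam(params, lr=lr)
    rng = np.random.default_rng(seed + 1)
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(features))
        losses = []
        for start in range(0, len(features), batch_size):
            idx = order[start:start + batch_size]
            logits = model.forward(features[idx])
            loss = cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            if clip_norm is not None:
                clip_grad_norm(params, clip_norm)
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    return model, history


# ---------------------------------------------------------------------------
# LinkNet classification head
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkNetHeadConfig:
    filters: tuple[int, ...] = (32, 64, 128, 256)
    kernel: int = 3
    input_side: int = 64
    n_classes: int = 3
    epochs: int = 25
    batch_size: int = 64
    lr: float = 2e-3

    def __post_init__(self):
        for a, b in zip(self.filters, self.filters[1:]):
            if b != 2 * a:
                raise ValueError("filters must double per encoder block")
        if len(self.filters) != 4:
            raise ValueError("the head uses four encoder blocks")


class LinkNetHead(Module):
    """Encoder blocks (conv-BN-ReLU ×2, max-pool) → GAP → dense softmax."""

    def __init__(self, config: LinkNetHeadConfig = LinkNetHeadConfig(),
                 seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.convs = []
        self.bns = []
        cin = 1
        for f in config.filters:
            self.convs.append(Conv2d(cin, f, config.kernel, rng))
            self.bns.append(BatchNorm2d(f))
            self.convs.append(Conv2d(f, f, config.kernel, rng))
            self.bns.append(BatchNorm2d(f))
            cin = f
        self.dense = Linear(config.filters[-1], config.n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        for blk in range(4):
            x = self.bns[2 * blk](self.convs[2 * blk](x)).relu()
            x = self.bns[2 * blk + 1](self.convs[2 * blk + 1](x)).relu()
            x = x.max_pool2d(2)
        pooled = x.mean(axis=(2, 3))
        return self.dense(pooled)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        x = _prep_images(images, self.config.input_side)
        logits = self.forward(Tensor(x)).data
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


def _prep_images(images: np.ndarray, side: int) -> np.ndarray:
    out = []
    for im in np.atleast_3d(np.asarray(images, dtype=float)).reshape(
            (-1,) + np.asarray(images).shape[-2:]):
        if im.shape != (side, side):
            im = resize(im, (side, side), order=1, anti_aliasing=True,
                        preserve_range=True)
        out.append(im)
    return np.stack(out)[:, None]


def linknet_classify(seg_image: np.ndarray, model: LinkNetHead) -> np.ndarray:
    """Per-class probabilities for one masked segmented image."""
    model.eval()
    return model.predict_proba(seg_image[None])[0]


def train_linknet(images: list[np.ndarray], labels: np.ndarray,
                  config: LinkNetHeadConfig = LinkNetHeadConfig(),
                  seed: int = 0) -> tuple[LinkNetHead, list[float]]:
    labels = np.asarray(labels)
    model = LinkNetHead(config, seed=seed)
    model.train()
    x = _prep_images(np.stack(images), config.input_side)
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(seed + 1)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), config.batch_size):
            idx = order[start:start + config.batch_size]
            loss = cross_entropy(model.forward(Tensor(x[idx])), labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    # class-mixed batches keep per-batch stats close to the pooled ones
    perm = np.random.default_rng(seed + 2).permutation(len(x))
    batches = [x[perm[i:i + config.batch_size]]
               for i in range(0, len(x), config.batch_size)]
    refresh_bn_stats(model, lambda b: model.forward(Tensor(b)), batches)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# fusion and the combined model
# ---------------------------------------------------------------------------

def fuse_predictions(link_p: np.ndarray, mlstm_p: np.ndarray) -> np.ndarray:
    """Elementwise mean of the two branch probability vectors."""
    link_p = np.asarray(link_p, dtype=float)
    mlstm_p = np.asarray(mlstm_p, dtype=float)
    if link_p.shape != mlstm_p.shape:
        raise ValueError("class counts differ between branches")
    return 0.5 * (link_p + mlstm_p)


@dataclass(frozen=True)
class TrainConfig:
    mlstm_epochs: int = 25
    mlstm_batch: int = 50
    mlstm_hidden: int = 128
    mlstm_lr: float = 2e-3
    seq_len: int = 16
    link_epochs: int = 25
    link_batch: int = 64
    link_side: int = 64
    link_lr: float = 2e-3
    act: ScReLUParams = field(default_factory=ScReLUParams)


@dataclass
class LMLSTM:
    """The trained hybrid classifier: both branches plus fusion."""

    mlstm: MLSTMClassifier
    linknet: LinkNetHead
    n_classes: int

    def predict_proba(self, features: np.ndarray,
                      masked_images: np.ndarray) -> np.ndarray:
        p_m = self.mlstm.predict_proba(features)
        p_l = self.linknet.predict_proba(masked_images)
        return fuse_predictions(p_l, p_m)

    def predict(self, features: np.ndarray,
                masked_images: np.ndarray) -> np.ndarray:
        return self.predict_proba(features, masked_images).argmax(axis=1)


def train_classifier(features: np.ndarray, masked_images: list[np.ndarray],
                     labels: np.ndarray, config: TrainConfig = TrainConfig(),
                     seed: int = 0) -> tuple[LMLSTM, dict]:
    """Train both branches independently (each fully seeded)."""
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("empty training set")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training set must contain at least 2 classes")
    n_classes = int(classes.max()) + 1
    mlstm, h_m = train_mlstm(
        features, labels, n_classes, epochs=config.mlstm_epochs,
        batch_size=config.mlstm_batch, lr=config.mlstm_lr,
        hidden=config.mlstm_hidden, seq_len=config.seq_len, act=config.act,
        seed=seed)
    link_cfg = LinkNetHeadConfig(
        input_side=config.link_side, n_classes=n_classes,
        epochs=config.link_epochs, batch_size=config.link_batch,
        lr=config.link_lr)
    linknet, h_l = train_linknet(masked_images, labels, link_cfg,
                                 seed=seed + 1)
    model = LMLSTM(mlstm=mlstm, linknet=linknet, n_classes=n_classes)
    return model, {"mlstm_loss": h_m, "linknet_loss": h_l}
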