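"""Four-family feature bank over segmented lesion images.

The concatenated descriptor is F = [Tex_F, Sha_F, Col_F, De_F]:

* **Tex_F** — 256-bin histograms of two per-pixel texture codes, plus
  a multi-texton block. The *modified LGIP* code thresholds the signs
  of eight directional Sobel responses (masks M0..M7, each a 45°
  ring-rotation of the horizontal Sobel kernel). The *improved LBP*
  code compares a gradient-and-context transform of each ring pixel,
  gᵢ = (pᵢ² − adj(pᵢ)/max(|pᵢ|, ε)) · ((L+R)/max(T, ε)), against the
  raw centre intensity (bit = 1 when gᵢ − g_c ≥ 0). Multi-texton
  counts six 2×2 binary micro-patterns on a stride-2 grid after Otsu
  binarisation.
* **Sha_F** — area, perimeter, circularity, bounding-box aspect
  ratio, eccentricity and solidity of the largest connected mask
  component. Perimeter is the convex-hull boundary length of the
  pixel support (exactly 4n for an n×n axis-aligned square and close
  to 2πr for rasterised disks; it underestimates concave supports).
* **Col_F** — a normalised intensity histogram over mask pixels
  (per-channel for RGB input).
* **De_F** — penultimate activations of two small from-scratch deep
  encoders (residual and VGG-style), trained on the phantom task or
  left at seeded-random weights per config.

Empty masks map every mask-restricted block to zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .nn import (Adam, BatchNorm2d, Conv2d, Linear, Module, Tensor,
                 cross_entropy, refresh_bn_stats)

__all__ = [
    "RING_OFFSETS", "SobelMaskSet", "TextonDictionary", "FeatureVector",
    "improved_lbp_code", "improved_lbp_map", "lgip_code", "lgip_map",
    "texture_features", "multi_texton_features", "shape_features",
    "color_features", "deep_features", "concat_features",
    "SmallResNet", "SmallVGG", "DeepEncoders", "train_deep_encoders",
    "random_deep_encoders", "extract_features",
]

EPS = 1e-6

# ring pixels in fixed clockwise order starting at top-left
RING_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, 1),
                (1, 1), (1, 0), (1, -1), (0, -1))

# outer-ring positions of a 3×3 mask, clockwise from top-left
_MASK_RING = ((0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0))


# ---------------------------------------------------------------------------
# texture codes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SobelMaskSet:
    """Eight 3×3 gradient masks; M0 is the horizontal Sobel and each
    subsequent mask rotates the outer ring by 45°."""

    masks: tuple = field(default=None)

    def __post_init__(self):
        if self.masks is None:
            m0 = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
            ring0 = np.array([m0[pos] for pos in _MASK_RING])
            masks = []
            for i in range(8):
                m = np.zeros((3, 3))
                for j, pos in enumerate(_MASK_RING):
                    m[pos] = ring0[(j - i) % 8]
                masks.append(m)
            object.__setattr__(self, "masks", tuple(masks))
        for m in self.masks:
            if abs(m.sum()) > 1e-12:
                raise ValueError("each Sobel mask must sum to zero")
        if not np.allclose(self.masks[4], -self.masks[0]):
            raise ValueError("M4 must equal -M0")


def lgip_code(patch: np.ndarray, masks: SobelMaskSet | None = None) -> int:
    """8-bit code from the signs of the eight Sobel responses (bit=1 iff > 0)."""
    masks = masks or SobelMaskSet()
    patch = np.asarray(patch, dtype=float)
    tol = 1e-9 * max(1.0, float(np.abs(patch).max()))  # absorbs float residue
    code = 0
    for i, m in enumerate(masks.masks):
        if float((m * patch).sum()) > tol:
            code |= 1 << i
    return code


def lgip_map(image: np.ndarray, masks: SobelMaskSet | None = None) -> np.ndarray:
    """Per-pixel LGIP codes with reflect borders (vectorised)."""
    masks = masks or SobelMaskSet()
    image = np.asarray(image, dtype=float)
    tol = 1e-9 * max(1.0, float(np.abs(image).max()))
    codes = np.zeros(image.shape, dtype=np.int64)
    for i, m in enumerate(masks.masks):
        r = ndimage.correlate(image, m, mode="reflect")
        codes |= (r > tol).astype(np.int64) << i
    return codes


def improved_lbp_code(context: np.ndarray) -> int:
    """Improved-LBP code of the centre pixel of a 5×5 context patch.

    The 5×5 window supplies the left/right/top grid neighbours of each
    ring pixel; the centre is ``context[2, 2]``.
    """
    context = np.asarray(context, dtype=float)
    if context.shape != (5, 5):
        raise ValueError("improved_lbp_code expects a 5x5 context patch")
    gc = context[2, 2]
    ring = [context[2 + dy, 2 + dx] for dy, dx in RING_OFFSETS]
    code = 0
    for i, (dy, dx) in enumerate(RING_OFFSETS):
        p = ring[i]
        adj = ring[(i - 1) % 8] + ring[(i + 1) % 8]
        left = context[2 + dy, 2 + dx - 1]
        right = context[2 + dy, 2 + dx + 1]
        top = context[2 + dy - 1, 2 + dx]
        g = (p * p - adj / max(abs(p), EPS)) * ((left + right) / max(top, EPS))
        if g - gc >= 0:
            code |= 1 << i
    return code


def improved_lbp_map(image: np.ndarray) -> np.ndarray:
    """Per-pixel improved-LBP codes, reflect padding (vectorised)."""
    image = np.asarray(image, dtype=float)
    pad = np.pad(image, 2, mode="symmetric")
    h, w = image.shape

    def shifted(dy, dx):
        return pad[2 + dy:2 + dy + h, 2 + dx:2 + dx + w]

    ring = [shifted(dy, dx) for dy, dx in RING_OFFSETS]
    codes = np.zeros((h, w), dtype=np.int64)
    gc = image
    for i, (dy, dx) in enumerate(RING_OFFSETS):
        p = ring[i]
        adj = ring[(i - 1) % 8] + ring[(i + 1) % 8]
        left = shifted(dy, dx - 1)
        right = shifted(dy, dx + 1)
        top = shifted(dy - 1, dx)
        g = ((p * p - adj / np.maximum(np.abs(p), EPS))
             * ((left + right) / np.maximum(top, EPS)))
        codes |= (g - gc >= 0).astype(np.int64) << i
    return codes


# ---------------------------------------------------------------------------
# multi-texton
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TextonDictionary:
    """The six classic 2×2 binary micro-patterns, detected on a
    stride-2 grid; blocks matching none fall into a no-texton bin."""

    stride: int = 2

    names = ("all_ones", "all_zeros", "horizontal", "vertical",
             "diagonal", "anti_diagonal")

    @staticmethod
    def classify_block(b: np.ndarray) -> int:
        """Template index 0..5, or 6 for no texton."""
        a, c, d, e = bool(b[0, 0]), bool(b[0, 1]), bool(b[1, 0]), bool(b[1, 1])
        if a and c and d and e:
            return 0
        if not (a or c or d or e):
            return 1
        if a == c and d == e and a != d:
            return 2     # horizontal pair of rows
        if a == d and c == e and a != c:
            return 3     # vertical pair of columns
        if a and e and not (c or d):
            return 4     # main diagonal
        if c and d and not (a or e):
            return 5     # anti-diagonal
        return 6


def multi_texton_features(image: np.ndarray,
                          textons: TextonDictionary | None = None) -> np.ndarray:
    """Distribution over the six textons + a no-texton bin."""
    textons = textons or TextonDictionary()
    image = np.asarray(image, dtype=float)
    if image.max() > image.min():
        binary = image > threshold_otsu(image)
    else:
        binary = np.zeros_like(image, dtype=bool)
    s = textons.stride
    h, w = binary.shape
    h2, w2 = (h // s) * s, (w // s) * s
    blocks = binary[:h2, :w2].reshape(h2 // s, s, w2 // s, s).transpose(0, 2, 1, 3)
    a = blocks[:, :, 0, 0].astype(int)
    c = blocks[:, :, 0, 1].astype(int)
    d = blocks[:, :, 1, 0].astype(int)
    e = blocks[:, :, 1, 1].astype(int)
    total = a + c + d + e
    counts = np.zeros(7)
    counts[0] = np.sum(total == 4)
    counts[1] = np.sum(total == 0)
    counts[2] = np.sum((a == c) & (d == e) & (a != d))
    counts[3] = np.sum((a == d) & (c == e) & (a != c))
    counts[4] = np.sum((a == 1) & (e == 1) & (c == 0) & (d == 0))
    counts[5] = np.sum((c == 1) & (d == 1) & (a == 0) & (e == 0))
    counts[6] = blocks.shape[0] * blocks.shape[1] - counts.sum()
    n = counts.sum()
    return counts / n if n > 0 else counts


# ---------------------------------------------------------------------------
# histogram families
# ---------------------------------------------------------------------------

def _code_histogram(codes: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = codes[mask]
    hist = np.bincount(vals, minlength=256).astype(float)
    return hist / hist.sum() if hist.sum() > 0 else hist


def texture_features(seg_image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Tex_F = LGIP histogram ‖ improved-LBP histogram ‖ texton block."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        return np.zeros(256 + 256 + 7)
    lgip_h = _code_histogram(lgip_map(seg_image), mask)
    ilbp_h = _code_histogram(improved_lbp_map(seg_image), mask)
    # textons over the mask's bounding box, so background borders
    # outside the lesion never change the block
    ys, xs = np.nonzero(mask)
    crop = (np.asarray(seg_image, dtype=float) * mask)[
        ys.min():ys.max() + 1, xs.min():xs.max() + 1]
    texton = multi_texton_features(crop)
    return np.concatenate([lgip_h, ilbp_h, texton])


def _hull_perimeter(mask: np.ndarray) -> float:
    """Convex-hull boundary length of the pixel-box support."""
    ys, xs = np.nonzero(mask)
    pts = np.concatenate([
        np.stack([ys + dy, xs + dx], axis=1)
        for dy in (-0.5, 0.5) for dx in (-0.5, 0.5)])
    if len(np.unique(pts, axis=0)) < 3:
        return 4.0 * len(ys)  # degenerate 1-2 pixel supports
    hull = ConvexHull(pts)
    v = pts[hull.vertices]
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def shape_features(mask: np.ndarray) -> np.ndarray:
    """[area, perimeter, circularity, aspect ratio, eccentricity, solidity]
    of the largest connected component; zeros for an empty mask."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        return np.zeros(6)
    labels = measure.label(mask, connectivity=2)
    largest = labels == np.argmax(np.bincount(labels.ravel())[1:]) + 1
    props = measure.regionprops(largest.astype(int))[0]
    area = float(largest.sum())
    perimeter = _hull_perimeter(largest)
    circularity = 4 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
    minr, minc, maxr, maxc = props.bbox
    hgt, wid = maxr - minr, maxc - minc
    aspect = max(hgt, wid) / min(hgt, wid)
    return np.array([area, perimeter, circularity, aspect,
                     float(props.eccentricity), float(props.solidity)])


def color_features(image: np.ndarray, mask: np.ndarray,
                   bins: int = 32) -> np.ndarray:
    """Normalised intensity histogram over mask pixels in [0, 1]."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask) > 0
    if image.ndim == 3:  # RGB: per-channel concatenation
        return np.concatenate([
            color_features(image[..., ch], mask, bins) for ch in range(image.shape[2])])
    if not mask.any():
        return np.zeros(bins)
    hist, _ = np.histogram(image[mask], bins=bins, range=(0.0, 1.0))
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# deep encoders
# ---------------------------------------------------------------------------

class _ResBlock(Module):
    def __init__(self, cin, cout, rng, stride=1):
        super().__init__()
        self.c1 = Conv2d(cin, cout, 3, rng, stride=stride)
        self.b1 = BatchNorm2d(cout)
        self.c2 = Conv2d(cout, cout, 3, rng)
        self.b2 = BatchNorm2d(cout)
        self.skip = (Conv2d(cin, cout, 1, rng, stride=stride, padding=0)
                     if (stride != 1 or cin != cout) else None)

    def __call__(self, x):
        y = self.b1(self.c1(x)).relu()
        y = self.b2(self.c2(y))
        s = x if self.skip is None else self.skip(x)
        return (y + s).relu()


class SmallResNet(Module):
    """Residual encoder (widths 16→64), GAP embedding + linear head."""

    def __init__(self, n_classes: int = 3, embed_dim: int = 64, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.stem = Conv2d(1, 16, 3, rng)
        self.bn = BatchNorm2d(16)
        self.blocks = [_ResBlock(16, 16, rng), _ResBlock(16, 32, rng, stride=2),
                       _ResBlock(32, 64, rng, stride=2), _ResBlock(64, embed_dim, rng)]
        self.head = Linear(embed_dim, n_classes, rng)
        self.embed_dim = embed_dim

    def embed(self, x: Tensor) -> Tensor:
        y = self.bn(self.stem(x)).relu()
        for b in self.blocks:
            y = b(y)
        return y.mean(axis=(2, 3))

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.embed(x))


class SmallVGG(Module):
    """Four conv stacks (VGG-style) with max-pooling; GAP embedding."""

    def __init__(self, n_classes: int = 3, embed_dim: int = 64, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        widths = (16, 32, 64, embed_dim)
        self.convs = []
        self.bns = []
        cin = 1
        for wdt in widths:
            self.convs.append(Conv2d(cin, wdt, 3, rng))
            self.bns.append(BatchNorm2d(wdt))
            cin = wdt
        self.head = Linear(embed_dim, n_classes, rng)
        self.embed_dim = embed_dim

    def embed(self, x: Tensor) -> Tensor:
        for conv, bn in zip(self.convs, self.bns):
            x = bn(conv(x)).relu().max_pool2d(2)
        return x.mean(axis=(2, 3))

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.embed(x))


@dataclass
class DeepEncoders:
    resnet: SmallResNet
    vgg: SmallVGG
    input_side: int = 32

    @property
    def output_dim(self) -> int:
        return self.resnet.embed_dim + self.vgg.embed_dim


def random_deep_encoders(n_classes: int = 3, seed: int = 0,
                         input_side: int = 32) -> DeepEncoders:
    """Seeded-random encoders (no training) for fast configurations."""
    enc = DeepEncoders(SmallResNet(n_classes, seed=seed),
                       SmallVGG(n_classes, seed=seed + 1), input_side)
    enc.resnet.eval()
    enc.vgg.eval()
    return enc


def train_deep_encoders(masked_images: list[np.ndarray], labels: np.ndarray,
                        n_classes: int, epochs: int = 5, batch_size: int = 32,
                        lr: float = 2e-3, input_side: int = 32,
                        seed: int = 0) -> DeepEncoders:
    """Train both encoders on the phantom classification task."""
    labels = np.asarray(labels)
    enc = DeepEncoders(SmallResNet(n_classes, seed=seed),
                       SmallVGG(n_classes, seed=seed + 1), input_side)
    x = np.stack([_resize(im, input_side) for im in masked_images])[:, None]
    for net, net_seed in ((enc.resnet, seed + 2), (enc.vgg, seed + 3)):
        net.train()
        opt = Adam(net.parameters(), lr=lr)
        rng = np.random.default_rng(net_seed)
        for _ in range(epochs):
            order = rng.permutation(len(x))
            for start in range(0, len(x), batch_size):
                idx = order[start:start + batch_size]
                loss = cross_entropy(net.forward(Tensor(x[idx])), labels[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
        perm = np.random.default_rng(net_seed + 1).permutation(len(x))
        batches = [x[perm[i:i + batch_size]]
                   for i in range(0, len(x), batch_size)]
        refresh_bn_stats(net, lambda b, _n=net: _n.forward(Tensor(b)), batches)
        net.eval()
    return enc


def _resize(im: np.ndarray, side: int) -> np.ndarray:
    im = np.asarray(im, dtype=float)
    if im.shape == (side, side):
        return im
    return resize(im, (side, side), order=1, anti_aliasing=True,
                  preserve_range=True)


def deep_features(seg_image: np.ndarray, encoders: DeepEncoders) -> np.ndarray:
    """De_F: concatenated penultimate activations of the two encoders."""
    return deep_features_batch(seg_image[None], encoders)[0]


def deep_features_batch(seg_images: np.ndarray,
                        encoders: DeepEncoders) -> np.ndarray:
    x = np.stack([_resize(im, encoders.input_side) for im in seg_images])[:, None]
    encoders.resnet.eval()
    encoders.vgg.eval()
    r = encoders.resnet.embed(Tensor(x)).data
    v = encoders.vgg.embed(Tensor(x)).data
    return np.concatenate([r, v], axis=1)


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """F = [Tex_F, Sha_F, Col_F, De_F] with recorded block offsets."""

    tex: np.ndarray
    sha: np.ndarray
    col: np.ndarray
    deep: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.tex, self.sha, self.col, self.deep])

    @property
    def offsets(self) -> dict:
        lengths = {"tex": len(self.tex), "sha": len(self.sha),
                   "col": len(self.col), "deep": len(self.deep)}
        out, pos = {}, 0
        for name, n in lengths.items():
            out[name] = (pos, pos + n)
            pos += n
        return out

    def block(self, name: str) -> np.ndarray:
        a, b = self.offsets[name]
        return self.vector[a:b]


def concat_features(tex: np.ndarray, sha: np.ndarray, col: np.ndarray,
                    deep: np.ndarray,
                    expected_lengths: tuple[int, int, int, int] | None = None
                    ) -> FeatureVector:
    blocks = (np.asarray(tex, float), np.asarray(sha, float),
              np.asarray(col, float), np.asarray(deep, float))
    if expected_lengths is not None:
        actual = tuple(len(b) for b in blocks)
        if actual != tuple(expected_lengths):
            raise ValueError(
                f"block lengths {actual} do not match declared {expected_lengths}")
    return FeatureVector(*blocks)


def extract_features(image: np.ndarray, mask: np.ndarray,
                     encoders: DeepEncoders, bins: int = 32) -> FeatureVector:
    """Full F for one (image, mask) pair; texture/colour restricted to
    the mask, deep features from the masked image."""
    from .itcnn import apply_mask

    seg = apply_mask(image, mask)
    return concat_features(
        texture_features(seg, mask),
        shape_features(mask),
        color_features(image, mask, bins=bins),
        deep_features(seg, encoders),
    )
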