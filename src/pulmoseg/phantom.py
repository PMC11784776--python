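"""Synthetic lung-phantom generation.

Phantoms stand in for chest-CT datasets so the whole pipeline —
filtering, segmentation, feature extraction, classification — can be
exercised and tested without external downloads. Each phantom is a
grayscale image with a bright thorax, two dark elliptical lung fields,
and (for diseased classes) a small number of textured lesion blobs
whose intensity statistics differ by class:

* class 0 ("normal"): no lesions, all-zero mask;
* class 1: smooth bright blobs (high base intensity, low speckle);
* class 2: darker, strongly speckled blobs with a stripe pattern.

Everything is a pure function of ``(config, seed)``; per-sample seeds
are derived from the master seed with SHA-256 so that extending a
dataset never changes existing samples.

Intensities are floats in [0, 1] internally; conversion to uint8
happens only at file I/O.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "TextureParams", "PhantomConfig", "PhantomSample", "NoiseSpec",
    "generate_phantom", "generate_dataset", "add_noise",
    "write_dataset", "load_dataset",
]


@dataclass(frozen=True)
class TextureParams:
    """Per-class lesion texture specification."""

    base_intensity: float = 0.0   # mean lesion intensity
    speckle_std: float = 0.0      # pixelwise gaussian speckle sd
    stripe_freq: float = 0.0      # stripe frequency, cycles/pixel
    stripe_amp: float = 0.0       # stripe amplitude


def _default_textures():
    return (
        TextureParams(),  # normal class: unused (no lesions)
        TextureParams(base_intensity=0.80, speckle_std=0.03),
        TextureParams(base_intensity=0.55, speckle_std=0.14,
                      stripe_freq=0.35, stripe_amp=0.12),
    )


@dataclass(frozen=True)
class PhantomConfig:
    image_size: tuple[int, int] = (128, 128)
    n_classes: int = 3
    lesion_count_range: tuple[tuple[int, int], ...] = ((0, 0), (1, 3), (1, 3))
    lesion_radius_range: tuple[float, float] = (7.0, 16.0)
    class_texture_params: tuple[TextureParams, ...] = field(
        default_factory=_default_textures)
    background_level: float = 0.70
    lung_level: float = 0.18
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.class_texture_params) != self.n_classes:
            raise ValueError("class_texture_params must have n_classes entries")
        if len(self.lesion_count_range) != self.n_classes:
            raise ValueError("lesion_count_range must have n_classes entries")


@dataclass
class PhantomSample:
    image: np.ndarray       # float64 in [0,1], H×W
    mask: np.ndarray        # bool, H×W
    label: int
    meta: dict


@dataclass(frozen=True)
class NoiseSpec:
    kind: str               # salt_pepper | gaussian | white_percent
    level: float
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("salt_pepper", "gaussian", "white_percent"):
            raise ValueError(f"unknown noise kind: {self.kind}")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("noise level must lie in [0, 1]")


def _sample_seed(master_seed: int, index: int) -> int:
    digest = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _lung_fields(shape) -> np.ndarray:
    """Boolean union of the two elliptical lung fields."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy = 0.52 * h
    ry, rx = 0.34 * h, 0.18 * w
    left = ((yy - cy) / ry) ** 2 + ((xx - 0.30 * w) / rx) ** 2 <= 1.0
    right = ((yy - cy) / ry) ** 2 + ((xx - 0.70 * w) / rx) ** 2 <= 1.0
    return left | right


def _thorax(shape) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return (((yy - 0.5 * h) / (0.46 * h)) ** 2
            + ((xx - 0.5 * w) / (0.44 * w)) ** 2) <= 1.0


def generate_phantom(config: PhantomConfig, label: int, seed: int) -> PhantomSample:
    """Generate one phantom image with its lesion mask.

    Deterministic in ``(config, label, seed)``.
    """
    if not 0 <= label < config.n_classes:
        raise ValueError(f"label {label} out of range for {config.n_classes} classes")
    rng = np.random.default_rng(seed)
    h, w = config.image_size
    lungs = _lung_fields((h, w))
    thorax = _thorax((h, w))

    image = np.full((h, w), 0.05)
    image[thorax] = config.background_level
    image[lungs] = config.lung_level
    # mild anatomical intensity gradient + scanner-like background noise
    yy = np.linspace(-1, 1, h)[:, None]
    image = image + 0.02 * yy
    image = image + rng.normal(0.0, 0.015, size=(h, w))

    mask = np.zeros((h, w), dtype=bool)
    lesions = []
    lo, hi = config.lesion_count_range[label]
    n_lesions = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    tex = config.class_texture_params[label]
    ys, xs = np.nonzero(lungs)
    yy2, xx2 = np.mgrid[0:h, 0:w]
    for _ in range(n_lesions):
        idx = rng.integers(len(ys))
        cy, cx = ys[idx], xs[idx]
        radius = rng.uniform(*config.lesion_radius_range)
        ratio = rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy2 - cy, xx2 - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        support = (u / radius) ** 2 + (v / (radius * ratio)) ** 2 <= 1.0
        support &= lungs  # lesions never leave the lung field
        if not support.any():
            continue
        value = np.full((h, w), tex.base_intensity)
        if tex.speckle_std > 0:
            value += rng.normal(0.0, tex.speckle_std, size=(h, w))
        if tex.stripe_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            ang = rng.uniform(0, np.pi)
            value += tex.stripe_amp * np.sin(
                2 * np.pi * tex.stripe_freq * (yy2 * np.cos(ang) + xx2 * np.sin(ang))
                + phase)
        weight = ndimage.gaussian_filter(support.astype(float), 1.2)
        weight = np.clip(weight, 0.0, 1.0)
        image = image * (1 - weight) + value * weight
        mask |= support
        lesions.append({"center": (int(cy), int(cx)), "radius": float(radius),
                        "ratio": float(ratio), "theta": float(theta)})

    image = np.clip(image, 0.0, 1.0)
    meta = {"seed": int(seed), "label": int(label), "lesions": lesions,
            "noise": None}
    return PhantomSample(image=image, mask=mask, label=int(label), meta=meta)


def generate_dataset(config: PhantomConfig, n_per_class: int,
                     seed: int | None = None) -> list[PhantomSample]:
    """Balanced phantom dataset; per-sample seeds derive from the master seed."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    master = config.seed if seed is None else seed
    samples = []
    index = 0
    for label in range(config.n_classes):
        for _ in range(n_per_class):
            s = generate_phantom(config, label, _sample_seed(master, index))
            s.meta["index"] = index
            samples.append(s)
            index += 1
    return samples


def add_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Corrupt an image in [0,1] per the noise specification.

    ``salt_pepper`` flips exactly ``round(level*N)`` pixels to 0/1 (half
    each); ``gaussian`` and ``white_percent`` add zero-mean noise with
    sd = level × dynamic range, then clip back into [0, 1].
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    if spec.level == 0.0:
        return image.copy()
    rng = np.random.default_rng(spec.seed)
    out = image.copy()
    if spec.kind == "salt_pepper":
        n = image.size
        n_sel = int(round(spec.level * n))
        flat_idx = rng.choice(n, size=n_sel, replace=False)
        n_salt = n_sel // 2
        out.flat[flat_idx[:n_salt]] = 1.0
        out.flat[flat_idx[n_salt:]] = 0.0
    else:  # gaussian / white_percent
        out = out + rng.normal(0.0, spec.level * 1.0, size=image.shape)
        out = np.clip(out, 0.0, 1.0)
    return out


def write_dataset(samples: list[PhantomSample], out_dir: str | Path) -> Path:
    """Write PNG images/masks and a `path,mask_path,label,seed` manifest."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        img_path = out_dir / "images" / f"phantom_{i:04d}.png"
        mask_path = out_dir / "masks" / f"phantom_{i:04d}_mask.png"
        iio.imwrite(img_path, np.round(s.image * 255).astype(np.uint8))
        iio.imwrite(mask_path, (s.mask.astype(np.uint8) * 255))
        rows.append({"path": str(img_path), "mask_path": str(mask_path),
                     "label": s.label, "seed": s.meta["seed"]})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def load_dataset(manifest_path: str | Path) -> list[PhantomSample]:
    """Read a dataset back from a manifest written by :func:`write_dataset`."""
    manifest = pd.read_csv(manifest_path)
    samples = []
    for _, row in manifest.iterrows():
        image = iio.imread(row["path"]).astype(float) / 255.0
        if image.ndim == 3:
            image = image.mean(axis=2)
        mask = iio.imread(row["mask_path"]) > 127
        samples.append(PhantomSample(
            image=image, mask=mask, label=int(row["label"]),
            meta={"seed": int(row["seed"]), "label": int(row["label"]),
                  "lesions": [], "noise": None}))
    return samples
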