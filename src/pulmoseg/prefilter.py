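"""Image preprocessing: median filtering plus mean/Gaussian baselines,
and the image-quality metrics (PSNR, SSIM) used to evaluate them.

The median filter slides a window over the image and replaces each
pixel with the median of its neighbourhood; with an even pixel count
the median is the average of the two middle values. It suppresses
impulse (salt-and-pepper) noise while preserving edges, which is why
it is preferred over linear smoothing for this pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["FilterSpec", "median_filter", "baseline_filter", "psnr", "ssim"]

_BORDER_TO_NUMPY = {"reflect": "symmetric", "edge": "edge", "constant": "constant"}
_BORDER_TO_SCIPY = {"reflect": "reflect", "edge": "nearest", "constant": "constant"}


@dataclass(frozen=True)
class FilterSpec:
    kind: str = "median"          # median | mean | gaussian
    window: int = 3
    sigma: float = 1.0            # gaussian only
    border: str = "reflect"       # reflect | edge | constant

    def __post_init__(self):
        if self.kind not in ("median", "mean", "gaussian"):
            raise ValueError(f"unknown filter kind: {self.kind}")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.border not in _BORDER_TO_NUMPY:
            raise ValueError(f"unknown border mode: {self.border}")
        if self.kind == "gaussian" and self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _check_window(image: np.ndarray, window: int):
    if window > image.shape[0] and window > image.shape[1]:
        raise ValueError("window larger than both image dimensions")


def _padded_windows(image: np.ndarray, window: int, border: str):
    """All window views centred per the (k-1)//2 left-offset convention."""
    left = (window - 1) // 2
    right = window // 2
    kwargs = {"constant_values": 0.0} if border == "constant" else {}
    padded = np.pad(image, ((left, right), (left, right)),
                    mode=_BORDER_TO_NUMPY[border], **kwargs)
    return np.lib.stride_tricks.sliding_window_view(padded, (window, window))


def median_filter(image: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Windowed median; even windows average the two middle values."""
    if spec.kind != "median":
        raise ValueError("median_filter requires spec.kind == 'median'")
    image = np.asarray(image, dtype=float)
    _check_window(image, spec.window)
    views = _padded_windows(image, spec.window, spec.border)
    return np.median(views, axis=(2, 3))


def baseline_filter(image: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Windowed arithmetic mean, or Gaussian convolution with spec.sigma."""
    image = np.asarray(image, dtype=float)
    if spec.kind == "mean":
        _check_window(image, spec.window)
        views = _padded_windows(image, spec.window, spec.border)
        return views.mean(axis=(2, 3))
    if spec.kind == "gaussian":
        cval = {"cval": 0.0} if spec.border == "constant" else {}
        return ndimage.gaussian_filter(image, spec.sigma,
                                       mode=_BORDER_TO_SCIPY[spec.border], **cval)
    raise ValueError("baseline_filter requires kind 'mean' or 'gaussian'")


def psnr(reference: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10·log10(MAX²/MSE), in decibels.

    Returns +inf when the images are identical (MSE = 0).
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("psnr requires images of identical shape")
    mse = np.mean((reference - test) ** 2)
    if mse == 0.0:
        return np.inf
    return 10.0 * np.log10(data_range**2 / mse)


def _gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def ssim(reference: np.ndarray, test: np.ndarray, window: int = 11,
         sigma: float = 1.5, data_range: float = 1.0,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity with a Gaussian-weighted local window.

    Local means/variances/covariance are computed with an 11×11
    Gaussian window (σ = 1.5); stabilisers C1 = (k1·L)², C2 = (k2·L)²
    with L the dynamic range. The SSIM map is averaged over the
    interior where the window fits entirely.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ValueError("ssim requires images of identical shape")
    if min(reference.shape) < window:
        raise ValueError("image smaller than the SSIM window")
    radius = window // 2
    k = _gaussian_kernel_1d(sigma, radius)

    def smooth(a):
        out = ndimage.correlate1d(a, k, axis=0, mode="nearest")
        return ndimage.correlate1d(out, k, axis=1, mode="nearest")

    mu_x, mu_y = smooth(reference), smooth(test)
    xx = smooth(reference * reference) - mu_x * mu_x
    yy = smooth(test * test) - mu_y * mu_y
    xy = smooth(reference * test) - mu_x * mu_y
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2 * mu_x * mu_y + c1) * (2 * xy + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (xx + yy + c2)
    smap = num / den
    interior = smap[radius:-radius, radius:-radius]
    return float(interior.mean())
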