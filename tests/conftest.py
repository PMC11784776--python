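"""Shared fixtures: phantom banks and one tiny trained segmenter.

Heavy artifacts are session-scoped so several tests reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pulmoseg import itcnn, phantom, prefilter

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def phantom_bank():
    """150 default-resolution phantoms (50 per class), fixed seed."""
    cfg = phantom.PhantomConfig(image_size=(128, 128), seed=11)
    samples = phantom.generate_dataset(cfg, 50)
    return samples


@pytest.fixture(scope="session")
def small_phantoms_64():
    """80 small phantoms for segmentation training tests."""
    cfg = phantom.PhantomConfig(image_size=(64, 64),
                                lesion_radius_range=(4.0, 9.0), seed=3)
    return phantom.generate_dataset(cfg, 27)  # 81 samples


@pytest.fixture(scope="session")
def tiny_seg_run(small_phantoms_64):
    """Median-filter + 5-epoch ITCNN training on 60 phantoms; the
    remaining samples are held out. Reused by several tests."""
    samples = small_phantoms_64
    spec = prefilter.FilterSpec()
    imgs = [prefilter.median_filter(s.image, spec) for s in samples]
    masks = [s.mask for s in samples]
    labels = np.array([s.label for s in samples])
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(samples))
    tr, te = idx[:60], idx[60:]
    model, history = itcnn.train_segmenter(
        [imgs[i] for i in tr], [masks[i] for i in tr],
        itcnn.SegConfig(input_side=64),
        itcnn.SegTrainConfig(epochs=5), seed=0)
    return {"model": model, "history": history, "images": imgs,
            "masks": masks, "labels": labels, "train": tr, "test": te}
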