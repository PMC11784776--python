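"""End-to-end orchestration: preprocess → segment → extract → classify.

The canonical experiment mirrors the four-stage flow: median-filter
the input image, segment lesions with the ITCNN, extract the
four-family feature vector from the masked image, and classify with
the hybrid L-MLSTM (LinkNet head on the masked image, MLSTM on the
features, probabilities averaged). Everything is deterministic in
``(config, seed)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import evalx, featx, itcnn, lmlstm, phantom, prefilter

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "run_phantom_benchmark", "demo"]


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str | None = None
    seed: int = 0
    # data
    data_manifest: str | None = None   # use existing data when set
    n_classes: int = 3
    image_size: tuple[int, int] = (128, 128)
    n_per_class: int = 30
    lp: float = 70.0
    # preprocessing
    filter_kind: str = "median"
    filter_window: int = 3
    # segmentation
    seg_side: int = 64
    seg_epochs: int = 5
    seg_lr: float = 3e-3
    seg_batch: int = 8
    seg_train_max: int | None = None   # cap on segmenter training images
    threshold: float = 0.5
    # features
    feat_bins: int = 32
    deep_mode: str = "trained"         # trained | random
    deep_epochs: int = 3
    deep_side: int = 32
    # classifier
    mlstm_epochs: int = 10
    mlstm_batch: int = 50
    mlstm_hidden: int = 128
    seq_len: int = 16
    link_epochs: int = 8
    link_batch: int = 64
    link_side: int = 32
    # robustness
    robustness_levels: tuple[float, ...] = (0.10, 0.20, 0.30)

    def to_yaml(self) -> str:
        d = asdict(self)
        d["image_size"] = list(d["image_size"])
        d["robustness_levels"] = list(d["robustness_levels"])
        return yaml.safe_dump(d, sort_keys=True)

    @staticmethod
    def from_yaml(text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        d["image_size"] = tuple(d["image_size"])
        d["robustness_levels"] = tuple(d["robustness_levels"])
        return PipelineConfig(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # output location does not affect the computation
        d["image_size"] = list(d["image_size"])
        d["robustness_levels"] = list(d["robustness_levels"])
        canonical = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config_hash: str
    predictions: pd.DataFrame          # per test image
    mean_dice: float
    mean_jaccard: float
    accuracy_fused: float
    accuracy_linknet: float
    accuracy_mlstm: float
    robustness: dict                   # noise level -> fused accuracy
    metrics: dict                      # macro/per-class bundles
    seg_loss_history: list
    clf_loss_history: dict
    masks: list = field(default_factory=list, repr=False)
    split: evalx.SplitCounts | None = None


def _filter_image(image: np.ndarray, config: PipelineConfig) -> np.ndarray:
    spec = prefilter.FilterSpec(kind=config.filter_kind,
                                window=config.filter_window)
    if config.filter_kind == "median":
        return prefilter.median_filter(image, spec)
    return prefilter.baseline_filter(image, spec)


def _segment_batch(images: list[np.ndarray], model: itcnn.SegModel,
                   threshold: float, batch: int = 16) -> list[np.ndarray]:
    masks = []
    for start in range(0, len(images), batch):
        probs = itcnn.segment_probs(np.stack(images[start:start + batch]), model)
        masks.extend([(p >= threshold).astype(np.uint8) for p in probs])
    return masks


def _extract_all(filtered: list[np.ndarray], masks: list[np.ndarray],
                 encoders: featx.DeepEncoders,
                 config: PipelineConfig) -> np.ndarray:
    seg_images = [itcnn.apply_mask(im, mk) for im, mk in zip(filtered, masks)]
    deep = featx.deep_features_batch(np.stack(seg_images), encoders)
    rows = []
    for i, (im, mk, seg) in enumerate(zip(filtered, masks, seg_images)):
        fv = featx.concat_features(
            featx.texture_features(seg, mk),
            featx.shape_features(mk),
            featx.color_features(im, mk, bins=config.feat_bins),
            deep[i])
        rows.append(fv.vector)
    return np.stack(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full experiment defined by ``config``.

    Generates (or loads) the dataset, trains the segmenter and both
    classifier branches on the learning-percentage training split, and
    evaluates segmentation overlap, classification accuracy and
    white-noise robustness on the held-out split. Artifacts are
    written under ``config.out_dir`` when it is set.
    """
    seed = config.seed
    if config.data_manifest is not None:
        samples = phantom.load_dataset(config.data_manifest)
    else:
        pconf = phantom.PhantomConfig(image_size=config.image_size,
                                      n_classes=config.n_classes, seed=seed)
        samples = phantom.generate_dataset(pconf, config.n_per_class)
    images = [s.image for s in samples]
    gt_masks = [s.mask for s in samples]
    labels = np.array([s.label for s in samples])
    n = len(samples)

    split, tr_idx, te_idx, _ = evalx.partition(n, config.lp, seed=seed,
                                               labels=labels)

    filtered = [_filter_image(im, config) for im in images]

    seg_tr = tr_idx if config.seg_train_max is None else tr_idx[:config.seg_train_max]
    seg_model, seg_hist = itcnn.train_segmenter(
        [filtered[i] for i in seg_tr], [gt_masks[i] for i in seg_tr],
        itcnn.SegConfig(input_side=config.seg_side, threshold=config.threshold),
        itcnn.SegTrainConfig(epochs=config.seg_epochs, lr=config.seg_lr,
                             batch_size=config.seg_batch),
        seed=seed)

    pred_masks = _segment_batch(filtered, seg_model, config.threshold)
    all_dices = [evalx.dice(pred_masks[i], gt_masks[i]) for i in range(n)]
    dices = [all_dices[i] for i in te_idx]
    jaccards = [evalx.jaccard(pred_masks[i], gt_masks[i]) for i in te_idx]

    masked_tr = [itcnn.apply_mask(filtered[i], pred_masks[i]) for i in tr_idx]
    if config.deep_mode == "trained":
        encoders = featx.train_deep_encoders(
            masked_tr, labels[tr_idx], config.n_classes,
            epochs=config.deep_epochs, input_side=config.deep_side, seed=seed)
    else:
        encoders = featx.random_deep_encoders(config.n_classes, seed=seed,
                                              input_side=config.deep_side)

    features = _extract_all(filtered, pred_masks, encoders, config)

    clf, clf_hist = lmlstm.train_classifier(
        features[tr_idx], [masked_tr[i] for i in range(len(tr_idx))],
        labels[tr_idx],
        lmlstm.TrainConfig(
            mlstm_epochs=config.mlstm_epochs, mlstm_batch=config.mlstm_batch,
            mlstm_hidden=config.mlstm_hidden, seq_len=config.seq_len,
            link_epochs=config.link_epochs, link_batch=config.link_batch,
            link_side=config.link_side),
        seed=seed)

    masked_all = [itcnn.apply_mask(filtered[i], pred_masks[i])
                  for i in range(n)]
    p_link_all = clf.linknet.predict_proba(np.stack(masked_all))
    p_mlstm_all = clf.mlstm.predict_proba(features)
    p_fused_all = lmlstm.fuse_predictions(p_link_all, p_mlstm_all)
    y_te = labels[te_idx]
    p_fused = p_fused_all[te_idx]
    acc_fused = float(np.mean(p_fused.argmax(1) == y_te))
    acc_link = float(np.mean(p_link_all[te_idx].argmax(1) == y_te))
    acc_mlstm = float(np.mean(p_mlstm_all[te_idx].argmax(1) == y_te))
    metrics = evalx.multiclass_metrics(y_te, p_fused.argmax(1),
                                       config.n_classes)

    def classify_images(raw_images: list[np.ndarray]) -> np.ndarray:
        filt = [_filter_image(im, config) for im in raw_images]
        mks = _segment_batch(filt, seg_model, config.threshold)
        feats = _extract_all(filt, mks, encoders, config)
        masked = [itcnn.apply_mask(f, m) for f, m in zip(filt, mks)]
        probs = lmlstm.fuse_predictions(
            clf.linknet.predict_proba(np.stack(masked)),
            clf.mlstm.predict_proba(feats))
        return probs.argmax(1)

    robustness = evalx.robustness_curve(
        classify_images, [images[i] for i in te_idx], y_te,
        levels=config.robustness_levels, seed=seed)

    in_test = np.zeros(n, dtype=bool)
    in_test[te_idx] = True
    predictions = pd.DataFrame({
        "index": np.arange(n),
        "split": np.where(in_test, "test", "train"),
        "label": labels,
        "pred": p_fused_all.argmax(1),
        **{f"prob_{c}": p_fused_all[:, c] for c in range(config.n_classes)},
        "dice": all_dices,
    })

    result = PipelineResult(
        config_hash=config.config_hash(),
        predictions=predictions,
        mean_dice=float(np.mean(dices)),
        mean_jaccard=float(np.mean(jaccards)),
        accuracy_fused=acc_fused,
        accuracy_linknet=acc_link,
        accuracy_mlstm=acc_mlstm,
        robustness=robustness,
        metrics=metrics,
        seg_loss_history=seg_hist,
        clf_loss_history=clf_hist,
        masks=pred_masks,
        split=split,
    )
    if config.out_dir is not None:
        _write_artifacts(result, samples, config)
    return result


def _write_artifacts(result: PipelineResult, samples, config: PipelineConfig):
    out = Path(config.out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    for i, m in enumerate(result.masks):
        iio.imwrite(out / "masks" / f"mask_{i:04d}.png",
                    (np.asarray(m) * 255).astype(np.uint8))
    preds = result.predictions.copy()
    preds.insert(0, "config_hash", result.config_hash)
    preds.to_csv(out / "predictions.csv", index=False, float_format="%.6f")
    report = {
        "config_hash": result.config_hash,
        "split": asdict(result.split) if result.split else None,
        "mean_dice": result.mean_dice,
        "mean_jaccard": result.mean_jaccard,
        "accuracy": {"fused": result.accuracy_fused,
                     "linknet": result.accuracy_linknet,
                     "mlstm": result.accuracy_mlstm},
        "robustness": {str(k): v for k, v in result.robustness.items()},
        "macro_metrics": result.metrics["macro"],
        "per_class": {str(c): b.as_dict()
                      for c, b in result.metrics["per_class"].items()},
        "confusion_matrix": result.metrics["matrix"].tolist(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True))


BENCHMARK_CONFIG = PipelineConfig(
    n_per_class=100, image_size=(128, 128), lp=70.0,
    seg_epochs=5, seg_side=64, seg_train_max=120,
    deep_mode="trained", deep_epochs=3,
    mlstm_epochs=10, link_epochs=8, link_side=32,
)


def run_phantom_benchmark(seed: int = 0, n_per_class: int = 100,
                          out_dir: str | None = None) -> PipelineResult:
    """The package's standard end-to-end experiment: 3-class phantoms
    (``n_per_class`` each, 128×128), learning percentage 70, tiny
    ITCNN trained 5 epochs, both classifier branches ≤10 epochs."""
    cfg = replace(BENCHMARK_CONFIG, seed=seed, n_per_class=n_per_class,
                  out_dir=out_dir)
    return run_pipeline(cfg)


DEMO_CONFIG = PipelineConfig(
    n_per_class=10, image_size=(64, 64), lp=70.0,
    seg_epochs=5, seg_side=64, deep_mode="random",
    mlstm_epochs=5, link_epochs=3, link_side=32,
    robustness_levels=(0.10,),
)


def demo(out_dir: str | Path, seed: int = 0) -> PipelineResult:
    """Small self-contained worked example (30 phantoms, tiny configs)."""
    cfg = replace(DEMO_CONFIG, seed=seed, out_dir=str(out_dir))
    return run_pipeline(cfg)
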