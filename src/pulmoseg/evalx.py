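"""Evaluation machinery: overlap scores, confusion-matrix metrics,
learning-percentage partitioning, k-fold and robustness harnesses,
rank-based AUC, and nonparametric model comparison.

Conventions: Dice and Jaccard of two empty masks are 1.0 (0.0 when
exactly one is empty); metric ratios with zero denominators return 0
and are flagged rather than raising, so batch evaluation stays total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .phantom import NoiseSpec, add_noise

__all__ = [
    "dice", "jaccard", "ConfusionCounts", "MetricsBundle",
    "confusion_metrics", "multiclass_metrics", "SplitCounts", "partition",
    "kfold_evaluate", "robustness_curve", "roc_auc", "compare_models",
]


def _as_mask(a) -> np.ndarray:
    return np.asarray(a) > 0


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); both empty → 1.0."""
    a, b = _as_mask(a), _as_mask(b)
    if a.shape != b.shape:
        raise ValueError("masks must share shape")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap |A∩B| / |A∪B|; both empty → 1.0."""
    a, b = _as_mask(a), _as_mask(b)
    if a.shape != b.shape:
        raise ValueError("masks must share shape")
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsBundle:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    f2_score: float
    npv: float
    fpr: float
    fnr: float
    mcc: float
    kappa: float
    undefined: tuple = field(default=())

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "undefined"}
        return d


def _ratio(num: float, den: float, name: str, flags: list) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def confusion_metrics(counts: ConfusionCounts) -> MetricsBundle:
    """Standard binary bundle; zero-denominator ratios → 0 + flag."""
    if counts.n == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    flags: list = []
    sens = _ratio(tp, tp + fn, "sensitivity", flags)
    spec = _ratio(tn, tn + fp, "specificity", flags)
    prec = _ratio(tp, tp + fp, "precision", flags)
    f1 = _ratio(2 * prec * sens, prec + sens, "f_measure", flags)
    f2 = _ratio(5 * prec * sens, 4 * prec + sens, "f2_score", flags)
    npv = _ratio(tn, tn + fn, "npv", flags)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", flags)
    po = (tp + tn) / counts.n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / counts.n**2
    kappa = _ratio(po - pe, 1 - pe, "kappa", flags)
    return MetricsBundle(
        accuracy=(tp + tn) / counts.n, sensitivity=sens, specificity=spec,
        precision=prec, f_measure=f1, f2_score=f2, npv=npv,
        fpr=1.0 - spec, fnr=1.0 - sens, mcc=mcc, kappa=kappa,
        undefined=tuple(flags))


def multiclass_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                       n_classes: int | None = None) -> dict:
    """Macro-averaged one-vs-rest bundle + the full K×K matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    matrix = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        matrix[t, p] += 1
    per_class = {}
    for c in range(n_classes):
        tp = int(matrix[c, c])
        fn = int(matrix[c].sum() - tp)
        fp = int(matrix[:, c].sum() - tp)
        tn = int(matrix.sum() - tp - fn - fp)
        per_class[c] = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
    keys = per_class[0].as_dict().keys()
    macro = {k: float(np.mean([per_class[c].as_dict()[k]
                               for c in range(n_classes)])) for k in keys}
    macro["accuracy"] = float(np.trace(matrix) / matrix.sum())
    return {"matrix": matrix, "per_class": per_class, "macro": macro}


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitCounts:
    lp: float
    n_total: int
    train: int
    test: int
    val: int


def partition(n_total: int, lp: float, seed: int = 0,
              labels: np.ndarray | None = None,
              disjoint_eval: bool = False):
    """Learning-percentage split: train = round(lp/100·n); test and
    validation are the held-out remainder (equal size, same indices by
    default; ``disjoint_eval`` halves the remainder instead).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 < lp < 100:
        raise ValueError("learning percentage must lie strictly in (0, 100)")
    n_train = int(round(lp / 100.0 * n_total))
    rng = np.random.default_rng(seed)
    if labels is not None:
        labels = np.asarray(labels)
        order = []
        # stratified round-robin over shuffled per-class pools
        pools = []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            pools.append(list(rng.permutation(idx)))
        while any(pools):
            for pool in pools:
                if pool:
                    order.append(pool.pop())
        order = np.array(order)
    else:
        order = rng.permutation(n_total)
    train_idx = np.sort(order[:n_train])
    rest = np.sort(order[n_train:])
    if disjoint_eval:
        half = len(rest) // 2
        test_idx, val_idx = rest[:half], rest[half:]
    else:
        test_idx = val_idx = rest
    counts = SplitCounts(lp=lp, n_total=n_total, train=n_train,
                         test=len(test_idx), val=len(val_idx))
    return counts, train_idx, test_idx, val_idx


# ---------------------------------------------------------------------------
# harnesses
# ---------------------------------------------------------------------------

def kfold_evaluate(model_factory, features: np.ndarray, labels: np.ndarray,
                   k: int, seed: int = 0) -> pd.DataFrame:
    """Stratified k-fold: a fresh model per fold; per-fold accuracy."""
    features = np.asarray(features)
    labels = np.asarray(labels)
    if k > len(labels):
        raise ValueError("k must not exceed the number of samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(features, labels)):
        model = model_factory()
        model.fit(features[tr], labels[tr])
        acc = float(np.mean(model.predict(features[te]) == labels[te]))
        rows.append({"fold": fold, "n_test": len(te), "accuracy": acc})
    df = pd.DataFrame(rows)
    df.attrs["mean_accuracy"] = float(df["accuracy"].mean())
    return df


def robustness_curve(predict_fn, images: list[np.ndarray],
                     labels: np.ndarray, levels=(0.10, 0.20, 0.30),
                     seed: int = 0) -> dict:
    """Accuracy after white-noise injection at each level.

    ``predict_fn`` maps a list of images to predicted labels; level 0
    reproduces the clean accuracy exactly.
    """
    labels = np.asarray(labels)
    out = {}
    for li, level in enumerate(levels):
        noisy = [add_noise(im, NoiseSpec("white_percent", level,
                                         seed=seed + 1000 * li + j))
                 for j, im in enumerate(images)]
        preds = np.asarray(predict_fn(noisy))
        out[float(level)] = float(np.mean(preds == labels))
    return out


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random positive outscores random negative),
    ties counted half (the Mann–Whitney U relation)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compare_models(accuracy_matrix: np.ndarray,
                   model_names: list[str] | None = None) -> dict:
    """Friedman test across models (rows) over runs (columns) plus
    pairwise Wilcoxon signed-rank p-values. Degenerate all-equal
    inputs are flagged with the p = 1 convention."""
    acc = np.asarray(accuracy_matrix, dtype=float)
    n_models, n_runs = acc.shape
    if n_models < 2:
        raise ValueError("need at least 2 models")
    if n_runs < 3:
        raise ValueError("need at least 3 runs per model")
    names = model_names or [f"model_{i}" for i in range(n_models)]
    degenerate = bool(np.all(acc == acc[0:1, :]))
    if degenerate:
        friedman_p = 1.0
    elif n_models >= 3:
        friedman_p = float(stats.friedmanchisquare(*acc).pvalue)
    else:
        friedman_p = float(stats.wilcoxon(acc[0], acc[1]).pvalue)
    rows = []
    for i in range(n_models):
        for j in range(i + 1, n_models):
            diff = acc[i] - acc[j]
            if np.all(diff == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(acc[i], acc[j],
                                         zero_method="zsplit").pvalue)
            rows.append({"model_a": names[i], "model_b": names[j],
                         "wilcoxon_p": p})
    return {"friedman_p": friedman_p, "degenerate": degenerate,
            "pairwise": pd.DataFrame(rows)}
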