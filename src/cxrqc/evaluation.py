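"""Evaluation machinery: classification metrics with bootstrap CIs,
mask IoU, occlusion-sensitivity saliency maps, and the text-removal
shortcut-learning experiment.

Metric definitions are written out explicitly from the confusion matrix
(the test suite cross-checks them against scikit-learn and a brute-force
oracle); AUROC is the tie-corrected rank statistic. Confidence intervals
are percentile bootstrap over resampled case indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

METRIC_NAMES = ("auroc", "accuracy", "precision", "recall", "specificity",
                "npv", "f1")
DEFAULT_N_BOOT = 1000


class MetricValue(NamedTuple):
    point: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass
class MetricSet:
    """The seven evaluation metrics, each a (point, ci_low, ci_high)
    triple; undefined metrics (zero denominators, single-class AUROC) are
    None rather than silently propagated NaN."""

    auroc: MetricValue
    accuracy: MetricValue
    precision: MetricValue
    recall: MetricValue
    specificity: MetricValue
    npv: MetricValue
    f1: MetricValue
    n_auroc_skipped: int = 0

    def __getitem__(self, name: str) -> MetricValue:
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": m, "point": self[m].point,
                 "ci_low": self[m].ci_low, "ci_high": self[m].ci_high}
                for m in METRIC_NAMES]
        return pd.DataFrame(rows)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> Tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return tp, fp, fn, tn


def _safe_div(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def auroc_score(y_true: np.ndarray, y_score: np.ndarray) -> Optional[float]:
    """Rank-statistic AUROC with ties averaged (Mann-Whitney U / (n1*n0));
    None when only one class is present."""
    y_true = np.asarray(y_true)
    n1 = int(np.sum(y_true == 1))
    n0 = int(np.sum(y_true == 0))
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(np.asarray(y_score, dtype=np.float64))
    u = ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def classification_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                           y_score: Optional[Sequence[float]] = None
                           ) -> Dict[str, Optional[float]]:
    """Point estimates of the seven metrics from binary labels/predictions
    (positive class = 1) and optional continuous scores for AUROC."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp, fp, fn, tn = _confusion(y_true, y_pred)
    n = tp + fp + fn + tn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    if precision is None or recall is None:
        f1 = None
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "auroc": auroc_score(y_true, y_score) if y_score is not None else None,
        "accuracy": _safe_div(tp + tn, n),
        "precision": precision,
        "recall": recall,
        "specificity": _safe_div(tn, tn + fp),
        "npv": _safe_div(tn, tn + fn),
        "f1": f1,
    }


def bootstrap_ci(y_true: Sequence[int], y_pred: Sequence[int],
                 y_score: Optional[Sequence[float]] = None,
                 n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
                 alpha: float = 0.05) -> MetricSet:
    """Percentile bootstrap CIs over resampled case indices.

    Resamples where a metric is undefined (e.g. single-class AUROC) are
    skipped for that metric; the AUROC skip count is reported.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    y_score_arr = None if y_score is None else np.asarray(y_score, dtype=np.float64)
    n = len(y_true)
    rng = np.random.default_rng(seed)

    point = classification_metrics(y_true, y_pred, y_score_arr)
    samples: Dict[str, List[float]] = {m: [] for m in METRIC_NAMES}
    auroc_skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        m = classification_metrics(
            y_true[idx], y_pred[idx],
            None if y_score_arr is None else y_score_arr[idx])
        for name in METRIC_NAMES:
            if m[name] is None:
                if name == "auroc" and y_score_arr is not None:
                    auroc_skipped += 1
                continue
            samples[name].append(m[name])

    values = {}
    for name in METRIC_NAMES:
        if point[name] is None:
            values[name] = MetricValue(None, None, None)
            continue
        s = np.array(samples[name])
        if s.size == 0:
            values[name] = MetricValue(point[name], None, None)
        else:
            lo, hi = np.percentile(s, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            values[name] = MetricValue(point[name], float(lo), float(hi))
    return MetricSet(n_auroc_skipped=auroc_skipped, **values)


def mask_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard index |A∩B| / |A∪B|; two empty masks return 1.0 (perfect
    agreement on "nothing present", a convention documented here because
    it is otherwise undefined)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes must agree")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def saliency_map(model, image: np.ndarray, patch: int = 32,
                 stride: int = 16) -> np.ndarray:
    """Occlusion-sensitivity attribution.

    Each patch in turn is replaced by the image mean; the drop in the
    model's score is accumulated over the patch footprint and the final
    map normalized to [0, 1]. ``model`` is anything with
    ``predict_score(image) -> float``.
    """
    if not (patch >= stride >= 1):
        raise ValueError("need patch >= stride >= 1")
    image = np.asarray(image, dtype=np.float64)
    base = _logit(model.predict_score(image))
    fill = float(image.mean())
    nrows, ncols = image.shape
    heat = np.zeros_like(image)
    count = np.zeros_like(image)

    def positions(dim: int) -> List[int]:
        pos = list(range(0, max(dim - patch, 0) + 1, stride))
        if pos[-1] != dim - patch and dim > patch:
            pos.append(dim - patch)
        return pos

    for r in positions(nrows):
        for c in positions(ncols):
            occluded = image.copy()
            occluded[r:r + patch, c:c + patch] = fill
            # influence on the log-odds scale: probabilities saturate for a
            # confident classifier and would hide real sensitivity
            delta = abs(base - _logit(model.predict_score(occluded)))
            heat[r:r + patch, c:c + patch] += delta
            count[r:r + patch, c:c + patch] += 1
    attr = np.divide(heat, count, out=np.zeros_like(heat), where=count > 0)
    if attr.max() > 0:
        attr = attr / attr.max()
    return attr


def _logit(p: float, eps: float = 1e-12) -> float:
    p = min(max(p, eps), 1.0 - eps)
    return float(np.log(p / (1.0 - p)))


def binarize_saliency(smap: np.ndarray, quantile: float = 0.9) -> np.ndarray:
    """Top-quantile binarization for IoU comparison; an all-zero map
    (model insensitive everywhere) binarizes to all-False."""
    smap = np.asarray(smap, dtype=np.float64)
    if smap.max() <= 0:
        return np.zeros_like(smap, dtype=bool)
    return smap >= np.quantile(smap, quantile)


# --------------------------------------------------------------------------
# Text-removal shortcut experiment
# --------------------------------------------------------------------------

@dataclass
class ShortcutExperimentConfig:
    """Conditions for the synthetic shortcut-learning study.

    Burned-in projection tokens correlate perfectly with the class by
    default (laterality/technique markers in practice are deterministic),
    while the anatomy signal is made imperfect (``ambiguity``) so that a
    model trained on original images has a genuine shortcut to prefer.
    """

    n_train_per_class: int = 150
    n_test_per_class: int = 60
    text_class_correlation: float = 1.0
    # ambiguity > 1 lets a film cross the midpoint toward the opposite
    # projection's prototype, so the anatomy signal alone has irreducible
    # error and the burned-in token is a genuinely attractive shortcut
    ambiguity_range: Tuple[float, float] = (0.4, 1.5)
    # same-length tokens ("PA" erect vs "LL" left-lateral) occupy the same
    # footprint, so the zero-intensity boxes of the zero-box variant carry
    # no class information of their own
    frontal_token: str = "PA"
    lateral_token: str = "LL"
    blur_sigma_range: Tuple[float, float] = (0.5, 1.5)
    noise_sd_range: Tuple[float, float] = (0.01, 0.03)
    n_boot: int = 200
    n_saliency_images: int = 20
    saliency_patch: int = 32
    saliency_stride: int = 16
    saliency_quantile: float = 0.9
    threshold: float = 0.5


TRAIN_VARIANTS = ("original", "inpainted", "zero_box")
TEST_VARIANTS = ("with_text", "text_removed", "never_annotated")


def _zero_box(image: np.ndarray, truth_mask: np.ndarray) -> np.ndarray:
    """Obscure annotations with zero-intensity bounding boxes around the
    truth-mask components."""
    from .annotation import AnnotationMask
    out = image.copy()
    for (r0, r1, c0, c1) in AnnotationMask.from_mask(truth_mask).components:
        out[r0:r1, c0:c1] = 0.0
    return out


def text_removal_experiment(config: ShortcutExperimentConfig = ShortcutExperimentConfig(),
                            seed: int = 0) -> dict:
    """Train projection models on original / inpainted / zero-box images
    and evaluate each on with-text / text-removed / never-annotated test
    sets; also compare occlusion-saliency overlap with the truth text
    masks (mean IoU per model, paired-bootstrap difference CIs).

    Returns a dict with an ``accuracy`` DataFrame (train variant x test
    variant), a ``metrics`` mapping of full MetricSets, ``mean_iou`` per
    model and ``iou_differences`` with CIs.
    """
    from .annotation import remove_annotations
    from .intensity import apply_windowing
    from .projection import FRONTAL, predict_projection, train_projection_model
    from .synthetic import DatasetConfig, generate_dataset

    if config.text_class_correlation <= 0:
        raise ValueError(
            "shortcut experiment requires text injection correlated with the "
            "class; set text_class_correlation > 0")

    rng = np.random.default_rng(seed)
    gen = DatasetConfig(
        frontal_fraction=0.5,
        text_prob=1.0,
        text_class_correlation=config.text_class_correlation,
        side_marker_prob=0.0,
        pad_prob=0.0, collim_prob=0.0, rotation_prob=0.0,
        blur_sigma_range=config.blur_sigma_range,
        noise_sd_range=config.noise_sd_range,
        ambiguity_range=config.ambiguity_range,
        missing_metadata_rate=0.0, multi_image_rate=0.0,
        frontal_token=config.frontal_token,
        lateral_token=config.lateral_token,
    )
    n_train = 2 * config.n_train_per_class
    n_test = 2 * config.n_test_per_class
    train_recs, _ = generate_dataset(n_train, gen, seed=int(rng.integers(2 ** 31)))
    test_recs, _ = generate_dataset(n_test, gen, seed=int(rng.integers(2 ** 31)))

    def window(rec):
        return apply_windowing(rec.image, rec.metadata.window_center,
                               rec.metadata.window_width)

    def prepare(recs):
        images = [window(rec) for rec, _ in recs]
        labels = [truth["projection"] for _, truth in recs]
        masks = [truth["text_mask"] for _, truth in recs]
        return images, labels, masks

    tr_img, tr_lab, tr_mask = prepare(train_recs)
    te_img, te_lab, te_mask = prepare(test_recs)

    def inpaint_all(images):
        return [remove_annotations(im)[0] for im in images]

    train_sets = {
        "original": tr_img,
        "inpainted": inpaint_all(tr_img),
        "zero_box": [_zero_box(im, m) for im, m in zip(tr_img, tr_mask)],
    }
    never_cfg_recs, _ = generate_dataset(
        n_test,
        DatasetConfig(**{**gen.__dict__, "text_prob": 0.0}),
        seed=int(rng.integers(2 ** 31)))
    na_img, na_lab, _ = prepare(never_cfg_recs)
    test_sets = {
        "with_text": (te_img, te_lab),
        "text_removed": (inpaint_all(te_img), te_lab),
        "never_annotated": (na_img, na_lab),
    }

    models = {}
    metrics: Dict[Tuple[str, str], MetricSet] = {}
    acc = pd.DataFrame(index=list(TRAIN_VARIANTS), columns=list(TEST_VARIANTS),
                       dtype=float)
    for tv in TRAIN_VARIANTS:
        model = train_projection_model(train_sets[tv], tr_lab,
                                       seed=int(rng.integers(2 ** 31)))
        models[tv] = model
        for sv in TEST_VARIANTS:
            images, labels = test_sets[sv]
            y_true = np.array([int(lb == FRONTAL) for lb in labels])
            calls = [predict_projection(model, im, config.threshold)
                     for im in images]
            y_pred = np.array([int(c.label == FRONTAL) for c in calls])
            y_score = np.array([c.score for c in calls])
            ms = bootstrap_ci(y_true, y_pred, y_score, n_boot=config.n_boot,
                              seed=int(rng.integers(2 ** 31)))
            metrics[(tv, sv)] = ms
            acc.loc[tv, sv] = ms.accuracy.point

    # saliency overlap with truth text masks, on with-text test images
    annotated = [i for i, m in enumerate(te_mask) if m.any()]
    chosen = annotated[:config.n_saliency_images]
    ious = {tv: [] for tv in TRAIN_VARIANTS}
    for i in chosen:
        for tv in TRAIN_VARIANTS:
            smap = saliency_map(models[tv], te_img[i],
                                patch=config.saliency_patch,
                                stride=config.saliency_stride)
            bmask = binarize_saliency(smap, config.saliency_quantile)
            ious[tv].append(mask_iou(bmask, te_mask[i]))
    mean_iou = {tv: float(np.mean(ious[tv])) for tv in TRAIN_VARIANTS}

    boot_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
    k = len(chosen)
    diffs = {}
    for a in TRAIN_VARIANTS:
        for b in TRAIN_VARIANTS:
            if a >= b:
                continue
            da = np.array(ious[a])
            db = np.array(ious[b])
            stat = []
            for _ in range(config.n_boot):
                idx = boot_rng.integers(0, k, size=k)
                stat.append(float(np.mean(da[idx] - db[idx])))
            lo, hi = np.percentile(stat, [2.5, 97.5])
            diffs[f"{a}-{b}"] = {"mean": float(np.mean(da - db)),
                                 "ci_low": float(lo), "ci_high": float(hi)}

    return {
        "accuracy": acc,
        "metrics": metrics,
        "mean_iou": mean_iou,
        "iou_differences": diffs,
        "iou_per_image": {tv: list(map(float, ious[tv])) for tv in TRAIN_VARIANTS},
        "models": models,
        "config": config,
    }
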