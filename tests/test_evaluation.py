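import numpy as np
import pytest

from cxrqc.evaluation import (DEFAULT_N_BOOT, auroc_score, binarize_saliency,
                              bootstrap_ci, classification_metrics, mask_iou,
                              saliency_map, text_removal_experiment,
                              ShortcutExperimentConfig)


def brute_force_metrics(y_true, y_pred):
    """Independent oracle: count the confusion matrix cell by cell."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    div = lambda a, b: a / b if b else None
    out = {"accuracy": div(tp + tn, tp + tn + fp + fn),
           "precision": div(tp, tp + fp), "recall": div(tp, tp + fn),
           "specificity": div(tn, tn + fp), "npv": div(tn, tn + fn)}
    p, r = out["precision"], out["recall"]
    out["f1"] = (None if p is None or r is None
                 else (0.0 if p + r == 0 else 2 * p * r / (p + r)))
    return out


class TestPointMetrics:
    def test_perfect_predictions(self):
        y = [0, 1, 0, 1, 1]
        m = classification_metrics(y, y, [0.1, 0.9, 0.2, 0.8, 0.7])
        for name in ("auroc", "accuracy", "precision", "recall", "specificity",
                     "npv", "f1"):
            assert m[name] == 1.0

    def test_inverted_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = classification_metrics(y, 1 - y, 1.0 - y.astype(float))
        assert m["accuracy"] == 0.0
        assert m["auroc"] == 0.0

    def test_hand_counted_confusion_matrix(self):
        y_true = [1] * 9 + [0] * 11
        y_pred = [1] * 8 + [0] * 1 + [1] * 2 + [0] * 9
        m = classification_metrics(y_true, y_pred)
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(8 / 9)
        assert m["accuracy"] == pytest.approx(0.85)

    def test_single_class_auroc_undefined(self):
        m = classification_metrics([1, 1, 1], [1, 0, 1], [0.9, 0.2, 0.8])
        assert m["auroc"] is None

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = int(rng.integers(2, 25))
            yt = rng.integers(0, 2, n)
            yp = rng.integers(0, 2, n)
            mine = classification_metrics(yt, yp)
            oracle = brute_force_metrics(yt.tolist(), yp.tolist())
            for k, v in oracle.items():
                if v is None:
                    assert mine[k] is None
                else:
                    assert mine[k] == pytest.approx(v)

    def test_auroc_equals_mannwhitney_normalization(self):
        rng = np.random.default_rng(13)
        yt = rng.integers(0, 2, 60)
        ys = rng.normal(size=60)  # tie-free continuous scores
        n1, n0 = yt.sum(), (1 - yt).sum()
        # brute force: count concordant pairs
        pos = ys[yt == 1]
        neg = ys[yt == 0]
        conc = sum(1 for p in pos for q in neg if p > q)
        assert auroc_score(yt, ys) == pytest.approx(conc / (n1 * n0))


class TestBootstrap:
    def test_default_resample_count(self):
        assert DEFAULT_N_BOOT == 1000

    def test_perfect_classifier_degenerate_cis(self):
        y = np.tile([0, 1], 30)
        ms = bootstrap_ci(y, y, y.astype(float), n_boot=200, seed=0)
        assert ms.accuracy == (1.0, 1.0, 1.0)
        assert ms.auroc.ci_low == 1.0 and ms.auroc.ci_high == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(14)
        yt = rng.integers(0, 2, 80)
        yp = np.where(rng.random(80) < 0.8, yt, 1 - yt)
        ys = rng.random(80)
        a = bootstrap_ci(yt, yp, ys, n_boot=300, seed=11)
        b = bootstrap_ci(yt, yp, ys, n_boot=300, seed=11)
        assert a == b

    def test_ci_contains_point_and_shrinks_with_n(self):
        rng = np.random.default_rng(15)
        widths = {}
        for n in (50, 500):
            yt = rng.integers(0, 2, n)
            yp = np.where(rng.random(n) < 0.8, yt, 1 - yt)
            ms = bootstrap_ci(yt, yp, n_boot=400, seed=3)
            assert ms.accuracy.ci_low <= ms.accuracy.point <= ms.accuracy.ci_high
            widths[n] = ms.accuracy.ci_high - ms.accuracy.ci_low
        assert widths[500] < widths[50]

    def test_full_sample_identity_resample_equals_point(self):
        # a bootstrap that happens to redraw the full sample reproduces the
        # point estimates exactly
        yt = np.array([0, 1, 1, 0, 1])
        yp = np.array([0, 1, 0, 0, 1])
        point = classification_metrics(yt, yp)
        resampled = classification_metrics(yt[np.arange(5)], yp[np.arange(5)])
        assert point == resampled

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([0, 1], [0, 1], n_boot=10, seed=0)


class TestMaskIoU:
    def test_identical_nonempty(self):
        m = np.zeros((8, 8), bool); m[2:5, 2:5] = True
        assert mask_iou(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((8, 8), bool); a[:2] = True
        b = np.zeros((8, 8), bool); b[6:] = True
        assert mask_iou(a, b) == 0.0

    def test_counted_overlap(self):
        a = np.zeros((30, 30), bool); a[0:10, 0:10] = True
        b = np.zeros((30, 30), bool); b[5:15, 0:10] = True
        assert mask_iou(a, b) == pytest.approx(50 / 150)

    def test_both_empty_convention(self):
        assert mask_iou(np.zeros((4, 4), bool), np.zeros((4, 4), bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_iou(np.zeros((4, 4), bool), np.zeros((4, 5), bool))


class _StripeModel:
    """Toy score function sensitive only to the top-left quadrant."""

    def predict_score(self, image):
        x = float(image[: image.shape[0] // 2, : image.shape[1] // 2].mean())
        return 1.0 / (1.0 + np.exp(-6 * (x - 0.5)))


class TestSaliency:
    def test_ignored_region_gets_zero_attribution(self):
        img = np.full((64, 64), 0.5)
        img[:32, :32] = 0.8
        smap = saliency_map(_StripeModel(), img, patch=16, stride=16)
        assert smap[40:, 40:].max() == 0.0
        assert smap[:16, :16].max() > 0.0

    def test_map_contract(self):
        img = np.random.default_rng(1).uniform(size=(48, 48))
        smap = saliency_map(_StripeModel(), img, patch=16, stride=8)
        assert smap.shape == img.shape
        assert 0.0 <= smap.min() and smap.max() <= 1.0

    def test_all_zero_map_binarizes_empty(self):
        assert not binarize_saliency(np.zeros((10, 10))).any()

    def test_invalid_patch_stride(self):
        with pytest.raises(ValueError):
            saliency_map(_StripeModel(), np.zeros((32, 32)), patch=4, stride=8)


class TestShortcutExperimentConfigValidation:
    def test_degenerate_config_refused(self):
        with pytest.raises(ValueError, match="text"):
            text_removal_experiment(
                ShortcutExperimentConfig(text_class_correlation=0.0), seed=0)
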