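import numpy as np
import pytest

from cxrqc.annotation import (AnnotationMask, MaskTooLargeError,
                              detect_annotations, inpaint, removal_outcome)
from cxrqc.synthetic import PhantomSpec, TextItem, generate_phantom
from .conftest import windowed


class TestDetect:
    def test_phantom_without_text_gives_empty_mask(self, frontal_phantom):
        rec, _ = frontal_phantom
        assert detect_annotations(windowed(rec)).is_empty()

    def test_burned_token_covered(self, text_phantom):
        rec, truth = text_phantom
        mask = detect_annotations(windowed(rec))
        covered = (mask.mask & truth["text_mask"]).sum() / truth["text_mask"].sum()
        assert covered >= 0.95

    def test_jewelry_disk_not_masked(self):
        rec, truth = generate_phantom(PhantomSpec(seed=41))
        img = rec.image.copy()
        rows, cols = np.nonzero(truth["lung_mask"])
        cy, cx = int(rows.mean()), int(cols.mean())
        yy, xx = np.ogrid[0:img.shape[0], 0:img.shape[1]]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= 30 ** 2
        img[disk] = 0.95
        mask = detect_annotations(img)
        assert not (mask.mask & disk).any()


class TestInpaint:
    def test_empty_mask_is_identity(self, frontal_phantom):
        rec, _ = frontal_phantom
        out = inpaint(rec.image, AnnotationMask.empty(rec.image.shape))
        np.testing.assert_array_equal(out, rec.image)

    def test_constant_image_fills_with_constant(self):
        img = np.full((64, 64), 0.3)
        mask = np.zeros((64, 64), bool)
        mask[20:30, 20:30] = True
        out = inpaint(img, mask)
        np.testing.assert_allclose(out, 0.3, atol=1e-12)

    def test_linear_gradient_reconstructed(self):
        img = np.tile(np.linspace(0.1, 0.9, 64), (64, 1))
        mask = np.zeros((64, 64), bool)
        mask[27:37, 27:37] = True
        out = inpaint(img, mask, match_noise=False)
        assert np.abs(out[mask] - img[mask]).mean() <= 0.02

    def test_unmasked_pixels_bit_identical(self, text_phantom):
        rec, _ = text_phantom
        img = windowed(rec)
        mask = detect_annotations(img)
        out = inpaint(img, mask)
        assert np.array_equal(out[~mask.mask], img[~mask.mask])

    def test_oversized_mask_refused(self):
        img = np.random.default_rng(0).uniform(size=(64, 64))
        mask = np.ones((64, 64), bool)
        with pytest.raises(MaskTooLargeError):
            inpaint(img, mask)

    def test_detect_inpaint_pair_idempotent(self, text_phantom):
        rec, _ = text_phantom
        img = windowed(rec)
        m1 = detect_annotations(img)
        once = inpaint(img, m1)
        m2 = detect_annotations(once)
        newly = (m2.mask & ~m1.mask).sum()
        assert newly <= 0.001 * img.size


class TestOutcome:
    def _mask(self, shape, sl):
        m = np.zeros(shape, bool)
        m[sl] = True
        return m

    def test_exact_match_is_complete(self):
        t = self._mask((50, 50), np.s_[5:10, 5:20])
        out = removal_outcome(t, t, np.zeros((50, 50), bool))
        assert out.category == "complete" and out.fraction_removed == 1.0

    def test_empty_prediction_fails(self):
        t = self._mask((50, 50), np.s_[5:10, 5:20])
        out = removal_outcome(np.zeros((50, 50), bool), t, np.zeros((50, 50), bool))
        assert out.category == "failed"

    def test_half_coverage_is_partial(self):
        t = self._mask((50, 50), np.s_[5:9, 5:15])  # 40 px
        p = self._mask((50, 50), np.s_[5:9, 5:10])  # 20 of them
        out = removal_outcome(p, t, np.zeros((50, 50), bool))
        assert out.category == "partial"
        assert out.fraction_removed == pytest.approx(0.5)

    def test_empty_truth_is_none_present(self):
        p = self._mask((50, 50), np.s_[5:9, 5:10])
        out = removal_outcome(p, np.zeros((50, 50), bool), np.zeros((50, 50), bool))
        assert out.category == "none_present"

    def test_false_positive_inside_lung_detected(self):
        lung = self._mask((50, 50), np.s_[20:40, 10:40])
        t = self._mask((50, 50), np.s_[2:6, 2:12])
        p = t | self._mask((50, 50), np.s_[25:28, 20:23])
        assert removal_outcome(p, t, lung).inpainted_in_lung

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            removal_outcome(np.zeros((4, 4), bool), np.zeros((5, 5), bool))
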