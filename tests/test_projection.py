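import numpy as np
import pytest

from cxrqc.projection import (FEATURE_LENGTH, ProjectionModel,
                              consistency_check, extract_projection_features,
                              header_token_stats, parse_series_description,
                              predict_projection, train_projection_model)
from cxrqc.synthetic import DatasetConfig, generate_dataset
from .conftest import windowed


@pytest.fixture(scope="module")
def trained():
    recs, _ = generate_dataset(
        120, DatasetConfig(pad_prob=0.0, collim_prob=0.0, rotation_prob=0.0,
                           text_prob=0.0), seed=55)
    images = [windowed(r) for r, t in recs]
    labels = [t["projection"] for r, t in recs]
    model = train_projection_model(images[:80], labels[:80], seed=3)
    return model, images[80:], labels[80:]


class TestFeatures:
    def test_deterministic(self, frontal_phantom):
        rec, _ = frontal_phantom
        a = extract_projection_features(rec.image)
        b = extract_projection_features(rec.image.copy())
        np.testing.assert_array_equal(a, b)

    def test_length_constant_across_resolutions(self, frontal_phantom):
        rec, _ = frontal_phantom
        small = rec.image[::2, ::2]
        assert extract_projection_features(rec.image).size == FEATURE_LENGTH
        assert extract_projection_features(small).size == FEATURE_LENGTH

    def test_frontal_symmetry_exceeds_lateral(self, frontal_phantom,
                                              lateral_phantom):
        f = extract_projection_features(frontal_phantom[0].image)
        l = extract_projection_features(lateral_phantom[0].image)
        sym_index = 32 * 32  # symmetry score follows the flattened pixels
        assert f[sym_index] > l[sym_index]


class TestTraining:
    def test_heldout_accuracy(self, trained):
        model, images, labels = trained
        calls = [predict_projection(model, im) for im in images]
        acc = np.mean([c.label == lb for c, lb in zip(calls, labels)])
        assert acc >= 0.95

    def test_retraining_reproduces_coefficients(self, trained):
        recs, _ = generate_dataset(
            60, DatasetConfig(pad_prob=0.0, collim_prob=0.0, rotation_prob=0.0),
            seed=56)
        images = [windowed(r) for r, t in recs]
        labels = [t["projection"] for r, t in recs]
        m1 = train_projection_model(images, labels, seed=9)
        m2 = train_projection_model(images, labels, seed=9)
        np.testing.assert_array_equal(m1.estimator[-1].coef_, m2.estimator[-1].coef_)

    def test_label_permutation_destroys_signal(self):
        recs, _ = generate_dataset(
            160, DatasetConfig(pad_prob=0.0, collim_prob=0.0, rotation_prob=0.0,
                               text_prob=0.0), seed=57)
        images = [windowed(r) for r, t in recs]
        rng = np.random.default_rng(4)
        labels = list(rng.permutation([t["projection"] for r, t in recs]))
        model = train_projection_model(images[:120], labels[:120], seed=4)
        acc = np.mean([predict_projection(model, im).label == lb
                       for im, lb in zip(images[120:], labels[120:])])
        assert 0.25 <= acc <= 0.75

    def test_single_class_rejected(self, frontal_phantom):
        img = frontal_phantom[0].image
        with pytest.raises(ValueError):
            train_projection_model([img] * 60, ["frontal"] * 60, seed=0)

    def test_model_roundtrip_through_file(self, trained, tmp_path):
        model, images, _ = trained
        path = model.save(tmp_path / "proj.joblib")
        loaded = ProjectionModel.load(path)
        assert loaded.predict_score(images[0]) == model.predict_score(images[0])


class TestPredict:
    def test_threshold_limits(self, trained):
        model, images, _ = trained
        assert predict_projection(model, images[0], threshold=0.0).label == "frontal"
        assert predict_projection(model, images[0], threshold=1.0 + 1e-9).label == "lateral"

    def test_score_invariant_to_padding_stripped_by_geometry(self, trained):
        from cxrqc.geometry import detect_border_crop
        model, images, _ = trained
        img = images[0]
        padded = np.pad(img, 12, constant_values=0.0)
        box = detect_border_crop(padded)
        np.testing.assert_allclose(model.predict_score(box.apply(padded)),
                                   model.predict_score(img), atol=1e-9)


class TestHeaderParsing:
    @pytest.mark.parametrize("text,expected", [
        ("CHEST PA", "frontal"),
        ("chest ap erect", "frontal"),
        ("XR CHEST", "absent"),
        (None, "absent"),
        ("CHEST LAT", "lateral"),
        ("PA AND LATERAL", "lateral"),  # lateral precedence
        ("LL VIEW", "lateral"),
    ])
    def test_token_match(self, text, expected):
        assert parse_series_description(text).declared == expected

    def test_token_coverage_counts(self):
        descs = ["CHEST PA"] * 30 + ["CHEST LAT"] * 30 + ["XR CHEST"] * 40
        frac, n = header_token_stats(descs)
        assert frac == pytest.approx(0.60)
        assert n == 60


class TestConsistency:
    def _call(self, label, score):
        from cxrqc.projection import ProjectionCall
        return ProjectionCall(label=label, score=score, threshold_used=0.5)

    def test_agreement_passes(self):
        d = parse_series_description("CHEST PA")
        assert consistency_check(d, self._call("frontal", 0.9)).action == "pass"

    def test_disagreement_flags(self):
        d = parse_series_description("CHEST PA")
        r = consistency_check(d, self._call("lateral", 0.2))
        assert r.action == "flag_for_review"
        assert r.reasons == ["metadata_mismatch"]

    def test_absent_declaration_passes(self):
        d = parse_series_description("XR CHEST")
        assert consistency_check(d, self._call("lateral", 0.1)).action == "pass"
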