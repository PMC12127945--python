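import numpy as np
import pytest

from cxrqc.geometry import upright_score
from cxrqc.synthetic import (DatasetConfig, PhantomSpec, TextItem,
                             generate_dataset, generate_phantom)


class TestPhantom:
    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(seed=201, blur_sigma=0.7, pad_width=6,
                           collim_widths=(5, 0, 9, 0),
                           text_items=[TextItem("PA", 10, 12)])
        a, _ = generate_phantom(spec)
        b, _ = generate_phantom(spec)
        np.testing.assert_array_equal(a.image, b.image)

    def test_frontal_more_mirror_symmetric_than_lateral(self):
        f, _ = generate_phantom(PhantomSpec(projection="frontal", seed=202))
        l, _ = generate_phantom(PhantomSpec(projection="lateral", seed=202))
        def sym(img):
            return -np.mean(np.abs(img - img[:, ::-1]))
        assert sym(f.image) > sym(l.image)

    def test_padding_truth_box(self):
        rec, truth = generate_phantom(PhantomSpec(seed=203, pad_width=10))
        nrows, ncols = rec.image.shape
        assert truth["crop_box"].as_tuple() == (10, nrows - 10, 10, ncols - 10)
        assert np.all(rec.image[:10] == 0.0)

    def test_truth_masks_consistent_with_image(self):
        # independent pixel counting: every truth text pixel is brighter than
        # the anatomy around it, and lung pixels are darker than the body
        spec = PhantomSpec(seed=204, text_items=[TextItem("LAT", 8, 8)])
        rec, truth = generate_phantom(spec)
        tm, lm = truth["text_mask"], truth["lung_mask"]
        assert rec.image[tm].min() > rec.image[~tm].mean()
        assert rec.image[lm].mean() < rec.image[~lm & (rec.image > 0.1)].mean()

    def test_rotation_applied_to_image_and_truth(self):
        spec0 = PhantomSpec(seed=205, text_items=[TextItem("R", 8, 8)])
        spec90 = PhantomSpec(seed=205, rotation=90,
                             text_items=[TextItem("R", 8, 8)])
        r0, t0 = generate_phantom(spec0)
        r90, t90 = generate_phantom(spec90)
        np.testing.assert_array_equal(np.rot90(r0.image, 1), r90.image)
        np.testing.assert_array_equal(np.rot90(t0["text_mask"], 1),
                                      t90["text_mask"])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(collim_widths=(0, 0, 120, 0))  # >45% of 224 cols
        with pytest.raises(ValueError):
            PhantomSpec(text_items=[TextItem("PA", 250, 5)])  # outside frame
        with pytest.raises(ValueError):
            PhantomSpec(rotation=45)


class TestDataset:
    def test_seeded_missing_metadata_count(self):
        cfg = DatasetConfig(missing_metadata_rate=0.1)
        _, table = generate_dataset(100, cfg, seed=301)
        strat = table[["manufacturer", "deviation_index", "sex", "age",
                       "ethnicity"]]
        n_missing = int(strat.isna().any(axis=1).sum())
        assert 4 <= n_missing <= 18  # binomial(100, 0.1), seeded and stable
        _, again = generate_dataset(100, cfg, seed=301)
        assert int(again[["manufacturer", "deviation_index", "sex", "age",
                          "ethnicity"]].isna().any(axis=1).sum()) == n_missing

    def test_perfect_text_class_correlation(self):
        cfg = DatasetConfig(text_prob=1.0, text_class_correlation=1.0,
                            side_marker_prob=0.0, collim_prob=0.0)
        recs, table = generate_dataset(40, cfg, seed=302)
        for (rec, truth), proj in zip(recs, table["projection"]):
            tokens = [t.text for t in truth["spec"].text_items]
            expected = cfg.frontal_token if proj == "frontal" else cfg.lateral_token
            assert tokens == [expected]

    def test_two_manufacturer_intensity_shift(self):
        cfg = DatasetConfig(pad_prob=0.0, collim_prob=0.0, rotation_prob=0.0,
                            missing_metadata_rate=0.0)
        recs, table = generate_dataset(60, cfg, seed=303)
        means = np.array([rec.image.mean() for rec, _ in recs])
        v = table["manufacturer"].values
        from cxrqc.intensity import standardized_mean_difference
        smd = standardized_mean_difference(means[v == "Vendor A"],
                                           means[v == "Vendor B"])
        assert smd > 0.5

    def test_fixture_directory_layout(self, tmp_path):
        generate_dataset(3, DatasetConfig(), seed=304, out_dir=tmp_path)
        assert len(list((tmp_path / "dicom").glob("*.dcm"))) == 3
        assert (tmp_path / "curation.csv").exists()
        assert len(list((tmp_path / "truth").glob("*_text_mask.png"))) == 3

    def test_clean_dataset_passes_pipeline_without_flags(self, tmp_path):
        from cxrqc.config import PipelineConfig
        from cxrqc.pipeline import run_pipeline
        cfg = DatasetConfig(pad_prob=0.0, collim_prob=0.0, rotation_prob=0.0,
                            missing_metadata_rate=0.0, jewelry_prob=0.0)
        generate_dataset(12, cfg, seed=305, out_dir=tmp_path)
        report = run_pipeline(tmp_path / "dicom", PipelineConfig())
        assert (report.image_table["action"] == "pass").all()
        assert report.flagged == []
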