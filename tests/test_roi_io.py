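import numpy as np
import pandas as pd
import pytest

from metabnet.roi_io import (
    AtlasDefinition,
    ZeroVarianceWarning,
    default_atlas,
    extract_roi_means,
    load_atlas,
    read_roi_table,
    write_roi_table,
)

from conftest import make_table


class TestAtlas:
    def test_bundled_atlas_has_90_regions(self, atlas):
        assert atlas.n_rois == 90
        assert len(set(atlas.abbreviations)) == 90

    def test_hemisphere_split_is_45_45(self, atlas):
        left, right = atlas.split_hemispheres()
        assert left.n_rois == 45
        assert right.n_rois == 45
        # homologous pairing: same base abbreviation on both sides
        strip = lambda s: s.rsplit(".", 1)[0]  # noqa: E731
        assert [strip(a) for a in left.abbreviations] == [
            strip(a) for a in right.abbreviations
        ]

    def test_duplicate_roi_id_rejected_with_id(self, tmp_path):
        p = tmp_path / "atlas.csv"
        p.write_text(
            "roi_id,abbreviation\n1,A.L\n1,B.R\n"
        )
        with pytest.raises(ValueError, match="1"):
            load_atlas(p)

    def test_hemisphere_parsed_from_suffix(self, tmp_path):
        p = tmp_path / "atlas.csv"
        p.write_text("roi_id,abbreviation\n1,FOO.L\n2,FOO.R\n")
        a = load_atlas(p)
        assert list(a.entries["hemisphere"]) == ["L", "R"]

    def test_unknown_hemisphere_code_rejected(self):
        df = pd.DataFrame({
            "roi_id": [1, 2], "abbreviation": ["A", "B"],
            "name": ["a", "b"], "hemisphere": ["L", "X"],
        })
        with pytest.raises(ValueError, match="X"):
            AtlasDefinition(df)


class TestExtractRoiMeans:
    @pytest.fixture()
    def tiny_atlas(self):
        return AtlasDefinition(pd.DataFrame({
            "roi_id": [1, 2, 3, 4],
            "abbreviation": ["A.L", "A.R", "B.L", "B.R"],
            "name": list("abcd"),
            "hemisphere": ["L", "R", "L", "R"],
        }))

    def test_constant_image_gives_constant_means(self, tiny_atlas):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 5, size=(6, 6, 6))
        for roi in tiny_atlas.roi_ids:
            labels.flat[roi] = roi  # ensure every label present
        image = np.full_like(labels, 3.5, dtype=float)
        means = extract_roi_means(image, labels, tiny_atlas)
        assert np.allclose(means, 3.5)

    def test_label_valued_image_matches_voxel_loop_oracle(self, tiny_atlas):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 5, size=(8, 8, 8))
        image = rng.normal(size=labels.shape)
        means = extract_roi_means(image, labels, tiny_atlas)
        # oracle: explicit per-label mean by voxel loop
        for k, roi in enumerate(tiny_atlas.roi_ids):
            vals = [
                image[i, j, l]
                for i in range(8) for j in range(8) for l in range(8)
                if labels[i, j, l] == roi
            ]
            assert means[k] == pytest.approx(np.mean(vals))
        # and when the image equals the label value, mean i = roi_id i
        means2 = extract_roi_means(labels.astype(float), labels, tiny_atlas)
        assert np.allclose(means2, tiny_atlas.roi_ids)

    def test_missing_label_named_in_error(self, tiny_atlas):
        labels = np.ones((4, 4, 4), dtype=int)  # only label 1 present
        with pytest.raises(ValueError, match="2"):
            extract_roi_means(np.zeros((4, 4, 4)), labels, tiny_atlas)

    def test_shape_mismatch_rejected(self, tiny_atlas):
        with pytest.raises(ValueError, match="shape"):
            extract_roi_means(np.zeros((3, 3, 3)), np.zeros((4, 4, 4), dtype=int), tiny_atlas)

    def test_global_mean_normalization(self, tiny_atlas):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 5, size=(6, 6, 6))
        image = rng.uniform(1, 2, size=labels.shape)
        raw = extract_roi_means(image, labels, tiny_atlas)
        norm = extract_roi_means(image, labels, tiny_atlas, normalize="global-mean")
        gm = image[labels > 0].mean()
        assert np.allclose(norm, raw / gm)
        with pytest.raises(ValueError, match="normalization"):
            extract_roi_means(image, labels, tiny_atlas, normalize="zscore")

    def test_nibabel_image_inputs_accepted(self, tiny_atlas):
        nib = pytest.importorskip("nibabel")
        rng = np.random.default_rng(2)
        labels = rng.integers(1, 5, size=(5, 5, 5))
        image = rng.normal(size=(5, 5, 5))
        img = nib.Nifti1Image(image, np.eye(4))
        lab = nib.Nifti1Image(labels.astype(np.int16), np.eye(4))
        assert np.allclose(
            extract_roi_means(img, lab, tiny_atlas),
            extract_roi_means(image, labels, tiny_atlas),
        )


class TestRoiTable:
    def test_round_trip_identity(self, tmp_path, atlas, small_cohort):
        table = small_cohort.tables["HC"]
        p = tmp_path / "hc.csv"
        write_roi_table(table, p)
        back = read_roi_table(p, atlas)
        assert back.roi_names == table.roi_names
        assert np.allclose(back.signals, table.signals)
        assert list(back.data["group"]) == list(table.data["group"])

    def test_permuted_columns_reordered_to_atlas(self, tmp_path, atlas, small_cohort):
        table = small_cohort.tables["AD"]
        df = table.data.copy()
        cols = list(df.columns)
        roi_cols = cols[4:]
        permuted = df[cols[:4] + roi_cols[::-1]]
        p = tmp_path / "ad.csv"
        permuted.to_csv(p, index=False)
        back = read_roi_table(p, atlas)
        assert back.roi_names == atlas.abbreviations
        # oracle: values must match after explicit column lookup
        for name in ("MTG.R", "PreCG.L", "ITG.R"):
            assert np.allclose(
                back.data[name].to_numpy(), table.data[name].to_numpy()
            )

    def test_zero_variance_roi_flagged_with_warning(self):
        sig = np.random.default_rng(0).normal(size=(8, 3))
        sig[:, 1] = 7.0
        table = make_table(sig)
        with pytest.warns(ZeroVarianceWarning, match="ROI1"):
            flat = table.flag_zero_variance()
        assert flat == ["ROI1"]

    def test_missing_covariate_column_rejected(self, tmp_path, atlas, small_cohort):
        df = small_cohort.tables["HC"].data.drop(columns=["age"])
        p = tmp_path / "bad.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="age"):
            read_roi_table(p, atlas)

    def test_non_numeric_signals_rejected(self):
        df = pd.DataFrame({
            "subject_id": ["a", "b", "c", "d", "e"],
            "group": "G", "age": 60.0, "sex": 0,
            "ROI0": ["x", "y", "z", "w", "v"],
        })
        with pytest.raises(ValueError, match="ROI0"):
            from metabnet.roi_io import RoiSignalTable
            RoiSignalTable(df, roi_names=["ROI0"])
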