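"""Synthetic fixtures and the data-preparation pipeline."""

import numpy as np
import pytest

import capgan as cg


class TestPhantoms:
    def test_count_shape_dtype(self):
        spec = cg.PhantomSpec(image_size=32, seed=1)
        imgs, manifest = cg.generate_phantoms(10, spec)
        assert imgs.shape == (10, 32, 32) and imgs.dtype == np.uint8
        assert len(manifest) == 10

    def test_seeded_determinism(self):
        spec = cg.PhantomSpec(image_size=16, seed=5)
        a, _ = cg.generate_phantoms(5, spec)
        b, _ = cg.generate_phantoms(5, spec)
        assert np.array_equal(a, b)

    def test_noiseless_single_shell_two_levels(self):
        spec = cg.PhantomSpec(image_size=32, n_shells=1, intensity_levels=(150,),
                              noise_sd=0.0, seed=2)
        imgs, _ = cg.generate_phantoms(3, spec)
        for img in imgs:
            assert set(np.unique(img)) == {0, 150}

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            cg.PhantomSpec(n_shells=3, intensity_levels=(10, 20))
        with pytest.raises(ValueError):
            cg.PhantomSpec(intensity_levels=(300, 20, 10))

    def test_write_and_reload(self, tmp_path):
        spec = cg.PhantomSpec(image_size=16, seed=3)
        imgs, _ = cg.generate_phantoms(4, spec, out_dir=tmp_path / "ph")
        loaded, manifest = cg.load_image_dir(tmp_path / "ph")
        assert np.array_equal(loaded, imgs)
        assert list(manifest.columns) == ["path", "center_row", "center_col", "label"]


class TestLesionDataset:
    def test_default_counts_and_imbalance(self):
        records = cg.generate_lesion_dataset(seed=0)
        assert len(records) == 325
        assert sum(r.label == "malignant" for r in records) == 75

    def test_seeded_determinism(self):
        a = cg.generate_lesion_dataset(5, 5, seed=3)
        b = cg.generate_lesion_dataset(5, 5, seed=3)
        assert all(np.array_equal(x.image, y.image) and x.center == y.center
                   for x, y in zip(a, b))

    def test_centers_inside_bounds(self, lesion_records):
        for r in lesion_records:
            assert 0 <= r.center[0] < r.image.shape[0]
            assert 0 <= r.center[1] < r.image.shape[1]

    def test_zero_separability_classes_indistinguishable(self):
        """With the separability knob at 0 the two labels are drawn from one
        distribution: a classifier should sit near chance AUC."""
        from sklearn.metrics import roc_auc_score
        records = cg.generate_lesion_dataset(75, 250, seed=1, separability=0.0)
        train, test = cg.split_dataset(records, 0.8, seed=1)
        params = cg.FeatureParams()
        X_tr = cg.extract_features(np.stack([cg.roi_crop(r) for r in train]), params)
        y_tr = np.array([r.label == "malignant" for r in train], int)
        X_te = cg.extract_features(np.stack([cg.roi_crop(r) for r in test]), params)
        y_te = np.array([r.label == "malignant" for r in test], int)
        clf = cg.train_eval_classifier(X_tr, y_tr, seed=0)
        auc = roc_auc_score(y_te, clf.predict_proba(X_te)[:, 1])
        assert abs(auc - 0.5) < 0.2


class TestSliceVolume:
    def test_depth_slices_in_order(self, rng):
        vol = rng.normal(size=(7, 5, 5))
        slices = cg.slice_volume(vol)
        assert len(slices) == 7
        assert np.array_equal(np.stack(slices), vol)

    def test_empty_and_wrong_rank_rejected(self):
        with pytest.raises(ValueError):
            cg.slice_volume(np.zeros((0, 4, 4)))
        with pytest.raises(ValueError):
            cg.slice_volume(np.zeros((4, 4)))

    def test_nifti_path(self, tmp_path, rng):
        nib = pytest.importorskip("nibabel")
        vol = rng.integers(0, 255, size=(6, 6, 4)).astype(np.int16)
        path = tmp_path / "vol.nii"
        nib.save(nib.Nifti1Image(vol, np.eye(4)), path)
        slices = cg.slice_volume(path)
        assert len(slices) == 4
        assert np.array_equal(slices[0], vol[:, :, 0])


class TestRoiCrop:
    def test_shape_and_center_pixel(self, lesion_records):
        rec = lesion_records[0]
        patch = cg.roi_crop(rec, side=35)
        assert patch.shape == (35, 35)
        assert patch[17, 17] == rec.image[rec.center]

    def test_corner_center_reflect_padded(self):
        img = np.arange(64 * 64, dtype=np.uint8).reshape(64, 64)
        rec = cg.LesionRecord(image=img, center=(0, 0), label="benign")
        patch = cg.roi_crop(rec, side=35)
        assert patch.shape == (35, 35)
        assert patch[17, 17] == img[0, 0]

    def test_side_larger_than_image_rejected(self, lesion_records):
        with pytest.raises(ValueError):
            cg.roi_crop(lesion_records[0], side=100)

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError):
            cg.LesionRecord(image=np.zeros((10, 10)), center=(12, 3), label="benign")


class TestAugment:
    def test_k_outputs_same_size(self, phantoms16):
        images, _ = phantoms16
        out = cg.augment(images[0], cg.AugmentationConfig(seed=1), k=10)
        assert len(out) == 10
        assert all(o.shape == images[0].shape for o in out)

    def test_zero_magnitude_gives_exact_copies(self, phantoms16):
        images, _ = phantoms16
        cfg = cg.AugmentationConfig(rotation_deg=0, translation_px=0,
                                    scale_range=(1.0, 1.0), noise_sd=0, seed=1)
        out = cg.augment(images[0], cfg, k=3)
        assert all(np.array_equal(o, images[0]) for o in out)

    def test_seeded_determinism(self, phantoms16):
        images, _ = phantoms16
        cfg = cg.AugmentationConfig(seed=9)
        a = cg.augment(images[0], cfg, k=4)
        b = cg.augment(images[0], cfg, k=4)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestExpansion:
    @pytest.mark.parametrize("n,k", [(3, 2), (5, 0), (2, 20)])
    def test_count_law(self, n, k, phantoms16):
        images, _ = phantoms16
        out = cg.expand_with_originals(images[:n], cg.AugmentationConfig(seed=2), k=k, seed=2)
        assert len(out) == n * (k + 1)
        assert np.array_equal(out[:n], images[:n])  # originals first

    def test_study_bookkeeping(self, phantoms16):
        images, _ = phantoms16
        out = cg.expand_with_originals(np.repeat(images, 5, axis=0)[:260],
                                       cg.AugmentationConfig(seed=0), k=20, seed=0)
        assert len(out) == 5460


class TestSplit:
    def test_study_split_counts(self):
        records = cg.generate_lesion_dataset(seed=4)
        train, test = cg.split_dataset(records, train_fraction=0.8, seed=4)
        assert len(train) == 260 and len(test) == 65
        assert sum(r.label == "malignant" for r in train) == 60
        assert sum(r.label == "malignant" for r in test) == 15

    def test_half_split_tiny(self):
        records = cg.generate_lesion_dataset(2, 2, seed=0)
        train, test = cg.split_dataset(records, train_fraction=0.5, seed=0)
        assert sum(r.label == "malignant" for r in train) == 1
        assert sum(r.label == "malignant" for r in test) == 1

    def test_partition_property(self):
        records = cg.generate_lesion_dataset(10, 30, seed=2)
        train, test = cg.split_dataset(records, 0.8, seed=2)
        ids = lambda recs: sorted(id(r) for r in recs)
        assert len(train) + len(test) == len(records)
        assert set(ids(train)).isdisjoint(ids(test))
        assert sorted(ids(train) + ids(test)) == ids(records)

    def test_small_class_rejected(self):
        records = cg.generate_lesion_dataset(1, 10, seed=0)
        with pytest.raises(ValueError):
            cg.split_dataset(records, 0.8, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            cg.split_dataset([], 1.0)
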