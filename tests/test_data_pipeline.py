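"""Database registry, split schemes, patch sampling, augmentation, I/O."""

import numpy as np
import pytest
from scipy import stats

from fundusnet.data_pipeline import (
    REGISTRY,
    AugmentParams,
    apply_augmentation,
    augment,
    fov_fallback,
    load_database,
    make_splits,
    prepare_samples,
    reduce_training_set,
    sample_batch,
    save_database,
    synthetic_dataset_spec,
)


class TestRegistry:
    @pytest.mark.parametrize("name,n,factor,patch,batch,scheme", [
        ("drive", 40, 1, 168, 50, "fixed_drive"),
        ("stare", 20, 1, 168, 50, "fourfold"),
        ("hrf", 45, 4, 400, 15, "fourfold"),
        ("chase_db1", 28, 2, 200, 40, "fourfold"),
    ])
    def test_protocol_constants(self, name, n, factor, patch, batch, scheme):
        db = REGISTRY[name]
        assert (db.n_images, db.resample_factor, db.patch_size,
                db.batch_size, db.split_scheme) == (n, factor, patch, batch, scheme)

    def test_image_shapes(self):
        assert REGISTRY["drive"].image_shape == (584, 565)
        assert REGISTRY["hrf"].image_shape == (2336, 3504)


class TestSplits:
    def test_drive_sizes(self):
        plan = make_splits(REGISTRY["drive"], 0, seed=1)
        assert (len(plan.train), len(plan.validation), len(plan.test)) == (16, 4, 20)
        with pytest.raises(ValueError):
            make_splits(REGISTRY["drive"], 1, seed=1)

    @pytest.mark.parametrize("fold", range(4))
    def test_stare_fold_sizes(self, fold):
        plan = make_splits(REGISTRY["stare"], fold, seed=3)
        assert (len(plan.train), len(plan.validation), len(plan.test)) == (11, 4, 5)

    @pytest.mark.parametrize("fold", range(4))
    def test_chase_fold_sizes(self, fold):
        plan = make_splits(REGISTRY["chase_db1"], fold, seed=3)
        assert (len(plan.train), len(plan.validation), len(plan.test)) == (17, 4, 7)

    def test_hrf_fold_sizes(self):
        sizes = [len(make_splits(REGISTRY["hrf"], f, seed=3).test)
                 for f in range(4)]
        assert sorted(sizes) == [11, 11, 11, 12]
        plan = make_splits(REGISTRY["hrf"], 0, seed=3)
        assert len(plan.validation) == 7
        assert len(plan.train) + len(plan.validation) + len(plan.test) == 45

    @pytest.mark.parametrize("name", ["stare", "hrf", "chase_db1"])
    def test_fourfold_tests_cover_every_image_once(self, name):
        db = REGISTRY[name]
        tests = [make_splits(db, f, seed=7).test for f in range(4)]
        flat = [i for t in tests for i in t]
        assert len(flat) == db.n_images
        assert len(set(flat)) == db.n_images

    def test_partition_and_determinism(self):
        db = REGISTRY["stare"]
        a = make_splits(db, 2, seed=9)
        b = make_splits(db, 2, seed=9)
        assert (a.train, a.validation, a.test) == (b.train, b.validation, b.test)
        c = make_splits(db, 2, seed=10)
        assert (a.train, a.validation, a.test) != (c.train, c.validation, c.test)
        union = set(a.train) | set(a.validation) | set(a.test)
        assert len(union) == db.n_images

    def test_invalid_fold(self):
        with pytest.raises(ValueError):
            make_splits(REGISTRY["stare"], 4, seed=0)


class TestReduction:
    def test_reduce_keeps_val_and_test(self):
        plan = make_splits(REGISTRY["drive"], 0, seed=1)
        red = reduce_training_set(plan, 8, seed=2)
        assert len(red.train) == 8
        assert set(red.train) <= set(plan.train)
        assert red.validation == plan.validation
        assert red.test == plan.test

    def test_identity_and_errors(self):
        plan = make_splits(REGISTRY["stare"], 0, seed=1)
        assert reduce_training_set(plan, len(plan.train), seed=0).train == plan.train
        with pytest.raises(ValueError):
            reduce_training_set(plan, 0, seed=0)
        with pytest.raises(ValueError):
            reduce_training_set(plan, 99, seed=0)

    def test_reduce_to_one(self):
        plan = make_splits(REGISTRY["hrf"], 1, seed=1)
        red = reduce_training_set(plan, 1, seed=5)
        assert len(red.train) == 1 and red.test == plan.test


class TestSampling:
    def _data(self, n=3, size=40):
        rng = np.random.default_rng(0)
        imgs = [rng.uniform(-1, 1, (size, size)).astype(np.float32)
                for _ in range(n)]
        labs = [rng.random((size, size)) > 0.8 for _ in range(n)]
        wgts = [np.ones((size, size), np.float32) for _ in range(n)]
        return imgs, labs, wgts

    def test_shapes_and_alignment(self):
        db = synthetic_dataset_spec(3, 40, patch_size=16, batch_size=5)
        imgs, labs, wgts = self._data()
        x, y, w = sample_batch(imgs, labs, wgts, db, rng=4)
        assert x.shape == (5, 1, 16, 16)
        assert y.shape == w.shape == (5, 16, 16)
        assert y.dtype == bool

    def test_determinism(self):
        db = synthetic_dataset_spec(3, 40, patch_size=16, batch_size=5)
        imgs, labs, wgts = self._data()
        x1, y1, w1 = sample_batch(imgs, labs, wgts, db, rng=11)
        x2, y2, w2 = sample_batch(imgs, labs, wgts, db, rng=11)
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(y1, y2)

    def test_patch_too_large(self):
        db = synthetic_dataset_spec(1, 8, patch_size=16, batch_size=2)
        imgs, labs, wgts = self._data(n=1, size=8)
        with pytest.raises(ValueError, match="patch"):
            sample_batch(imgs, labs, wgts, db, rng=0)

    def test_positions_uniform_chi2(self):
        """Top-left corners are uniform over the admissible grid."""
        size, p = 12, 5  # 8x8 = 64 admissible corners
        img = np.arange(size ** 2, dtype=np.float32).reshape(size, size)
        db = synthetic_dataset_spec(1, size, patch_size=p, batch_size=50)
        rng = np.random.default_rng(123)
        counts = np.zeros((8, 8))
        for _ in range(60):
            x, _, _ = sample_batch([img], [img > -1], [img * 0 + 1], db, rng)
            for k in range(x.shape[0]):
                v = x[k, 0, 0, 0]  # encodes the corner: v = top*size + left
                top, left = divmod(int(v), size)
                counts[top, left] += 1
        chi2 = stats.chisquare(counts.ravel())
        assert chi2.pvalue > 1e-3


class TestAugmentation:
    def _triple(self, size=24):
        rng = np.random.default_rng(1)
        img = rng.uniform(-1, 1, (size, size)).astype(np.float32)
        lab = rng.random((size, size)) > 0.7
        wgt = rng.uniform(1, 3, (size, size)).astype(np.float32)
        return img, lab, wgt

    def test_zero_magnitudes_identity(self):
        img, lab, wgt = self._triple()
        out_i, out_l, out_w = apply_augmentation(img, lab, wgt, AugmentParams())
        np.testing.assert_allclose(out_i, img, atol=1e-5)
        np.testing.assert_array_equal(out_l, lab)
        np.testing.assert_allclose(out_w, wgt, atol=1e-5)

    def test_labels_stay_binary_and_shape_preserved(self):
        img, lab, wgt = self._triple()
        rng = np.random.default_rng(8)
        for _ in range(5):
            out_i, out_l, out_w = augment(img, lab, wgt, rng)
            assert out_i.shape == img.shape
            assert out_l.dtype == bool
            assert set(np.unique(out_l)) <= {False, True}
            assert np.all(out_w >= 1.0 - 1e-6)

    def test_zoom_preserves_shape(self):
        img, lab, wgt = self._triple()
        params = AugmentParams(zoom=1.5)
        out_i, out_l, _ = apply_augmentation(img, lab, wgt, params)
        assert out_i.shape == img.shape and out_l.shape == lab.shape

    def test_seeded_determinism(self):
        img, lab, wgt = self._triple()
        a = augment(img, lab, wgt, np.random.default_rng(5))
        b = augment(img, lab, wgt, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


def test_database_roundtrip(tmp_path, phantom_batch):
    root = save_database(phantom_batch, tmp_path / "db")
    loaded = load_database(root)
    assert len(loaded) == len(phantom_batch)
    for orig, back in zip(phantom_batch, loaded):
        np.testing.assert_array_equal(orig.rgb, back.rgb)
        np.testing.assert_array_equal(orig.fov, back.fov)
        np.testing.assert_array_equal(orig.annotation, back.annotation)
        fg = orig.annotation
        np.testing.assert_allclose(orig.diameter_map[fg],
                                   back.diameter_map[fg], atol=1e-6)


def test_fov_fallback_recovers_disc(phantom):
    est = fov_fallback(phantom.rgb)
    true = phantom.fov
    iou = (est & true).sum() / (est | true).sum()
    assert iou > 0.95


def test_prepare_samples_contract(phantom_batch):
    db = synthetic_dataset_spec(len(phantom_batch), 192, patch_size=64,
                                batch_size=4)
    prepared = prepare_samples(phantom_batch, db)
    assert set(prepared) == {s.image_id for s in phantom_batch}
    for values, label, weights in prepared.values():
        assert values.shape == label.shape == weights.shape
        assert values.min() >= -1.0 and values.max() <= 1.0
        assert np.all(weights >= 1.0)
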