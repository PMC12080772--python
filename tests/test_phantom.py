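import numpy as np
import pytest

from retcf.phantom import (FUNDUS_GRADES, OCT_CLASSES,
                           PhantomConfig, balance_by_oversampling,
                           generate_dataset, generate_fundus_phantom,
                           generate_oct_phantom, lesion_oracle)


def cfg(**kw):
    return PhantomConfig(**{"modality": "fundus", "image_size": 32, **kw})


class TestGenerators:
    def test_healthy_has_no_lesions(self):
        im = generate_fundus_phantom(cfg(grade="healthy"))
        assert all(v == 0 for v in im.lesion_counts.values())
        assert all(not m.any() for m in im.lesion_masks.values())

    def test_pixels_in_unit_range_and_shape(self):
        im = generate_fundus_phantom(cfg(grade="severe", subject_id=4))
        assert im.pixels.shape == (3, 32, 32)
        assert im.pixels.min() >= 0.0 and im.pixels.max() <= 1.0
        oct_im = generate_oct_phantom(cfg(modality="oct", grade="DME"))
        assert oct_im.pixels.shape == (1, 32, 32)

    def test_deterministic_given_seed(self):
        a = generate_fundus_phantom(cfg(grade="moderate", subject_id=3, seed=9))
        b = generate_fundus_phantom(cfg(grade="moderate", subject_id=3, seed=9))
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert a.lesion_counts == b.lesion_counts

    def test_same_subject_shares_anatomy_across_grades(self):
        healthy = generate_fundus_phantom(cfg(grade="healthy", subject_id=5, seed=2))
        severe = generate_fundus_phantom(cfg(grade="severe", subject_id=5, seed=2))
        assert healthy.meta["disc"] == severe.meta["disc"]
        # vessels/disc pixels identical outside lesion areas
        lesioned = np.zeros((32, 32), dtype=bool)
        for m in severe.lesion_masks.values():
            lesioned |= m
        from scipy.ndimage import binary_dilation
        keep = ~binary_dilation(lesioned, iterations=4)
        np.testing.assert_allclose(healthy.pixels[:, keep], severe.pixels[:, keep],
                                   atol=1e-6)

    def test_invalid_grade_and_size_rejected(self):
        with pytest.raises(ValueError, match="grade"):
            cfg(grade="terrible")
        with pytest.raises(ValueError, match="image_size"):
            cfg(image_size=16)
        with pytest.raises(ValueError, match="modality"):
            PhantomConfig(modality="xray")

    def test_moderate_counts_exceed_mild_for_every_type(self):
        """Monte-Carlo over the count distributions, 200 draws per grade."""
        sums = {"mild": {}, "moderate": {}}
        for grade in sums:
            for i in range(200):
                im = generate_fundus_phantom(cfg(grade=grade, subject_id=i, seed=1))
                for t, c in im.lesion_counts.items():
                    sums[grade][t] = sums[grade].get(t, 0) + c
        for t in sums["mild"]:
            assert sums["moderate"][t] > sums["mild"][t]

    def test_lesion_area_monotone_in_severity(self):
        means = []
        for grade in FUNDUS_GRADES:
            areas = []
            for i in range(100):
                im = generate_fundus_phantom(cfg(grade=grade, subject_id=i, seed=3))
                areas.append(sum(int(m.sum()) for m in im.lesion_masks.values()))
            means.append(np.mean(areas))
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestOctPhantom:
    def test_normal_has_no_lesions_and_flat_rpe(self):
        im = generate_oct_phantom(cfg(modality="oct", grade="normal"))
        assert all(v == 0 for v in im.lesion_counts.values())

    def test_drusen_elevates_rpe_boundary(self):
        vn, vd = [], []
        for i in range(100):
            n = generate_oct_phantom(cfg(modality="oct", grade="normal", subject_id=i))
            d = generate_oct_phantom(cfg(modality="oct", grade="drusen", subject_id=i))
            vn.append(np.var(n.meta["boundaries"][3]))
            vd.append(np.var(d.meta["boundaries"][3]))
        assert np.mean(vd) > np.mean(vn)
        assert np.mean(np.array(vd) > np.array(vn)) > 0.95

    def test_dme_has_cavities(self):
        im = generate_oct_phantom(cfg(modality="oct", grade="DME", subject_id=2))
        assert im.lesion_counts["cavity"] >= 1
        assert im.lesion_masks["cavity"].any()


class TestDataset:
    def test_subjectwise_split_and_counts(self):
        ds = generate_dataset(10, 2, (0.75, 0.15, 0.10), seed=0,
                              modality="fundus", image_size=32)
        assert len(ds.images) == 10 * len(FUNDUS_GRADES)
        for a in ("train", "val", "test"):
            for b in ("train", "val", "test"):
                if a != b:
                    assert not (ds.subjects(a) & ds.subjects(b))

    def test_images_of_one_subject_share_vessels(self):
        ds = generate_dataset(4, 2, (1.0, 0.0, 0.0), seed=0,
                              modality="fundus", image_size=32)
        by_subj = {}
        for im in ds.images:
            by_subj.setdefault(im.subject_id, []).append(im)
        two = next(v for v in by_subj.values() if len(v) == 2)
        assert two[0].meta["disc"] == two[1].meta["disc"]

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            generate_dataset(4, 1, (0.5, 0.2, 0.2), seed=0, image_size=32)

    def test_oversampling_equalizes_train_classes(self):
        ds = generate_dataset(12, 1, (0.75, 0.15, 0.10), seed=0,
                              modality="oct", image_size=32,
                              classes=("normal", "DME"))
        # unbalance by dropping some train entries of one class
        images, splits = [], []
        dropped = 0
        for im, s in zip(ds.images, ds.splits):
            if s == "train" and im.grade == "DME" and dropped < 5:
                dropped += 1
                continue
            images.append(im)
            splits.append(s)
        ds.images, ds.splits = images, splits
        before_val = len(ds.subset("val")) + len(ds.subset("test"))
        bal = balance_by_oversampling(ds)
        counts = bal.class_counts("train")
        assert len(set(counts.values())) == 1
        assert len(bal.subset("val")) + len(bal.subset("test")) == before_val
        # oversampled entries are pixel-identical duplicates
        train = bal.subset("train")
        ids = [id(im.pixels) for im in train]
        assert len(set(ids)) < len(ids)

    def test_balanced_input_unchanged(self):
        ds = generate_dataset(8, 1, (1.0, 0.0, 0.0), seed=0,
                              modality="oct", image_size=32,
                              classes=("normal", "DME"))
        bal = balance_by_oversampling(ds)
        assert len(bal.images) == len(ds.images)


class TestLesionOracle:
    def test_fidelity_on_generated_images(self):
        """Exact ground-truth recovery on >= 99% of 500 fundus phantoms."""
        ok = tot = 0
        for seed in range(4):
            for sid in range(25):
                for grade in FUNDUS_GRADES:
                    im = generate_fundus_phantom(cfg(grade=grade, subject_id=sid,
                                                     seed=seed))
                    ok += lesion_oracle(im.pixels, "fundus") == im.lesion_counts
                    tot += 1
        assert tot == 500
        assert ok / tot >= 0.99

    def test_fidelity_on_oct(self):
        ok = tot = 0
        for seed in range(2):
            for sid in range(25):
                for grade in OCT_CLASSES:
                    im = generate_oct_phantom(cfg(modality="oct", grade=grade,
                                                  subject_id=sid, seed=seed))
                    ok += lesion_oracle(im.pixels, "oct") == im.lesion_counts
                    tot += 1
        assert ok / tot >= 0.99

    def test_blank_image_counts_zero(self):
        counts = lesion_oracle(np.zeros((3, 32, 32), dtype=np.float32), "fundus")
        assert all(v == 0 for v in counts.values())

    def test_stamped_templates_are_counted(self):
        """Three manually stamped microaneurysm dots on a plain background."""
        from retcf.phantom import _stamp
        img = np.full((3, 32, 32), 0.0, dtype=np.float32)
        yy, xx = np.mgrid[0:32, 0:32].astype(np.float32)
        fov = np.sqrt((yy - 16) ** 2 + (xx - 16) ** 2) <= 0.47 * 32
        for c, v in enumerate((0.72, 0.42, 0.13)):
            img[c] = v * fov
        mask = np.zeros((32, 32), dtype=bool)
        for (cy, cx) in ((12, 12), (20, 10), (16, 22)):
            _stamp(img, mask, cy, cx, 1.1, (0.26, 0.045, 0.03))
        counts = lesion_oracle(np.clip(img, 0, 1), "fundus")
        assert counts["microaneurysm"] == 3
        assert counts["hemorrhage"] == 0

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="expects"):
            lesion_oracle(np.zeros((1, 32, 32)), "fundus")
        with pytest.raises(ValueError, match="expects"):
            lesion_oracle(np.zeros((3, 32, 32)), "oct")

    def test_mask_components_match_counts(self):
        from skimage.measure import label as cc_label
        im = generate_fundus_phantom(cfg(grade="severe", subject_id=1, seed=4))
        for t, m in im.lesion_masks.items():
            n_comp = cc_label(m, connectivity=2).max()
            assert n_comp == im.lesion_counts[t]
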