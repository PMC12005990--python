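"""Tests for normalization, augmentation, balancing, and splitting."""

import numpy as np
import pytest

from dcef.preprocessing import (
    BENIGN,
    MALIGNANT,
    LabeledImage,
    SplitPlan,
    augment,
    class_weights,
    crop_to_roi,
    flip_image,
    normalize_and_resize,
    read_manifest,
    rotate_image,
    smote_oversample,
    stratified_split,
    translate_image,
    undersample_majority,
    write_manifest,
)


def make_image(rng, label=BENIGN, size=(16, 16), sid="s0", with_mask=True):
    img = rng.random(size)
    mask = None
    if with_mask:
        mask = np.zeros(size, dtype=bool)
        mask[4:9, 5:10] = True
    return LabeledImage(image=img, label=label, roi_mask=mask, source_id=sid)


class TestNormalizeAndResize:
    def test_endpoint_values_map_to_unit_range(self):
        img = LabeledImage(
            image=np.array([[0.0, 255.0], [255.0, 0.0]]), label=0
        )
        out = normalize_and_resize(img, (2, 2))
        assert out.image.min() == pytest.approx(0.0)
        assert out.image.max() == pytest.approx(1.0)

    def test_constant_image_warns_and_zeroes(self):
        img = LabeledImage(image=np.full((4, 4), 9.0), label=0)
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_and_resize(img, (4, 4))
        assert np.all(out.image == 0.0)

    def test_downsampling_preserves_mean_of_ramp(self):
        ramp = np.tile(np.linspace(0, 1, 64), (64, 1)) * 255
        img = LabeledImage(image=ramp, label=0)
        out = normalize_and_resize(img, (32, 32))
        assert out.image.shape == (32, 32)
        assert out.image.mean() == pytest.approx(
            (ramp / 255).mean(), rel=0.01
        )

    def test_mask_resampled_nearest_stays_binary(self, rng):
        img = make_image(rng)
        out = normalize_and_resize(img, (8, 8))
        assert out.roi_mask.dtype == bool
        assert out.roi_mask.any()


class TestCropToRoi:
    def test_crop_contains_whole_mask(self, rng):
        img = make_image(rng, size=(32, 32))
        out = crop_to_roi(img, margin=0.25)
        assert out.roi_mask.sum() == img.roi_mask.sum()
        assert out.image.shape[0] < 32

    def test_no_mask_is_identity(self, rng):
        img = make_image(rng, with_mask=False)
        assert crop_to_roi(img) is img


class TestAugment:
    def test_flip_is_involution(self, rng):
        img = make_image(rng)
        twice = flip_image(flip_image(img))
        assert np.array_equal(twice.image, img.image)
        assert np.array_equal(twice.roi_mask, img.roi_mask)

    def test_zero_rotation_is_identity(self, rng):
        img = make_image(rng)
        out = rotate_image(img, 0.0)
        assert np.array_equal(out.image, img.image)

    def test_right_angle_rotations_are_exact(self, rng):
        img = make_image(rng)
        out = rotate_image(img, 180.0)
        assert np.array_equal(out.image, img.image[::-1, ::-1])

    def test_translate_there_and_back_restores_interior(self, rng):
        img = make_image(rng)
        out = translate_image(translate_image(img, (2, 3)), (-2, -3))
        # reflection padding corrupts only the border strip
        assert np.array_equal(out.image[4:-4, 4:-4], img.image[4:-4, 4:-4])

    def test_labels_sources_and_masks_preserved(self, rng):
        img = make_image(rng, label=MALIGNANT, sid="case_7")
        for variant in augment(img, ("rotate", "flip", "translate"), seed=3):
            assert variant.label == MALIGNANT
            assert variant.source_id == "case_7"
            assert variant.roi_mask is not None
            assert set(np.unique(variant.roi_mask)) <= {False, True}

    def test_deterministic_under_seed(self, rng):
        img = make_image(rng)
        a = augment(img, ("translate",), seed=5)
        b = augment(img, ("translate",), seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.image, y.image)

    def test_empty_ops_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            augment(make_image(rng), (), seed=0)


class TestSmote:
    def test_already_balanced_returns_no_rows(self, rng):
        x = rng.standard_normal((10, 4))
        out = smote_oversample(x, target_count=10, k_neighbors=3)
        assert out.shape == (0, 4)

    def test_rows_lie_on_neighbor_segments(self, rng):
        x = rng.standard_normal((5, 3))
        synth = smote_oversample(x, target_count=20, k_neighbors=3, seed=1)
        assert synth.shape == (15, 3)
        for row in synth:
            on_segment = False
            for i in range(5):
                for j in range(5):
                    if i == j:
                        continue
                    d = x[j] - x[i]
                    denom = float(d @ d)
                    if denom == 0:
                        continue
                    g = float((row - x[i]) @ d) / denom
                    if -1e-9 <= g <= 1 + 1e-9 and np.allclose(
                        row, x[i] + g * d, atol=1e-9
                    ):
                        on_segment = True
            assert on_segment

    def test_degenerate_identical_points(self):
        x = np.ones((4, 2))
        synth = smote_oversample(x, target_count=7, k_neighbors=2, seed=0)
        assert np.allclose(synth, 1.0)

    def test_too_few_minority_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="augmentation"):
            smote_oversample(rng.standard_normal((3, 2)), 10, k_neighbors=5)


class TestUndersample:
    def test_kept_count_and_membership(self, rng):
        items = list(range(20))
        kept = undersample_majority(items, 8, seed=4)
        assert len(kept) == 8
        assert set(kept) <= set(items)
        assert len(set(kept)) == 8

    def test_seed_reproducibility(self):
        items = list(range(30))
        assert undersample_majority(items, 10, seed=2) == undersample_majority(
            items, 10, seed=2
        )

    def test_target_above_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            undersample_majority([1, 2, 3], 5)


class TestClassWeights:
    def test_default_two_to_one_ratio(self):
        w = class_weights({BENIGN: 27, MALIGNANT: 68})
        assert w[BENIGN] / w[MALIGNANT] == pytest.approx(2.0)
        assert w[BENIGN] == pytest.approx(4 / 3)
        assert w[MALIGNANT] == pytest.approx(2 / 3)
        assert (w[BENIGN] + w[MALIGNANT]) / 2 == pytest.approx(1.0)

    def test_unit_ratio_gives_unit_weights(self):
        w = class_weights({BENIGN: 5, MALIGNANT: 5}, ratio=(1, 1))
        assert w == {BENIGN: 1.0, MALIGNANT: 1.0}

    def test_three_to_one_ratio(self):
        w = class_weights({BENIGN: 4, MALIGNANT: 12}, ratio=(3, 1))
        assert w[BENIGN] / w[MALIGNANT] == pytest.approx(3.0)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            class_weights({BENIGN: 0, MALIGNANT: 5})


def cohort(rng, n_benign, n_malignant):
    items = []
    for i in range(n_benign):
        items.append(make_image(rng, BENIGN, sid=f"b{i}", with_mask=False))
    for i in range(n_malignant):
        items.append(make_image(rng, MALIGNANT, sid=f"m{i}", with_mask=False))
    return items


class TestStratifiedSplit:
    def test_cohort_counts_reproduce_expected_test_split(self, rng):
        # 38 benign + 97 malignant at 50/20/30: test gets 11 and 29
        items = cohort(rng, 38, 97)
        train, val, test = stratified_split(items, SplitPlan(seed=0))
        test_labels = [it.label for it in test]
        assert test_labels.count(BENIGN) == 11
        assert test_labels.count(MALIGNANT) == 29
        assert len(train) + len(val) + len(test) == 135

    def test_all_train_fractions(self, rng):
        items = cohort(rng, 5, 5)
        train, val, test = stratified_split(
            items, SplitPlan(fractions=(1.0, 0.0, 0.0))
        )
        assert len(train) == 10 and not val and not test

    def test_balanced_hundred_gives_50_20_30(self, rng):
        items = cohort(rng, 50, 50)
        train, val, test = stratified_split(items, SplitPlan(seed=1))
        assert (len(train), len(val), len(test)) == (50, 20, 30)

    @pytest.mark.parametrize("seed", range(0, 200, 10))
    def test_partition_is_exact_across_seeds(self, rng, seed):
        items = cohort(rng, 9, 17)
        train, val, test = stratified_split(items, SplitPlan(seed=seed))
        ids = [it.source_id for it in train + val + test]
        assert sorted(ids) == sorted(it.source_id for it in items)
        assert len(set(ids)) == len(ids)

    def test_sources_never_straddle_splits(self, rng):
        # three images per source: all must land in the same split
        items = []
        for i in range(12):
            label = BENIGN if i < 5 else MALIGNANT
            for _ in range(3):
                items.append(
                    make_image(rng, label, sid=f"p{i}", with_mask=False)
                )
        train, val, test = stratified_split(items, SplitPlan(seed=3))
        sets = [
            {it.source_id for it in split} for split in (train, val, test)
        ]
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])

    def test_deterministic_under_seed(self, rng):
        items = cohort(rng, 10, 20)
        a = stratified_split(items, SplitPlan(seed=8))
        b = stratified_split(items, SplitPlan(seed=8))
        for sa, sb in zip(a, b):
            assert [x.source_id for x in sa] == [x.source_id for x in sb]


class TestManifestIO:
    def test_png_roundtrip(self, tmp_path, rng):
        items = [make_image(rng, MALIGNANT, sid="a"), make_image(rng, BENIGN, sid="b")]
        path = write_manifest(items, tmp_path)
        loaded = read_manifest(path)
        assert [it.label for it in loaded] == [MALIGNANT, BENIGN]
        assert loaded[0].roi_mask.sum() == items[0].roi_mask.sum()
        # 8-bit PNG quantization: pixel error bounded by one level
        assert np.abs(loaded[0].image / 255 - items[0].image).max() < 1 / 255 + 1e-9

    def test_nifti_roundtrip(self, tmp_path, rng):
        items = [make_image(rng, BENIGN, sid="n")]
        path = write_manifest(items, tmp_path, nifti=True)
        loaded = read_manifest(path)
        assert np.allclose(loaded[0].image, items[0].image, atol=1e-6)
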