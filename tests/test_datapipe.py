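"""Resize/normalize, standardization, augmentation, expansion, splitting,
and the class-imbalance statistic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cervseg.annotations import BinaryMask
from cervseg.datapipe import (AugmentationPolicy, DatasetManifest, SamplePair,
                              SplitSpec, augment_pair, backbone_destandardize,
                              backbone_standardize, class_imbalance_percent,
                              expand_dataset, expanded_class_targets,
                              largest_remainder_allocation, resize_normalize,
                              stratified_split, STANDARDIZATION)
from cervseg.synthetic import PhantomSpec, generate_phantom_dataset


class TestResizeNormalize:
    def test_constant_image_maps_to_unit_scale(self):
        img = np.full((512, 512, 3), 255, np.uint8)
        pair = resize_normalize(img, np.zeros((512, 512), np.uint8), 256)
        assert pair.image.shape == (256, 256, 3)
        assert np.allclose(pair.image, 1.0)

    def test_all_ones_mask_survives_any_resize(self):
        img = np.zeros((100, 80, 3), np.uint8)
        pair = resize_normalize(img, np.ones((100, 80), np.uint8) * 255, 64)
        assert pair.mask.data.all()

    def test_half_foreground_fraction_preserved(self):
        mask = np.zeros((100, 80), np.uint8)
        mask[:50] = 255
        pair = resize_normalize(np.zeros((100, 80, 3), np.uint8), mask, 256)
        assert abs(pair.mask.data.mean() - 0.5) < 0.02

    def test_mask_stays_binary_after_interpolation(self, rng):
        mask = (rng.random((37, 53)) > 0.5).astype(np.uint8) * 255
        pair = resize_normalize(rng.random((37, 53, 3)), mask, 64)
        assert set(np.unique(pair.mask.data)) <= {0, 1}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            resize_normalize(np.zeros((0, 5, 3)), np.zeros((0, 5)), 64)


class TestBackboneStandardize:
    @pytest.mark.parametrize("backbone", sorted(STANDARDIZATION))
    def test_zero_image_closed_form(self, backbone):
        mean, std = STANDARDIZATION[backbone]
        out = backbone_standardize(np.zeros((4, 4, 3)), backbone)
        assert np.allclose(out, -mean / std)

    @pytest.mark.parametrize("backbone", sorted(STANDARDIZATION))
    def test_mean_valued_image_maps_to_zero(self, backbone):
        mean, _ = STANDARDIZATION[backbone]
        img = np.broadcast_to(mean / 255.0, (4, 4, 3))
        assert np.allclose(backbone_standardize(img, backbone), 0.0)

    @pytest.mark.parametrize("backbone", sorted(STANDARDIZATION))
    def test_invertibility(self, backbone, rng):
        img = rng.random((8, 8, 3))
        out = backbone_standardize(img, backbone)
        assert np.allclose(backbone_destandardize(out, backbone), img, atol=1e-6)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(KeyError):
            backbone_standardize(np.zeros((4, 4, 3)), "vgg-branch")


def _blob_pair(size=32, seed=0):
    r = np.random.default_rng(seed)
    mask = np.zeros((size, size), np.uint8)
    mask[4:10, 5:12] = 1
    image = r.random((size, size, 3)) * 0.2
    image[..., 0] += mask * 0.7
    image = np.clip(image, 0, 1)
    return SamplePair(image=image, mask=BinaryMask(mask))


class TestAugmentation:
    def test_identity_policy_is_noop(self):
        pair = _blob_pair()
        policy = AugmentationPolicy(rotation_limit=0, flip_horizontal=False,
                                    flip_vertical=False, brightness_limit=0,
                                    contrast_limit=0, elastic_alpha=0)
        out = augment_pair(pair, policy, np.random.default_rng(0))
        assert np.array_equal(out.image, pair.image)
        assert np.array_equal(out.mask.data, pair.mask.data)

    def test_horizontal_flip_mirrors_mask_and_is_involutive(self):
        pair = _blob_pair()
        policy = AugmentationPolicy(rotation_limit=0, flip_horizontal=True,
                                    flip_vertical=False, brightness_limit=0,
                                    contrast_limit=0, elastic_alpha=0)
        seed = next(s for s in range(50)
                    if np.random.default_rng(s).random() < 0.5)  # flip fires
        once = augment_pair(pair, policy, np.random.default_rng(seed))
        assert np.array_equal(once.mask.data, pair.mask.data[:, ::-1])
        twice = augment_pair(once, policy, np.random.default_rng(seed))
        assert np.array_equal(twice.mask.data, pair.mask.data)

    @pytest.mark.parametrize("seed", range(5))
    def test_geometry_applied_jointly_to_image_and_mask(self, seed):
        pair = _blob_pair(seed=seed)
        policy = AugmentationPolicy(brightness_limit=0, contrast_limit=0,
                                    elastic_alpha=0)
        out = augment_pair(pair, policy, np.random.default_rng(seed))
        assert set(np.unique(out.mask.data)) <= {0, 1}
        if out.mask.data.sum() == 0:
            return
        # the bright-red blob must land where the mask lands
        red = out.image[..., 0] - np.median(out.image[..., 0])
        m_r, m_c = np.argwhere(out.mask.data).mean(axis=0)
        bright = np.argwhere(red > 0.35)
        b_r, b_c = bright.mean(axis=0)
        assert abs(m_r - b_r) <= 1.0 and abs(m_c - b_c) <= 1.0

    def test_elastic_deformation_keeps_mask_binary(self):
        pair = _blob_pair()
        policy = AugmentationPolicy(rotation_limit=0, flip_horizontal=False,
                                    flip_vertical=False, brightness_limit=0,
                                    contrast_limit=0, elastic_alpha=8, elastic_sigma=4)
        out = augment_pair(pair, policy, np.random.default_rng(3))
        assert set(np.unique(out.mask.data)) <= {0, 1}
        assert out.image.shape == pair.image.shape


class TestExpansion:
    def test_proportional_case(self):
        assert expanded_class_targets((10, 10, 10), 60) == [20, 20, 20]

    def test_largest_remainder_hand_computation(self):
        assert expanded_class_targets((1, 2, 3), 12) == [2, 4, 6]

    def test_published_cohort_counts_within_one_of_exact_shares(self):
        targets = expanded_class_targets((278, 286, 296), 2000)
        assert sum(targets) == 2000
        exact = [2000 * n / 860 for n in (278, 286, 296)]
        assert all(abs(t - e) <= 1 for t, e in zip(targets, exact))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(counts=st.lists(st.integers(1, 10_000), min_size=1, max_size=6),
           extra=st.integers(0, 10_000))
    def test_allocation_sums_exactly_and_stays_near_quota(self, counts, extra):
        total = sum(counts) + extra
        alloc = largest_remainder_allocation(counts, total)
        assert sum(alloc) == total
        quotas = [c * total / sum(counts) for c in counts]
        assert all(abs(a - q) < 1 for a, q in zip(alloc, quotas))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(counts=st.lists(st.integers(0, 10_000), min_size=1, max_size=6)
           .filter(lambda c: sum(c) > 0))
    def test_imbalance_bounded_between_zero_and_hundred(self, counts):
        value = class_imbalance_percent(counts)
        assert 0.0 <= value <= 100.0

    def test_allocation_always_sums_to_total(self, rng):
        for _ in range(50):
            counts = rng.integers(1, 500, size=3)
            total = int(counts.sum() + rng.integers(0, 1000))
            assert sum(largest_remainder_allocation(counts, total)) == total

    def test_expand_retains_originals_and_writes_augmented(self, tmp_path):
        manifest = generate_phantom_dataset(
            (3, 3, 3), tmp_path / "phantoms",
            spec_template=PhantomSpec(size=32, specular_artifacts=0), seed=5)
        policy = AugmentationPolicy(elastic_alpha=0)
        out = expand_dataset(manifest, 12, policy, seed=1, out_dir=tmp_path / "aug")
        assert len(out) == 12
        assert manifest.ids() <= out.ids()
        assert out.counts_per_class == {"CIN1": 4, "CIN2": 4, "CIN3": 4}
        aug_recs = [r for r in out.records if "-aug" in r["id"]]
        assert len(aug_recs) == 3
        pair = out.load_pair(out.records.index(aug_recs[0]))
        assert set(np.unique(pair.mask.data)) <= {0, 1}

    def test_shrinking_rejected(self, tmp_path):
        manifest = DatasetManifest(records=[
            {"id": f"{c}{i}", "image_path": "x", "mask_path": "y", "class_label": c}
            for c in ("CIN1", "CIN2", "CIN3") for i in range(4)])
        with pytest.raises(ValueError):
            expand_dataset(manifest, 6, AugmentationPolicy(), 0, tmp_path)


def _dummy_manifest(counts):
    records = []
    for cls, n in zip(("CIN1", "CIN2", "CIN3"), counts):
        for i in range(n):
            records.append({"id": f"{cls}-{i}", "image_path": "i", "mask_path": "m",
                            "class_label": cls})
    return DatasetManifest(records=records)


class TestSplit:
    def test_eight_one_one_sizes(self):
        train, val, test = stratified_split(_dummy_manifest((640, 660, 700)),
                                            SplitSpec((0.8, 0.1, 0.1), seed=0))
        assert (len(train), len(val), len(test)) == (1600, 200, 200)

    def test_deterministic_given_seed(self):
        m = _dummy_manifest((40, 30, 30))
        a = stratified_split(m, SplitSpec(seed=7))
        b = stratified_split(m, SplitSpec(seed=7))
        assert all(x.ids() == y.ids() for x, y in zip(a, b))

    def test_stratification_arithmetic(self):
        train, val, test = stratified_split(_dummy_manifest((40, 30, 30)),
                                            SplitSpec((0.8, 0.1, 0.1), seed=3))
        counts = train.counts_per_class
        assert (counts["CIN1"], counts["CIN2"], counts["CIN3"]) == (32, 24, 24)

    def test_partition_disjoint_and_exhaustive(self):
        m = _dummy_manifest((13, 17, 11))
        train, val, test = stratified_split(m, SplitSpec(seed=9))
        ids = [train.ids(), val.ids(), test.ids()]
        assert ids[0] | ids[1] | ids[2] == m.ids()
        assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) and not (ids[1] & ids[2])

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec((0.5, 0.2, 0.2))


class TestImbalance:
    def test_published_cohort_value(self):
        assert class_imbalance_percent((278, 286, 296)) == 2.09

    def test_balanced_classes(self):
        assert class_imbalance_percent((100, 100, 100)) == 0.0

    def test_hand_computed_case(self):
        assert class_imbalance_percent((1, 1, 2)) == 25.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            class_imbalance_percent((0, 0, 0))


class TestManifestIO:
    def test_csv_roundtrip(self, tmp_path):
        m = _dummy_manifest((2, 3, 4))
        m.to_csv(tmp_path / "m.csv")
        back = DatasetManifest.from_csv(tmp_path / "m.csv")
        assert back.ids() == m.ids()
        assert back.counts_per_class == m.counts_per_class
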