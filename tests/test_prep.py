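"""Cropping, augmentation arithmetic/bounds, and leakage-free splitting."""

import numpy as np
import pytest

from olfbulb import AugmentConfig, augment, augment_dataset, crop_around_bulb, subject_split
from olfbulb.prep import _sample_transform, build_dataset


def test_interior_anchor_crop_is_centred(rng):
    img = rng.integers(0, 255, size=(672, 896)).astype(np.uint8)
    crop = crop_around_bulb(img, (350.0, 450.0), 150)
    assert crop.shape == (150, 150)
    assert np.array_equal(crop, img[275:425, 375:525])


def test_corner_anchor_clamps_inward():
    img = np.arange(300 * 300).reshape(300, 300)
    crop = crop_around_bulb(img, (0.0, 0.0), 150)
    assert np.array_equal(crop, img[:150, :150])
    crop = crop_around_bulb(img, (299.0, 299.0), 150)
    assert np.array_equal(crop, img[150:, 150:])


def test_crop_idempotent_and_size_guard():
    img = np.arange(150 * 150, dtype=float).reshape(150, 150)
    again = crop_around_bulb(img, (75.0, 75.0), 150)
    assert np.array_equal(again, img)
    with pytest.raises(ValueError):
        crop_around_bulb(img[:100], (10, 10), 150)


def test_augment_count_conservation(rng):
    imgs = [rng.random((20, 20)) for _ in range(9)]
    labels = ["PD"] * 5 + ["NPOD"] * 4
    cfg = AugmentConfig(n_per_scan=25, seed=0)
    out_imgs, out_labels = augment_dataset(imgs, labels, cfg)
    assert len(out_imgs) == 9 * 25
    assert out_labels.count("PD") == 125 and out_labels.count("NPOD") == 100


def test_identity_config_returns_rescaled_copies(rng):
    img = rng.integers(0, 255, size=(32, 32)).astype(np.uint8)
    cfg = AugmentConfig(n_per_scan=25, rotation_max_deg=0, width_shift_max=0,
                        height_shift_max=0, shear_intensity=0, horizontal_flip=False)
    outs = augment(img, cfg)
    assert len(outs) == 25
    for o in outs:
        assert np.allclose(o, img / 255.0, atol=1e-12)


def test_flip_only_config_on_symmetric_image(rng):
    half = rng.random((24, 12))
    sym = np.concatenate([half, half[:, ::-1]], axis=1)
    cfg = AugmentConfig(n_per_scan=10, rotation_max_deg=0, width_shift_max=0,
                        height_shift_max=0, shear_intensity=0, horizontal_flip=True,
                        rescale=1.0, seed=4)
    for o in augment(sym, cfg):
        assert np.allclose(o, sym, atol=1e-12)


def test_sampled_transform_parameters_within_bounds(rng):
    cfg = AugmentConfig()
    for _ in range(10_000):
        _, _, draws = _sample_transform((150, 150), cfg, rng)
        assert abs(draws["angle_deg"]) <= 5.0
        assert abs(draws["shear"]) <= 0.05
        assert abs(draws["shift_rows"]) <= 0.05 * 150
        assert abs(draws["shift_cols"]) <= 0.05 * 150


def test_augment_deterministic_under_seed(rng):
    img = rng.random((20, 20))
    cfg = AugmentConfig(n_per_scan=5, seed=99)
    a = augment(img, cfg)
    b = augment(img, cfg)
    for x, y in zip(a, b):
        assert np.array_equal(x, y)


def test_canonical_split_18_6_6():
    sids = [f"pd{i}" for i in range(15)] + [f"np{i}" for i in range(15)]
    groups = ["PD"] * 15 + ["NPOD"] * 15
    assign = subject_split(sids, groups, ratios=(3, 1, 1), seed=0)
    parts = {p: [s for s, a in assign.items() if a == p]
             for p in ("train", "validation", "test")}
    assert (len(parts["train"]), len(parts["validation"]), len(parts["test"])) == (18, 6, 6)
    for p, expect in (("train", 9), ("validation", 3), ("test", 3)):
        assert sum(1 for s in parts[p] if s.startswith("pd")) == expect


def test_minimal_split_ratios_one_zero_one():
    assign = subject_split(["a", "b", "c", "d"], ["PD", "PD", "NPOD", "NPOD"],
                           ratios=(1, 0, 1), seed=1)
    parts = [assign[s] for s in ("a", "b", "c", "d")]
    assert parts.count("train") == 2 and parts.count("test") == 2


def test_split_partition_properties():
    sids = [f"s{i}" for i in range(23)]
    groups = ["PD"] * 12 + ["NPOD"] * 11
    for seed in range(5):
        assign = subject_split(sids, groups, seed=seed)
        assert set(assign) == set(sids)  # union = everyone, exactly once


def test_split_errors():
    with pytest.raises(ValueError):
        subject_split(["a"], ["PD"], ratios=(3, 1, 1), seed=0)  # fewer than partitions
    with pytest.raises(ValueError):
        subject_split(["a", "a"], ["PD", "PD"], seed=0)  # duplicate ids


def test_dataset_has_no_subject_leakage(small_cohort):
    patients = small_cohort.subjects_in("PD", "NPOD")
    assign = subject_split([s.subject_id for s in patients],
                           [s.group for s in patients], ratios=(2, 1, 1), seed=0)
    ds = build_dataset(small_cohort, assign, crop_size=150, image_size=32,
                       augment_config=AugmentConfig(n_per_scan=2, seed=0))
    subject_sets = {p: set(ds[p][2]) for p in ("train", "validation", "test")}
    assert subject_sets["train"] & subject_sets["test"] == set()
    assert subject_sets["train"] & subject_sets["validation"] == set()
    # training partition augmented, others not
    n_train_subject_scans = sum(
        len(small_cohort.stacks[s].bulb_slice_indices)
        for s in subject_sets["train"])
    assert len(ds["train"][1]) == n_train_subject_scans * 2
    assert ds["train"][0].shape[1:] == (32, 32, 3)
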