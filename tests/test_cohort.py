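"""Phantom-cohort generator: counts, determinism, geometry and the
planted group structure."""

import numpy as np
import pytest

from olfbulb import (
    CohortConfig,
    generate_cohort,
    group_expected_tdi,
    render_slice,
    sample_behavioral_truth,
    scan_table,
    subject_volumes,
)
from olfbulb.cohort import BulbGeometry, write_cohort


def test_default_cohort_counts(small_cohort):
    by_group = {g: len(small_cohort.subjects_in(g)) for g in ("PD", "NPOD", "control")}
    assert by_group == {"PD": 4, "NPOD": 4, "control": 4}
    assert set(small_cohort.stacks) == {s.subject_id for s in small_cohort.subjects}


def test_forty_five_participant_cohort():
    cfg = CohortConfig(n_pd=15, n_npod=15, n_control=15,
                       raster_shape=(220, 300), noise_sd=0.0, seed=7)
    cohort = generate_cohort(cfg)
    assert len(cohort.subjects) == 45


def test_degenerate_single_control_cohort():
    cfg = CohortConfig(n_pd=0, n_npod=0, n_control=1, raster_shape=(220, 300), seed=3)
    cohort = generate_cohort(cfg)
    assert len(cohort.subjects) == 1
    assert cohort.subjects[0].group == "control"
    assert scan_table(cohort).empty  # no patient scans


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_pd=0, n_npod=0, n_control=0).validate()


def test_invalid_configs_rejected():
    for bad in (dict(surround_effect=1.5), dict(pixel_spacing=0.0),
                dict(bulb_volume_means={"control": -1.0, "PD": 37.0, "NPOD": 37.0}),
                dict(slices_per_subject_range=(9, 5))):
        with pytest.raises(ValueError):
            CohortConfig(**bad).validate()


def test_scan_counts_within_configured_range():
    cfg = CohortConfig(n_pd=15, n_npod=15, n_control=0,
                       raster_shape=(220, 300), noise_sd=0.0, seed=5)
    cohort = generate_cohort(cfg)
    table = scan_table(cohort)
    per_subject = table.groupby("subject_id").size()
    assert per_subject.between(5, 9).all()
    assert 150 <= len(table) <= 270
    assert 5 <= per_subject.mean() <= 9


def test_patient_only_fields():
    cohort_cfg = CohortConfig(n_pd=2, n_npod=2, n_control=2,
                              raster_shape=(220, 300), seed=9)
    cohort = generate_cohort(cohort_cfg)
    for rec in cohort.subjects:
        clinical = (rec.hoehn_yahr, rec.disease_duration, rec.ledd_mg)
        if rec.group == "PD":
            assert all(v is not None for v in clinical)
        else:
            assert all(v is None for v in clinical)
        assert rec.true_bulb_volume_left > 0 and rec.true_bulb_volume_right > 0


def test_seed_determinism_byte_identical(tmp_path):
    cfg = dict(n_pd=2, n_npod=2, n_control=1, raster_shape=(220, 300), seed=21)
    a = generate_cohort(CohortConfig(**cfg))
    b = generate_cohort(CohortConfig(**cfg))
    assert a.subjects == b.subjects
    for sid in a.stacks:
        for sa, sb in zip(a.stacks[sid].slices, b.stacks[sid].slices):
            assert sa.tobytes() == sb.tobytes()
        for ca, cb in zip(a.contours[sid], b.contours[sid]):
            assert np.array_equal(ca.vertices, cb.vertices)
    write_cohort(a, tmp_path / "a")
    write_cohort(b, tmp_path / "b")
    assert (tmp_path / "a" / "cohort.csv").read_bytes() == (tmp_path / "b" / "cohort.csv").read_bytes()


def test_group_volume_effect(small_cohort):
    vols = subject_volumes(small_cohort).groupby("group")["volume_mm3"].mean()
    assert vols["control"] > vols["PD"]
    assert vols["control"] > vols["NPOD"]


def test_ground_truth_volume_consistency(small_cohort):
    v = subject_volumes(small_cohort)
    rel = np.abs(v.volume_mm3 - v.true_volume_mm3) / v.true_volume_mm3
    assert rel.max() <= 0.05


def test_render_ellipse_pixel_count_matches_analytic_area():
    a, b = 18.0, 12.0
    img = render_slice((200, 200), [BulbGeometry(center=(100, 100), semi_axes=(a, b),
                                                 intensity=200)], None, 0.0, seed=0)
    n_bulb = int((img > 100).sum())
    assert abs(n_bulb - np.pi * a * b) / (np.pi * a * b) < 0.05


def test_render_deterministic_and_background_constant():
    bulbs = [BulbGeometry(center=(60, 60), semi_axes=(8, 6))]
    im1 = render_slice((120, 120), bulbs, None, 4.0, seed=42)
    im2 = render_slice((120, 120), bulbs, None, 4.0, seed=42)
    assert np.array_equal(im1, im2)
    blank = render_slice((64, 64), [], None, 0.0, seed=0)
    assert len(np.unique(blank)) == 1


def test_render_rejects_out_of_bounds_geometry():
    with pytest.raises(ValueError):
        render_slice((50, 50), [BulbGeometry(center=(5, 5), semi_axes=(10, 10))],
                     None, 0.0, seed=0)


def test_behavioral_truth_group_calibration(rng):
    assert group_expected_tdi("control") > 30.3
    assert 16 <= group_expected_tdi("PD") <= 30.3
    assert abs(group_expected_tdi("PD") - 17.5) < 2.0
    with pytest.raises(ValueError):
        sample_behavioral_truth("unknown", rng)
    # sampled subjects stay on valid scales
    for group in ("PD", "NPOD", "control"):
        t = sample_behavioral_truth(group, rng)
        assert 1 <= t.threshold_scale <= 16
        assert 0 <= t.p_discrimination <= 1 and 0 <= t.p_identification <= 1


def test_anchor_inside_raster(small_cohort):
    table = scan_table(small_cohort)
    h, w = small_cohort.config.raster_shape
    assert ((table.anchor_row > 0) & (table.anchor_row < h)).all()
    assert ((table.anchor_col > 0) & (table.anchor_col < w)).all()
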