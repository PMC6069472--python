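"""Facial deformation/pose distances and hemiface feature selection."""

import numpy as np
import pytest

from painface import facemap, geometry, pipeline, synthetic
from painface.data import LandmarkFrame, LandmarkSequence
from painface.facemap import ConfigError, DEFORMATION_NAMES, POSE_NAMES


def _frame(points, index=0):
    return LandmarkFrame(points=np.asarray(points, dtype=float), frame_index=index)


def test_degenerate_frame_gives_all_zero_distances(template):
    frame = _frame(np.zeros((68, 2)))
    deform = geometry.compute_deformation(frame)
    pose = geometry.compute_pose(frame)
    assert set(deform) == set(DEFORMATION_NAMES) and len(deform) == 11
    assert set(pose) == set(POSE_NAMES) and len(pose) == 8
    assert all(v == 0.0 for v in deform.values())
    assert all(v == 0.0 for v in pose.values())


def test_translation_invariance(template):
    frame = _frame(template)
    shifted = _frame(template + np.array([10.0, -3.0]))
    for compute in (geometry.compute_deformation, geometry.compute_pose):
        a, b = compute(frame), compute(shifted)
        for name in a:
            assert b[name] == pytest.approx(a[name], abs=1e-9)


def test_scaling_scales_every_distance(template):
    frame = _frame(template)
    scaled = _frame(template * 2.5)
    for compute in (geometry.compute_deformation, geometry.compute_pose):
        a, b = compute(frame), compute(scaled)
        for name in a:
            assert b[name] == pytest.approx(2.5 * a[name], rel=1e-12)


def test_mouth_width_hand_computed(template):
    """Fixture with the inner mouth corners moved to (10, 50) and (40, 50)."""
    pts = template.copy()
    pts[facemap.DEFAULT_MAPPING["groups"]["inner_corner_right"][0]] = (10.0, 50.0)
    pts[facemap.DEFAULT_MAPPING["groups"]["inner_corner_left"][0]] = (40.0, 50.0)
    deform = geometry.compute_deformation(_frame(pts))
    assert deform["d_mw"] == pytest.approx(30.0)


def test_anchors_are_group_centroids(template):
    """d_el equals the hand-computed distance between lid-group centroids."""
    groups = facemap.DEFAULT_MAPPING["groups"]
    upper = template[groups["upper_lid_left"]].mean(axis=0)
    lower = template[groups["lower_lid_left"]].mean(axis=0)
    deform = geometry.compute_deformation(_frame(template))
    assert deform["d_el"] == pytest.approx(float(np.linalg.norm(upper - lower)))


def test_pose_symmetry_on_symmetric_template(template):
    pose = geometry.compute_pose(_frame(template))
    for left, right in [("d_bbl", "d_bbr"), ("d_bel", "d_ber"), ("d_bnl", "d_bnr"), ("d_bml", "d_bmr")]:
        assert pose[left] == pytest.approx(pose[right], abs=1e-9)


def test_boundary_shift_produces_headshake_signature(template):
    """Shifting all boundary points 5 px toward -x moves the boundary toward
    the subject's left components (shrinking left-side distances) and away
    from the right ones (growing right-side distances)."""
    pts = template.copy()
    pts[0:17, 0] -= 5.0
    base = geometry.compute_pose(_frame(template))
    moved = geometry.compute_pose(_frame(pts))
    for name in ("d_bbl", "d_bel", "d_bnl", "d_bml"):
        assert moved[name] < base[name]
    for name in ("d_bbr", "d_ber", "d_bnr", "d_bmr"):
        assert moved[name] > base[name]


def test_pose_asymmetry_flips_sign_under_mirroring(template):
    pts = template.copy()
    pts[0:17, 0] -= 5.0  # asymmetric head-shake frame
    mirrored = pts.copy()
    mirrored[:, 0] = 256.0 - mirrored[:, 0]
    # mirroring the image swaps anatomical sides: re-index so landmark k holds
    # the mirrored partner's coordinates
    swap = np.arange(68)
    swap[0:17] = np.arange(16, -1, -1)
    swap[17:27] = np.concatenate([np.arange(26, 21, -1), np.arange(21, 16, -1)])
    swap[31:36] = np.arange(35, 30, -1)
    swap[36:42] = [45, 44, 43, 42, 47, 46]
    swap[42:48] = [39, 38, 37, 36, 41, 40]
    swap[48:60] = [54, 53, 52, 51, 50, 49, 48, 59, 58, 57, 56, 55]
    swap[60:68] = [64, 63, 62, 61, 60, 67, 66, 65]
    mirrored = mirrored[swap]
    base = geometry.compute_pose(_frame(pts))
    flip = geometry.compute_pose(_frame(mirrored))
    for left, right in [("d_bbl", "d_bbr"), ("d_bel", "d_ber"), ("d_bnl", "d_bnr"), ("d_bml", "d_bmr")]:
        assert (base[left] - base[right]) == pytest.approx(-(flip[left] - flip[right]), abs=1e-9)


def test_missing_group_raises_config_error(template):
    mapping = facemap.default_mapping()
    del mapping["groups"]["eye_left"]
    with pytest.raises(ConfigError):
        geometry.compute_deformation(_frame(template), mapping)


def test_geometry_signals_shapes_and_constancy(template):
    seq = LandmarkSequence.from_array(np.broadcast_to(template, (8, 68, 2)).copy(), fs=30.0)
    deform, pose = geometry.geometry_signals(seq)
    assert len(deform) == 11 and len(pose) == 8
    for sig in list(deform.values()) + list(pose.values()):
        assert len(sig.x) == 8 and sig.fs == 30.0
        np.testing.assert_allclose(sig.x, sig.x[0])


def test_pain_mode_squeezes_eyelids():
    base = dict(n_subjects=1, epochs_per_subject=2, frames_per_epoch=20,
                render_images=False, noise_sd=0.0, seed=3)
    recs = synthetic.generate_cohort(synthetic.CohortSpec(**base))
    by_label = {r.label: r for r in recs}
    deform_n, _ = geometry.geometry_signals(by_label["no_pain"].sequence)
    deform_p, _ = geometry.geometry_signals(by_label["pain"].sequence)
    assert np.mean(deform_p["d_el"].x) < np.mean(deform_n["d_el"].x)
    assert np.mean(deform_p["d_mh"].x) > np.mean(deform_n["d_mh"].x)


# --- hemiface selection ---------------------------------------------------

@pytest.mark.parametrize("stream", ["DG_DisFace", "DG_DisPose", "DA_Gradient", "DA_LBP-TOP"])
def test_hemiface_whole_is_identity(stream):
    names = pipeline.stream_feature_names(stream)
    assert geometry.hemiface_select(names, "whole") == names


def test_hemiface_partition_property():
    for stream in ("DG_DisFace", "DG_DisPose", "DA_Gradient", "DA_LBP-TOP"):
        names = pipeline.stream_feature_names(stream)
        left = set(geometry.hemiface_select(names, "left"))
        right = set(geometry.hemiface_select(names, "right"))
        assert left | right == set(names)
        midline = {n for n in names if geometry.feature_side(n) == "mid"}
        assert left & right == midline


def test_hemiface_midline_distances():
    names = pipeline.stream_feature_names("DG_DisFace")
    left = set(geometry.hemiface_select(names, "left"))
    right = set(geometry.hemiface_select(names, "right"))
    shared_signals = {n.split("|")[0] for n in left & right}
    assert shared_signals == {"d_nm", "d_mw", "d_mh"}


def test_hemiface_rejects_unknown_side():
    with pytest.raises(ValueError):
        geometry.hemiface_select(["d_nm|s|max"], "frontal")


def test_symmetric_video_left_right_feature_agreement():
    """On a noise-free symmetric pain video, each left-hemiface distance value
    equals its mirrored right-hemiface partner."""
    spec = synthetic.CohortSpec(n_subjects=1, epochs_per_subject=2, frames_per_epoch=20,
                                render_images=False, noise_sd=0.0, headshake_amp=0.0, seed=5)
    rec = [r for r in synthetic.generate_cohort(spec) if r.pain][0]
    deform, pose = geometry.geometry_signals(rec.sequence)
    pairs = [("d_ebl", "d_ebr"), ("d_el", "d_er"), ("d_mbl", "d_mbr"), ("d_eml", "d_emr"),
             ("d_bbl", "d_bbr"), ("d_bel", "d_ber"), ("d_bnl", "d_bnr"), ("d_bml", "d_bmr")]
    signals = {**deform, **pose}
    for left, right in pairs:
        np.testing.assert_allclose(signals[left].x, signals[right].x, atol=1e-9)
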