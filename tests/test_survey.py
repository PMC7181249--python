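"""Frame registration and sequential overlap de-duplication."""

from __future__ import annotations

import numpy as np
import pytest

import cattlecount as cc
from cattlecount.survey import (CountedObject, FrameRecord,
                                RegistrationError, SurveyOrderError,
                                dedup_survey, objects_from_truth)


def _survey(seed=0, n_frames=5, n_animals=10, overlap=0.7, **scene_kw):
    spec = cc.SurveySpec(
        frame_width=640, frame_height=640, n_frames=n_frames, overlap=overlap,
        scene=cc.SceneSpec(n_animals=n_animals, width=640, height=640,
                           **scene_kw))
    return cc.generate_survey(spec, seed)


# ---------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------

def test_identity_registration_of_frame_with_itself():
    survey = _survey(seed=1, n_frames=1, n_animals=4)
    frame = survey.frames[0]
    tf = cc.register_pair(frame, frame)
    origin = tf.apply(np.array([[100.0, 100.0], [400.0, 250.0]]))
    assert np.allclose(origin, [[100, 100], [400, 250]], atol=0.5)
    assert tf.detector_used in ("primary", "fallback")


def test_known_translation_recovered_within_one_pixel():
    survey = _survey(seed=2, n_frames=2, n_animals=4)
    a, b = survey.frames
    (r0, c0), (r1, c1) = survey.translations
    tf = cc.register_pair(a, b)
    # a point in a maps into b shifted by the true inter-frame translation
    pt = np.array([[300.0, 256.0]])
    expected = pt + [[c0 - c1, r0 - r1]]
    assert np.allclose(tf.apply(pt), expected, atol=1.0)


def test_truth_backend_returns_exact_transform():
    survey = _survey(seed=3, n_frames=2, n_animals=4)
    cfg = cc.RunConfig(registration_backend="truth")
    (r0, c0), (r1, c1) = survey.translations
    tf = cc.register_pair(survey.frames[0], survey.frames[1], cfg,
                          truth_translation=(r0 - r1, c0 - c1))
    assert tf.detector_used == "truth"
    assert np.allclose(tf.apply(np.array([[10.0, 20.0]])),
                       [[10.0 + c0 - c1, 20.0]])


def test_uncorrelated_noise_fails_registration():
    rng = np.random.default_rng(0)
    a = cc.RgbImage(pixels=rng.integers(0, 256, (256, 256, 3), dtype=np.uint8),
                    image_id="noise_a")
    b = cc.RgbImage(pixels=rng.integers(0, 256, (256, 256, 3), dtype=np.uint8),
                    image_id="noise_b")
    with pytest.raises(RegistrationError):
        cc.register_pair(a, b)


def test_transform_must_be_invertible():
    with pytest.raises(ValueError):
        cc.PairTransform("a", "b", np.zeros((3, 3)), 0, "truth")


# ---------------------------------------------------------------------
# de-duplication on ground-truth objects
# ---------------------------------------------------------------------

def _truth_records_and_transforms(survey, reverse=False):
    records, transforms = [], []
    for frame, truth, (dr, dc) in zip(survey.frames, survey.frame_truths,
                                      survey.translations):
        records.append(FrameRecord(
            image=frame, objects=objects_from_truth(truth),
            shape=frame.shape))
        transforms.append(cc.PairTransform(
            frame.image_id, "world",
            np.array([[1, 0, dc], [0, 1, dr], [0, 0, 1]], float),
            0, "truth"))
    if reverse:
        records = records[::-1]
        transforms = transforms[::-1]
        for i, rec in enumerate(records):
            rec.image.timestamp = float(i)
    return records, transforms


def test_single_image_survey_total_is_frame_estimate():
    survey = _survey(seed=4, n_frames=1, n_animals=4)
    records, transforms = _truth_records_and_transforms(survey)
    tally = dedup_survey(records, transforms)
    assert tally.total == 4
    assert tally.rows[0].adjusted == 4


def test_dedup_on_truth_objects_is_exact():
    """Static survey, perfect counting stage: tally equals the registry."""
    for seed in range(8):
        survey = _survey(seed=seed, n_frames=5, n_animals=10)
        records, transforms = _truth_records_and_transforms(survey)
        tally = dedup_survey(records, transforms)
        assert tally.total == survey.count, f"seed {seed}"


def test_dedup_exact_with_clustered_truth_objects():
    survey = _survey(seed=11, n_frames=4, n_animals=9,
                     cluster_size_distribution={1: 0.5, 3: 0.5})
    records, transforms = [], []
    for frame, truth, (dr, dc) in zip(survey.frames, survey.frame_truths,
                                      survey.translations):
        records.append(FrameRecord(
            image=frame,
            objects=objects_from_truth(truth, merge_clusters=True),
            shape=frame.shape))
        transforms.append(cc.PairTransform(
            frame.image_id, "world",
            np.array([[1, 0, dc], [0, 1, dr], [0, 0, 1]], float),
            0, "truth"))
    tally = dedup_survey(records, transforms)
    assert tally.total == survey.count


def test_reversed_chronology_gives_same_total_on_truth():
    survey = _survey(seed=5, n_frames=4, n_animals=8)
    fwd_records, fwd_tf = _truth_records_and_transforms(survey)
    fwd = dedup_survey(fwd_records, fwd_tf).total
    rev_records, rev_tf = _truth_records_and_transforms(survey, reverse=True)
    rev = dedup_survey(rev_records, rev_tf).total
    assert fwd == rev == survey.count


def test_tally_arithmetic_identity():
    survey = _survey(seed=6, n_frames=5, n_animals=10)
    records, transforms = _truth_records_and_transforms(survey)
    tally = dedup_survey(records, transforms)
    for row in tally.rows:
        assert row.adjusted == (row.raw - row.border_removed
                                - row.overlap_removed + row.credited)
    assert tally.total == sum(r.adjusted for r in tally.rows)


def test_border_object_credited_in_next_frame():
    """An object in frame 0's border band, interior in frame 1, is
    excluded once and credited once."""
    img0 = cc.RgbImage(pixels=np.zeros((100, 100, 3), np.uint8),
                       timestamp=0.0, image_id="f0")
    img1 = cc.RgbImage(pixels=np.zeros((100, 100, 3), np.uint8),
                       timestamp=1.0, image_id="f1")
    # world = frame 0 coords; frame 1 shifted 30 px right
    on_border = CountedObject(count=2, centroid=(50.0, 97.0),
                              bbox=(45.0, 93.0, 55.0, 100.0))
    same_interior = CountedObject(count=2, centroid=(50.0, 67.0),
                                  bbox=(45.0, 63.0, 55.0, 70.0))
    records = [FrameRecord(image=img0, objects=[on_border], shape=(100, 100)),
               FrameRecord(image=img1, objects=[same_interior],
                           shape=(100, 100))]
    transforms = [
        cc.PairTransform("f0", "world", np.eye(3), 0, "truth"),
        cc.PairTransform("f1", "world",
                         np.array([[1, 0, 30], [0, 1, 0], [0, 0, 1]], float),
                         0, "truth")]
    tally = dedup_survey(records, transforms)
    assert tally.rows[0].border_removed == 2
    assert tally.rows[0].adjusted == 0
    assert tally.rows[1].overlap_removed == 2
    assert tally.rows[1].credited == 2
    assert tally.total == 2


def test_non_monotone_timestamps_rejected():
    survey = _survey(seed=7, n_frames=2, n_animals=4)
    records, transforms = _truth_records_and_transforms(survey)
    records[1].image.timestamp = -1.0
    with pytest.raises(SurveyOrderError):
        dedup_survey(records, transforms)


def test_missing_transform_rejected():
    survey = _survey(seed=8, n_frames=2, n_animals=4)
    records, transforms = _truth_records_and_transforms(survey)
    with pytest.raises(RegistrationError):
        dedup_survey(records, transforms[:1])


# ---------------------------------------------------------------------
# end to end on pixels
# ---------------------------------------------------------------------

def test_run_survey_truth_backend_counts_registry(oracle_config):
    survey = _survey(seed=9, n_frames=3, n_animals=6)
    cfg = oracle_config.model_copy(update={"registration_backend": "truth"})
    cfg = cc.RunConfig(**cfg.model_dump())
    tally = cc.run_survey(survey.frames, cfg, truth=survey)
    assert tally.total == survey.count
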