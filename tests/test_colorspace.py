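"""Quadrant splitting, correction factor, channel decomposition and the
Y histogram-valley threshold, cross-checked against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cattlecount as cc
from cattlecount.colorspace import (DegenerateInputError, UndefinedCfError,
                                    decompose_channels, split_quadrants)
from conftest import uniform_roi
from oracles import custom_channel_oracle, y_threshold_oracle


# ---------------------------------------------------------------------
# quadrants and cf
# ---------------------------------------------------------------------

@pytest.mark.parametrize("h,w,top_rows,left_cols", [
    (100, 100, 50, 50),
    (101, 100, 51, 50),
    (100, 101, 50, 51),
])
def test_quadrant_windows(h, w, top_rows, left_cols):
    roi = uniform_roi(85, (h, w))
    quads = split_quadrants(roi)
    assert [q.window for q in quads] == [
        (0, top_rows, 0, left_cols), (0, top_rows, left_cols, w),
        (top_rows, h, 0, left_cols), (top_rows, h, left_cols, w)]


def test_quadrants_reassemble_bit_exactly():
    rng = np.random.default_rng(0)
    px = rng.integers(0, 256, (101, 67, 3), dtype=np.uint8)
    roi = cc.RoiImage(pixels=px, roi_mask=np.ones((101, 67), bool))
    rebuilt = np.zeros_like(px)
    for q in split_quadrants(roi):
        r0, r1, c0, c1 = q.window
        rebuilt[r0:r1, c0:c1] = q.pixels
    assert np.array_equal(rebuilt, px)


def test_degenerate_image_rejected():
    with pytest.raises(DegenerateInputError):
        split_quadrants(uniform_roi(0, (1, 10)))


@pytest.mark.parametrize("value,expected_cf", [(85, 1.0), (170, 0.5)])
def test_correction_factor_uniform(value, expected_cf):
    q = split_quadrants(uniform_roi(value))[0]
    assert cc.correction_factor(q) == pytest.approx(expected_cf)


def test_correction_factor_excludes_non_roi_pixels():
    px = np.full((64, 64, 3), 85, dtype=np.uint8)
    mask = np.zeros((64, 64), dtype=bool)
    mask[:32] = True
    px[~mask] = 0          # zeroed non-cattle tiles must not deflate the mean
    roi = cc.RoiImage(pixels=px, roi_mask=mask)
    q = split_quadrants(roi)[0]
    assert cc.correction_factor(q) == pytest.approx(1.0)


def test_all_zero_quadrant_has_no_cf():
    px = np.zeros((64, 64, 3), dtype=np.uint8)
    roi = cc.RoiImage(pixels=px, roi_mask=np.zeros((64, 64), bool))
    with pytest.raises(UndefinedCfError):
        cc.correction_factor(split_quadrants(roi)[0])


# ---------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------

@pytest.mark.parametrize("rgb,cmy", [
    ((255, 255, 255), (0, 0, 0)),      # white: no ink
    ((255, 0, 0), (0, 255, 255)),      # pure red
    ((0, 0, 0), (0, 0, 0)),            # black: all in the K channel
])
def test_cmy_decomposition_definition(rgb, cmy):
    px = np.full((4, 4, 3), rgb, dtype=np.uint8)
    ch = decompose_channels(px)
    assert (ch.C == cmy[0]).all()
    assert (ch.M == cmy[1]).all()
    assert (ch.Y == cmy[2]).all()


@given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255))
def test_custom_channel_matches_reference_formulas(r, g, b):
    """Pseudo-CIELAB third channel vs a from-scratch Lab→sRGB evaluation.

    Agreement to ±1 intensity level (the reference uses the textbook
    XYZ→sRGB matrix to 4 decimals, the implementation a higher-precision
    one)."""
    px = np.full((1, 1, 3), (r, g, b), dtype=np.uint8)
    got = int(decompose_channels(px).custom[0, 0])
    assert abs(got - custom_channel_oracle(r, g, b)) <= 1


def test_custom_channel_midgray_frozen_value():
    px = np.full((1, 1, 3), 128, dtype=np.uint8)
    expected = custom_channel_oracle(128, 128, 128)
    assert abs(int(decompose_channels(px).custom[0, 0]) - expected) <= 1


# ---------------------------------------------------------------------
# fixed thresholds
# ---------------------------------------------------------------------

@pytest.mark.parametrize("cf,expected", [
    (1.0, (40.0, 30.0, 120.0)),
    (5.0, (100.0, 30.0, 150.0)),       # caps engaged
    (0.5, (20.0, 30.0, 60.0)),
])
def test_fixed_threshold_worked_examples(cf, expected):
    assert cc.fixed_thresholds(cf) == expected


@given(st.floats(0.01, 20), st.floats(0.01, 20))
def test_fixed_thresholds_monotone_and_capped(cf1, cf2):
    lo, hi = sorted([cf1, cf2])
    t_lo, t_hi = cc.fixed_thresholds(lo), cc.fixed_thresholds(hi)
    assert t_lo[0] <= t_hi[0] <= 100.0
    assert t_lo[2] <= t_hi[2] <= 150.0
    assert t_lo[1] == t_hi[1] == 30.0


# ---------------------------------------------------------------------
# Y-channel threshold rule chain
# ---------------------------------------------------------------------

def _dark_quadrant_values(rng, n=60000):
    """60% of mass in bins 0–9, the rest spread over 100–255."""
    dark = rng.integers(0, 10, int(n * 0.6))
    bright = rng.integers(100, 256, n - len(dark))
    return np.concatenate([dark, bright]).astype(np.uint8)


def test_dark_quadrant_threshold_is_ten(config):
    rng = np.random.default_rng(0)
    y = _dark_quadrant_values(rng).reshape(200, 300)
    res = cc.y_quadrant_threshold(y, config=config)
    assert res.status == "dark"
    assert res.threshold == 10


def test_unimodal_histogram_discarded(config):
    rng = np.random.default_rng(1)
    y = np.clip(rng.normal(140, 12, (200, 300)), 0, 255).astype(np.uint8)
    res = cc.y_quadrant_threshold(y, config=config)
    assert res.status == "discarded"
    assert res.threshold is None


def test_bimodal_valley_matches_bin_scan_oracle(config):
    """Constructed peaks at ~60 and ~180 with a flat low valley."""
    rng = np.random.default_rng(2)
    lo = np.clip(rng.normal(60, 8, 30000), 0, 255)
    hi = np.clip(rng.normal(180, 10, 60000), 0, 255)
    y = np.concatenate([lo, hi]).astype(np.uint8)
    hist = np.bincount(y, minlength=256)[:256]
    res = cc.y_threshold_from_histogram(hist, config)
    status, thr = y_threshold_oracle(hist)
    assert res.status == status == "valid"
    assert res.threshold == thr
    assert 60 < res.threshold < 180


def _random_histogram(rng):
    """Histogram families that exercise every branch of the rule chain."""
    kind = rng.integers(4)
    if kind == 0:
        return rng.integers(0, 2000, 256)
    if kind == 1:          # mixture of gaussians
        n_modes = rng.integers(1, 5)
        vals = np.concatenate([
            rng.normal(rng.uniform(0, 255), rng.uniform(3, 30),
                       rng.integers(500, 20000))
            for _ in range(n_modes)])
        return np.bincount(np.clip(vals, 0, 255).astype(int),
                           minlength=256)[:256]
    if kind == 2:          # heavy dark mass
        vals = np.concatenate([
            rng.integers(0, 10, rng.integers(5000, 30000)),
            rng.integers(0, 256, rng.integers(100, 20000))])
        return np.bincount(vals, minlength=256)[:256]
    hist = rng.integers(0, 50, 256)
    hist[rng.integers(0, 256)] += rng.integers(0, 30000)   # spike
    return hist


def test_y_threshold_oracle_equivalence_sample(config):
    """Rule chain equals the literal bin-by-bin implementation."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        hist = _random_histogram(rng)
        if hist.sum() == 0:
            continue
        res = cc.y_threshold_from_histogram(hist, config)
        status, thr = y_threshold_oracle(hist)
        assert (res.status, res.threshold) == (status, thr)


def test_empty_histogram_rejected(config):
    with pytest.raises(DegenerateInputError):
        cc.y_threshold_from_histogram(np.zeros(256), config)


# ---------------------------------------------------------------------
# full mask set
# ---------------------------------------------------------------------

def test_low_content_quadrant_discarded(config):
    """A quadrant with <50,000 nonzero-Y pixels contributes all black."""
    px = np.zeros((448, 448, 3), dtype=np.uint8)
    mask = np.ones((448, 448), dtype=bool)
    # quadrant 0: plenty of Y>0 content (low blue => high Y), bimodal
    rng = np.random.default_rng(3)
    px[:224, :224] = (180, 170, 60)
    px[:224, :224, 2] += rng.integers(0, 30, (224, 224)).astype(np.uint8)
    px[:50, :50] = (230, 225, 200)
    # quadrant 1: only 49,999 pixels with Y > 0
    q1 = np.zeros((224, 224, 3), dtype=np.uint8)
    flat = q1.reshape(-1, 3)
    flat[:49999] = (120, 110, 60)
    px[:224, 224:448] = q1
    roi = cc.RoiImage(pixels=px, roi_mask=mask)
    masks = cc.build_mask_set(roi, config)
    statuses = {e["quadrant"]: e["status"] for e in masks.quadrant_log}
    assert statuses[1] == "too_little_content"
    for m in (masks.c, masks.m, masks.custom, masks.y_full):
        assert not m[:224, 224:448].any()


def test_mask_set_nestedness_and_roi_confinement(small_roi, config):
    masks = cc.build_mask_set(small_roi, config)
    assert masks.y_valid
    assert not masks.y_quarter[~masks.y_half].any()
    assert not masks.y_half[~masks.y_full].any()
    for m in (masks.c, masks.m, masks.custom, masks.y_full):
        assert not m[~small_roi.roi_mask].any()


def test_animal_pixels_white_in_full_y_mask(small_scene, small_roi, config):
    """Every truth animal pixel is below the global Y threshold."""
    _, _, truth = small_scene
    masks = cc.build_mask_set(small_roi, config)
    animal = truth.animal_mask()
    covered = (masks.y_full & animal).sum() / animal.sum()
    assert covered > 0.99


def test_all_inactive_image_flagged(config):
    roi = cc.RoiImage(pixels=np.zeros((448, 448, 3), np.uint8),
                      roi_mask=np.zeros((448, 448), bool))
    masks = cc.build_mask_set(roi, config)
    assert not masks.any_active
    assert not masks.y_valid
    assert masks.global_y_threshold is None
    assert not masks.c.any() and not masks.y_full.any()
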