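"""Metric correctness against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from monetseg.data_pipeline import PatientVolume
from monetseg.metrics import (
    BinaryMask,
    UndefinedMetricError,
    dice_score,
    hausdorff_distance,
    per_patient_metrics,
    soft_dice_loss,
    soft_dice_score,
)


# -- brute-force oracles ----------------------------------------------------

def brute_dice(a, b):
    sa = {tuple(p) for p in np.argwhere(a)}
    sb = {tuple(p) for p in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def brute_hausdorff(a, b, spacing=None, percentile=None):
    pa = np.argwhere(a).astype(float)
    pb = np.argwhere(b).astype(float)
    if spacing is not None:
        pa = pa * spacing
        pb = pb * spacing
    d = cdist(pa, pb)
    dab, dba = d.min(axis=1), d.min(axis=0)
    if percentile is None:
        return max(dab.max(), dba.max())
    return max(np.percentile(dab, percentile), np.percentile(dba, percentile))


def _random_mask(rng, shape, p=0.3, nonempty=True):
    while True:
        m = (rng.random(shape) < p).astype(np.uint8)
        if not nonempty or m.any():
            return m


# -- soft Dice --------------------------------------------------------------

def test_soft_dice_perfect_and_disjoint():
    a = np.zeros((6, 6))
    a[1:3, 1:4] = 1
    assert soft_dice_loss(a, a, epsilon=1e-12) == pytest.approx(0, abs=1e-10)
    b = np.zeros((6, 6))
    b[4:, 4:] = 1
    assert soft_dice_loss(a, b, epsilon=1e-12) == pytest.approx(1, abs=1e-10)


def test_soft_dice_constant_half_prediction():
    """pred = 0.5 everywhere on 4x4, target = 8 ones: direct formula."""
    pred = np.full((4, 4), 0.5)
    target = np.zeros((4, 4))
    target.flat[:8] = 1
    eps = 1e-6
    expected = 1 - (2 * 0.5 * 8 + eps) / (8 + 8 + eps)
    assert soft_dice_loss(pred, target, eps) == pytest.approx(expected,
                                                              rel=1e-12)


def test_soft_dice_shape_mismatch_and_bad_epsilon():
    with pytest.raises(ValueError):
        soft_dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(ValueError):
        soft_dice_loss(np.zeros((2, 2)), np.zeros((2, 2)), epsilon=0)


@given(st.integers(0, 2 ** 31 - 1), st.floats(1e-9, 1e-2))
@settings(max_examples=30, deadline=None)
def test_soft_dice_loss_score_identity(seed, eps):
    rng = np.random.default_rng(seed)
    p = rng.random((5, 5))
    t = (rng.random((5, 5)) < 0.4).astype(float)
    assert soft_dice_loss(p, t, eps) + soft_dice_score(p, t, eps) == \
        pytest.approx(1.0, abs=1e-14)


# -- hard Dice --------------------------------------------------------------

def test_dice_trivial_cases():
    a = np.zeros((4, 4), dtype=np.uint8)
    a[:2, :2] = 1
    assert dice_score(a, a) == 1.0
    # |A| = |B| = 4 with |A & B| = 2
    a = np.zeros((4, 4), dtype=np.uint8)
    b = np.zeros((4, 4), dtype=np.uint8)
    a.flat[[0, 1, 2, 3]] = 1
    b.flat[[2, 3, 4, 5]] = 1
    assert dice_score(a, b) == 0.5
    assert dice_score(np.zeros((3, 3)), np.zeros((3, 3))) == 1.0
    assert dice_score(a, np.zeros((4, 4))) == 0.0


def test_dice_random_masks_match_set_oracle(rng):
    for _ in range(100):
        a = _random_mask(rng, (16, 16), nonempty=False)
        b = _random_mask(rng, (16, 16), nonempty=False)
        assert dice_score(a, b) == pytest.approx(brute_dice(a, b), abs=1e-12)


def test_dice_permutation_invariance(rng):
    a = _random_mask(rng, (8, 8))
    b = _random_mask(rng, (8, 8))
    perm = rng.permutation(64)
    ap = a.ravel()[perm].reshape(8, 8)
    bp = b.ravel()[perm].reshape(8, 8)
    assert dice_score(ap, bp) == pytest.approx(dice_score(a, b), abs=1e-12)


# -- Hausdorff --------------------------------------------------------------

def test_hausdorff_trivial_cases():
    a = np.zeros((8, 8), dtype=np.uint8)
    a[2, 2] = 1
    assert hausdorff_distance(a, a) == 0.0
    b = np.zeros((8, 8), dtype=np.uint8)
    b[5, 6] = 1      # (3, 4) offset -> distance 5
    assert hausdorff_distance(a, b) == pytest.approx(5.0)


def test_hausdorff_empty_mask_is_undefined():
    a = np.zeros((4, 4), dtype=np.uint8)
    b = a.copy()
    b[0, 0] = 1
    with pytest.raises(UndefinedMetricError):
        hausdorff_distance(a, b)


def test_hausdorff_random_masks_match_bruteforce(rng):
    for i in range(110):
        shape = (int(rng.integers(3, 21)), int(rng.integers(3, 21)))
        a = _random_mask(rng, shape, p=0.2)
        b = _random_mask(rng, shape, p=0.2)
        assert hausdorff_distance(a, b) == pytest.approx(
            brute_hausdorff(a, b), abs=1e-10)
        assert hausdorff_distance(a, b, percentile=95) == pytest.approx(
            brute_hausdorff(a, b, percentile=95), abs=1e-10)


def test_hausdorff_symmetry_and_spacing_scaling(rng):
    a = _random_mask(rng, (12, 12), p=0.15)
    b = _random_mask(rng, (12, 12), p=0.15)
    assert hausdorff_distance(a, b) == hausdorff_distance(b, a)
    h1 = hausdorff_distance(a, b)
    h3 = hausdorff_distance(a, b, spacing=(3.0, 3.0))
    assert h3 == pytest.approx(3 * h1, rel=1e-12)
    assert dice_score(BinaryMask(a, (3.0, 3.0)), BinaryMask(b, (3.0, 3.0))) \
        == dice_score(a, b)


def test_hausdorff_3d_matches_bruteforce(rng):
    a = _random_mask(rng, (4, 9, 9), p=0.1)
    b = _random_mask(rng, (4, 9, 9), p=0.1)
    sp = (2.5, 1.0, 1.0)
    assert hausdorff_distance(a, b, spacing=sp) == pytest.approx(
        brute_hausdorff(a, b, spacing=sp), abs=1e-10)


# -- per-patient aggregation ------------------------------------------------

def _volume_from_masks(masks):
    labels = np.stack(masks).astype(np.int32)
    return PatientVolume("p0", np.zeros_like(labels, dtype=np.float32),
                         labels, (1.0, 1.0, 1.0))


def test_per_patient_perfect_prediction(rng):
    masks = [_random_mask(rng, (10, 10)) for _ in range(3)]
    vol = _volume_from_masks(masks)
    rep = per_patient_metrics([m.astype(float) for m in masks], vol)
    assert rep.dice == 1.0 and rep.hausdorff == 0.0 and rep.slice_count == 3


def test_per_patient_single_slice_reduces_to_2d(rng):
    m = _random_mask(rng, (10, 10))
    p = _random_mask(rng, (10, 10)).astype(float)
    vol = _volume_from_masks([m])
    rep = per_patient_metrics([p], vol)
    assert rep.dice == pytest.approx(dice_score(p.astype(np.uint8), m))
    assert rep.hausdorff == pytest.approx(
        hausdorff_distance(p.astype(np.uint8), m))


def test_per_patient_two_slice_offset_matches_3d_bruteforce():
    t0 = np.zeros((8, 8), dtype=np.uint8)
    t0[2:4, 2:4] = 1
    t1 = np.roll(t0, 1, axis=1)
    p0, p1 = t1.astype(float), t0.astype(float)   # swapped slices
    vol = _volume_from_masks([t0, t1])
    rep = per_patient_metrics([p0, p1], vol)
    pv = np.stack([t1, t0])
    tv = np.stack([t0, t1])
    assert rep.dice == pytest.approx(brute_dice(pv, tv))
    assert rep.hausdorff == pytest.approx(brute_hausdorff(pv, tv))


def test_per_patient_empty_masks_flagged():
    vol = _volume_from_masks([np.zeros((6, 6), dtype=np.uint8)])
    rep = per_patient_metrics([np.zeros((6, 6))], vol)
    assert rep.dice == 1.0 and rep.both_empty
    assert not rep.hausdorff_defined and np.isnan(rep.hausdorff)


def test_per_patient_slice_count_mismatch():
    vol = _volume_from_masks([np.zeros((6, 6), dtype=np.uint8)] * 2)
    with pytest.raises(ValueError):
        per_patient_metrics([np.zeros((6, 6))], vol)
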