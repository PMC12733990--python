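"""Pixel/region confidence and the mask -> ROI extraction pipeline."""

import numpy as np
import pytest
from _oracles import flood_fill_components

from diagnext.phantom import PhantomSpec, generate_phantom
from diagnext.roi import (
    ConfidenceWeights,
    ROIRecord,
    connected_components,
    expand_bbox,
    extract_patch,
    normalize_roi,
    pixel_confidence,
    region_confidence,
    roi_pipeline,
)

RNG = np.random.default_rng(5)
W = ConfidenceWeights()


def _onehot_probs(mask, k=5):
    return np.moveaxis(np.eye(k)[mask], -1, 0)


def test_pixel_confidence_fully_confident():
    mask = np.zeros((4, 4, 2), dtype=int)
    mask[1:3, 1:3, :] = 2
    p = _onehot_probs(mask)
    c = pixel_confidence(p, [p] * 5, W)
    np.testing.assert_allclose(c, 1.0, atol=1e-6)


def test_pixel_confidence_uniform_and_disagreeing():
    """Uniform prediction + maximally disagreeing passes: only the w1 term
    and the 1/5 consistency floor survive."""
    k = 5
    p = np.full((k, 1, 1, 1), 1.0 / k)
    passes = [_onehot_probs(np.full((1, 1, 1), c), k) for c in range(k)]
    c = pixel_confidence(p, passes, W)
    want = W.w1 * 0.2 + W.w2 * 0.0 + W.w3 * (1.0 / 5.0)
    np.testing.assert_allclose(c, want, atol=1e-9)


def test_pixel_confidence_hand_arithmetic():
    p = np.array([0.6, 0.1, 0.1, 0.1, 0.1]).reshape(5, 1, 1, 1)
    c = pixel_confidence(p, [p] * 5, W)
    h = -(0.6 * np.log(0.6) + 4 * 0.1 * np.log(0.1))
    want = 0.5 * 0.6 + 0.3 * (1.0 - h / np.log(5)) + 0.2 * 1.0
    np.testing.assert_allclose(c.ravel(), [want], atol=1e-6)


def test_pixel_confidence_requires_passes():
    p = np.full((5, 2, 2, 2), 0.2)
    with pytest.raises(ValueError):
        pixel_confidence(p, [], W)


def test_vmin_boundary_26_vs_27():
    mask = np.zeros((20, 20, 8), dtype=int)
    # blob A: 27 voxels (3x3x3); blob B: 26 voxels
    mask[1:4, 1:4, 1:4] = 2
    mask[10:13, 10:13, 4:7] = 2
    mask[12, 12, 6] = 0  # remove one voxel -> 26
    comps = connected_components(mask, 2)
    assert len(comps) == 1
    assert len(comps[0]) == 27


def test_connected_components_empty_and_oracle():
    assert connected_components(np.zeros((8, 8, 4), dtype=int), 3) == []
    rng = np.random.default_rng(13)
    for _ in range(50):
        mask = (rng.random((16, 16, 16)) > 0.72).astype(int) * 4
        got = connected_components(mask, 4, v_min=1)
        want = flood_fill_components(mask == 4, min_size=1)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            assert frozenset(map(tuple, g)) == w


def test_expand_bbox_arithmetic_and_clipping():
    comp = np.array([[x, 5, 5] for x in range(10, 20)])
    bbox = expand_bbox(comp, (100, 100, 100), margin=0.15)
    assert bbox[0] == 8 and bbox[3] == 22  # ceil(1.5) = 2 per side
    # clipping at zero
    comp0 = np.array([[0, 0, 0], [3, 3, 3]])
    b0 = expand_bbox(comp0, (100, 100, 100))
    assert b0[:3] == (0, 0, 0)
    # expanded box contains the tight box
    assert b0[3] >= 4 and b0[4] >= 4 and b0[5] >= 4


def test_extract_patch_identity_and_constant():
    img = RNG.normal(size=(120, 120, 50))
    bbox = (10, 10, 9, 106, 106, 41)  # exactly 96 x 96 x 32
    out = extract_patch(img, bbox)
    np.testing.assert_allclose(out, img[10:106, 10:106, 9:41], atol=1e-5)
    const = np.full((50, 60, 40), 4.2)
    out2 = extract_patch(const, (5, 5, 5, 45, 45, 25))
    np.testing.assert_allclose(out2, 4.2, atol=1e-9)


def test_extract_patch_extreme_aspect_preserved():
    """A 96x96x8 crop (scale ratio 4:1) triggers uniform-scale + padding."""
    img = np.zeros((120, 120, 20))
    img[10:106, 10:106, 5:13] = 1.0
    out = extract_patch(img, (10, 10, 5, 106, 106, 13))
    assert out.shape == (96, 96, 32)
    # content occupies the full in-plane extent but only ~8 of 32 slices
    occupied = np.where(out.max(axis=(0, 1)) > 0.5)[0]
    in_aspect = 96 / 8.0
    out_aspect = 96.0 / len(occupied)
    assert abs(out_aspect - in_aspect) / in_aspect < 0.05
    # symmetric padding
    assert occupied.min() >= 10 and occupied.max() <= 21


def test_normalize_roi_guard_range_and_hand_zscore():
    assert (normalize_roi(np.full((4, 4, 4), 9.0)) == 0).all()
    patch = RNG.normal(100, 10, size=(96, 96, 32))
    out = normalize_roi(patch)
    assert out.min() >= -3.0 and out.max() <= 3.0
    # value at mu + 3 sigma clips exactly to 3
    p = np.concatenate([np.full(500, 90.0), np.full(500, 110.0), [130.0]])
    mu, sd = p.mean(), p.std()
    z = np.clip((130.0 - mu) / (sd + 1e-6), -3, 3)
    got = normalize_roi(p.reshape(-1, 1, 1))
    assert got.ravel()[-1] == pytest.approx(z)
    assert got.ravel()[-1] == 3.0 or z < 3.0


def test_region_confidence_ideal_and_split():
    mask = np.zeros((16, 16, 8), dtype=int)
    mask[4:10, 4:10, 2:6] = 2
    probs = _onehot_probs(mask)
    conf = pixel_confidence(probs, [probs], W)
    comps = connected_components(mask, 2)
    s = region_confidence(comps[0], probs[2], conf)
    assert s == pytest.approx(1.0, abs=1e-6)
    # equal-size twin component in the same box -> spatial consistency 0.5
    mask2 = np.zeros_like(mask)
    mask2[4:10, 4:10, 1:3] = 2
    mask2[4:10, 4:10, 5:7] = 2
    probs2 = _onehot_probs(mask2)
    conf2 = pixel_confidence(probs2, [probs2], W)
    comps2 = connected_components(mask2, 2, v_min=1)
    assert len(comps2) == 2 and len(comps2[0]) == len(comps2[1])
    big_box = (0, 0, 0, 16, 16, 8)
    s2 = region_confidence(comps2[0], probs2[2], conf2, bbox=big_box)
    # certainty 1, sharpness 1, consistency 0.5
    assert s2 == pytest.approx((1.0 + 1.0 + 0.5) / 3.0, abs=1e-6)


def test_roi_pipeline_oracle_mask_single_cyst():
    spec = PhantomSpec(seed=2)
    v = generate_phantom(spec, "R1", "cyst")
    probs = _onehot_probs(v.mask.astype(int))
    recs = roi_pipeline(v.image, probs, v.patient_id)
    assert len(recs) == 1
    r = recs[0]
    assert r.predicted_class == "cyst"
    assert r.patch.shape == (96, 96, 32)
    assert 0.0 <= r.confidence_S <= 1.0
    assert r.voxel_count == (v.mask == 2).sum() >= 27


def test_roi_pipeline_speckle_noise_goes_normal():
    """Only sub-threshold speckle components: no pathological ROI, one
    whole-kidney normal ROI."""
    spec = PhantomSpec(seed=4)
    v = generate_phantom(spec, "R2", "normal")
    mask = v.mask.astype(int)
    rng = np.random.default_rng(0)
    kidney_vox = np.argwhere(mask == 1)
    for _ in range(10):  # implant 10 isolated 1-voxel "tumor" speckles
        i = rng.integers(len(kidney_vox))
        mask[tuple(kidney_vox[i])] = 3
    probs = _onehot_probs(mask)
    recs = roi_pipeline(v.image, probs, v.patient_id)
    assert len(recs) == 1
    assert recs[0].predicted_class == "normal"


def test_roi_pipeline_deterministic():
    spec = PhantomSpec(seed=6)
    v = generate_phantom(spec, "R3", "stone")
    probs = _onehot_probs(v.mask.astype(int))
    a = roi_pipeline(v.image, probs, v.patient_id)
    b = roi_pipeline(v.image, probs, v.patient_id)
    assert len(a) == len(b)
    for ra, rb in zip(a, b):
        np.testing.assert_array_equal(ra.patch, rb.patch)
        assert ra.source_bbox == rb.source_bbox
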