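"""Particle filter: boundary geometry, filter steps and marginals."""

import numpy as np
import pytest

from uncertainscan import (
    CueMeasurement,
    SegmentationBelief,
    boundary_distance,
    boundary_likelihood,
    entropy_map,
    incorporate,
    map_segmentation,
    predict,
    resample,
    uncertainty,
    weight,
)
from uncertainscan.segmentation import (
    LN2,
    boundary_cracks,
    boundary_mask,
    warp_labels,
)


def vertical_split(h, w, col):
    """Raster split into left/right halves at crack column ``col``."""
    out = np.zeros((h, w), dtype=np.int32)
    out[:, col:] = 1
    return out


def brute_chamfer(a, b, sentinel):
    """Reference symmetric mean chamfer distance via double loops."""
    ca, cb = boundary_cracks(a), boundary_cracks(b)
    if ca.size == 0 and cb.size == 0:
        return 0.0
    if ca.size == 0 or cb.size == 0:
        return sentinel
    def one_way(p, q):
        return np.mean([np.sqrt(((pt - q) ** 2).sum(axis=1)).min() for pt in p])
    return 0.5 * (one_way(ca, cb) + one_way(cb, ca)) / 2.0


# -------------------------------------------------------------------------
# Boundary geometry
# -------------------------------------------------------------------------


def test_uniform_raster_has_no_cracks():
    assert boundary_cracks(np.zeros((6, 6), np.int32)).size == 0
    assert not boundary_mask(np.full((6, 6), 3, np.int32)).any()


def test_parallel_splits_d_apart_have_distance_d():
    h, w = 16, 32
    for d in (1, 3, 7):
        a = vertical_split(h, w, 10)
        b = vertical_split(h, w, 10 + d)
        assert boundary_distance(a, b) == pytest.approx(float(d), abs=1e-12)


def test_boundary_distance_zero_iff_same_partition():
    a = vertical_split(8, 8, 4)
    assert boundary_distance(a, a) == 0.0
    relabeled = 5 - a  # same partition, different labels
    assert boundary_distance(a, relabeled) == 0.0
    assert boundary_distance(a, vertical_split(8, 8, 5)) > 0.0


def test_boundary_free_raster_yields_sentinel():
    a = vertical_split(8, 8, 4)
    empty = np.zeros((8, 8), np.int32)
    assert boundary_distance(a, empty) == pytest.approx(np.hypot(8, 8))
    assert boundary_distance(empty, empty) == 0.0


def test_boundary_distance_shape_mismatch():
    with pytest.raises(ValueError):
        boundary_distance(np.zeros((4, 4), np.int32), np.zeros((4, 5), np.int32))


def test_mask_only_measurement_ignores_remote_structure():
    h = w = 40
    base = np.zeros((h, w), np.int32)
    base[4:10, 4:10] = 1
    with_remote = base.copy()
    with_remote[30:36, 30:36] = 2  # far away from the measured mask
    mask = np.zeros((h, w), np.int32)
    mask[4:10, 4:10] = 1
    m = CueMeasurement("prompted", mask, prompt_point=(6.0, 6.0), mask_only=True)
    d1 = boundary_distance(base, m, window_px=4)
    d2 = boundary_distance(with_remote, m, window_px=4)
    assert d1 == pytest.approx(d2)
    assert d1 == pytest.approx(0.0, abs=1e-12)


def test_boundary_mask_is_two_pixels_thick():
    a = vertical_split(6, 8, 4)
    bm = boundary_mask(a)
    assert bm[:, 3].all() and bm[:, 4].all()
    assert not bm[:, :3].any() and not bm[:, 5:].any()


# -------------------------------------------------------------------------
# Filter steps
# -------------------------------------------------------------------------


def make_belief(rasters, weights=None, seed=0):
    rasters = np.stack(rasters).astype(np.int32)
    p = rasters.shape[0]
    w = np.full(p, 1.0 / p) if weights is None else np.asarray(weights, float)
    return SegmentationBelief(rasters, w, np.random.default_rng(seed))


def test_warp_labels_integer_translation():
    labels = vertical_split(8, 8, 4)
    flow = np.zeros((8, 8, 2))
    flow[:, :, 0] = 2.0  # shift right
    out = warp_labels(labels, flow)
    assert np.array_equal(out[:, 2:8], labels[:, 0:6])
    # holes on the left take the nearest filled label
    assert (out[:, :2] == 0).all()


def test_warp_labels_nan_flow_is_an_error():
    flow = np.full((4, 4, 2), np.nan)
    with pytest.raises(ValueError):
        warp_labels(np.zeros((4, 4), np.int32), flow)


def test_predict_preserves_weights_and_moves_labels():
    belief = make_belief([vertical_split(8, 8, 3), vertical_split(8, 8, 5)],
                         weights=[0.25, 0.75])
    flow = np.zeros((8, 8, 2))
    flow[:, :, 0] = 1.0
    out = predict(belief, flow)
    assert np.allclose(out.weights, [0.25, 0.75])
    assert np.array_equal(out.labels[0], vertical_split(8, 8, 4))
    assert np.array_equal(out.labels[1], vertical_split(8, 8, 6))


def test_weight_matches_exponential_boundary_likelihood():
    h = w = 16
    a = vertical_split(h, w, 6)
    b = vertical_split(h, w, 10)
    meas = CueMeasurement("semantic", vertical_split(h, w, 6), confidence=2.0)
    belief = make_belief([a, b])
    lam = 5.0
    out = weight(belief, [meas], lambda_d=lam)
    d_a = boundary_distance(a, meas.labels)
    d_b = boundary_distance(b, meas.labels)
    expected = np.exp(-2.0 * np.array([d_a, d_b]) / lam)
    expected /= expected.sum()
    assert np.allclose(out.weights, expected, rtol=1e-12)


def test_weight_multiplies_over_measurements():
    h = w = 16
    rasters = [vertical_split(h, w, c) for c in (4, 8, 12)]
    ms = [CueMeasurement("semantic", vertical_split(h, w, 6)),
          CueMeasurement("appearance", vertical_split(h, w, 9), confidence=1.5)]
    belief = make_belief(rasters)
    out = weight(belief, ms, lambda_d=3.0)
    loglik = np.zeros(3)
    for m in ms:
        for i, r in enumerate(rasters):
            loglik[i] -= m.confidence * boundary_distance(r, m.labels) / 3.0
    expected = np.exp(loglik - loglik.max())
    expected /= expected.sum()
    assert np.allclose(out.weights, expected, rtol=1e-12)


def test_weight_mask_only_windowing():
    h = w = 32
    near = np.zeros((h, w), np.int32); near[4:10, 4:10] = 1
    far = np.zeros((h, w), np.int32); far[22:28, 22:28] = 1
    mask = np.zeros((h, w), np.int32); mask[4:10, 4:10] = 1
    m = CueMeasurement("prompted", mask, confidence=3.0,
                       prompt_point=(6.0, 6.0), mask_only=True)
    belief = make_belief([near, far])
    out = weight(belief, [m], lambda_d=4.0, mask_window_px=4.0)
    # the particle agreeing inside the window dominates; the far one has no
    # boundary there and is punished with the window sentinel
    assert out.weights[0] > out.weights[1]
    d_near = boundary_distance(near, m, window_px=4.0)
    d_far = boundary_distance(far, m, window_px=4.0)
    expected = np.exp(-3.0 * np.array([d_near, d_far]) / 4.0)
    expected /= expected.sum()
    assert np.allclose(out.weights, expected, rtol=1e-12)


def test_weight_invalid_lambda():
    belief = make_belief([vertical_split(4, 4, 2)])
    with pytest.raises(ValueError):
        weight(belief, [], lambda_d=0.0)


def test_resample_concentrates_on_heavy_particle():
    a, b = vertical_split(8, 8, 3), vertical_split(8, 8, 5)
    belief = make_belief([a, b], weights=[1.0, 0.0])
    out = resample(belief)
    assert np.allclose(out.weights, 1.0 / 2)
    assert all(np.array_equal(out.labels[i], a) for i in range(2))


def test_resample_is_deterministic_given_rng_state():
    rasters = [vertical_split(8, 8, c) for c in (2, 4, 6)]
    out1 = resample(make_belief(rasters, weights=[0.6, 0.3, 0.1], seed=9))
    out2 = resample(make_belief(rasters, weights=[0.6, 0.3, 0.1], seed=9))
    assert np.array_equal(out1.labels, out2.labels)


def test_incorporate_mask_only_overwrites_fresh_label():
    base = vertical_split(8, 8, 4)
    mask = np.zeros((8, 8), np.int32)
    mask[2:5, 2:5] = 1
    m = CueMeasurement("prompted", mask, prompt_point=(3.0, 3.0), mask_only=True)
    belief = make_belief([base, base], seed=1)
    out = incorporate(belief, [m], fraction=1.0)
    for i in range(2):
        vals = np.unique(out.labels[i][mask > 0])
        assert vals.size == 1
        assert vals[0] not in np.unique(base)  # fresh label
        assert np.array_equal(out.labels[i][mask == 0], base[mask == 0])


def test_incorporate_full_frame_adopts_partition():
    base = vertical_split(8, 8, 4)
    m = CueMeasurement("semantic", vertical_split(8, 8, 6))
    belief = make_belief([base], seed=1)
    out = incorporate(belief, [m], fraction=1.0)
    assert boundary_distance(out.labels[0], m.labels) == 0.0


def test_incorporate_fraction_and_validation():
    base = vertical_split(8, 8, 4)
    belief = make_belief([base] * 10, seed=2)
    m = CueMeasurement("semantic", vertical_split(8, 8, 6))
    out = incorporate(belief, [m], fraction=0.25)
    changed = sum(
        boundary_distance(out.labels[i], m.labels) == 0.0 for i in range(10)
    )
    assert changed == 3  # ceil(0.25 * 10)
    same = incorporate(belief, [m], fraction=0.0)
    assert np.array_equal(same.labels, belief.labels)
    with pytest.raises(ValueError):
        incorporate(belief, [m], fraction=1.5)


def test_unique_cache_consistency_through_all_steps():
    rng = np.random.default_rng(0)
    rasters = [vertical_split(12, 12, c) for c in (3, 3, 6, 9)]
    belief = make_belief(rasters, seed=3)
    m = CueMeasurement("semantic", vertical_split(12, 12, 5))
    flow = np.zeros((12, 12, 2)); flow[:, :, 1] = 1.0
    for step in (lambda b: predict(b, flow),
                 lambda b: weight(b, [m], 4.0),
                 lambda b: incorporate(b, [m], 0.5),
                 lambda b: resample(b)):
        belief = step(belief)
        uniq, inverse = belief.unique()
        assert np.array_equal(uniq[inverse], belief.labels)


# -------------------------------------------------------------------------
# Marginals
# -------------------------------------------------------------------------


def test_boundary_likelihood_hand_computed():
    a, b = vertical_split(8, 8, 4), vertical_split(8, 8, 6)
    belief = make_belief([a, b], weights=[0.75, 0.25])
    pb = boundary_likelihood(belief)
    assert np.allclose(pb[:, 3], 0.75) and np.allclose(pb[:, 4], 0.75)
    assert np.allclose(pb[:, 5], 0.25) and np.allclose(pb[:, 6], 0.25)
    assert np.allclose(pb[:, :3], 0.0) and np.allclose(pb[:, 7], 0.0)


def test_entropy_map_values():
    pb = np.array([[0.0, 0.5, 1.0]])
    H = entropy_map(pb)
    assert H[0, 0] == 0.0 and H[0, 2] == 0.0
    assert H[0, 1] == pytest.approx(LN2)
    with pytest.raises(ValueError):
        entropy_map(np.array([[1.5]]))


def test_map_segmentation_roundtrip():
    labels = np.zeros((24, 24), np.int32)
    labels[4:12, 4:12] = 1
    labels[14:22, 14:20] = 2
    belief = make_belief([labels])
    seg = map_segmentation(boundary_likelihood(belief))
    # identical partition up to renaming
    for v in np.unique(labels):
        region = seg[labels == v]
        assert len(np.unique(region)) == 1
    assert len(np.unique(seg)) == len(np.unique(labels))


def test_map_segmentation_validation():
    with pytest.raises(ValueError):
        map_segmentation(np.zeros((4, 4)), threshold=0.0)


def test_uncertainty_rescaling_bounds():
    H = np.zeros((16, 16))
    H[8, 8] = LN2
    umap = uncertainty(H, blur_sigma_dva=1.0, u_min=1.0 / 3.0, px_per_dva=2.0)
    assert umap.U.min() >= 0.0 and umap.U.max() <= 1.0
    assert umap.U_prime.min() >= 1.0 / 3.0 and umap.U_prime.max() <= 1.0
    assert np.allclose(umap.U_prime, 1.0 / 3.0 + (2.0 / 3.0) * umap.U)
    flat = uncertainty(H, 1.0, u_min=1.0, px_per_dva=2.0)
    assert np.allclose(flat.U_prime, 1.0)  # u_min = 1 disables uncertainty
    with pytest.raises(ValueError):
        uncertainty(H, 1.0, u_min=-0.1, px_per_dva=2.0)
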