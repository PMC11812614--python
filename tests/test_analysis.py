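"""Analysis layer: categories, fits, KS statistics, angle profile, grid search."""

import numpy as np
import pandas as pd
import pytest

from uncertainscan import (
    ModelParams,
    SyntheticCueProvider,
    angle_profile,
    build_scanpath,
    category_shares,
    category_time_course,
    classify_foveations,
    fit_distribution,
    generate_scene,
    grid_search,
    ks_statistic,
    simulate,
)
from uncertainscan.analysis import (
    N_ANGLE_BINS,
    angle_bin,
    relative_angle_durations,
    _circular_moving_average,
)

from conftest import NOISELESS, small_spec


def make_path(gt_ids, angles=None, dur=100.0, seed=0):
    """Alternating event table with the given per-foveation ground-truth IDs."""
    foveations, saccades = [], []
    t = 0.0
    for k, gid in enumerate(gt_ids):
        foveations.append({"t_start_ms": t, "t_end_ms": t + dur, "duration_ms": dur,
                           "x_px": 0.0, "y_px": 0.0, "object_id": k + 1,
                           "gt_object_id": gid})
        t += dur
        if k < len(gt_ids) - 1:
            ang = angles[k] if angles else 0.0
            saccades.append({"t_start_ms": t, "t_end_ms": t + 30.0, "duration_ms": 30.0,
                             "x_px": 0.0, "y_px": 0.0, "object_id": k + 2,
                             "gt_object_id": np.nan, "amplitude_dva": 2.0,
                             "angle_deg": ang})
            t += 30.0
    return build_scanpath(foveations, saccades, "unit", seed, 30.0, 4.0)


# ---------------------------------------------------------------------------
# Foveation categories
# ---------------------------------------------------------------------------


def test_classification_rules():
    sp = classify_foveations(make_path([0, 1, 1, 2, 1]))
    assert list(sp.foveations.category) == [
        "Background", "Detection", "Inspection", "Detection", "Return"]


def test_classification_partitions_foveations():
    sp = classify_foveations(make_path([0, 3, 3, 0, 2, 3, 2, 2]))
    cats = sp.foveations.category
    assert cats.notna().all()
    assert set(cats) <= {"Background", "Detection", "Inspection", "Return"}


def test_classification_from_gt_labels_lookup():
    sp = make_path([0, 0])
    sp.events["gt_object_id"] = np.nan
    gt = np.zeros((9, 8, 8), dtype=np.int32)
    gt[:, 0, 0] = 5  # the gaze position in make_path is (0, 0)
    out = classify_foveations(sp, gt_labels=gt)
    assert list(out.foveations.category) == ["Detection", "Inspection"]
    with pytest.raises(ValueError):
        classify_foveations(make_path([0]).events.pipe(
            lambda e: None) or _strip_gt(make_path([0])))


def _strip_gt(sp):
    sp.events["gt_object_id"] = np.nan
    return classify_foveations(sp)


def test_category_shares_are_time_weighted():
    a = classify_foveations(make_path([1, 1]))        # Detection, Inspection
    b = classify_foveations(make_path([0], dur=200))  # Background, twice as long
    shares = category_shares([a, b])
    assert shares.sum() == pytest.approx(1.0)
    assert shares["Detection"] == pytest.approx(100 / 400)
    assert shares["Inspection"] == pytest.approx(100 / 400)
    assert shares["Background"] == pytest.approx(200 / 400)
    assert shares["Return"] == 0.0
    with pytest.raises(ValueError):
        category_shares([make_path([0])])  # no categories assigned yet


def test_category_time_course_rows_sum_to_one():
    sps = [classify_foveations(make_path([0, 1, 2, 1, 1, 3]))]
    tc = category_time_course(sps, window_ms=150.0)
    assert np.allclose(tc.sum(axis=1), 1.0)
    assert list(tc.columns) == ["Background", "Detection", "Inspection", "Return"]


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------


def brute_ks(a, b):
    pts = np.concatenate([a, b])
    return max(abs(np.mean(a <= x) - np.mean(b <= x)) for x in pts)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ks_statistic_matches_brute_force(seed, rng):
    r = np.random.default_rng(seed)
    a = r.normal(size=int(r.integers(5, 100)))
    b = r.normal(0.3, 1.2, size=int(r.integers(5, 100)))
    assert ks_statistic(a, b) == pytest.approx(brute_ks(a, b), abs=1e-12)
    with pytest.raises(ValueError):
        ks_statistic(a, np.array([]))


def test_lognormal_fit_closed_form():
    logs = np.array([0.1, 0.5, 1.0, 1.2, 2.0])
    fit = fit_distribution(np.exp(logs), "lognormal")
    assert fit.params["mu"] == pytest.approx(logs.mean())
    assert fit.params["sigma"] == pytest.approx(logs.std(ddof=0))
    assert fit.expected_value == pytest.approx(
        np.exp(logs.mean() + logs.std(ddof=0) ** 2 / 2))


def test_gamma_fit_recovers_parameters():
    rng = np.random.default_rng(42)
    sample = rng.gamma(shape=3.0, scale=0.5, size=20000)
    fit = fit_distribution(sample, "gamma")
    assert fit.params["alpha"] == pytest.approx(3.0, rel=0.05)
    assert fit.params["beta"] == pytest.approx(2.0, rel=0.05)
    assert fit.expected_value == pytest.approx(1.5, rel=0.03)


def test_fit_distribution_errors():
    with pytest.raises(ValueError):
        fit_distribution(np.array([1.0, -1.0]), "lognormal")
    with pytest.raises(ValueError):
        fit_distribution(np.array([]), "gamma")
    with pytest.raises(ValueError):
        fit_distribution(np.array([1.0]), "weibull")


# ---------------------------------------------------------------------------
# Temporal-IOR angle profile
# ---------------------------------------------------------------------------


def test_angle_bin_edges():
    assert angle_bin(-168.0) == 0      # bins are half-open (lo, hi]
    assert angle_bin(-167.9) == 1
    assert angle_bin(0.0) == 14
    assert angle_bin(0.1) == 15
    assert angle_bin(180.0) == N_ANGLE_BINS - 1
    assert angle_bin(-180.0) == N_ANGLE_BINS - 1  # +-180 share the terminal bin
    assert angle_bin(540.0) == N_ANGLE_BINS - 1


def test_collinear_saccades_fill_only_the_zero_bin():
    sp = make_path([1, 2, 3, 1, 2], angles=[30.0, 30.0, 30.0, 30.0])
    prof = angle_profile([sp])
    nonzero = np.nonzero(prof.counts)[0]
    assert list(nonzero) == [angle_bin(0.0)]
    assert prof.counts[angle_bin(0.0)] == 3  # first saccade has no reference


def test_angle_profile_hand_built_oracle():
    # 6 events: 3 foveations of known durations, saccades at 0, 90, 80 degrees
    foveations, saccades = [], []
    durs = [100.0, 150.0, 240.0, 60.0]
    angs = [0.0, 90.0, 80.0]
    t = 0.0
    for k, d in enumerate(durs):
        foveations.append({"t_start_ms": t, "t_end_ms": t + d, "duration_ms": d,
                           "x_px": 0.0, "y_px": 0.0, "object_id": 1,
                           "gt_object_id": 0})
        t += d
        if k < len(angs):
            saccades.append({"t_start_ms": t, "t_end_ms": t + 30, "duration_ms": 30.0,
                             "x_px": 0.0, "y_px": 0.0, "object_id": 1,
                             "gt_object_id": np.nan, "amplitude_dva": 1.0,
                             "angle_deg": angs[k]})
            t += 30.0
    sp = build_scanpath(foveations, saccades, "unit", 0, 30.0, 4.0)
    pairs = relative_angle_durations([sp])
    # saccade 2: rel 90 after foveation of 150 ms; saccade 3: rel -10 after 240 ms
    assert pairs == [(90.0, 150.0), (-10.0, 240.0)]
    prof = angle_profile([sp])
    assert prof.medians[angle_bin(90.0)] == 150.0
    assert prof.medians[angle_bin(-10.0)] == 240.0
    assert prof.counts.sum() == 2
    # smoothing: isolated bins keep their own value (window renormalized)
    assert prof.smoothed[angle_bin(90.0)] == 150.0


def test_smoothing_preserves_mean_for_full_profiles():
    values = np.arange(N_ANGLE_BINS, dtype=float) ** 1.3
    sm = _circular_moving_average(values, 5)
    assert sm.mean() == pytest.approx(values.mean())
    with_gap = values.copy()
    with_gap[3] = np.nan
    sm = _circular_moving_average(with_gap, 5)
    assert not np.isnan(sm[3])  # missing bins are interpolated from neighbours


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_scene():
    return generate_scene(small_spec(n_frames=10), seed=0)


def test_grid_search_self_consistency(tiny_scene):
    """The generating parameter set scores a perfect (zero) KS distance."""
    base = ModelParams()
    factory = lambda s: SyntheticCueProvider(noise=NOISELESS, seed=s)
    ref = simulate(tiny_scene, provider=factory(0), params=base, seed=0,
                   classify=False)
    grid = {"theta": [3.0, 4.0]}
    res = grid_search([tiny_scene], grid, ref.foveation_durations,
                      ref.saccade_amplitudes, n_seeds=1, base_params=base,
                      provider_factory=factory, refine=False, seed0=0)
    assert res.best.theta == 4.0  # the generating value
    assert res.best.score == 0.0
    assert set(res.table.columns) >= {"theta", "D_FD", "D_SA", "score", "error"}
    assert res.table.score.between(0, 1).all()


def test_grid_search_deterministic_and_order_invariant(tiny_scene):
    base = ModelParams()
    factory = lambda s: SyntheticCueProvider(noise=NOISELESS, seed=s)
    ref_d = np.array([100.0, 150.0, 200.0])
    ref_a = np.array([1.0, 2.0, 3.0])
    g1 = {"theta": [3.0, 4.0], "f_min": [0.3]}
    g2 = {"f_min": [0.3], "theta": [4.0, 3.0]}
    r1 = grid_search([tiny_scene], g1, ref_d, ref_a, n_seeds=1, base_params=base,
                     provider_factory=factory, refine=False)
    r1b = grid_search([tiny_scene], g1, ref_d, ref_a, n_seeds=1, base_params=base,
                      provider_factory=factory, refine=False)
    r2 = grid_search([tiny_scene], g2, ref_d, ref_a, n_seeds=1, base_params=base,
                     provider_factory=factory, refine=False)
    pd.testing.assert_frame_equal(r1.table, r1b.table)
    # per-point scores do not depend on the order the grid dict lists values
    s1 = r1.table.set_index(["theta", "f_min"]).score.sort_index()
    s2 = r2.table.set_index(["theta", "f_min"]).score.sort_index()
    pd.testing.assert_series_equal(s1, s2)


def test_grid_search_keeps_invalid_points_with_error(tiny_scene):
    base = ModelParams()
    factory = lambda s: SyntheticCueProvider(noise=NOISELESS, seed=s)
    grid = {"theta": [4.0, -1.0]}  # -1 violates theta > 0
    with pytest.warns(UserWarning):
        res = grid_search([tiny_scene], grid, np.array([100.0]), np.array([1.0]),
                          n_seeds=1, base_params=base, provider_factory=factory,
                          refine=False)
    bad = res.table[res.table.theta == -1.0]
    assert len(bad) == 1
    assert np.isnan(bad.score.iloc[0]) and bad.error.iloc[0] != ""
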