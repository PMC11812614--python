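"""Multi-alternative drift-diffusion scanpath engine.

Every frame, three rasters are multiplied into an evidence map
``E = S * F' * U'``: the gaze-dependent visual sensitivity ``S`` (a
peak-normalized isotropic Gaussian of spread sigma_S, overwritten with 1 on
the currently foveated perceptual unit), the floor-rescaled feature map
``F'`` and the floor-rescaled segmentation-uncertainty map ``U'``.  Each
segment of the current most-likely segmentation is a potential saccade
target ``i`` accumulating evidence ``V_i`` at a drift rate given by the mean
evidence over its mask times a logarithmic area factor, perturbed by
Gaussian diffusion noise.  The first accumulator to cross the shared
threshold theta triggers a saccade: a landing point is sampled within the
target mask, the saccade duration follows a linear amplitude-duration law,
and all accumulators reset.  Between saccades the gaze point moves with the
optical flow (fixation or smooth pursuit).  Optional extensions: saccadic
momentum, presaccadic attention, and a saccadic dead time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from . import segmentation as seg
from .scanpath import Scanpath, build_scanpath, wrap_angle
from .scene import CueProvider, Scene, SyntheticCueProvider
from .tracking import TrackState, match_ids


@dataclass
class MomentumParams:
    """Saccadic-momentum extension: sensitivity raised along the previous
    saccade's direction, decaying linearly with angular deviation."""

    enabled: bool = False
    max_value: float = 1.0
    min_value: float = 0.5
    angle_range_deg: float = 180.0


@dataclass
class PresaccadicParams:
    """Presaccadic-attention extension: objects whose evidence exceeds
    ``trigger_fraction * theta`` get full sensitivity, as if foveated."""

    enabled: bool = False
    trigger_fraction: float = 0.3


@dataclass
class ModelParams:
    """Free and fixed parameters of the saccadic decision process.

    ``theta`` (decision threshold) and ``s`` (diffusion noise) are the free
    DDM parameters; ``f_min``/``u_min`` rescale the feature and uncertainty
    maps into [f_min, 1]/[u_min, 1], trading off their influence;
    ``sigma_s_dva`` = 7 dva is the sensitivity spread; the update step is
    one frame.  ``dead_time_ms`` > 0 prolongs each foveation by a saccadic
    dead time during which no evidence is accumulated (use theta 3.5 with
    the 50 ms dead time to preserve foveation durations).
    """

    f_min: float = 0.3
    u_min: float = 1.0 / 3.0
    theta: float = 4.0
    s: float = 0.3
    sigma_s_dva: float = 7.0
    dt: float = 1.0  # frames
    momentum: MomentumParams = field(default_factory=MomentumParams)
    presaccadic: PresaccadicParams = field(default_factory=PresaccadicParams)
    dead_time_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.s < 0 or self.sigma_s_dva <= 0:
            raise ValueError("require theta > 0, s >= 0, sigma_S > 0")
        if not 0 < self.presaccadic.trigger_fraction < 1:
            raise ValueError("trigger_fraction must lie in (0, 1)")


@dataclass
class GazeState:
    """Current gaze position (px), foveated unit and saccade history."""

    position: tuple[float, float]
    foveated_object: int | None = None
    prev_saccade_angle: float | None = None


@dataclass
class DecisionState:
    """Per-object accumulators of the multi-option drift-diffusion model."""

    V: dict[int, float] = field(default_factory=dict)
    last_reset_frame: int = -1


# ---------------------------------------------------------------------------
# Map construction
# ---------------------------------------------------------------------------


def scale_feature(F: np.ndarray, f_min: float) -> np.ndarray:
    """Linearly rescale a [0, 1] feature map into [f_min, 1]."""
    F = np.asarray(F, dtype=np.float64)
    if F.size and (F.min() < -1e-6 or F.max() > 1 + 1e-6):
        raise ValueError("feature map must lie in [0, 1]")
    return f_min + (1.0 - f_min) * F


def sensitivity_map(
    gaze: GazeState,
    foveated_mask: np.ndarray,
    params: ModelParams,
    px_per_dva: float,
    presaccadic_masks: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Gaze-dependent visual sensitivity S in (0, 1].

    Peak-normalized isotropic Gaussian around the gaze position (sigma_S),
    uniform (1) across the foveated object.  With momentum enabled the map is
    multiplied by an angle-preference raster; presaccadic target objects are
    then set to 1 as if foveated.
    """
    h, w = foveated_mask.shape
    x0, y0 = gaze.position
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    sigma = params.sigma_s_dva * px_per_dva
    s_map = np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))
    s_map[foveated_mask] = 1.0
    if params.momentum.enabled and gaze.prev_saccade_angle is not None:
        mom = params.momentum
        ang = np.degrees(np.arctan2(-(yy - y0), xx - x0))
        dev = np.abs(wrap_angle(ang - gaze.prev_saccade_angle))
        pref = mom.max_value - (mom.max_value - mom.min_value) * np.minimum(
            dev, mom.angle_range_deg
        ) / mom.angle_range_deg
        pref[int(round(y0)) % h, int(round(x0)) % w] = mom.max_value
        s_map = s_map * pref
    if params.presaccadic.enabled and presaccadic_masks:
        for mask in presaccadic_masks:
            s_map[mask] = 1.0
    return s_map


def evidence_map(S: np.ndarray, F_prime: np.ndarray, U_prime: np.ndarray) -> np.ndarray:
    """Elementwise product E = S * F' * U'."""
    if not (S.shape == F_prime.shape == U_prime.shape):
        raise ValueError("maps must share shape")
    return S * F_prime * U_prime


def drift_rates(
    E: np.ndarray, segmentation: np.ndarray, px_per_dva: float
) -> dict[int, float]:
    """Per-object drift rate: mask-mean evidence times a log area factor.

    ``mu_i = mean(E over O_i) * max(1, log2(A_i))`` with the mask area A_i
    converted from px^2 to dva^2.
    """
    if px_per_dva <= 0:
        raise ValueError("px_per_dva must be positive")
    segmentation = np.asarray(segmentation)
    ids, inverse = np.unique(segmentation, return_inverse=True)
    areas = np.bincount(inverse.ravel())
    sums = np.bincount(inverse.ravel(), weights=E.ravel())
    out: dict[int, float] = {}
    for k, oid in enumerate(ids):
        if areas[k] == 0:
            continue
        area_dva = areas[k] / px_per_dva**2
        out[int(oid)] = float(sums[k] / areas[k] * max(1.0, np.log2(max(area_dva, 1e-12))))
    return out


# ---------------------------------------------------------------------------
# DDM dynamics
# ---------------------------------------------------------------------------


def ddm_step(
    state: DecisionState,
    mu: dict[int, float],
    params: ModelParams,
    nu: float,
    rng: np.random.Generator,
) -> tuple[DecisionState, tuple[int, float] | None]:
    """One drift-diffusion update; returns the threshold crossing, if any.

    Each accumulator is incremented by ``nu * (mu_i dt + s eps_i sqrt(dt))``
    with independent standard-normal ``eps_i``; ``nu`` is the fraction of the
    step spent foveating (no evidence is accumulated during saccades or dead
    time).  Assuming a linear update within the step, the exact sub-step
    crossing time of the threshold is interpolated; the earliest-crossing
    object wins (ties broken by larger drift, then lower ID), and all
    accumulators reset to zero.
    """
    if not 0.0 <= nu <= 1.0:
        raise ValueError("nu must lie in [0, 1]")
    ids = sorted(mu)
    v_old = np.array([state.V.get(i, 0.0) for i in ids])
    mus = np.array([mu[i] for i in ids])
    if nu == 0.0 or not ids:
        return DecisionState(V=dict(zip(ids, v_old)), last_reset_frame=state.last_reset_frame), None
    eps = rng.standard_normal(len(ids))
    dt = params.dt
    v_new = v_old + nu * (mus * dt + params.s * eps * np.sqrt(dt))
    crossed = v_new >= params.theta
    if not crossed.any():
        return DecisionState(V=dict(zip(ids, v_new)), last_reset_frame=state.last_reset_frame), None
    order = sorted(
        (
            float(np.clip((params.theta - v_old[k]) / (v_new[k] - v_old[k]), 0.0, 1.0)),
            -float(mus[k]),
            ids[k],
        )
        for k in range(len(ids))
        if crossed[k]
    )
    t_best, _, winner = order[0]
    return DecisionState(V={}, last_reset_frame=state.last_reset_frame), (winner, float(t_best))


def saccade_duration(amplitude_dva: float) -> float:
    """Linear amplitude-duration law: 2.7 ms/dva * amplitude + 23 ms."""
    if amplitude_dva < 0:
        raise ValueError("amplitude must be nonnegative")
    return 2.7 * amplitude_dva + 23.0


def sample_landing(
    target_mask: np.ndarray,
    F_prime: np.ndarray,
    S: np.ndarray,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Sample a landing pixel within the target, p ~ O_i * F' * S."""
    if not target_mask.any():
        raise ValueError("target mask is empty")
    weights = (target_mask * F_prime * S).ravel()
    total = weights.sum()
    if total <= 0:
        warnings.warn("degenerate landing distribution; sampling uniformly over the mask")
        weights = target_mask.ravel().astype(float)
        total = weights.sum()
    idx = rng.choice(weights.size, p=weights / total)
    h, w = target_mask.shape
    return (float(idx % w), float(idx // w))


def pursue(
    gaze: GazeState, flow: np.ndarray, frame_shape: tuple[int, int] | None = None
) -> GazeState:
    """Advance the gaze point with the bilinearly interpolated optical flow."""
    h, w = flow.shape[:2] if frame_shape is None else frame_shape
    x, y = gaze.position
    fx = _bilinear(flow[:, :, 0], x, y)
    fy = _bilinear(flow[:, :, 1], x, y)
    nx = float(np.clip(x + fx, 0.0, w - 1.0))
    ny = float(np.clip(y + fy, 0.0, h - 1.0))
    return replace(gaze, position=(nx, ny))


def _bilinear(raster: np.ndarray, x: float, y: float) -> float:
    h, w = raster.shape
    x = float(np.clip(x, 0, w - 1))
    y = float(np.clip(y, 0, h - 1))
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    dx, dy = x - x0, y - y0
    top = raster[y0, x0] * (1 - dx) + raster[y0, x1] * dx
    bot = raster[y1, x0] * (1 - dx) + raster[y1, x1] * dx
    return float(top * (1 - dy) + bot * dy)


# ---------------------------------------------------------------------------
# Full simulation loop
# ---------------------------------------------------------------------------


def simulate(
    scene: Scene,
    provider: CueProvider | None = None,
    params: ModelParams | None = None,
    seed: int = 0,
    filter_params: seg.FilterParams | None = None,
    use_prompt: bool = True,
    gt_objects: bool = False,
    initial_gaze: tuple[float, float] | None = None,
    classify: bool = True,
) -> Scanpath:
    """Simulate one scanpath on a scene; fully reproducible from ``seed``.

    Per frame: gather the global cues (plus the prompted cue at the current
    gaze), update the segmentation belief (predict, weight, incorporate,
    resample), marginalize to a most-likely segmentation with stable IDs and
    an uncertainty map, build S/F'/U' and the evidence map, accumulate
    evidence per object, and on a threshold crossing execute a saccade
    (otherwise pursue the scene motion at the gaze point).  With
    ``gt_objects`` the decision stage consumes the ground-truth objects as
    perceptual units while the uncertainty is still estimated by the filter.
    """
    if scene.n_frames < 2:
        raise ValueError("scene must have at least 2 frames")
    params = params or ModelParams()
    fp = filter_params or seg.FilterParams()
    provider = provider if provider is not None else SyntheticCueProvider(seed=seed)
    rng = np.random.default_rng(seed)
    h, w = scene.height, scene.width
    frame_ms = scene.frame_ms
    clip_end = scene.n_frames * frame_ms
    lambda_d = fp.lambda_d_dva * scene.px_per_dva
    window_px = fp.mask_window_dva * scene.px_per_dva

    if initial_gaze is None:
        initial_gaze = (float(rng.uniform(0, w - 1)), float(rng.uniform(0, h - 1)))
    gaze = GazeState(position=initial_gaze)
    track = TrackState()
    dstate = DecisionState()

    belief: seg.SegmentationBelief | None = None
    blocked_until = 0.0  # absolute ms before which no evidence accumulates
    pending_landing: tuple[float, float] | None = None

    foveations: list[dict] = []
    saccades: list[dict] = []
    trace: list[tuple[float, float]] = []
    trace_gt: list[int] = []
    trace_obj: list[int] = []
    traces: list[np.ndarray] = []
    fov_start = 0.0

    def close_foveation(end_ms: float) -> None:
        if end_ms <= fov_start or not trace:
            return
        arr = np.array(trace)
        gt_id = _majority(trace_gt)
        foveations.append(
            {
                "t_start_ms": fov_start,
                "t_end_ms": end_ms,
                "duration_ms": end_ms - fov_start,
                "x_px": float(arr[:, 0].mean()),
                "y_px": float(arr[:, 1].mean()),
                "object_id": _majority(trace_obj),
                "gt_object_id": gt_id,
            }
        )
        traces.append(arr)

    for t in range(scene.n_frames):
        frame_start = t * frame_ms
        frame_end = frame_start + frame_ms
        in_flight = pending_landing is not None and blocked_until >= frame_end
        if pending_landing is not None and blocked_until < frame_end:
            gaze = replace(gaze, position=pending_landing)
            pending_landing = None

        # --- perception: cues and belief update -------------------------
        measurements = provider.global_cues(scene, t)
        if use_prompt and not in_flight:
            prompted = provider.prompted(scene, t, gaze.position)
            if prompted is not None:
                measurements = measurements + [prompted]
        if belief is None:
            belief = seg.SegmentationBelief.from_measurements(
                measurements, (h, w), n_particles=fp.n_particles, rng=rng
            )
        else:
            belief = seg.predict(belief, scene.flow_at(t - 1))
        belief = seg.weight(belief, measurements, lambda_d, mask_window_px=window_px)
        belief = seg.incorporate(
            belief,
            [m for m in measurements if m.kind in fp.incorporate_kinds],
            fp.incorporate_fraction,
        )
        belief = seg.resample(belief)
        pb = seg.boundary_likelihood(belief)
        umap = seg.uncertainty(
            seg.entropy_map(pb), fp.blur_sigma_dva, params.u_min, scene.px_per_dva
        )

        # --- perceptual units -------------------------------------------
        if gt_objects:
            units = scene.gt_labels[t].astype(np.int32) + 1
        else:
            units, track = match_ids(seg.map_segmentation(pb, fp.pb_threshold), track)

        gx = int(np.clip(round(gaze.position[0]), 0, w - 1))
        gy = int(np.clip(round(gaze.position[1]), 0, h - 1))
        fov_unit = int(units[gy, gx])
        fov_mask = np.zeros((h, w), dtype=bool) if in_flight else units == fov_unit
        gaze = replace(gaze, foveated_object=None if in_flight else fov_unit)

        # --- evidence ----------------------------------------------------
        F_prime = scale_feature(scene.feature[t], params.f_min)
        presacc_masks = None
        if params.presaccadic.enabled:
            trigger = params.presaccadic.trigger_fraction * params.theta
            presacc_masks = [
                units == oid for oid, v in dstate.V.items() if v > trigger
            ]
        S = sensitivity_map(gaze, fov_mask, params, scene.px_per_dva, presacc_masks)
        E = evidence_map(S, F_prime, umap.U_prime)
        mu = drift_rates(E, units, scene.px_per_dva)

        acc_start = max(frame_start, blocked_until)
        nu = min(1.0, max(0.0, frame_end - acc_start) / frame_ms)
        dstate, crossing = ddm_step(dstate, mu, params, nu, rng)

        if not in_flight:
            trace.append(gaze.position)
            trace_obj.append(fov_unit)
            trace_gt.append(
                int(scene.gt_labels[t][gy, gx]) if scene.gt_labels is not None else 0
            )

        if crossing is not None:
            target, frac = crossing
            t_cross = acc_start + frac * (frame_end - acc_start)
            target_mask = units == target
            if not target_mask.any():  # vanished between steps; skip
                crossing = None
            else:
                landing = sample_landing(target_mask, F_prime, S, rng)
                dx = landing[0] - gaze.position[0]
                dy = landing[1] - gaze.position[1]
                amplitude = float(np.hypot(dx, dy)) / scene.px_per_dva
                tau_s = saccade_duration(amplitude)
                fov_end = min(t_cross + params.dead_time_ms, clip_end)
                sac_end = min(fov_end + tau_s, clip_end)
                close_foveation(fov_end)
                angle = float(np.degrees(np.arctan2(-dy, dx)))
                saccades.append(
                    {
                        "t_start_ms": fov_end,
                        "t_end_ms": sac_end,
                        "duration_ms": sac_end - fov_end,
                        "x_px": landing[0],
                        "y_px": landing[1],
                        "object_id": target,
                        "gt_object_id": np.nan,
                        "amplitude_dva": amplitude,
                        "angle_deg": angle,
                    }
                )
                gaze = replace(gaze, prev_saccade_angle=angle)
                blocked_until = fov_end + tau_s
                pending_landing = landing
                fov_start = blocked_until
                trace, trace_gt, trace_obj = [], [], []

        # --- gaze update: fixation or smooth pursuit ---------------------
        if pending_landing is None and t < scene.n_frames - 1:
            gaze = pursue(gaze, scene.flow[t], (h, w))

    if pending_landing is not None and saccades:
        # clip ended mid-saccade: truncate the saccade at the clip end
        saccades[-1]["t_end_ms"] = min(saccades[-1]["t_end_ms"], clip_end)
        saccades[-1]["duration_ms"] = saccades[-1]["t_end_ms"] - saccades[-1]["t_start_ms"]
        if saccades[-1]["duration_ms"] <= 0:
            saccades.pop()
    else:
        close_foveation(clip_end)

    path = build_scanpath(
        foveations,
        saccades,
        scene_id=scene.scene_id,
        seed=seed,
        fps=scene.fps,
        px_per_dva=scene.px_per_dva,
        traces=traces,
    )
    if classify and scene.gt_labels is not None:
        from .analysis import classify_foveations

        path = classify_foveations(path)
    return path


def _majority(values: list[int]) -> int:
    if not values:
        return 0
    vals, counts = np.unique(np.asarray(values), return_counts=True)
    return int(vals[np.argmax(counts)])
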