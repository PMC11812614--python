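"""Scene data model, pluggable cue providers, and the synthetic-scene generator.

A :class:`Scene` is an ordered stack of frames with per-frame dense optical
flow, a saliency/feature raster in [0, 1], and (for synthetic scenes)
ground-truth object and part label rasters.  Object-segmentation cues enter
the rest of the package only as :class:`CueMeasurement` objects produced by a
:class:`CueProvider`, so real vision backends can be dropped in behind the
same contract.  The bundled :class:`SyntheticCueProvider` emulates the
statistical structure of four cue types:

* *appearance* -- ground truth split into per-part segments; objects that are
  camouflaged against the background disappear from this cue,
* *motion* -- connected components of near-equal nonzero optical flow; static
  objects are counted toward the background,
* *semantic* -- whole-object ground truth with morphological boundary jitter
  and occasional whole-object merge errors,
* *prompted* -- a single high-confidence mask of the object under the current
  gaze position (or a local background patch when gaze rests on background).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage as ndi

#: Default display geometry: 38.2 dva across 1,536 px.
DISPLAY_PX_PER_DVA = 1536.0 / 38.2  # ~40.2

#: Confidence multipliers: the prompted foveal cue is trusted more than the
#: pre-attentive global cues.
GLOBAL_CUE_CONFIDENCE = 1.0
PROMPTED_CUE_CONFIDENCE = 3.0

GLOBAL_CUE_KINDS = ("appearance", "motion", "semantic")


# ---------------------------------------------------------------------------
# Core data types
# ---------------------------------------------------------------------------


@dataclass
class Scene:
    """A dynamic scene: frames, flow, features and optional ground truth.

    Parameters
    ----------
    feature : (T, H, W) float array
        Per-frame saliency/feature raster ``F`` in [0, 1].
    flow : (T-1, H, W, 2) float array
        Dense optical flow in px/frame mapping frame ``t`` to ``t+1``;
        last axis is ``(dx, dy)``.
    gt_labels : (T, H, W) int array, optional
        Ground-truth object labels (0 = background), identities stable over
        time.  Present for synthetic scenes.
    gt_parts : (T, H, W) int array, optional
        Ground-truth *part* labels; each object may consist of several parts
        with distinct appearance identities.
    px_per_dva : float
        Pixels per degree of visual angle.
    """

    feature: np.ndarray
    flow: np.ndarray
    gt_labels: np.ndarray | None = None
    gt_parts: np.ndarray | None = None
    fps: float = 30.0
    px_per_dva: float = DISPLAY_PX_PER_DVA
    scene_id: str = "scene"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature = np.asarray(self.feature, dtype=np.float32)
        self.flow = np.asarray(self.flow, dtype=np.float32)
        if self.feature.ndim != 3:
            raise ValueError("feature must be (T, H, W)")
        t, h, w = self.feature.shape
        if self.flow.shape != (max(t - 1, 0), h, w, 2):
            raise ValueError("flow must be (T-1, H, W, 2) and match feature")
        if self.feature.size and (self.feature.min() < -1e-6 or self.feature.max() > 1 + 1e-6):
            raise ValueError("feature raster must lie in [0, 1]")
        for name in ("gt_labels", "gt_parts"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.int32)
                if arr.shape != (t, h, w):
                    raise ValueError(f"{name} must be (T, H, W)")
                setattr(self, name, arr)

    @property
    def n_frames(self) -> int:
        return self.feature.shape[0]

    @property
    def height(self) -> int:
        return self.feature.shape[1]

    @property
    def width(self) -> int:
        return self.feature.shape[2]

    @property
    def frame_ms(self) -> float:
        return 1000.0 / self.fps

    def flow_at(self, t: int) -> np.ndarray:
        """Flow raster used for frame ``t`` (the last frame reuses T-2)."""
        return self.flow[min(t, self.n_frames - 2)]

    def save(self, path) -> None:
        """Write the scene as a compressed NPZ plus a small YAML sidecar."""
        import os

        os.makedirs(path, exist_ok=True)
        arrays = {"feature": self.feature, "flow": self.flow}
        if self.gt_labels is not None:
            arrays["gt_labels"] = self.gt_labels
        if self.gt_parts is not None:
            arrays["gt_parts"] = self.gt_parts
        np.savez_compressed(os.path.join(path, "scene.npz"), **arrays)
        info = {
            "fps": float(self.fps),
            "px_per_dva": float(self.px_per_dva),
            "scene_id": self.scene_id,
            "meta": _plain(self.meta),
        }
        with open(os.path.join(path, "scene.yaml"), "w") as fh:
            yaml.safe_dump(info, fh)

    @classmethod
    def load(cls, path) -> "Scene":
        import os

        with np.load(os.path.join(path, "scene.npz")) as npz:
            arrays = {k: npz[k] for k in npz.files}
        with open(os.path.join(path, "scene.yaml")) as fh:
            info = yaml.safe_load(fh)
        return cls(
            feature=arrays["feature"],
            flow=arrays["flow"],
            gt_labels=arrays.get("gt_labels"),
            gt_parts=arrays.get("gt_parts"),
            fps=info.get("fps", 30.0),
            px_per_dva=info.get("px_per_dva", DISPLAY_PX_PER_DVA),
            scene_id=info.get("scene_id", "scene"),
            meta=info.get("meta") or {},
        )


def _plain(obj):
    """Recursively convert numpy scalars/containers for YAML round-trips."""
    if isinstance(obj, dict):
        return {_plain(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class CueMeasurement:
    """One object-segmentation measurement entering the particle filter."""

    kind: str  # appearance | motion | semantic | prompted
    labels: np.ndarray  # int raster, 0 = background/absent
    confidence: float = GLOBAL_CUE_CONFIDENCE
    prompt_point: tuple[float, float] | None = None  # (x, y), prompted only
    mask_only: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.kind == "prompted":
            seg_ids = np.unique(self.labels[self.labels > 0])
            if seg_ids.size != 1:
                raise ValueError("prompted measurement must contain exactly one segment")
            if self.prompt_point is None:
                raise ValueError("prompted measurement requires prompt_point")
            x, y = int(round(self.prompt_point[0])), int(round(self.prompt_point[1]))
            if self.labels[y, x] == 0:
                raise ValueError("prompted segment must contain the prompt point")


class CueProvider:
    """Behavioural contract for cue backends.

    Implementations must be deterministic given ``(scene, t, gaze, seed)``.
    """

    def global_cues(self, scene: Scene, t: int) -> list[CueMeasurement]:
        raise NotImplementedError

    def prompted(self, scene: Scene, t: int, gaze: tuple[float, float]) -> CueMeasurement:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Synthetic scenes
# ---------------------------------------------------------------------------


@dataclass
class ObjectSpec:
    """Descriptor of one moving shape in a synthetic scene.

    Geometry is in pixels; ``center`` is the position at frame 0 and
    ``velocity`` the screen displacement per frame.  ``n_parts`` splits the
    shape into vertical bands with distinct appearance identities (a shirt
    and trousers of one person, say).  A ``camouflaged`` object is invisible
    to the appearance cue.  ``saliency`` is the peak amplitude of the
    object's Gaussian feature bump; ``saliency_sigma`` its spatial spread
    (defaults to the object's characteristic radius).
    """

    center: tuple[float, float]
    size: float | tuple[float, float]
    shape: str = "disk"  # disk | rect
    velocity: tuple[float, float] = (0.0, 0.0)
    n_parts: int = 1
    camouflaged: bool = False
    saliency: float = 1.0
    saliency_sigma: float | None = None

    @property
    def radius(self) -> float:
        if self.shape == "disk":
            return float(self.size)
        w, h = self.size
        return 0.5 * float(min(w, h))


@dataclass
class SyntheticSceneSpec:
    """Parametric description of a moving-shape scene.

    The defaults describe the desk-scale study condition used throughout the
    test battery: 128x128 px, 90 frames at 30 fps, 8 px/dva (a ~16 dva
    field of view).
    """

    objects: list[ObjectSpec] = field(default_factory=list)
    n_frames: int = 90
    height: int = 128
    width: int = 128
    fps: float = 30.0
    px_per_dva: float = 8.0
    background_velocity: tuple[float, float] = (0.0, 0.0)
    scene_id: str = "synthetic"


def _object_mask(obj: ObjectSpec, cx: float, cy: float, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    if obj.shape == "disk":
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= float(obj.size) ** 2
    if obj.shape == "rect":
        w, h = obj.size
        return (np.abs(xx - cx) <= w / 2.0) & (np.abs(yy - cy) <= h / 2.0)
    raise ValueError(f"unknown shape {obj.shape!r}")


def generate_scene(spec: SyntheticSceneSpec, seed: int = 0) -> Scene:
    """Rasterize a synthetic scene from its parametric spec.

    Trajectories are deterministic, so ``seed`` is accepted only for API
    symmetry with the cue generators.  Overlaps are resolved by descriptor
    order (later objects occlude earlier ones, painter's algorithm); the flow
    of occluded pixels follows the occluder.  An object whose mask becomes
    empty (left the frame) raises :class:`ValueError`.
    """
    t_n, h, w = spec.n_frames, spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    gt = np.zeros((t_n, h, w), dtype=np.int32)
    parts = np.zeros((t_n, h, w), dtype=np.int32)
    feature = np.zeros((t_n, h, w), dtype=np.float32)
    flow = np.zeros((max(t_n - 1, 0), h, w, 2), dtype=np.float32)

    part_to_object: dict[int, int] = {}
    camouflaged: list[int] = []
    next_part = 1
    part_ids: list[list[int]] = []
    for i, obj in enumerate(spec.objects):
        ids = list(range(next_part, next_part + obj.n_parts))
        next_part += obj.n_parts
        part_ids.append(ids)
        for pid in ids:
            part_to_object[pid] = i + 1
        if obj.camouflaged:
            camouflaged.append(i + 1)

    for t in range(t_n):
        frame_feature = np.zeros((h, w), dtype=np.float64)
        if t < t_n - 1:
            flow[t, :, :, 0] = spec.background_velocity[0]
            flow[t, :, :, 1] = spec.background_velocity[1]
        for i, obj in enumerate(spec.objects):
            cx = obj.center[0] + obj.velocity[0] * t
            cy = obj.center[1] + obj.velocity[1] * t
            mask = _object_mask(obj, cx, cy, yy, xx)
            if not mask.any():
                raise ValueError(
                    f"object {i} leaves the frame entirely at t={t}"
                )
            gt[t][mask] = i + 1
            # Vertical part bands in object-local coordinates.
            if obj.n_parts == 1:
                parts[t][mask] = part_ids[i][0]
            else:
                cols = np.where(mask.any(axis=0))[0]
                lo, hi = cols.min(), cols.max() + 1
                edges = np.linspace(lo, hi, obj.n_parts + 1)
                band = np.clip(
                    np.searchsorted(edges[1:-1], xx[0], side="right"), 0, obj.n_parts - 1
                )
                for j, pid in enumerate(part_ids[i]):
                    parts[t][mask & (band[None, :] == j).repeat(h, axis=0)] = pid
            if t < t_n - 1:
                flow[t, mask, 0] = obj.velocity[0]
                flow[t, mask, 1] = obj.velocity[1]
            sigma = obj.saliency_sigma if obj.saliency_sigma is not None else obj.radius
            frame_feature += obj.saliency * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
            )
        peak = frame_feature.max()
        if peak > 1.0:
            frame_feature /= peak
        feature[t] = frame_feature

    return Scene(
        feature=feature,
        flow=flow,
        gt_labels=gt,
        gt_parts=parts,
        fps=spec.fps,
        px_per_dva=spec.px_per_dva,
        scene_id=spec.scene_id,
        meta={
            "camouflaged": camouflaged,
            "part_to_object": part_to_object,
            "n_objects": len(spec.objects),
        },
    )


def sample_scene_spec(
    rng: np.random.Generator,
    n_objects: int = 3,
    n_frames: int = 90,
    height: int = 128,
    width: int = 128,
    px_per_dva: float = 8.0,
) -> SyntheticSceneSpec:
    """Draw a randomized multi-object scene for the simulation battery.

    The battery's study conditions: ``n_objects`` shapes with radii of
    1.5-2.5 dva, distinct saliency amplitudes, one slowly moving object, one
    two-part object and one camouflaged object, placed with margins so no
    object ever leaves the frame.
    """
    ppd = px_per_dva
    objects: list[ObjectSpec] = []
    speed = np.zeros((n_objects, 2))
    if n_objects:
        ang = rng.uniform(0, 2 * np.pi)
        speed[0] = 0.8 * np.array([np.cos(ang), np.sin(ang)])
    saliencies = np.linspace(1.0, 0.5, max(n_objects, 1))
    centers = _spread_centers(rng, n_objects, height, width, margin=3.2 * ppd, min_sep=5.5 * ppd)
    for i in range(n_objects):
        radius = rng.uniform(1.5, 2.5) * ppd
        vx, vy = speed[i]
        # Keep the moving object inside the frame for the whole clip.
        cx, cy = centers[i]
        vx = _fit_velocity(vx, cx, radius, width, n_frames)
        vy = _fit_velocity(vy, cy, radius, height, n_frames)
        objects.append(
            ObjectSpec(
                center=(cx, cy),
                size=radius,
                shape="disk" if i != 1 else "rect",
                velocity=(float(vx), float(vy)),
                n_parts=2 if i == 1 else 1,
                camouflaged=(i == 2),
                saliency=float(saliencies[i]),
            )
        )
        if i == 1:
            objects[-1].size = (2 * radius, 2 * radius)
    return SyntheticSceneSpec(
        objects=objects,
        n_frames=n_frames,
        height=height,
        width=width,
        px_per_dva=px_per_dva,
        scene_id=f"battery-{rng.integers(1 << 30)}",
    )


def _fit_velocity(v, c, radius, extent, n_frames):
    """Reflect, and if necessary slow, a velocity component so the object's
    centre stays within [radius, extent - radius] for the whole clip."""
    if v == 0.0:
        return 0.0
    if not (radius < c + v * n_frames < extent - radius):
        v = -v
    if not (radius < c + v * n_frames < extent - radius):
        room = (extent - radius - 1.0 - c) if v > 0 else (c - radius - 1.0)
        v = float(np.sign(v)) * max(min(abs(v), room / n_frames), 0.0)
    return float(v)


def _spread_centers(rng, n, height, width, margin, min_sep):
    """Rejection-sample object centres with a minimum pairwise separation."""
    for _ in range(200):
        pts = np.column_stack(
            [
                rng.uniform(margin, width - margin, size=n),
                rng.uniform(margin, height - margin, size=n),
            ]
        )
        if n < 2:
            return pts
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        if d[np.triu_indices(n, 1)].min() >= min_sep:
            return pts
    return pts  # fall back to the last draw


# ---------------------------------------------------------------------------
# Synthetic cues
# ---------------------------------------------------------------------------


@dataclass
class CueNoiseSpec:
    """Noise model for the synthetic cue generators.

    ``jitter_px`` is the magnitude of morphological boundary jitter on the
    semantic cue; ``merge_prob``/``split_prob`` are per-object probabilities
    of a whole-object merge into the nearest other segment / a split into
    two halves; ``prompt_jitter_px`` jitters the prompted mask boundary;
    ``background_patch_dva`` is the radius of the patch returned when gaze
    rests on background.
    """

    jitter_px: float = 2.0
    merge_prob: float = 0.05
    split_prob: float = 0.0
    prompt_jitter_px: float = 0.5
    background_patch_dva: float = 1.0


def _jitter_mask(mask: np.ndarray, k: int) -> np.ndarray:
    """Dilate (k > 0) or erode (k < 0) a binary mask by |k| pixels."""
    if k == 0 or not mask.any():
        return mask
    if k > 0:
        return ndi.binary_dilation(mask, iterations=k)
    out = ndi.binary_erosion(mask, iterations=-k)
    return out if out.any() else mask  # never erase an object entirely


def synthetic_cues(
    scene: Scene, t: int, noise: CueNoiseSpec | None = None, seed: int = 0,
    kinds: tuple[str, ...] = GLOBAL_CUE_KINDS,
) -> list[CueMeasurement]:
    """Generate the three pre-attentive global cues for frame ``t``.

    Deterministic given ``(scene, t, noise, seed)``.
    """
    if not 0 <= t < scene.n_frames:
        raise ValueError(f"invalid frame index {t}")
    if scene.gt_labels is None:
        raise ValueError("synthetic cues require ground-truth labels")
    noise = noise or CueNoiseSpec()
    rng = np.random.default_rng([int(seed) % (1 << 31), t])
    gt = scene.gt_labels[t]
    out: list[CueMeasurement] = []

    if "appearance" in kinds:
        labels = scene.gt_parts[t].copy() if scene.gt_parts is not None else gt.copy()
        for oid in scene.meta.get("camouflaged", []):
            labels[gt == oid] = 0
        out.append(CueMeasurement("appearance", labels))

    if "motion" in kinds:
        out.append(CueMeasurement("motion", _motion_cue(scene, t)))

    if "semantic" in kinds:
        labels = gt.copy()
        ids = [int(i) for i in np.unique(gt) if i != 0]
        for oid in ids:
            mask = labels == oid
            if not mask.any():
                continue
            if rng.random() < noise.merge_prob:
                labels[mask] = _nearest_other_label(labels, mask)
                continue
            if noise.split_prob and rng.random() < noise.split_prob:
                cols = np.where(mask.any(axis=0))[0]
                mid = (cols.min() + cols.max() + 1) // 2
                right = mask & (np.arange(labels.shape[1])[None, :] >= mid)
                labels[right] = labels.max() + 1
                mask = mask & ~right
            if noise.jitter_px > 0:
                k = int(rng.integers(-round(noise.jitter_px), round(noise.jitter_px) + 1))
                new_mask = _jitter_mask(mask, k)
                labels[mask & ~new_mask] = 0
                labels[new_mask] = oid
        out.append(CueMeasurement("semantic", labels))
    return out


def _motion_cue(scene: Scene, t: int) -> np.ndarray:
    """Connected components of near-equal nonzero (relative) flow."""
    fl = scene.flow_at(t)
    q = np.round(fl * 4.0).astype(np.int64)  # quantize to quarter-px bins
    # Background motion = the modal flow vector; segments must differ from it.
    code2d = q[..., 0] * (1 << 32) + q[..., 1]  # pack (dx, dy) into one key
    uniq, inv, counts = np.unique(code2d.ravel(), return_inverse=True, return_counts=True)
    bg = np.argmax(counts)
    codes = inv.reshape(fl.shape[:2])
    moving = codes != bg
    labels = np.zeros(fl.shape[:2], dtype=np.int32)
    next_label = 1
    for code in np.unique(codes[moving]):
        comp, n = ndi.label(codes == code)
        nz = comp > 0
        labels[nz] = comp[nz] + (next_label - 1)
        next_label += n
    return labels


def _nearest_other_label(labels: np.ndarray, mask: np.ndarray) -> int:
    """Label of the segment nearest to ``mask`` (may be 0 = background)."""
    other = ~mask
    _, (iy, ix) = ndi.distance_transform_edt(~other, return_indices=True)
    # nearest non-mask pixel for each mask pixel; take the modal label
    vals = labels[iy[mask], ix[mask]]
    vals, counts = np.unique(vals, return_counts=True)
    return int(vals[np.argmax(counts)])


def prompted_cue(
    scene: Scene,
    t: int,
    gaze: tuple[float, float],
    noise: CueNoiseSpec | None = None,
    seed: int = 0,
    kind: str = "semantic",
) -> CueMeasurement:
    """High-confidence mask of the object (or background patch) under gaze.

    ``kind='semantic'`` returns the whole ground-truth object containing the
    gaze point (all parts); ``kind='appearance'`` returns only the touched
    part.  On background, a local disk patch is returned so foveating the
    background still resolves uncertainty locally.
    """
    if not 0 <= t < scene.n_frames:
        raise ValueError(f"invalid frame index {t}")
    noise = noise or CueNoiseSpec()
    h, w = scene.height, scene.width
    x = int(np.clip(round(gaze[0]), 0, w - 1))
    y = int(np.clip(round(gaze[1]), 0, h - 1))
    rng = np.random.default_rng([int(seed) % (1 << 31), t, 7919, x, y])
    gt = scene.gt_labels[t]
    oid = int(gt[y, x])
    if oid > 0:
        if kind == "appearance" and scene.gt_parts is not None:
            pid = int(scene.gt_parts[t][y, x])
            mask = scene.gt_parts[t] == pid
        else:
            mask = gt == oid
        j = noise.prompt_jitter_px
        if j > 0:
            k = int(rng.integers(-round(j), round(j) + 1))
            mask = _jitter_mask(mask, k)
    else:
        r = noise.background_patch_dva * scene.px_per_dva
        yy, xx = np.mgrid[0:h, 0:w]
        mask = ((xx - x) ** 2 + (yy - y) ** 2 <= r**2) & (gt == 0)
    # The segment must stay connected and contain the prompt point.
    mask[y, x] = True
    comp, _ = ndi.label(mask)
    mask = comp == comp[y, x]
    labels = np.zeros((h, w), dtype=np.int32)
    labels[mask] = 1
    return CueMeasurement(
        "prompted",
        labels,
        confidence=PROMPTED_CUE_CONFIDENCE,
        prompt_point=(float(gaze[0]), float(gaze[1])),
        mask_only=True,
    )


@dataclass
class SyntheticCueProvider(CueProvider):
    """Cue provider backed by the synthetic generators.

    ``global_kinds`` selects the pre-attentive cue subset ('all-g' =
    appearance+motion+semantic, 'll-g' = appearance+motion, 'hl-g' =
    semantic only); ``prompt_kind`` selects the foveal cue ('semantic' =
    whole-object high-level prompt, 'appearance' = touched-part low-level
    prompt, ``None`` = no prompted measurements).
    """

    noise: CueNoiseSpec = field(default_factory=CueNoiseSpec)
    seed: int = 0
    global_kinds: tuple[str, ...] = GLOBAL_CUE_KINDS
    prompt_kind: str | None = "semantic"

    def global_cues(self, scene: Scene, t: int) -> list[CueMeasurement]:
        return synthetic_cues(scene, t, self.noise, seed=self.seed, kinds=self.global_kinds)

    def prompted(self, scene: Scene, t: int, gaze) -> CueMeasurement | None:
        if self.prompt_kind is None:
            return None
        return prompted_cue(scene, t, gaze, self.noise, seed=self.seed, kind=self.prompt_kind)


# ---------------------------------------------------------------------------
# YAML spec I/O
# ---------------------------------------------------------------------------


def spec_to_yaml(spec: SyntheticSceneSpec, path) -> None:
    doc = {
        "n_frames": spec.n_frames,
        "height": spec.height,
        "width": spec.width,
        "fps": spec.fps,
        "px_per_dva": spec.px_per_dva,
        "background_velocity": list(spec.background_velocity),
        "scene_id": spec.scene_id,
        "objects": [
            {
                "shape": o.shape,
                "center": list(o.center),
                "size": list(o.size) if isinstance(o.size, (tuple, list)) else o.size,
                "velocity": list(o.velocity),
                "n_parts": o.n_parts,
                "camouflaged": o.camouflaged,
                "saliency": o.saliency,
                "saliency_sigma": o.saliency_sigma,
            }
            for o in spec.objects
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(doc), fh)


def spec_from_yaml(path) -> SyntheticSceneSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    objects = [
        ObjectSpec(
            center=tuple(o["center"]),
            size=tuple(o["size"]) if isinstance(o["size"], list) else o["size"],
            shape=o.get("shape", "disk"),
            velocity=tuple(o.get("velocity", (0.0, 0.0))),
            n_parts=int(o.get("n_parts", 1)),
            camouflaged=bool(o.get("camouflaged", False)),
            saliency=float(o.get("saliency", 1.0)),
            saliency_sigma=o.get("saliency_sigma"),
        )
        for o in doc.get("objects", [])
    ]
    return SyntheticSceneSpec(
        objects=objects,
        n_frames=int(doc.get("n_frames", 90)),
        height=int(doc.get("height", 128)),
        width=int(doc.get("width", 128)),
        fps=float(doc.get("fps", 30.0)),
        px_per_dva=float(doc.get("px_per_dva", 8.0)),
        background_velocity=tuple(doc.get("background_velocity", (0.0, 0.0))),
        scene_id=doc.get("scene_id", "synthetic"),
    )
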