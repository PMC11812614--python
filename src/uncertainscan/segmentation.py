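"""Recursive Bayesian particle filter over scene segmentations.

The belief over the segmentation of a frame is a weighted set of label
rasters (particles).  Each frame the filter (i) *predicts* by advecting every
particle with the optical flow, (ii) *weights* particles by the distance of
their object boundaries to each cue measurement, (iii) directly
*incorporates* measured segments into a random subset of particles, and
(iv) *resamples*.  Marginalizing the set yields a per-pixel boundary
likelihood, a most-likely segmentation, and a binary-entropy uncertainty map.

Boundary geometry uses inter-pixel "cracks": a crack sits at the midpoint
between two 4-neighbour pixels with different labels.  Distances between
segmentations are symmetric mean chamfer distances between crack sets; the
per-pixel boundary indicator used for the likelihood map marks every pixel
touching a crack (a two-pixel-thick band, symmetric on both sides).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.special import xlogy

from .scene import CueMeasurement

LN2 = float(np.log(2.0))


@dataclass
class FilterParams:
    """Tunable parameters of the segmentation filter.

    ``lambda_d_dva`` is the length scale of the exponential boundary-distance
    likelihood; ``incorporate_fraction`` the per-step share of particles that
    directly adopt measured segments; ``incorporate_kinds`` the measurement
    kinds eligible for incorporation; ``blur_sigma_dva`` the Gaussian blur of
    the entropy map; ``pb_threshold`` the boundary-likelihood threshold for
    the most-likely segmentation.
    """

    n_particles: int = 50
    lambda_d_dva: float = 2.0
    incorporate_fraction: float = 0.2
    incorporate_kinds: tuple[str, ...] = ("prompted", "semantic")
    pb_threshold: float = 0.5
    blur_sigma_dva: float = 1.0
    mask_window_dva: float = 2.0


@dataclass
class SegmentationBelief:
    """Weighted particle set representing p(segmentation | measurements)."""

    labels: np.ndarray  # (P, H, W) int32
    weights: np.ndarray  # (P,) summing to 1
    rng: np.random.Generator
    # memoized (unique rasters, inverse) -- reset on construction, propagated
    # across filter steps so particle stacks are hashed at most once
    _cache: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.labels.ndim != 3 or self.weights.shape != (self.labels.shape[0],):
            raise ValueError("labels must be (P, H, W) with one weight per particle")

    @property
    def n_particles(self) -> int:
        return self.labels.shape[0]

    @classmethod
    def from_measurements(
        cls,
        measurements: list[CueMeasurement],
        shape: tuple[int, int],
        n_particles: int = 50,
        rng: np.random.Generator | None = None,
    ) -> "SegmentationBelief":
        """Initialize particles round-robin from the full-frame cues."""
        rng = rng or np.random.default_rng()
        full = [m for m in measurements if not m.mask_only]
        if full:
            uniq = np.stack([m.labels for m in full]).astype(np.int32)
            inverse = np.arange(n_particles, dtype=np.intp) % len(full)
        else:
            uniq = np.zeros((1,) + tuple(shape), dtype=np.int32)
            inverse = np.zeros(n_particles, dtype=np.intp)
        weights = np.full(n_particles, 1.0 / n_particles)
        out = cls(uniq[inverse], weights, rng)
        out._cache = (uniq, inverse)
        return out

    def unique(self) -> tuple[np.ndarray, np.ndarray]:
        """Deduplicated particle rasters and the index of each particle.

        Returns ``(uniq, inverse)`` with ``uniq[inverse[i]] == labels[i]``.
        Exploits that resampling produces many exact duplicates.  The result
        is memoized and propagated across filter steps.
        """
        if self._cache is None:
            p = self.n_particles
            flat = self.labels.reshape(p, -1)
            seen: dict[bytes, int] = {}
            inverse = np.empty(p, dtype=np.intp)
            keep: list[int] = []
            for i in range(p):
                key = flat[i].tobytes()
                j = seen.get(key)
                if j is None:
                    j = len(keep)
                    seen[key] = j
                    keep.append(i)
                inverse[i] = j
            self._cache = (self.labels[keep], inverse)
        return self._cache


# ---------------------------------------------------------------------------
# Boundary geometry
# ---------------------------------------------------------------------------


def boundary_cracks(labels: np.ndarray) -> np.ndarray:
    """Inter-pixel boundary elements of a label raster.

    Returns an (N, 2) integer array of crack coordinates on a 2x-upsampled
    grid: the crack between pixels (r, c) and (r, c+1) sits at (2r, 2c+1),
    between (r, c) and (r+1, c) at (2r+1, 2c).  Euclidean distances on this
    grid divided by two are distances in pixel units.
    """
    labels = np.asarray(labels)
    hdiff = labels[:, :-1] != labels[:, 1:]
    vdiff = labels[:-1, :] != labels[1:, :]
    hr, hc = np.nonzero(hdiff)
    vr, vc = np.nonzero(vdiff)
    out = np.empty((hr.size + vr.size, 2), dtype=np.int64)
    out[: hr.size, 0] = 2 * hr
    out[: hr.size, 1] = 2 * hc + 1
    out[hr.size :, 0] = 2 * vr + 1
    out[hr.size :, 1] = 2 * vc
    return out


def _batch_boundary_cracks(stack: np.ndarray) -> list[np.ndarray]:
    """``boundary_cracks`` of every raster in a (K, H, W) stack at once."""
    hdiff = stack[:, :, :-1] != stack[:, :, 1:]
    vdiff = stack[:, :-1, :] != stack[:, 1:, :]
    hk, hr, hc = np.nonzero(hdiff)
    vk, vr, vc = np.nonzero(vdiff)
    k = stack.shape[0]
    h_counts = np.bincount(hk, minlength=k)
    v_counts = np.bincount(vk, minlength=k)
    h_pts = np.column_stack([2 * hr, 2 * hc + 1])
    v_pts = np.column_stack([2 * vr + 1, 2 * vc])
    h_split = np.split(h_pts, np.cumsum(h_counts)[:-1])
    v_split = np.split(v_pts, np.cumsum(v_counts)[:-1])
    return [
        np.concatenate([h_split[i], v_split[i]]).astype(np.int64) for i in range(k)
    ]


def boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Pixels with any 4-neighbour of different label (both boundary sides)."""
    labels = np.asarray(labels)
    out = np.zeros(labels.shape, dtype=bool)
    hdiff = labels[:, :-1] != labels[:, 1:]
    vdiff = labels[:-1, :] != labels[1:, :]
    out[:, :-1] |= hdiff
    out[:, 1:] |= hdiff
    out[:-1, :] |= vdiff
    out[1:, :] |= vdiff
    return out


def _crop_cracks(cracks: np.ndarray, bbox: tuple[int, int, int, int]) -> np.ndarray:
    """Restrict cracks to a pixel bounding box (r0, r1, c0, c1), half-open."""
    r0, r1, c0, c1 = bbox
    keep = (
        (cracks[:, 0] >= 2 * r0)
        & (cracks[:, 0] <= 2 * (r1 - 1))
        & (cracks[:, 1] >= 2 * c0)
        & (cracks[:, 1] <= 2 * (c1 - 1))
    )
    return cracks[keep]


def _mask_bbox(mask: np.ndarray, pad: int) -> tuple[int, int, int, int]:
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    h, w = mask.shape
    return (
        max(int(rows[0]) - pad, 0),
        min(int(rows[-1]) + 1 + pad, h),
        max(int(cols[0]) - pad, 0),
        min(int(cols[-1]) + 1 + pad, w),
    )


def _chamfer(cracks_a: np.ndarray, cracks_b: np.ndarray, sentinel: float) -> float:
    """Symmetric mean nearest-neighbour distance between crack sets (px)."""
    if cracks_a.size == 0 and cracks_b.size == 0:
        return 0.0
    if cracks_a.size == 0 or cracks_b.size == 0:
        return sentinel
    tree_b = cKDTree(cracks_b)
    d_ab = tree_b.query(cracks_a, k=1)[0].mean()
    tree_a = cKDTree(cracks_a)
    d_ba = tree_a.query(cracks_b, k=1)[0].mean()
    return 0.5 * (d_ab + d_ba) / 2.0  # halve: doubled-grid units -> px


def _batched_chamfer(
    crack_sets: list[np.ndarray], m_cracks: np.ndarray, sentinel: float
) -> np.ndarray:
    """Symmetric mean chamfer distance (px) of each crack set to ``m_cracks``.

    All non-empty sets are stacked into a single KD-tree with the set index
    encoded as a widely spaced third coordinate, so nearest-neighbour queries
    never cross sets and both chamfer directions need one batched query each.
    """
    n = len(crack_sets)
    d = np.zeros(n)
    sizes = np.array([c.shape[0] for c in crack_sets])
    live = np.nonzero(sizes)[0]
    if m_cracks.size == 0:
        d[sizes > 0] = sentinel
        return d
    d[sizes == 0] = sentinel
    if live.size == 0:
        return d
    offset = 8.0 * (sentinel + 1.0)
    stacked = np.concatenate([crack_sets[i] for i in live]).astype(np.float64)
    owner = np.repeat(np.arange(live.size), sizes[live])
    # set -> measurement direction: one 2-D query, then per-set means
    d_ab = cKDTree(m_cracks).query(stacked, k=1)[0]
    sums = np.bincount(owner, weights=d_ab, minlength=live.size)
    mean_ab = sums / sizes[live]
    # measurement -> set direction: replicate measurement cracks per set and
    # query the offset-stacked 3-D tree once
    pts3 = np.column_stack([stacked, owner * offset])
    tree3 = cKDTree(pts3)
    k = live.size
    q = np.empty((k * m_cracks.shape[0], 3))
    q[:, :2] = np.tile(m_cracks, (k, 1))
    q[:, 2] = np.repeat(np.arange(k) * offset, m_cracks.shape[0])
    d_ba = tree3.query(q, k=1)[0].reshape(k, m_cracks.shape[0])
    mean_ba = d_ba.mean(axis=1)
    d[live] = 0.5 * (mean_ab + mean_ba) / 2.0  # doubled-grid units -> px
    return d


def _multi_chamfer(
    crack_sets: list[np.ndarray],
    m_cracks_list: list[np.ndarray],
    sentinel: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Chamfer distances of every crack set to every full-frame measurement.

    Returns an (n_measurements, n_sets) array.  The set -> measurement
    direction uses one exact Euclidean distance transform per measurement on
    the doubled grid (indexing serves all sets at once); the measurement ->
    set direction uses one batched query per measurement against a KD-tree of
    all sets stacked with a widely spaced third coordinate.
    """
    h, w = shape
    n_u, n_m = len(crack_sets), len(m_cracks_list)
    d = np.zeros((n_m, n_u))
    sizes = np.array([c.shape[0] for c in crack_sets])
    live = np.nonzero(sizes)[0]
    empty_u = sizes == 0
    d_union = None
    uinv = np.empty(0, dtype=np.intp)
    nonempty_m = [mc for mc in m_cracks_list if mc.shape[0]]
    if nonempty_m:
        # measurements share many crack points: dedupe and query their union
        all_m = np.concatenate(nonempty_m)
        codes = all_m[:, 0] * (2 * w) + all_m[:, 1]
        ucodes, uinv = np.unique(codes, return_inverse=True)
        if live.size:
            stacked = np.concatenate([crack_sets[i] for i in live])
            owner = np.repeat(np.arange(live.size), sizes[live])
            offset = 8.0 * (sentinel + 1.0)
            tree3 = cKDTree(
                np.column_stack([stacked.astype(np.float64), owner * offset])
            )
            union = np.column_stack([ucodes // (2 * w), ucodes % (2 * w)]).astype(np.float64)
            q = np.empty((live.size * union.shape[0], 3))
            q[:, :2] = np.tile(union, (live.size, 1))
            q[:, 2] = np.repeat(np.arange(live.size) * offset, union.shape[0])
            d_union = tree3.query(q, k=1)[0].reshape(live.size, -1)
    pos = 0
    for j, mc in enumerate(m_cracks_list):
        if mc.shape[0] == 0:
            d[j, ~empty_u] = sentinel  # boundary-free vs boundary-bearing
            continue
        cols = uinv[pos : pos + mc.shape[0]]
        pos += mc.shape[0]
        d[j, empty_u] = sentinel
        if live.size == 0:
            continue
        grid = np.ones((2 * h - 1, 2 * w - 1), dtype=bool)
        grid[mc[:, 0], mc[:, 1]] = False
        dmap = ndi.distance_transform_edt(grid)
        vals = dmap[stacked[:, 0], stacked[:, 1]]
        mean_ab = np.bincount(owner, weights=vals, minlength=live.size) / sizes[live]
        mean_ba = d_union[:, cols].mean(axis=1)
        d[j, live] = 0.5 * (mean_ab + mean_ba) / 2.0  # doubled-grid units -> px
    return d


def boundary_distance(
    a: np.ndarray,
    b: np.ndarray | CueMeasurement,
    window_px: float | None = None,
) -> float:
    """Average distance between the object boundaries of two segmentations.

    Symmetric mean chamfer distance between the inter-pixel boundary sets of
    ``a`` and ``b`` (pixel units).  For a mask-only measurement ``b`` the
    comparison is restricted to a window around the measured mask (its
    bounding box dilated by ``window_px``), so a local measurement does not
    penalize remote structure.  Zero iff the boundary sets coincide; if
    exactly one raster is boundary-free, the frame diagonal is returned as a
    maximal-disagreement sentinel.
    """
    mask_only = False
    if isinstance(b, CueMeasurement):
        mask_only = b.mask_only
        b_labels = b.labels
    else:
        b_labels = np.asarray(b)
    a = np.asarray(a)
    if a.shape != b_labels.shape:
        raise ValueError("rasters must share shape")
    cracks_a = boundary_cracks(a)
    cracks_b = boundary_cracks(b_labels)
    h, w = a.shape
    sentinel = float(np.hypot(h, w))
    if mask_only:
        pad = int(round(window_px if window_px is not None else 0))
        bbox = _mask_bbox(b_labels > 0, pad)
        cracks_a = _crop_cracks(cracks_a, bbox)
        cracks_b = _crop_cracks(cracks_b, bbox)
        sentinel = float(np.hypot(bbox[1] - bbox[0], bbox[3] - bbox[2]))
    return float(_chamfer(cracks_a, cracks_b, sentinel))


# ---------------------------------------------------------------------------
# Filter steps
# ---------------------------------------------------------------------------


@lru_cache(maxsize=4)
def _grid_cache(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:h, 0:w]
    yy.setflags(write=False)
    xx.setflags(write=False)
    return yy, xx


def warp_labels(labels: np.ndarray, flow: np.ndarray) -> np.ndarray:
    """Forward-warp label rasters by a flow field, nearest-label hole fill.

    ``labels`` may be a single (H, W) raster or a batch (P, H, W); ``flow``
    is (H, W, 2) in px/frame with last axis (dx, dy).  Collisions are
    resolved last-write-wins in raster order; holes (pixels no source maps
    to) take the label of the nearest filled pixel.
    """
    flow = np.asarray(flow, dtype=np.float64)
    if np.isnan(flow).any():
        raise ValueError("flow contains NaN")
    single = labels.ndim == 2
    batch = labels[None] if single else labels
    h, w = batch.shape[1:]
    yy, xx = _grid_cache(h, w)
    dst_x = np.rint(xx + flow[:, :, 0]).astype(np.intp)
    dst_y = np.rint(yy + flow[:, :, 1]).astype(np.intp)
    valid = (dst_x >= 0) & (dst_x < w) & (dst_y >= 0) & (dst_y < h)
    out = np.full_like(batch, -1)
    out[:, dst_y[valid], dst_x[valid]] = batch[:, yy[valid], xx[valid]]
    holes = out[0] < 0  # hole pattern is particle-independent
    if holes.any():
        _, (iy, ix) = ndi.distance_transform_edt(holes, return_indices=True)
        out[:, holes] = out[:, iy[holes], ix[holes]]
    return out[0] if single else out


def predict(belief: SegmentationBelief, flow: np.ndarray) -> SegmentationBelief:
    """Advect every particle's segmentation by the optical flow (Bayes-filter
    prediction step); weights unchanged."""
    uniq, inverse = belief.unique()
    warped = warp_labels(uniq, flow)
    out = replace(belief, labels=warped[inverse], weights=belief.weights.copy())
    out._cache = (warped, inverse)
    return out


def weight(
    belief: SegmentationBelief,
    measurements: list[CueMeasurement],
    lambda_d: float,
    mask_window_px: float | None = None,
) -> SegmentationBelief:
    """Reweight particles by their boundary distance to each measurement.

    Per-measurement likelihood ``exp(-confidence * d / lambda_d)``; the new
    particle weight is the normalized product over measurements (previous
    weights are reset by the per-frame resampling convention).
    """
    if lambda_d <= 0:
        raise ValueError("lambda_d must be positive")
    uniq, inverse = belief.unique()
    h, w = belief.labels.shape[1:]
    frame_sentinel = float(np.hypot(h, w))
    uniq_cracks = _batch_boundary_cracks(uniq)
    loglik = np.zeros(len(uniq))
    full = [m for m in measurements if not m.mask_only]
    if full:
        dmat = _multi_chamfer(
            uniq_cracks, [boundary_cracks(m.labels) for m in full], frame_sentinel, (h, w)
        )
        for j, m in enumerate(full):
            loglik -= m.confidence * dmat[j] / lambda_d
    for m in measurements:
        if not m.mask_only:
            continue
        m_cracks = boundary_cracks(m.labels)
        pad = int(round(mask_window_px or 0))
        bbox = _mask_bbox(m.labels > 0, pad)
        m_cracks = _crop_cracks(m_cracks, bbox)
        sentinel = float(np.hypot(bbox[1] - bbox[0], bbox[3] - bbox[2]))
        p_cracks = [_crop_cracks(c, bbox) for c in uniq_cracks]
        d = _batched_chamfer(p_cracks, m_cracks, sentinel)
        loglik -= m.confidence * d / lambda_d
    loglik = loglik[inverse]
    w = np.exp(loglik - loglik.max())
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        warnings.warn("all measurement likelihoods vanished; falling back to uniform weights")
        w = np.full(belief.n_particles, 1.0)
        total = w.sum()
    out = replace(belief, labels=belief.labels, weights=w / total)
    out._cache = (uniq, inverse)
    return out


def resample(belief: SegmentationBelief) -> SegmentationBelief:
    """Systematic resampling with replacement proportional to the weights."""
    p = belief.n_particles
    positions = (np.arange(p) + belief.rng.random()) / p
    cum = np.cumsum(belief.weights)
    cum[-1] = 1.0
    idx = np.searchsorted(cum, positions, side="left")
    uniq, inverse = belief.unique()
    new_inverse = inverse[idx]
    survivors, new_inverse = np.unique(new_inverse, return_inverse=True)
    new_uniq = uniq[survivors]
    out = replace(
        belief,
        labels=new_uniq[new_inverse],
        weights=np.full(p, 1.0 / p),
    )
    out._cache = (new_uniq, new_inverse)
    return out


def incorporate(
    belief: SegmentationBelief,
    measurements: list[CueMeasurement],
    fraction: float,
) -> SegmentationBelief:
    """Overwrite measured segments into a random subset of particles.

    For mask-only (prompted) measurements only the measured mask is
    overwritten with a fresh label; a full-frame measurement contributes its
    complete partition (its background region counts as a measured segment),
    so the chosen particles adopt the measurement exactly up to labelling.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = int(np.ceil(fraction * belief.n_particles))
    if n == 0 or not measurements:
        out = replace(belief, labels=belief.labels.copy(), weights=belief.weights.copy())
        out._cache = belief._cache
        return out
    uniq, inverse = belief.unique()
    labels = belief.labels.copy()
    chosen = belief.rng.choice(belief.n_particles, size=n, replace=False)
    # one shared offset keeps adopted full partitions byte-identical across
    # particles (labels are arbitrary; only the partition matters)
    offset = int(labels.max()) + 1
    for m in measurements:
        if m.mask_only:
            mask = m.labels > 0
            for i in chosen:
                labels[i][mask] = labels[i].max() + 1
        else:
            base = m.labels - m.labels.min()  # ensure nonnegative ids
            for i in chosen:
                labels[i] = base + offset
    # rebuild the dedup cache: untouched particles keep their raster; the
    # touched ones are deduplicated among themselves and appended
    new_inverse = inverse.copy()
    seen: dict[bytes, int] = {}
    extra: list[np.ndarray] = []
    for i in chosen:
        key = labels[i].tobytes()
        j = seen.get(key)
        if j is None:
            j = len(uniq) + len(extra)
            seen[key] = j
            extra.append(labels[i])
        new_inverse[i] = j
    new_uniq = np.concatenate([uniq, np.stack(extra)]) if extra else uniq
    out = replace(belief, labels=labels, weights=belief.weights.copy())
    out._cache = (new_uniq, new_inverse)
    return out


# ---------------------------------------------------------------------------
# Marginals
# ---------------------------------------------------------------------------


def boundary_likelihood(belief: SegmentationBelief) -> np.ndarray:
    """Per-pixel posterior probability of an object boundary, p_b(x, y).

    Summed weight of the particles that have a boundary at each pixel,
    normalized by the total weight.
    """
    uniq, inverse = belief.unique()
    wsum = np.zeros(len(uniq))
    np.add.at(wsum, inverse, belief.weights)
    total = belief.weights.sum()
    pb = np.zeros(belief.labels.shape[1:], dtype=np.float64)
    for u in range(len(uniq)):
        pb += wsum[u] * boundary_mask(uniq[u])
    return pb / total


def entropy_map(pb: np.ndarray) -> np.ndarray:
    """Binary entropy of the boundary likelihood, in nats (0 log 0 := 0)."""
    pb = np.asarray(pb, dtype=np.float64)
    if pb.min() < -1e-12 or pb.max() > 1 + 1e-12:
        raise ValueError("p_b must lie in [0, 1]")
    pb = np.clip(pb, 0.0, 1.0)
    return -(xlogy(pb, pb) + xlogy(1.0 - pb, 1.0 - pb))


def map_segmentation(pb: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Most-likely segmentation: threshold p_b, close contours, label regions.

    Pixels of the closed boundary mask are assigned to the nearest labelled
    region, so every pixel carries a region label (labels start at 1).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    bmask = np.asarray(pb) >= threshold
    bmask = ndi.binary_closing(bmask, structure=np.ones((3, 3), bool))
    regions, n = ndi.label(~bmask)
    if n == 0:
        warnings.warn("boundary mask covers the whole frame; returning a single region")
        return np.ones(bmask.shape, dtype=np.int32)
    out = regions.astype(np.int32)
    if bmask.any():
        _, (iy, ix) = ndi.distance_transform_edt(bmask, return_indices=True)
        out[bmask] = out[iy[bmask], ix[bmask]]
        _resolve_assignment_ties(out, bmask)
    return out


def _resolve_assignment_ties(out: np.ndarray, bmask: np.ndarray) -> None:
    """Re-assign distance-tied boundary pixels by local band consistency.

    A boundary pixel equidistant from several regions (e.g. the inner corner
    pixel of a rectangular object) is given the tied region whose assignment
    best reproduces the observed boundary band in its neighbourhood, which
    makes the decoded partition exact for clean (converged) bands.
    """
    h, w = out.shape
    ry, rx = np.nonzero(~bmask)
    if ry.size == 0:
        return
    tree = cKDTree(np.column_stack([ry, rx]))
    by, bx = np.nonzero(bmask)
    k = min(12, ry.size)
    dd, ii = tree.query(np.column_stack([by, bx]), k=k)
    dd = np.atleast_2d(dd.T).T
    ii = np.atleast_2d(ii.T).T
    region_of = out[ry, rx]
    for p in range(by.size):
        tied = dd[p] <= dd[p, 0] + 1e-9
        cands = np.unique(region_of[ii[p][tied]])
        if cands.size < 2:
            continue
        y, x = int(by[p]), int(bx[p])
        y0, y1 = max(y - 2, 0), min(y + 3, h)
        x0, x1 = max(x - 2, 0), min(x + 3, w)
        ref = bmask[y0:y1, x0:x1]
        best, best_err = int(out[y, x]), None
        for cand in cands:
            prev = out[y, x]
            out[y, x] = cand
            err = int(np.sum(boundary_mask(out[y0:y1, x0:x1]) != ref))
            out[y, x] = prev
            if best_err is None or err < best_err:
                best, best_err = int(cand), err
        out[y, x] = best


@dataclass
class UncertaintyMap:
    """Entropy raster H, its blurred/normalized form U, and rescaled U'."""

    H: np.ndarray
    U: np.ndarray
    U_prime: np.ndarray


def uncertainty(
    H: np.ndarray,
    blur_sigma_dva: float,
    u_min: float,
    px_per_dva: float,
) -> UncertaintyMap:
    """Blur the entropy map and rescale it into [u_min, 1].

    The blur attributes boundary uncertainty to both adjacent objects.  H is
    normalized by its value-range maximum ln 2, making U base-independent;
    U' = u_min + (1 - u_min) * U.
    """
    if not 0.0 <= u_min <= 1.0:
        raise ValueError("u_min must lie in [0, 1]")
    H = np.asarray(H, dtype=np.float64)
    u = ndi.gaussian_filter(H, sigma=blur_sigma_dva * px_per_dva) / LN2
    u = np.clip(u, 0.0, 1.0)
    return UncertaintyMap(H=H, U=u, U_prime=u_min + (1.0 - u_min) * u)
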