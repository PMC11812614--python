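"""Stable object identities via discounted-IoU bipartite matching.

Segments of the current most-likely segmentation are matched against the
object identities seen over the previous 10 frames.  The match weight of an
(old ID, new segment) pair is the sum over the stored history frames of the
intersection-over-union of the old ID's mask with the new segment, discounted
geometrically for older frames so currently used IDs are favoured.  The
maximum-weight assignment (a variation of the Hungarian algorithm) decides
which segments keep their IDs; segments matching nothing above a weight floor
receive fresh IDs, and retired IDs are never reused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class TrackState:
    """Rolling window of ID-resolved label rasters plus the ID counter."""

    history: list[np.ndarray] = field(default_factory=list)
    next_id: int = 1
    discount: float = 0.9
    weight_floor: float = 0.1
    max_history: int = 10


def _discounted_weights(current: np.ndarray, state: TrackState):
    """Weighted bipartite graph between historic IDs and current segments."""
    new_ids = [int(v) for v in np.unique(current)]
    old_ids: list[int] = sorted(
        {int(v) for raster in state.history for v in np.unique(raster)}
    )
    weights = np.zeros((len(old_ids), len(new_ids)))
    if not old_ids or not new_ids:
        return old_ids, new_ids, weights
    old_index = {v: i for i, v in enumerate(old_ids)}
    new_index = {v: j for j, v in enumerate(new_ids)}
    new_areas = np.bincount(current.ravel())
    # history[-1] is the most recent frame (undiscounted); older frames decay.
    for age, raster in enumerate(reversed(state.history)):
        gamma = state.discount**age
        k = current.max() + 1
        joint = np.bincount(
            raster.ravel().astype(np.int64) * k + current.ravel(),
            minlength=int((raster.max() + 1) * k),
        ).reshape(-1, k)
        old_areas = joint.sum(axis=1)
        for o in np.nonzero(old_areas)[0]:
            if int(o) not in old_index:
                continue
            for nseg in np.nonzero(joint[o])[0]:
                inter = joint[o, nseg]
                union = old_areas[o] + new_areas[nseg] - inter
                if union > 0:
                    weights[old_index[int(o)], new_index[int(nseg)]] += gamma * inter / union
    return old_ids, new_ids, weights


def match_ids(current: np.ndarray, state: TrackState) -> tuple[np.ndarray, TrackState]:
    """Relabel ``current`` so segments keep the IDs of their best matches.

    Returns the relabelled raster and the updated state (history extended by
    the relabelled raster, trimmed to the window length).  With an empty
    history every segment receives a fresh ID.
    """
    current = np.asarray(current, dtype=np.int32)
    new_ids = [int(v) for v in np.unique(current)]
    if not new_ids:
        raise ValueError("current segmentation has no segments")
    old_ids, new_ids, weights = _discounted_weights(current, state)
    assignment: dict[int, int] = {}
    if old_ids:
        w = weights.copy()
        w[w < state.weight_floor] = 0.0
        rows, cols = linear_sum_assignment(-w)
        for r, c in zip(rows, cols):
            if w[r, c] >= state.weight_floor:
                assignment[new_ids[c]] = old_ids[r]

    next_id = state.next_id
    if old_ids:
        next_id = max(next_id, max(old_ids) + 1)
    lut_size = current.max() + 1
    lut = np.zeros(lut_size, dtype=np.int32)
    for seg in new_ids:
        if seg in assignment:
            lut[seg] = assignment[seg]
        else:
            lut[seg] = next_id
            next_id += 1
    relabeled = lut[current]

    history = state.history + [relabeled]
    if len(history) > state.max_history:
        history = history[-state.max_history :]
    return relabeled, TrackState(
        history=history,
        next_id=next_id,
        discount=state.discount,
        weight_floor=state.weight_floor,
        max_history=state.max_history,
    )
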