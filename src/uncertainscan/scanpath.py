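"""Scanpath event tables: alternating foveation and saccade events.

A scanpath is stored as a pandas DataFrame with one row per event and the
columns ``event_type`` (foveation | saccade), ``t_start_ms``, ``t_end_ms``,
``x_px``, ``y_px`` (foveation: mean gaze position; saccade: landing point),
``object_id`` (tracked perceptual-unit ID), ``gt_object_id`` (ground-truth
object under the foveation, 0 = background), ``category`` (Background /
Detection / Inspection / Return, filled by the analysis layer),
``amplitude_dva``, ``duration_ms``, ``rel_angle_deg`` (signed change of
saccade direction relative to the previous saccade, positive counter-
clockwise) and ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = [
    "event_type",
    "t_start_ms",
    "t_end_ms",
    "x_px",
    "y_px",
    "object_id",
    "gt_object_id",
    "category",
    "amplitude_dva",
    "duration_ms",
    "rel_angle_deg",
    "seed",
]

CATEGORIES = ("Background", "Detection", "Inspection", "Return")


def wrap_angle(deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees into the half-open interval (-180, 180]."""
    wrapped = np.mod(np.asarray(deg, dtype=float) + 180.0, 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return float(wrapped) if np.isscalar(deg) else wrapped


@dataclass
class Scanpath:
    """Ordered foveation/saccade events of one simulation on one scene."""

    events: pd.DataFrame
    scene_id: str = "scene"
    seed: int = 0
    fps: float = 30.0
    px_per_dva: float = 40.2
    traces: list[np.ndarray] = field(default_factory=list)  # per-foveation gaze traces

    def __post_init__(self) -> None:
        for col in COLUMNS:
            if col not in self.events.columns:
                self.events[col] = np.nan
        self.events = self.events[COLUMNS].reset_index(drop=True)

    @property
    def foveations(self) -> pd.DataFrame:
        return self.events[self.events.event_type == "foveation"]

    @property
    def saccades(self) -> pd.DataFrame:
        return self.events[self.events.event_type == "saccade"]

    @property
    def foveation_durations(self) -> np.ndarray:
        return self.foveations.duration_ms.to_numpy(dtype=float)

    @property
    def saccade_amplitudes(self) -> np.ndarray:
        return self.saccades.amplitude_dva.to_numpy(dtype=float)

    def validate(self) -> None:
        kinds = self.events.event_type.to_numpy()
        for a, b in zip(kinds[:-1], kinds[1:]):
            if a == b:
                raise ValueError("events must alternate foveation/saccade")
        if (self.events.duration_ms <= 0).any():
            raise ValueError("durations must be positive")
        sac = self.saccades
        if (sac.amplitude_dva < 0).any():
            raise ValueError("amplitudes must be nonnegative")

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scene_id: str = "scene", fps: float = 30.0,
                 px_per_dva: float = 40.2) -> "Scanpath":
        events = pd.read_csv(path)
        seed = int(events["seed"].iloc[0]) if len(events) else 0
        return cls(events=events, scene_id=scene_id, seed=seed, fps=fps,
                   px_per_dva=px_per_dva)


def build_scanpath(
    foveations: list[dict],
    saccades: list[dict],
    scene_id: str,
    seed: int,
    fps: float,
    px_per_dva: float,
    traces: list[np.ndarray] | None = None,
) -> Scanpath:
    """Interleave foveation and saccade dicts into an event table.

    ``foveations`` and ``saccades`` must already be in temporal order with
    ``len(saccades) in (len(foveations) - 1, len(foveations))``; relative
    saccade angles are derived here from the absolute angles.
    """
    rows: list[dict] = []
    prev_angle = None
    for k, fov in enumerate(foveations):
        rows.append({**fov, "event_type": "foveation", "seed": seed})
        if k < len(saccades):
            sac = dict(saccades[k])
            if prev_angle is None:
                sac["rel_angle_deg"] = np.nan
            else:
                sac["rel_angle_deg"] = wrap_angle(sac["angle_deg"] - prev_angle)
            prev_angle = sac["angle_deg"]
            sac.pop("angle_deg", None)
            rows.append({**sac, "event_type": "saccade", "seed": seed})
    events = pd.DataFrame(rows)
    return Scanpath(
        events=events,
        scene_id=scene_id,
        seed=seed,
        fps=fps,
        px_per_dva=px_per_dva,
        traces=traces or [],
    )
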