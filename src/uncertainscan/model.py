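"""High-level modelling interface in the Model/Results idiom.

``ScanpathModel`` bundles a scene battery with the simulator configuration;
``simulate`` draws scanpaths and ``fit`` calibrates the free parameters
{s, theta, f_min, u_min} against reference foveation-duration and
saccade-amplitude samples by KS grid search, returning a
:class:`ScanpathFitResults` with the selected parameters, their fit scores
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import analysis
from .decision import ModelParams, simulate
from .scanpath import Scanpath
from .scene import CueNoiseSpec, Scene, SyntheticCueProvider
from .segmentation import FilterParams

DEFAULT_GRID = {
    "s": [0.2, 0.3, 0.4],
    "theta": [3.0, 4.0, 5.0],
    "f_min": [0.0, 0.3, 0.6],
    "u_min": [0.0, 1.0 / 3.0, 1.0],
}


@dataclass
class ScanpathFitResults:
    """Grid-search fit: selected parameters, KS scores and the full table."""

    params: ModelParams
    d_fd: float
    d_sa: float
    table: pd.DataFrame
    refined: pd.DataFrame | None = None

    @property
    def score(self) -> float:
        return 0.5 * (self.d_fd + self.d_sa)

    def summary(self) -> str:
        lines = [
            "Scanpath model fit (KS grid search)",
            "=" * 43,
            f"{'noise level s':<28}{self.params.s:>15.4g}",
            f"{'decision threshold theta':<28}{self.params.theta:>15.4g}",
            f"{'feature floor f_min':<28}{self.params.f_min:>15.4g}",
            f"{'uncertainty floor u_min':<28}{self.params.u_min:>15.4g}",
            "-" * 43,
            f"{'D_FD (foveation durations)':<28}{self.d_fd:>15.4f}",
            f"{'D_SA (saccade amplitudes)':<28}{self.d_sa:>15.4f}",
            f"{'score (D_FD + D_SA) / 2':<28}{self.score:>15.4f}",
            "=" * 43,
            f"grid points evaluated: {len(self.table)}"
            + (f" (+{len(self.refined)} refined)" if self.refined is not None else ""),
        ]
        return "\n".join(lines)


class ScanpathModel:
    """Uncertainty-driven scanpath simulator over a battery of scenes."""

    def __init__(
        self,
        scenes: list[Scene] | Scene,
        params: ModelParams | None = None,
        filter_params: FilterParams | None = None,
        noise: CueNoiseSpec | None = None,
        use_prompt: bool = True,
        gt_objects: bool = False,
        global_kinds=("appearance", "motion", "semantic"),
        prompt_kind: str | None = "semantic",
    ):
        self.scenes = [scenes] if isinstance(scenes, Scene) else list(scenes)
        self.params = params or ModelParams()
        self.filter_params = filter_params or FilterParams()
        self.noise = noise or CueNoiseSpec()
        self.use_prompt = use_prompt and prompt_kind is not None
        self.gt_objects = gt_objects
        self.global_kinds = tuple(global_kinds)
        self.prompt_kind = prompt_kind

    def _provider(self, seed: int) -> SyntheticCueProvider:
        return SyntheticCueProvider(
            noise=self.noise,
            seed=seed,
            global_kinds=self.global_kinds,
            prompt_kind=self.prompt_kind,
        )

    def simulate(self, seed: int = 0, n: int = 1,
                 params: ModelParams | None = None) -> list[Scanpath]:
        """Simulate ``n`` scanpaths per scene (seeds ``seed .. seed+n-1``)."""
        params = params or self.params
        out: list[Scanpath] = []
        for scene in self.scenes:
            for k in range(n):
                run_seed = (seed + k) % (1 << 31)
                out.append(
                    simulate(
                        scene,
                        provider=self._provider(run_seed),
                        params=params,
                        seed=run_seed,
                        filter_params=self.filter_params,
                        use_prompt=self.use_prompt,
                        gt_objects=self.gt_objects,
                    )
                )
        return out

    def fit(
        self,
        reference_durations: np.ndarray,
        reference_amplitudes: np.ndarray,
        grid: dict[str, list[float]] | None = None,
        n_seeds: int = 5,
        refine: bool = True,
        seed: int = 0,
    ) -> ScanpathFitResults:
        """Calibrate {s, theta, f_min, u_min} by KS grid search."""
        grid = grid or DEFAULT_GRID
        res = analysis.grid_search(
            self.scenes,
            grid,
            np.asarray(reference_durations, dtype=float),
            np.asarray(reference_amplitudes, dtype=float),
            n_seeds=n_seeds,
            base_params=self.params,
            provider_factory=self._provider,
            filter_params=self.filter_params,
            refine=refine,
            seed0=seed,
        )
        pool = res.table if res.refined is None else pd.concat([res.table, res.refined])
        best = pool[pool.score.notna()].sort_values("score").iloc[0]
        fitted = replace(self.params, **{k: float(best[k]) for k in grid})
        self.params = fitted
        return ScanpathFitResults(
            params=fitted,
            d_fd=float(best.D_FD),
            d_sa=float(best.D_SA),
            table=res.table,
            refined=res.refined,
        )
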