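"""Evaluation layer: foveation categories, distribution fits, KS statistics,
the temporal-IOR angle profile, and the grid-search parameter fit.

Foveations are classified by what they do for scene exploration:
*Background* (gaze on no ground-truth object), *Detection* (first foveation
of an object in this scanpath), *Inspection* (same object as the immediately
preceding foveation, i.e. a within-object saccade), *Return* (an object
foveated before but not immediately before).  Foveation durations are
summarized by a log-normal fit, saccade amplitudes by a gamma fit, and two
scanpath samples are compared with the two-sample Kolmogorov-Smirnov
statistic D = sup_x |N(x) - M(x)|, the objective of the parameter grid
search over {s, theta, f_min, u_min}.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .scanpath import CATEGORIES, Scanpath, wrap_angle

N_ANGLE_BINS = 30  # 12 degree bins over (-180, 180]
SMOOTH_WINDOW = 5


# ---------------------------------------------------------------------------
# Foveation categories
# ---------------------------------------------------------------------------


def classify_foveations(
    scanpath: Scanpath, gt_labels: np.ndarray | None = None
) -> Scanpath:
    """Assign the Background/Detection/Inspection/Return categories.

    The ground-truth object of each foveation is the majority label along its
    positional trace (already stored as ``gt_object_id`` by the simulator);
    when absent, it is looked up from ``gt_labels`` at the foveation position
    and midpoint frame.
    """
    events = scanpath.events.copy()
    fov_idx = events.index[events.event_type == "foveation"]
    gt_ids: list[int] = []
    for i in fov_idx:
        row = events.loc[i]
        gid = row.gt_object_id
        if pd.isna(gid):
            if gt_labels is None:
                raise ValueError("no ground-truth object information available")
            t_mid = 0.5 * (row.t_start_ms + row.t_end_ms)
            frame = int(np.clip(t_mid / 1000.0 * scanpath.fps, 0, len(gt_labels) - 1))
            x = int(np.clip(round(row.x_px), 0, gt_labels.shape[2] - 1))
            y = int(np.clip(round(row.y_px), 0, gt_labels.shape[1] - 1))
            gid = int(gt_labels[frame, y, x])
        gt_ids.append(int(gid))

    seen: set[int] = set()
    prev: int | None = None
    cats: list[str] = []
    for gid in gt_ids:
        if gid == 0:
            cats.append("Background")
        elif gid == prev:
            cats.append("Inspection")
        elif gid in seen:
            cats.append("Return")
        else:
            cats.append("Detection")
        if gid != 0:
            seen.add(gid)
        prev = gid
    events["category"] = events["category"].astype(object)
    events.loc[fov_idx, "category"] = cats
    events.loc[fov_idx, "gt_object_id"] = gt_ids
    return replace(scanpath, events=events)


def category_shares(scanpaths: list[Scanpath]) -> pd.Series:
    """Share of total foveation *time* spent in each category."""
    total: dict[str, float] = {c: 0.0 for c in CATEGORIES}
    for sp in scanpaths:
        fov = sp.foveations
        for cat, dur in zip(fov.category, fov.duration_ms):
            if isinstance(cat, str):
                total[cat] += float(dur)
    grand = sum(total.values())
    if grand == 0:
        raise ValueError("no categorized foveation time")
    return pd.Series({c: total[c] / grand for c in CATEGORIES})


def category_time_course(
    scanpaths: list[Scanpath], window_ms: float = 500.0
) -> pd.DataFrame:
    """Per-category share of foveation time in consecutive time windows.

    Shares sum to one in every window that contains foveation time; empty
    windows are omitted.
    """
    t_max = max(float(sp.events.t_end_ms.max()) for sp in scanpaths)
    n_win = int(np.ceil(t_max / window_ms))
    acc = np.zeros((n_win, len(CATEGORIES)))
    cat_index = {c: j for j, c in enumerate(CATEGORIES)}
    for sp in scanpaths:
        for _, row in sp.foveations.iterrows():
            if not isinstance(row.category, str):
                continue
            j = cat_index[row.category]
            for k in range(int(row.t_start_ms // window_ms), int(np.ceil(row.t_end_ms / window_ms))):
                lo, hi = k * window_ms, (k + 1) * window_ms
                overlap = min(hi, row.t_end_ms) - max(lo, row.t_start_ms)
                if overlap > 0 and k < n_win:
                    acc[k, j] += overlap
    totals = acc.sum(axis=1)
    keep = totals > 0
    shares = acc[keep] / totals[keep, None]
    return pd.DataFrame(
        shares, columns=list(CATEGORIES), index=np.nonzero(keep)[0] * window_ms
    )


# ---------------------------------------------------------------------------
# Distributions and their comparison
# ---------------------------------------------------------------------------


def ks_statistic(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic D in [0, 1]."""
    sample_a = np.asarray(sample_a, dtype=float)
    sample_b = np.asarray(sample_b, dtype=float)
    if sample_a.size == 0 or sample_b.size == 0:
        raise ValueError("samples must be nonempty")
    return float(stats.ks_2samp(sample_a, sample_b, method="asymp").statistic)


@dataclass
class DistributionFit:
    """Maximum-likelihood fit of a log-normal or gamma distribution.

    Log-normal: ``params = {'mu', 'sigma'}`` of the underlying normal, with
    expected value ``exp(mu + sigma^2 / 2)``.  Gamma: ``params = {'alpha',
    'beta'}`` (shape and *rate*), expected value ``alpha / beta``.
    """

    family: str
    params: dict[str, float]

    @property
    def expected_value(self) -> float:
        if self.family == "lognormal":
            return float(np.exp(self.params["mu"] + self.params["sigma"] ** 2 / 2.0))
        if self.family == "gamma":
            return float(self.params["alpha"] / self.params["beta"])
        raise ValueError(f"unknown family {self.family!r}")


def fit_distribution(sample: np.ndarray, family: str) -> DistributionFit:
    """Fit a log-normal or gamma distribution by maximum likelihood."""
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0 or (sample <= 0).any():
        raise ValueError("sample must be positive-valued and nonempty")
    if family == "lognormal":
        logs = np.log(sample)
        mu = float(logs.mean())
        sigma = float(logs.std(ddof=0))
        return DistributionFit("lognormal", {"mu": mu, "sigma": sigma})
    if family == "gamma":
        alpha, _, scale = stats.gamma.fit(sample, floc=0.0)
        return DistributionFit("gamma", {"alpha": float(alpha), "beta": float(1.0 / scale)})
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Temporal-IOR angle profile
# ---------------------------------------------------------------------------


@dataclass
class AngleProfile:
    """Median pre-saccade foveation duration per relative-angle bin.

    30 half-open bins of 12 degrees over (-180, 180]; ``smoothed`` applies a
    centered circular moving average over 5 bins, skipping missing bins with
    a renormalized window.
    """

    bin_centers: np.ndarray
    medians: np.ndarray
    smoothed: np.ndarray
    counts: np.ndarray


def angle_bin(rel_angle_deg: float) -> int:
    """Bin index of a relative angle; +-180 degrees share the terminal bin."""
    a = wrap_angle(rel_angle_deg)
    return int(np.clip(np.ceil((a + 180.0) / 12.0) - 1, 0, N_ANGLE_BINS - 1))


def angle_profile(scanpaths: list[Scanpath]) -> AngleProfile:
    """Temporal-IOR profile: how long the foveation before a saccade lasted,
    as a function of the saccade's direction change."""
    pairs = relative_angle_durations(scanpaths)
    per_bin: list[list[float]] = [[] for _ in range(N_ANGLE_BINS)]
    for ang, dur in pairs:
        per_bin[angle_bin(ang)].append(dur)
    medians = np.array([np.median(b) if b else np.nan for b in per_bin])
    counts = np.array([len(b) for b in per_bin])
    smoothed = _circular_moving_average(medians, SMOOTH_WINDOW)
    edges = np.linspace(-180.0, 180.0, N_ANGLE_BINS + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return AngleProfile(bin_centers=centers, medians=medians, smoothed=smoothed, counts=counts)


def relative_angle_durations(scanpaths: list[Scanpath]) -> list[tuple[float, float]]:
    """(relative angle, preceding foveation duration) pairs, pooled."""
    out: list[tuple[float, float]] = []
    for sp in scanpaths:
        ev = sp.events
        for i in ev.index[ev.event_type == "saccade"]:
            rel = ev.loc[i, "rel_angle_deg"]
            if pd.isna(rel):
                continue  # first saccade has no reference direction
            if i - 1 in ev.index and ev.loc[i - 1, "event_type"] == "foveation":
                out.append((float(rel), float(ev.loc[i - 1, "duration_ms"])))
    return out


def _circular_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    n = len(values)
    out = np.full(n, np.nan)
    for i in range(n):
        neigh = [values[(i + k) % n] for k in range(-half, half + 1)]
        neigh = [v for v in neigh if not np.isnan(v)]
        if neigh:
            out[i] = float(np.mean(neigh))
    return out


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


@dataclass
class GridSearchResult:
    """Ranked grid-search table plus the per-u_min refined optima."""

    table: pd.DataFrame
    refined: pd.DataFrame | None = None

    @property
    def best(self) -> pd.Series:
        ranked = self.table[self.table.score.notna()]
        return ranked.sort_values("score").iloc[0]


def grid_search(
    scenes,
    grid: dict[str, list[float]],
    reference_durations: np.ndarray,
    reference_amplitudes: np.ndarray,
    n_seeds: int = 5,
    base_params=None,
    provider_factory=None,
    filter_params=None,
    refine: bool = False,
    seed0: int = 0,
) -> GridSearchResult:
    """Coarse grid search over {s, theta, f_min, u_min} scored by KS fit.

    For every grid point, ``n_seeds`` scanpaths are simulated per scene; the
    pooled foveation durations and saccade amplitudes are compared with the
    reference samples via the KS statistics D_FD and D_SA, and parameter sets
    are ranked by the mean (D_FD + D_SA) / 2.  A failing simulation marks the
    grid point invalid (score NaN with the error recorded) instead of being
    dropped silently.  With ``refine`` a second pass evaluates midpoints (a
    factor-2 finer spacing) around the best point of every u_min value.
    """
    from .decision import ModelParams, simulate

    base_params = base_params or ModelParams()
    names = sorted(grid)
    rows = []
    for combo in itertools.product(*(grid[n] for n in names)):
        point = dict(zip(names, combo))
        rows.append(_score_point(point, scenes, reference_durations, reference_amplitudes,
                                 n_seeds, base_params, provider_factory, filter_params, seed0))
    table = pd.DataFrame(rows).sort_values("score", na_position="last").reset_index(drop=True)

    refined = None
    if refine and "u_min" in grid:
        ref_rows = []
        for u in grid["u_min"]:
            sub = table[(table.u_min == u) & table.score.notna()]
            if sub.empty:
                continue
            best = sub.sort_values("score").iloc[0]
            for point in _refinement_points(best, grid, u):
                ref_rows.append(
                    _score_point(point, scenes, reference_durations, reference_amplitudes,
                                 n_seeds, base_params, provider_factory, filter_params, seed0)
                )
        if ref_rows:
            refined = pd.DataFrame(ref_rows).sort_values("score").reset_index(drop=True)
    return GridSearchResult(table=table, refined=refined)


def _refinement_points(best: pd.Series, grid: dict, u_min: float) -> list[dict]:
    points = [dict(best[[n for n in grid]].items())]
    for name, values in grid.items():
        if name == "u_min" or len(values) < 2:
            continue
        values = sorted(values)
        step = 0.5 * min(np.diff(values))
        for delta in (-step, step):
            cand = dict(points[0])
            cand[name] = float(best[name] + delta)
            cand["u_min"] = u_min
            if cand[name] > 0:
                points.append(cand)
    for p in points:
        p["u_min"] = u_min
    return points[1:]  # the centre itself is already scored


def _score_point(point, scenes, ref_dur, ref_amp, n_seeds, base_params,
                 provider_factory, filter_params, seed0):
    from .decision import simulate

    durations: list[np.ndarray] = []
    amplitudes: list[np.ndarray] = []
    try:
        params = replace(base_params, **point)
        for si, scene in enumerate(scenes):
            for k in range(n_seeds):
                run_seed = (seed0 + 10007 * si + k) % (1 << 31)
                provider = provider_factory(run_seed) if provider_factory else None
                sp = simulate(scene, provider=provider, params=params,
                              seed=run_seed, filter_params=filter_params, classify=False)
                durations.append(sp.foveation_durations)
                amplitudes.append(sp.saccade_amplitudes)
        d_fd = ks_statistic(np.concatenate(durations), ref_dur)
        d_sa = ks_statistic(np.concatenate(amplitudes), ref_amp)
        return {**point, "D_FD": d_fd, "D_SA": d_sa, "score": 0.5 * (d_fd + d_sa),
                "error": ""}
    except Exception as exc:  # invalid grid point, kept in the table
        warnings.warn(f"grid point {point} failed: {exc}")
        return {**point, "D_FD": np.nan, "D_SA": np.nan, "score": np.nan,
                "error": str(exc)}
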