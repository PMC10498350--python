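"""Windowed velocity decomposition and whole-trajectory descriptors.

Momentary velocities are chord displacements over sliding windows of ``n``
frames, divided by the window duration ``delta_t = n * dt`` and projected
onto the thermal-gradient axis and its normal.  The assay's defaults are
non-overlapping windows of n = 2 frames (delta_t = 1 min); polar windrose
summaries use 10-min overlapping windows with the centroid resolution filter
applied first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import (
    Trajectory,
    TrialMeta,
    WindowedKinematics,
    project_onto_axis,
)

__all__ = [
    "momentary_velocities",
    "mean_velocity_components",
    "windrose",
    "first_passage_time",
    "fraction_time_warmer",
    "end_to_end_angle",
    "step_lengths",
    "FirstPassage",
]

DEFAULT_SPEED_BIN_EDGES = (0.0, 0.025, 0.05, 0.1, 0.2, np.inf)


def momentary_velocities(
    traj: Trajectory,
    meta: TrialMeta,
    n: int = 2,
    overlapping: bool = False,
) -> WindowedKinematics:
    """Windowed momentary-velocity decomposition.

    Windows span ``n`` frames; non-overlapping windows tile the series from
    the start (stride n), overlapping windows use stride 1.  A window is kept
    only if every frame it touches is valid (gaps are skipped, not
    interpolated).  Velocities are the chord displacement between the window
    endpoints over ``delta_t = n * dt`` minutes, projected on the gradient
    axis; ``speed`` is the chord length over ``delta_t``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    N = traj.n_frames
    stride = 1 if overlapping else n
    starts = np.arange(0, N - n, stride, dtype=int) if N > n else np.array([], dtype=int)
    if starts.size == 0:
        empty = np.array([])
        return WindowedKinematics(n, overlapping, empty, empty, empty, empty,
                                  empty, empty, empty, traj.dt_min)
    ends = starts + n
    # all frames within the window must be valid
    cs = np.concatenate([[0], np.cumsum(traj.valid.astype(int))])
    ok = (cs[ends + 1] - cs[starts]) == (n + 1)
    starts, ends = starts[ok], ends[ok]
    dt = n * traj.dt_min
    dx = traj.x[ends] - traj.x[starts]
    dy = traj.y[ends] - traj.y[starts]
    vpar, vort = project_onto_axis(dx, dy, meta.theta)
    disp = np.hypot(dx, dy)
    t = traj.t
    return WindowedKinematics(
        window_n=n,
        overlapping=overlapping,
        t_mid=(t[starts] + t[ends]) / 2.0,
        dx=dx,
        dy=dy,
        v_parallel=vpar / dt,
        v_orthogonal=vort / dt,
        speed=disp / dt,
        displacement=disp,
        dt_min=traj.dt_min,
    )


def mean_velocity_components(kin: WindowedKinematics) -> tuple[float, float, float]:
    """Arithmetic means over windows: (v_parallel, v_orthogonal, speed)."""
    if len(kin) == 0:
        raise ValueError("no windows to average")
    return (
        float(np.mean(kin.v_parallel)),
        float(np.mean(kin.v_orthogonal)),
        float(np.mean(kin.speed)),
    )


def windrose(
    kin: WindowedKinematics,
    n_dir_bins: int = 16,
    speed_bin_edges=DEFAULT_SPEED_BIN_EDGES,
    resolution_limit_mm: float | None = None,
) -> np.ndarray:
    """Normalised 2-D histogram of windowed velocities (speed x direction).

    Direction is the window velocity's angle relative to the warm axis
    (0 = due warm), binned into ``n_dir_bins`` equal sectors centred on 0;
    speeds are binned by ``speed_bin_edges`` (mm min⁻¹).  Counts are
    normalised so the whole histogram sums to 1 (empty input gives an
    all-zero histogram).  If ``resolution_limit_mm`` is not None the centroid
    resolution filter is applied first.
    """
    from .imaging import RESOLUTION_LIMIT_MM, resolution_filter

    if resolution_limit_mm is not None:
        kin = resolution_filter(kin, resolution_limit_mm)
    edges = np.asarray(speed_bin_edges, dtype=float)
    hist = np.zeros((len(edges) - 1, n_dir_bins))
    if len(kin) == 0:
        return hist
    ang = np.arctan2(kin.v_orthogonal, kin.v_parallel)  # 0 = due warm
    width = 2 * np.pi / n_dir_bins
    # sectors centred on bin angles: shift by half a width
    dir_idx = np.floor((ang + width / 2) / width).astype(int) % n_dir_bins
    spd_idx = np.clip(np.searchsorted(edges, kin.speed, side="right") - 1,
                      0, len(edges) - 2)
    np.add.at(hist, (spd_idx, dir_idx), 1.0)
    return hist / hist.sum()


@dataclass
class FirstPassage:
    """First-passage time to a radial distance, or censored if never reached."""

    time_min: float | None
    censored: bool


def first_passage_time(traj: Trajectory, radius_mm: float = 5.0) -> FirstPassage:
    """First time the radial distance from the start reaches ``radius_mm``."""
    if not np.any(traj.valid):
        return FirstPassage(None, True)
    r = np.hypot(traj.x, traj.y)
    hit = np.flatnonzero(traj.valid & (r >= radius_mm))
    if hit.size == 0:
        return FirstPassage(None, True)
    return FirstPassage(float(traj.t[hit[0]] - traj.t[np.flatnonzero(traj.valid)[0]]),
                        False)


def fraction_time_warmer(traj: Trajectory, meta: TrialMeta) -> float:
    """Fraction of valid frames strictly warmer than the start.

    "Warmer" means a strictly positive projection of the position onto the
    warm axis; frames exactly at the starting isotherm do not count.
    """
    if not np.any(traj.valid):
        raise ValueError("no valid frames")
    par, _ = project_onto_axis(traj.x[traj.valid], traj.y[traj.valid], meta.theta)
    return float(np.mean(par > 0.0))


def end_to_end_angle(traj: Trajectory, meta: TrialMeta) -> float:
    """Signed angle (degrees, in (-180, 180]) between the end-to-end vector
    and the warm axis; positive = left of warm.  Undefined (ValueError) for
    zero net displacement."""
    idx = np.flatnonzero(traj.valid)
    if idx.size < 2:
        raise ValueError("need at least two valid frames")
    dx = traj.x[idx[-1]] - traj.x[idx[0]]
    dy = traj.y[idx[-1]] - traj.y[idx[0]]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("zero net displacement: end-to-end angle undefined")
    par, ort = project_onto_axis(dx, dy, meta.theta)
    ang = float(np.degrees(np.arctan2(ort, par)))
    return 180.0 if ang == -180.0 else ang


def step_lengths(
    traj: Trajectory,
    meta: TrialMeta,
    window_min: float = 2.0,
    overlapping: bool = True,
    component: str = "parallel",
) -> np.ndarray:
    """Momentary step-length sample for distribution fitting.

    Absolute windowed displacements (mm) over windows of ``window_min``
    minutes: the magnitude of the gradient-axis component by default
    (``component="parallel"``), or the full chord (``"total"``).
    """
    n = max(int(round(window_min / traj.dt_min)), 1)
    kin = momentary_velocities(traj, meta, n=n, overlapping=overlapping)
    dt = n * traj.dt_min
    if component == "parallel":
        return np.abs(kin.v_parallel) * dt
    if component == "total":
        return kin.displacement
    raise ValueError("component must be 'parallel' or 'total'")


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-trial metric dicts into a one-row-per-trial table."""
    return pd.DataFrame(rows)
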