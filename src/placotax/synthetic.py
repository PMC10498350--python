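"""Synthetic trajectory and image-stack generators.

These stand in for raw assay data: random walkers with the statistical
structure the analysis assumes (exponentially distributed momentary
displacements, direction — not speed — biased up the thermal gradient,
minute-scale freezing pauses, wall termination in a 52.5 mm circular arena),
plus a renderer that turns a trajectory into a grayscale blob stack with a
ground-truth table for exercising the segmentation stage.

Modes
-----
``ballistic``
    Constant-length steps straight up the warm axis (straightness = 1).
``diffusive``
    Isotropic headings, exponential step lengths.
``biased_crw``
    Correlated random walk: each frame's heading is a von Mises draw whose
    mean is the previous heading tilted towards the warm axis with weight
    ``drift_bias`` in [0, 1].  Bias acts on direction only; step lengths stay
    exponential with rate ``step_rate`` regardless of bias, mirroring taxis
    that raises the parallel velocity without raising momentary speed.
``wlc``
    Discrete worm-like chain: fixed step length, Gaussian heading increments
    with variance ``2 * step / Lp_target`` so the tangent correlation decays
    as ``exp(-s / Lp_target)`` along arc length s.
``taylor_process``
    2-D Ornstein–Uhlenbeck velocity with RMS speed ``v`` and decorrelation
    time ``tau``; its ensemble RMSD follows the ballistic-to-diffusive
    crossover form used for the dispersal fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .trajectory import FRAME_INTERVAL_MIN, Trajectory, TrialMeta

__all__ = ["SyntheticSpec", "simulate_trajectory", "simulate_cohort", "simulate_image_stack"]

_MODES = ("ballistic", "diffusive", "biased_crw", "wlc", "taylor_process")


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic trial.

    ``step_rate`` is the exponential rate (mm⁻¹) of per-frame (30 s) momentary
    displacement magnitudes; the default 10 mm⁻¹ means a 0.1 mm mean step,
    i.e. a mean momentary speed of ~0.2 mm min⁻¹ — a realistic gliding speed
    for a millimetre-scale animal that crosses a 52.5 mm arena over hours.
    ``drift_bias`` in [0, 1] tilts step *direction* (never length) towards the
    warm axis.  Pauses are geometric-duration freezes (zero displacement).
    """

    mode: str = "biased_crw"
    step_rate: float = 10.0
    drift_bias: float = 0.0
    turn_kappa: float = 4.0
    Lp_target: float = 2.0
    v: float = 0.2
    tau: float = 5.0
    pause_prob: float = 0.0
    pause_mean_min: float = 2.0
    n_frames: int = 1200
    arena_diameter: float = 52.5
    theta: float = np.pi / 2
    grad: float = 0.1
    t2: float = 18.0
    organism_area: float = 0.5
    dt_min: float = FRAME_INTERVAL_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        for name in ("step_rate", "turn_kappa", "Lp_target", "v", "tau",
                     "pause_mean_min", "arena_diameter", "dt_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.drift_bias <= 1.0:
            raise ValueError("drift_bias must be in [0, 1]")
        if not 0.0 <= self.pause_prob < 1.0:
            raise ValueError("pause_prob must be in [0, 1)")


def _pause_mask(spec: SyntheticSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Boolean mask of frozen frames (True = paused)."""
    if spec.pause_prob == 0.0:
        return np.zeros(n, dtype=bool)
    mean_frames = max(spec.pause_mean_min / spec.dt_min, 1.0)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if rng.random() < spec.pause_prob:
            dur = rng.geometric(1.0 / mean_frames)
            mask[i : i + dur] = True
            i += dur
        else:
            i += 1
    return mask


def _headings_biased_crw(spec: SyntheticSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """Sequential von Mises headings with mean tilted towards the warm axis."""
    warm = np.array([np.cos(spec.theta), np.sin(spec.theta)])
    h = rng.uniform(0.0, 2.0 * np.pi)
    out = np.empty(n)
    b = spec.drift_bias
    for i in range(n):
        mean_vec = (1.0 - b) * np.array([np.cos(h), np.sin(h)]) + b * warm
        if np.hypot(*mean_vec) < 1e-12:  # exactly anti-warm at b=0.5
            mu = h
        else:
            mu = np.arctan2(mean_vec[1], mean_vec[0])
        h = rng.vonmises(mu, spec.turn_kappa)
        out[i] = h
    return out


def simulate_trajectory(spec: SyntheticSpec) -> tuple[Trajectory, TrialMeta]:
    """Simulate one trial; returns the trajectory and its metadata.

    The walk starts at (0, 0) and is truncated at the first frame whose
    radial distance from the arena centre reaches ``arena_diameter / 2``
    (organisms climb the wall and are lost to segmentation there).
    Reproducible: the same spec (including seed) gives identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n_steps = spec.n_frames - 1
    dt = spec.dt_min

    if spec.mode == "ballistic":
        lengths = np.full(n_steps, 1.0 / spec.step_rate)
        headings = np.full(n_steps, spec.theta)
    elif spec.mode == "diffusive":
        lengths = rng.exponential(1.0 / spec.step_rate, n_steps)
        headings = rng.uniform(0.0, 2.0 * np.pi, n_steps)
    elif spec.mode == "biased_crw":
        lengths = rng.exponential(1.0 / spec.step_rate, n_steps)
        headings = _headings_biased_crw(spec, rng, n_steps)
    elif spec.mode == "wlc":
        step = 1.0 / spec.step_rate
        lengths = np.full(n_steps, step)
        sigma = np.sqrt(2.0 * step / spec.Lp_target)
        headings = rng.uniform(0.0, 2.0 * np.pi) + np.cumsum(
            np.concatenate([[0.0], rng.normal(0.0, sigma, n_steps - 1)])
        )
    elif spec.mode == "taylor_process":
        rho = np.exp(-dt / spec.tau)
        s = spec.v / np.sqrt(2.0)  # per-component stationary s.d.
        eps = rng.normal(0.0, s * np.sqrt(1.0 - rho**2), (n_steps, 2))
        u = np.empty((n_steps, 2))
        u[0] = rng.normal(0.0, s, 2)
        for i in range(1, n_steps):
            u[i] = rho * u[i - 1] + eps[i]
        disp = u * dt
        lengths = np.hypot(disp[:, 0], disp[:, 1])
        headings = np.arctan2(disp[:, 1], disp[:, 0])
    else:  # pragma: no cover
        raise AssertionError

    paused = _pause_mask(spec, rng, n_steps)
    lengths = np.where(paused, 0.0, lengths)
    dx = lengths * np.cos(headings)
    dy = lengths * np.sin(headings)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])

    r = np.hypot(x, y)
    wall = np.flatnonzero(r >= spec.arena_diameter / 2.0)
    if wall.size:
        end = wall[0] + 1
        x, y = x[:end], y[:end]
    n = len(x)
    area = spec.organism_area * (1.0 + 0.05 * rng.standard_normal(n))
    perimeter = 2.0 * np.sqrt(np.pi * np.abs(area)) * (1.0 + 0.02 * rng.standard_normal(n))

    traj = Trajectory(
        frame=np.arange(n), x=x, y=y, area=area, perimeter=perimeter,
        dt_min=dt, area_unit="mm2",
    )
    is_gradient = spec.drift_bias > 0.0
    meta = TrialMeta(
        condition="gradient" if is_gradient else "control",
        t2=spec.t2,
        t1=spec.t2 + (spec.grad if is_gradient else 0.0) * spec.arena_diameter / 10.0,
        grad=spec.grad if is_gradient else 0.0,
        theta=spec.theta,
        arena_diameter=spec.arena_diameter,
        organism_area=spec.organism_area,
        trial_id=f"synthetic-{spec.mode}-seed{spec.seed}",
    )
    return traj, meta


def simulate_cohort(
    n_trials: int,
    spec_gradient: SyntheticSpec,
    spec_control: SyntheticSpec,
    base_seed: int = 0,
) -> list[tuple[Trajectory, TrialMeta]]:
    """Simulate ``n_trials`` gradient plus ``n_trials`` control trials.

    Per-trial seeds are ``base_seed + index`` (index runs over all trials in
    order gradient first, then control), so a cohort is reproducible from a
    single integer.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    out: list[tuple[Trajectory, TrialMeta]] = []
    idx = 0
    for cond_spec in (spec_gradient, spec_control):
        for _ in range(n_trials):
            sp = replace(cond_spec, seed=base_seed + idx)
            traj, meta = simulate_trajectory(sp)
            meta.trial_id = f"{meta.condition}-{idx:03d}"
            out.append((traj, meta))
            idx += 1
    return out


# ----------------------------------------------------------------------
def simulate_image_stack(
    traj: Trajectory,
    blob_diameter_px: float = 15.0,
    px_per_mm: float = 16.64,
    noise_sd: float = 0.0,
    shape_wobble: float = 0.0,
    frame_shape: tuple[int, int] | None = None,
    seed: int = 0,
):
    """Render a trajectory as a multipage grayscale stack plus ground truth.

    One soft elliptical Gaussian blob per frame, centred at the true centroid.
    The mm frame maps to pixels as ``col = centre + x * px_per_mm``,
    ``row = centre + y * px_per_mm`` (image rows carry +y).  Returns
    ``(stack, truth)`` where ``stack`` is ``uint8 (n, H, W)`` and ``truth`` a
    DataFrame with the pixel-coordinate centroids.  A truncation warning is
    issued if a blob extends past the frame edge.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    xs, ys = traj.x, traj.y
    if frame_shape is None:
        pad = 4 * blob_diameter_px
        extent = max(np.max(np.abs(xs)), np.max(np.abs(ys)), 1.0) * px_per_mm
        side = int(np.ceil(2 * extent + 2 * pad))
        frame_shape = (side, side)
    H, W = frame_shape
    cy0, cx0 = (H - 1) / 2.0, (W - 1) / 2.0
    sigma = blob_diameter_px / 4.0
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    stack = np.empty((traj.n_frames, H, W), dtype=np.uint8)
    truth_rows = []
    truncated = False
    for i in range(traj.n_frames):
        cx = cx0 + xs[i] * px_per_mm
        cy = cy0 + ys[i] * px_per_mm
        if shape_wobble > 0:
            sx = sigma * (1.0 + shape_wobble * rng.uniform(-1, 1))
            sy = sigma * (1.0 + shape_wobble * rng.uniform(-1, 1))
            phi = rng.uniform(0, np.pi)
        else:
            sx = sy = sigma
            phi = 0.0
        c, s = np.cos(phi), np.sin(phi)
        u = (cols - cx) * c + (rows - cy) * s
        v = -(cols - cx) * s + (rows - cy) * c
        img = 10.0 + 200.0 * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        stack[i] = np.clip(img, 0, 255).astype(np.uint8)
        margin = 3 * max(sx, sy)
        if cx < margin or cy < margin or cx > W - 1 - margin or cy > H - 1 - margin:
            truncated = True
        truth_rows.append({"frame": int(traj.frame[i]), "cx_px": cx, "cy_px": cy})
    if truncated:
        warnings.warn("blob extends past the frame edge in at least one frame",
                      stacklevel=2)
    return stack, pd.DataFrame(truth_rows)
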