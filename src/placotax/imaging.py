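"""Segmentation of image stacks to centroid trajectories, the centroid
resolution filter, and bead-pair body-orientation series.

Segmentation follows the assay's preprocessing recipe: threshold each frame,
size-filter connected components until a single organism-sized blob remains,
take its binary-mask centroid, and end the trajectory when the centroid
reaches the arena wall.  Frames where zero or more than one candidate
survives the size filter are marked invalid rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .trajectory import Trajectory, WindowedKinematics

__all__ = [
    "SegmentationConfig",
    "OrientationSeries",
    "RESOLUTION_LIMIT_MM",
    "segment_stack",
    "resolution_filter",
    "orientation_series",
]

#: Centroid displacement resolution limit of the imaging setup, in mm.
RESOLUTION_LIMIT_MM = 0.0601


@dataclass
class SegmentationConfig:
    """Thresholding / size-filter / termination parameters.

    ``threshold`` is an absolute intensity, or ``"otsu"`` to pick it per
    frame.  Components with pixel area outside ``[min_area_px, max_area_px]``
    are discarded.  ``wall_radius_px`` terminates the trajectory (measured
    from the frame centre); ``px_per_mm`` converts centroids to mm.
    """

    threshold: float | str = "otsu"
    min_area_px: float = 10.0
    max_area_px: float = 1e6
    wall_radius_px: float = np.inf
    px_per_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.min_area_px >= self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if self.wall_radius_px <= 0:
            raise ValueError("wall_radius_px must be > 0")


@dataclass
class OrientationSeries:
    """Body-axis angle (bead1 -> bead2 vs +x) per frame, degrees."""

    t: np.ndarray
    theta_deg: np.ndarray          # unwrapped (continuous through +-180)
    theta_wrapped_deg: np.ndarray  # raw atan2 values in (-180, 180]
    valid: np.ndarray


def segment_stack(stack: np.ndarray, cfg: SegmentationConfig,
                  dt_min: float = 0.5) -> Trajectory:
    """Segment a grayscale stack into a centroid trajectory.

    Per frame: threshold, label, keep components within the size range.  If
    exactly one survives, record its centroid (mm, frame centre as pixel
    origin), pixel area and perimeter; otherwise mark the frame invalid.
    The trajectory is truncated at the first frame whose centroid radius
    reaches ``wall_radius_px``, and recentred so the first valid centroid is
    (0, 0).
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("expected a non-empty (n, H, W) grayscale stack")
    n, H, W = stack.shape
    cy0, cx0 = (H - 1) / 2.0, (W - 1) / 2.0
    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    areas = np.full(n, np.nan)
    perims = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    end = n
    for i in range(n):
        img = stack[i]
        thr = threshold_otsu(img) if cfg.threshold == "otsu" else cfg.threshold
        mask = img > thr
        props = [p for p in regionprops(label(mask))
                 if cfg.min_area_px <= p.area <= cfg.max_area_px]
        if len(props) != 1:
            continue
        p = props[0]
        cy, cx = p.centroid
        xs[i] = (cx - cx0) / cfg.px_per_mm
        ys[i] = (cy - cy0) / cfg.px_per_mm
        areas[i] = p.area
        perims[i] = p.perimeter
        valid[i] = True
        if np.hypot(cx - cx0, cy - cy0) >= cfg.wall_radius_px:
            end = i + 1
            break
    traj = Trajectory(
        frame=np.arange(end), x=np.nan_to_num(xs[:end]), y=np.nan_to_num(ys[:end]),
        area=areas[:end], perimeter=perims[:end], valid=valid[:end],
        dt_min=dt_min, area_unit="px",
    )
    return traj.recentred()


def resolution_filter(kin: WindowedKinematics,
                      limit_mm: float = RESOLUTION_LIMIT_MM) -> WindowedKinematics:
    """Drop windows whose displacement is at or below the resolution limit in
    *both* x and y (|dx| <= limit and |dy| <= limit); idempotent."""
    keep = ~((np.abs(kin.dx) <= limit_mm) & (np.abs(kin.dy) <= limit_mm))
    return kin.select(keep)


def orientation_series(bead1: np.ndarray, bead2: np.ndarray,
                       t: np.ndarray) -> OrientationSeries:
    """Angle of the bead1 -> bead2 segment versus the +x axis, per frame.

    Frames where the beads coincide are invalid.  The angle is unwrapped by
    nearest-branch continuation over valid frames so a smooth rotation gives
    a continuous series; the raw wrapped values are retained.
    """
    b1 = np.asarray(bead1, dtype=float)
    b2 = np.asarray(bead2, dtype=float)
    t = np.asarray(t, dtype=float)
    if b1.shape != b2.shape or len(b1) != len(t):
        raise ValueError("bead tracks and time base must have equal length")
    d = b2 - b1
    valid = np.hypot(d[:, 0], d[:, 1]) > 0
    wrapped = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    unwrapped = np.full(len(t), np.nan)
    if np.any(valid):
        unwrapped[valid] = np.degrees(np.unwrap(np.radians(wrapped[valid])))
    return OrientationSeries(t=t, theta_deg=unwrapped,
                             theta_wrapped_deg=wrapped, valid=valid)
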