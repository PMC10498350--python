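"""Core domain types for centroid-trajectory analysis.

A trial is a long time-lapse recording (30 s per frame) of a single
*Trichoplax adhaerens* gliding in a circular arena, reduced by segmentation to
a centroid time series in millimetres with the starting point recentred to
(0, 0).  Every statistic downstream consumes the :class:`Trajectory` /
:class:`TrialMeta` pair defined here, plus the small record types for windowed
kinematics, nonlinear fits and per-trial path metrics.

Coordinate conventions
----------------------
The thermal gradient axis is a unit vector at angle ``theta`` (radians) from
the +x axis, pointing towards the *warm* side; the default ``theta = pi/2``
puts the heat source at +y.  ``project_onto_axis`` decomposes a displacement
into its component along the warm axis (``parallel``) and the component 90°
counter-clockwise of it (``orthogonal``; left-of-warm is positive).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FRAME_INTERVAL_MIN",
    "Trajectory",
    "TrialMeta",
    "WindowedKinematics",
    "FitResult",
    "PathMetrics",
    "project_onto_axis",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_trial_meta",
    "write_trial_meta",
]

#: Default sampling interval: one frame every 30 s.
FRAME_INTERVAL_MIN = 0.5

_CSV_COLUMNS = ("frame", "x_mm", "y_mm", "area", "perimeter", "valid")


class TrajectoryFormatError(ValueError):
    """A trajectory file does not have the expected columns."""


class TrajectoryDataError(ValueError):
    """A trajectory file parses but violates a data invariant."""


@dataclass
class Trajectory:
    """Centroid time series of one trial.

    Parameters
    ----------
    frame
        Integer frame indices, strictly increasing with constant step.
    x, y
        Centroid position in mm.  The first *valid* sample is recentred to
        (0, 0) by the constructors in this module.
    area, perimeter
        Projected organism area and outline length per frame, in the unit
        named by ``area_unit`` (``"mm2"`` or ``"px"``).
    valid
        Per-frame segmentation-success flag.  Invalid frames are carried as
        gaps; window statistics skip windows touching a gap rather than
        interpolating across it.
    dt_min
        Frame interval in minutes (0.5 for the standard 30 s cadence).
    """

    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray
    area: np.ndarray | None = None
    perimeter: np.ndarray | None = None
    valid: np.ndarray | None = None
    dt_min: float = FRAME_INTERVAL_MIN
    area_unit: str = "mm2"

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frame)
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        for name in ("area", "perimeter"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise TrajectoryDataError("field lengths differ")
        if n > 1:
            steps = np.diff(self.frame)
            if np.any(steps <= 0):
                raise TrajectoryDataError("frame indices must be strictly increasing")
            if np.any(steps != steps[0]):
                raise TrajectoryDataError("frame indices must be evenly spaced")
        if self.dt_min <= 0:
            raise TrajectoryDataError("dt_min must be positive")
        bad = ~np.isfinite(self.x[self.valid]) | ~np.isfinite(self.y[self.valid])
        if np.any(bad):
            raise TrajectoryDataError("non-finite coordinates among valid frames")

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.frame)

    @property
    def t(self) -> np.ndarray:
        """Time in minutes (``frame * dt_min``)."""
        return self.frame * self.dt_min

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y)."""
        return np.column_stack([self.x, self.y])

    def recentred(self) -> "Trajectory":
        """Return a copy with the first valid sample moved to (0, 0)."""
        if not np.any(self.valid):
            return replace(self)
        i0 = int(np.flatnonzero(self.valid)[0])
        return replace(self, x=self.x - self.x[i0], y=self.y - self.y[i0])

    def to_dataframe(self) -> pd.DataFrame:
        n = self.n_frames
        return pd.DataFrame(
            {
                "frame": self.frame,
                "x_mm": self.x,
                "y_mm": self.y,
                "area": self.area if self.area is not None else np.full(n, np.nan),
                "perimeter": self.perimeter
                if self.perimeter is not None
                else np.full(n, np.nan),
                "valid": self.valid.astype(int),
            }
        )


@dataclass
class TrialMeta:
    """Per-trial experimental metadata.

    ``t1`` is the temperature at the warm side of the arena, ``t2`` at the
    cold side, ``grad`` the gradient strength in °C cm⁻¹ and ``theta`` the
    angle (radians from +x) of the warm direction.
    """

    condition: str = "gradient"
    t1: float = float("nan")
    t2: float = float("nan")
    grad: float = 0.0
    theta: float = np.pi / 2
    arena_diameter: float = 52.5
    organism_area: float | None = None
    drug_add_time: float | None = None
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.condition not in ("gradient", "control", "drug"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "gradient" and np.isfinite(self.t1) and np.isfinite(self.t2):
            if self.t1 < self.t2:
                raise ValueError("gradient trials require t1 >= t2")
        if self.grad < 0:
            raise ValueError("grad must be >= 0")
        if self.arena_diameter <= 0:
            raise ValueError("arena_diameter must be > 0")

    def warm_unit(self) -> np.ndarray:
        return np.array([np.cos(self.theta), np.sin(self.theta)])


@dataclass
class WindowedKinematics:
    """Windowed velocity decomposition of a trajectory.

    Each entry summarises one window of ``window_n`` frames by the chord
    displacement between its endpoints: ``(dx, dy)`` in mm, its projection
    onto the gradient axis (``v_parallel``, ``v_orthogonal``) and the chord
    speed, all in mm min⁻¹.
    """

    window_n: int
    overlapping: bool
    t_mid: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    v_parallel: np.ndarray
    v_orthogonal: np.ndarray
    speed: np.ndarray
    displacement: np.ndarray
    dt_min: float = FRAME_INTERVAL_MIN

    def __len__(self) -> int:
        return len(self.t_mid)

    @property
    def delta_t(self) -> float:
        """Window duration in minutes."""
        return self.window_n * self.dt_min

    def select(self, mask: np.ndarray) -> "WindowedKinematics":
        return WindowedKinematics(
            window_n=self.window_n,
            overlapping=self.overlapping,
            t_mid=self.t_mid[mask],
            dx=self.dx[mask],
            dy=self.dy[mask],
            v_parallel=self.v_parallel[mask],
            v_orthogonal=self.v_orthogonal[mask],
            speed=self.speed[mask],
            displacement=self.displacement[mask],
            dt_min=self.dt_min,
        )


@dataclass
class FitResult:
    """Outcome of a nonlinear (or log-linear) least-squares fit."""

    model: str
    params: dict[str, float]
    r2: float
    domain: tuple[float, float] | None = None
    converged: bool = True
    message: str = ""
    extras: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.params[key]


@dataclass
class PathMetrics:
    """Whole-trajectory directedness descriptors."""

    D: float
    L_total: float
    straightness: float
    directionality: float
    end_to_end_angle_deg: float
    first_passage_min: float | None
    first_passage_censored: bool
    frac_time_warmer: float
    positive_thermotaxis: bool
    effective_thermotaxis: bool
    defined: bool = True


# ----------------------------------------------------------------------
def project_onto_axis(dx, dy, theta: float):
    """Decompose displacement(s) into warm-axis and orthogonal components.

    Returns ``(parallel, orthogonal)`` where ``parallel`` is the component
    along the warm direction ``(cos theta, sin theta)`` and ``orthogonal`` is
    the component along its 90° counter-clockwise normal (left-of-warm
    positive).  Norm-preserving: ``parallel**2 + orthogonal**2 ==
    dx**2 + dy**2``.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    parallel = dx * c + dy * s
    orthogonal = -dx * s + dy * c
    return parallel, orthogonal


# ----------------------------------------------------------------------
# Trajectory CSV I/O.  Column names default to the package's own dialect
# (frame,x_mm,y_mm,area,perimeter,valid); a `dialect` map absorbs deposited
# files with other headers or pixel units.

_DEFAULT_DIALECT = {
    "frame": "frame",
    "x": "x_mm",
    "y": "y_mm",
    "area": "area",
    "perimeter": "perimeter",
    "valid": "valid",
}


def read_trajectory_csv(
    path,
    dialect: Mapping[str, str] | None = None,
    mm_per_px: float | None = None,
    dt_min: float = FRAME_INTERVAL_MIN,
    recentre: bool = True,
) -> Trajectory:
    """Read a centroid-trajectory CSV.

    ``dialect`` maps the roles ``frame``/``x``/``y`` (required) and
    ``area``/``perimeter``/``valid`` (optional) to the file's column names.
    If ``mm_per_px`` is given, coordinates are converted from pixels to mm
    and areas from px² to mm².  The origin is recentred to the first valid
    sample unless ``recentre=False``.
    """
    cols = dict(_DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path)
    for role in ("frame", "x", "y"):
        if cols[role] not in df.columns:
            raise TrajectoryFormatError(
                f"column {cols[role]!r} (role {role!r}) missing from {path}"
            )
    frame = df[cols["frame"]].to_numpy()
    x = df[cols["x"]].to_numpy(dtype=float)
    y = df[cols["y"]].to_numpy(dtype=float)
    area_unit = "mm2"
    area = perim = None
    if cols["area"] in df.columns:
        area = df[cols["area"]].to_numpy(dtype=float)
    if cols["perimeter"] in df.columns:
        perim = df[cols["perimeter"]].to_numpy(dtype=float)
    valid = None
    if cols["valid"] in df.columns:
        valid = df[cols["valid"]].to_numpy().astype(bool)
    if mm_per_px is not None:
        x = x * mm_per_px
        y = y * mm_per_px
        if area is not None:
            area = area * mm_per_px**2
        if perim is not None:
            perim = perim * mm_per_px
    elif dialect and dialect.get("x", "").endswith("px"):
        area_unit = "px"
    traj = Trajectory(
        frame=frame, x=x, y=y, area=area, perimeter=perim, valid=valid,
        dt_min=dt_min, area_unit=area_unit,
    )
    return traj.recentred() if recentre else traj


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Write a trajectory with fixed float formatting (lossless round-trip
    for coordinates written at 1e-9 mm resolution; byte-stable)."""
    df = traj.to_dataframe()
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.9f", lineterminator="\n")
    Path(path).write_text(buf.getvalue())


# ----------------------------------------------------------------------
def write_trial_meta(meta: TrialMeta, path) -> None:
    """YAML sidecar for one trial's metadata."""
    d = {
        "condition": meta.condition,
        "t1": float(meta.t1),
        "t2": float(meta.t2),
        "grad": float(meta.grad),
        "theta": float(meta.theta),
        "arena_diameter": float(meta.arena_diameter),
        "organism_area": None if meta.organism_area is None else float(meta.organism_area),
        "drug_add_time": None if meta.drug_add_time is None else float(meta.drug_add_time),
        "trial_id": meta.trial_id,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_trial_meta(path) -> TrialMeta:
    d = yaml.safe_load(Path(path).read_text())
    return TrialMeta(
        condition=d.get("condition", "gradient"),
        t1=d.get("t1", float("nan")) if d.get("t1") is not None else float("nan"),
        t2=d.get("t2", float("nan")) if d.get("t2") is not None else float("nan"),
        grad=d.get("grad", 0.0) or 0.0,
        theta=d.get("theta", np.pi / 2),
        arena_diameter=d.get("arena_diameter", 52.5),
        organism_area=d.get("organism_area"),
        drug_add_time=d.get("drug_add_time"),
        trial_id=d.get("trial_id", ""),
    )
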