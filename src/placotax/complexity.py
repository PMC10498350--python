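"""Long-range-correlation and entropy metrics, plus the rank tests used for
group and before/after comparisons.

Detrended fluctuation analysis (DFA) distinguishes genuine long-range
correlation from local patchiness — exactly the ambiguity posed by jittery
centroid tracks with near-stationary segments.  Windowed Shannon entropy of
the smoothed momentary-velocity series falls with window size when long
stretches of the series are directionally organised.  Group comparisons use
a Mann–Whitney U rank test with an exact small-sample null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .trajectory import FitResult, Trajectory, TrialMeta
from .kinematics import momentary_velocities

__all__ = [
    "dfa_exponent",
    "windowed_entropy",
    "mann_whitney",
    "MannWhitneyResult",
    "drug_window_compare",
    "DrugWindowComparison",
]


def dfa_exponent(
    series,
    scale_min: int = 4,
    scale_max: int | None = None,
    n_scales: int = 10,
    order: int = 1,
) -> FitResult:
    """Detrended fluctuation analysis scaling exponent.

    The series is integrated (cumulative sum of deviations from the mean),
    cut into non-overlapping boxes of each scale, detrended box-wise with a
    polynomial of the given order, and the RMS fluctuation F(s) is regressed
    against scale on log–log axes over ``n_scales`` log-spaced scales from
    ``scale_min`` to ``scale_max`` (default N/4).  White noise gives an
    exponent of 0.5, its cumulative sum 1.5; the exponent is invariant under
    affine transforms of the series.
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        x = x[np.isfinite(x)]
    N = len(x)
    if scale_max is None:
        scale_max = N // 4
    if N < 4 * scale_min or scale_max <= scale_min:
        raise ValueError("series too short for the requested scales")
    if np.ptp(x) == 0:
        raise ValueError("constant series has zero fluctuation")
    profile = np.cumsum(x - np.mean(x))
    scales = np.unique(
        np.round(np.geomspace(scale_min, scale_max, n_scales)).astype(int)
    )
    F = np.empty(len(scales))
    for i, s in enumerate(scales):
        nbox = N // s
        seg = profile[: nbox * s].reshape(nbox, s)
        t = np.arange(s)
        # least-squares polynomial detrend per box
        coef = np.polynomial.polynomial.polyfit(t, seg.T, order)
        trend = np.polynomial.polynomial.polyval(t, coef)
        F[i] = np.sqrt(np.mean((seg - trend) ** 2))
    # treat numerically-zero fluctuations (profile exactly removed by the
    # detrend, up to round-off) as zero
    tol = 1e-10 * (np.max(np.abs(profile)) + 1.0)
    keep = F > tol
    if keep.sum() < 3:
        raise ValueError("fluctuation vanished at nearly all scales "
                         "(series is deterministic at the detrend order)")
    slope, intercept = np.polyfit(np.log(scales[keep]), np.log(F[keep]), 1)
    pred = slope * np.log(scales[keep]) + intercept
    ss = np.sum((np.log(F[keep]) - np.mean(np.log(F[keep]))) ** 2)
    r2 = 1.0 - np.sum((np.log(F[keep]) - pred) ** 2) / ss if ss > 0 else 1.0
    return FitResult(
        model="dfa",
        params={"dfa_alpha": float(slope), "intercept": float(intercept)},
        r2=float(r2),
        domain=(float(scales.min()), float(scales.max())),
        extras={"scales": scales, "F": F},
    )


def windowed_entropy(
    series,
    window_sizes,
    n_levels: int = 10,
) -> dict[int, float]:
    """Shannon entropy (bits) of the sliding-mean-smoothed series per window.

    For each window size the series is smoothed by a sliding-window mean,
    discretised into ``n_levels`` equal-width bins spanning the *raw*
    series' range (fixed across window sizes, so that smoothing — which
    concentrates the values — genuinely lowers the entropy), and the
    entropy ``-sum p log2 p`` of the symbol distribution is reported.  A
    constant series has zero entropy at every window; because the bin edges
    scale with the series' own range, the value is invariant to affine
    rescaling.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    out: dict[int, float] = {}
    lo, hi = (x.min(), x.max()) if len(x) else (0.0, 0.0)
    for w in window_sizes:
        w = int(w)
        if w < 1 or w > len(x):
            raise ValueError(f"window size {w} out of range for series of {len(x)}")
        if hi == lo:
            out[w] = 0.0
            continue
        sm = np.convolve(x, np.ones(w) / w, mode="valid")
        sym = np.clip(((sm - lo) / (hi - lo) * n_levels).astype(int), 0, n_levels - 1)
        p = np.bincount(sym, minlength=n_levels) / len(sym)
        p = p[p > 0]
        out[w] = float(-np.sum(p * np.log2(p)))
    return out


# ----------------------------------------------------------------------
@dataclass
class MannWhitneyResult:
    U: float
    p: float
    method: str  # "exact" or "normal"


def _exact_u_tail_counts(n_a: int, n_b: int) -> np.ndarray:
    """Null distribution of U (count of (a, b) pairs with a > b) by
    enumeration of all rank assignments."""
    total = n_a + n_b
    counts = np.zeros(n_a * n_b + 1, dtype=np.int64)
    ranks = range(total)
    for a_pos in combinations(ranks, n_a):
        # U = sum over a-ranks of (number of b-ranks below)
        u = sum(r - i for i, r in enumerate(sorted(a_pos)))
        counts[u] += 1
    return counts


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U rank test.

    ``U`` counts pairs where a sample from ``group_a`` exceeds one from
    ``group_b`` (ties count 1/2).  With min(n_a, n_b) <= 8 and no ties the
    p-value is exact (full enumeration of the null rank distribution);
    otherwise a normal approximation with tie correction and continuity
    correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    r_a = float(np.sum(ranks[:n_a]))
    U = r_a - n_a * (n_a + 1) / 2.0
    has_ties = len(np.unique(combined)) < len(combined)
    mn = n_a * n_b

    if min(n_a, n_b) <= 8 and not has_ties:
        counts = _exact_u_tail_counts(n_a, n_b)
        total = comb(n_a + n_b, n_a)
        u = int(round(U))
        u_lo = min(u, mn - u)
        p = (counts[: u_lo + 1].sum() + counts[mn - u_lo :].sum()) / total
        return MannWhitneyResult(U=float(U), p=float(min(p, 1.0)), method="exact")

    # normal approximation with tie correction
    N = n_a + n_b
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    sigma2 = mn / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if sigma2 <= 0:
        return MannWhitneyResult(U=float(U), p=1.0, method="normal")
    z = (U - mn / 2.0)
    z = (abs(z) - 0.5) / np.sqrt(sigma2) if abs(z) > 0.5 else 0.0
    p = 2.0 * stats.norm.sf(z)
    return MannWhitneyResult(U=float(U), p=float(min(p, 1.0)), method="normal")


# ----------------------------------------------------------------------
@dataclass
class DrugWindowComparison:
    """Directionality and mean momentary speed in equal windows before and
    after a perturbation (e.g. channel-blocker addition)."""

    directionality_before: float
    directionality_after: float
    speed_before: float
    speed_after: float
    window_min: float


def _window_metrics(traj: Trajectory, meta: TrialMeta, t_lo: float, t_hi: float,
                    sub_window_frames: int, overlapping: bool,
                    min_frames: int = 2):
    from .trajectory import Trajectory as _T
    from .trajectory import project_onto_axis

    sel = (traj.t >= t_lo) & (traj.t <= t_hi)
    idx = np.flatnonzero(sel)
    if idx.size < max(sub_window_frames + 1, min_frames):
        raise ValueError("insufficient data in comparison window")
    sub = _T(
        frame=traj.frame[idx], x=traj.x[idx], y=traj.y[idx],
        valid=traj.valid[idx], dt_min=traj.dt_min,
    )
    vidx = np.flatnonzero(sub.valid)
    if vidx.size < 2:
        raise ValueError("insufficient valid data in comparison window")
    dx = sub.x[vidx[-1]] - sub.x[vidx[0]]
    dy = sub.y[vidx[-1]] - sub.y[vidx[0]]
    steps = np.hypot(np.diff(sub.x[vidx]), np.diff(sub.y[vidx]))
    L = float(np.sum(steps))
    par, _ = project_onto_axis(dx, dy, meta.theta)
    directionality = float(par) / L if L > 0 else np.nan
    kin = momentary_velocities(sub, meta, n=sub_window_frames, overlapping=overlapping)
    if len(kin) == 0:
        raise ValueError("insufficient valid data in comparison window")
    return directionality, float(np.mean(kin.speed))


def drug_window_compare(
    traj: Trajectory,
    meta: TrialMeta,
    window_min: float = 20.0,
    sub_window_frames: int = 1,
    overlapping: bool = False,
) -> DrugWindowComparison:
    """Directionality index and mean momentary speed in the ``window_min``
    minutes immediately before and after ``meta.drug_add_time``.

    Momentary speed uses non-overlapping 30 s (1-frame) sub-windows by
    default.  Raises if the perturbation time is unset or either side lacks
    data.
    """
    if meta.drug_add_time is None:
        raise ValueError("drug_add_time not set in trial metadata")
    t0 = float(meta.drug_add_time)
    # require full coverage of the window on each side
    min_frames = int(round(window_min / traj.dt_min))
    d_before, s_before = _window_metrics(
        traj, meta, t0 - window_min, t0 - 1e-9, sub_window_frames, overlapping,
        min_frames)
    d_after, s_after = _window_metrics(
        traj, meta, t0 + 1e-9, t0 + window_min, sub_window_frames, overlapping,
        min_frames)
    return DrugWindowComparison(
        directionality_before=d_before,
        directionality_after=d_after,
        speed_before=s_before,
        speed_after=s_after,
        window_min=window_min,
    )
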