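"""Dispersal and persistence statistics.

Axis-resolved time-averaged mean squared displacement (MSD) and its log–log
slope alpha (1 = diffusive, 2 = ballistic), straightness and directionality
indices, worm-like-chain persistence-length scans, the ballistic-to-diffusive
RMSD crossover fit, and step-length distribution model comparison
(exponential vs Lévy vs power law on 40-bin histograms).

Unless asked otherwise, MSD is computed on a fixed 200-point window near the
end of the trajectory — the 200 samples from ``last-210`` to ``last-11``
(a 100 min stretch ending 5 min before the last frame) — which normalises
trials of very different lengths and avoids the stagnant unfolding period at
the start and the wall approach at the end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .trajectory import FitResult, PathMetrics, Trajectory, TrialMeta, project_onto_axis
from .kinematics import end_to_end_angle, first_passage_time, fraction_time_warmer

__all__ = [
    "MSDCurve",
    "msd_axis",
    "loglog_slope",
    "path_metrics",
    "persistence_length_scan",
    "wlc_mean_square_displacement",
    "taylor_rmsd",
    "fit_rmsd_taylor",
    "fit_rmsd_ballistic",
    "step_length_fits",
    "END_WINDOW_POINTS",
    "DEFAULT_MAX_LAG",
]

#: Number of samples in the standard end-of-trajectory MSD window.
END_WINDOW_POINTS = 200
#: Frames trimmed off the very end before taking the window (5 min).
END_WINDOW_TRIM = 10
#: Default maximum lag (frames) for the log–log slope fit: 10 min, one tenth
#: of the 100-min window.  Time-averaged MSD at lags comparable to the window
#: length rests on very few samples, and regressing log(MSD) there biases the
#: slope low; capping the fit range keeps an unbiased walk reading alpha = 1.
DEFAULT_MAX_LAG = 20


@dataclass
class MSDCurve:
    """Time-averaged MSD of one projected coordinate: ``msd[i]`` (mm²) at
    ``lag_min[i]`` minutes (``lag_frames[i]`` frames)."""

    lag_frames: np.ndarray
    lag_min: np.ndarray
    msd: np.ndarray
    component: str = "parallel"
    n_points: int = 0

    def rmsd(self) -> np.ndarray:
        return np.sqrt(self.msd)


def _axis_coordinate(traj: Trajectory, meta: TrialMeta, component: str) -> np.ndarray:
    par, ort = project_onto_axis(traj.x, traj.y, meta.theta)
    s = {"parallel": par, "orthogonal": ort}[component]
    s = s.astype(float).copy()
    s[~traj.valid] = np.nan
    return s


def msd_axis(
    traj: Trajectory,
    meta: TrialMeta,
    component: str = "parallel",
    window_rule: str = "paper_end_window",
) -> MSDCurve:
    """Time-averaged MSD of the gradient-axis (or orthogonal) coordinate.

    ``window_rule="paper_end_window"`` uses the standard 200-point end
    window (requires at least 211 frames); ``"full"`` uses the whole series.
    Lags run from 1 frame (30 s) to one less than the window length; invalid
    frames propagate as NaN and are excluded from each lag's average.
    """
    if component not in ("parallel", "orthogonal"):
        raise ValueError("component must be 'parallel' or 'orthogonal'")
    s = _axis_coordinate(traj, meta, component)
    N = len(s)
    if window_rule == "paper_end_window":
        need = END_WINDOW_POINTS + END_WINDOW_TRIM + 1
        if N < need:
            raise ValueError(
                f"end-window MSD needs >= {need} frames, got {N}"
            )
        s = s[N - END_WINDOW_POINTS - END_WINDOW_TRIM : N - END_WINDOW_TRIM]
    elif window_rule != "full":
        raise ValueError("window_rule must be 'paper_end_window' or 'full'")
    M = len(s)
    lags = np.arange(1, M)
    msd = np.empty(M - 1)
    for i, lag in enumerate(lags):
        d = s[lag:] - s[:-lag]
        d = d[np.isfinite(d)]
        msd[i] = np.mean(d**2) if d.size else np.nan
    return MSDCurve(
        lag_frames=lags,
        lag_min=lags * traj.dt_min,
        msd=msd,
        component=component,
        n_points=M,
    )


def loglog_slope(
    msd: MSDCurve,
    lag_range: tuple[int, int] | None = None,
    max_lag: int | None = DEFAULT_MAX_LAG,
) -> FitResult:
    """Least-squares slope of log(MSD) vs log(lag): the alpha exponent.

    ``lag_range=(lo, hi)`` restricts the fit to lags in frames [lo, hi];
    otherwise lags up to ``max_lag`` are used (``max_lag=None`` fits all
    lags).  Zero/negative/NaN MSD points are excluded; fewer than 3 usable
    points is an error.
    """
    keep = np.isfinite(msd.msd) & (msd.msd > 0)
    if lag_range is not None:
        keep &= (msd.lag_frames >= lag_range[0]) & (msd.lag_frames <= lag_range[1])
    elif max_lag is not None:
        keep &= msd.lag_frames <= max_lag
    if keep.sum() < 3:
        raise ValueError("need at least 3 positive MSD points for a slope fit")
    lx = np.log(msd.lag_min[keep])
    ly = np.log(msd.msd[keep])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum((ly - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    return FitResult(
        model="loglog_slope",
        params={"alpha": float(slope), "intercept": float(intercept)},
        r2=float(r2),
        domain=(float(msd.lag_min[keep].min()), float(msd.lag_min[keep].max())),
    )


# ----------------------------------------------------------------------
def path_metrics(traj: Trajectory, meta: TrialMeta,
                 first_passage_radius_mm: float = 5.0) -> PathMetrics:
    """Whole-trajectory directedness metrics.

    ``straightness = D / L`` (end-to-end displacement over total path
    length, direction-blind) and ``directionality = D cos(theta_e) / L``
    where ``theta_e`` is the end-to-end vector's angle to the warm axis —
    the efficiency of travel towards the stimulus.  A trial counts as
    positive thermotaxis when directionality > 0 and as *effective*
    thermotaxis when it exceeds 0.1.
    """
    idx = np.flatnonzero(traj.valid)
    if idx.size < 2:
        return PathMetrics(np.nan, np.nan, np.nan, np.nan, np.nan, None, True,
                           np.nan, False, False, defined=False)
    x, y = traj.x[idx], traj.y[idx]
    steps = np.hypot(np.diff(x), np.diff(y))
    L = float(np.sum(steps))
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    D = float(np.hypot(dx, dy))
    if L == 0.0:
        return PathMetrics(D, L, np.nan, np.nan, np.nan, None, True,
                           np.nan, False, False, defined=False)
    par, _ = project_onto_axis(dx, dy, meta.theta)
    straightness = D / L
    directionality = float(par) / L
    try:
        angle = end_to_end_angle(traj, meta)
    except ValueError:
        angle = np.nan
    fp = first_passage_time(traj, first_passage_radius_mm)
    return PathMetrics(
        D=D,
        L_total=L,
        straightness=straightness,
        directionality=directionality,
        end_to_end_angle_deg=angle,
        first_passage_min=fp.time_min,
        first_passage_censored=fp.censored,
        frac_time_warmer=fraction_time_warmer(traj, meta),
        positive_thermotaxis=directionality > 0.0,
        effective_thermotaxis=directionality > 0.1,
    )


# ----------------------------------------------------------------------
def wlc_mean_square_displacement(L, Lp):
    """Worm-like-chain relation: mean square end-to-end distance of a contour
    of arc length ``L`` with persistence length ``Lp``:
    ``2 Lp^2 (L/Lp - 1 + exp(-L/Lp))``."""
    L = np.asarray(L, dtype=float)
    u = L / Lp
    return 2.0 * Lp**2 * (u - 1.0 + np.exp(-u))


LP_UPPER_BOUND = 1e3  # mm; binds on straight-path degeneracy


def _contour_r2(x: np.ndarray, y: np.ndarray, L: float) -> np.ndarray:
    """Squared end-to-end displacements of maximal non-overlapping contours
    of arc length L, walking from the path start; the cut point is linearly
    interpolated inside the segment where the running arc length crosses L,
    and the trailing remainder is discarded."""
    seg = np.hypot(np.diff(x), np.diff(y))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    r2 = []
    s0 = 0.0
    px, py = x[0], y[0]
    while s0 + L <= total + 1e-12:
        s1 = s0 + L
        j = int(np.searchsorted(cum, s1, side="right") - 1)
        if j >= len(seg):
            qx, qy = x[-1], y[-1]
        else:
            frac = 0.0 if seg[j] == 0 else (s1 - cum[j]) / seg[j]
            qx = x[j] + frac * (x[j + 1] - x[j])
            qy = y[j] + frac * (y[j + 1] - y[j])
        r2.append((qx - px) ** 2 + (qy - py) ** 2)
        s0, px, py = s1, qx, qy
    return np.asarray(r2)


def _fit_lp(L: float, mean_r2: float, lower: float) -> tuple[float, bool]:
    """Solve 2 Lp^2 (L/Lp - 1 + e^{-L/Lp}) = mean_r2 for Lp.

    The left side increases monotonically with Lp from 0 towards L^2, so a
    single averaged point determines Lp by root finding; when mean_r2 is at
    or beyond the straight-path limit L^2 the fit diverges and the upper
    bound is returned with a flag.
    """
    if mean_r2 <= 0:
        return lower, True
    f = lambda lp: wlc_mean_square_displacement(L, lp) - mean_r2
    if f(LP_UPPER_BOUND) <= 0:
        return LP_UPPER_BOUND, True
    lo = min(lower, 1e-6)
    if f(lo) > 0:
        return lower, True
    lp = optimize.brentq(f, lo, LP_UPPER_BOUND, xtol=1e-10, rtol=1e-12)
    return float(lp), False


def persistence_length_scan(
    traj: Trajectory,
    L_max_mm: float = 20.0,
    L_step_mm: float = 1.0,
) -> tuple[pd.DataFrame, float, FitResult]:
    """Persistence length as a function of contour window length.

    For each window length ``L`` up to ``L_max_mm`` (2 cm), the path is cut
    into maximal non-overlapping contours of arc length ``L``; the averaged
    squared end-to-end displacement of those contours is fitted to the
    worm-like-chain relation to give ``Lp(L)``.  Returns the scan table, the
    ``L`` with the longest fitted persistence length, and the FitResult at
    that optimum.  Window lengths yielding fewer than two contours are
    skipped.
    """
    idx = np.flatnonzero(traj.valid)
    if idx.size < 2:
        raise ValueError("need at least two valid frames")
    x, y = traj.x[idx], traj.y[idx]
    Ls = np.arange(L_step_mm, L_max_mm + 1e-9, L_step_mm)
    rows = []
    for L in Ls:
        r2 = _contour_r2(x, y, L)
        if len(r2) < 2:
            continue
        lp, diverged = _fit_lp(L, float(np.mean(r2)), L_step_mm)
        rows.append({"L_mm": float(L), "Lp_mm": lp, "n_contours": len(r2),
                     "mean_r2_mm2": float(np.mean(r2)), "diverged": diverged})
    if not rows:
        raise ValueError("path too short for any contour window")
    table = pd.DataFrame(rows)
    best = table.loc[table["Lp_mm"].idxmax()]
    # a single averaged point determines Lp exactly, so the residual at the
    # root is zero whenever the bounded solve converged
    fit = FitResult(
        model="wlc_persistence",
        params={"Lp": float(best["Lp_mm"]), "L_at_max": float(best["L_mm"])},
        r2=np.nan if best["diverged"] else 1.0,
        domain=(float(table["L_mm"].min()), float(table["L_mm"].max())),
        converged=not bool(best["diverged"]),
        message="Lp at upper bound (straight-path degeneracy)" if best["diverged"] else "",
        extras={"n_contours": int(best["n_contours"])},
    )
    return table, float(best["L_mm"]), fit


# ----------------------------------------------------------------------
def taylor_rmsd(t, v, tau):
    """Velocity-autocorrelation dispersal law: RMSD(t) =
    sqrt(2 v^2 tau (t - tau (1 - exp(-t/tau)))) — ballistic (v t) at short
    times, diffusive (sqrt(2 v^2 tau t)) at long times."""
    t = np.asarray(t, dtype=float)
    return np.sqrt(2.0 * v**2 * tau * (t - tau * (1.0 - np.exp(-t / tau))))


def _r2(y, pred) -> float:
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    if ss_tot == 0:
        return 1.0 if np.allclose(y, pred) else 0.0
    return float(1.0 - np.sum((y - pred) ** 2) / ss_tot)


def fit_rmsd_taylor(lag_min, rmsd_mm) -> FitResult:
    """Nonlinear least-squares fit of the ballistic-to-diffusive crossover
    RMSD form; returns speed ``v`` (mm min⁻¹) and decorrelation time ``tau``
    (min), both constrained positive."""
    t = np.asarray(lag_min, dtype=float)
    y = np.asarray(rmsd_mm, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y) & (t > 0)
    t, y = t[keep], y[keep]
    if len(t) < 3:
        raise ValueError("need at least 3 RMSD points")
    v0 = max(y[-1] / t[-1], 1e-6)
    tau0 = max(t[-1] / 4.0, t[0])
    try:
        popt, _ = optimize.curve_fit(
            taylor_rmsd, t, y, p0=[v0, tau0],
            bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=20000,
        )
        v, tau = float(popt[0]), float(popt[1])
        return FitResult(
            model="taylor",
            params={"v": v, "tau": tau},
            r2=_r2(y, taylor_rmsd(t, v, tau)),
            domain=(float(t.min()), float(t.max())),
        )
    except RuntimeError as exc:
        return FitResult(model="taylor", params={"v": np.nan, "tau": np.nan},
                         r2=np.nan, domain=(float(t.min()), float(t.max())),
                         converged=False, message=str(exc))


def fit_rmsd_ballistic(lag_min, rmsd_mm) -> FitResult:
    """One-parameter through-origin fit RMSD(t) = v t (pure ballistic)."""
    t = np.asarray(lag_min, dtype=float)
    y = np.asarray(rmsd_mm, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    denom = np.sum(t**2)
    v = float(np.sum(t * y) / denom) if denom > 0 else 0.0
    return FitResult(
        model="ballistic",
        params={"v": v},
        r2=_r2(y, v * t),
        domain=(float(t.min()), float(t.max())) if len(t) else None,
    )


# ----------------------------------------------------------------------
# Step-length distribution model comparison on histogram densities.

def levy_pdf(x, c, mu):
    """One-sided Lévy density
    ``sqrt(c / 2 pi) exp(-c / (2 (x - mu))) / (x - mu)^{3/2}`` for x > mu
    (0 at and below mu)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    m = x > mu
    z = x[m] - mu
    out[m] = np.sqrt(c / (2.0 * np.pi)) * np.exp(-c / (2.0 * z)) / z**1.5
    return out


def _exp_model(x, a, lam):
    return a * np.exp(-lam * x)


def _powerlaw_model(x, a, k):
    return a * np.power(x, -k)


def step_length_fits(
    displacements,
    n_bins: int = 40,
    ml_exponential: bool = False,
) -> tuple[list[FitResult], str]:
    """Fit exponential, Lévy and power-law models to a step-length histogram.

    The sample is binned into ``n_bins`` equal-width density bins and each
    model is least-squares fitted to the bin heights; models are ranked by
    r² against those heights and the best model's name is returned alongside
    the fits.  ``ml_exponential=True`` additionally reports the closed-form
    maximum-likelihood rate (1/mean) in the exponential fit's extras.
    """
    d = np.asarray(displacements, dtype=float)
    d = d[np.isfinite(d)]
    if len(d) < 100:
        raise ValueError("need at least 100 displacements")
    if np.ptp(d) == 0:
        raise ValueError("degenerate sample: all displacements equal")
    heights, edges = np.histogram(d, bins=n_bins, density=True)
    centers = (edges[:-1] + edges[1:]) / 2.0
    fits: list[FitResult] = []

    # exponential a * exp(-lam x)
    lam0 = 1.0 / max(np.mean(d), 1e-12)
    try:
        popt, _ = optimize.curve_fit(
            _exp_model, centers, heights, p0=[heights.max() or 1.0, lam0],
            bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=20000)
        fr = FitResult("exponential", {"a": float(popt[0]), "lambda": float(popt[1])},
                       _r2(heights, _exp_model(centers, *popt)),
                       domain=(float(edges[0]), float(edges[-1])))
    except RuntimeError as exc:
        fr = FitResult("exponential", {"a": np.nan, "lambda": np.nan}, -np.inf,
                       converged=False, message=str(exc))
    if ml_exponential:
        fr.extras["lambda_ml"] = float(1.0 / np.mean(d))
    fits.append(fr)

    # Lévy (c, mu), mu constrained below the sample minimum
    mu_max = float(d.min()) - 1e-9
    try:
        popt, _ = optimize.curve_fit(
            levy_pdf, centers, heights,
            p0=[max(np.median(d), 1e-3), mu_max - 0.5 * max(np.std(d), 1e-3)],
            bounds=([1e-12, -np.inf], [np.inf, mu_max]), maxfev=20000)
        fits.append(FitResult("levy", {"c": float(popt[0]), "mu": float(popt[1])},
                              _r2(heights, levy_pdf(centers, *popt)),
                              domain=(float(edges[0]), float(edges[-1]))))
    except RuntimeError as exc:
        fits.append(FitResult("levy", {"c": np.nan, "mu": np.nan}, -np.inf,
                              converged=False, message=str(exc)))

    # power law a x^-k on strictly positive bin centers
    pos = centers > 0
    try:
        popt, _ = optimize.curve_fit(
            _powerlaw_model, centers[pos], heights[pos], p0=[1.0, 1.0],
            bounds=([0, -10], [np.inf, 10]), maxfev=20000)
        fits.append(FitResult("powerlaw", {"a": float(popt[0]), "k": float(popt[1])},
                              _r2(heights[pos], _powerlaw_model(centers[pos], *popt)),
                              domain=(float(edges[0]), float(edges[-1]))))
    except RuntimeError as exc:
        fits.append(FitResult("powerlaw", {"a": np.nan, "k": np.nan}, -np.inf,
                              converged=False, message=str(exc)))

    best = max(fits, key=lambda f: f.r2 if np.isfinite(f.r2) else -np.inf)
    return fits, best.model
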