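"""Figure helpers: kymographs, windrose polar histograms, MSD curves and
step-length histograms with fitted models."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .trajectory import project_onto_axis
from .trajstats import levy_pdf, taylor_rmsd

__all__ = ["plot_kymograph", "plot_windrose", "plot_msd", "plot_step_histogram"]


def plot_kymograph(trials, ax=None, cmap="coolwarm"):
    """Warm-axis coordinate vs time, one curve per trial, aligned at t=0."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for traj, meta in trials:
        par, _ = project_onto_axis(traj.x, traj.y, meta.theta)
        ax.plot(traj.t, par, lw=0.8, alpha=0.8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("position along warm axis (mm)")
    return ax


def plot_windrose(hist, speed_bin_edges=None, ax=None, rmax=0.1):
    """Stacked polar bar chart of the (speed x direction) histogram; bar
    height is probability mass, radial limit defaults to 0.1."""
    hist = np.asarray(hist)
    n_speed, n_dir = hist.shape
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4.5, 4.5))
    width = 2 * np.pi / n_dir
    angles = np.arange(n_dir) * width
    bottom = np.zeros(n_dir)
    cm = plt.get_cmap("viridis", n_speed)
    for s in range(n_speed):
        label = None
        if speed_bin_edges is not None:
            lo, hi = speed_bin_edges[s], speed_bin_edges[s + 1]
            label = f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"
        ax.bar(angles, hist[s], width=width, bottom=bottom, color=cm(s),
               edgecolor="none", label=label)
        bottom += hist[s]
    ax.set_theta_zero_location("N")  # due warm at the top
    ax.set_theta_direction(-1)
    if rmax is not None:
        ax.set_rmax(rmax)
    if speed_bin_edges is not None:
        ax.legend(title="speed (mm/min)", fontsize=6, loc="lower left",
                  bbox_to_anchor=(1.0, 0.0))
    return ax


def plot_msd(msd_curves, labels=None, ax=None):
    """Log–log MSD curves."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    for i, c in enumerate(msd_curves):
        lbl = labels[i] if labels else c.component
        ax.loglog(c.lag_min, c.msd, label=lbl)
    ax.set_xlabel("lag (min)")
    ax.set_ylabel(r"MSD (mm$^2$)")
    ax.legend(fontsize=8)
    return ax


def plot_step_histogram(displacements, fits=None, n_bins=40, ax=None):
    """Step-length density histogram with fitted model curves overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    heights, edges, _ = ax.hist(displacements, bins=n_bins, density=True,
                                color="0.8", edgecolor="0.5")
    if fits:
        xg = np.linspace(edges[0], edges[-1], 300)
        for f in fits:
            if not f.converged:
                continue
            if f.model == "exponential":
                y = f["a"] * np.exp(-f["lambda"] * xg)
            elif f.model == "levy":
                y = levy_pdf(xg, f["c"], f["mu"])
            elif f.model == "powerlaw":
                with np.errstate(divide="ignore"):
                    y = f["a"] * np.power(np.maximum(xg, 1e-12), -f["k"])
            else:
                continue
            ax.plot(xg, y, label=f"{f.model} (r2={f.r2:0.3f})")
        ax.legend(fontsize=8)
    ax.set_xlabel("step length (mm)")
    ax.set_ylabel("density")
    return ax
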