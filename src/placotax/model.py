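"""Model/Results interface over the trajectory statistics.

Mirrors the fitted-model idiom of statistical packages: a
:class:`TrajectoryModel` is constructed from data (a trajectory plus trial
metadata, a CSV file, or a DataFrame), its :meth:`~TrajectoryModel.fit`
runs the full metric battery and returns a :class:`TrajectoryResults`
carrying the estimates, fit diagnostics and a ``summary()`` table.
:class:`CohortModel` does the same for a collection of trials and adds
group comparisons.

Example
-------
>>> from placotax import SyntheticSpec, simulate_trajectory, TrajectoryModel
>>> traj, meta = simulate_trajectory(SyntheticSpec(mode="biased_crw",
...     drift_bias=0.3, n_frames=1200, seed=7))
>>> res = TrajectoryModel(traj, meta).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .trajectory import (
    FitResult,
    PathMetrics,
    Trajectory,
    TrialMeta,
    read_trajectory_csv,
    read_trial_meta,
)
from . import kinematics as _kin
from . import trajstats as _ts
from . import complexity as _cx

__all__ = ["TrajectoryModel", "TrajectoryResults", "CohortModel", "CohortResults"]


class TrajectoryModel:
    """Per-trial analysis model for one centroid trajectory.

    Parameters
    ----------
    trajectory, meta
        The centroid series and its trial metadata (gradient axis,
        condition, arena geometry).
    """

    def __init__(self, trajectory: Trajectory, meta: TrialMeta):
        self.trajectory = trajectory
        self.meta = meta

    @classmethod
    def from_csv(cls, traj_path, meta_path=None, meta: TrialMeta | None = None,
                 dialect=None, mm_per_px=None) -> "TrajectoryModel":
        traj = read_trajectory_csv(traj_path, dialect=dialect, mm_per_px=mm_per_px)
        if meta is None:
            meta = read_trial_meta(meta_path) if meta_path else TrialMeta()
        return cls(traj, meta)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, meta: TrialMeta | None = None,
                       dt_min: float = 0.5) -> "TrajectoryModel":
        traj = Trajectory(
            frame=df["frame"].to_numpy(),
            x=df["x_mm"].to_numpy(dtype=float),
            y=df["y_mm"].to_numpy(dtype=float),
            area=df["area"].to_numpy(dtype=float) if "area" in df else None,
            perimeter=df["perimeter"].to_numpy(dtype=float) if "perimeter" in df else None,
            valid=df["valid"].to_numpy().astype(bool) if "valid" in df else None,
            dt_min=dt_min,
        ).recentred()
        return cls(traj, meta or TrialMeta())

    def fit(
        self,
        momentary_n: int = 2,
        msd_window_rule: str = "auto",
        msd_max_lag: int | None = _ts.DEFAULT_MAX_LAG,
        step_window_min: float = 2.0,
        persistence_L_max_mm: float = 20.0,
        persistence_L_step_mm: float = 1.0,
        complexity_series: str = "v_parallel",
        entropy_window_sizes: Sequence[int] = (1, 5, 10, 20, 40),
        entropy_levels: int = 10,
    ) -> "TrajectoryResults":
        """Run the metric battery; missing-data failures in individual
        statistics are recorded as ``None`` with a note rather than raised.

        ``msd_window_rule="auto"`` uses the standard 200-point end window
        when the trajectory is long enough (>= 211 frames) and the full
        series otherwise.
        """
        traj, meta = self.trajectory, self.meta
        notes: list[str] = []
        if msd_window_rule == "auto":
            need = _ts.END_WINDOW_POINTS + _ts.END_WINDOW_TRIM + 1
            msd_window_rule = "paper_end_window" if traj.n_frames >= need else "full"
            if msd_window_rule == "full":
                notes.append("trajectory shorter than the standard end window; "
                             "MSD computed on the full series")

        kin = _kin.momentary_velocities(traj, meta, n=momentary_n, overlapping=False)
        mean_v = _kin.mean_velocity_components(kin) if len(kin) else (np.nan,) * 3

        def _try(fn, label):
            try:
                return fn()
            except (ValueError, RuntimeError) as exc:
                notes.append(f"{label}: {exc}")
                return None

        msd_par = _try(lambda: _ts.msd_axis(traj, meta, "parallel", msd_window_rule),
                       "msd_parallel")
        msd_ort = _try(lambda: _ts.msd_axis(traj, meta, "orthogonal", msd_window_rule),
                       "msd_orthogonal")
        alpha_par = _try(lambda: _ts.loglog_slope(msd_par, max_lag=msd_max_lag),
                         "alpha_parallel") if msd_par is not None else None
        alpha_ort = _try(lambda: _ts.loglog_slope(msd_ort, max_lag=msd_max_lag),
                         "alpha_orthogonal") if msd_ort is not None else None
        taylor = ballistic = None
        if msd_par is not None:
            taylor = _try(lambda: _ts.fit_rmsd_taylor(msd_par.lag_min, msd_par.rmsd()),
                          "taylor_fit")
            ballistic = _try(
                lambda: _ts.fit_rmsd_ballistic(msd_par.lag_min, msd_par.rmsd()),
                "ballistic_fit")

        pm = _ts.path_metrics(traj, meta)
        persistence = _try(
            lambda: _ts.persistence_length_scan(
                traj, persistence_L_max_mm, persistence_L_step_mm),
            "persistence_scan")

        steps = _try(lambda: _kin.step_lengths(traj, meta, step_window_min),
                     "step_lengths")
        step_fits = best_step = None
        if steps is not None:
            got = _try(lambda: _ts.step_length_fits(steps), "step_length_fits")
            if got is not None:
                step_fits, best_step = got

        series = kin.v_parallel if complexity_series == "v_parallel" else kin.speed
        dfa = _try(lambda: _cx.dfa_exponent(series), "dfa")
        entropy = _try(
            lambda: _cx.windowed_entropy(
                series, [w for w in entropy_window_sizes if w <= len(series)],
                entropy_levels),
            "entropy")

        return TrajectoryResults(
            model=self,
            kinematics=kin,
            mean_v_parallel=float(mean_v[0]),
            mean_v_orthogonal=float(mean_v[1]),
            mean_speed=float(mean_v[2]),
            path_metrics=pm,
            msd_parallel=msd_par,
            msd_orthogonal=msd_ort,
            alpha_parallel=alpha_par,
            alpha_orthogonal=alpha_ort,
            taylor_fit=taylor,
            ballistic_fit=ballistic,
            persistence=persistence,
            step_lengths=steps,
            step_fits=step_fits,
            best_step_model=best_step,
            dfa=dfa,
            entropy=entropy,
            notes=notes,
        )


@dataclass
class TrajectoryResults:
    """Estimates and diagnostics from :meth:`TrajectoryModel.fit`."""

    model: TrajectoryModel
    kinematics: object
    mean_v_parallel: float
    mean_v_orthogonal: float
    mean_speed: float
    path_metrics: PathMetrics
    msd_parallel: object
    msd_orthogonal: object
    alpha_parallel: FitResult | None
    alpha_orthogonal: FitResult | None
    taylor_fit: FitResult | None
    ballistic_fit: FitResult | None
    persistence: tuple | None
    step_lengths: np.ndarray | None
    step_fits: list | None
    best_step_model: str | None
    dfa: FitResult | None
    entropy: dict | None
    notes: list = field(default_factory=list)

    def metrics_row(self) -> dict:
        """Flat per-trial metric record (one row of a cohort table)."""
        meta = self.model.meta
        pm = self.path_metrics
        row = {
            "trial_id": meta.trial_id,
            "condition": meta.condition,
            "grad_C_per_cm": meta.grad,
            "n_frames": self.model.trajectory.n_frames,
            "directionality": pm.directionality,
            "straightness": pm.straightness,
            "end_to_end_angle_deg": pm.end_to_end_angle_deg,
            "first_passage_min": pm.first_passage_min,
            "first_passage_censored": pm.first_passage_censored,
            "frac_time_warmer": pm.frac_time_warmer,
            "positive_thermotaxis": pm.positive_thermotaxis,
            "effective_thermotaxis": pm.effective_thermotaxis,
            "mean_v_parallel": self.mean_v_parallel,
            "mean_v_orthogonal": self.mean_v_orthogonal,
            "mean_speed": self.mean_speed,
            "alpha_parallel": self.alpha_parallel["alpha"] if self.alpha_parallel else np.nan,
            "alpha_orthogonal": self.alpha_orthogonal["alpha"] if self.alpha_orthogonal else np.nan,
            "taylor_v": self.taylor_fit["v"] if self.taylor_fit else np.nan,
            "taylor_tau": self.taylor_fit["tau"] if self.taylor_fit else np.nan,
            "taylor_r2": self.taylor_fit.r2 if self.taylor_fit else np.nan,
            "ballistic_v": self.ballistic_fit["v"] if self.ballistic_fit else np.nan,
            "ballistic_r2": self.ballistic_fit.r2 if self.ballistic_fit else np.nan,
            "Lp_max_mm": self.persistence[2]["Lp"] if self.persistence else np.nan,
            "L_at_max_Lp_mm": self.persistence[1] if self.persistence else np.nan,
            "best_step_model": self.best_step_model,
            "dfa_alpha": self.dfa["dfa_alpha"] if self.dfa else np.nan,
        }
        if self.step_fits:
            for f in self.step_fits:
                row[f"step_r2_{f.model}"] = f.r2
                if f.model == "exponential":
                    row["step_lambda_per_mm"] = f.params.get("lambda", np.nan)
        return row

    def summary(self) -> str:
        """Human-readable per-trial summary table."""
        meta = self.model.meta
        pm = self.path_metrics
        lines = []
        w = 74
        lines.append("=" * w)
        lines.append("Trajectory analysis summary".center(w))
        lines.append("=" * w)
        lines.append(f"trial: {meta.trial_id or '(unnamed)'}    condition: "
                     f"{meta.condition}    gradient: {meta.grad:g} degC/cm")
        lines.append(f"frames: {self.model.trajectory.n_frames}  "
                     f"({self.model.trajectory.n_frames * self.model.trajectory.dt_min:.0f} min "
                     f"at {self.model.trajectory.dt_min * 60:.0f} s/frame)")
        lines.append("-" * w)
        f3 = lambda v: "   nan" if v is None or not np.isfinite(v) else f"{v:8.4f}"
        lines.append(f"directionality index        {f3(pm.directionality)}"
                     f"    straightness index      {f3(pm.straightness)}")
        fp = "censored" if pm.first_passage_censored else f"{pm.first_passage_min:8.1f}"
        lines.append(f"end-to-end angle (deg)      {f3(pm.end_to_end_angle_deg)}"
                     f"    first passage 5 mm (min) {fp:>8}")
        lines.append(f"fraction of time warmer     {f3(pm.frac_time_warmer)}"
                     f"    positive / effective     "
                     f"{str(pm.positive_thermotaxis):>5} / {str(pm.effective_thermotaxis)}")
        lines.append(f"mean v_parallel (mm/min)    {f3(self.mean_v_parallel)}"
                     f"    mean v_orthogonal       {f3(self.mean_v_orthogonal)}")
        lines.append(f"mean momentary speed        {f3(self.mean_speed)}")
        lines.append("-" * w)
        if self.alpha_parallel:
            lines.append(f"MSD alpha parallel          {f3(self.alpha_parallel['alpha'])}"
                         f"    alpha orthogonal        "
                         f"{f3(self.alpha_orthogonal['alpha'] if self.alpha_orthogonal else np.nan)}")
        if self.taylor_fit:
            lines.append(f"crossover fit v (mm/min)    {f3(self.taylor_fit['v'])}"
                         f"    tau (min)               {f3(self.taylor_fit['tau'])}"
                         f"   r2 {self.taylor_fit.r2:6.4f}")
        if self.ballistic_fit:
            lines.append(f"ballistic fit v (mm/min)    {f3(self.ballistic_fit['v'])}"
                         f"    r2                      {f3(self.ballistic_fit.r2)}")
        if self.persistence:
            _, L_at_max, lpfit = self.persistence
            lines.append(f"persistence length Lp (mm)  {f3(lpfit['Lp'])}"
                         f"    at window L (mm)        {f3(L_at_max)}"
                         + ("   [diverged]" if not lpfit.converged else ""))
        if self.step_fits:
            r2s = "  ".join(f"{f.model} r2={f.r2:0.3f}" for f in self.step_fits)
            lines.append(f"step-length fits: {r2s}")
            lines.append(f"best step-length model: {self.best_step_model}")
        if self.dfa:
            lines.append(f"DFA exponent                {f3(self.dfa['dfa_alpha'])}")
        if self.entropy:
            ent = "  ".join(f"w={k}:{v:0.2f}" for k, v in sorted(self.entropy.items()))
            lines.append(f"entropy (bits) vs window:   {ent}")
        for note in self.notes:
            lines.append(f"note: {note}")
        lines.append("=" * w)
        return "\n".join(lines)


class CohortModel:
    """A collection of trials analysed together."""

    def __init__(self, trials: Sequence[tuple[Trajectory, TrialMeta]]):
        self.trials = list(trials)

    @classmethod
    def from_files(cls, pairs, dialect=None, mm_per_px=None) -> "CohortModel":
        """Build from ``(trajectory_csv, meta_yaml)`` path pairs."""
        trials = []
        for traj_path, meta_path in pairs:
            traj = read_trajectory_csv(traj_path, dialect=dialect, mm_per_px=mm_per_px)
            trials.append((traj, read_trial_meta(meta_path)))
        return cls(trials)

    @classmethod
    def from_synthetic(cls, n_trials, spec_gradient, spec_control,
                       base_seed=0) -> "CohortModel":
        from .synthetic import simulate_cohort

        return cls(simulate_cohort(n_trials, spec_gradient, spec_control, base_seed))

    def fit(self, **fit_kwargs) -> "CohortResults":
        results, failures = [], []
        for traj, meta in self.trials:
            try:
                results.append(TrajectoryModel(traj, meta).fit(**fit_kwargs))
            except Exception as exc:  # per-trial failure: record and continue
                failures.append((meta.trial_id, str(exc)))
        return CohortResults(model=self, trial_results=results, failures=failures)


@dataclass
class CohortResults:
    model: CohortModel
    trial_results: list[TrajectoryResults]
    failures: list

    @property
    def table(self) -> pd.DataFrame:
        """One row per trial, one column per statistic."""
        return pd.DataFrame([r.metrics_row() for r in self.trial_results])

    def compare(self, metric: str, group_a: str = "gradient",
                group_b: str = "control") -> dict:
        """Mann–Whitney comparison of one metric between two conditions."""
        t = self.table
        a = t.loc[t["condition"] == group_a, metric].dropna().to_numpy()
        b = t.loc[t["condition"] == group_b, metric].dropna().to_numpy()
        mw = _cx.mann_whitney(a, b)
        return {
            "metric": metric,
            "group_a": group_a,
            "group_b": group_b,
            "n_a": len(a),
            "n_b": len(b),
            "median_a": float(np.median(a)) if len(a) else np.nan,
            "median_b": float(np.median(b)) if len(b) else np.nan,
            "U": mw.U,
            "p": mw.p,
            "method": mw.method,
        }

    def comparison_table(self, metrics=("directionality", "mean_v_parallel",
                                        "mean_speed", "alpha_parallel",
                                        "alpha_orthogonal", "dfa_alpha")) -> pd.DataFrame:
        rows = []
        for m in metrics:
            try:
                rows.append(self.compare(m))
            except ValueError:
                continue
        return pd.DataFrame(rows)

    def summary(self) -> str:
        t = self.table
        lines = ["=" * 74, "Cohort summary".center(74), "=" * 74]
        for cond, sub in t.groupby("condition"):
            lines.append(
                f"{cond:>9}: n={len(sub):3d}  median directionality="
                f"{sub['directionality'].median():7.3f}  "
                f"median alpha_par={sub['alpha_parallel'].median():6.3f}  "
                f"effective={100 * sub['effective_thermotaxis'].mean():4.0f}%"
            )
        comp = self.comparison_table()
        if len(comp):
            lines.append("-" * 74)
            for _, r in comp.iterrows():
                lines.append(
                    f"{r['metric']:<18} median {r['median_a']:7.3f} vs "
                    f"{r['median_b']:7.3f}   U={r['U']:7.1f}  p={r['p']:.3g} "
                    f"({r['method']})"
                )
        if self.failures:
            lines.append(f"failures: {len(self.failures)}")
        lines.append("=" * 74)
        return "\n".join(lines)
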