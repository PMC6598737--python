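"""Differential equation model (DEM) of long-term biomarker trajectories.

The DEM reconstructs a decades-long average trajectory from short-term
longitudinal data in four steps, per biomarker:

1. fit a least-squares line per subject across their visits; the slope is
   that subject's rate of change and is paired with their average value;
2. regress slope on value with a Gaussian process (squared-exponential +
   observation noise) to get a smooth rate-of-change function du/dt = f(u)
   with a 95% band;
3. integrate dt/du = 1/f(u) from the upper integration limit downward,
   yielding value-as-a-function-of-time up to an arbitrary time origin;
4. anchor the time origin t0 at the biomarker threshold that best separates
   controls from patients and convert values to control-referenced z-scores
   so trajectories are comparable across biomarkers.

Subjects can then be staged continuously (years from t0) by least-squares
matching of their observed z-scores to the fitted trajectories, and
uncertainty is quantified by refitting on subject-level bootstrap resamples.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import ttest_ind, ttest_rel
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

__all__ = [
    "SlopePoint",
    "RateModel",
    "Trajectory",
    "SubjectStagePosition",
    "fit_subject_slopes",
    "fit_rate_model",
    "integrate_trajectory",
    "anchor_t0",
    "fit_dem",
    "stage_subjects_dem",
    "bootstrap_trajectories",
    "compare_trajectory_values",
]


@dataclass(frozen=True)
class SlopePoint:
    """One subject's rate of change paired with their average biomarker value."""

    subject_id: str
    mean_value: float
    slope: float
    n_visits: int
    follow_up_span: float


@dataclass
class RateModel:
    """GP posterior for du/dt as a function of biomarker value u."""

    grid: np.ndarray
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    hyperparameters: dict
    gp: GaussianProcessRegressor | None = None

    def rate(self, u) -> np.ndarray:
        return np.interp(np.asarray(u, dtype=float), self.grid, self.mean)


@dataclass
class Trajectory:
    """Biomarker value (and z-score, once anchored) versus years from t0."""

    time: np.ndarray
    value: np.ndarray
    value_low: float
    value_high: float
    z: np.ndarray | None = None
    t0_threshold: float | None = None
    meta: dict = field(default_factory=dict)

    def value_at(self, t) -> np.ndarray:
        """Interpolated value; clamps to the endpoints outside the grid."""
        return np.interp(np.asarray(t, dtype=float), self.time, self.value)

    def z_at(self, t, *, clamp: bool = True) -> np.ndarray:
        if self.z is None:
            raise ValueError("trajectory not anchored: no z-scores")
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.time, self.z)
        if not clamp:
            out = np.where((t < self.time[0]) | (t > self.time[-1]), np.nan, out)
        return out


@dataclass(frozen=True)
class SubjectStagePosition:
    """Continuous disease-time position for one subject."""

    subject_id: str
    stage_time: float
    residual: float


# ---------------------------------------------------------------------------
# Step 1: per-subject slopes

def fit_subject_slopes(table: pd.DataFrame, biomarker: str,
                       time_col: str = "years_since_baseline") -> list[SlopePoint]:
    """OLS line per subject; subjects with < 2 usable visits are excluded."""
    points = []
    excluded = 0
    for sid, grp in table.groupby("subject_id", sort=False):
        t = grp[time_col].to_numpy(float)
        y = grp[biomarker].to_numpy(float)
        ok = np.isfinite(t) & np.isfinite(y)
        t, y = t[ok], y[ok]
        if len(t) < 2 or np.ptp(t) == 0:
            excluded += 1
            continue
        slope = float(np.polyfit(t, y, 1)[0])
        points.append(SlopePoint(
            subject_id=str(sid), mean_value=float(y.mean()), slope=slope,
            n_visits=int(len(t)), follow_up_span=float(np.ptp(t)),
        ))
    if excluded:
        warnings.warn(f"{biomarker}: {excluded} subjects excluded (<2 usable visits)")
    return points


# ---------------------------------------------------------------------------
# Step 2: GP rate-of-change model

def fit_rate_model(slopes: Sequence[SlopePoint], grid_size: int = 200,
                   n_restarts: int = 5, random_state: int = 0) -> RateModel:
    """GP regression of rate of change on biomarker value.

    Squared-exponential kernel plus a white observation-noise term;
    hyperparameters by marginal-likelihood maximisation with restarts. The
    posterior mean and pointwise 95% band are evaluated on a uniform grid
    over the observed value range.
    """
    if len(slopes) < 5:
        raise ValueError("need at least 5 slope points")
    u = np.array([p.mean_value for p in slopes])
    y = np.array([p.slope for p in slopes])
    span = float(np.ptp(u))
    if span <= 0:
        raise ValueError("degenerate value range across slope points")

    y_scale = max(float(np.std(y)), 1e-8)
    # rate structure narrower than ~1/5 of the value range is indistinguishable
    # from subject-level slope noise here, so bound the length-scale away from
    # zero (also guards against interpolating duplicated bootstrap points)
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * RBF(length_scale=span / 3, length_scale_bounds=(span / 5, span * 10))
        + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-4, 1e3))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, n_restarts_optimizer=n_restarts,
        random_state=random_state, alpha=1e-10,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp.fit(u.reshape(-1, 1), y / y_scale)

    grid = np.linspace(u.min(), u.max(), grid_size)
    mean, sd = gp.predict(grid.reshape(-1, 1), return_std=True)
    mean, sd = mean * y_scale, sd * y_scale
    return RateModel(
        grid=grid, mean=mean, lo95=mean - 1.96 * sd, hi95=mean + 1.96 * sd,
        hyperparameters={"kernel": str(gp.kernel_),
                         "log_marginal_likelihood": float(gp.log_marginal_likelihood_value_)},
        gp=gp,
    )


# ---------------------------------------------------------------------------
# Step 3: trajectory reconstruction

def integrate_trajectory(model: RateModel, n_fine: int = 2000,
                         n_time: int = 500,
                         zero_tol_factor: float = 1e-3,
                         sign_tol_factor: float = 0.25) -> Trajectory:
    """Line-integrate the rate model into an (unanchored) trajectory.

    Solves dt/du = 1/f(u) from the upper integration limit downward on a
    fine value grid and inverts to value(t) on a uniform time grid. The
    integration limits are where the rate reaches zero (within the zero
    tolerance, ``zero_tol_factor`` x max|rate|) or the limits of the data;
    t = 0 at the upper limit is arbitrary until anchoring. Integration
    covers the contiguous segment around the dominant rate, so trajectories
    asymptote at fixed points of the dynamics. A substantial opposite-sign
    excursion (beyond ``sign_tol_factor`` x max|rate|) means the rate
    alternates between increasing and decreasing, which the method cannot
    integrate — an error naming the crossing value is raised; smaller
    opposite excursions are extrapolation noise beyond a zero crossing of
    the rate (a fixed point) and are truncated.
    """
    u = np.linspace(model.grid[0], model.grid[-1], n_fine)
    f = np.interp(u, model.grid, model.mean)
    fmax = float(np.abs(f).max())
    tol = zero_tol_factor * fmax
    if not np.any(np.abs(f) > tol):
        raise ValueError("rate model is zero everywhere within tolerance")

    peak = int(np.argmax(np.abs(f)))
    sign = float(np.sign(f[peak]))

    # maximal contiguous run of same-signed, above-tolerance rate around the
    # peak; outside it the dynamics are (numerically) at a fixed point
    active = f * sign > tol
    top = peak
    while top + 1 < n_fine and active[top + 1]:
        top += 1
    bottom = peak
    while bottom - 1 >= 0 and active[bottom - 1]:
        bottom -= 1

    opposite = f * sign < -sign_tol_factor * fmax
    if opposite.any():
        crossing = float(u[np.argmax(opposite)])
        if (u[top] - u[bottom]) < 0.6 * (u[-1] - u[0]):
            raise ValueError(
                f"rate changes sign in the interior near value {crossing:.6g}; "
                "trajectory integration requires a single-signed rate"
            )
        warnings.warn(
            f"rate attains the opposite sign near value {crossing:.4g}, beyond "
            "the integration limits; trajectory truncated at the zero crossing"
        )
    u_seg = u[bottom: top + 1][::-1]              # descending from upper limit
    f_seg = np.interp(u_seg, model.grid, model.mean)
    t_seg = cumulative_trapezoid(1.0 / f_seg, u_seg, initial=0.0)

    order = np.argsort(t_seg)
    t_sorted, u_sorted = t_seg[order], u_seg[order]
    t_grid = np.linspace(t_sorted[0], t_sorted[-1], n_time)
    value = np.interp(t_grid, t_sorted, u_sorted)
    return Trajectory(
        time=t_grid, value=value,
        value_low=float(u_seg.min()), value_high=float(u_seg.max()),
        meta={"rate_sign": sign, "zero_tolerance": tol},
    )


# ---------------------------------------------------------------------------
# Step 4: anchoring

def anchor_t0(traj: Trajectory, control_values, patient_values) -> Trajectory:
    """Anchor the time origin at the control/patient separating threshold.

    Candidate thresholds are midpoints of the sorted pooled values; the one
    maximising classification accuracy (patients on the abnormal side) wins,
    with ties broken by the median of the maximisers (warned). The time axis
    is shifted so value(0) equals the threshold, and values are converted to
    z-scores with respect to the control sample. Shape is untouched: value
    differences between any two times are unchanged.
    """
    ctl = np.asarray(control_values, dtype=float)
    pat = np.asarray(patient_values, dtype=float)
    ctl, pat = ctl[np.isfinite(ctl)], pat[np.isfinite(pat)]
    if len(ctl) == 0 or len(pat) == 0:
        raise ValueError("both control and patient samples must be non-empty")

    patient_low = np.median(pat) < np.median(ctl)
    pooled = np.sort(np.concatenate([ctl, pat]))
    candidates = (pooled[:-1] + pooled[1:]) / 2.0

    def accuracy(thr: np.ndarray) -> np.ndarray:
        thr = thr[:, None]
        if patient_low:
            correct = (ctl[None, :] >= thr).sum(axis=1) + (pat[None, :] < thr[:, 0:1]).sum(axis=1)
        else:
            correct = (ctl[None, :] <= thr).sum(axis=1) + (pat[None, :] > thr[:, 0:1]).sum(axis=1)
        return correct / (len(ctl) + len(pat))

    acc = accuracy(candidates)
    best = acc.max()
    maximisers = candidates[acc >= best - 1e-12]
    if len(maximisers) > 1 and best < 0.75:
        warnings.warn("multiple equal-accuracy thresholds; using their median")
    threshold = float(np.median(maximisers))

    # locate t* with value(t*) = threshold on the monotone trajectory
    v = traj.value
    increasing = v[-1] >= v[0]
    thr_clamped = float(np.clip(threshold, v.min(), v.max()))
    if increasing:
        t_star = float(np.interp(thr_clamped, v, traj.time))
    else:
        t_star = float(np.interp(thr_clamped, v[::-1], traj.time[::-1]))

    mu, sd = float(ctl.mean()), float(ctl.std(ddof=1))
    if not sd > 0:
        raise ValueError("control sample has zero spread")
    return Trajectory(
        time=traj.time - t_star, value=traj.value,
        value_low=traj.value_low, value_high=traj.value_high,
        z=(traj.value - mu) / sd, t0_threshold=threshold,
        meta={**traj.meta, "t0_accuracy": float(best),
              "control_mean": mu, "control_sd": sd},
    )


def fit_dem(table: pd.DataFrame, biomarker: str, *,
            time_col: str = "years_since_baseline",
            grid_size: int = 200, n_restarts: int = 5,
            random_state: int = 0) -> Trajectory:
    """Full DEM for one biomarker: slopes → GP rate model → integration →
    t0 anchoring (controls vs patients at baseline)."""
    slopes = fit_subject_slopes(table, biomarker, time_col=time_col)
    model = fit_rate_model(slopes, grid_size=grid_size, n_restarts=n_restarts,
                           random_state=random_state)
    traj = integrate_trajectory(model)
    base = table[table["visit_index"] == 0] if "visit_index" in table.columns else table
    ctl = base.loc[base["group"] == "control", biomarker].to_numpy(float)
    pat = base.loc[base["group"] != "control", biomarker].to_numpy(float)
    return anchor_t0(traj, ctl, pat)


# ---------------------------------------------------------------------------
# Staging

def stage_subjects_dem(trajectories: Mapping[str, Trajectory],
                       subject_z: pd.DataFrame,
                       n_grid: int = 600) -> list[SubjectStagePosition]:
    """Stage subjects along the common disease timeline.

    ``subject_z`` has one row per subject (index = subject id) and one
    column per biomarker, holding control-referenced z-scores. The stage is
    the time minimising the summed squared difference between observed
    z-scores and each anchored trajectory's z(t), over non-missing
    biomarkers, with trajectories clamped at their endpoints (subjects
    beyond a trajectory's support are staged at the boundary).
    """
    if not trajectories:
        raise ValueError("at least one anchored trajectory required")
    t_lo = min(tr.time[0] for tr in trajectories.values())
    t_hi = max(tr.time[-1] for tr in trajectories.values())
    grid = np.linspace(t_lo, t_hi, n_grid)
    curves = {b: tr.z_at(grid) for b, tr in trajectories.items()}

    out = []
    for sid, row in subject_z.iterrows():
        sq = np.zeros_like(grid)
        n_used = 0
        for b, curve in curves.items():
            val = row.get(b, np.nan)
            if pd.notna(val):
                sq += (curve - float(val)) ** 2
                n_used += 1
        if n_used == 0:
            warnings.warn(f"subject {sid}: all biomarkers missing, skipped")
            continue
        k = int(np.argmin(sq))
        out.append(SubjectStagePosition(subject_id=str(sid),
                                        stage_time=float(grid[k]),
                                        residual=float(sq[k])))
    return out


# ---------------------------------------------------------------------------
# Bootstrap and comparisons

def bootstrap_trajectories(table: pd.DataFrame, biomarker: str,
                           n_boot: int = 100, seed: int = 0,
                           **fit_kwargs) -> list[Trajectory]:
    """DEM refits on subject-level bootstrap resamples (with replacement,
    stratified by group). Replicates whose integration fails are dropped and
    counted; more than 50% failures is an error."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = table.drop_duplicates("subject_id")[["subject_id", "group"]]
    by_group = {g: grp["subject_id"].to_numpy() for g, grp in subjects.groupby("group")}
    indexed = table.set_index("subject_id")
    ensemble = []
    failures = 0
    for b in range(n_boot):
        ids = np.concatenate([rng.choice(v, size=len(v), replace=True)
                              for v in by_group.values()])
        boot = indexed.loc[ids]
        # resampled duplicates must stage as distinct subjects
        boot = boot.reset_index()
        boot["subject_id"] = boot["subject_id"] + "_" + boot.groupby(
            ["subject_id", "visit_index"]).cumcount().astype(str)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ensemble.append(fit_dem(boot, biomarker, **fit_kwargs))
        except ValueError:
            failures += 1
    if failures > n_boot / 2:
        raise ValueError(f"{failures}/{n_boot} bootstrap replicates failed")
    if failures:
        warnings.warn(f"{biomarker}: {failures}/{n_boot} bootstrap replicates failed")
    return ensemble


def _ensemble_values(ensemble: Sequence[Trajectory], t: float) -> np.ndarray:
    """Replicate z-values at time t; NaN where t is outside a replicate's support."""
    return np.array([tr.z_at(t, clamp=False) for tr in ensemble], dtype=float)


def compare_trajectory_values(ensembles_by_group: Mapping[str, Mapping[str, Sequence[Trajectory]]],
                              times: Sequence[float] = (-10.0, 0.0, 10.0),
                              alpha: float = 0.05) -> pd.DataFrame:
    """t-tests on trajectory values at fixed times from t0, across bootstrap
    replicates.

    Within-group: paired t-tests between all biomarker pairs at each time.
    Between-group: two-sample t-tests per biomarker at each time (first two
    groups). A single Bonferroni-corrected threshold over all evaluable
    tests is reported in the ``corrected_threshold`` column; comparisons at
    times outside a trajectory's support are marked not evaluable.
    """
    rows = []
    for group, ensembles in ensembles_by_group.items():
        for (bi, ei), (bj, ej) in itertools.combinations(ensembles.items(), 2):
            n = min(len(ei), len(ej))
            for t in times:
                xi, xj = _ensemble_values(ei[:n], t), _ensemble_values(ej[:n], t)
                ok = np.isfinite(xi) & np.isfinite(xj)
                if ok.sum() < 3 or np.allclose(xi[ok] - xj[ok], (xi[ok] - xj[ok])[0]):
                    rows.append(dict(family="within", group=group, biomarker_i=bi,
                                     biomarker_j=bj, time=t, statistic=np.nan,
                                     p=np.nan, evaluable=False))
                    continue
                stat, p = ttest_rel(xi[ok], xj[ok])
                rows.append(dict(family="within", group=group, biomarker_i=bi,
                                 biomarker_j=bj, time=t, statistic=float(stat),
                                 p=float(p), evaluable=True))
    groups = list(ensembles_by_group)
    if len(groups) >= 2:
        ga, gb = groups[0], groups[1]
        shared = [b for b in ensembles_by_group[ga] if b in ensembles_by_group[gb]]
        for b in shared:
            for t in times:
                xa = _ensemble_values(ensembles_by_group[ga][b], t)
                xb = _ensemble_values(ensembles_by_group[gb][b], t)
                xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
                if len(xa) < 3 or len(xb) < 3 or (np.ptp(xa) == 0 and np.ptp(xb) == 0):
                    rows.append(dict(family="between", group=f"{ga}|{gb}",
                                     biomarker_i=b, biomarker_j=None, time=t,
                                     statistic=np.nan, p=np.nan, evaluable=False))
                    continue
                stat, p = ttest_ind(xa, xb)
                rows.append(dict(family="between", group=f"{ga}|{gb}",
                                 biomarker_i=b, biomarker_j=None, time=t,
                                 statistic=float(stat), p=float(p), evaluable=True))
    out = pd.DataFrame(rows)
    m = int(out["evaluable"].sum())
    out["corrected_threshold"] = alpha / max(m, 1)
    out["significant"] = out["evaluable"] & (out["p"] < out["corrected_threshold"])
    return out
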