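"""Preprocessing of longitudinal biomarker tables.

Covers the steps between a raw per-region visit table and model-ready
biomarkers: general-linear-model covariate adjustment (TIV, age, gender,
scanner, site, with one-hot encoded categoricals), bilateral averaging and
region-of-interest aggregation, z-scoring relative to controls, a common
abnormality orientation, and the floor-score discontinuation rule for
longitudinal cognitive series.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RoiMapping",
    "ControlReference",
    "adjust_covariates",
    "aggregate_rois",
    "zscore_to_controls",
    "orient_abnormality",
    "apply_floor_rule",
    "apply_floor_rule_table",
    "default_roi_mapping",
    "ID_COLUMNS",
]

# columns that are never treated as biomarkers
ID_COLUMNS = ("subject_id", "group", "visit_index", "years_since_baseline",
              "age", "gender", "tiv", "scanner", "site")


@dataclass
class RoiMapping:
    """Assignment of (bilateral) regions to composite ROI groups.

    Input tables may carry hemispheric columns (``{left_prefix}{region}`` /
    ``{right_prefix}{region}``) which are averaged before grouping, or
    already-bilateral columns named ``region``. Every retained region maps
    to exactly one ROI group; regions in ``drop`` are discarded.
    """

    roi_groups: Mapping[str, Sequence[str]]
    drop: Sequence[str] = field(default_factory=list)
    left_prefix: str = "Left "
    right_prefix: str = "Right "

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for roi, regions in self.roi_groups.items():
            for r in regions:
                if r in seen:
                    raise ValueError(
                        f"region {r!r} assigned to both {seen[r]!r} and {roi!r}"
                    )
                seen[r] = roi

    @property
    def regions(self) -> list[str]:
        return [r for regions in self.roi_groups.values() for r in regions]

    @classmethod
    def from_file(cls, path) -> "RoiMapping":
        with open(path) as fh:
            raw = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
        raw.pop("description", None)
        return cls(**raw)


def default_roi_mapping() -> RoiMapping:
    """The packaged 46-region → 8-ROI default mapping.

    A synthetic reconstruction of a Neuromorphometrics-style grouping into
    whole-brain, hippocampal, occipital, frontal, entorhinal, temporal,
    parietal and ventricle composites (see the data file's description).
    """
    ref = resources.files("progmod.data") / "roi_mapping_46to8_synthetic.json"
    raw = json.loads(ref.read_text())
    raw.pop("description", None)
    return RoiMapping(**raw)


@dataclass
class ControlReference:
    """Per-biomarker control mean/SD (post-adjustment) and abnormality direction."""

    means: Mapping[str, float]
    sds: Mapping[str, float]
    directions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for b, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"control SD for {b!r} must be > 0")

    @classmethod
    def from_controls(cls, table: pd.DataFrame, biomarkers: Sequence[str],
                      directions: Mapping[str, str] | None = None,
                      baseline_only: bool = True) -> "ControlReference":
        """Control mean/SD per biomarker, from baseline control visits by
        default (so multi-visit controls are not over-weighted)."""
        ctl = table[table["group"] == "control"]
        if baseline_only and "visit_index" in ctl.columns:
            ctl = ctl[ctl["visit_index"] == 0]
        means = {b: float(ctl[b].mean()) for b in biomarkers}
        sds = {b: float(ctl[b].std(ddof=1)) for b in biomarkers}
        return cls(means=means, sds=sds, directions=dict(directions or {}))


# ---------------------------------------------------------------------------
# Covariate adjustment

def _design_matrix(table: pd.DataFrame, covariate_names: Sequence[str]):
    """Intercept-free covariate design with one-hot categoricals (first level
    as reference). Returns (matrix DataFrame, column names)."""
    parts = []
    for cov in covariate_names:
        if cov not in table.columns:
            raise KeyError(f"covariate column {cov!r} missing from table")
        col = table[cov]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype("category"), prefix=cov,
                                     drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float).to_frame(cov))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=table.index)
    return X


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns beyond the numerical rank, identified by pivoted QR."""
    from scipy.linalg import qr
    _, r, piv = qr(X, pivoting=True, mode="economic")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def adjust_covariates(table: pd.DataFrame,
                      covariate_names: Sequence[str] = ("tiv", "age", "gender",
                                                        "scanner", "site"),
                      biomarkers: Sequence[str] | None = None,
                      reference: str = "controls_only") -> pd.DataFrame:
    """Remove linear covariate effects from biomarker columns.

    Fits, per biomarker, an ordinary-least-squares model of value on the
    covariates (categoricals one-hot encoded with the first level as
    reference) and returns ``value - fitted covariate contribution``; the
    intercept is retained so adjusted values stay on the native scale. With
    ``reference="controls_only"`` (default) coefficients are estimated on
    control rows only and applied to everyone, so disease effects correlated
    with age are not regressed out; ``reference="all"`` fits on the full
    table. Rows with missing covariates are excluded from fitting but kept
    (unadjusted covariate contribution subtracted where computable).
    """
    if reference not in ("controls_only", "all"):
        raise ValueError("reference must be 'controls_only' or 'all'")
    if biomarkers is None:
        biomarkers = [c for c in table.columns if c not in ID_COLUMNS]

    X_all = _design_matrix(table, covariate_names)
    fit_rows = (table["group"] == "control") if reference == "controls_only" \
        else pd.Series(True, index=table.index)
    fit_rows &= X_all.notna().all(axis=1)
    if fit_rows.sum() < X_all.shape[1] + 1:
        raise ValueError("not enough complete reference rows to fit the covariate model")

    # unseen category: a dummy column that is all-zero on the reference rows
    # but nonzero elsewhere cannot be estimated
    Xf = X_all[fit_rows]
    unseen = [c for c in X_all.columns
              if Xf[c].abs().sum() == 0 and X_all[c].abs().sum() > 0]
    if unseen:
        raise ValueError(f"categories unseen in the reference sample: {unseen}")

    design = np.column_stack([np.ones(int(fit_rows.sum())), Xf.to_numpy(float)])
    names = ["intercept", *X_all.columns]
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")

    out = table.copy()
    apply_ok = X_all.notna().all(axis=1)
    # centre at reference means so subtracting the contribution keeps values
    # on the native scale (intercept retained)
    centre = Xf.to_numpy(float).mean(axis=0)
    X_apply = X_all[apply_ok].to_numpy(float) - centre
    for b in biomarkers:
        y = table.loc[fit_rows, b].to_numpy(float)
        ok = np.isfinite(y)
        beta, *_ = np.linalg.lstsq(design[ok], y[ok], rcond=None)
        contribution = X_apply @ beta[1:]
        out.loc[apply_ok, b] = table.loc[apply_ok, b].to_numpy(float) - contribution
    return out


# ---------------------------------------------------------------------------
# ROI aggregation

def aggregate_rois(region_table: pd.DataFrame, mapping: RoiMapping) -> pd.DataFrame:
    """Average regions into composite ROIs.

    Left/right hemispheric columns are averaged first; each ROI value is the
    unweighted mean of its constituent bilateral regions. Non-region columns
    (IDs, covariates) are passed through. Missing region columns raise,
    naming the absent regions.
    """
    cols = set(region_table.columns)
    bilateral: dict[str, np.ndarray] = {}
    missing = []
    for region in mapping.regions:
        left = mapping.left_prefix + region
        right = mapping.right_prefix + region
        if left in cols and right in cols:
            bilateral[region] = (region_table[left].to_numpy(float)
                                 + region_table[right].to_numpy(float)) / 2.0
        elif region in cols:
            bilateral[region] = region_table[region].to_numpy(float)
        else:
            missing.append(region)
    if missing:
        raise KeyError(f"missing region columns: {missing}")

    region_cols = {mapping.left_prefix + r for r in mapping.regions} \
        | {mapping.right_prefix + r for r in mapping.regions} \
        | set(mapping.regions) | set(mapping.drop) \
        | {mapping.left_prefix + r for r in mapping.drop} \
        | {mapping.right_prefix + r for r in mapping.drop}
    passthrough = [c for c in region_table.columns if c not in region_cols]
    out = region_table[passthrough].copy()
    for roi, regions in mapping.roi_groups.items():
        out[roi] = np.mean([bilateral[r] for r in regions], axis=0)
    return out


# ---------------------------------------------------------------------------
# z-scores and orientation

def zscore_to_controls(table: pd.DataFrame, reference: ControlReference,
                       biomarkers: Sequence[str] | None = None) -> pd.DataFrame:
    """z = (value - control mean) / control SD, per biomarker."""
    if biomarkers is None:
        biomarkers = list(reference.means)
    out = table.copy()
    for b in biomarkers:
        sd = reference.sds[b]
        if not sd > 0:
            raise ValueError(f"control SD for {b!r} is zero")
        out[b] = (table[b].astype(float) - reference.means[b]) / sd
    return out


def orient_abnormality(table: pd.DataFrame, directions: Mapping[str, str],
                       biomarkers: Sequence[str] | None = None) -> pd.DataFrame:
    """Flip increasing-abnormal biomarkers so abnormality is always a decrease.

    Returns a copy whose ``attrs["oriented"]`` records the flipped columns;
    applying the operation twice restores the original values.
    """
    if biomarkers is None:
        biomarkers = [c for c in table.columns if c not in ID_COLUMNS]
    undeclared = [b for b in biomarkers if b not in directions]
    if undeclared:
        raise KeyError(f"no abnormality direction declared for: {undeclared}")
    out = table.copy()
    flipped = []
    for b in biomarkers:
        if directions[b] == "increasing":
            out[b] = -table[b].astype(float)
            flipped.append(b)
        elif directions[b] != "decreasing":
            raise ValueError(f"unknown direction {directions[b]!r} for {b!r}")
    out.attrs["oriented"] = flipped
    return out


# ---------------------------------------------------------------------------
# Floor-score rule

def apply_floor_rule(series, floor_value: float):
    """Discontinuation handling for one subject's longitudinal test scores.

    After the first visit at floor, the next visit is assigned the floor
    score (whatever was recorded) and all later visits become missing.
    The series must be time-ordered; existing missing values are preserved.
    """
    index = series.index if isinstance(series, pd.Series) else None
    values = list(pd.Series(series, dtype=float))
    for i, v in enumerate(values):
        if pd.notna(v) and v <= floor_value:
            if i + 1 < len(values):
                values[i + 1] = floor_value
            for j in range(i + 2, len(values)):
                values[j] = np.nan
            break
    return pd.Series(values, index=index)


def apply_floor_rule_table(table: pd.DataFrame, floors: Mapping[str, float],
                           time_col: str = "years_since_baseline") -> pd.DataFrame:
    """Apply :func:`apply_floor_rule` per subject and per floored test."""
    out = table.sort_values(["subject_id", time_col]).copy()
    for test, floor in floors.items():
        if test not in out.columns:
            warnings.warn(f"floored test {test!r} not in table; skipped")
            continue
        out[test] = out.groupby("subject_id", group_keys=False)[test].apply(
            lambda s: apply_floor_rule(s, floor)
        )
    return out.sort_index()
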