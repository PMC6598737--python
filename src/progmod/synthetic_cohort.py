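"""Synthetic longitudinal cohorts with known progression ground truth.

Generates visit tables that emulate a multi-centre neurodegeneration study:
two patient groups whose regional brain volumes (and optionally cognitive
scores) become abnormal in group-specific orders, plus a healthy control
group. Each biomarker follows a sigmoid transition from a healthy plateau to
an abnormal plateau over a latent disease-time axis; subjects are observed at
annual visits with dropout, additive covariate effects (age, gender, TIV,
scanner, site) and Gaussian measurement noise. Cognitive scores may be
floor-censored. The generator records full ground truth (per-group event
ordering, per-visit latent times, noise-free values) so that trajectory and
ordering recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .kde_ebm import EventSequence

__all__ = [
    "BiomarkerSpec",
    "CohortConfig",
    "GroundTruth",
    "sigmoid_value",
    "generate_cohort",
    "ground_truth_ordering",
    "default_roi_specs",
    "default_cognitive_specs",
    "default_two_group_config",
    "trajectory_recovery_rmse",
    "write_cohort_csv",
    "write_ground_truth_json",
    "config_from_yaml",
]

CONTROL_GROUP = "control"


@dataclass(frozen=True)
class BiomarkerSpec:
    """Latent sigmoid trajectory for one biomarker.

    The noise-free value is ``healthy_mean + abnormal_shift * logistic((t -
    onset_time) / (transition_duration / 6))`` so that ~95% of the transition
    happens within ``transition_duration`` years around ``onset_time``.

    ``direction`` is "decreasing" for quantities that shrink with disease
    (volumes, correct-response scores) and "increasing" for quantities that
    grow (ventricles, timed scores); ``abnormal_shift`` must carry the
    matching sign. ``floor_value``, if given, is the minimum attainable value
    (cognitive scores only) and observed values are clipped there.
    """

    name: str
    direction: str = "decreasing"
    onset_time: float = 0.0
    transition_duration: float = 8.0
    healthy_mean: float = 100.0
    healthy_sd: float = 10.0
    abnormal_shift: float = -40.0
    noise_sd: float = 3.0
    floor_value: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("decreasing", "increasing"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.transition_duration <= 0:
            raise ValueError("transition_duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.healthy_sd <= 0:
            raise ValueError("healthy_sd must be > 0")
        sign = -1.0 if self.direction == "decreasing" else 1.0
        if self.abnormal_shift * sign <= 0:
            raise ValueError(
                f"abnormal_shift sign inconsistent with direction for {self.name!r}"
            )


def sigmoid_value(t, spec: BiomarkerSpec):
    """Noise-free biomarker value at latent disease time ``t`` (years).

    Monotone in ``t`` and bounded between ``healthy_mean`` and
    ``healthy_mean + abnormal_shift``; equals the midpoint at
    ``t = onset_time``.
    """
    scale = spec.transition_duration / 6.0
    return spec.healthy_mean + spec.abnormal_shift * expit(
        (np.asarray(t, dtype=float) - spec.onset_time) / scale
    )


# Covariate effect sizes are expressed in units of each biomarker's healthy SD
# (continuous covariates are standardised internally), so one set of
# coefficients applies across biomarkers on different native scales.
DEFAULT_COVARIATE_EFFECTS: dict[str, float | dict[str, float]] = {
    "age": -0.02,          # SD per year of age beyond the cohort centre
    "tiv": 0.3,            # SD per SD of total intracranial volume
    "gender": {"F": -0.1},
    "scanner": {"3T": 0.2},
    "site": {"site2": 0.15, "site3": -0.15},
}

_AGE_CENTER, _AGE_SD = 64.0, 7.0
_TIV_CENTER, _TIV_SD = 1400.0, 130.0


@dataclass
class CohortConfig:
    """Design of a synthetic two-arm longitudinal study.

    ``biomarkers`` maps each patient-group label to its list of
    :class:`BiomarkerSpec`; groups share biomarker names and healthy
    parameters but differ in onset times, which defines the ground-truth
    orderings. Patients' baseline latent times are uniform over
    ``latent_time_range`` (so the cross-section spans the disease course);
    controls sit at a fixed pre-onset latent time. Visits are
    ``visit_interval`` years apart, up to ``max_visits``, with independent
    per-visit dropout (or an explicit ``visits_distribution`` over
    1..max_visits).
    """

    biomarkers: Mapping[str, Sequence[BiomarkerSpec]]
    n_controls: int = 115
    n_patients_per_group: int | Mapping[str, int] = 90
    max_visits: int = 6
    visit_interval: float = 1.0
    dropout_prob_per_visit: float = 0.4
    visits_distribution: Sequence[float] | None = None
    covariate_effects: Mapping[str, float | Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    latent_time_range: tuple[float, float] = (-8.0, 12.0)
    control_latent_time: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.biomarkers:
            raise ValueError("at least one patient group with biomarkers required")
        names = None
        for group, specs in self.biomarkers.items():
            if group == CONTROL_GROUP:
                raise ValueError("'control' is reserved for the control group")
            these = [s.name for s in specs]
            if len(set(these)) != len(these):
                raise ValueError(f"duplicate biomarker names in group {group!r}")
            if names is None:
                names = these
            elif set(these) != set(names):
                raise ValueError("all groups must share the same biomarker names")
        if self.n_controls < 0:
            raise ValueError("n_controls must be >= 0")
        for n in self._group_sizes().values():
            if n < 0:
                raise ValueError("n_patients_per_group must be >= 0")
        if not (0.0 <= self.dropout_prob_per_visit <= 1.0):
            raise ValueError("dropout_prob_per_visit must be in [0, 1]")
        if self.visits_distribution is not None:
            p = np.asarray(self.visits_distribution, dtype=float)
            if len(p) != self.max_visits or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError(
                    "visits_distribution must be a probability vector over 1..max_visits"
                )
        lo, hi = self.latent_time_range
        if not hi > lo:
            raise ValueError("latent_time_range must be increasing")

    def _group_sizes(self) -> dict[str, int]:
        if isinstance(self.n_patients_per_group, Mapping):
            return dict(self.n_patients_per_group)
        return {g: int(self.n_patients_per_group) for g in self.biomarkers}

    @property
    def biomarker_names(self) -> list[str]:
        first = next(iter(self.biomarkers.values()))
        return [s.name for s in first]

    def spec_for(self, group: str, biomarker: str) -> BiomarkerSpec:
        for s in self.biomarkers[group]:
            if s.name == biomarker:
                return s
        raise KeyError(biomarker)


@dataclass
class GroundTruth:
    """Oracle record of everything the generator knows.

    ``orderings`` holds the true event sequence per patient group;
    ``table`` mirrors the observed cohort table but carries the latent
    disease time of each visit and the noise-free, covariate-free biomarker
    values.
    """

    orderings: dict[str, EventSequence]
    table: pd.DataFrame

    def latent_times(self, subject_id: str) -> np.ndarray:
        rows = self.table[self.table["subject_id"] == subject_id]
        return rows["latent_time"].to_numpy()

    def to_json(self, path) -> None:
        payload = {
            "orderings": {
                g: {"events": list(seq.events), "ties": [list(t) for t in seq.ties]}
                for g, seq in self.orderings.items()
            },
            "table": self.table.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _pre_onset_time(config: CohortConfig) -> float:
    """A latent time safely before every biomarker's transition."""
    onset = min(s.onset_time for specs in config.biomarkers.values() for s in specs)
    dur = max(s.transition_duration for specs in config.biomarkers.values() for s in specs)
    return onset - dur


def _covariate_contribution_sd(cov_effects, age, gender, tiv, scanner, site) -> float:
    """Total covariate effect in healthy-SD units for one visit."""
    total = 0.0
    for name, eff in cov_effects.items():
        if name == "age":
            total += float(eff) * (age - _AGE_CENTER)
        elif name == "tiv":
            total += float(eff) * (tiv - _TIV_CENTER) / _TIV_SD
        elif isinstance(eff, Mapping):
            level = {"gender": gender, "scanner": scanner, "site": site}.get(name)
            total += float(eff.get(level, 0.0))
        else:
            raise ValueError(f"unknown continuous covariate {name!r}")
    return total


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one cohort; returns the observed visit table and its ground truth.

    Identical configs (including seed) yield byte-identical tables. With
    ``noise_sd = 0`` and zero covariate effects the observed values equal
    :func:`sigmoid_value` exactly (up to floor clipping).
    """
    rng = np.random.default_rng(config.seed)
    names = config.biomarker_names
    control_time = (
        config.control_latent_time
        if config.control_latent_time is not None
        else _pre_onset_time(config)
    )
    # control biomarkers use healthy parameters; onset identical across groups
    control_specs = {s.name: s for s in next(iter(config.biomarkers.values()))}

    rows: list[dict] = []
    truth_rows: list[dict] = []

    def n_visits_for_subject() -> int:
        if config.visits_distribution is not None:
            return int(rng.choice(np.arange(1, config.max_visits + 1),
                                  p=np.asarray(config.visits_distribution, dtype=float)))
        n = 1
        while n < config.max_visits and rng.random() >= config.dropout_prob_per_visit:
            n += 1
        return n

    def emit_subject(sid: str, group: str, baseline_latent: float,
                     specs: Mapping[str, BiomarkerSpec]) -> None:
        age0 = float(np.clip(rng.normal(_AGE_CENTER, _AGE_SD), 40.0, 90.0))
        gender = "M" if rng.random() < 0.5 else "F"
        tiv = float(rng.normal(_TIV_CENTER, _TIV_SD))
        scanner = "3T" if rng.random() < 0.5 else "1.5T"
        site = str(rng.choice(["site1", "site2", "site3"], p=[0.7, 0.15, 0.15]))
        for v in range(n_visits_for_subject()):
            years = v * config.visit_interval
            latent = baseline_latent + years
            row = {
                "subject_id": sid, "group": group, "visit_index": v,
                "years_since_baseline": years, "age": age0 + years,
                "gender": gender, "tiv": tiv, "scanner": scanner, "site": site,
            }
            truth = dict(row)
            truth["latent_time"] = latent
            cov_sd = _covariate_contribution_sd(
                config.covariate_effects, age0 + years, gender, tiv, scanner, site
            )
            for name in names:
                spec = specs[name]
                clean = float(sigmoid_value(latent, spec))
                observed = clean + cov_sd * spec.healthy_sd
                if spec.noise_sd > 0:
                    observed += rng.normal(0.0, spec.noise_sd)
                if spec.floor_value is not None:
                    observed = max(observed, spec.floor_value)
                row[name] = observed
                truth[name] = clean
            rows.append(row)
            truth_rows.append(truth)

    for i in range(config.n_controls):
        emit_subject(f"C{i:04d}", CONTROL_GROUP, control_time, control_specs)
    lo, hi = config.latent_time_range
    for gi, (group, specs) in enumerate(config.biomarkers.items()):
        spec_map = {s.name: s for s in specs}
        n = config._group_sizes()[group]
        for i in range(n):
            baseline = float(rng.uniform(lo, hi))
            emit_subject(f"{chr(ord('A') + gi)}{i:04d}", group, baseline, spec_map)

    table = pd.DataFrame(rows)
    truth_table = pd.DataFrame(truth_rows)
    orderings = {
        group: _ordering_from_specs(specs) for group, specs in config.biomarkers.items()
    }
    return table, GroundTruth(orderings=orderings, table=truth_table)


def _ordering_from_specs(specs: Sequence[BiomarkerSpec]) -> EventSequence:
    onsets = [(s.onset_time, s.name) for s in specs]
    ordered = sorted(onsets, key=lambda p: (p[0], p[1]))
    ties = tuple(
        (a[1], b[1]) for a, b in zip(ordered, ordered[1:]) if a[0] == b[0]
    )
    return EventSequence(events=tuple(name for _, name in ordered), ties=ties)


def ground_truth_ordering(truth: GroundTruth, group: str) -> EventSequence:
    """True abnormality ordering for one patient group (ties flagged)."""
    if group not in truth.orderings:
        raise KeyError(f"unknown group {group!r}")
    return truth.orderings[group]


# ---------------------------------------------------------------------------
# Default study designs

def default_roi_specs(group: str) -> list[BiomarkerSpec]:
    """Eight-ROI volume design for a posterior-first ('groupA') or
    medial-temporal-first ('groupB') patient group.

    Group A mimics a posterior cortical syndrome (occipital/parietal onset);
    group B an amnestic-predominant syndrome (hippocampal/entorhinal onset).
    Later events (temporal atrophy, ventricular expansion) are shared.
    """
    onsets = {
        "groupA": {"occipital": 0.0, "parietal": 1.0, "temporal": 3.0,
                   "ventricle": 4.0, "whole_brain": 5.0, "frontal": 6.5,
                   "entorhinal": 8.0, "hippocampal": 9.0},
        "groupB": {"hippocampal": 0.0, "entorhinal": 1.0, "temporal": 3.0,
                   "ventricle": 4.0, "whole_brain": 5.0, "frontal": 6.5,
                   "parietal": 8.0, "occipital": 9.0},
    }[group]
    scale = {   # (healthy_mean, healthy_sd, shift magnitude in SD units)
        "whole_brain": (1100.0, 90.0), "hippocampal": (3.4, 0.35),
        "occipital": (44.0, 4.5), "frontal": (150.0, 14.0),
        "entorhinal": (1.9, 0.2), "temporal": (95.0, 9.0),
        "parietal": (98.0, 9.5), "ventricle": (28.0, 11.0),
    }
    specs = []
    for name, onset in onsets.items():
        mean, sd = scale[name]
        direction = "increasing" if name == "ventricle" else "decreasing"
        shift = 4.0 * sd * (1.0 if direction == "increasing" else -1.0)
        specs.append(BiomarkerSpec(
            name=name, direction=direction, onset_time=onset,
            transition_duration=8.0, healthy_mean=mean, healthy_sd=sd,
            abnormal_shift=shift, noise_sd=0.35 * sd,
        ))
    return specs


def default_cognitive_specs(group: str) -> list[BiomarkerSpec]:
    """Floored cognitive-test design: visuospatial tests decline first in
    group A, working-memory tests first in group B."""
    onsets = {
        "groupA": {"a_cancellation": 0.0, "fragmented_letters": 1.0,
                   "dot_counting": 2.5, "digit_span_backwards": 4.0,
                   "mmse": 5.0, "verbal_memory": 7.0, "digit_span_forwards": 9.0},
        "groupB": {"digit_span_forwards": 0.0, "verbal_memory": 1.5,
                   "digit_span_backwards": 3.0, "mmse": 5.0,
                   "dot_counting": 7.0, "fragmented_letters": 8.0,
                   "a_cancellation": 9.0},
    }[group]
    scale = {
        "a_cancellation": (19.0, 1.2, 0.0), "fragmented_letters": (19.0, 1.5, 0.0),
        "dot_counting": (9.5, 0.8, 0.0), "digit_span_backwards": (7.0, 1.8, 0.0),
        "mmse": (29.0, 1.0, 0.0), "verbal_memory": (24.0, 3.5, 0.0),
        "digit_span_forwards": (8.5, 1.4, 0.0),
    }
    specs = []
    for name, onset in onsets.items():
        mean, sd, floor = scale[name]
        specs.append(BiomarkerSpec(
            name=name, direction="decreasing", onset_time=onset,
            transition_duration=7.0, healthy_mean=mean, healthy_sd=sd,
            abnormal_shift=-(mean - floor), noise_sd=0.4 * sd, floor_value=floor,
        ))
    return specs


def default_two_group_config(seed: int = 0, *, cognitive: bool = False,
                             **overrides) -> CohortConfig:
    """The standard two-group study design used throughout the test-bench."""
    builder = default_cognitive_specs if cognitive else default_roi_specs
    kwargs = dict(
        biomarkers={"groupA": builder("groupA"), "groupB": builder("groupB")},
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


def trajectory_recovery_rmse(time, value, spec: BiomarkerSpec,
                             window_factor: float = 1.5) -> float:
    """Best-aligned RMSE between a reconstructed trajectory and its
    generating sigmoid, in biomarker units.

    Scored over a window of ``window_factor`` x the transition duration
    centred on the reconstructed midpoint crossing: the plateaus outside it
    are flat, and the time spent on them is not identifiable from
    rate-of-change data. The reconstruction's time origin is arbitrary, so
    the generating sigmoid is aligned by an exhaustive shift search centred
    on matching the midpoints.
    """
    time = np.asarray(time, dtype=float)
    value = np.asarray(value, dtype=float)
    mid = spec.healthy_mean + spec.abnormal_shift / 2.0
    order = np.argsort(value)
    t_mid = float(np.interp(mid, value[order], time[order]))
    half = window_factor * spec.transition_duration / 2.0
    t_eval = np.linspace(t_mid - half, t_mid + half, 200)
    t_eval = t_eval[(t_eval >= time[0]) & (t_eval <= time[-1])]
    v = np.interp(t_eval, time, value)
    shifts = spec.onset_time - t_mid + np.linspace(-20.0, 20.0, 801)
    return min(
        float(np.sqrt(np.mean((v - sigmoid_value(t_eval + s, spec)) ** 2)))
        for s in shifts
    )


# ---------------------------------------------------------------------------
# I/O

def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    truth.to_json(path)


def config_from_yaml(path) -> CohortConfig:
    """Build a :class:`CohortConfig` from a YAML/JSON mapping.

    Biomarker specs are given as mappings of :class:`BiomarkerSpec` fields
    under ``biomarkers: {group: [spec, ...]}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    biomarkers = {
        group: [BiomarkerSpec(**spec) for spec in specs]
        for group, specs in raw.pop("biomarkers").items()
    }
    if "latent_time_range" in raw:
        raw["latent_time_range"] = tuple(raw["latent_time_range"])
    return CohortConfig(biomarkers=biomarkers, **raw)
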