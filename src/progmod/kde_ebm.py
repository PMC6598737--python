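"""Event-based model (EBM) of biomarker abnormality orderings.

The EBM treats disease progression as a sequence of events, each event being
one biomarker's transition from a normal to an abnormal distribution. Given
cross-sectional data it infers the most likely ordering of those events, a
posterior over orderings, and a discrete stage for each subject.

Two mixture flavours describe each biomarker's normal/abnormal densities:

* ``gaussian`` — a constrained two-component Gaussian mixture (volumes),
  with the normal component initialised from controls and kept on the
  control side of the abnormal component during EM;
* ``kde`` — kernel-density components (cognitive scores), fitted by an
  alternating responsibility/refit scheme, which accommodates skewed and
  floor-censored score distributions.

The sequence likelihood marginalises a uniform prior over the subject's
stage k (number of events that have occurred):

    P(X | S) = prod_j  (1/(N+1)) sum_{k=0}^{N}
               prod_{i<=k} p(x_{s(i),j} | E) prod_{i>k} p(x_{s(i),j} | not E)

with missing values contributing a factor of 1.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import gaussian_kde, norm

__all__ = [
    "EventSequence",
    "MixtureFit",
    "PosteriorChain",
    "PositionalVariance",
    "PatientStageEBM",
    "fit_gaussian_mixture",
    "fit_kde_mixture",
    "fit_mixtures",
    "sequence_log_likelihood",
    "find_ml_sequence",
    "mcmc_sample",
    "thin_chain",
    "positional_variance",
    "bootstrap_sequences",
    "stage_subjects_ebm",
    "positions_from_sequences",
]

DENSITY_FLOOR = 1e-12


@dataclass(frozen=True)
class EventSequence:
    """An ordering of biomarker abnormality events."""

    events: tuple[str, ...]
    log_likelihood: float | None = None
    ties: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.events)) != len(self.events):
            raise ValueError("events must be a permutation (no repeats)")

    def position(self, biomarker: str) -> int:
        """1-based position of ``biomarker`` in the sequence."""
        return self.events.index(biomarker) + 1

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class MixtureFit:
    """Normal/abnormal density pair for one biomarker."""

    biomarker: str
    flavour: str                      # "gaussian" or "kde"
    pdf_normal: Callable[[np.ndarray], np.ndarray]
    pdf_abnormal: Callable[[np.ndarray], np.ndarray]
    mixing: float                     # P(abnormal)
    diagnostics: dict = field(default_factory=dict)

    def prob_abnormal(self, x) -> np.ndarray:
        """Posterior P(event occurred | x) under the fitted mixture."""
        x = np.asarray(x, dtype=float)
        fe = np.maximum(self.pdf_abnormal(x), DENSITY_FLOOR)
        fn = np.maximum(self.pdf_normal(x), DENSITY_FLOOR)
        num = self.mixing * fe
        return num / (num + (1.0 - self.mixing) * fn)


@dataclass
class PosteriorChain:
    """MCMC samples over event orderings."""

    events: tuple[str, ...]
    samples: np.ndarray               # (n_samples, N) permutation indices
    log_likelihoods: np.ndarray
    acceptance_rate: float
    seed: int
    thinning: int = 1

    def sequences(self) -> list[EventSequence]:
        return [
            EventSequence(
                events=tuple(self.events[i] for i in row),
                log_likelihood=float(ll),
            )
            for row, ll in zip(self.samples, self.log_likelihoods)
        ]

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class PositionalVariance:
    """P[event, position]: probability an event occupies each position."""

    events: tuple[str, ...]
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = len(self.events)
        return pd.DataFrame(
            self.matrix, index=list(self.events),
            columns=[f"position_{i+1}" for i in range(n)],
        )


@dataclass
class PatientStageEBM:
    """Discrete EBM stage for one subject (0 = no events, N = all events)."""

    subject_id: str
    stage: int
    posterior: np.ndarray             # length N+1, sums to 1


# ---------------------------------------------------------------------------
# Mixture fitting

def _normal_pdf(mean: float, sd: float) -> Callable[[np.ndarray], np.ndarray]:
    frozen = norm(loc=mean, scale=max(sd, 1e-9))
    return frozen.pdf


def fit_gaussian_mixture(values, group_labels, *, biomarker: str = "",
                         max_iter: int = 200, tol: float = 1e-8) -> MixtureFit:
    """Constrained two-component Gaussian mixture for one biomarker.

    The normal component is initialised from control values, the abnormal
    component from patient values, then refined by EM on the pooled data.
    After each M-step the normal mean is constrained to the control side of
    the abnormal mean (preventing component swapping on weakly separated
    biomarkers). Non-convergence returns the best iterate with a warning
    flag in ``diagnostics``.
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    mask = np.isfinite(x)
    x, labels = x[mask], labels[mask]
    is_control = labels == "control"
    if is_control.sum() == 0 or (~is_control).sum() == 0:
        raise ValueError("both controls and patients are required")

    mu_n, sd_n = float(x[is_control].mean()), float(x[is_control].std(ddof=1))
    mu_a, sd_a = float(x[~is_control].mean()), float(x[~is_control].std(ddof=1))
    sd_n = max(sd_n, 1e-6)
    sd_a = max(sd_a, 1e-6)
    control_side = np.sign(mu_n - mu_a) or 1.0
    pi = float((~is_control).mean())

    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        fn = np.maximum(norm.pdf(x, mu_n, sd_n), DENSITY_FLOOR)
        fa = np.maximum(norm.pdf(x, mu_a, sd_a), DENSITY_FLOOR)
        num = pi * fa
        resp = num / (num + (1 - pi) * fn)          # P(abnormal | x)
        ll = float(np.log(num + (1 - pi) * fn).sum())
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        wa = resp.sum()
        wn = (1 - resp).sum()
        pi = float(np.clip(wa / len(x), 1e-6, 1 - 1e-6))
        mu_a = float((resp * x).sum() / max(wa, 1e-12))
        mu_n = float(((1 - resp) * x).sum() / max(wn, 1e-12))
        sd_a = float(np.sqrt((resp * (x - mu_a) ** 2).sum() / max(wa, 1e-12)))
        sd_n = float(np.sqrt(((1 - resp) * (x - mu_n) ** 2).sum() / max(wn, 1e-12)))
        sd_a, sd_n = max(sd_a, 1e-6), max(sd_n, 1e-6)
        # keep the normal component on the control side of the abnormal one
        if (mu_n - mu_a) * control_side < 0:
            mu_n = mu_a

    # components less than one pooled SD apart carry no ordering signal
    separation = abs(mu_n - mu_a) / max(sd_n, sd_a)
    diagnostics = {
        "mu_normal": mu_n, "sd_normal": sd_n,
        "mu_abnormal": mu_a, "sd_abnormal": sd_a,
        "log_likelihood": prev_ll, "converged": converged,
        "uninformative": bool(separation < 1.0),
    }
    if not converged:
        warnings.warn(f"EM did not converge for {biomarker or 'biomarker'}")
    return MixtureFit(
        biomarker=biomarker, flavour="gaussian",
        pdf_normal=_normal_pdf(mu_n, sd_n), pdf_abnormal=_normal_pdf(mu_a, sd_a),
        mixing=pi, diagnostics=diagnostics,
    )


def _weighted_kde(x: np.ndarray, weights: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
    """Gaussian KDE with Silverman bandwidth on responsibility-weighted data.

    Falls back to a narrow Gaussian when the weighted sample is (nearly)
    degenerate — e.g. a component concentrated on a score floor — where the
    sample covariance would be singular.
    """
    w = weights / weights.sum()
    mean = float((w * x).sum())
    var = float((w * (x - mean) ** 2).sum())
    spread = max(np.ptp(x), abs(mean), 1.0)
    if var < (1e-6 * spread) ** 2:
        return _normal_pdf(mean, 1e-3 * spread)
    kde = gaussian_kde(x, bw_method="silverman", weights=w)
    return lambda q: kde(np.atleast_1d(np.asarray(q, dtype=float)))


def fit_kde_mixture(values, group_labels, *, biomarker: str = "",
                    max_iter: int = 50, tol: float = 1e-4) -> MixtureFit:
    """KDE-component mixture for skewed / floor-censored biomarkers.

    Assignments are initialised from the group labels (controls → normal,
    patients → abnormal), then the scheme alternates between fitting a
    Gaussian KDE per component on its assigned points (Silverman bandwidth)
    and reassigning each point to the component with the larger weighted
    density, until the assignment vector stabilises (classification EM —
    hard assignments keep the two kernel densities from absorbing each
    other). If assignments still oscillate after ``max_iter`` sweeps the
    last iterate is returned with a warning. The returned ``prob_abnormal``
    is nevertheless continuous, computed from the final densities and
    mixing weight.
    """
    del tol  # convergence is exact assignment stability
    x = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    mask = np.isfinite(x)
    x, labels = x[mask], labels[mask]
    is_control = labels == "control"
    if is_control.sum() == 0 or (~is_control).sum() == 0:
        raise ValueError("both controls and patients are required")

    assign = (~is_control).astype(float)        # 1 = abnormal component
    pi = float(assign.mean())
    pdf_n = pdf_a = None
    converged = False
    for _ in range(max_iter):
        pdf_n = _weighted_kde(x, 1.0 - assign)
        pdf_a = _weighted_kde(x, assign)
        fn = np.maximum(pdf_n(x), DENSITY_FLOOR)
        fa = np.maximum(pdf_a(x), DENSITY_FLOOR)
        new_assign = (pi * fa > (1 - pi) * fn).astype(float)
        if new_assign.sum() == 0 or new_assign.sum() == len(x):
            break                               # one component emptied; keep last
        if np.array_equal(new_assign, assign):
            converged = True
            break
        assign = new_assign
        pi = float(np.clip(assign.mean(), 1e-6, 1 - 1e-6))
    if not converged:
        warnings.warn(f"KDE mixture assignments did not stabilise for {biomarker or 'biomarker'}")
    diagnostics = {"converged": converged, "bandwidth_rule": "silverman",
                   "n": int(len(x))}
    return MixtureFit(
        biomarker=biomarker, flavour="kde",
        pdf_normal=pdf_n, pdf_abnormal=pdf_a, mixing=pi, diagnostics=diagnostics,
    )


def fit_mixtures(table: pd.DataFrame, biomarkers: Sequence[str],
                 flavour: str | dict[str, str] = "gaussian",
                 group_col: str = "group") -> dict[str, MixtureFit]:
    """Fit one mixture per biomarker from a long-format visit table.

    ``flavour`` is either a single flavour or a per-biomarker mapping
    (e.g. ``gaussian`` for volumes, ``kde`` for cognitive scores).
    """
    labels = np.where(table[group_col] == "control", "control", "patient")
    fits = {}
    for b in biomarkers:
        fl = flavour[b] if isinstance(flavour, dict) else flavour
        fitter = fit_gaussian_mixture if fl == "gaussian" else fit_kde_mixture
        fits[b] = fitter(table[b].to_numpy(), labels, biomarker=b)
    return fits


# ---------------------------------------------------------------------------
# Sequence likelihood

def _log_density_matrices(X: np.ndarray, fits: Sequence[MixtureFit]):
    """(log p(x|E), log p(x|not E)) per subject x biomarker; missing → 0."""
    X = np.asarray(X, dtype=float)
    n_subj, n_bio = X.shape
    logE = np.zeros((n_subj, n_bio))
    logN = np.zeros((n_subj, n_bio))
    for j, fit in enumerate(fits):
        col = X[:, j]
        ok = np.isfinite(col)
        if ok.any():
            logE[ok, j] = np.log(np.maximum(fit.pdf_abnormal(col[ok]), DENSITY_FLOOR))
            logN[ok, j] = np.log(np.maximum(fit.pdf_normal(col[ok]), DENSITY_FLOOR))
    return logE, logN


def _stage_loglik(logE: np.ndarray, logN: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Per-subject log-likelihood at each stage k = 0..N for ordering ``order``."""
    A = logE[:, order]
    B = logN[:, order]
    n = A.shape[1]
    prefA = np.concatenate([np.zeros((A.shape[0], 1)), np.cumsum(A, axis=1)], axis=1)
    prefB = np.concatenate([np.zeros((B.shape[0], 1)), np.cumsum(B, axis=1)], axis=1)
    totB = prefB[:, -1:]
    return prefA + (totB - prefB)      # (n_subj, N+1)


def _loglik_of_order(logE, logN, order) -> float:
    stage_ll = _stage_loglik(logE, logN, order)
    n = stage_ll.shape[1] - 1
    per_subject = logsumexp(stage_ll, axis=1) - math.log(n + 1)
    return float(per_subject.sum())


def _align(X, fits: Sequence[MixtureFit] | dict[str, MixtureFit]):
    """Normalise (X, fits) into (matrix, ordered fit list, event names)."""
    if isinstance(X, pd.DataFrame):
        if isinstance(fits, dict):
            names = [c for c in X.columns if c in fits]
            fit_list = [fits[c] for c in names]
        else:
            names = list(X.columns)
            fit_list = list(fits)
        mat = X[names].to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if isinstance(fits, dict):
            fit_list = list(fits.values())
            names = list(fits.keys())
        else:
            fit_list = list(fits)
            names = [f.biomarker or str(i) for i, f in enumerate(fit_list)]
    if mat.shape[1] != len(fit_list):
        raise ValueError("number of biomarker columns does not match fits")
    return mat, fit_list, tuple(names)


def sequence_log_likelihood(X, S: EventSequence | Sequence[str],
                            fits) -> float:
    """Log P(X | S) under the stage-marginalised EBM likelihood.

    ``X`` is subjects x biomarkers (DataFrame or ndarray; NaN = missing,
    contributing a factor of 1). The prior over stages k = 0..N is uniform.
    """
    mat, fit_list, names = _align(X, fits)
    events = S.events if isinstance(S, EventSequence) else tuple(S)
    if set(events) != set(names):
        raise ValueError("sequence events do not match biomarker set")
    order = np.array([names.index(e) for e in events])
    logE, logN = _log_density_matrices(mat, fit_list)
    return _loglik_of_order(logE, logN, order)


# ---------------------------------------------------------------------------
# Sequence search

def _greedy_ascent(logE, logN, order: np.ndarray) -> tuple[np.ndarray, float]:
    """Steepest-ascent over pairwise swaps until no swap improves."""
    n = len(order)
    best_ll = _loglik_of_order(logE, logN, order)
    improved = True
    while improved:
        improved = False
        best_swap = None
        for i in range(n - 1):
            for j in range(i + 1, n):
                order[i], order[j] = order[j], order[i]
                ll = _loglik_of_order(logE, logN, order)
                order[i], order[j] = order[j], order[i]
                if ll > best_ll + 1e-12:
                    best_ll = ll
                    best_swap = (i, j)
        if best_swap is not None:
            i, j = best_swap
            order[i], order[j] = order[j], order[i]
            improved = True
    return order, best_ll


def find_ml_sequence(X, fits, n_starts: int = 10, seed: int = 0,
                     method: str = "greedy") -> EventSequence:
    """Maximum-likelihood event ordering.

    ``method="greedy"`` runs steepest-ascent over pairwise swaps from
    ``n_starts`` random permutations and keeps the best;
    ``method="exhaustive"`` enumerates all N! permutations (N <= 7 only).
    """
    mat, fit_list, names = _align(X, fits)
    n = len(names)
    logE, logN = _log_density_matrices(mat, fit_list)
    if n == 1:
        return EventSequence(events=names,
                             log_likelihood=_loglik_of_order(logE, logN, np.array([0])))
    if method == "exhaustive":
        if n > 7:
            raise ValueError("exhaustive search limited to 7 events")
        best_order, best_ll = None, -np.inf
        for perm in itertools.permutations(range(n)):
            ll = _loglik_of_order(logE, logN, np.array(perm))
            if ll > best_ll:
                best_order, best_ll = np.array(perm), ll
    elif method == "greedy":
        rng = np.random.default_rng(seed)
        best_order, best_ll = None, -np.inf
        for s in range(n_starts):
            start = np.arange(n) if s == 0 else rng.permutation(n)
            order, ll = _greedy_ascent(logE, logN, start.copy())
            if ll > best_ll:
                best_order, best_ll = order.copy(), ll
    else:
        raise ValueError(f"unknown method {method!r}")
    return EventSequence(events=tuple(names[i] for i in best_order),
                         log_likelihood=best_ll)


def mcmc_sample(X, fits, init: EventSequence, n_iter: int = 100_000,
                seed: int = 0) -> PosteriorChain:
    """Metropolis–Hastings over orderings with random pairwise-swap proposals.

    The proposal is symmetric, so acceptance is min(1, L'/L). Every sample
    (including rejections, which repeat the current state) is stored; thin
    with :func:`thin_chain` before treating samples as independent.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    mat, fit_list, names = _align(X, fits)
    if set(init.events) != set(names):
        raise ValueError("init events do not match biomarker set")
    logE, logN = _log_density_matrices(mat, fit_list)
    rng = np.random.default_rng(seed)
    n = len(names)
    order = np.array([names.index(e) for e in init.events])
    ll = _loglik_of_order(logE, logN, order)
    samples = np.empty((n_iter, n), dtype=np.int64)
    lls = np.empty(n_iter)
    accepted = 0
    for it in range(n_iter):
        if n >= 2:
            i, j = rng.choice(n, size=2, replace=False)
            order[i], order[j] = order[j], order[i]
            new_ll = _loglik_of_order(logE, logN, order)
            if math.log(rng.random()) < new_ll - ll:
                ll = new_ll
                accepted += 1
            else:
                order[i], order[j] = order[j], order[i]
        samples[it] = order
        lls[it] = ll
    return PosteriorChain(events=names, samples=samples, log_likelihoods=lls,
                          acceptance_rate=accepted / n_iter, seed=seed)


def thin_chain(chain: PosteriorChain, factor: int = 100) -> PosteriorChain:
    """Keep every ``factor``-th sample (indices 0, factor, 2*factor, ...)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return PosteriorChain(
        events=chain.events,
        samples=chain.samples[::factor].copy(),
        log_likelihoods=chain.log_likelihoods[::factor].copy(),
        acceptance_rate=chain.acceptance_rate,
        seed=chain.seed,
        thinning=chain.thinning * factor,
    )


# ---------------------------------------------------------------------------
# Positional variance, bootstrap, staging

def positional_variance(sequences: Sequence[EventSequence]) -> PositionalVariance:
    """Event-by-position probability matrix from a set of orderings.

    Since every sample is a permutation the matrix is doubly stochastic:
    rows (events) and columns (positions) each sum to 1.
    """
    if not sequences:
        raise ValueError("at least one sequence required")
    events = tuple(sorted(sequences[0].events))
    n = len(events)
    index = {e: i for i, e in enumerate(events)}
    mat = np.zeros((n, n))
    for seq in sequences:
        if set(seq.events) != set(events):
            raise ValueError("sequences have inconsistent biomarker sets")
        for pos, e in enumerate(seq.events):
            mat[index[e], pos] += 1.0
    mat /= len(sequences)
    return PositionalVariance(events=events, matrix=mat)


def bootstrap_sequences(table: pd.DataFrame, biomarkers: Sequence[str],
                        flavour: str | dict[str, str] = "gaussian",
                        n_boot: int = 50, seed: int = 0,
                        group_col: str = "group",
                        n_starts: int = 4) -> list[EventSequence]:
    """ML sequences over subject-level bootstrap replicates.

    Subjects are resampled with replacement within group (controls among
    controls, patients among patients), mixtures refit and the ML sequence
    re-estimated per replicate.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = table.drop_duplicates("subject_id")[["subject_id", group_col]]
    by_group = {g: grp["subject_id"].to_numpy() for g, grp in subjects.groupby(group_col)}
    if "control" not in by_group or len(by_group) < 2:
        raise ValueError("table must contain controls and at least one patient group")
    indexed = table.set_index("subject_id")
    out = []
    for b in range(n_boot):
        ids = np.concatenate([rng.choice(v, size=len(v), replace=True)
                              for v in by_group.values()])
        boot = indexed.loc[ids].reset_index()
        fits = fit_mixtures(boot, biomarkers, flavour, group_col=group_col)
        patients = boot[boot[group_col] != "control"]
        seq = find_ml_sequence(patients[list(biomarkers)], fits,
                               n_starts=n_starts,
                               seed=int(rng.integers(2**31 - 1)))
        out.append(seq)
    return out


def stage_subjects_ebm(X, S: EventSequence, fits,
                       subject_ids: Sequence[str] | None = None) -> list[PatientStageEBM]:
    """Stage each subject along sequence ``S``.

    The stage posterior is proportional to
    ``prod_{i<=k} p(x|E) * prod_{i>k} p(x|not E)`` over k = 0..N (uniform
    prior); the reported stage is the argmax with ties resolved to the
    smallest k. Subjects with all biomarkers missing are skipped with a
    warning.
    """
    mat, fit_list, names = _align(X, fits)
    if isinstance(X, pd.DataFrame) and subject_ids is None:
        subject_ids = [str(i) for i in X.index]
    if subject_ids is None:
        subject_ids = [str(i) for i in range(mat.shape[0])]
    order = np.array([names.index(e) for e in S.events])
    logE, logN = _log_density_matrices(mat, fit_list)
    stage_ll = _stage_loglik(logE, logN, order)
    out = []
    for row, sid, ll in zip(mat, subject_ids, stage_ll):
        if not np.isfinite(row).any():
            warnings.warn(f"subject {sid}: all biomarkers missing, stage undefined")
            continue
        post = np.exp(ll - logsumexp(ll))
        post /= post.sum()
        out.append(PatientStageEBM(subject_id=sid, stage=int(np.argmax(post)),
                                   posterior=post))
    return out


def positions_from_sequences(sequences: Sequence[EventSequence],
                             biomarker: str) -> np.ndarray:
    """1-based positions of ``biomarker`` across a set of orderings."""
    return np.array([seq.position(biomarker) for seq in sequences])
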