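import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from progmod.kde_ebm import (EventSequence, MixtureFit, bootstrap_sequences,
                             find_ml_sequence, fit_gaussian_mixture,
                             fit_kde_mixture, fit_mixtures, mcmc_sample,
                             positional_variance, positions_from_sequences,
                             sequence_log_likelihood, stage_subjects_ebm,
                             thin_chain)


def constant_fit(name, dens_normal, dens_abnormal):
    """Mixture stub with constant densities — for hand-arithmetic checks."""
    return MixtureFit(
        biomarker=name, flavour="gaussian",
        pdf_normal=lambda x, d=dens_normal: np.full(np.shape(x), d),
        pdf_abnormal=lambda x, d=dens_abnormal: np.full(np.shape(x), d),
        mixing=0.5,
    )


def staged_data(rng, n_subjects, order, mu_sep=4.0, noise=1.0):
    """Subjects at uniform stages; events before the stage are abnormal."""
    n = len(order)
    X = np.empty((n_subjects, n))
    for j in range(n_subjects):
        k = rng.integers(0, n + 1)
        for pos, bio in enumerate(order):
            loc = -mu_sep if pos < k else 0.0
            X[j, bio] = rng.normal(loc, noise)
    return X


def gaussian_fits(names, mu_sep=4.0, sd=1.0):
    from scipy.stats import norm
    return [MixtureFit(biomarker=b, flavour="gaussian",
                       pdf_normal=norm(0, sd).pdf,
                       pdf_abnormal=norm(-mu_sep, sd).pdf, mixing=0.5)
            for b in names]


class TestGaussianMixture:
    def test_parameter_recovery(self, rng):
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(-4, 1, 200)])
        labels = np.array(["control"] * 200 + ["patient"] * 200)
        fit = fit_gaussian_mixture(x, labels)
        assert abs(fit.diagnostics["mu_normal"] - 0.0) < 0.3
        assert abs(fit.diagnostics["mu_abnormal"] + 4.0) < 0.3

    def test_null_biomarker_flagged_uninformative(self, rng):
        x = rng.normal(0, 1, 400)
        labels = np.array(["control"] * 200 + ["patient"] * 200)
        fit = fit_gaussian_mixture(x, labels)
        assert fit.diagnostics["uninformative"]

    def test_densities_normalised(self, rng):
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(-4, 1, 100)])
        labels = np.array(["control"] * 100 + ["patient"] * 100)
        fit = fit_gaussian_mixture(x, labels)
        for pdf in (fit.pdf_normal, fit.pdf_abnormal):
            area, _ = quad(lambda v: float(pdf(np.array([v]))[0]
                           if np.ndim(pdf(np.array([v]))) else pdf(v)), -20, 20)
            assert area == pytest.approx(1.0, abs=1e-3)


class TestKdeMixture:
    def test_separable_crossover(self, rng):
        x = np.concatenate([rng.normal(0, 0.5, 150), rng.normal(-4, 0.5, 150)])
        labels = np.array(["control"] * 150 + ["patient"] * 150)
        fit = fit_kde_mixture(x, labels)
        assert fit.prob_abnormal(-4.0) > 0.9
        assert fit.prob_abnormal(0.0) < 0.1
        mid = fit.prob_abnormal(np.linspace(-4, 0, 50))
        assert np.any(mid > 0.5) and np.any(mid < 0.5)

    def test_floored_scores_put_abnormal_mass_at_floor(self, rng):
        patients = np.where(rng.random(200) < 0.4, 0.0,
                            np.abs(rng.normal(4, 2, 200)))
        controls = rng.normal(12, 2, 150)
        x = np.concatenate([controls, patients])
        labels = np.array(["control"] * 150 + ["patient"] * 200)
        fit = fit_kde_mixture(x, labels)
        # mass of the abnormal component near the floor spike
        area, _ = quad(lambda v: float(np.atleast_1d(fit.pdf_abnormal(v))[0]),
                       -2.0, 2.0, limit=200)
        assert area >= 0.3

    def test_densities_normalised(self, rng):
        x = np.concatenate([rng.normal(10, 1, 100), rng.normal(4, 2, 100)])
        labels = np.array(["control"] * 100 + ["patient"] * 100)
        fit = fit_kde_mixture(x, labels)
        for pdf in (fit.pdf_normal, fit.pdf_abnormal):
            area, _ = quad(lambda v: float(np.atleast_1d(pdf(v))[0]), -20, 40,
                           limit=200)
            assert area == pytest.approx(1.0, abs=1e-3)

    def test_agrees_with_gaussian_on_gaussian_data(self, rng):
        x = np.concatenate([rng.normal(0, 1, 200), rng.normal(-4, 1, 200)])
        labels = np.array(["control"] * 200 + ["patient"] * 200)
        g = fit_gaussian_mixture(x, labels)
        k = fit_kde_mixture(x, labels)
        diff = np.abs(g.prob_abnormal(x) - k.prob_abnormal(x))
        assert np.mean(diff < 0.1) >= 0.95


class TestSequenceLikelihood:
    def test_two_event_hand_arithmetic(self):
        a, A = 0.2, 0.7          # biomarker 1 normal / abnormal densities
        b, B = 0.1, 0.6          # biomarker 2
        fits = [constant_fit("m1", a, A), constant_fit("m2", b, B)]
        X = np.array([[0.0, 0.0]])
        ll = sequence_log_likelihood(X, ("m1", "m2"), fits)
        expected = math.log((a * b + A * b + A * B) / 3.0)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_relabelling_invariance(self, rng):
        order = [0, 1, 2, 3]
        X = staged_data(rng, 40, order)
        fits = gaussian_fits(["a", "b", "c", "d"])
        ll = sequence_log_likelihood(X, ("a", "b", "c", "d"), fits)
        perm = [2, 0, 3, 1]
        X2 = X[:, perm]
        fits2 = [fits[i] for i in perm]
        names2 = tuple(["a", "b", "c", "d"][i] for i in perm)
        ll2 = sequence_log_likelihood(X2, ("a", "b", "c", "d"),
                                      dict(zip(names2, fits2)))
        assert ll2 == pytest.approx(ll, abs=1e-9)

    def test_missing_subject_contributes_factor_one(self):
        fits = [constant_fit("m1", 0.2, 0.7), constant_fit("m2", 0.1, 0.6)]
        X1 = np.array([[0.0, 0.0]])
        X2 = np.array([[0.0, 0.0], [np.nan, np.nan]])
        ll1 = sequence_log_likelihood(X1, ("m1", "m2"), fits)
        ll2 = sequence_log_likelihood(X2, ("m1", "m2"), fits)
        assert ll2 == pytest.approx(ll1, abs=1e-12)

    def test_non_permutation_rejected(self):
        fits = [constant_fit("m1", 0.2, 0.7), constant_fit("m2", 0.1, 0.6)]
        with pytest.raises(ValueError):
            sequence_log_likelihood(np.zeros((1, 2)), ("m1", "m1"), fits)


class TestMlSequence:
    def test_single_event_trivial(self, rng):
        X = rng.normal(0, 1, (20, 1))
        fits = gaussian_fits(["only"])
        assert find_ml_sequence(X, fits).events == ("only",)

    def test_greedy_equals_exhaustive(self, rng):
        order = [3, 1, 4, 0, 2]
        X = staged_data(rng, 200, order)
        names = list("abcde")
        fits = gaussian_fits(names)
        greedy = find_ml_sequence(X, fits, n_starts=5, seed=0)
        exact = find_ml_sequence(X, fits, method="exhaustive")
        assert greedy.log_likelihood == pytest.approx(exact.log_likelihood,
                                                      abs=1e-9)

    def test_recovers_generating_order(self, rng):
        order = [2, 0, 3, 1]
        X = staged_data(rng, 300, order, mu_sep=6.0, noise=0.5)
        names = list("abcd")
        fits = gaussian_fits(names, mu_sep=6.0, sd=0.5)
        ml = find_ml_sequence(X, fits, n_starts=5, seed=0)
        assert ml.events == tuple(names[i] for i in order)


class TestMcmc:
    def test_seeded_reproducibility(self, rng):
        X = staged_data(rng, 50, [0, 1, 2])
        fits = gaussian_fits(list("abc"))
        init = find_ml_sequence(X, fits, seed=0)
        c1 = mcmc_sample(X, fits, init, n_iter=300, seed=9)
        c2 = mcmc_sample(X, fits, init, n_iter=300, seed=9)
        np.testing.assert_array_equal(c1.samples, c2.samples)

    def test_samples_are_permutations(self, rng):
        X = staged_data(rng, 50, [0, 1, 2, 3])
        fits = gaussian_fits(list("abcd"))
        init = find_ml_sequence(X, fits, seed=0)
        chain = mcmc_sample(X, fits, init, n_iter=500, seed=2)
        sorted_rows = np.sort(chain.samples, axis=1)
        assert (sorted_rows == np.arange(4)).all()

    def test_modal_sequence_is_ml_on_separated_data(self, rng):
        order = [1, 0, 2]
        X = staged_data(rng, 150, order, mu_sep=6.0, noise=0.5)
        fits = gaussian_fits(list("abc"), mu_sep=6.0, sd=0.5)
        ml = find_ml_sequence(X, fits, method="exhaustive")
        chain = mcmc_sample(X, fits, ml, n_iter=2000, seed=4)
        rows, counts = np.unique(chain.samples, axis=0, return_counts=True)
        modal = tuple(chain.events[i] for i in rows[np.argmax(counts)])
        assert modal == ml.events

    def test_bad_iteration_count_rejected(self, rng):
        X = staged_data(rng, 10, [0, 1])
        fits = gaussian_fits(list("ab"))
        with pytest.raises(ValueError):
            mcmc_sample(X, fits, EventSequence(("a", "b")), n_iter=0)


class TestThinning:
    def test_paper_rate(self, rng):
        X = staged_data(rng, 20, [0, 1])
        fits = gaussian_fits(list("ab"))
        chain = mcmc_sample(X, fits, EventSequence(("a", "b")),
                            n_iter=10_000, seed=0)
        assert len(thin_chain(chain, 100)) == 100

    def test_identity_and_boundary(self, rng):
        X = staged_data(rng, 20, [0, 1])
        fits = gaussian_fits(list("ab"))
        chain = mcmc_sample(X, fits, EventSequence(("a", "b")), n_iter=50, seed=0)
        assert len(thin_chain(chain, 1)) == 50
        assert len(thin_chain(chain, 100)) == 1


class TestPositionalVariance:
    def test_degenerate_chain_is_permutation_matrix(self):
        seqs = [EventSequence(("b", "a", "c"))] * 7
        pv = positional_variance(seqs)
        assert pv.matrix.sum() == pytest.approx(3.0)
        assert set(np.unique(pv.matrix)) == {0.0, 1.0}

    def test_hand_counted_frequencies(self):
        seqs = [EventSequence(("a", "b", "c")), EventSequence(("a", "c", "b")),
                EventSequence(("b", "a", "c"))]
        pv = positional_variance(seqs)
        df = pv.to_frame()
        assert df.loc["a", "position_1"] == pytest.approx(2 / 3)
        assert df.loc["b", "position_2"] == pytest.approx(1 / 3)
        assert df.loc["c", "position_3"] == pytest.approx(2 / 3)

    def test_doubly_stochastic(self, rng):
        base = list("abcde")
        seqs = [EventSequence(tuple(rng.permutation(base))) for _ in range(20)]
        pv = positional_variance(seqs)
        np.testing.assert_allclose(pv.matrix.sum(axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(pv.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_inconsistent_event_sets_rejected(self):
        with pytest.raises(ValueError):
            positional_variance([EventSequence(("a", "b")),
                                 EventSequence(("a", "c"))])


class TestBootstrapSequences:
    def test_reproducible_and_first_event_stable(self):
        # strong-effect design: the first event leads the next by 4 years,
        # so bootstrap replicates should agree on it almost always
        import dataclasses
        from progmod.synthetic_cohort import CohortConfig, generate_cohort
        from progmod.synthetic_cohort import default_roi_specs
        specs = [dataclasses.replace(s, onset_time={"occipital": -3.0}.get(
            s.name, s.onset_time)) for s in default_roi_specs("groupA")[:5]]
        cfg = CohortConfig(biomarkers={"groupA": specs}, n_controls=80,
                           n_patients_per_group=120, covariate_effects={},
                           seed=13)
        table, truth = generate_cohort(cfg)
        sub = table[table["visit_index"] == 0]
        bios = [s.name for s in specs]
        s1 = bootstrap_sequences(sub, bios, n_boot=20, seed=3)
        s2 = bootstrap_sequences(sub, bios, n_boot=20, seed=3)
        assert [s.events for s in s1] == [s.events for s in s2]
        first_truth = truth.orderings["groupA"].events[0]
        assert first_truth == "occipital"
        frac = np.mean([s.events[0] == first_truth for s in s1])
        assert frac >= 0.9


class TestStaging:
    def test_healthy_and_end_stage_limits(self, rng):
        names = list("abcd")
        fits = gaussian_fits(names)
        healthy = np.zeros((1, 4))
        sick = np.full((1, 4), -4.0)
        seq = EventSequence(tuple(names))
        assert stage_subjects_ebm(healthy, seq, fits)[0].stage == 0
        assert stage_subjects_ebm(sick, seq, fits)[0].stage == 4

    def test_two_event_posterior_hand_arithmetic(self):
        a, A = 0.2, 0.7
        b, B = 0.1, 0.6
        fits = [constant_fit("m1", a, A), constant_fit("m2", b, B)]
        X = np.array([[0.0, 0.0]])
        post = stage_subjects_ebm(X, EventSequence(("m1", "m2")), fits)[0].posterior
        raw = np.array([a * b, A * b, A * B])
        np.testing.assert_allclose(post, raw / raw.sum(), atol=1e-10)

    def test_posterior_sums_to_one_on_cohort(self, roi_cohort):
        cfg, table, _ = roi_cohort
        base = table[table["visit_index"] == 0]
        sub = base[base["group"].isin(["control", "groupA"])]
        bios = cfg.biomarker_names
        fits = fit_mixtures(sub, bios)
        X = sub[sub["group"] == "groupA"].set_index("subject_id")[bios]
        ml = find_ml_sequence(X, fits, seed=0)
        for s in stage_subjects_ebm(X, ml, fits):
            assert s.posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_staging_invariant_to_joint_relabelling(self, rng):
        names = list("abcd")
        fits = gaussian_fits(names)
        X = staged_data(rng, 10, [0, 1, 2, 3])
        seq = EventSequence(tuple(names))
        stages = stage_subjects_ebm(X, seq, fits)
        perm = [3, 1, 0, 2]
        X2 = X[:, perm]
        fits2 = [fits[i] for i in perm]
        names2 = [names[i] for i in perm]
        for f, nm in zip(fits2, names2):
            f.biomarker = nm
        stages2 = stage_subjects_ebm(X2, seq, dict(zip(names2, fits2)))
        assert [s.stage for s in stages] == [s.stage for s in stages2]
        for s1, s2 in zip(stages, stages2):
            np.testing.assert_allclose(s1.posterior, s2.posterior, atol=1e-12)

    def test_all_missing_subject_skipped(self):
        fits = gaussian_fits(["a", "b"])
        X = np.array([[np.nan, np.nan], [0.0, 0.0]])
        with pytest.warns(UserWarning, match="missing"):
            out = stage_subjects_ebm(X, EventSequence(("a", "b")), fits)
        assert len(out) == 1


class TestPositionsHelper:
    def test_positions_extracted(self):
        seqs = [EventSequence(("a", "b", "c")), EventSequence(("c", "b", "a"))]
        np.testing.assert_array_equal(positions_from_sequences(seqs, "a"), [1, 3])
        np.testing.assert_array_equal(positions_from_sequences(seqs, "b"), [2, 2])
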