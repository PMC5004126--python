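import numpy as np
import pytest
from scipy import stats

from streammodes.errors import DegenerateSampleError, InputError
from streammodes.mixture import (GMMFit, aic, bic, classify, em_fit,
                                 goodness_of_fit, select_k)


def two_well_separated(n=2_000, seed=0):
    rng = np.random.default_rng(seed)
    comp = rng.integers(0, 2, size=n)
    return rng.normal(np.where(comp, 3.0, -3.0), 0.5), rng


class TestGMMFit:
    def test_sorted_by_mean(self):
        f = GMMFit(weights=[0.3, 0.7], means=[2.0, -1.0], sds=[1.0, 0.5],
                   loglik=0.0, n_iter=1, converged=True)
        np.testing.assert_allclose(f.means, [-1.0, 2.0])
        np.testing.assert_allclose(f.weights, [0.7, 0.3])

    def test_invalid_weights_rejected(self):
        with pytest.raises(InputError):
            GMMFit(weights=[0.5, 0.6], means=[0, 1], sds=[1, 1],
                   loglik=0.0, n_iter=0, converged=True)

    def test_roundtrip_dict(self):
        f = GMMFit(weights=[0.4, 0.6], means=[0.0, 2.0], sds=[1.0, 0.5],
                   loglik=-12.5, n_iter=7, converged=True)
        g = GMMFit.from_dict(f.to_dict())
        np.testing.assert_allclose(g.means, f.means)
        assert g.loglik == f.loglik

    def test_cdf_ppf_inverse(self):
        f = GMMFit(weights=[0.2, 0.8], means=[-1.0, 1.0], sds=[0.5, 1.0],
                   loglik=0.0, n_iter=0, converged=True)
        qs = np.array([0.05, 0.3, 0.5, 0.9])
        np.testing.assert_allclose(f.cdf(f.ppf(qs)), qs, atol=1e-9)


class TestEMFit:
    def test_k1_closed_form(self):
        rng = np.random.default_rng(10)
        x = rng.normal(2.0, 1.0, size=5_000)
        f = em_fit(x, K=1)
        assert f.means[0] == pytest.approx(np.mean(x), abs=1e-9)
        assert f.sds[0] == pytest.approx(np.std(x), abs=1e-9)
        assert f.weights[0] == 1.0
        assert f.means[0] == pytest.approx(2.0, abs=3 / np.sqrt(len(x)))
        assert f.sds[0] == pytest.approx(1.0, rel=0.05)

    def test_well_separated_recovery(self):
        x, _ = two_well_separated()
        f = em_fit(x, K=2, seed=0)
        np.testing.assert_allclose(f.means, [-3.0, 3.0], atol=0.1)
        np.testing.assert_allclose(f.weights, [0.5, 0.5], atol=0.05)

    def test_user_init_respected(self):
        x, _ = two_well_separated()
        init = {"weights": [0.5, 0.5], "means": [-3.0, 3.0], "sds": [0.5, 0.5]}
        f = em_fit(x, K=2, init=init)
        np.testing.assert_allclose(f.means, [-3.0, 3.0], atol=0.1)

    def test_monotone_loglik_on_random_datasets(self):
        # the EM loop asserts non-decreasing log-likelihood every iteration
        rng = np.random.default_rng(99)
        for i in range(100):
            n = int(rng.integers(50, 300))
            k = int(rng.integers(1, 4))
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2.0), size=n)
            if rng.random() < 0.5:
                x = np.concatenate([x, rng.exponential(2.0, size=n // 2)])
            em_fit(x, K=k, seed=i, max_iter=150, tol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(InputError):
            em_fit(np.arange(5.0), K=2)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            em_fit(np.ones(100), K=2)

    def test_nonfinite_values_ignored(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=1_000)
        x[::50] = np.nan
        f = em_fit(x, K=1)
        assert np.isfinite(f.loglik)


class TestSelectK:
    def test_single_gaussian_picks_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5_000)
        tab = select_k(x, 1, 4, criterion="both", n_restarts=2, max_iter=200,
                       tol=1e-6, seed=0)
        assert tab.chosen_k == 1
        assert tab.agree is True

    def test_two_mixture_picks_two(self):
        x, _ = two_well_separated(n=4_000)
        tab = select_k(x, 1, 4, criterion="BIC", n_restarts=2, max_iter=200,
                       tol=1e-6, seed=0)
        assert tab.chosen_k == 2

    def test_table_formulas(self):
        x, _ = two_well_separated(n=1_000)
        tab = select_k(x, 1, 3, criterion="AIC", n_restarts=1, max_iter=100,
                       tol=1e-6, seed=0)
        for row in tab.rows:
            assert row["n_params"] == 3 * row["K"] - 1
            assert row["AIC"] == pytest.approx(2 * row["n_params"] - 2 * row["loglik"])
            assert row["BIC"] == pytest.approx(
                row["n_params"] * np.log(1_000) - 2 * row["loglik"])

    def test_aic_bic_hand_computation(self):
        # hand check: K=3, loglik=-3300, n=32196 -> 8 free params
        assert aic(-3300.0, 8) == pytest.approx(6616.0)
        assert bic(-3300.0, 8, 32_196) == pytest.approx(8 * np.log(32_196) + 6600.0)

    def test_unknown_criterion_rejected(self):
        with pytest.raises(InputError):
            select_k(np.random.default_rng(0).normal(size=100), 1, 2,
                     criterion="DIC")


class TestClassify:
    def symmetric_fit(self):
        return GMMFit(weights=[0.5, 0.5], means=[-1.0, 1.0], sds=[0.7, 0.7],
                      loglik=0.0, n_iter=0, converged=True)

    def test_symmetric_midpoint(self):
        f = self.symmetric_fit()
        a = classify(f, [0.0])
        np.testing.assert_allclose(a.posteriors[0], [0.5, 0.5], atol=1e-12)
        assert a.boundaries[0] == pytest.approx(0.0, abs=1e-10)
        assert a.labels[0] == 0      # tie goes to the lower-mean component

    def test_far_tail_limit(self):
        f = self.symmetric_fit()
        a = classify(f, [-50.0])
        assert a.posteriors[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_printed_parameters_label_low(self, default_mixture):
        f = GMMFit(weights=default_mixture.weights, means=default_mixture.means,
                   sds=default_mixture.sds, loglik=0.0, n_iter=0, converged=True)
        a = classify(f, [-0.59])
        assert a.class_names[a.labels[0]] == "low"
        # independent evaluation of the posterior formula
        num = np.asarray(f.weights) * stats.norm.pdf(-0.59, f.means, f.sds)
        np.testing.assert_allclose(a.posteriors[0], num / num.sum(), atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        f = self.symmetric_fit()
        a = classify(f, rng.normal(size=500))
        np.testing.assert_allclose(a.posteriors.sum(axis=1), 1.0, atol=1e-9)

    def test_nonfinite_masked(self):
        f = self.symmetric_fit()
        a = classify(f, [np.nan, 0.5, np.inf])
        assert a.labels.tolist()[0] == -1 and a.labels.tolist()[2] == -1
        assert np.isnan(a.posteriors[0]).all()

    def test_labels_match_boundary_thresholding(self, default_mixture):
        f = GMMFit(weights=default_mixture.weights, means=default_mixture.means,
                   sds=default_mixture.sds, loglik=0.0, n_iter=0, converged=True)
        x = np.linspace(-1.2, 1.2, 2_001)
        a = classify(f, x)
        by_threshold = np.searchsorted(a.boundaries, x)
        np.testing.assert_array_equal(a.labels, by_threshold)

    def test_class_proportions_match_quadrature(self, default_mixture,
                                                default_mixture_sample):
        """Label frequencies vs numeric integration of the posterior regions."""
        f = GMMFit(weights=default_mixture.weights, means=default_mixture.means,
                   sds=default_mixture.sds, loglik=0.0, n_iter=0, converged=True)
        a = classify(f, default_mixture_sample)
        edges = np.concatenate([[-np.inf], a.boundaries, [np.inf]])
        expected = np.diff(f.cdf(np.clip(edges, -1e9, 1e9)))
        n = len(default_mixture_sample)
        sds = np.sqrt(expected * (1 - expected) / n)
        np.testing.assert_array_less(np.abs(a.proportions - expected), 3 * sds)


class TestGoodnessOfFit:
    def fit_for(self, x):
        return em_fit(x, K=1)

    def test_qq_diagonal_when_data_is_model(self):
        f = GMMFit(weights=[1.0], means=[0.0], sds=[1.0], loglik=0.0,
                   n_iter=0, converged=True)
        n = 5_000
        x = f.ppf((np.arange(n) + 0.5) / n)     # perfect plug-in sample
        rep = goodness_of_fit(f, x, n_bins=20)
        np.testing.assert_allclose(rep.qq_pairs[:, 0], rep.qq_pairs[:, 1],
                                   atol=5e-3)
        assert rep.ks_stat < 0.001

    def test_gross_misfit_detected(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2_000)
        f = self.fit_for(x)
        rep = goodness_of_fit(f, x + 5.0, n_bins=20)
        assert rep.ks_stat > 0.95
        assert rep.ks_p < 1e-10

    def test_ks_p_calibration_under_true_model(self):
        """Fixed-parameter simulation oracle: p-values are ~uniform."""
        f = GMMFit(weights=[0.3, 0.7], means=[-1.0, 1.0], sds=[0.6, 0.9],
                   loglik=0.0, n_iter=0, converged=True)
        rng = np.random.default_rng(4)
        hits = 0
        reps = 200
        for _ in range(reps):
            comp = rng.choice(2, size=800, p=f.weights)
            x = rng.normal(f.means[comp], f.sds[comp])
            rep = goodness_of_fit(f, x, n_bins=20)
            hits += rep.ks_p < 0.05
        sd = np.sqrt(0.05 * 0.95 / reps)
        assert abs(hits / reps - 0.05) < 3 * sd

    def test_chi2_df_convention(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=2_000)
        f = self.fit_for(x)
        rep = goodness_of_fit(f, x, n_bins=25)
        assert rep.chi2_df == 25 - 1 - 2       # K=1 -> 3K-1 = 2 params
        assert rep.chi2_stat >= 0

    def test_warning_flag_present(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=1_000)
        rep = goodness_of_fit(self.fit_for(x), x, n_bins=10)
        assert "optimistic" in rep.warning

    def test_insufficient_data_rejected(self):
        with pytest.raises(InputError):
            goodness_of_fit(self.fit_for(np.random.default_rng(0).normal(size=600)),
                            np.arange(40.0), n_bins=20)
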