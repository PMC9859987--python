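"""Bernoulli ML fitting of the seriality model and profile-likelihood CIs."""

import math

import numpy as np
import pytest
from scipy import optimize

from seridose import CohortDataset, SerialityParams, fit, neg_log_likelihood
from seridose.fitting import DEFAULT_BOUNDS, _nll_from_matrices, profile_ci, profile_interval
from seridose.seriality import ntcp
from seridose.synthetic import default_cohort_spec, make_cohort

from conftest import make_ddvh


def uniform_cohort(doses, labels, organ="rectum"):
    dvhs = [make_ddvh([d], [1.0]) for d in doses]
    return CohortDataset(organ=organ, planned=dvhs, labels=np.array(labels, dtype=bool))


class TestNegLogLikelihood:
    def test_single_patient_at_half_probability(self, rectum):
        """y = 1 with P_I = 0.5 contributes exactly ln 2."""
        cohort = uniform_cohort([67.0], [True])
        assert neg_log_likelihood(rectum, cohort) == pytest.approx(math.log(2), abs=1e-12)

    def test_all_negative_labels_with_vanishing_risk(self):
        params = SerialityParams(d50=1e5, gamma=5.0, s=1.0)
        cohort = uniform_cohort([10.0, 20.0, 30.0], [False, False, False])
        assert neg_log_likelihood(params, cohort) == pytest.approx(0.0, abs=1e-8)

    def test_matches_per_patient_sum_oracle(self, rng, rectum):
        """Direct per-patient summation on a 10-patient fixture."""
        dvhs, labels = [], []
        for i in range(10):
            doses = np.sort(rng.uniform(0, 80, 6))
            dv = rng.dirichlet(np.ones(6))
            dvhs.append(make_ddvh(doses, dv))
            labels.append(bool(i % 3 == 0))
        cohort = CohortDataset(organ="rectum", planned=dvhs, labels=np.array(labels))
        oracle = 0.0
        for d, y in zip(dvhs, labels):
            p = min(max(ntcp(d, rectum), 1e-12), 1 - 1e-12)
            oracle -= math.log(p) if y else math.log1p(-p)
        assert neg_log_likelihood(rectum, cohort) == pytest.approx(oracle, rel=1e-12)

    def test_invariant_to_order_and_doubling(self, rng, rectum):
        doses = rng.uniform(30, 75, 12)
        labels = rng.random(12) < 0.4
        labels[:2] = [True, False]
        cohort = uniform_cohort(doses, labels)
        perm = rng.permutation(12)
        shuffled = uniform_cohort(doses[perm], labels[perm])
        doubled = uniform_cohort(np.tile(doses, 2), np.tile(labels, 2))
        base = neg_log_likelihood(rectum, cohort)
        assert neg_log_likelihood(rectum, shuffled) == pytest.approx(base, rel=1e-12)
        assert neg_log_likelihood(rectum, doubled) == pytest.approx(2 * base, rel=1e-12)

    def test_empty_cohort_rejected(self, rectum):
        cohort = uniform_cohort([50.0], [True])
        cohort.planned, cohort.labels = [], np.array([], dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            neg_log_likelihood(rectum, cohort)


@pytest.fixture(scope="module")
def rectum_cohort_500():
    spec = default_cohort_spec(seed=1000)
    return make_cohort(spec, "rectum", n_patients=500, bin_width=1.0)


@pytest.fixture(scope="module")
def rectum_fit_500(rectum_cohort_500):
    return fit(rectum_cohort_500)


class TestFit:
    def test_recovers_rectum_truth(self, rectum_fit_500):
        """D50/gamma recovered within twice their asymptotic SE (n = 500)."""
        res = rectum_fit_500
        assert res.converged
        # Cramer-Rao at the truth on this cohort: SE(D50) ~ 3.3 Gy, SE(gamma) ~ 1
        assert res.params.d50 == pytest.approx(67.0, abs=6.6)
        assert res.params.gamma == pytest.approx(2.5, abs=2.0)

    def test_stationarity_of_returned_optimum(self, rectum_cohort_500, rectum_fit_500):
        """Restarting L-BFGS-B from the optimum does not improve it."""
        dose, dv = rectum_cohort_500.dose_matrix()
        labels = rectum_cohort_500.labels
        p = rectum_fit_500.params
        x0 = np.array([p.d50, p.gamma, np.log10(p.s)])
        res = optimize.minimize(
            lambda th: _nll_from_matrices(th, dose, dv, labels),
            x0,
            method="L-BFGS-B",
            bounds=DEFAULT_BOUNDS,
        )
        assert res.fun >= -rectum_fit_500.loglik - 1e-6

    def test_training_auc_at_least_chance(self, rectum_cohort_500, rectum_fit_500):
        from seridose import roc_auc

        scores = [ntcp(d, rectum_fit_500.params) for d in rectum_cohort_500.planned]
        assert roc_auc(scores, rectum_cohort_500.labels).auc >= 0.5

    def test_null_labels_give_near_flat_curve(self):
        """Dose-ignoring coin-flip labels produce a flat fitted dose response."""
        spec = default_cohort_spec(seed=77)
        cohort = make_cohort(spec, "rectum", n_patients=250, bin_width=1.0)
        rng = np.random.default_rng(5)
        cohort.labels = rng.random(250) < 0.25
        res = fit(cohort)
        # flatness where the labels constrain the model: the fitted NTCP
        # across the cohort's own DVHs barely varies and sits at the base rate
        probs = np.array([ntcp(d, res.params) for d in cohort.planned])
        flat = probs.max() - probs.min() < 0.15
        assert flat or res.separation_flag
        assert probs.mean() == pytest.approx(cohort.labels.mean(), abs=0.05)

    def test_too_few_responders_rejected(self, rectum):
        cohort = uniform_cohort([40, 50, 60, 70, 75], [True, False, False, False, False])
        with pytest.raises(ValueError, match="at least"):
            fit(cohort)


class TestProfileInterval:
    def test_one_parameter_quadratic_matches_wald(self):
        """0.5 ((x - mu)/sigma)^2 has the analytic mu +/- 1.96 sigma interval."""
        mu, sigma = 3.0, 0.7
        nll = lambda x: 0.5 * ((x[0] - mu) / sigma) ** 2
        iv = profile_interval(nll, np.array([mu]), 0, [(-50.0, 50.0)], 0.95)
        z = 1.959964
        assert iv.low == pytest.approx(mu - z * sigma, rel=0.02)
        assert iv.high == pytest.approx(mu + z * sigma, rel=0.02)
        assert not iv.low_at_bound and not iv.high_at_bound

    def test_correlated_quadratic_profiles_out_nuisance(self):
        """Profile CI of a 2-D Gaussian NLL equals mu0 +/- 1.96 sqrt(Sigma00)."""
        cov = np.array([[2.0, 1.2], [1.2, 1.5]])
        prec = np.linalg.inv(cov)
        mu = np.array([1.0, -2.0])
        nll = lambda x: 0.5 * (x - mu) @ prec @ (x - mu)
        iv = profile_interval(nll, mu.copy(), 0, [(-50, 50), (-50, 50)], 0.95)
        half = 1.959964 * math.sqrt(cov[0, 0])
        assert iv.low == pytest.approx(mu[0] - half, rel=0.02)
        assert iv.high == pytest.approx(mu[0] + half, rel=0.02)

    def test_bound_limited_side_flagged(self):
        nll = lambda x: 0.5 * ((x[0] - 3.0) / 0.7) ** 2
        iv = profile_interval(nll, np.array([3.0]), 0, [(2.5, 50.0)], 0.95)
        assert iv.low == 2.5 and iv.low_at_bound
        assert not iv.high_at_bound


@pytest.fixture(scope="module")
def small_fit():
    spec = default_cohort_spec(seed=42)
    cohort = make_cohort(spec, "rectum", n_patients=150, bin_width=1.0)
    return cohort, fit(cohort)


class TestProfileCI:
    def test_ci_brackets_mle_and_widens_with_level(self, small_fit):
        cohort, res = small_fit
        iv95 = profile_ci(cohort, res, "d50", 0.95)
        iv80 = profile_ci(cohort, res, "d50", 0.80)
        assert iv95.low <= res.params.d50 <= iv95.high
        assert iv95.low <= iv80.low and iv80.high <= iv95.high

    def test_unconverged_fit_rejected(self, small_fit):
        import dataclasses

        cohort, res = small_fit
        bad = dataclasses.replace(res, converged=False)
        with pytest.raises(ValueError, match="converged"):
            profile_ci(cohort, bad, "d50")

    def test_unknown_parameter_rejected(self, small_fit):
        cohort, res = small_fit
        with pytest.raises(ValueError, match="unknown"):
            profile_ci(cohort, res, "alpha")
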