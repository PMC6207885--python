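"""Group inference: design coding, CVA, PEB, BMR, classification."""

import numpy as np
import pytest

from neurodcm.group import (
    PEBModel,
    _peb_evidence,
    _reduced_log_evidence,
    bmr_search,
    build_design,
    classify,
    cva,
    peb_fit,
)
from neurodcm.inversion import Posterior


class TestBuildDesign:
    def test_exact_coding(self):
        X = build_design(["control", "encephalopathy", "nmdar"])
        np.testing.assert_array_equal(
            X, [[1, 0, 0], [1, 1, 0], [1, 1, 1]]
        )

    def test_all_controls(self):
        X = build_design(["control"] * 4)
        assert X[:, 1:].sum() == 0

    def test_cohort_sized_column_sums(self):
        groups = ["nmdar"] * 29 + ["encephalopathy"] * 18 + ["control"] * 18
        X = build_design(groups)
        # 65 subjects; 47 encephalopathic in the nested coding; 29 with the
        # NMDAR-encephalitis label
        np.testing.assert_array_equal(X.sum(axis=0), [65, 47, 29])

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError):
            build_design(["patient"])


class TestCVA:
    def test_perfect_separation_gives_unit_correlation(self, rng):
        n = 30
        contrast = (np.arange(n) < 15).astype(float)
        Y = np.column_stack([contrast, rng.standard_normal(n)])
        res = cva(Y, contrast)
        assert res.canonical_correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_search_over_unit_vectors(self, rng):
        """First canonical correlation equals a brute-force scan over
        unit-norm 2-vector mixtures (grid-search oracle)."""
        n = 40
        x = rng.standard_normal(n)
        Y = np.column_stack([
            0.8 * x + 0.3 * rng.standard_normal(n),
            -0.5 * x + 0.6 * rng.standard_normal(n),
        ])
        res = cva(Y, x)
        best = 0.0
        for phi in np.linspace(0, np.pi, 2001):
            w = np.array([np.cos(phi), np.sin(phi)])
            r = abs(np.corrcoef(Y @ w, x)[0, 1])
            best = max(best, r)
        assert res.canonical_correlations[0] == pytest.approx(best, abs=1e-3)

    def test_null_calibration_of_p_values(self, rng):
        """With Y independent of X the test should reject at roughly the
        nominal rate (permutation calibration oracle)."""
        n, p = 40, 3
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            Y = rng.standard_normal((n, p))
            x = rng.standard_normal(n)
            rejections += cva(Y, x).p_value < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09

    def test_invariance_to_contrast_scaling(self, rng):
        n = 30
        Y = rng.standard_normal((n, 3))
        x = (np.arange(n) < 12).astype(float)
        p1 = cva(Y, x).p_value
        p2 = cva(Y, 5.0 * x - 2.0).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_too_few_subjects_raise(self, rng):
        with pytest.raises(ValueError):
            cva(rng.standard_normal((4, 5)), np.arange(4.0))


def _make_posteriors(theta, cov_scale=0.05, labels=None):
    n, p = theta.shape
    labels = labels or tuple(f"p{i}" for i in range(p))
    return [Posterior(theta[i], cov_scale * np.eye(p), -1.0, labels=labels)
            for i in range(n)]


class TestPEB:
    def test_intercept_only_recovers_average(self):
        theta = np.tile(np.array([0.3, -0.1]), (5, 1))
        posts = _make_posteriors(theta)
        X = np.ones((5, 1))
        # a nearly flat prior on beta so the average is not shrunk
        model = peb_fit(posts, X, optimize_q=False, beta_prior_var=1e8)
        np.testing.assert_allclose(model.effect(0), [0.3, -0.1], atol=1e-6)

    def test_recovers_known_group_effect(self, rng):
        n, p = 24, 4
        X = build_design(["control"] * 8 + ["encephalopathy"] * 8
                         + ["nmdar"] * 8)
        beta3 = np.array([0.0, -0.8, 0.0, 0.0])
        theta = X[:, 2:3] @ beta3[None, :] + 0.05 * rng.standard_normal((n, p))
        posts = _make_posteriors(theta)
        model = peb_fit(posts, X)
        est = model.effect(2)
        se = np.sqrt(np.diag(model.beta_cov)[2 * p:3 * p])
        assert abs(est[1] - (-0.8)) <= 2 * se[1]

    def test_permutation_invariance(self, rng):
        n, p = 12, 3
        theta = rng.standard_normal((n, p))
        X = build_design(["control"] * 4 + ["encephalopathy"] * 4
                         + ["nmdar"] * 4)
        posts = _make_posteriors(theta)
        m1 = peb_fit(posts, X, optimize_q=False)
        perm = rng.permutation(n)
        m2 = peb_fit([posts[i] for i in perm], X[perm], optimize_q=False)
        np.testing.assert_allclose(m1.beta_mean, m2.beta_mean, atol=1e-9)

    def test_singular_design_raises(self, rng):
        posts = _make_posteriors(rng.standard_normal((6, 2)))
        X = np.ones((6, 2))
        with pytest.raises(ValueError):
            peb_fit(posts, X)


class TestBMR:
    def test_identity_reduction_changes_nothing(self, rng):
        mu = rng.standard_normal(4)
        Sq = np.eye(4) * 0.3
        v = np.ones(4)
        assert _reduced_log_evidence(mu, Sq, v, v) == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_reduced_evidence_matches_direct_refit(self, rng):
        """Conjugate closed form: switching off a parameter by shrinking
        its prior variance must give the same evidence change as refitting
        the linear-Gaussian model with the reduced prior."""
        n, d, tau = 15, 2, 30.0
        J = rng.standard_normal((n, d))
        y = J @ np.array([0.7, 0.0]) + rng.standard_normal(n) / np.sqrt(tau)
        v_full = np.array([0.5, 0.5])
        shrink = 1e-8

        def evidence(v):
            C = J @ np.diag(v) @ J.T + np.eye(n) / tau
            s, ld = np.linalg.slogdet(C)
            return -0.5 * (n * np.log(2 * np.pi) + ld
                           + y @ np.linalg.solve(C, y))

        Pp = np.diag(1.0 / v_full)
        Sq = np.linalg.inv(tau * J.T @ J + Pp)
        mu = Sq @ (tau * J.T @ y)
        v_red = np.array([0.5, shrink * 0.5])
        dF = _reduced_log_evidence(mu, Sq, v_full, v_red)
        assert dF == pytest.approx(evidence(v_red) - evidence(v_full),
                                   abs=1e-6)

    def test_probabilities_monotone_in_effect_size(self, rng):
        probs = []
        X = build_design(["control"] * 7 + ["encephalopathy"] * 6
                         + ["nmdar"] * 7)
        for effect in (0.0, 0.4, 1.2):
            theta = X[:, 2:3] * np.array([[effect, 0.0, 0.0]]) \
                + 0.05 * rng.standard_normal((20, 3))
            posts = _make_posteriors(theta)
            model = peb_fit(posts, X)
            res = bmr_search(model, covariates=(2,))
            probs.append(res.effect_probability[(2, "p0")])
        assert probs[0] <= probs[1] <= probs[2]
        assert probs[2] > 0.95

    def test_type_one_error_control(self, rng):
        """With no simulated effects, few parameters cross P > 0.95."""
        X = build_design(["control"] * 8 + ["encephalopathy"] * 6
                         + ["nmdar"] * 6)
        crossings, total = 0, 0
        for _ in range(20):
            theta = 0.1 * rng.standard_normal((20, 5))
            posts = _make_posteriors(theta, cov_scale=0.02)
            model = peb_fit(posts, X)
            res = bmr_search(model, covariates=(1, 2))
            crossings += sum(p > 0.95
                             for p in res.effect_probability.values())
            total += len(res.effect_probability)
        assert crossings / total <= 0.10


class TestClassify:
    def test_perfect_separation(self):
        Y = np.array([[0.0], [0.1], [2.0], [2.1]])
        labels = ["other", "other", "nmdar", "nmdar"]
        res = classify(Y, np.array([1.0]), labels)
        assert res["accuracy"] == 1.0

    def test_alpha_adjustment_recovers_confounded_subjects(self, rng):
        """An additive alpha-power confound misclassifies a minority of
        patients; regressing it out restores the separation."""
        n_pos, n_neg = 10, 10
        scores_true = np.concatenate([np.full(n_pos, 2.0),
                                      np.full(n_neg, 0.0)])
        scores_true += 0.1 * rng.standard_normal(n_pos + n_neg)
        alpha = np.zeros(n_pos + n_neg)
        alpha[:3] = 4.0  # three confounded patients
        observed = scores_true - 0.8 * alpha
        labels = ["nmdar"] * n_pos + ["other"] * n_neg
        Y = observed[:, None]
        plain = classify(Y, np.array([1.0]), labels)
        adjusted = classify(Y, np.array([1.0]), labels, alpha_power=alpha)
        assert plain["accuracy"] < 1.0
        assert adjusted["accuracy"] > plain["accuracy"]

    def test_single_subject_raises(self):
        with pytest.raises(ValueError):
            classify(np.array([[1.0]]), np.array([1.0]), ["nmdar"])

    def test_missing_covariate_values_raise(self):
        Y = np.array([[0.0], [1.0]])
        with pytest.raises(ValueError):
            classify(Y, np.array([1.0]), ["nmdar", "other"],
                     alpha_power=np.array([1.0, np.nan]))
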