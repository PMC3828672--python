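"""QDA correctness against closed forms, brute-force Bayes evaluation and
an independent library implementation; cross-validation metrics."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from muhit.classify import (EvalResult, FoldCounts, QdaModel,
                            crossval_5fold, fit_qda, predict_qda)


def _two_gaussians(rng, n, d, mu0, mu1, s0=1.0, s1=1.0):
    X = np.vstack([mu0 + s0 * rng.standard_normal((n, d)),
                   mu1 + s1 * rng.standard_normal((n, d))])
    y = np.repeat([0, 1], n)
    return X, y


class TestFit:
    def test_equal_covariance_limit_is_linear_midpoint(self, rng):
        """With equal covariances QDA reduces to LDA: the boundary along
        the mean-difference axis crosses at the midpoint."""
        X, y = _two_gaussians(rng, 1000, 2, np.zeros(2), 3 * np.ones(2))
        model = fit_qda(X, y)

        def decision(t):
            p = np.array([[t, t]])
            return float(predict_qda(model, p)[0])

        lo, hi = 0.0, 3.0
        for _ in range(40):
            mid = (lo + hi) / 2
            if decision(mid) == 0:
                lo = mid
            else:
                hi = mid
        assert (lo + hi) / 2 == pytest.approx(1.5, abs=0.1)

    def test_scalar_quadratic_boundary_roots(self, rng):
        """1-D, unequal variances: the fitted model's own log-density
        equality is a quadratic whose roots must be exactly where the
        prediction flips."""
        X, y = _two_gaussians(rng, 2000, 1, np.array([0.0]),
                              np.array([1.0]), s0=1.0, s1=2.0)
        model = fit_qda(X, y, regularization=0.0)
        (m0,), (m1,) = model.means
        v0, v1 = model.covariances[0, 0, 0], model.covariances[1, 0, 0]
        p0, p1 = model.priors
        # a x^2 + b x + c = 0 from equating the class log densities
        a = 0.5 * (1 / v0 - 1 / v1)
        b = m1 / v1 - m0 / v0
        c = (0.5 * (m0 ** 2 / v0 - m1 ** 2 / v1)
             + 0.5 * np.log(v0 / v1) + np.log(p1 / p0))
        roots = np.sort(np.roots([a, b, c]))
        assert len(roots) == 2
        for r in roots:
            eps = 1e-6
            left = predict_qda(model, [[r - eps]])[0]
            right = predict_qda(model, [[r + eps]])[0]
            assert left != right

    def test_duplicate_rows_still_fit(self):
        X = np.array([[1.0, 2.0]] * 10 + [[3.0, 4.0]] * 10)
        y = np.repeat([0, 1], 10)
        model = fit_qda(X, y)
        for cov in model.covariances:
            assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            fit_qda(np.zeros((4, 2)), np.zeros(4))


class TestPredict:
    def test_class_mean_maps_to_class(self, rng):
        X, y = _two_gaussians(rng, 200, 3, np.zeros(3), 4 * np.ones(3))
        model = fit_qda(X, y)
        assert predict_qda(model, model.means[:1])[0] == model.classes[0]
        assert predict_qda(model, model.means[1:])[0] == model.classes[1]

    def test_tie_breaks_to_larger_prior_then_label_order(self):
        cov = np.eye(1)[None].repeat(2, axis=0)
        means = np.array([[-1.0], [1.0]])
        m = QdaModel(classes=np.array([0, 1]), means=means,
                     covariances=cov, priors=np.array([0.3, 0.7]),
                     regularization=0.0)
        assert predict_qda(m, [[0.0]])[0] == 1        # larger prior
        m_eq = QdaModel(classes=np.array([0, 1]), means=means,
                        covariances=cov, priors=np.array([0.5, 0.5]),
                        regularization=0.0)
        assert predict_qda(m_eq, [[0.0]])[0] == 0     # then label order

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _two_gaussians(rng, 50, 2, np.zeros(2), np.ones(2))
        model = fit_qda(X, y)
        with pytest.raises(ValueError, match="dimension"):
            predict_qda(model, np.zeros((1, 3)))

    def test_matches_bruteforce_bayes_rule(self, rng):
        """Predictions equal argmax of prior x Gaussian density computed
        independently with scipy, on 100 random points."""
        X, y = _two_gaussians(rng, 300, 3, np.zeros(3), np.ones(3), s1=1.7)
        model = fit_qda(X, y)
        pts = rng.uniform(-3, 4, size=(100, 3))
        dens = np.column_stack([
            model.priors[k] * multivariate_normal(
                mean=model.means[k], cov=model.covariances[k]).pdf(pts)
            for k in range(2)
        ])
        expected = model.classes[np.argmax(dens, axis=1)]
        np.testing.assert_array_equal(predict_qda(model, pts), expected)

    def test_matches_sklearn_qda(self, rng):
        """Independent implementation agreement on well-separated data."""
        from sklearn.discriminant_analysis import (
            QuadraticDiscriminantAnalysis)
        X, y = _two_gaussians(rng, 400, 2, np.zeros(2), 2 * np.ones(2),
                              s1=1.5)
        model = fit_qda(X, y, regularization=0.0)
        sk = QuadraticDiscriminantAnalysis().fit(X, y)
        pts = rng.uniform(-3, 5, size=(200, 2))
        np.testing.assert_array_equal(predict_qda(model, pts),
                                      sk.predict(pts))


class TestMetrics:
    def test_formula_arithmetic(self):
        f = FoldCounts(tp=8, fn=2, tn=7, fp=3)
        assert f.error_pct == pytest.approx(25.0)
        res = EvalResult(folds=[f])
        assert res.sensitivity_pct == pytest.approx(80.0)
        assert res.specificity_pct == pytest.approx(70.0)
        assert res.accuracy_pct == pytest.approx(75.0)

    def test_accuracy_error_identity(self, rng):
        X, y = _two_gaussians(rng, 50, 2, np.zeros(2), np.ones(2))
        res = crossval_5fold(X, y, seed=3)
        assert res.accuracy_pct + res.mean_error_pct == pytest.approx(100.0)
        for v in (res.mean_error_pct, res.sensitivity_pct,
                  res.specificity_pct, res.accuracy_pct):
            assert 0.0 <= v <= 100.0


class TestCrossval:
    def test_perfect_separation(self, rng):
        X, y = _two_gaussians(rng, 100, 2, np.zeros(2), 50 * np.ones(2))
        res = crossval_5fold(X, y, seed=1)
        assert res.mean_error_pct == 0.0
        assert res.sensitivity_pct == 100.0
        assert res.specificity_pct == 100.0

    def test_fold_reproducibility(self, rng):
        X, y = _two_gaussians(rng, 60, 3, np.zeros(3), np.ones(3))
        r1 = crossval_5fold(X, y, seed=9)
        r2 = crossval_5fold(X, y, seed=9)
        assert r1.to_dict() == r2.to_dict()

    def test_too_few_samples_rejected(self, rng):
        X, y = _two_gaussians(rng, 4, 2, np.zeros(2), np.ones(2))
        with pytest.raises(ValueError, match="5 samples"):
            crossval_5fold(X, y)

    def test_shuffled_labels_give_chance(self):
        """Label permutation: mean error across 50 seeded runs must lie in
        the 99% binomial band around 50%."""
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 3))
            y = np.repeat([0, 1], 20)
            rng.shuffle(y)
            errors.append(crossval_5fold(X, y, seed=seed).mean_error_pct)
        n_total = 50 * 40
        half_width = 100 * 2.576 * np.sqrt(0.25 / n_total)
        assert np.mean(errors) == pytest.approx(50.0, abs=half_width)

    def test_bayes_consistency(self, rng):
        """N(0,1) vs N(2,1): Bayes accuracy is Phi(1) = 84.13%; CV accuracy
        at n=500/class must come within 3 points."""
        from scipy.stats import norm
        X, y = _two_gaussians(rng, 500, 1, np.array([0.0]), np.array([2.0]))
        res = crossval_5fold(X, y, seed=4)
        bayes = 100 * norm.cdf(1.0)
        assert res.accuracy_pct == pytest.approx(bayes, abs=3.0)
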