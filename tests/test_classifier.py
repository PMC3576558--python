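"""Mahalanobis discriminant classifier and leave-one-out harness."""

import numpy as np
import pytest

import swallowscreen as sw
from swallowscreen.classifier import SAFE, UNSAFE, regularize


def gaussian_classes(rng, n_per_class=50, dim=4, separation=4.0):
    """Two spherical Gaussian clouds separated along the first coordinate."""
    mu_u = np.zeros(dim)
    mu_u[0] = separation
    X = np.vstack(
        [rng.standard_normal((n_per_class, dim)), mu_u + rng.standard_normal((n_per_class, dim))]
    )
    y = np.array([SAFE] * n_per_class + [UNSAFE] * n_per_class)
    return X, y


def brute_force_label(x, X, y, gamma=0.1):
    """Independent nearest-class-by-Mahalanobis oracle: direct formula, no model object."""
    best, label = None, None
    for c in (SAFE, UNSAFE):
        m = X[y == c]
        mu = m.mean(axis=0)
        cov = np.cov(m, rowvar=False, ddof=1)
        d = cov.shape[0]
        cov = (1 - gamma) * cov + gamma * (np.trace(cov) / d) * np.eye(d)
        diff = x - mu
        dist = float(diff @ np.linalg.solve(cov, diff))
        if best is None or dist < best - 1e-9 or (abs(dist - best) <= 1e-9 and c == UNSAFE):
            best, label = dist, c
    return label


class TestMahalanobis:
    def test_zero_at_mean(self):
        mu = np.array([1.0, -2.0])
        assert sw.mahalanobis_sq(mu, mu, np.eye(2)) == 0.0

    def test_identity_reduces_to_euclidean(self):
        assert sw.mahalanobis_sq(np.array([3.0, 4.0]), np.zeros(2), np.eye(2)) == pytest.approx(25.0)

    def test_diagonal_hand_inverse(self):
        # 1/2 + 1/0.5 = 2.5
        d = sw.mahalanobis_sq(np.array([1.0, 1.0]), np.zeros(2), np.diag([2.0, 0.5]))
        assert d == pytest.approx(2.5)

    def test_singular_covariance_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            sw.mahalanobis_sq(np.ones(2), np.zeros(2), np.zeros((2, 2)))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sw.mahalanobis_sq(np.ones(3), np.zeros(2), np.eye(2))

    def test_affine_invariance(self, rng):
        dim = 5
        for _ in range(10):
            A = rng.standard_normal((dim, dim)) + dim * np.eye(dim)
            b = rng.standard_normal(dim)
            x, mu = rng.standard_normal(dim), rng.standard_normal(dim)
            C = rng.standard_normal((dim, dim))
            cov = C @ C.T + np.eye(dim)
            d1 = sw.mahalanobis_sq(x, mu, cov)
            d2 = sw.mahalanobis_sq(A @ x + b, A @ mu + b, A @ cov @ A.T)
            assert d2 == pytest.approx(d1, rel=1e-6)


class TestFit:
    def test_parameter_recovery(self, rng):
        n, dim, sep = 50, 4, 6.0
        X, y = gaussian_classes(rng, n, dim, sep)
        model = sw.fit_discriminant(X, y)
        se = 1.0 / np.sqrt(n)  # unit-variance generator
        assert np.all(np.abs(model.means[SAFE] - 0.0) < 3 * se)
        target = np.zeros(dim)
        target[0] = sep
        assert np.all(np.abs(model.means[UNSAFE] - target) < 3 * se)

    def test_full_shrinkage_gives_scaled_identity(self, rng):
        X, y = gaussian_classes(rng)
        model = sw.fit_discriminant(X, y, sw.ClassifierConfig(shrinkage=1.0))
        cov = model.covariances[SAFE]
        assert np.allclose(cov, cov[0, 0] * np.eye(cov.shape[0]))

    def test_absent_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="unsafe"):
            sw.fit_discriminant(X, np.array([SAFE] * 10))

    def test_singleton_class_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        y = np.array([SAFE] * 4 + [UNSAFE])
        with pytest.raises(ValueError, match="member"):
            sw.fit_discriminant(X, y)

    def test_zero_shrinkage_small_class_rejected(self, rng):
        X, y = gaussian_classes(rng, n_per_class=5, dim=4)
        with pytest.raises(ValueError, match="shrinkage required"):
            sw.fit_discriminant(X, y, sw.ClassifierConfig(shrinkage=0.0))

    def test_pooled_mode_shares_covariance(self, rng):
        X, y = gaussian_classes(rng)
        model = sw.fit_discriminant(X, y, sw.ClassifierConfig(covariance="pooled"))
        np.testing.assert_array_equal(model.covariances[SAFE], model.covariances[UNSAFE])

    def test_json_round_trip(self, rng, tmp_path):
        X, y = gaussian_classes(rng)
        model = sw.fit_discriminant(X, y, feature_names=[f"f{i}" for i in range(4)])
        model.to_json(tmp_path / "model.json")
        back = sw.DiscriminantModel.from_json(tmp_path / "model.json")
        x = rng.standard_normal(4)
        assert sw.classify(back, x).label == sw.classify(model, x).label
        np.testing.assert_allclose(back.means[SAFE], model.means[SAFE])


class TestClassify:
    def test_class_mean_classified_to_class(self, rng):
        X, y = gaussian_classes(rng)
        model = sw.fit_discriminant(X, y)
        assert sw.classify(model, model.means[UNSAFE]).label == UNSAFE
        assert sw.classify(model, model.means[SAFE]).label == SAFE

    def test_exact_tie_goes_unsafe(self):
        model = sw.DiscriminantModel(
            means={SAFE: np.array([-1.0, 0.0]), UNSAFE: np.array([1.0, 0.0])},
            covariances={SAFE: np.eye(2), UNSAFE: np.eye(2)},
            shrinkage=0.0,
        )
        r = sw.classify(model, np.array([0.0, 5.0]))
        assert r.d_safe == r.d_unsafe
        assert r.label == UNSAFE

    def test_agrees_with_brute_force_oracle(self, rng):
        X, y = gaussian_classes(rng, n_per_class=100, dim=4, separation=2.0)
        model = sw.fit_discriminant(X, y)
        test = rng.standard_normal((1000, 4)) * 2.0 + 1.0
        mismatch = sum(
            1
            for x in test
            if sw.classify(model, x).label != brute_force_label(x, X, y)
        )
        assert mismatch == 0


class TestLeaveOneOut:
    def test_structural(self, rng):
        X, y = gaussian_classes(rng, n_per_class=5, dim=2)
        keys = [(i,) for i in range(10)]
        results = sw.loo_evaluate(X, y, keys=keys)
        assert len(results) == 10
        assert sorted(r.key for r in results) == keys

    def test_separable_classes_fully_recovered(self, rng):
        X, y = gaussian_classes(rng, n_per_class=40, dim=3, separation=12.0)
        results = sw.loo_evaluate(X, y)
        assert all(r.label == y[i] for i, r in enumerate(results))

    def test_permuted_labels_give_chance_accuracy(self, rng):
        X, _ = gaussian_classes(rng, n_per_class=100, dim=3, separation=3.0)
        y = np.array([SAFE, UNSAFE] * 100)
        y = y[rng.permutation(200)]
        results = sw.loo_evaluate(X, y)
        acc = np.mean([r.label == y[i] for i, r in enumerate(results)])
        se = 0.5 / np.sqrt(200)
        assert abs(acc - 0.5) < 3 * se

    def test_order_invariance(self, rng):
        X, y = gaussian_classes(rng, n_per_class=20, dim=3, separation=1.0)
        keys = [(i,) for i in range(40)]
        r1 = {r.key: r.label for r in sw.loo_evaluate(X, y, keys=keys)}
        perm = rng.permutation(40)
        r2 = {r.key: r.label for r in sw.loo_evaluate(X[perm], y[perm], keys=[keys[i] for i in perm])}
        assert r1 == r2

    def test_fold_losing_a_class_flagged_untestable(self, rng, caplog):
        X = np.vstack([rng.standard_normal((8, 2)), [[5.0, 5.0], [5.1, 5.1]]])
        y = np.array([SAFE] * 8 + [UNSAFE] * 2)
        with caplog.at_level("WARNING", logger="swallowscreen"):
            results = sw.loo_evaluate(X, y)
        assert len(results) == 10  # nothing silently dropped
        assert sum(r.untestable for r in results) == 2
        assert any("untestable" in m for m in caplog.messages)

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            sw.loo_evaluate(np.zeros((2, 2)), np.array([SAFE, UNSAFE]))

    def test_monotone_degradation_with_separation(self):
        """LOO sensitivity must fall (allowing 1 inversion in 10 replicates)
        as class separation shrinks across {4, 2, 1, 0.5} standardized units."""
        separations = [4.0, 2.0, 1.0, 0.5]
        inversions = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            sens = []
            for sep in separations:
                X, y = gaussian_classes(rng, n_per_class=300, dim=4, separation=sep)
                results = sw.loo_evaluate(X, y)
                truth_unsafe = [i for i in range(len(y)) if y[i] == UNSAFE]
                tp = sum(results[i].label == UNSAFE for i in truth_unsafe)
                sens.append(tp / len(truth_unsafe))
            inversions += sum(1 for a, b in zip(sens, sens[1:]) if b > a + 1e-12)
        assert inversions <= 1


def test_regularized_covariance_positive_definite(rng):
    # near-singular raw covariance becomes SPD after shrinkage
    X = rng.standard_normal((6, 10))
    cov = np.cov(X, rowvar=False, ddof=1)  # rank-deficient
    reg = regularize(cov, 0.1)
    np.linalg.cholesky(reg)
    np.testing.assert_allclose(reg, reg.T)
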