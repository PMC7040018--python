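"""Tests of the PCA+LDA discriminator and the distance-ratio rule."""

import numpy as np
import pytest
from scipy import linalg
from sklearn.base import clone

from dropsig.discriminant import (
    PCALDAClassifier,
    centroid_trajectory,
    classify,
    fit_lda,
    fit_pca,
    ld_function_map,
)


def _two_clouds(rng, n_per=20, dim=5, shift=6.0, axis=None, scale=1.0):
    if axis is None:
        axis = np.zeros(dim)
        axis[0] = 1.0
    axis = axis / np.linalg.norm(axis)
    a = rng.normal(size=(n_per, dim)) * scale
    b = rng.normal(size=(n_per, dim)) * scale + shift * axis
    X = np.vstack([a, b])
    y = np.array([0] * n_per + [1] * n_per)
    return X, y, axis


def _brute_force_lda_direction(scores, y, ridge=1e-6):
    """Independent dense solve of inv(Sw_reg) @ Sb for the leading direction."""
    classes = np.unique(y)
    overall = scores.mean(axis=0)
    d = scores.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xc = scores[y == c]
        mc = Xc.mean(axis=0)
        Sw += (Xc - mc).T @ (Xc - mc)
        dm = (mc - overall)[:, None]
        Sb += len(Xc) * dm @ dm.T
    lam = ridge * np.trace(Sw) / d
    M = np.linalg.inv(Sw + lam * np.eye(d)) @ Sb
    vals, vecs = np.linalg.eig(M)
    lead = vecs[:, np.argmax(vals.real)].real
    return lead / np.linalg.norm(lead)


class TestFitPCA:
    def test_collinear_points_single_component(self, rng):
        t = rng.normal(size=30)
        X = np.outer(t, [1.0, 2.0, -1.0])
        model = fit_pca(X)
        assert model.explained_variance[0] / model.explained_variance.sum() > 1 - 1e-9

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(10, 6))
        model = fit_pca(X)
        scores_full = (X - model.mean) @ model.components.T
        recon = scores_full @ model.components + model.mean
        assert np.allclose(recon, X, atol=1e-8)

    def test_half_rule_on_six_samples(self, rng):
        model = fit_pca(rng.normal(size=(6, 10)))
        assert model.n_keep == 2  # floor(5 / 2)

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_pca(np.ones((5, 4)))

    def test_orthonormal_loadings(self, rng):
        model = fit_pca(rng.normal(size=(12, 8)))
        G = model.components @ model.components.T
        assert np.allclose(G, np.eye(G.shape[0]), atol=1e-8)


class TestFitLDA:
    def test_leading_direction_matches_displacement_axis(self, rng):
        # isotropic clouds, well separated: at large n the sample scatter is
        # near-identity and the discriminant aligns with the displacement
        axis = np.array([1.0, -2.0, 0.5, 0.0, 1.0])
        X, y, axis = _two_clouds(rng, n_per=400, shift=8.0, axis=axis)
        model = fit_lda(X, y)
        cos = abs(model.directions[0] @ axis)
        assert cos > 0.99

    def test_equal_means_give_no_separation(self, rng):
        X = rng.normal(size=(1000, 4))
        y = np.array([0, 1] * 500)
        model = fit_lda(X, y)
        sep = np.linalg.norm(model.centroids[0] - model.centroids[1])
        spread = model.training_projections.std()
        assert sep < 0.3 * spread

    def test_isotropic_within_scatter_closed_form(self, rng):
        # with Sw proportional to identity the discriminant is the
        # mean-difference direction itself
        X, y, _ = _two_clouds(rng, n_per=500, dim=2, shift=3.0, axis=np.array([1.0, 1.0]))
        model = fit_lda(X, y)
        diff = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        diff /= np.linalg.norm(diff)
        assert abs(model.directions[0] @ diff) > 0.99

    def test_matches_brute_force_generalised_eigensolve(self, rng):
        # oracle equivalence on small instances
        for trial in range(10):
            n_keep = int(rng.integers(2, 5))
            n = int(rng.integers(4, 9))
            y = np.array([0] * (n // 2) + [1] * (n - n // 2))
            X = rng.normal(size=(n, n_keep)) + 3.0 * y[:, None]
            model = fit_lda(X, y)
            oracle = _brute_force_lda_direction(X, y)
            assert abs(model.directions[0] @ oracle) > 1 - 1e-6

    def test_requires_two_samples_per_class(self, rng):
        X = rng.normal(size=(3, 4))
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_lda(X, np.array([0, 1, 1]))

    def test_unit_norm_and_deterministic_sign(self, rng):
        X, y, _ = _two_clouds(rng)
        model = fit_lda(X, y)
        assert np.allclose(np.linalg.norm(model.directions, axis=1), 1.0)
        for row in model.directions:
            assert row[np.argmax(np.abs(row))] > 0


class TestClassify:
    def test_sample_at_centroid_has_zero_ratio(self, rng):
        X, y, _ = _two_clouds(rng)
        model = fit_lda(X, y)
        # construct a score point projecting exactly onto centroid 0
        probe = np.linalg.lstsq(model.directions, model.centroids[0], rcond=None)[0]
        rep = classify(model, probe[None, :])
        assert rep.predictions[0] == model.classes[0]
        assert rep.distance_ratio[0] == pytest.approx(0.0, abs=1e-9)

    def test_equidistant_tie_goes_to_first_class_and_is_flagged(self, rng):
        X, y, _ = _two_clouds(rng)
        model = fit_lda(X, y)
        # force exactly symmetric centroids so the origin is a true tie
        model.centroids = np.array([[1.0, 0.0], [-1.0, 0.0]])
        rep = classify(model, np.zeros((1, X.shape[1])))
        assert rep.distance_ratio[0] == 1.0
        assert rep.predictions[0] == model.classes[0]
        assert rep.ties[0]

    def test_ratio_rule_equals_nearest_centroid(self, rng):
        X, y, _ = _two_clouds(rng, n_per=30)
        model = fit_lda(X, y)
        probes = rng.normal(size=(1000, X.shape[1])) * 4.0
        rep = classify(model, probes)
        proj = model.project(probes)
        d0 = np.linalg.norm(proj - model.centroids[0], axis=1)
        d1 = np.linalg.norm(proj - model.centroids[1], axis=1)
        nearest = np.where(d0 <= d1, model.classes[0], model.classes[1])
        assert np.array_equal(rep.predictions, nearest)

    def test_error_rate_invariant_under_relabelling(self, rng):
        X, y, _ = _two_clouds(rng, shift=2.0)
        m1 = fit_lda(X, y)
        m2 = fit_lda(X, 1 - y)
        e1 = classify(m1, X, truth=y).error_rate
        e2 = classify(m2, X, truth=1 - y).error_rate
        assert e1 == pytest.approx(e2)


class TestLDFunctionMap:
    def test_pc_axis_direction_recovers_loading(self, rng):
        X = rng.normal(size=(20, 2444))
        pca = fit_pca(X, n_keep=4)
        scores = pca.transform(X)
        y = np.array([0] * 10 + [1] * 10)
        model = fit_lda(scores, y)
        # replace LD1 with the first PC axis in score space
        model.directions[0] = np.eye(4)[0]
        m1, _ = ld_function_map(pca, model)
        assert np.allclose(m1.reshape(-1), pca.components[0], atol=1e-12)

    def test_back_projection_preserves_orthogonality(self, rng):
        X = rng.normal(size=(30, 2444))
        pca = fit_pca(X, n_keep=6)
        scores = pca.transform(X)
        y = np.array([0] * 15 + [1] * 15)
        model = fit_lda(scores, y)
        m1, m2 = ld_function_map(pca, model)
        back1 = pca.components[:6] @ m1.reshape(-1)
        back2 = pca.components[:6] @ m2.reshape(-1)
        assert np.isclose(back1 @ back2, model.directions[0] @ model.directions[1], atol=1e-8)


class TestCentroidTrajectory:
    def test_identical_clouds_coincide(self, rng):
        pts = rng.normal(size=(40, 2))
        proj = np.vstack([pts, pts])
        conds = np.array(["a"] * 40 + ["b"] * 40)
        cents = centroid_trajectory(proj, conds, order=["a", "b"])
        assert np.allclose(cents[0], cents[1])

    def test_monotone_effect_gives_monotone_ld1(self, rng):
        from scipy.stats import spearmanr

        conds, proj = [], []
        for i, c in enumerate(["c0", "c1", "c2"]):
            pts = rng.normal(size=(25, 2)) * 0.3 + np.array([2.0 * i, 0.0])
            proj.append(pts)
            conds += [c] * 25
        cents = centroid_trajectory(np.vstack(proj), np.array(conds), order=["c0", "c1", "c2"])
        rho, _ = spearmanr(np.arange(3), cents[:, 0])
        assert rho == 1.0

    def test_single_condition_single_centroid(self, rng):
        cents = centroid_trajectory(rng.normal(size=(10, 2)), np.array(["x"] * 10))
        assert cents.shape == (1, 2)

    def test_empty_condition_rejected(self, rng):
        with pytest.raises(ValueError, match="no samples"):
            centroid_trajectory(rng.normal(size=(4, 2)), np.array(["a"] * 4), order=["a", "b"])


class TestPCALDAClassifier:
    def test_scores_invariant_to_orthogonal_feature_rotation(self, rng):
        X, y, _ = _two_clouds(rng, dim=6)
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        e1 = PCALDAClassifier().fit(X, y).error_rate(X, y)
        e2 = PCALDAClassifier().fit(X @ Q, y).error_rate(X @ Q, y)
        assert e1 == pytest.approx(e2)

    def test_separable_data_classified_perfectly(self, rng):
        X, y, _ = _two_clouds(rng, shift=10.0)
        clf = PCALDAClassifier().fit(X, y)
        assert clf.error_rate(X, y) == 0.0
        assert clf.lda_.centroids.shape == (2, 2)

    def test_sklearn_protocol(self, rng):
        X, y, _ = _two_clouds(rng)
        clf = PCALDAClassifier(n_keep=3)
        assert clone(clf).get_params()["n_keep"] == 3
        clf.fit(X, y)
        assert clf.transform(X).shape == (len(y), 2)
        assert set(np.unique(clf.predict(X))) <= {0, 1}
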