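import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from cytomatch.matrix import CellMatrix
from cytomatch.tsne import (
    EmbeddingParams,
    SweepGrid,
    TSNEEmbedder,
    calibrate_bandwidths,
    exact_tsne,
    joint_probabilities,
    kl_and_grad,
    knn_purity,
    parameter_sweep,
    run_embedding,
    separability_scores,
)


def _two_clusters(rng, n_per=100, dim=5, sep=20.0):
    X = np.vstack(
        [rng.normal(0, 1, (n_per, dim)), rng.normal(sep, 1, (n_per, dim))]
    )
    labels = np.repeat([0, 1], n_per)
    return X, labels


class TestCalibration:
    def test_equidistant_points_uniform(self):
        """31 mutually equidistant points at target perplexity 30: symmetry
        forces the uniform conditional, whose perplexity is exactly 30."""
        n = 31
        d = np.ones((n, n)) - np.eye(n)
        sigmas, P = calibrate_bandwidths(d, perplexity=30, tol=1e-5)
        np.testing.assert_allclose(P[0, 1:], 1.0 / 30.0, rtol=1e-12)
        H = -np.sum(P[0, 1:] * np.log2(P[0, 1:]))
        assert 2.0**H == pytest.approx(30.0, abs=1e-9)

    def test_achieved_perplexity_within_tol(self, rng):
        X = rng.standard_normal((100, 10))
        d = squareform(pdist(X))
        _, P = calibrate_bandwidths(d, perplexity=30, tol=1e-5)
        # independent recomputation of 2^H from the returned similarities
        logP = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0)), 0.0)
        H = -np.sum(P * logP, axis=1)
        assert np.max(np.abs(2.0**H - 30.0)) <= 1e-5 + 1e-9
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diag(P) == 0)

    def test_perplexity_exceeds_n(self, rng):
        X = rng.standard_normal((50, 3))
        d = squareform(pdist(X))
        with pytest.raises(ValueError):
            calibrate_bandwidths(d, perplexity=100)

    def test_joint_probabilities_symmetric_normalised(self, rng):
        X = rng.standard_normal((40, 4))
        d = squareform(pdist(X))
        _, cond = calibrate_bandwidths(d, perplexity=10)
        P = joint_probabilities(cond)
        np.testing.assert_allclose(P, P.T, atol=1e-15)
        assert P.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(P >= 0)


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self, rng):
        """n=3 KL gradient vs central differences, rel. error < 1e-4."""
        Y = rng.normal(size=(3, 2))
        M = rng.random((3, 3))
        P = M + M.T
        np.fill_diagonal(P, 0.0)
        P /= P.sum()
        _, grad = kl_and_grad(Y, P)
        num = np.zeros_like(grad)
        eps = 1e-6
        for i in range(3):
            for j in range(2):
                yp, ym = Y.copy(), Y.copy()
                yp[i, j] += eps
                ym[i, j] -= eps
                num[i, j] = (kl_and_grad(yp, P)[0] - kl_and_grad(ym, P)[0]) / (2 * eps)
        rel = np.max(np.abs(grad - num)) / np.max(np.abs(num))
        assert rel < 1e-4


class TestExactTSNE:
    def test_separates_distant_clusters(self, rng):
        X, labels = _two_clusters(rng)
        res = exact_tsne(X, EmbeddingParams(perplexity=30, n_iter=600, seed=0))
        assert knn_purity(res.coords, labels) >= 0.99

    def test_shape_and_finiteness(self, rng):
        X = rng.standard_normal((60, 4))
        res = exact_tsne(X, EmbeddingParams(perplexity=10, n_iter=100, seed=1))
        assert res.coords.shape == (60, 2)
        assert np.all(np.isfinite(res.coords))
        assert res.final_objective >= 0

    def test_kl_decreases_from_initialization(self, rng):
        X, _ = _two_clusters(rng, n_per=50)
        short = exact_tsne(X, EmbeddingParams(perplexity=15, n_iter=1, seed=3))
        long = exact_tsne(X, EmbeddingParams(perplexity=15, n_iter=400, seed=3))
        assert long.final_objective < short.final_objective

    def test_duplicate_rows_jittered(self):
        X = np.zeros((12, 3))
        res = exact_tsne(X, EmbeddingParams(perplexity=5, n_iter=50, seed=0))
        assert np.all(np.isfinite(res.coords))

    def test_nan_input_rejected(self):
        X = np.full((10, 2), np.nan)
        with pytest.raises(ValueError):
            exact_tsne(X, EmbeddingParams(perplexity=3, n_iter=10))

    def test_cap_enforced(self, rng):
        X = rng.standard_normal((30, 2))
        with pytest.raises(ValueError, match="approximate"):
            exact_tsne(X, EmbeddingParams(perplexity=5, n_iter=10), exact_cap=20)


class TestRunEmbedding:
    def test_backends_agree_on_separability(self, rng):
        """Exact reference vs scikit-learn's exact method: 1-NN truth purity
        within 0.02 of each other on a 5-cluster problem."""
        centers = rng.normal(0, 5, (5, 8))
        labels = rng.integers(0, 5, 600)
        X = centers[labels] + rng.normal(0, 0.5, (600, 8))
        ours = run_embedding(X, EmbeddingParams(n_iter=500, seed=9), backend="exact")
        theirs = run_embedding(
            X, EmbeddingParams(n_iter=500, seed=9, theta=0.0), backend="approximate"
        )
        p1 = knn_purity(ours.coords, labels)
        p2 = knn_purity(theirs.coords, labels)
        assert abs(p1 - p2) < 0.02

    def test_theta_recorded(self, rng):
        X = rng.standard_normal((120, 3))
        res = run_embedding(X, EmbeddingParams(n_iter=260, theta=0.8, seed=0))
        assert res.params.theta == 0.8

    def test_single_iteration_finite(self, rng):
        X = rng.standard_normal((50, 3))
        res = run_embedding(
            X, EmbeddingParams(perplexity=10, n_iter=1, seed=0), backend="exact"
        )
        assert np.all(np.isfinite(res.coords))

    def test_estimator_interface(self, rng):
        X, labels = _two_clusters(rng, n_per=60, dim=4)
        est = TSNEEmbedder(perplexity=20, n_iter=300, backend="exact", random_state=4)
        Y = est.fit_transform(X)
        assert Y.shape == (120, 2)
        assert est.kl_divergence_ >= 0
        assert est.get_params()["perplexity"] == 20

    def test_params_validation(self):
        with pytest.raises(ValueError):
            EmbeddingParams(perplexity=-1)
        with pytest.raises(ValueError):
            EmbeddingParams(theta=1.5)


def test_island_positions_vary_but_separability_is_stable(rng):
    """Different seeds place the same populations in different parts of the
    map, yet the populations stay equally well separated."""
    X, labels = _two_clusters(rng, n_per=80, dim=4)
    a = run_embedding(X, EmbeddingParams(perplexity=20, n_iter=400, seed=1),
                      backend="exact")
    b = run_embedding(X, EmbeddingParams(perplexity=20, n_iter=400, seed=2),
                      backend="exact")
    assert not np.allclose(a.coords, b.coords, atol=1e-3)
    assert knn_purity(a.coords, labels) >= 0.99
    assert knn_purity(b.coords, labels) >= 0.99


class TestQualityMetrics:
    def test_rigid_motion_invariance(self, rng):
        """Separability metrics are unchanged by rotation/reflection."""
        coords = rng.normal(size=(200, 2))
        labels = rng.integers(0, 3, 200)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        flipped = coords @ R.T * np.array([1, -1])
        a = separability_scores(coords, labels)
        b = separability_scores(flipped, labels)
        assert a["knn_purity"] == pytest.approx(b["knn_purity"])
        assert a["silhouette"] == pytest.approx(b["silhouette"], abs=1e-9)


class TestSweep:
    def test_grid_bookkeeping(self, rng):
        X, labels = _two_clusters(rng, n_per=60, dim=3)
        grid = SweepGrid(perplexities=(5, 15), n_iters=(260,), thetas=(0.5, 0.8),
                         repeats=2)
        report = parameter_sweep(X, grid, labels,
                                 base_params=EmbeddingParams(seed=5))
        assert len(report) == 2 * 1 * 2 * 2
        assert report["seed"].nunique() == len(report)
        assert set(report.columns) >= {
            "perplexity", "n_iter", "theta", "repeat", "seed", "kl",
            "silhouette", "knn_purity",
        }

    def test_single_point_grid(self, rng):
        X, labels = _two_clusters(rng, n_per=50, dim=3)
        grid = SweepGrid(perplexities=(10,), n_iters=(260,), thetas=(0.5,))
        report = parameter_sweep(X, grid, labels,
                                 base_params=EmbeddingParams(seed=2))
        assert len(report) == 1
        direct = run_embedding(
            X,
            EmbeddingParams(perplexity=10, n_iter=260, theta=0.5,
                            seed=int(report["seed"].iloc[0])),
        )
        assert report["kl"].iloc[0] == pytest.approx(direct.final_objective)

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            SweepGrid(perplexities=())
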