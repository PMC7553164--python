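"""Unit and property tests for the locality-weighted metric."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from bcd.containers import FeatureMatrix
from bcd.metric import (
    BatchDesign,
    DegenerateDesignError,
    WhiteningError,
    KNNDistances,
    bcd_distance,
    bcd_distance_squared,
    compute_batch_centroids,
    compute_corrected_covariance,
    compute_locality_weights,
    pairwise_bcd,
    whiten,
)

from conftest import sigma_two_loop, random_instance


def make_design(batch_index, labels, length_scale=1.0):
    batch_index = np.asarray(batch_index)
    B = batch_index.max() + 1
    return BatchDesign(
        batch_index=batch_index,
        batch_ids=np.array([f"b{j}" for j in range(B)], dtype=object),
        batch_labels=np.atleast_2d(np.asarray(labels, dtype=float)).reshape(B, -1),
        length_scale=length_scale,
    )


class TestLocalityWeights:
    def test_closed_forms(self):
        # two batches one day apart, unit length scale
        design = make_design([0, 1], [[0.0], [1.0]], length_scale=1.0)
        W = compute_locality_weights(design).W
        # own batch: zero label distance -> weight exactly 1
        assert W[0, 0] == 1.0 and W[1, 1] == 1.0
        # unit label distance at l=1: independent scalar evaluation
        assert W[0, 1] == pytest.approx(math.exp(-0.5), abs=1e-12)
        assert W[0, 1] == pytest.approx(0.606531, abs=1e-6)

    def test_large_length_scale_recovers_uniform_weights(self):
        design = make_design([0, 1, 2], [[0.0], [5.0], [9.0]], length_scale=1e6)
        W = compute_locality_weights(design).W
        assert np.all(W > 1 - 1e-9)

    def test_vector_labels(self):
        # concatenated [week, location] labels use one Euclidean norm
        design = make_design([0, 1], [[11.5, 0.0], [11.5, 2.0]], length_scale=2.0)
        W = compute_locality_weights(design).W
        assert W[0, 1] == pytest.approx(math.exp(-4.0 / (2 * 4.0)))

    def test_monotone_in_distance_and_length_scale(self):
        dists = np.linspace(0.1, 5.0, 20)
        for l in (0.5, 1.0, 3.0):
            w = np.exp(-(dists**2) / (2 * l**2))
            design = make_design(
                np.arange(len(dists) + 1),
                np.concatenate([[0.0], dists])[:, None],
                length_scale=l,
            )
            W = compute_locality_weights(design).W
            # W of the reference batch (label 0) against increasing gaps
            row = W[0, 1:]
            assert np.allclose(row, w)
            assert np.all(np.diff(row) < 0), "strictly decreasing in distance"
        # increasing in l at fixed nonzero distance
        ws = []
        for l in (0.5, 1.0, 2.0, 4.0):
            design = make_design([0, 1], [[0.0], [2.0]], length_scale=l)
            ws.append(compute_locality_weights(design).W[0, 1])
        assert np.all(np.diff(ws) > 0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        gap=st.floats(0, 30),
        l=st.floats(0.01, 100),
    )
    def test_kernel_range_property(self, gap, l):
        # W always lies in (0, 1] and hits 1 exactly at zero label gap
        design = make_design([0, 1], [[0.0], [gap]], length_scale=l)
        W = compute_locality_weights(design).W
        assert 0 < W[0, 1] <= 1
        if gap == 0.0:
            assert W[0, 1] == 1.0
        elif gap >= 1e-6 * l:  # below this the exponent underflows to 0
            assert W[0, 1] < 1.0

    def test_parameter_errors(self):
        with pytest.raises(ValueError, match="length_scale"):
            make_design([0, 1], [[0.0], [1.0]], length_scale=0.0)
        with pytest.raises(ValueError):
            BatchDesign(
                batch_index=np.array([0, 1]),
                batch_ids=np.array(["a", "b"], dtype=object),
                batch_labels=np.array([[0.0, 1.0]]),  # one label row for two batches
            )


class TestCentroids:
    def test_trivial_cases(self):
        design = make_design([0], [[0.0]])
        x = np.array([[3.0, -1.0]])
        assert np.allclose(compute_batch_centroids(x, design), x)
        design = make_design([0, 0], [[0.0]])
        m = compute_batch_centroids(np.array([[0.0, 0.0], [2.0, 2.0]]), design)
        assert np.allclose(m, [[1.0, 1.0]])

    def test_matches_naive_loop(self, rng):
        X, design = random_instance(rng, n=40, B=3, k=4)
        m = compute_batch_centroids(X, design)
        for j in range(3):
            assert np.allclose(m[j], X[design.batch_index == j].mean(axis=0))

    def test_empty_batch_rejected(self):
        design = BatchDesign(
            batch_index=np.array([0, 0]),
            batch_ids=np.array(["a", "b"], dtype=object),
            batch_labels=np.array([[0.0], [1.0]]),
        )
        with pytest.raises(ValueError, match="zero cells"):
            compute_batch_centroids(np.zeros((2, 2)), design)


class TestCorrectedCovariance:
    def test_hand_example_two_singleton_batches(self):
        # 1-D cells at 0 and 2 in their own batches, W == 1:
        # Sigma~ = (0-2)^2 + (2-0)^2 = 8
        X = np.array([[0.0], [2.0]])
        design = make_design([0, 1], [[0.0], [0.0]])  # same label -> W == 1
        cov = compute_corrected_covariance(X, design, ridge=0.0)
        assert cov.sigma_tilde == pytest.approx(np.array([[8.0]]))

    def test_matches_two_loop_oracle(self, rng):
        for _ in range(5):
            X, design = random_instance(rng, n=50, B=4, k=5)
            W = compute_locality_weights(design).W
            cov = compute_corrected_covariance(X, design, ridge=0.0)
            oracle = sigma_two_loop(X, design.batch_index, W)
            assert np.abs(cov.sigma_tilde - oracle).max() < 1e-10

    def test_uniform_weights_give_unweighted_between_batch_scatter(self, rng):
        # W == 1 reduces to the unweighted alternative-clustering scatter
        X, design = random_instance(rng, n=30, B=3, k=4)
        design.length_scale = 1e9  # effectively W == 1
        cov = compute_corrected_covariance(X, design, ridge=0.0)
        ones = np.ones((30, 3))
        oracle = sigma_two_loop(X, design.batch_index, ones)
        assert np.allclose(cov.sigma_tilde, oracle, atol=1e-8)

    def test_normalize_option_rescales_only(self, rng):
        X, design = random_instance(rng, n=30, B=3, k=4)
        raw = compute_corrected_covariance(X, design, ridge=0.0)
        norm = compute_corrected_covariance(X, design, ridge=0.0, normalize=True)
        total_w = 0.0
        W = compute_locality_weights(design).W
        for j in range(3):
            total_w += W[design.batch_index != j, j].sum()
        assert np.allclose(norm.sigma_tilde * total_w, raw.sigma_tilde)

    def test_zero_scatter_needs_ridge(self):
        # all batches are point masses at the same location -> Sigma~ = 0
        X = np.zeros((4, 3))
        design = make_design([0, 0, 1, 1], [[0.0], [1.0]])
        with pytest.raises(WhiteningError, match="eigenvalue"):
            compute_corrected_covariance(X, design, ridge=0.0)
        cov = compute_corrected_covariance(X, design, ridge=4.0)
        assert np.allclose(cov.sigma_tilde, 0.0)
        assert np.allclose(cov.whitener, np.eye(3) / 2.0)

    def test_single_batch_rejected_with_guidance(self):
        X = np.zeros((3, 2))
        design = make_design([0, 0, 0], [[0.0]])
        with pytest.raises(DegenerateDesignError, match="Euclidean"):
            compute_corrected_covariance(X, design)

    def test_auto_ridge_is_scale_aware(self, rng):
        X, design = random_instance(rng, n=40, B=3, k=4)
        cov = compute_corrected_covariance(X, design, ridge="auto")
        expected = 1e-6 * np.trace(cov.sigma_tilde) / 4
        assert cov.ridge == pytest.approx(expected)

    def test_runtime_grows_gently_with_n(self, rng):
        # O(n k^2 + k^3): doubling n at fixed k should not blow up the cost
        import time

        def timed(n):
            X, design = random_instance(rng, n=n, B=5, k=10)
            t0 = time.perf_counter()
            compute_corrected_covariance(X, design, ridge=0.0)
            return time.perf_counter() - t0

        timed(1000)  # warm-up
        t1 = min(timed(2000) for _ in range(3))
        t2 = min(timed(8000) for _ in range(3))
        assert t2 < 50 * max(t1, 1e-4), "covariance cost is not near-linear in n"


class TestWhitening:
    def test_identity_covariance_is_noop(self):
        X = FeatureMatrix(np.arange(6, dtype=float).reshape(3, 2))
        cov = compute_corrected_covariance(
            np.zeros((4, 2)), make_design([0, 0, 1, 1], [[0.0], [1.0]]), ridge=1.0
        )
        out = whiten(X, cov)
        assert np.allclose(out.values, X.values)

    def test_scalar_cholesky(self):
        # Sigma~ + ridge = 4 in 1-D -> whitener 1/2, points {0, 2} -> {0, 1}
        design = make_design([0, 1], [[0.0], [1.0]])
        cov = compute_corrected_covariance(np.zeros((2, 1)), design, ridge=4.0)
        assert cov.whitener[0, 0] == pytest.approx(0.5)
        out = whiten(np.array([[0.0], [2.0]]), cov)
        assert np.allclose(out.values, [[0.0], [1.0]])

    def test_whitened_euclidean_equals_mahalanobis(self, rng):
        # oracle: explicit matrix inversion of Sigma~ + ridge I
        for _ in range(5):
            X, design = random_instance(rng, n=30, B=4, k=5)
            cov = compute_corrected_covariance(X, design, ridge=1e-3)
            white = whiten(X, cov).values
            A_inv = np.linalg.inv(cov.regularized)
            D_white = squareform(pdist(white))
            n = X.shape[0]
            for i in range(0, n, 7):
                for j in range(0, n, 5):
                    d = X[i] - X[j]
                    expected = np.sqrt(d @ A_inv @ d)
                    assert D_white[i, j] == pytest.approx(expected, rel=1e-8, abs=1e-10)

    def test_whitener_whitens_sigma(self, rng):
        X, design = random_instance(rng, n=60, B=4, k=6)
        cov = compute_corrected_covariance(X, design)
        T = cov.whitener
        assert np.allclose(T @ cov.regularized @ T.T, np.eye(6), atol=1e-8)

    def test_dimension_mismatch(self, rng):
        X, design = random_instance(rng, n=20, B=2, k=3)
        cov = compute_corrected_covariance(X, design)
        with pytest.raises(ValueError, match="whitener expects"):
            whiten(np.zeros((5, 4)), cov)


class TestBCDDistance:
    @pytest.fixture
    def cov(self, rng):
        X, design = random_instance(rng, n=40, B=4, k=5)
        return compute_corrected_covariance(X, design, ridge=1e-3)

    def test_zero_self_distance(self, cov, rng):
        x = rng.normal(size=5)
        assert bcd_distance(x, x, cov) == 0.0

    def test_identity_covariance_is_euclidean(self):
        X = np.zeros((4, 3))
        design = make_design([0, 0, 1, 1], [[0.0], [1.0]])
        cov = compute_corrected_covariance(X, design, ridge=1.0)
        a, b = np.array([1.0, 2.0, 2.0]), np.array([1.0, 0.0, 0.0])
        assert bcd_distance(a, b, cov) == pytest.approx(np.sqrt(8.0))

    def test_consistent_with_whitening(self, cov, rng):
        for _ in range(20):
            a, b = rng.normal(size=(2, 5))
            za = cov.whitener @ a
            zb = cov.whitener @ b
            assert bcd_distance(a, b, cov) == pytest.approx(
                np.linalg.norm(za - zb), rel=1e-8
            )

    def test_squared_form_accessor(self, cov, rng):
        a, b = rng.normal(size=(2, 5))
        assert bcd_distance(a, b, cov) ** 2 == pytest.approx(
            bcd_distance_squared(a, b, cov), rel=1e-10
        )

    def test_metric_axioms_on_random_triples(self, cov, rng):
        for _ in range(300):
            a, b, c = rng.normal(size=(3, 5)) * rng.uniform(0.1, 10)
            dab = bcd_distance(a, b, cov)
            dba = bcd_distance(b, a, cov)
            dac = bcd_distance(a, c, cov)
            dbc = bcd_distance(b, c, cov)
            assert dab == dba
            assert dab >= 0
            assert dac <= dab + dbc + 1e-9


class TestPairwise:
    def test_identical_cells(self):
        X = np.ones((2, 3))
        design = make_design([0, 1], [[0.0], [1.0]])
        cov = compute_corrected_covariance(X, design, ridge=1.0)
        D = pairwise_bcd(X, cov, mode="full")
        assert np.allclose(D, 0.0)

    def test_full_matches_pairwise_loop(self, rng):
        X, design = random_instance(rng, n=20, B=3, k=4)
        cov = compute_corrected_covariance(X, design, ridge=1e-3)
        D = pairwise_bcd(X, cov, mode="full")
        assert D.shape == (20, 20)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0.0)
        for i in range(20):
            for j in range(20):
                assert D[i, j] == pytest.approx(
                    bcd_distance(X[i], X[j], cov), abs=1e-10
                )

    def test_knn_matches_full_argsort(self, rng):
        X, design = random_instance(rng, n=50, B=4, k=5)
        cov = compute_corrected_covariance(X, design, ridge=1e-3)
        D = pairwise_bcd(X, cov, mode="full")
        knn = pairwise_bcd(X, cov, mode="knn", k_neighbors=5)
        assert isinstance(knn, KNNDistances)
        for i in range(50):
            row = D[i].copy()
            row[i] = np.inf
            expected = np.argsort(row, kind="stable")[:5]
            assert np.array_equal(knn.indices[i], expected)

    def test_knn_parameter_error(self, rng):
        X, design = random_instance(rng, n=10, B=2, k=3)
        cov = compute_corrected_covariance(X, design, ridge=1e-3)
        with pytest.raises(ValueError, match="k_neighbors"):
            pairwise_bcd(X, cov, mode="knn", k_neighbors=10)


def test_suppression_of_between_batch_direction():
    """Whitening shrinks the axis separating two proximal batches.

    Two batches whose centroids differ only along axis 0, with
    within-batch variance only along axis 1: after whitening, the
    between-centroid separation along axis 0 shrinks relative to the
    within-batch spread along axis 1.
    """
    rng = np.random.default_rng(7)
    n = 200
    axis1 = rng.normal(0, 1, size=(2 * n,))
    X = np.zeros((2 * n, 2))
    X[:, 1] = axis1
    X[n:, 0] += 4.0  # batch offset along axis 0
    design = make_design([0] * n + [1] * n, [[0.0], [0.0]])
    cov = compute_corrected_covariance(X, design)
    white = whiten(X, cov).values

    def ratio(M):
        sep = abs(M[n:, 0].mean() - M[:n, 0].mean())
        spread = M[:, 1].std()
        return sep / spread

    assert ratio(white) < 0.5 * ratio(X)  # clearly, not marginally, suppressed
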