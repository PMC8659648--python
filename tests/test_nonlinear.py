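"""Tests for the geometry-based estimators on manifolds of known dimension,
plus the shared invariances (translation/rotation/scale) and the exhaustive
neighbor-search oracle."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import special_ortho_group

from manifolddim import (
    correlation_dimension,
    fisher_separability_dimension,
    lbmle,
    two_nn,
)
from manifolddim.nonlinear import drop_duplicate_points, kneighbor_distances


def embed(points, ambient_dim, seed=0):
    """Embed a low-dim cloud into ambient_dim via a random orthonormal map."""
    rng = np.random.default_rng(seed)
    Q = np.linalg.qr(rng.standard_normal((ambient_dim, points.shape[1])))[0]
    return points @ Q.T


@pytest.fixture(scope="module")
def clouds():
    rng = np.random.default_rng(7)
    return {
        "circle_in_3d": np.column_stack(
            [np.cos(u := rng.uniform(0, 2 * np.pi, 2000)), np.sin(u), np.zeros(2000)]
        ),
        "square_in_5d": embed(rng.random((2000, 2)), 5, seed=1),
        "line_in_3d": embed(rng.random((2000, 1)), 3, seed=2),
        "gauss5": rng.standard_normal((2000, 5)),
        "cube2_5000": rng.random((5000, 2)),
        "cube6_in_96d": embed(rng.random((5000, 6)), 96, seed=3),
        "sphere6_in_96d": embed(
            (x := rng.standard_normal((5000, 6)))
            / np.linalg.norm(x, axis=1, keepdims=True),
            96,
            seed=4,
        ),
    }


class TestCorrelationDimension:
    def test_circle(self, clouds):
        assert abs(correlation_dimension(clouds["circle_in_3d"]).value - 1) < 0.15

    def test_square(self, clouds):
        assert abs(correlation_dimension(clouds["square_in_5d"]).value - 2) < 0.3

    def test_scale_invariance(self, clouds):
        a = correlation_dimension(clouds["square_in_5d"]).value
        b = correlation_dimension(clouds["square_in_5d"] * 37.5).value
        assert a == pytest.approx(b, rel=1e-9)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            correlation_dimension(np.ones((200, 3)))


class TestLBMLE:
    def test_line(self, clouds):
        assert abs(lbmle(clouds["line_in_3d"]).value - 1) < 0.2

    def test_gaussian_5d(self, clouds):
        assert abs(lbmle(clouds["gauss5"]).value - 5) < 0.5

    def test_recovers_d_on_noise_free_linear(self, linear_ds_small):
        assert abs(lbmle(linear_ds_small.observed).value - 6) < 0.5

    def test_duplicate_warning(self, rng):
        pts = rng.random((300, 4))
        data = np.vstack([pts, pts[:30]])  # 10% duplicates
        with pytest.warns(UserWarning, match="duplicate"):
            lbmle(data)

    def test_k_range_validation(self, clouds):
        with pytest.raises(ValueError):
            lbmle(clouds["gauss5"], k1=10, k2=10)


class TestTwoNN:
    def test_square_2d(self, clouds):
        assert abs(two_nn(clouds["cube2_5000"]).value - 2) < 0.2

    def test_cube6_embedded(self, clouds):
        assert abs(two_nn(clouds["cube6_in_96d"]).value - 6) < 0.7

    def test_discard_fraction_validation(self, clouds):
        with pytest.raises(ValueError):
            two_nn(clouds["cube2_5000"], discard_fraction=0.6)


class TestFSA:
    def test_sphere6(self, clouds):
        assert abs(fisher_separability_dimension(clouds["sphere6_in_96d"]).value - 6) < 0.6

    def test_near_line(self, rng):
        data = np.outer(np.linspace(0, 1, 2000), rng.standard_normal(5))
        data += 1e-3 * rng.standard_normal(data.shape)
        assert abs(fisher_separability_dimension(data).value - 1) < 0.3

    def test_ball_calibration_runs_low(self, clouds):
        sphere = fisher_separability_dimension(
            clouds["sphere6_in_96d"], calibration="sphere"
        ).value
        ball = fisher_separability_dimension(
            clouds["sphere6_in_96d"], calibration="ball"
        ).value
        assert ball < sphere

    def test_alpha_validation(self, clouds):
        with pytest.raises(ValueError):
            fisher_separability_dimension(clouds["gauss5"], alpha_sep=1.5)


class TestSharedInvariances:
    @pytest.mark.parametrize(
        "estimator",
        [correlation_dimension, lbmle, two_nn, fisher_separability_dimension],
        ids=["CD", "LBMLE", "TNN", "FSA"],
    )
    def test_translation_rotation_scale_invariance(self, estimator, rng):
        pts = rng.random((600, 3))
        data = embed(pts, 8, seed=5)
        base = estimator(data).value
        R = special_ortho_group.rvs(8, random_state=11)
        transformed = (data @ R) * 3.2 + rng.standard_normal(8)
        moved = estimator(transformed).value
        assert moved == pytest.approx(base, rel=0.05)

    def test_monotone_in_dimension(self, rng):
        # uniform hypercubes: every estimator's output non-decreasing in d
        dims = [1, 2, 4, 6, 8]
        data = {d: rng.random((2000, d)) for d in dims}
        for est in (lbmle, two_nn, fisher_separability_dimension):
            vals = [est(data[d]).value for d in dims]
            assert all(b >= a - 0.05 for a, b in zip(vals, vals[1:])), (est, vals)


class TestNeighborOracle:
    def test_matches_exhaustive_distances(self, rng):
        # accelerated neighbor path must agree exactly with brute-force
        # pairwise distances at small M
        pts = rng.standard_normal((150, 10))
        pts, removed = drop_duplicate_points(pts)
        assert removed == 0
        got = kneighbor_distances(pts, 12)
        full = cdist(pts, pts)
        np.fill_diagonal(full, np.inf)
        expected = np.sort(full, axis=1)[:, :12]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_duplicate_removal_counts(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [2.0, 0.0]])
        uniq, removed = drop_duplicate_points(pts)
        assert removed == 1
        assert uniq.shape == (3, 2)
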