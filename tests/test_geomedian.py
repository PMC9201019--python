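"""Weighted geometric median: operators, solver, and robustness properties."""

import numpy as np
import pandas as pd
import pytest

from metabreduce import (
    GeometricMedian,
    MetaboliteTable,
    WeightedPointSet,
    geometric_median,
    objective_C,
    preprocess,
    split_regions,
)
from metabreduce.geomedian import (
    modified_step,
    r_tilde,
    reduce_region_mwa,
    weiszfeld_T,
)
from metabreduce.errors import CoincidenceError, DomainError
from oracles import geometric_median_oracle, in_convex_hull, objective_sum_dist

TRIANGLE = WeightedPointSet(np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]]))


# ---------------------------------------------------------------- objective
@pytest.mark.parametrize(
    "y, X, eta, expected",
    [
        ([0.0, 0.0], [[3.0, 4.0]], [1.0], 5.0),           # 3-4-5 triangle
        ([1.0, 2.0], [[1.0, 2.0]], [1.0], 0.0),           # coincidence
        ([0.0], [[-1.0], [1.0]], [2.0, 3.0], 5.0),        # 1-D weighted
    ],
)
def test_objective_examples(y, X, eta, expected):
    points = WeightedPointSet(np.array(X), np.array(eta))
    assert objective_C(np.array(y), points) == pytest.approx(expected, abs=1e-12)


def test_objective_dimension_mismatch():
    with pytest.raises(DomainError):
        objective_C(np.zeros(3), TRIANGLE)


# ------------------------------------------------------------- Weiszfeld T
def test_weiszfeld_symmetric_fixed_point():
    points = WeightedPointSet(np.array([[0.0], [10.0]]))
    np.testing.assert_allclose(weiszfeld_T(np.array([5.0]), points), [5.0])


def test_weiszfeld_matches_direct_formula():
    y = np.array([1.0, 1.0])
    d = np.linalg.norm(TRIANGLE.X - y, axis=1)
    expected = (TRIANGLE.X / d[:, None]).sum(axis=0) / (1.0 / d).sum()
    np.testing.assert_allclose(weiszfeld_T(y, TRIANGLE), expected, atol=1e-14)


def test_weiszfeld_output_in_convex_hull(rng):
    for _ in range(25):
        X = rng.normal(size=(rng.integers(2, 8), rng.integers(1, 5)))
        y = rng.normal(size=X.shape[1]) * 3
        points = WeightedPointSet(X, rng.uniform(0.5, 2.0, len(X)))
        assert in_convex_hull(weiszfeld_T(y, points), X)


def test_weiszfeld_raises_on_coincidence():
    with pytest.raises(CoincidenceError):
        weiszfeld_T(np.array([0.0, 0.0]), TRIANGLE)


# ------------------------------------------------------------------ r_tilde
def test_r_tilde_unit_directions():
    points = WeightedPointSet(np.array([[4.0, 0.0], [0.0, 3.0]]))
    R = r_tilde(np.zeros(2), points)
    np.testing.assert_allclose(R, [1.0, 1.0], atol=1e-14)
    assert np.linalg.norm(R) == pytest.approx(np.sqrt(2))


def test_r_tilde_points_toward_data(rng):
    X = rng.normal(size=(6, 3))
    y = X.mean(axis=0) + 10.0
    points = WeightedPointSet(X)
    assert r_tilde(y, points) @ (X.mean(axis=0) - y) > 0


def test_r_tilde_is_negative_gradient(rng):
    for _ in range(10):
        X = rng.normal(size=(5, 3))
        eta = rng.uniform(0.5, 2.0, 5)
        points = WeightedPointSet(X, eta)
        y = rng.normal(size=3) * 2
        h = 1e-7
        grad = np.array(
            [
                (objective_C(y + h * e, points) - objective_C(y - h * e, points))
                / (2 * h)
                for e in np.eye(3)
            ]
        )
        np.testing.assert_allclose(r_tilde(y, points), -grad, atol=1e-6)


# ------------------------------------------------------------ modified step
def test_modified_step_equals_weiszfeld_off_data(rng):
    for _ in range(20):
        X = rng.normal(size=(6, 4))
        points = WeightedPointSet(X, rng.uniform(0.5, 2.0, 6))
        y = rng.normal(size=4) * 2
        np.testing.assert_allclose(
            modified_step(y, points), weiszfeld_T(y, points), atol=1e-12
        )


def test_modified_step_dominant_vertex_is_fixed():
    points = WeightedPointSet(TRIANGLE.X, np.array([10.0, 1.0, 1.0]))
    out = modified_step(np.zeros(2), points)
    np.testing.assert_array_equal(out, [0.0, 0.0])  # psi capped at 1


def test_modified_step_hand_evaluation_at_vertex():
    # unit weights at (0,0): eta(y)=1, r=sqrt(2), psi=1/sqrt(2);
    # T~ over the two non-coincident points
    y = np.zeros(2)
    psi = 1.0 / np.sqrt(2.0)
    w = np.array([1.0 / 4.0, 1.0 / 3.0])
    T = (w @ TRIANGLE.X[1:]) / w.sum()
    expected = (1 - psi) * T + psi * y
    np.testing.assert_allclose(modified_step(y, TRIANGLE), expected, atol=1e-14)


def test_modified_step_all_points_coincident():
    points = WeightedPointSet(np.zeros((3, 2)))
    np.testing.assert_array_equal(modified_step(np.zeros(2), points), [0.0, 0.0])


# ------------------------------------------------------------------- solver
def test_solver_1d_three_points_returns_middle():
    points = WeightedPointSet(np.array([[0.0], [1.0], [10.0]]))
    res = geometric_median(points)
    assert res.y[0] == pytest.approx(1.0, abs=1e-4)
    assert res.converged


def test_solver_symmetric_cross():
    points = WeightedPointSet(
        np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    )
    res = geometric_median(points)
    np.testing.assert_allclose(res.y, [0.0, 0.0], atol=1e-4)


def test_solver_single_point():
    res = geometric_median(WeightedPointSet(np.array([[2.0, 3.0]])))
    np.testing.assert_array_equal(res.y, [2.0, 3.0])
    assert res.objective == 0.0 and res.converged


def test_solver_matches_brute_force_oracle(rng):
    for _ in range(20):
        d = int(rng.integers(1, 5))
        n = int(rng.choice([3, 5, 7, 9]) if d == 1 else rng.integers(3, 11))
        X = rng.normal(size=(n, d)) * rng.uniform(0.5, 3)
        res = geometric_median(WeightedPointSet(X), epsilon=1e-9, max_iter=2000)
        oracle = geometric_median_oracle(X)
        assert np.linalg.norm(res.y - oracle) <= 1e-3


def test_objective_trace_non_increasing(rng):
    for _ in range(30):
        X = rng.normal(size=(rng.integers(2, 10), rng.integers(1, 5)))
        res = geometric_median(WeightedPointSet(X), epsilon=1e-9, max_iter=500)
        trace = np.array(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-12)
        assert res.objective == pytest.approx(
            objective_C(res.y, WeightedPointSet(X)), abs=1e-9
        )


def test_solution_in_convex_hull(rng):
    for _ in range(10):
        X = rng.normal(size=(6, 3)) + 5.0
        res = geometric_median(WeightedPointSet(X), epsilon=1e-9, max_iter=1000)
        assert in_convex_hull(res.y, X)


def test_translation_rotation_equivariance(rng):
    X = rng.normal(size=(7, 3))
    theta = 0.7
    R = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    b = np.array([2.0, -1.0, 0.5])
    y1 = geometric_median(WeightedPointSet(X), epsilon=1e-10, max_iter=3000).y
    y2 = geometric_median(
        WeightedPointSet(X @ R.T + b), epsilon=1e-10, max_iter=3000,
        y0=R @ np.zeros(3) + b,
    ).y
    np.testing.assert_allclose(y2, R @ y1 + b, atol=1e-6)


def test_vertex_optimality_when_weight_dominates():
    # eta_k = 10 >= ||R~(x_k)|| = sqrt(2): the vertex is the optimum
    points = WeightedPointSet(TRIANGLE.X, np.array([10.0, 1.0, 1.0]))
    assert 10.0 >= np.linalg.norm(r_tilde(TRIANGLE.X[0], points))
    res = geometric_median(points, y0=np.array([2.0, 2.0]), epsilon=1e-8,
                           max_iter=1000)
    np.testing.assert_allclose(res.y, [0.0, 0.0], atol=1e-4)


def test_start_at_dominant_vertex_stays_exactly():
    points = WeightedPointSet(TRIANGLE.X, np.array([10.0, 1.0, 1.0]))
    res = geometric_median(points, y0=np.array([0.0, 0.0]))
    np.testing.assert_array_equal(res.y, [0.0, 0.0])
    assert res.converged


def test_start_at_non_optimal_vertex_escapes():
    # psi < 1 at a non-dominant vertex: the iteration leaves it and finds
    # the true optimum (the middle point of the 1-D triple)
    points = WeightedPointSet(np.array([[0.0], [1.0], [10.0]]))
    res = geometric_median(points, y0=np.array([0.0]), epsilon=1e-8,
                           max_iter=1000)
    assert res.y[0] == pytest.approx(1.0, abs=1e-5)


def test_1d_odd_n_equals_sample_median(rng):
    for _ in range(10):
        n = int(rng.choice([3, 5, 7, 9, 11]))
        x = rng.normal(size=(n, 1)) * 4
        res = geometric_median(WeightedPointSet(x), epsilon=1e-8, max_iter=2000)
        assert res.y[0] == pytest.approx(float(np.median(x)), abs=1e-5)


def test_robust_to_displaced_replicate(rng):
    # one of 8 replicates displaced by 20 sigma: the median beats the mean
    sigma = 0.3
    wins = 0
    trials = 60
    for _ in range(trials):
        center = rng.uniform(-4, 1, size=20)
        X = center + rng.normal(0, sigma, size=(8, 20))
        X[0] += 20 * sigma
        clean_centroid = X[1:].mean(axis=0)
        med = geometric_median(WeightedPointSet(X), epsilon=1e-8, max_iter=500).y
        if np.linalg.norm(med - clean_centroid) < np.linalg.norm(
            X.mean(axis=0) - clean_centroid
        ):
            wins += 1
    assert wins >= 0.95 * trials


# --------------------------------------------------------- region reduction
def _log_block(values):
    from metabreduce.io import RegionBlock

    return RegionBlock(np.asarray(values, float), "R1", "A", scale="log")


def test_identical_columns_reduce_to_that_column():
    col = np.array([1.0, -2.0, 0.5])
    block = _log_block(np.column_stack([col] * 5))
    np.testing.assert_allclose(reduce_region_mwa(block), col, atol=1e-9)


def test_two_columns_objective_equals_their_distance():
    a, b = np.array([0.0, 0.0]), np.array([3.0, 4.0])
    block = _log_block(np.column_stack([a, b]))
    y = reduce_region_mwa(block, epsilon=1e-10, max_iter=2000)
    points = WeightedPointSet(np.vstack([a, b]))
    assert objective_C(y, points) == pytest.approx(5.0, abs=1e-6)


def test_block_reduction_matches_oracle(rng):
    block_vals = rng.normal(-1.5, 1.0, size=(47, 8))
    block = _log_block(block_vals)
    y = reduce_region_mwa(block, epsilon=1e-9, max_iter=2000)
    oracle = geometric_median_oracle(block_vals.T)
    assert np.linalg.norm(y - oracle) <= 1e-3


def test_raw_block_rejected(tiny_table):
    block = split_regions(tiny_table)[0]
    with pytest.raises(DomainError, match="log-scale"):
        reduce_region_mwa(block)


# ---------------------------------------------------------------- estimator
def test_estimator_api(rng):
    X = rng.normal(size=(9, 4))
    est = GeometricMedian(epsilon=1e-8, max_iter=500).fit(X)
    assert est.median_.shape == (4,)
    assert est.converged_
    assert est.get_params()["epsilon"] == 1e-8
    res = geometric_median(WeightedPointSet(X), epsilon=1e-8, max_iter=500)
    np.testing.assert_array_equal(est.median_, res.y)
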