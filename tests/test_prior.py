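"""vMF prior construction, conjugate MAP estimation, regularized alignment."""

import numpy as np
import pytest
import scipy.sparse

from promises import (
    CovarianceModel,
    DataStack,
    build_identity_F,
    build_spatial_F,
    center_columns,
    gpa_align,
    haar_orthogonal,
    load_custom_F,
    make_grid_coords,
    map_rotation,
    optimal_rotation_mle,
    posterior_location,
    promises_align,
    select_k_cv,
    simulate_stack,
    SimulationConfig,
    vmf_log_unnorm,
)

from conftest import angle_dist, angle_of

# the climbing-plant example: x and y axes pooled, z excluded — rank 2 of 3
PLANT_F = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 0.0], [0.0, 0.0, 1.0]])


# ---------------------------------------------------------------------------
# location-matrix builders
# ---------------------------------------------------------------------------


def test_identity_prior_properties():
    spec = build_identity_F(3)
    assert spec.rank == 3 and spec.full_rank
    assert scipy.sparse.issparse(spec.F)  # no dense m x m ever allocated
    P = spec.orientation_part
    assert np.allclose(np.asarray(P.todense()), np.eye(3))
    assert build_identity_F(1).m == 1
    with pytest.raises(ValueError):
        build_identity_F(0)


def test_spatial_prior_kernel(rng):
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 3.0, 4.0]])
    spec = build_spatial_F(coords)
    F = spec.F
    assert np.allclose(np.diag(F), 1.0)
    assert abs(F[0, 1] - np.exp(-1.0)) < 1e-12
    assert abs(F[0, 2] - np.exp(-5.0)) < 1e-12
    assert np.all(F > 0) and np.all(F <= 1)

    # 2x2x1 integer grid against an explicit double-loop oracle
    grid = make_grid_coords((2, 2, 1))
    F = build_spatial_F(grid).F
    m = grid.shape[0]
    oracle = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            oracle[i, j] = np.exp(-np.sqrt(np.sum((grid[i] - grid[j]) ** 2)))
    assert np.abs(F - oracle).max() < 1e-14


def test_spatial_prior_duplicates_and_validation():
    with pytest.warns(UserWarning, match="duplicated"):
        spec = build_spatial_F(np.zeros((2, 3)))
    assert spec.F[0, 1] == 1.0
    with pytest.raises(ValueError, match="finite"):
        build_spatial_F(np.array([[0.0, 0, np.inf]]))
    with pytest.raises(ValueError, match="m x 3"):
        build_spatial_F(np.zeros((4, 2)))


def test_spatial_prior_sparsification():
    grid = make_grid_coords((4, 4, 1))
    spec = build_spatial_F(grid, cutoff=1.5)
    assert scipy.sparse.issparse(spec.F)
    F = np.asarray(spec.F.todense())
    d = np.sqrt(((grid[:, None, :] - grid[None, :, :]) ** 2).sum(-1))
    assert np.all(F[d > 1.5] == 0.0)  # beyond the cutoff: exactly zero
    assert np.allclose(F[d <= 1.5], np.exp(-d[d <= 1.5]))


def test_load_custom_F_rank_diagnostics():
    with pytest.warns(UserWarning, match="rank-deficient"):
        spec = load_custom_F(PLANT_F)
    assert spec.rank == 2 and not spec.full_rank

    spec = load_custom_F(np.eye(4))  # full rank: silent
    assert spec.rank == 4

    with pytest.warns(UserWarning, match="no orientation"):
        spec = load_custom_F(np.zeros((3, 3)))
    assert spec.rank == 0

    with pytest.raises(ValueError, match="square"):
        load_custom_F(np.zeros((2, 3)))


def test_load_custom_F_from_files(tmp_path):
    dense = tmp_path / "F.tsv"
    np.savetxt(dense, PLANT_F, delimiter="\t")
    with pytest.warns(UserWarning, match="rank-deficient"):
        spec = load_custom_F(dense)
    assert np.abs(spec.F - PLANT_F).max() < 1e-12

    trip = tmp_path / "F_triplets.txt"
    trip.write_text(
        "0 0 0.5\n0 1 0.5\n1 0 0.5\n1 1 0.5\n2 2 1.0\n"
    )  # the same rank-2 matrix as triplets
    with pytest.warns(UserWarning, match="rank-deficient"):
        spec = load_custom_F(trip, sparse_triplet=True)
    assert scipy.sparse.issparse(spec.F)
    assert np.abs(spec.F.toarray() - PLANT_F).max() == 0.0


def test_polar_decomposition_consistency(rng):
    F = rng.standard_normal((4, 4))
    spec = load_custom_F(F)
    P, K = spec.orientation_part, spec.concentration_part
    assert np.linalg.norm(P @ K - F) < 1e-10
    assert np.linalg.norm(P.T @ P - np.eye(4)) < 1e-10
    assert np.linalg.norm(K - K.T) < 1e-10
    assert np.linalg.eigvalsh(K).min() > -1e-10


def test_max_trace_identity(rng):
    """For full-rank F the vMF mode P attains max tr(F.T R) = sum of
    singular values of F, over all of O(m)."""
    F = rng.standard_normal((5, 5))
    spec = load_custom_F(F, k=1.0)
    at_mode = vmf_log_unnorm(spec.orientation_part, spec)
    nuclear = np.linalg.svd(F, compute_uv=False).sum()
    assert abs(at_mode - nuclear) < 1e-10
    # and no Haar draw beats it
    vals = [vmf_log_unnorm(haar_orthogonal(5, rng), spec) for _ in range(50)]
    assert max(vals) <= at_mode + 1e-10


# ---------------------------------------------------------------------------
# density / posterior / MAP
# ---------------------------------------------------------------------------


def test_vmf_log_unnorm_cases(rng):
    spec0 = build_identity_F(3, k=0.0)
    assert vmf_log_unnorm(haar_orthogonal(3, rng), spec0) == 0.0

    spec = build_identity_F(3, k=2.5)
    assert abs(vmf_log_unnorm(np.eye(3), spec) - 2.5 * 3) < 1e-12

    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    spec2 = build_identity_F(2, k=1.3)
    assert abs(vmf_log_unnorm(R, spec2) - 2 * 1.3 * np.cos(th)) < 1e-12

    with pytest.raises(ValueError, match="orthogonal"):
        vmf_log_unnorm(np.full((3, 3), 0.5), spec)
    with pytest.raises(ValueError, match="3 x 3"):
        vmf_log_unnorm(np.eye(2), spec)


def test_posterior_location_formula(rng):
    X, M = rng.standard_normal((5, 3)), rng.standard_normal((5, 3))
    spec = load_custom_F(rng.standard_normal((3, 3)), k=1.7)

    assert np.allclose(posterior_location(X, M, prior=spec.with_k(0.0)), X.T @ M)
    assert np.allclose(posterior_location(np.zeros_like(X), M, prior=spec),
                       1.7 * spec.F)

    dn = np.diag(rng.uniform(0.5, 2.0, 5))
    dm = np.diag(rng.uniform(0.5, 2.0, 3))
    cov = CovarianceModel(sigma_n=dn, sigma_m=dm)
    got = posterior_location(X, M, cov, spec)
    oracle = X.T @ np.linalg.inv(dn) @ M @ np.linalg.inv(dm) + 1.7 * spec.F
    assert np.abs(got - oracle).max() < 1e-12


def test_map_reduces_to_mle_at_k_zero(rng):
    X, M = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
    spec = build_identity_F(3, k=0.0)
    R_map, _ = map_rotation(X, M, prior=spec)
    R_mle, _ = optimal_rotation_mle(X, M)
    assert np.array_equal(R_map, R_mle)


def test_map_dirac_limit(rng):
    X, M = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
    k = 1e12 * np.linalg.norm(X.T @ M)
    R, fac = map_rotation(X, M, prior=build_identity_F(3, k=k))
    assert np.linalg.norm(R - np.eye(3)) < 1e-6
    assert fac.unique


def test_map_matches_o2_grid_oracle(rng, o2_grid_solver):
    spec = build_identity_F(2, k=1.0)
    for _ in range(20):
        X, M = rng.standard_normal((2, 2)), rng.standard_normal((2, 2))
        R, _ = map_rotation(X, M, prior=spec)
        R_grid, _, th, det = o2_grid_solver(X.T @ M + spec.k * np.eye(2))
        assert np.sign(np.linalg.det(R)) == det
        assert angle_dist(angle_of(R), th) < o2_grid_solver.step


# ---------------------------------------------------------------------------
# regularized iterative alignment
# ---------------------------------------------------------------------------


def _centered(seed=3, **kw):
    defaults = dict(n=10, m=6, N=5, rotations="haar", noise_sd=0.1, seed=seed)
    defaults.update(kw)
    stack, truth = simulate_stack(SimulationConfig(**defaults))
    return center_columns(stack), truth


def test_promises_k0_identical_to_gpa():
    stack, _ = _centered()
    a = gpa_align(stack, tol=1e-10, max_iter=300)
    b = promises_align(stack, prior=build_identity_F(6, k=0.0),
                       tol=1e-10, max_iter=300)
    for Ra, Rb in zip(a.rotations, b.rotations):
        assert np.abs(Ra - Rb).max() < 1e-12
    assert np.abs(a.template - b.template).max() < 1e-12


def test_promises_unique_flag_tracks_prior_rank():
    stack, _ = _centered(n=8, m=3)
    res = promises_align(stack, prior=build_identity_F(3, k=1.0),
                         tol=1e-10, max_iter=500)
    assert res.unique
    with pytest.warns(UserWarning, match="rank-deficient"):
        deficient = load_custom_F(PLANT_F, k=1.0)
    res = promises_align(stack, prior=deficient, tol=1e-10, max_iter=500)
    assert not res.unique


def test_monotone_trust_in_concentration():
    """With F = I, increasing k pulls the MAP solutions toward the prior
    mode: the total trace of the rotations is non-decreasing in k."""
    stack, _ = _centered()
    traces = []
    for k in [0.0, 0.5, 1.0, 2.0, 5.0, 20.0, 100.0]:
        res = promises_align(stack, prior=build_identity_F(6, k=k),
                             tol=1e-10, max_iter=2000, rotation_tol=1e-8)
        traces.append(sum(np.trace(R) for R in res.rotations))
    assert np.all(np.diff(traces) >= -1e-6)


def test_shrinkage_toward_true_identity():
    """When the true rotations are the identity, the identity prior reduces
    the rotation estimation error (seeded replicates)."""
    wins = 0
    for rep in range(10):
        stack, _ = _centered(seed=100 + rep, n=20, m=10, N=10,
                             rotations="identity", noise_sd=1.0)
        err = {}
        for k in (0.0, 5.0):
            res = promises_align(stack, prior=build_identity_F(10, k=k),
                                 tol=1e-9, max_iter=300)
            err[k] = np.mean([np.linalg.norm(R - np.eye(10)) for R in res.rotations])
        wins += err[5.0] < err[0.0]
    assert wins >= 9


def test_select_k_cv_trivial_cases(rng):
    X = rng.standard_normal((8, 4))
    X -= X.mean(axis=0)
    identical = DataStack([X.copy() for _ in range(3)], centered=True)
    assert select_k_cv(identical, k_grid=[0.0]) == 0.0
    # noiseless identical subjects: every k ties, smallest wins
    assert select_k_cv(identical, k_grid=[0.0, 1.0, 10.0]) == 0.0

    with pytest.raises(ValueError, match="at least N = 3"):
        select_k_cv(DataStack([X, X.copy()], centered=True), k_grid=[0.0, 1.0])
    with pytest.raises(ValueError, match="non-empty"):
        select_k_cv(identical, k_grid=[])


def test_select_k_cv_prefers_regularization_under_noise():
    """True rotations identity + strong noise in the high-dimensional
    regime (m > n): CV should pick k > 0 in the vast majority of seeded
    replicates, because the unregularized held-out rotation over-fits the
    fitting rows and generalizes worse to the scored rows."""
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        stack, _ = _centered(seed=500 + rep, n=8, m=10, N=4,
                             rotations="identity", noise_sd=1.5)
        k_sel = select_k_cv(stack, k_grid=[0.0, 1.0, 10.0, 100.0],
                            tol=1e-8, max_iter=100)
        hits += k_sel > 0
    assert hits >= 0.8 * n_rep
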