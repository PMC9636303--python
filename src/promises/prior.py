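"""von Mises-Fisher prior on the orthogonal group and MAP alignment.

The matrix von Mises-Fisher (vMF) density on O(m),

    f(R) = C(F, k) * exp{ k * tr(F.T @ R) },

is conjugate to the matrix-normal perturbation model: the posterior is again
vMF with location ``F_star = X.T @ inv(Sigma_n) @ M @ inv(Sigma_m) + k F``.
The MAP orthogonal transformation is therefore the polar (SVD) solution of
``F_star`` — the same computation as the ML Procrustes step, applied to the
cross-product shifted by ``k F``.  A full-rank ``F`` makes the MAP unique,
removing the rotational non-identifiability of plain GPA, and its polar
orientation part ``P`` (``F = P K``) is the prior mode toward which the
estimate shrinks as ``k`` grows.

The normalizing constant ``C(F, k)`` (a hypergeometric function of matrix
argument) is never needed for MAP estimation and is not computed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import scipy.sparse
import scipy.spatial

from .model_core import (
    CovarianceModel,
    DataStack,
    AlignmentResult,
    SVDFactors,
    optimal_scale,
    _cross_product,
    _numerical_rank,
    _procrustes_svd,
    _gpa_loop,
)

__all__ = [
    "PriorSpec",
    "build_identity_F",
    "build_spatial_F",
    "load_custom_F",
    "vmf_log_unnorm",
    "posterior_location",
    "map_rotation",
    "promises_align",
    "select_k_cv",
]

# beyond this size, dense rank/polar diagnostics of a sparse F are skipped
_DENSE_DIAG_LIMIT = 2000


class PriorSpec:
    """Location matrix F (dense or sparse) and concentration k of a vMF prior.

    ``k = 0`` reproduces the unregularized perturbation model.  ``rank`` is
    the numerical rank of F; ``rank == m`` guarantees a unique MAP solution,
    anything less attaches a warning.  The polar factors ``orientation_part``
    (orthogonal P, the prior mode) and ``concentration_part`` (symmetric PSD
    K with F = P @ K) are computed on demand.
    """

    def __init__(self, F, k: float = 0.0, is_identity: bool = False):
        if k < 0:
            raise ValueError("concentration k must be non-negative")
        if scipy.sparse.issparse(F):
            self.F = F.tocsr()
        else:
            self.F = np.asarray(F, dtype=float)
            if self.F.ndim != 2 or self.F.shape[0] != self.F.shape[1]:
                raise ValueError("F must be a square matrix")
        if self.F.shape[0] != self.F.shape[1]:
            raise ValueError("F must be a square matrix")
        self.k = float(k)
        self.is_identity = bool(is_identity)
        self._rank: int | None = None
        self._svd: tuple | None = None

    @property
    def m(self) -> int:
        return self.F.shape[0]

    def with_k(self, k: float) -> "PriorSpec":
        out = PriorSpec.__new__(PriorSpec)
        out.F = self.F
        out.k = float(k)
        if k < 0:
            raise ValueError("concentration k must be non-negative")
        out.is_identity = self.is_identity
        out._rank = self._rank
        out._svd = self._svd
        return out

    # -- diagnostics ---------------------------------------------------------

    def _dense_F(self) -> np.ndarray | None:
        if not scipy.sparse.issparse(self.F):
            return self.F
        if self.m <= _DENSE_DIAG_LIMIT:
            return self.F.toarray()
        return None

    def _compute_svd(self):
        if self._svd is None:
            Fd = self._dense_F()
            if Fd is None:
                raise ValueError(
                    f"polar/rank diagnostics of a sparse {self.m} x {self.m} F "
                    f"would require densification; not computed above "
                    f"m = {_DENSE_DIAG_LIMIT}"
                )
            self._svd = np.linalg.svd(Fd)
        return self._svd

    @property
    def rank(self) -> int | None:
        if self._rank is None:
            if self.is_identity:
                self._rank = self.m
            else:
                try:
                    _, s, _ = self._compute_svd()
                except ValueError:
                    warnings.warn(
                        "rank of large sparse F not computed; uniqueness "
                        "cannot be certified"
                    )
                    return None
                self._rank = _numerical_rank(s, self.F.shape)
        return self._rank

    @property
    def full_rank(self) -> bool:
        return self.rank == self.m

    @property
    def orientation_part(self) -> np.ndarray | scipy.sparse.spmatrix:
        """Polar factor P of F = P @ K — the mode of the prior."""
        if self.is_identity:
            return scipy.sparse.identity(self.m, format="csr")
        U, _, Vt = self._compute_svd()
        return U @ Vt

    @property
    def concentration_part(self) -> np.ndarray | scipy.sparse.spmatrix:
        """Symmetric PSD polar factor K of F = P @ K."""
        if self.is_identity:
            return scipy.sparse.identity(self.m, format="csr")
        U, s, Vt = self._compute_svd()
        return Vt.T @ (s[:, None] * Vt)

    # -- use in estimation ---------------------------------------------------

    def add_location(self, cross: np.ndarray) -> np.ndarray:
        """Posterior vMF location: ``cross + k * F`` (sparse-aware)."""
        if self.k == 0:
            return cross
        if scipy.sparse.issparse(self.F):
            return cross + self.k * self.F.toarray()
        return cross + self.k * self.F

    def warn_if_deficient(self) -> None:
        r = self.rank
        if r is None:
            return
        if r == 0:
            warnings.warn("prior has no orientation information (rank-0 F)")
        elif r < self.m:
            warnings.warn(
                f"F is rank-deficient (rank {r} of {self.m}): MAP uniqueness "
                f"is not guaranteed"
            )


# ---------------------------------------------------------------------------
# location-matrix builders
# ---------------------------------------------------------------------------


def build_identity_F(m: int, k: float = 0.0) -> PriorSpec:
    """Identity location matrix: shrink toward combining same-index columns.

    Stored sparse so that no dense m x m array is ever allocated (the
    efficient path relies on this at fMRI scale).
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    return PriorSpec(scipy.sparse.identity(m, format="csr"), k=k, is_identity=True)


def build_spatial_F(
    coords: np.ndarray,
    k: float = 0.0,
    cutoff: float | None = None,
) -> PriorSpec:
    """Euclidean similarity location matrix from voxel/landmark coordinates.

    Entry (i, j) is ``exp(-d_ij)`` with ``d_ij`` the Euclidean distance
    between coordinates i and j: unit diagonal, entries decaying with
    distance.  When ``cutoff`` is set (default: 3.0 grid units for
    m > 2000, none below), entries at distance beyond it are exactly zero
    and the matrix is stored sparse; the resulting F may lose full rank,
    which the rank diagnostics will report.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be an m x 3 table")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    m = coords.shape[0]
    if cutoff is None and m > _DENSE_DIAG_LIMIT:
        cutoff = 3.0

    if cutoff is None:
        d = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(coords)
        )
        if np.any(d[np.triu_indices(m, k=1)] == 0.0):
            warnings.warn("duplicated coordinates: off-diagonal entries equal to 1")
        return PriorSpec(np.exp(-d), k=k)

    tree = scipy.spatial.cKDTree(coords)
    d = tree.sparse_distance_matrix(tree, max_distance=cutoff, output_type="coo_matrix")
    F = scipy.sparse.coo_matrix(
        (np.exp(-d.data), (d.row, d.col)), shape=(m, m)
    ).tolil()
    # zero-distance pairs may be dropped by the sparse container; restore them
    duplicates = tree.query_pairs(r=0.0)
    if duplicates:
        warnings.warn("duplicated coordinates: off-diagonal entries equal to 1")
        for i, j in duplicates:
            F[i, j] = 1.0
            F[j, i] = 1.0
    F.setdiag(1.0)
    return PriorSpec(F.tocsr(), k=k)


def load_custom_F(source, k: float = 0.0, sparse_triplet: bool = False) -> PriorSpec:
    """Load a user-supplied location matrix and attach rank diagnostics.

    ``source`` may be an in-memory (dense or sparse) matrix, a delimited
    dense matrix file, or — with ``sparse_triplet=True`` — a text file of
    0-based ``row col value`` triplets.  Rank-deficient matrices are
    accepted but warned about, since MAP uniqueness then fails.
    """
    if isinstance(source, (str, Path)):
        if sparse_triplet:
            trip = np.loadtxt(source, ndmin=2)
            if trip.shape[1] != 3:
                raise ValueError("triplet file must have 3 columns: row col value")
            rows = trip[:, 0].astype(int)
            cols = trip[:, 1].astype(int)
            m = int(max(rows.max(), cols.max())) + 1
            F = scipy.sparse.coo_matrix((trip[:, 2], (rows, cols)), shape=(m, m)).tocsr()
        else:
            from .io_cli import read_matrix

            F = read_matrix(source)
    else:
        F = source
    if not scipy.sparse.issparse(F):
        F = np.asarray(F, dtype=float)
        if F.ndim != 2 or F.shape[0] != F.shape[1]:
            raise ValueError(f"F must be square; got shape {F.shape}")
        if not np.isfinite(F).all():
            raise ValueError("F contains non-finite entries")
    spec = PriorSpec(F, k=k)
    spec.warn_if_deficient()
    return spec


# ---------------------------------------------------------------------------
# density, posterior, MAP
# ---------------------------------------------------------------------------


def vmf_log_unnorm(R: np.ndarray, prior: PriorSpec) -> float:
    """Unnormalized vMF log-density ``k * tr(F.T @ R)`` at an orthogonal R."""
    R = np.asarray(R, dtype=float)
    if R.shape != (prior.m, prior.m):
        raise ValueError(f"R must be {prior.m} x {prior.m}; got {R.shape}")
    if np.linalg.norm(R.T @ R - np.eye(R.shape[0])) > 1e-8:
        raise ValueError("R is not orthogonal within 1e-8")
    if scipy.sparse.issparse(prior.F):
        return prior.k * float(prior.F.multiply(R).sum())
    return prior.k * float(np.vdot(prior.F, R))


def posterior_location(
    X: np.ndarray,
    M: np.ndarray,
    cov: CovarianceModel | None = None,
    prior: PriorSpec | None = None,
) -> np.ndarray:
    """Conjugate posterior location ``X.T @ inv(Sigma_n) @ M @ inv(Sigma_m) + k F``."""
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    if X.shape != M.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs M {M.shape}")
    cov = cov or CovarianceModel.identity()
    cross = _cross_product(X, M, cov)
    if prior is None:
        return cross
    if prior.m != X.shape[1]:
        raise ValueError("prior dimension does not match the data")
    return prior.add_location(cross)


def map_rotation(
    X: np.ndarray,
    M: np.ndarray,
    cov: CovarianceModel | None = None,
    prior: PriorSpec | None = None,
) -> tuple[np.ndarray, SVDFactors]:
    """MAP orthogonal transformation under the vMF prior.

    The SVD solution of the posterior location; with ``k = 0`` this is
    exactly the ML estimator.  ``factors.unique`` reports whether the
    posterior location has full rank (guaranteed by a full-rank F).
    """
    K = posterior_location(X, M, cov, prior)
    return _procrustes_svd(K)


# ---------------------------------------------------------------------------
# iterative MAP alignment and concentration selection
# ---------------------------------------------------------------------------


def promises_align(
    stack: DataStack,
    cov: CovarianceModel | None = None,
    prior: PriorSpec | None = None,
    scaling: bool = False,
    tol: float = 1e-7,
    max_iter: int = 50,
    initial_template: np.ndarray | None = None,
    rotation_tol: float | None = None,
) -> AlignmentResult:
    """GPA with the MAP rotation step: the regularized alignment model.

    Identical loop to :func:`~promises.model_core.gpa_align`, with the prior
    location ``k F`` added to every cross-product before its SVD.  With a
    full-rank F and k > 0 the fixed point is unique (no arbitrary common
    rotation), and ``result.unique`` is set accordingly.
    """
    cov = cov or CovarianceModel.identity()
    return _gpa_loop(
        stack,
        cov,
        prior=prior,
        scaling=scaling,
        tol=tol,
        max_iter=max_iter,
        initial_template=initial_template,
        rotation_tol=rotation_tol,
    )


def _column_correlation_score(A: np.ndarray, B: np.ndarray) -> float:
    """Mean column-wise Pearson correlation, skipping constant columns."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    na = np.linalg.norm(Ac, axis=0)
    nb = np.linalg.norm(Bc, axis=0)
    ok = (na > 0) & (nb > 0)
    if not ok.any():
        raise ValueError("all columns constant: correlation score undefined")
    r = np.sum(Ac[:, ok] * Bc[:, ok], axis=0) / (na[ok] * nb[ok])
    return float(np.mean(r))


def select_k_cv(
    stack: DataStack,
    cov: CovarianceModel | None = None,
    prior_F: PriorSpec | None = None,
    k_grid=(0.0, 0.1, 1.0, 10.0),
    scaling: bool = False,
    tol: float = 1e-7,
    max_iter: int = 50,
    fit_fraction: float = 0.5,
) -> float:
    """Leave-one-subject-out cross-validation of the concentration k.

    For each candidate k the N-1 training subjects are aligned, the held-out
    subject's MAP rotation toward the training template is fitted on the
    first ``fit_fraction`` of the rows, and the fit is scored as the mean
    column-wise Pearson correlation between the *remaining* rows (rotated)
    and the template's remaining rows.  Scoring on rows not used to fit the
    rotation is what makes the criterion sensitive to over-fitting: scored
    on the fitting rows themselves, k = 0 wins almost by construction.
    Returns the k with the best mean score; exact ties go to the smallest k.
    """
    k_grid = sorted(float(k) for k in k_grid)
    if len(k_grid) == 0:
        raise ValueError("k_grid must be non-empty")
    if any(k < 0 for k in k_grid):
        raise ValueError("k_grid entries must be non-negative")
    N = stack.n_subjects
    if N < 3:
        raise ValueError("cross-validation needs at least N = 3 subjects")
    cov = cov or CovarianceModel.identity()
    if prior_F is None:
        prior_F = build_identity_F(stack.m)
    if not 0 < fit_fraction < 1:
        raise ValueError("fit_fraction must be in (0, 1)")
    h = max(1, int(round(fit_fraction * stack.n)))
    if h >= stack.n:
        raise ValueError("too few rows to split into fitting and scoring sets")
    # row whitening couples the fitting rows; the split uses identity rows
    fit_cov = CovarianceModel(
        sigma_m=cov.sigma_m, sigma_m_scale=cov.sigma_m_scale, mode=cov.mode
    )

    scores = []
    for k in k_grid:
        prior_k = prior_F.with_k(k)
        fold_scores = []
        for j in range(N):
            train = DataStack(
                matrices=[X for i, X in enumerate(stack.matrices) if i != j],
                subject_ids=[s for i, s in enumerate(stack.subject_ids) if i != j],
                centered=stack.centered,
            )
            res = promises_align(
                train,
                cov,
                prior=prior_k if k > 0 else None,
                scaling=scaling,
                tol=tol,
                max_iter=max_iter,
            )
            X_j = stack.matrices[j]
            R, fac = map_rotation(
                X_j[:h], res.template[:h], fit_cov, prior_k if k > 0 else None
            )
            aligned = X_j[h:] @ R
            if scaling:
                aligned = aligned / optimal_scale(X_j[:h], R, fit_cov, fac.D)
            fold_scores.append(_column_correlation_score(aligned, res.template[h:]))
        scores.append(float(np.mean(fold_scores)))
    best = int(np.argmax(scores))  # argmax takes the first (smallest k) on ties
    return k_grid[best]
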