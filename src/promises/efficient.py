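"""Efficient alignment for n << m via thin-SVD reduction.

When rows (time points) are far fewer than columns (voxels), the m x m SVD
at the heart of each Procrustes step is intractable.  Writing the thin SVD
``X_i = L_i @ diag(S_i) @ Q_i.T`` with semi-orthogonal ``Q_i`` (m x n), the
trace criterion satisfies

    max_{R in O(m)} tr(R.T @ X_i.T @ inv(Sigma_n) @ X_j)
        = max_{R* in O(n)} tr(R*.T @ Q_i.T @ X_i.T @ inv(Sigma_n) @ X_j @ Q_j),

so alignment can run entirely on the reduced n x n matrices ``X_i @ Q_i``
and be projected back through ``Q_i`` afterwards — O(m n^2) time and
O(m n) memory per subject instead of O(m^3) / O(m^2).  The identity needs an
isotropic column covariance ``Sigma_m = sigma^2 I``; the prior enters the
reduced problem as ``Q_i.T @ F @ Q_i``.  The reduced and full paths reach
the same data fit, but under different constraint sets (rank-n transports
vs full orthogonal matrices), so the individual solutions differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse

from .model_core import (
    AlignmentResult,
    CovarianceModel,
    DataStack,
    _EPS,
    _numerical_rank,
    _procrustes_svd,
    optimal_scale,
)
from .prior import PriorSpec

__all__ = [
    "ReducedRepresentation",
    "ReducedRotation",
    "thin_svd_reduce",
    "reduce_prior",
    "efficient_align",
]


@dataclass
class ReducedRepresentation:
    """Thin-SVD factors of one subject: ``X = L @ diag(S) @ Q.T``."""

    L: np.ndarray  # n x n, orthogonal columns
    S: np.ndarray  # n singular values, non-increasing
    Q: np.ndarray  # m x n, semi-orthogonal (Q.T @ Q = I_n)

    @property
    def reduced(self) -> np.ndarray:
        """The n x n reduced data matrix ``X @ Q`` (= L @ diag(S))."""
        return self.L * self.S

    @property
    def rank(self) -> int:
        return _numerical_rank(self.S, (self.Q.shape[0], self.Q.shape[0]))


@dataclass
class ReducedRotation:
    """Factored orthogonal transport ``Q @ R_star @ Q.T`` (never materialized).

    ``R_star`` is n x n orthogonal; the induced m x m operator has rank n.
    Applying it to a data matrix costs O(m n^2): ``X @ Q @ R_star @ Q.T``.
    """

    R_star: np.ndarray  # n x n orthogonal
    Q: np.ndarray  # m x n semi-orthogonal

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X @ self.Q) @ self.R_star @ self.Q.T


def thin_svd_reduce(X: np.ndarray) -> ReducedRepresentation:
    """Thin SVD of an n x m matrix with n <= m, with the deterministic
    sign convention of the Procrustes solver applied to L (and Q).

    Trailing zero singular values are allowed (rank-deficient X); the
    corresponding Q columns are an arbitrary orthonormal completion and
    carry no data weight — a warning reports how many.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n > m:
        raise ValueError(
            f"thin-SVD reduction requires n <= m (got {n} x {m}); "
            f"use the standard full-space path instead"
        )
    L, S, Qt = np.linalg.svd(X, full_matrices=False)
    idx = np.argmax(np.abs(L), axis=0)
    signs = np.sign(L[idx, np.arange(L.shape[1])])
    signs[signs == 0] = 1.0
    L = L * signs
    Qt = Qt * signs[:, None]
    r = _numerical_rank(S, X.shape)
    if r < n:
        warnings.warn(
            f"data matrix has rank {r} < n = {n}: trailing reduced "
            f"directions carry no data weight"
        )
    return ReducedRepresentation(L=L, S=S, Q=Qt.T)


def reduce_prior(F, Q_left: np.ndarray, Q_right: np.ndarray) -> np.ndarray:
    """Project an m x m location matrix into the reduced frames:
    ``Q_left.T @ F @ Q_right`` (n x n), computed sparsely when F is sparse."""
    if scipy.sparse.issparse(F):
        return np.asarray(Q_left.T @ (F @ Q_right))
    return Q_left.T @ np.asarray(F, dtype=float) @ Q_right


def efficient_align(
    stack: DataStack,
    cov: CovarianceModel | None = None,
    prior: PriorSpec | None = None,
    scaling: bool = False,
    tol: float = 1e-7,
    max_iter: int = 50,
) -> AlignmentResult:
    """GPA / MAP alignment run in each subject's reduced n-dimensional frame.

    Per sweep and subject the posterior location is the n x n matrix
    ``(X_i Q_i).T @ inv(Sigma_n) @ (M Q_i) / sigma^2 + k Q_i.T F Q_i`` with M
    the full-space template (mean of the back-projected aligned matrices);
    its SVD gives the reduced transport R*_i.  Rotations are returned in
    factored :class:`ReducedRotation` form — no m x m array is allocated.

    Requires an isotropic (or identity) column covariance; an explicit
    Sigma_m breaks the reduction identity and raises.
    """
    cov = cov or CovarianceModel.identity()
    if not cov.sigma_m_isotropic:
        raise ValueError(
            "the efficient path requires isotropic Sigma_m = sigma^2 I "
            "(the thin-SVD trace identity assumes it); "
            "use the standard path for an explicit column covariance"
        )
    if not stack.centered:
        raise ValueError("stack must be column-centered before alignment")
    N, n, m = stack.n_subjects, stack.n, stack.m
    if N < 2:
        raise ValueError("alignment needs at least N = 2 subjects")
    if n > m:
        raise ValueError("efficient path requires n <= m; use the standard path")
    use_prior = prior is not None and prior.k > 0
    if use_prior and prior.m != m:
        raise ValueError(f"prior location matrix is {prior.m} x {prior.m}, data has m={m}")
    sigma2 = cov.sigma_m_scale if cov.sigma_m_scale is not None else 1.0

    reps = [thin_svd_reduce(X) for X in stack.matrices]
    Ys = [rep.reduced for rep in reps]  # n x n reduced data
    if use_prior:
        if prior.is_identity:
            F_red = [np.eye(n)] * N  # Q.T @ I @ Q = I_n analytically
        else:
            F_red = [reduce_prior(prior.F, rep.Q, rep.Q) for rep in reps]

    M = np.mean(stack.matrices, axis=0)
    R_stars = [np.eye(n) for _ in range(N)]
    scales = np.ones(N)
    aligned = [X.copy() for X in stack.matrices]
    data_scale = sum(float(np.sum(Y * Y)) for Y in Ys)
    trace: list[float] = []
    all_unique = True
    converged = False
    prev_loss = None
    it = 0
    for it in range(1, max_iter + 1):
        prior_term = 0.0
        for i in range(N):
            MQ = cov.rows_whiten(M) @ reps[i].Q  # n x n projected template
            K = (Ys[i].T @ MQ) / sigma2
            if use_prior:
                K = K + prior.k * F_red[i]
            R_star, fac = _procrustes_svd(K)
            if not fac.unique:
                all_unique = False
            R_stars[i] = R_star
            if scaling:
                # Frobenius norms are preserved by the semi-orthogonal frame
                scales[i] = optimal_scale(Ys[i], R_star, cov, fac.D)
            aligned[i] = (Ys[i] @ R_star) @ reps[i].Q.T / scales[i]
            if use_prior:
                prior_term += prior.k * float(np.vdot(F_red[i], R_star))
        M = np.mean(aligned, axis=0)
        loss = sum(float(np.sum((A - M) ** 2)) for A in aligned)
        penalized = loss - 2.0 * prior_term
        trace.append(-penalized)
        if prev_loss is not None:
            denom = max(abs(prev_loss), _EPS * max(data_scale, 1.0))
            if abs(penalized - prev_loss) <= tol * denom:
                converged = True
                break
        elif loss <= _EPS * max(data_scale, 1.0):
            converged = True
            break
        prev_loss = penalized
    if not converged:
        warnings.warn(
            f"efficient GPA did not converge in {max_iter} sweeps "
            f"(last relative change above tol={tol:g})"
        )
    rotations = [ReducedRotation(R_star=R_stars[i], Q=reps[i].Q) for i in range(N)]
    return AlignmentResult(
        rotations=rotations,
        scales=scales,
        template=M,
        objective_trace=trace,
        n_iter=it,
        converged=converged,
        unique=bool(use_prior and prior.full_rank and all_unique),
        subject_ids=list(stack.subject_ids),
    )
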