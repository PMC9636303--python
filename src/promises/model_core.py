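"""Perturbation model core: data containers, single-pair estimators, GPA.

The generative model for N matrices to be aligned is

    X_i = alpha_i * (M + E_i) @ R_i.T,      R_i in O(m),

with matrix-normal noise ``E_i ~ MN(0, Sigma_n, Sigma_m)``: ``M`` (n x m) is
the shared reference configuration, ``R_i`` an orthogonal transformation
(rotation or reflection) of the column space, and ``alpha_i > 0`` an
isotropic scale.  Translations are removed beforehand by column centering.

Given the nuisance parameters, the maximum-likelihood rotation is the
classical orthogonal Procrustes solution: with the singular value
decomposition ``X.T @ inv(Sigma_n) @ M @ inv(Sigma_m) = U D V.T`` the MLE is
``R_hat = U @ V.T`` and the scale is
``alpha_hat = ||inv_sqrt(Sigma_m) @ R_hat.T @ X.T @ inv_sqrt(Sigma_n)||^2 / tr(D)``.
With all nuisance parameters unknown the joint solution is found by
generalized Procrustes analysis (GPA): sweep over subjects solving the pair
problem against the running template, then update the template as the
element-wise mean of the aligned matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse

__all__ = [
    "DataStack",
    "CovarianceModel",
    "AlignmentResult",
    "SVDFactors",
    "DegenerateSVDWarning",
    "center_columns",
    "optimal_rotation_mle",
    "optimal_scale",
    "estimate_covariances",
    "min_subjects_required",
    "gpa_align",
    "total_alignment_loss",
]

# numerical-rank rule: singular values below max(n, m) * eps * s_max are zero
_EPS = np.finfo(float).eps


class DegenerateSVDWarning(UserWarning):
    """Equal singular values: the Procrustes solution has a degenerate SVD."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class DataStack:
    """An ordered collection of N conforming n x m data matrices.

    Rows are observations (time points / stimuli), columns are landmarks or
    voxels.  ``column_means`` stores the translations removed by
    :func:`center_columns` so that the original data can be reconstructed.
    """

    matrices: list[np.ndarray]
    subject_ids: list[str] | None = None
    column_means: list[np.ndarray] | None = None
    centered: bool = False

    def __post_init__(self) -> None:
        self.matrices = [np.asarray(X, dtype=float) for X in self.matrices]
        if len(self.matrices) == 0:
            raise ValueError("DataStack needs at least one matrix")
        shape = self.matrices[0].shape
        if len(shape) != 2:
            raise ValueError("matrices must be two-dimensional")
        for X in self.matrices:
            if X.shape != shape:
                raise ValueError(
                    f"all matrices must share one shape; got {X.shape} != {shape}"
                )
        if self.subject_ids is None:
            self.subject_ids = [f"subject_{i}" for i in range(len(self.matrices))]
        if len(self.subject_ids) != len(self.matrices):
            raise ValueError("subject_ids length must match the number of matrices")

    @property
    def n_subjects(self) -> int:
        return len(self.matrices)

    @property
    def n(self) -> int:
        return self.matrices[0].shape[0]

    @property
    def m(self) -> int:
        return self.matrices[0].shape[1]


class CovarianceModel:
    """Row (Sigma_n) and column (Sigma_m) covariances of the noise term.

    ``sigma_n is None`` means identity; ``sigma_m is None`` means identity;
    ``sigma_m_scale`` not None means the isotropic form ``sigma^2 * I_m``
    (the only column covariance the efficient path accepts).
    """

    def __init__(
        self,
        sigma_n: np.ndarray | None = None,
        sigma_m: np.ndarray | None = None,
        sigma_m_scale: float | None = None,
        mode: str = "known",
    ):
        if sigma_m is not None and sigma_m_scale is not None:
            raise ValueError("pass either an explicit sigma_m or an isotropic scale")
        if mode not in ("known", "identity", "estimate"):
            raise ValueError(f"unknown mode {mode!r}")
        self.sigma_n = self._validate_spd(sigma_n, "sigma_n")
        self.sigma_m = self._validate_spd(sigma_m, "sigma_m")
        if sigma_m_scale is not None and not sigma_m_scale > 0:
            raise ValueError("isotropic sigma_m scale must be positive")
        self.sigma_m_scale = None if sigma_m_scale is None else float(sigma_m_scale)
        self.mode = mode
        self._sigma_n_inv_sqrt: np.ndarray | None = None
        self._sigma_m_inv_sqrt: np.ndarray | None = None

    @staticmethod
    def _validate_spd(S: np.ndarray | None, name: str) -> np.ndarray | None:
        if S is None:
            return None
        S = np.asarray(S, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError(f"{name} must be square")
        scale = max(np.abs(S).max(), 1.0)
        if np.abs(S - S.T).max() > 1e-10 * scale:
            raise ValueError(f"{name} must be symmetric")
        ev = np.linalg.eigvalsh(S)
        if ev.min() <= 0:
            raise ValueError(f"{name} must be positive definite (min eigenvalue {ev.min():g})")
        return S

    @classmethod
    def identity(cls) -> "CovarianceModel":
        return cls(mode="identity")

    @classmethod
    def isotropic_columns(cls, sigma2: float, sigma_n: np.ndarray | None = None) -> "CovarianceModel":
        return cls(sigma_n=sigma_n, sigma_m_scale=sigma2, mode="known")

    @property
    def sigma_m_isotropic(self) -> bool:
        return self.sigma_m is None

    # -- linear operators used by the estimators -----------------------------

    def rows_whiten(self, M: np.ndarray) -> np.ndarray:
        """Return ``inv(Sigma_n) @ M`` (identity: M unchanged)."""
        if self.sigma_n is None:
            return M
        return scipy.linalg.solve(self.sigma_n, M, assume_a="pos")

    def cols_whiten(self, K: np.ndarray) -> np.ndarray:
        """Return ``K @ inv(Sigma_m)`` for explicit/isotropic/identity Sigma_m."""
        if self.sigma_m is not None:
            return scipy.linalg.solve(self.sigma_m, K.T, assume_a="pos").T
        if self.sigma_m_scale is not None:
            return K / self.sigma_m_scale
        return K

    @staticmethod
    def _inv_sqrt(S: np.ndarray) -> np.ndarray:
        ev, V = np.linalg.eigh(S)
        return (V / np.sqrt(ev)) @ V.T

    def sigma_n_inv_sqrt(self) -> np.ndarray | None:
        if self.sigma_n is None:
            return None
        if self._sigma_n_inv_sqrt is None:
            self._sigma_n_inv_sqrt = self._inv_sqrt(self.sigma_n)
        return self._sigma_n_inv_sqrt

    def sigma_m_inv_sqrt(self) -> np.ndarray | None:
        if self.sigma_m is None:
            return None
        if self._sigma_m_inv_sqrt is None:
            self._sigma_m_inv_sqrt = self._inv_sqrt(self.sigma_m)
        return self._sigma_m_inv_sqrt


@dataclass
class AlignmentResult:
    """Outcome of an iterative (generalized) Procrustes alignment.

    ``rotations`` holds N orthogonal m x m arrays for the full-space paths,
    or factored :class:`~promises.efficient.ReducedRotation` objects for the
    efficient path.  ``objective_trace`` records, per sweep, the negative
    (prior-penalized) total Frobenius loss, which is non-decreasing because
    every GPA half-step solves its subproblem exactly.
    """

    rotations: list
    scales: np.ndarray
    template: np.ndarray
    objective_trace: list[float]
    n_iter: int
    converged: bool
    unique: bool
    subject_ids: list[str] = field(default_factory=list)

    @property
    def loss_trace(self) -> np.ndarray:
        """Per-sweep total loss when no prior penalty was active."""
        return -np.asarray(self.objective_trace)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def center_columns(stack: DataStack) -> DataStack:
    """Remove each column's mean from every matrix (the translation term).

    Applying the centering operator ``C_n = I_n - J_n / n`` row-wise makes
    every column sum to zero; the removed means are kept in
    ``column_means``.  Centering an already-centered stack is a warned no-op.
    """
    if stack.centered:
        warnings.warn("stack is already column-centered; returning it unchanged")
        return stack
    centered, means = [], []
    for X in stack.matrices:
        mu = X.mean(axis=0)
        centered.append(X - mu)
        means.append(mu)
    return DataStack(
        matrices=centered,
        subject_ids=list(stack.subject_ids),
        column_means=means,
        centered=True,
    )


# ---------------------------------------------------------------------------
# single-pair estimators
# ---------------------------------------------------------------------------


class SVDFactors(NamedTuple):
    U: np.ndarray
    D: np.ndarray  # singular values, non-negative, non-increasing
    Vt: np.ndarray
    rank: int
    unique: bool  # full rank => the orthogonal solution is unique


def _numerical_rank(s: np.ndarray, shape: tuple[int, int]) -> int:
    if s.size == 0 or s[0] == 0:
        return 0
    tol = max(shape) * _EPS * s[0]
    return int(np.count_nonzero(s > tol))


def _procrustes_svd(K: np.ndarray) -> tuple[np.ndarray, SVDFactors]:
    """Orthogonal matrix maximizing ``tr(R.T @ K)`` over O(m), via SVD.

    A deterministic sign convention is applied: each left singular vector is
    flipped so its largest-magnitude entry (ties: lowest index) is positive,
    with the matching right vector flipped too.  Near-equal singular values
    are flagged, since the factors (not the product U @ V.T for full-rank K)
    are then ambiguous.
    """
    K = np.asarray(K, dtype=float)
    if not np.isfinite(K).all():
        raise ValueError("cross-product matrix contains non-finite entries")
    norm = np.linalg.norm(K)
    if norm == 0.0:
        raise ValueError("degenerate alignment problem: zero cross-product matrix")
    U, s, Vt = np.linalg.svd(K)
    # sign convention for bit-reproducibility
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    Vt = Vt * signs[:, None]
    if s.size > 1 and np.any(np.diff(s) > -1e-12 * s[0]):
        warnings.warn(
            "equal (or numerically tied) singular values: SVD factors are "
            "degenerate, the factor ordering follows the backend output",
            DegenerateSVDWarning,
        )
    rank = _numerical_rank(s, K.shape)
    R = U @ Vt
    return R, SVDFactors(U=U, D=s, Vt=Vt, rank=rank, unique=rank == K.shape[0])


def _cross_product(X: np.ndarray, M: np.ndarray, cov: CovarianceModel) -> np.ndarray:
    """``X.T @ inv(Sigma_n) @ M @ inv(Sigma_m)`` (m x m)."""
    return cov.cols_whiten(X.T @ cov.rows_whiten(M))


def optimal_rotation_mle(
    X: np.ndarray,
    M: np.ndarray,
    cov: CovarianceModel | None = None,
) -> tuple[np.ndarray, SVDFactors]:
    """Maximum-likelihood orthogonal transformation aligning ``X`` to ``M``.

    Returns ``R_hat = U @ V.T`` from the SVD of the whitened cross-product
    together with the SVD factors.  ``factors.unique`` is False when the
    cross-product is rank-deficient (always the case when n < m), in which
    case infinitely many orthogonal matrices attain the maximum.
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    if X.shape != M.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs M {M.shape}")
    cov = cov or CovarianceModel.identity()
    return _procrustes_svd(_cross_product(X, M, cov))


def optimal_scale(
    X: np.ndarray,
    R: np.ndarray,
    cov: CovarianceModel | None = None,
    D: np.ndarray | None = None,
) -> float:
    """ML/MAP isotropic scale given the rotation and its SVD spectrum.

    Implements ``alpha_hat = ||inv_sqrt(Sigma_m) @ R.T @ X.T @
    inv_sqrt(Sigma_n)||^2 / tr(D)`` with ``D`` the singular values of the
    (posterior) cross-product that produced ``R``.  The aligned matrix is
    then ``X @ R / alpha_hat``.
    """
    if D is None:
        raise ValueError("optimal_scale needs the singular values D of the cross-product")
    cov = cov or CovarianceModel.identity()
    trD = float(np.sum(D))
    if trD <= 0:
        raise ValueError("degenerate scale problem: tr(D) is not positive")
    A = R.T @ X.T  # m x n
    left = cov.sigma_m_inv_sqrt()
    if left is not None:
        A = left @ A
    elif cov.sigma_m_scale is not None:
        A = A / math.sqrt(cov.sigma_m_scale)
    right = cov.sigma_n_inv_sqrt()
    if right is not None:
        A = A @ right
    alpha = float(np.sum(A * A)) / trD
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError(f"degenerate scale estimate: {alpha!r}")
    return alpha


# ---------------------------------------------------------------------------
# covariance estimation (two-stage flip-flop)
# ---------------------------------------------------------------------------


def min_subjects_required(n: int, m: int) -> int:
    """Smallest N with ``N >= m/n + 1``, the existence condition for the
    two-stage covariance estimator (e.g. 1001 for n=200, m=200000)."""
    return -(-m // n) + 1  # ceil(m / n) + 1


def estimate_covariances(
    stack: DataStack,
    template: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CovarianceModel:
    """Two-stage (flip-flop) ML estimation of Sigma_n and Sigma_m.

    Alternates
    ``Sigma_n = sum_i Res_i @ inv(Sigma_m) @ Res_i.T / (N m)`` and
    ``Sigma_m = sum_i Res_i.T @ inv(Sigma_n) @ Res_i / (N n)`` on the
    residuals ``Res_i = X_i - template`` until the relative Frobenius change
    of both factors falls below ``tol``.  The Kronecker scale indeterminacy
    (only ``Sigma_m (x) Sigma_n`` is identified) is fixed by normalizing
    ``tr(Sigma_n) = n``.
    """
    N, n, m = stack.n_subjects, stack.n, stack.m
    n_min = min_subjects_required(n, m)
    if N < n_min:
        raise ValueError(
            f"covariance estimation needs N >= m/n + 1 subjects; "
            f"got N={N} < {n_min} (n={n}, m={m})"
        )
    template = np.asarray(template, dtype=float)
    residuals = [X - template for X in stack.matrices]
    if max(np.abs(R).max() for R in residuals) == 0.0:
        raise ValueError("degenerate: zero residual covariance")

    sigma_n = np.eye(n)
    sigma_m = np.eye(m)
    for _ in range(max_iter):
        sn_new = np.zeros((n, n))
        for Res in residuals:
            sn_new += Res @ scipy.linalg.solve(sigma_m, Res.T, assume_a="pos")
        sn_new /= N * m
        sm_new = np.zeros((m, m))
        for Res in residuals:
            sm_new += Res.T @ scipy.linalg.solve(sn_new, Res, assume_a="pos")
        sm_new /= N * n
        dn = np.linalg.norm(sn_new - sigma_n) / max(np.linalg.norm(sigma_n), _EPS)
        dm = np.linalg.norm(sm_new - sigma_m) / max(np.linalg.norm(sigma_m), _EPS)
        sigma_n, sigma_m = sn_new, sm_new
        if max(dn, dm) < tol:
            break
    c = n / np.trace(sigma_n)
    sigma_n = sigma_n * c
    sigma_m = sigma_m / c
    # symmetrize away accumulated round-off before the SPD validation
    sigma_n = (sigma_n + sigma_n.T) / 2.0
    sigma_m = (sigma_m + sigma_m.T) / 2.0
    return CovarianceModel(sigma_n=sigma_n, sigma_m=sigma_m, mode="known")


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------


def total_alignment_loss(
    stack: DataStack,
    rotations: Sequence[np.ndarray],
    scales: Sequence[float],
    template: np.ndarray,
) -> float:
    """``sum_i || X_i @ R_i / alpha_i - template ||_F^2``."""
    loss = 0.0
    for X, R, a in zip(stack.matrices, rotations, scales):
        loss += float(np.sum((X @ R / a - template) ** 2))
    return loss


def _prior_trace(prior, R: np.ndarray) -> float:
    """``k * tr(F.T @ R)`` for dense or sparse F."""
    if scipy.sparse.issparse(prior.F):
        return prior.k * float(prior.F.multiply(R).sum())
    return prior.k * float(np.vdot(prior.F, R))


def _gpa_loop(
    stack: DataStack,
    cov: CovarianceModel,
    prior=None,
    scaling: bool = False,
    tol: float = 1e-7,
    max_iter: int = 50,
    initial_template: np.ndarray | None = None,
    rotation_tol: float | None = None,
) -> AlignmentResult:
    """Shared GPA sweep used by both the ML and the MAP (prior) paths.

    Per sweep, each subject's orthogonal transformation is re-solved against
    the current template (plus ``k * F`` in the cross-product when a prior is
    given, per the conjugate posterior location), the scale is re-estimated
    immediately after the subject's rotation when enabled, and the template
    is then refreshed as the element-wise mean of the aligned matrices.

    Convergence requires the relative change of the (penalized) total loss
    to fall below ``tol``; when ``rotation_tol`` is set, additionally the
    largest per-sweep rotation change ``max_i ||R_i - R_i_prev||_F`` must
    fall below it.  The extra criterion matters when the loss has flattened
    to machine precision but the solution still drifts along a weakly pinned
    mode (weak prior), e.g. to certify uniqueness to tight tolerance.
    """
    if not stack.centered:
        raise ValueError("stack must be column-centered before alignment")
    N = stack.n_subjects
    if N < 2:
        raise ValueError("alignment needs at least N = 2 subjects")
    n, m = stack.n, stack.m
    use_prior = prior is not None and prior.k > 0
    if use_prior and prior.m != m:
        raise ValueError(f"prior location matrix is {prior.m} x {prior.m}, data has m={m}")

    if initial_template is None:
        M = np.mean(stack.matrices, axis=0)
    else:
        M = np.asarray(initial_template, dtype=float)
        if M.shape != (n, m):
            raise ValueError("initial template shape mismatch")

    rotations = [np.eye(m) for _ in range(N)]
    scales = np.ones(N)
    aligned = [X.copy() for X in stack.matrices]
    data_scale = sum(float(np.sum(X * X)) for X in stack.matrices)
    trace: list[float] = []
    all_unique = True
    converged = False
    prev_loss = None
    it = 0
    for it in range(1, max_iter + 1):
        prior_term = 0.0
        rot_change = 0.0
        for i, X in enumerate(stack.matrices):
            K = _cross_product(X, M, cov)
            if use_prior:
                K = prior.add_location(K)
            R, fac = _procrustes_svd(K)
            if not fac.unique:
                all_unique = False
            rot_change = max(rot_change, float(np.linalg.norm(R - rotations[i])))
            rotations[i] = R
            if scaling:
                scales[i] = optimal_scale(X, R, cov, fac.D)
            aligned[i] = X @ R / scales[i]
            if use_prior:
                prior_term += _prior_trace(prior, R)
        M = np.mean(aligned, axis=0)
        loss = sum(float(np.sum((A - M) ** 2)) for A in aligned)
        penalized = loss - 2.0 * prior_term
        trace.append(-penalized)
        rotations_settled = rotation_tol is None or rot_change <= rotation_tol
        if prev_loss is not None:
            denom = max(abs(prev_loss), _EPS * max(data_scale, 1.0))
            if abs(penalized - prev_loss) <= tol * denom and rotations_settled:
                converged = True
                break
        elif loss <= _EPS * max(data_scale, 1.0) and rotations_settled:
            converged = True  # already perfectly aligned after one sweep
            break
        prev_loss = penalized
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} sweeps "
            f"(last relative change above tol={tol:g})"
        )
    unique = bool(use_prior and prior.full_rank and all_unique)
    return AlignmentResult(
        rotations=rotations,
        scales=scales,
        template=M,
        objective_trace=trace,
        n_iter=it,
        converged=converged,
        unique=unique,
        subject_ids=list(stack.subject_ids),
    )


def gpa_align(
    stack: DataStack,
    cov: CovarianceModel | None = None,
    scaling: bool = False,
    tol: float = 1e-7,
    max_iter: int = 50,
    initial_template: np.ndarray | None = None,
    rotation_tol: float | None = None,
) -> AlignmentResult:
    """Generalized Procrustes alignment of a centered stack (ML, no prior).

    The solution is never unique: right-multiplying every rotation and the
    template by any fixed orthogonal Z leaves the loss unchanged, so
    ``result.unique`` is always False on this path.
    """
    cov = cov or CovarianceModel.identity()
    return _gpa_loop(
        stack,
        cov,
        prior=None,
        scaling=scaling,
        tol=tol,
        max_iter=max_iter,
        initial_template=initial_template,
        rotation_tol=rotation_tol,
    )
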