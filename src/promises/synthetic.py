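"""Ground-truth generator for the perturbation model.

Draws ``X_i = alpha_i * (M + E_i) @ R_i.T`` with matrix-normal noise
``E_i = noise_sd * sqrt(Sigma_n) @ G @ sqrt(Sigma_m)`` (G standard normal)
and orthogonal ``R_i`` that are either the identity, Haar-uniform on O(m),
or user-supplied.  Every draw is reproducible: the same configuration and
seed give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse

from .model_core import DataStack

__all__ = [
    "SimulationConfig",
    "simulate_stack",
    "haar_orthogonal",
    "make_grid_coords",
]

_MAX_GRID_SIZE = 10_000_000


@dataclass
class SimulationConfig:
    """Stated world of one simulation: sizes, transformations, noise, seed."""

    n: int
    m: int
    N: int
    template: np.ndarray | str = "random-normal"
    rotations: str | list = "identity"  # "identity" | "haar" | explicit list
    scales: np.ndarray | None = None  # default: all ones
    sigma_n: np.ndarray | None = None  # default: identity
    sigma_m: np.ndarray | None = None  # default: identity
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1 or self.N < 1:
            raise ValueError("n, m and N must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.scales is not None:
            self.scales = np.asarray(self.scales, dtype=float)
            if self.scales.shape != (self.N,) or np.any(self.scales <= 0):
                raise ValueError("scales must be N positive reals")


def _sqrt_psd(S: np.ndarray, name: str) -> np.ndarray:
    """Symmetric matrix square root; tiny negative eigenvalues are clipped."""
    S = np.asarray(S, dtype=float)
    ev, V = np.linalg.eigh(S)
    floor = -1e-10 * max(abs(ev.max()), 1.0)
    if ev.min() < floor:
        raise ValueError(f"{name} is not positive (semi-)definite")
    if ev.min() < 0:
        warnings.warn(f"clipping tiny negative eigenvalues of {name} at 0")
        ev = np.clip(ev, 0.0, None)
    return (V * np.sqrt(ev)) @ V.T


def haar_orthogonal(m: int, rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform draw from O(m): QR of a Gaussian matrix with the
    standard sign correction on the R-factor diagonal."""
    G = rng.standard_normal((m, m))
    Q, R = np.linalg.qr(G)
    d = np.sign(np.diag(R))
    d[d == 0] = 1.0
    return Q * d


def simulate_stack(config: SimulationConfig) -> tuple[DataStack, dict]:
    """Draw N matrices from the perturbation model with known ground truth.

    Returns the (uncentered) stack and a dict with the shared template
    ``M``, the orthogonal transformations ``R`` and the scales ``alpha``
    actually used.
    """
    rng = np.random.default_rng(config.seed)
    n, m, N = config.n, config.m, config.N

    if isinstance(config.template, str):
        if config.template != "random-normal":
            raise ValueError(f"unknown template spec {config.template!r}")
        M = rng.standard_normal((n, m))
    else:
        M = np.asarray(config.template, dtype=float)
        if M.shape != (n, m):
            raise ValueError(f"template must be {n} x {m}")

    identity_rotations = False
    if isinstance(config.rotations, str):
        if config.rotations == "identity":
            # never materialize m x m identities (fMRI-scale m)
            identity_rotations = True
            Rs = [scipy.sparse.identity(m, format="csr") for _ in range(N)]
        elif config.rotations == "haar":
            Rs = [haar_orthogonal(m, rng) for _ in range(N)]
        else:
            raise ValueError(f"unknown rotation spec {config.rotations!r}")
    else:
        Rs = [np.asarray(R, dtype=float) for R in config.rotations]
        if len(Rs) != N:
            raise ValueError("need one rotation per subject")
        for R in Rs:
            if R.shape != (m, m) or np.linalg.norm(R.T @ R - np.eye(m)) > 1e-10:
                raise ValueError("user rotations must be orthogonal m x m matrices")

    alphas = np.ones(N) if config.scales is None else config.scales
    sq_n = None if config.sigma_n is None else _sqrt_psd(config.sigma_n, "sigma_n")
    sq_m = None if config.sigma_m is None else _sqrt_psd(config.sigma_m, "sigma_m")

    matrices = []
    for i in range(N):
        E = config.noise_sd * rng.standard_normal((n, m))
        if sq_n is not None:
            E = sq_n @ E
        if sq_m is not None:
            E = E @ sq_m
        if identity_rotations:
            matrices.append(alphas[i] * (M + E))
        else:
            matrices.append(alphas[i] * (M + E) @ Rs[i].T)

    stack = DataStack(
        matrices=matrices,
        subject_ids=[f"sim_{i}" for i in range(N)],
        centered=False,
    )
    truth = {"M": M, "R": Rs, "alpha": alphas}
    return stack, truth


def make_grid_coords(dims: tuple[int, int, int]) -> np.ndarray:
    """Integer lattice coordinates of a dx x dy x dz grid, row-major, 0-based.

    Support plumbing for the spatial similarity prior: feeds
    :func:`promises.prior.build_spatial_F` with voxel-index coordinates.
    """
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or any(d < 1 for d in dims):
        raise ValueError("dims must be three positive integers")
    m = dims[0] * dims[1] * dims[2]
    if m > _MAX_GRID_SIZE:
        raise ValueError(f"grid of {m} voxels exceeds the limit of {_MAX_GRID_SIZE}")
    grid = np.indices(dims).reshape(3, m).T
    return np.ascontiguousarray(grid, dtype=float)
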