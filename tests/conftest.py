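import numpy as np
import pytest

GRID_STEP = 1e-4  # radians; resolution of the brute-force O(2) oracle


@pytest.fixture(scope="session")
def o2_grid_solver():
    """Brute-force maximizer of tr(R.T @ K) over O(2) on a fine angle grid.

    Evaluates both components of O(2) — rotations [[c,-s],[s,c]] and
    reflections [[c,s],[s,-c]] — at every grid angle and returns the best
    orthogonal matrix, its trace value, the angle, and the determinant.
    Completely independent of any SVD: the oracle for the closed-form
    Procrustes/MAP solutions.
    """
    thetas = np.arange(0.0, 2 * np.pi, GRID_STEP)
    c, s = np.cos(thetas), np.sin(thetas)

    def solve(K):
        rot_vals = c * (K[0, 0] + K[1, 1]) + s * (K[1, 0] - K[0, 1])
        ref_vals = c * (K[0, 0] - K[1, 1]) + s * (K[0, 1] + K[1, 0])
        i_rot = int(np.argmax(rot_vals))
        i_ref = int(np.argmax(ref_vals))
        if rot_vals[i_rot] >= ref_vals[i_ref]:
            th = thetas[i_rot]
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            return R, float(rot_vals[i_rot]), th, 1.0
        th = thetas[i_ref]
        R = np.array([[np.cos(th), np.sin(th)], [np.sin(th), -np.cos(th)]])
        return R, float(ref_vals[i_ref]), th, -1.0

    solve.step = GRID_STEP
    return solve


def angle_of(R):
    """Angle parameter of a 2x2 orthogonal matrix (either component)."""
    if np.linalg.det(R) > 0:
        return np.arctan2(R[1, 0], R[0, 0])
    return np.arctan2(R[0, 1], R[0, 0])


def angle_dist(a, b):
    """Distance between two angles on the circle."""
    d = abs(a - b) % (2 * np.pi)
    return min(d, 2 * np.pi - d)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
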