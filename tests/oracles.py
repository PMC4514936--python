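"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from splintacc.pose import euler_to_matrix


def rotation_misfit(angles_deg, plan_vectors, post_vectors):
    R = euler_to_matrix(*angles_deg)
    return float(np.sum((plan_vectors @ R.T - post_vectors) ** 2))


def brute_force_rotation(plan_vectors, post_vectors, span=25.0, step=2.0):
    """Dense Euler-angle grid search over small rotations, refined locally.

    Independent of the Kabsch estimator: scans pitch/roll/yaw on a regular
    grid within +/-span degrees (vectorised), then polishes the best grid
    point with Nelder-Mead.  Returns (angles_deg (pitch, roll, yaw), misfit).
    """
    grid = np.arange(-span, span + step / 2, step)
    P, Rl, Y = np.meshgrid(grid, grid, grid, indexing="ij")
    angles = np.column_stack([Y.ravel(), Rl.ravel(), P.ravel()])  # zyx order
    mats = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
    rotated = np.einsum("nij,kj->nki", mats, plan_vectors)
    misfit = ((rotated - post_vectors[None]) ** 2).sum(axis=(1, 2))
    k = int(np.argmin(misfit))
    start = (angles[k, 2], angles[k, 1], angles[k, 0])  # pitch, roll, yaw
    res = minimize(
        rotation_misfit, start, args=(plan_vectors, post_vectors),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
    )
    return np.asarray(res.x), float(res.fun)
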