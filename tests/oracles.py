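"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own algorithms: superposition is
minimized by brute force over a quaternion grid (with derivative-free
local polish), and eigenvalues come from deflated power iteration.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def _rmsd_given_rotation(X: np.ndarray, Y: np.ndarray, R: np.ndarray) -> float:
    """RMSD with the optimal translation for a fixed rotation (centroid match)."""
    Yr = Y @ R.T
    d = (X - X.mean(axis=0)) - (Yr - Yr.mean(axis=0))
    return float(np.sqrt((d**2).sum(axis=1).mean()))


def quaternion_grid_rmsd(
    X: np.ndarray, Y: np.ndarray, *, n_grid: int = 4000, seed: int = 12345
) -> float:
    """Minimum RMSD over rotations, by quaternion-grid search plus polish.

    A fixed seeded set of uniform random unit quaternions covers SO(3);
    the best grid rotation seeds a Nelder-Mead refinement over the
    rotation vector. Independent of the closed-form solution under test.
    """
    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_grid, 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rots = Rotation.from_quat(quats)

    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    # vectorized residual over the whole grid
    Yr = np.einsum("gij,nj->gni", rots.as_matrix(), Yc)
    d = Yr - Xc[None]
    vals = np.sqrt((d**2).sum(axis=2).mean(axis=1))
    best = int(np.argmin(vals))

    x0 = rots[best].as_rotvec()
    res = minimize(
        lambda v: _rmsd_given_rotation(X, Y, Rotation.from_rotvec(v).as_matrix()),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    return float(min(res.fun, vals[best]))


def power_iteration_eigs(
    C: np.ndarray, k: int, *, n_iter: int = 10000, tol: float = 1e-12, seed: int = 7
) -> np.ndarray:
    """Top-k eigenvalues of a symmetric PSD matrix by deflated power iteration."""
    rng = np.random.default_rng(seed)
    C = C.copy().astype(float)
    n = C.shape[0]
    out = []
    vecs = []
    for _ in range(k):
        v = rng.normal(size=n)
        for u in vecs:
            v -= (v @ u) * u
        nv = np.linalg.norm(v)
        if nv == 0:
            out.append(0.0)
            continue
        v /= nv
        lam_old = 0.0
        for _ in range(n_iter):
            w = C @ v
            for u in vecs:
                w -= (w @ u) * u
            nw = np.linalg.norm(w)
            if nw < 1e-300:
                v = np.zeros(n)
                break
            v = w / nw
            lam = float(v @ C @ v)
            if abs(lam - lam_old) < tol * max(1.0, abs(lam)):
                break
            lam_old = lam
        lam = float(v @ C @ v)
        out.append(max(lam, 0.0))
        if np.linalg.norm(v) > 0:
            vecs.append(v)
            C = C - lam * np.outer(v, v)
    return np.array(out)
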