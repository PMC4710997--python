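"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the constrained-l1
oracle is a general-purpose SLSQP solve of the convex program, and the
aggregation oracle builds the patch-extraction matrices explicitly and
solves the normal equations densely.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def l1_min_oracle(psi: np.ndarray, y: np.ndarray, budget: float) -> np.ndarray:
    """Solve min ||a||_1 s.t. ||y - psi a||^2 <= budget by SLSQP on the
    positive/negative split a = p - q, p, q >= 0."""
    n, k = psi.shape

    def fun(z):
        return np.sum(z)

    def jac(z):
        return np.ones(2 * k)

    def con(z):
        a = z[:k] - z[k:]
        r = y - psi @ a
        return budget - r @ r

    def con_jac(z):
        a = z[:k] - z[k:]
        r = y - psi @ a
        g = 2.0 * psi.T @ r
        return np.concatenate([g, -g])

    # multi-start SLSQP; keep the best feasible solution
    a0, *_ = np.linalg.lstsq(psi, y, rcond=None)
    rng = np.random.default_rng(0)
    starts = [a0, 0.5 * a0, a0 * (1.0 + 0.2 * rng.standard_normal(k))]
    best = None
    best_l1 = np.inf
    for a_start in starts:
        z0 = np.concatenate([np.clip(a_start, 0, None), np.clip(-a_start, 0, None)])
        res = minimize(
            fun,
            z0,
            jac=jac,
            method="SLSQP",
            bounds=[(0.0, None)] * (2 * k),
            constraints=[{"type": "ineq", "fun": con, "jac": con_jac}],
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        a = res.x[:k] - res.x[k:]
        feasible = con(res.x) >= -1e-9 * (budget + 1.0)
        l1 = np.sum(np.abs(a))
        if feasible and l1 < best_l1:
            best, best_l1 = a, l1
    if best is None:
        raise RuntimeError("oracle found no feasible solution from any start")
    return best


def extraction_matrices(image_shape_2d, patch_side, stride):
    """Explicit R matrices (n_pix x n_image_pixels) for one 2D slice."""
    from dwidenoise_sr.patches import patch_grid

    rows, cols = image_shape_2d
    n_img = rows * cols
    mats = []
    for r0 in patch_grid(rows, patch_side, stride):
        for c0 in patch_grid(cols, patch_side, stride):
            R = np.zeros((patch_side**2, n_img))
            for a in range(patch_side):
                for b in range(patch_side):
                    R[a * patch_side + b, (r0 + a) * cols + (c0 + b)] = 1.0
            mats.append(R)
    return mats


def dense_aggregate_oracle(y_2d, coded_patches, patch_side, stride, lam):
    """Literal dense solve of the weighted-aggregation normal equations for
    one slice: x = (lam I + sum R'R)^(-1) (lam y + sum R' p)."""
    rows, cols = y_2d.shape
    mats = extraction_matrices((rows, cols), patch_side, stride)
    assert len(mats) == coded_patches.shape[1]
    n = rows * cols
    A = lam * np.eye(n)
    b = lam * y_2d.ravel()
    for p, R in enumerate(mats):
        A += R.T @ R
        b += R.T @ coded_patches[:, p]
    return np.linalg.solve(A, b).reshape(rows, cols)
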