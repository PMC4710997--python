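"""Diffusion tensor fitting, fractional anisotropy, and FA error metrics.

Tensors are fit voxelwise by ordinary least squares on the log-linearized
signal model ln S = ln S0 - b g'Dg (7 unknowns: ln S0 and the 6 unique
tensor entries).  FA follows the standard eigenvalue-dispersion definition
FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, clamped to [0, 1];
colored FA encodes the principal eigenvector as RGB = FA * |e1| with
red/green/blue for left-right / anterior-posterior / superior-inferior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DWISequence, TensorField

__all__ = [
    "FAMaps",
    "FAErrorStats",
    "default_mask",
    "fit_tensors",
    "fa",
    "colored_fa",
    "rmse_fa",
    "fa_error_stats",
]

# lower-triangular tensor channel order used throughout the package
TENSOR_CHANNELS = ("Dxx", "Dxy", "Dyy", "Dxz", "Dyz", "Dzz")
_LT_INDEX = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


@dataclass
class FAMaps:
    """Scalar FA map, direction-encoded color map, and the tissue mask."""

    fa: np.ndarray  # (rows, cols, n_slices) in [0, 1]
    rgb: np.ndarray  # (rows, cols, n_slices, 3) in [0, 1]
    mask: np.ndarray  # bool


@dataclass
class FAErrorStats:
    """Voxelwise FA error summary over the shared mask.

    rmse^2 = bias^2 + variance * (q-1)/q (sample-variance convention).
    """

    bias: float
    variance: float
    rmse: float
    q: int


def default_mask(dwi: DWISequence, threshold: float = 0.1) -> np.ndarray:
    """Tissue mask: voxels whose b=0 intensity exceeds ``threshold`` times
    the mean b=0 intensity."""
    b0 = dwi.scheme.b0_indices
    if b0.size == 0:
        raise ValueError("sequence has no b=0 volume")
    vol = dwi.data[..., b0].mean(axis=-1)
    return vol > threshold * vol.mean()


def _design_matrix(scheme) -> np.ndarray:
    """(n_volumes, 7) design: ln S = B @ [ln S0, Dxx, Dxy, Dyy, Dxz, Dyz, Dzz]."""
    b = scheme.b_values
    g = scheme.directions
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -2 * b * gx * gy,
            -b * gy * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
            -b * gz * gz,
        ]
    )


def fit_tensors(
    dwi: DWISequence,
    mask: np.ndarray | None = None,
    *,
    weighted: bool = False,
    intensity_floor: float = 1e-8,
) -> TensorField:
    """Voxelwise least-squares tensor fit.

    Ordinary least squares on ln S (the standard log-linear fit); with
    ``weighted=True`` a one-pass WLS with weights S^2 (the first-order
    variance correction for log-transformed Rician-corrupted magnitudes).
    Intensities <= 0 are floored before the log.  Negative eigenvalues are
    retained in the returned field's tensors; FA computation clamps them.
    """
    scheme = dwi.scheme
    n_dw = int(np.sum(scheme.b_values > 0))
    if n_dw < 6 or scheme.b0_indices.size < 1:
        raise ValueError(
            "tensor fit needs >= 6 diffusion-weighted volumes and >= 1 b=0 volume"
        )
    if mask is None:
        mask = default_mask(dwi)
    B = _design_matrix(scheme)
    cond = np.linalg.cond(B)
    if cond > 1e8:
        raise ValueError(
            f"gradient scheme gives a rank-deficient design (condition number {cond:.3g})"
        )
    S = dwi.data[mask]  # (n_masked, n_volumes)
    logS = np.log(np.maximum(S, intensity_floor))
    if weighted:
        coeffs = np.empty((S.shape[0], 7))
        for i in range(S.shape[0]):
            w = S[i] ** 2
            Bw = B * w[:, None]
            coeffs[i] = np.linalg.solve(B.T @ Bw, Bw.T @ logS[i])
    else:
        coeffs, *_ = np.linalg.lstsq(B, logS.T, rcond=None)
        coeffs = coeffs.T  # (n_masked, 7)
    d6 = coeffs[:, 1:]
    tensors = np.zeros(mask.shape + (3, 3))
    vox = np.zeros((d6.shape[0], 3, 3))
    for c, (i, j) in enumerate(_LT_INDEX):
        vox[:, i, j] = d6[:, c]
        vox[:, j, i] = d6[:, c]
    tensors[mask] = vox
    # background voxels stay zero tensors (symmetric, PSD)
    return TensorField(tensors=tensors, mask=np.asarray(mask, dtype=bool))


def fa(tensor: np.ndarray) -> float:
    """Fractional anisotropy of one 3x3 symmetric tensor, in [0, 1]."""
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3) or np.max(np.abs(t - t.T)) > 1e-10:
        raise ValueError("fa expects a single symmetric 3x3 tensor")
    lam = np.clip(np.linalg.eigvalsh(t), 0.0, None)
    norm = np.linalg.norm(lam)
    if norm == 0:
        return 0.0
    dev = lam - lam.mean()
    return float(np.clip(np.sqrt(1.5) * np.linalg.norm(dev) / norm, 0.0, 1.0))


def _eig_field(field: TensorField) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of masked tensors: (eigenvalues asc, eigenvectors)."""
    t = field.tensors[field.mask]
    w, V = np.linalg.eigh(t)
    return w, V


def colored_fa(field: TensorField) -> FAMaps:
    """FA and direction-encoded color maps for a tensor field.

    Eigenvalues are clamped to zero before the FA ratio so noisy fits stay
    in [0, 1]; the eigenvector sign ambiguity is removed by the absolute
    value in RGB = FA * |e1|.
    """
    shape = field.shape
    fa_map = np.zeros(shape)
    rgb = np.zeros(shape + (3,))
    if np.any(field.mask):
        w, V = _eig_field(field)
        lam = np.clip(w, 0.0, None)
        norm = np.linalg.norm(lam, axis=1)
        dev = lam - lam.mean(axis=1, keepdims=True)
        vals = np.zeros(lam.shape[0])
        ok = norm > 0
        vals[ok] = np.sqrt(1.5) * np.linalg.norm(dev[ok], axis=1) / norm[ok]
        vals = np.clip(vals, 0.0, 1.0)
        e1 = V[:, :, 2]  # eigh ascending -> last column is principal
        fa_map[field.mask] = vals
        rgb[field.mask] = vals[:, None] * np.abs(e1)
    return FAMaps(fa=fa_map, rgb=np.clip(rgb, 0.0, 1.0), mask=field.mask.copy())


def _shared_diff(fa_ref: FAMaps, fa_est: FAMaps) -> np.ndarray:
    if fa_ref.fa.shape != fa_est.fa.shape:
        raise ValueError("FA maps have different shapes")
    mask = fa_ref.mask & fa_est.mask
    if not np.any(mask):
        raise ValueError("empty shared mask")
    return fa_est.fa[mask] - fa_ref.fa[mask]


def rmse_fa(fa_ref: FAMaps, fa_est: FAMaps) -> float:
    """Root mean squared FA error over the shared non-background mask:
    sqrt( sum_q (FA_q - FA_hat_q)^2 / Q )."""
    d = _shared_diff(fa_ref, fa_est)
    return float(np.sqrt(np.mean(d**2)))


def fa_error_stats(fa_ref: FAMaps, fa_est: FAMaps) -> FAErrorStats:
    """Bias (mean error), variance, RMSE and voxel count of the FA error."""
    d = _shared_diff(fa_ref, fa_est)
    q = d.size
    var = float(np.var(d, ddof=1)) if q > 1 else 0.0
    return FAErrorStats(
        bias=float(np.mean(d)),
        variance=var,
        rmse=float(np.sqrt(np.mean(d**2))),
        q=q,
    )
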