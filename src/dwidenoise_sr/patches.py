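"""Overlapping patch extraction and closed-form weighted reaggregation.

A patch operator R lifts the pixels of a square window out of a slice; its
adjoint R' scatters a represented patch back.  Because the sum of R'R over
all patch positions is diagonal (each diagonal entry counts how many patches
cover that pixel), the clean-image update

    x_l = (lam*I + sum R'R)^(-1) (lam*y_l + sum R' * coded_patch)

reduces to a pixelwise ratio, computed here without ever forming R.

Vectorization order: patches are flattened row-major (C order) within the
window, i.e. element ``p[a, b]`` of a ``side x side`` window maps to entry
``a * side + b`` of the column vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PatchSet", "extract_patches", "aggregate_clean_image", "patch_grid"]


@dataclass
class PatchSet:
    """Vectorized patches plus the bookkeeping to put them back.

    ``patches`` is (n_pix, n_patches) with n_pix = patch_side**2;
    ``origins`` is (n_patches, 3) rows of (slice, row, col) top-left corners,
    0-based; patches never cross the image border.
    """

    patches: np.ndarray
    origins: np.ndarray
    patch_side: int
    image_shape: tuple[int, int, int]  # (rows, cols, n_slices)

    def __post_init__(self):
        if self.patches.shape[0] != self.patch_side**2:
            raise ValueError("patches rows must equal patch_side**2")
        if self.origins.shape != (self.patches.shape[1], 3):
            raise ValueError("origins must be (n_patches, 3)")

    @property
    def n_patches(self) -> int:
        return self.patches.shape[1]

    @property
    def n_pix(self) -> int:
        return self.patches.shape[0]


def patch_grid(extent: int, patch_side: int, stride: int) -> np.ndarray:
    """Top-left offsets along one axis: multiples of ``stride`` plus the
    flush-to-border offset so every pixel is covered."""
    last = extent - patch_side
    offs = np.arange(0, last + 1, stride)
    if offs[-1] != last:
        offs = np.append(offs, last)
    return offs


def extract_patches(images: np.ndarray, patch_side: int, stride: int = 1) -> PatchSet:
    """Extract all square patches from a (rows, cols, n_slices) slice stack.

    Patches are taken at every multiple of ``stride`` plus the patches flush
    against the right/bottom borders; with stride=1 that is the full
    maximally-overlapping grid.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[..., None]
    rows, cols, n_slices = images.shape
    if patch_side > min(rows, cols):
        raise ValueError(
            f"patch_side {patch_side} exceeds image extent {min(rows, cols)}"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if stride > patch_side:
        raise ValueError(
            f"stride {stride} > patch_side {patch_side} would leave pixels uncovered"
        )

    r_offs = patch_grid(rows, patch_side, stride)
    c_offs = patch_grid(cols, patch_side, stride)
    n_per_slice = r_offs.size * c_offs.size

    n_pix = patch_side**2
    n_patches = n_per_slice * n_slices
    patches = np.empty((n_pix, n_patches))
    origins = np.empty((n_patches, 3), dtype=np.int64)

    # windows view: (n_r, n_c, side, side) per slice via stride tricks
    idx = 0
    for l in range(n_slices):
        sl = images[:, :, l]
        win = np.lib.stride_tricks.sliding_window_view(sl, (patch_side, patch_side))
        block = win[np.ix_(r_offs, c_offs)]  # (nr, nc, side, side)
        nr, nc = block.shape[:2]
        patches[:, idx : idx + n_per_slice] = (
            block.reshape(nr * nc, n_pix).T
        )
        rr, cc = np.meshgrid(r_offs, c_offs, indexing="ij")
        origins[idx : idx + n_per_slice, 0] = l
        origins[idx : idx + n_per_slice, 1] = rr.ravel()
        origins[idx : idx + n_per_slice, 2] = cc.ravel()
        idx += n_per_slice
    return PatchSet(
        patches=patches,
        origins=origins,
        patch_side=patch_side,
        image_shape=(rows, cols, n_slices),
    )


def _scatter_add(patchset: PatchSet, values: np.ndarray):
    """Sum of R' * value over all patches, and the per-pixel cover counts
    (vectorized bincount over linear pixel indices)."""
    rows, cols, n_slices = patchset.image_shape
    side = patchset.patch_side
    dr, dc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    dr = dr.ravel()[:, None]  # (n_pix, 1)
    dc = dc.ravel()[:, None]
    l = patchset.origins[:, 0][None, :]
    r = patchset.origins[:, 1][None, :] + dr
    c = patchset.origins[:, 2][None, :] + dc
    lin = ((r * cols + c) * n_slices + l).ravel()
    n = rows * cols * n_slices
    acc = np.bincount(lin, weights=values.ravel(), minlength=n)
    cnt = np.bincount(lin, minlength=n).astype(float)
    return acc.reshape(rows, cols, n_slices), cnt.reshape(rows, cols, n_slices)


def aggregate_clean_image(
    noisy: np.ndarray,
    patchset: PatchSet,
    coded_patches: np.ndarray,
    lam: float,
) -> np.ndarray:
    """Closed-form clean-image update from represented patches.

    Solves, independently per slice,
    ``x = (lam*I + sum R'R)^(-1) (lam*y + sum R' p_hat)``
    where ``p_hat`` are the coded (represented) patches.  ``sum R'R`` is the
    diagonal matrix of per-pixel cover counts, so the solve is a pixelwise
    ratio, exact to the closed form.
    """
    noisy = np.asarray(noisy, dtype=float)
    if noisy.ndim == 2:
        noisy = noisy[..., None]
    if noisy.shape != patchset.image_shape:
        raise ValueError(
            f"noisy shape {noisy.shape} != patchset image shape {patchset.image_shape}"
        )
    if coded_patches.shape != patchset.patches.shape:
        raise ValueError(
            f"coded_patches shape {coded_patches.shape} != "
            f"patch matrix shape {patchset.patches.shape}"
        )
    if lam < 0:
        raise ValueError("lam must be >= 0")
    acc, cnt = _scatter_add(patchset, coded_patches)
    if np.any(cnt == 0) and lam == 0:
        raise ValueError("some pixels are covered by no patch and lam=0")
    return (lam * noisy + acc) / (lam + cnt)
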