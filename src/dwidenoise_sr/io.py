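"""Readers and writers for diffusion MRI bundles.

A bundle is the FSL-style trio: a 4D NIfTI image, a ``.bval`` text file
(one whitespace-separated row of b-values) and a ``.bvec`` file (three
rows: x, y, z components, one column per volume).  Ground-truth tensor
fields are stored as 4D NIfTI with 6 channels in lower-triangular order
(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import DWISequence, GradientScheme, TensorField
from .tensor_metrics import FAMaps, _LT_INDEX

__all__ = [
    "DatasetBundle",
    "read_dwi",
    "write_dwi",
    "write_bundle",
    "read_tensor_field",
    "write_tensor_field",
    "write_fa_maps",
]


@dataclass
class DatasetBundle:
    """A resolved on-disk DWI dataset plus provenance for write-back."""

    image_path: Path
    bval_path: Path
    bvec_path: Path
    sequence: DWISequence
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)


def _read_gradients(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.atleast_1d(np.loadtxt(bval_path))
    if bvals.ndim != 1:
        raise ValueError(f"{bval_path}: expected a single row of b-values")
    bvecs = np.atleast_2d(np.loadtxt(bvec_path))
    if bvecs.shape[0] != 3:
        raise ValueError(
            f"{bvec_path}: expected the FSL dialect with exactly 3 rows (x, y, z), "
            f"got {bvecs.shape[0]} rows — a column-major (one-column-per-axis) "
            "table must be transposed first"
        )
    return bvals, bvecs.T  # (n, 3)


def read_dwi(image_path, bval_path, bvec_path) -> DatasetBundle:
    """Load and validate a NIfTI + bval + bvec bundle.

    Diffusion-weighted b-vectors are re-normalized to unit length (with a
    warning when off by more than 1e-3); the image affine is kept untouched
    for write-back.
    """
    image_path, bval_path, bvec_path = map(Path, (image_path, bval_path, bvec_path))
    img = nib.load(image_path)
    if img.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4D image, got {img.ndim}D")
    data = np.asarray(img.get_fdata(), dtype=float)
    bvals, bvecs = _read_gradients(bval_path, bvec_path)
    n_vol = data.shape[3]
    if bvals.shape[0] != n_vol or bvecs.shape[0] != n_vol:
        raise ValueError(
            f"volume count mismatch: image has {n_vol} volumes, "
            f"bval has {bvals.shape[0]} entries, bvec has {bvecs.shape[0]} columns"
        )
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        warnings.warn(
            "diffusion-weighted b-vectors deviate from unit norm by more than "
            "1e-3; re-normalizing",
            stacklevel=2,
        )
    bvecs = bvecs.copy()
    bvecs[dw] /= np.linalg.norm(bvecs[dw], axis=1, keepdims=True)
    seq = DWISequence(data=data, scheme=GradientScheme(bvals, bvecs))
    return DatasetBundle(
        image_path=image_path,
        bval_path=bval_path,
        bvec_path=bvec_path,
        sequence=seq,
        affine=img.affine.copy(),
        provenance={
            "shape": data.shape,
            "dtype": str(img.get_data_dtype()),
            "min": float(data.min()),
            "max": float(data.max()),
        },
    )


def write_dwi(sequence: DWISequence, bundle: DatasetBundle, out_path) -> dict:
    """Write a sequence back next to its source bundle.

    The original affine is preserved, the datatype promoted to float32, and
    bval/bvec copied alongside.  Negative intensities (possible after
    processing) are preserved with a warning, never clipped.
    """
    out_path = Path(out_path)
    if sequence.shape != tuple(bundle.provenance.get("shape", sequence.shape)):
        raise ValueError(
            f"sequence shape {sequence.shape} does not match bundle "
            f"{bundle.provenance.get('shape')}"
        )
    if sequence.data.min() < 0:
        warnings.warn(
            "sequence contains negative intensities; writing them unchanged",
            stacklevel=2,
        )
    img = nib.Nifti1Image(sequence.data.astype(np.float32), bundle.affine)
    nib.save(img, out_path)
    base = out_path.name.split(".")[0]
    bval_out = out_path.parent / f"{base}.bval"
    bvec_out = out_path.parent / f"{base}.bvec"
    _write_gradients(sequence.scheme, bval_out, bvec_out)
    return {"image": out_path, "bval": bval_out, "bvec": bvec_out}


def _write_gradients(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.9g")


def write_bundle(sequence: DWISequence, out_prefix, affine=None) -> DatasetBundle:
    """Write a (possibly simulated) sequence as ``<prefix>.nii.gz/.bval/.bvec``."""
    out_prefix = Path(out_prefix)
    affine = np.eye(4) if affine is None else affine
    image_path = out_prefix.with_suffix(".nii.gz")
    nib.save(nib.Nifti1Image(sequence.data.astype(np.float32), affine), image_path)
    bval_path = out_prefix.with_suffix(".bval")
    bvec_path = out_prefix.with_suffix(".bvec")
    _write_gradients(sequence.scheme, bval_path, bvec_path)
    return DatasetBundle(
        image_path=image_path,
        bval_path=bval_path,
        bvec_path=bvec_path,
        sequence=sequence,
        affine=affine,
        provenance={"shape": sequence.shape},
    )


def write_tensor_field(field_: TensorField, path, affine=None) -> None:
    """Tensor field as 4D NIfTI, channels (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)."""
    affine = np.eye(4) if affine is None else affine
    shape = field_.shape
    out = np.empty(shape + (6,), dtype=np.float32)
    for c, (i, j) in enumerate(_LT_INDEX):
        out[..., c] = field_.tensors[..., i, j]
    nib.save(nib.Nifti1Image(out, affine), path)


def read_tensor_field(path, mask_threshold: float = 0.0) -> TensorField:
    """Inverse of :func:`write_tensor_field`; mask = any nonzero channel."""
    img = nib.load(path)
    d6 = np.asarray(img.get_fdata(), dtype=float)
    if d6.ndim != 4 or d6.shape[3] != 6:
        raise ValueError(f"{path}: expected a 4D image with 6 tensor channels")
    tensors = np.zeros(d6.shape[:3] + (3, 3))
    for c, (i, j) in enumerate(_LT_INDEX):
        tensors[..., i, j] = d6[..., c]
        tensors[..., j, i] = d6[..., c]
    mask = np.any(np.abs(d6) > mask_threshold, axis=-1)
    return TensorField(tensors=tensors, mask=mask)


def write_fa_maps(maps: FAMaps, out_prefix, affine=None, png: bool = False) -> None:
    """Scalar FA as NIfTI, colored FA as a 3-channel NIfTI; optional PNG
    montage (one panel per slice) for quick inspection."""
    affine = np.eye(4) if affine is None else affine
    out_prefix = Path(out_prefix)
    nib.save(
        nib.Nifti1Image(maps.fa.astype(np.float32), affine),
        out_prefix.parent / (out_prefix.name + "_fa.nii.gz"),
    )
    nib.save(
        nib.Nifti1Image(maps.rgb.astype(np.float32), affine),
        out_prefix.parent / (out_prefix.name + "_rgb.nii.gz"),
    )
    if png:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n_slices = maps.fa.shape[2]
        fig, axes = plt.subplots(2, n_slices, figsize=(2.2 * n_slices, 4.6))
        axes = np.atleast_2d(axes)
        for s in range(n_slices):
            axes[0, s].imshow(maps.fa[:, :, s], cmap="gray", vmin=0, vmax=1)
            axes[1, s].imshow(maps.rgb[:, :, s])
            for ax in (axes[0, s], axes[1, s]):
                ax.set_axis_off()
        fig.tight_layout()
        fig.savefig(out_prefix.parent / (out_prefix.name + "_fa.png"), dpi=120)
        plt.close(fig)
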