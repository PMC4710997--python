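"""Synthetic DWI phantom: parametric tensor fields and the forward model.

The phantom stands in for a real acquisition: a smooth 3x3 diffusion-tensor
field on a voxel grid, a gradient scheme (one or more b=0 volumes plus
diffusion-weighted directions on the half-sphere), the Stejskal-Tanner
forward signal S = S0 * exp(-b g'Dg), and independent Rician noise of a
standard deviation calibrated to 1/10 of the mean b=0 intensity in the
image center.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "GradientScheme",
    "TensorField",
    "DWISequence",
    "make_gradient_scheme",
    "make_tensor_field",
    "simulate_dwi",
    "add_rician_noise",
    "b0_center_noise_level",
]

#: diffusivity of free-ish background tissue, mm^2/s
_BACKGROUND_DIFFUSIVITY = 0.2e-3
_ISO_DIFFUSIVITY = 0.7e-3
_ANISO_EIGVALS = np.array([1.7e-3, 0.3e-3, 0.3e-3])

PATTERNS = ("uniform", "two_region", "crossing")


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion-encoding scheme: b-values (s/mm^2) and unit directions."""

    b_values: np.ndarray
    directions: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        if g.ndim != 2 or g.shape[1] != 3 or g.shape[0] != b.shape[0]:
            raise ValueError(
                f"directions must be (n, 3) matching {b.shape[0]} b-values, got {g.shape}"
            )
        if not np.any(b == 0):
            raise ValueError("gradient scheme must contain at least one b=0 entry")
        norms = np.linalg.norm(g[b > 0], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("diffusion-weighted directions must be unit vectors")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    def __len__(self) -> int:
        return self.b_values.shape[0]

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.b_values == 0)


@dataclass
class TensorField:
    """Per-voxel 3x3 symmetric diffusion tensors on a (rows, cols, slices) grid."""

    tensors: np.ndarray  # (rows, cols, n_slices, 3, 3), mm^2/s
    mask: np.ndarray  # (rows, cols, n_slices) bool, True = tissue

    def __post_init__(self):
        t = np.asarray(self.tensors, dtype=float)
        m = np.asarray(self.mask, dtype=bool)
        if t.ndim != 5 or t.shape[3:] != (3, 3) or t.shape[:3] != m.shape:
            raise ValueError(f"tensors {t.shape} incompatible with mask {m.shape}")
        if np.max(np.abs(t - t.transpose(0, 1, 2, 4, 3))) > 1e-12:
            raise ValueError("tensors must be symmetric")
        self.tensors = t
        self.mask = m

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def masked_eigenvalues(self) -> np.ndarray:
        """Eigenvalues of every masked tensor, shape (n_masked, 3) ascending."""
        return np.linalg.eigvalsh(self.tensors[self.mask])


@dataclass
class DWISequence:
    """A 4D stack of DWI slices: (rows, cols, n_slices, n_volumes)."""

    data: np.ndarray
    scheme: GradientScheme
    sigma: float | None = None

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4:
            raise ValueError(f"data must be 4D (rows, cols, slices, volumes), got {d.shape}")
        if d.shape[3] != len(self.scheme):
            raise ValueError(
                f"{d.shape[3]} volumes but gradient scheme has {len(self.scheme)} entries"
            )
        self.data = d

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def volume(self, v: int) -> np.ndarray:
        return self.data[..., v]


def make_gradient_scheme(
    n_directions: int = 32, b_value: float = 1000.0, n_b0: int = 1
) -> GradientScheme:
    """Quasi-uniform half-sphere scheme: ``n_b0`` b=0 volumes + ``n_directions``
    diffusion-weighted directions at ``b_value`` (s/mm^2).

    Directions follow a spherical Fibonacci spiral restricted to z >= 0, a
    standard deterministic stand-in for electrostatic-repulsion schemes that
    keeps the tensor design matrix well conditioned.
    """
    if n_directions < 6:
        raise ValueError("need at least 6 directions to identify a tensor")
    i = np.arange(n_directions)
    golden = (1 + np.sqrt(5)) / 2
    # z in (0, 1]: half-sphere only; antipodal directions are redundant in DTI
    z = (i + 0.5) / n_directions
    phi = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    b = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b_value))])
    g = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(b, g)


def _rotz(theta: np.ndarray) -> np.ndarray:
    """Stack of rotations about the slice axis, shape (..., 3, 3)."""
    c, s = np.cos(theta), np.sin(theta)
    out = np.zeros(theta.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def _tensors_from_eig(eigvals: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """D = R diag(eigvals) R', R = in-plane rotation by theta. Symmetrized."""
    R = _rotz(theta)
    D = np.einsum("...ij,...j,...kj->...ik", R, eigvals, R)
    return 0.5 * (D + np.swapaxes(D, -1, -2))


def make_tensor_field(
    shape: tuple[int, int, int], pattern: str, seed: int = 0
) -> TensorField:
    """Generate a smooth synthetic tensor field.

    Patterns
    --------
    ``uniform``
        every tissue voxel is isotropic, diag(0.7, 0.7, 0.7) x 1e-3 mm^2/s.
    ``two_region``
        a wavy boundary splits the tissue into a high-FA region (anisotropic,
        principal direction rotating smoothly in-plane) and a near-isotropic
        low-FA region; mimics white matter next to gray matter.
    ``crossing``
        two oblique anisotropic stripes with different orientations over an
        isotropic ground.

    Background voxels (outside the elliptical tissue mask) are isotropic with
    small diffusivity.  Deterministic for a given (shape, pattern, seed).
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; valid patterns: {PATTERNS}")
    rows, cols, n_slices = shape
    if rows < 4 or cols < 4 or n_slices < 1:
        raise ValueError(f"shape {shape} too small")

    rng = np.random.default_rng(seed)
    rr, cc, ss = np.meshgrid(
        np.arange(rows), np.arange(cols), np.arange(n_slices), indexing="ij"
    )
    u = (rr - (rows - 1) / 2) / (rows / 2)  # in [-1, 1]
    v = (cc - (cols - 1) / 2) / (cols / 2)
    mask = u**2 + v**2 <= 0.9**2

    # smooth seeded perturbations: orientation jitter and eigenvalue jitter
    smooth = gaussian_filter(rng.standard_normal(shape), sigma=(4, 4, 1), mode="nearest")
    smooth /= max(np.max(np.abs(smooth)), 1e-12)

    eigvals = np.empty(shape + (3,))
    theta = np.zeros(shape)
    iso = np.full(3, _ISO_DIFFUSIVITY)

    if pattern == "uniform":
        eigvals[...] = iso
    elif pattern == "two_region":
        aniso_region = u < 0.2 * np.sin(3 * np.pi * v)  # wavy split
        # principal direction rotates smoothly with column + mild seeded jitter
        theta = 0.6 * np.pi * v + 0.15 * smooth
        jitter = 1.0 + 0.05 * smooth[..., None]
        eigvals = np.where(aniso_region[..., None], _ANISO_EIGVALS, iso) * jitter
    else:  # crossing
        d1 = np.abs(u - v) < 0.25
        d2 = np.abs(u + v) < 0.25
        theta = np.where(d1, np.pi / 4, np.where(d2, -np.pi / 4, 0.0)) + 0.1 * smooth
        stripe = d1 | d2
        jitter = 1.0 + 0.05 * smooth[..., None]
        eigvals = np.where(stripe[..., None], _ANISO_EIGVALS, iso) * jitter

    tensors = _tensors_from_eig(eigvals, theta)
    tensors[~mask] = np.diag([_BACKGROUND_DIFFUSIVITY] * 3)
    return TensorField(tensors=tensors, mask=mask)


def simulate_dwi(
    field: TensorField,
    scheme: GradientScheme,
    s0: float = 100.0,
    background_scale: float = 0.05,
) -> DWISequence:
    """Noise-free Stejskal-Tanner forward simulation.

    Each tissue voxel gets intensity ``s0 * exp(-b g'Dg)``; b=0 volumes equal
    ``s0`` exactly inside the mask.  Background voxels use a dim unweighted
    amplitude ``s0 * background_scale`` so that intensity-based tissue masks
    behave as on real magnitude images.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    eig = field.masked_eigenvalues()
    if eig.size and eig.min() < -1e-10:
        raise ValueError(
            "tensor field contains non-PSD tensors inside the mask; "
            "signal would grow with b"
        )
    amp = np.where(field.mask, s0, s0 * background_scale)
    # quadratic form g'Dg for every voxel/volume: (r,c,s,v)
    quad = np.einsum("rcsij,vi,vj->rcsv", field.tensors, scheme.directions,
                     scheme.directions, optimize=True)
    data = amp[..., None] * np.exp(-scheme.b_values[None, None, None, :] * quad)
    return DWISequence(data=data, scheme=scheme, sigma=None)


def add_rician_noise(clean: DWISequence, sigma: float, seed: int = 0) -> DWISequence:
    """Magnitude-MRI (Rician) corruption: ``sqrt((x + e1)^2 + e2^2)`` with
    ``e1, e2 ~ N(0, sigma^2)`` i.i.d. per voxel and volume."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return DWISequence(data=clean.data.copy(), scheme=clean.scheme, sigma=0.0)
    rng = np.random.default_rng(seed)
    e1 = rng.normal(0.0, sigma, size=clean.data.shape)
    e2 = rng.normal(0.0, sigma, size=clean.data.shape)
    noisy = np.hypot(clean.data + e1, e2)
    return DWISequence(data=noisy, scheme=clean.scheme, sigma=float(sigma))


def b0_center_noise_level(clean: DWISequence, center_fraction: float = 0.25) -> float:
    """Noise standard deviation as 1/10 of the mean intensity in the central
    ``center_fraction`` window (per axis) of the first b=0 volume."""
    if not (0 < center_fraction <= 1):
        raise ValueError("center_fraction must be in (0, 1]")
    b0 = clean.scheme.b0_indices
    if b0.size == 0:
        raise ValueError("sequence has no b=0 volume")
    vol = clean.volume(int(b0[0]))
    rows, cols = vol.shape[:2]
    hr = max(1, int(round(rows * center_fraction)))
    hc = max(1, int(round(cols * center_fraction)))
    r0 = (rows - hr) // 2
    c0 = (cols - hc) // 2
    return 0.1 * float(np.mean(vol[r0 : r0 + hr, c0 : c0 + hc, :]))
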