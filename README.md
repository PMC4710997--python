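# dwidenoise-sr

Sparse-representation denoising for 3D diffusion-weighted MRI (DWI), built
around K-SVD dictionary learning over groups of adjacent slices.

## The problem

Diffusion tensor imaging (DTI) estimates a 3×3 symmetric positive
semidefinite tensor D at every voxel from a sequence of diffusion-weighted
volumes following the Stejskal–Tanner model

    S(b, g) = S0 · exp(−b gᵀ D g),

where b is the diffusion weighting (s/mm²) and g a unit gradient direction.
Magnitude MRI corrupts these volumes with Rician noise, which biases the
fitted tensors and the fractional anisotropy (FA) maps derived from them —
exactly the quantities clinicians and neuroscientists read. This package
denoises the DWI volumes *before* tensor fitting.

## The method

Each 2D slice is decomposed into all overlapping √n×√n patches. A patch y is
modeled as Ψα with Ψ an overcomplete dictionary (n × k, k > n, unit-norm
columns) and α sparse. Denoising solves, per group of L adjacent slices,

    argmin_{α,X}  λ‖Y − X‖² + Σ_{ijl} ‖R_ijl X − Ψ α_ijl‖² + Σ_{ijl} μ_ijl ‖α_ijl‖₁

by block-coordinate relaxation:

1. **Sparse coding** — every patch solves
   `min ‖α‖₁ s.t. ‖y − Ψα‖² ≤ C·n·σ²` (error-constrained Lasso, solved
   exactly along the LARS-lasso path with a closed-form stop at the budget),
2. **Dictionary update** — K-SVD: each atom is replaced by the leading
   singular vector of its restricted representation residual, starting from
   an overcomplete 2D-DCT dictionary,
3. **Reconstruction** — the clean slice has the closed form
   `x_l = (λI + Σ RᵀR)⁻¹ (λ y_l + Σ Rᵀ Ψα)`, a pixelwise weighted average
   of the coded patches and the noisy input.

The key idea is *context redundancy*: adjacent slices of a 3D volume share
structure, so one dictionary is trained on the pooled patches of L
neighboring slices, giving more training samples per dictionary and fewer
dictionaries to train. Across successive gradient volumes, the learned
dictionary warm-starts the next volume's training, which cuts the number of
K-SVD rounds substantially.

A parametric tensor phantom (uniform / two-region / crossing-fiber
patterns), a Rician noise simulator calibrated to σ = 1/10 of the mean
central b=0 intensity, log-linear least-squares tensor fitting, and FA /
colored-FA error metrics (bias, variance, RMSE_FA) make the whole pipeline
testable end to end without any external data.

## Worked example

```python
import numpy as np
import dwidenoise_sr as dsr

# simulate: two-region tensor field, 1 b=0 + 32 directions at b=1000 s/mm²
field  = dsr.make_tensor_field((64, 64, 5), "two_region", seed=1)
scheme = dsr.make_gradient_scheme(n_directions=32, b_value=1000.0)
clean  = dsr.simulate_dwi(field, scheme, s0=100.0)
sigma  = dsr.b0_center_noise_level(clean)        # 10.0  (1/10 of mean b0 center)
noisy  = dsr.add_rician_noise(clean, sigma, seed=11)

# denoise: 8x8 patches, 64x256 dictionary, C=1.2, sparsity cap 5
result = dsr.DWIDenoiser(noisy, dsr.DenoiseConfig(seed=1)).fit()
print(result.summary())

rmse = lambda a, b: np.sqrt(np.mean((a - b) ** 2))
print(f"RMSE  noisy: {rmse(noisy.data, clean.data):.3f}"
      f"  denoised: {rmse(result.data, clean.data):.3f}")

ref   = dsr.colored_fa(field)
den   = dsr.colored_fa(dsr.fit_tensors(result.denoised, field.mask))
nsy   = dsr.colored_fa(dsr.fit_tensors(noisy, field.mask))
print(f"RMSE_FA noisy: {dsr.rmse_fa(ref, nsy):.4f}"
      f"  denoised: {dsr.rmse_fa(ref, den):.4f}")
```

Output (abridged):

```
Sparse-representation DWI denoising
================================================
sequence shape: 64 x 64, 5 slices, 33 volumes
sigma: 10   lambda: 3
patch 8x8, dictionary 64 x 256, C=1.2, sparsity cap 5
slice groups per volume: 1 (L=5), max 15 training rounds
...
RMSE  noisy: 10.409  denoised: 6.366
RMSE_FA noisy: 0.1707  denoised: 0.0850
```

The denoiser removes ~39% of the voxelwise error and roughly halves the FA
error; the FA bias (Rician noise inflates apparent anisotropy, here from
+0.108 to +0.020) and variance shrink accordingly.

## Command line

```bash
dwidenoise-sr simulate --out-prefix phantom --rows 64 --cols 64 --slices 5
dwidenoise-sr run --in phantom.nii.gz --bval phantom.bval --bvec phantom.bvec \
    --out denoised.nii.gz --estimate-sigma --report report.json
dwidenoise-sr eval --ref phantom_clean.nii.gz --test denoised.nii.gz \
    --bval phantom.bval --bvec phantom.bvec --out stats.json
```

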