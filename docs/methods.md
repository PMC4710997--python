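# Methods

## Signal model and noise

A DWI sequence samples S(b, g) = S0·exp(−b gᵀDg) per voxel, with D the 3×3
symmetric PSD diffusion tensor (mm²/s). Magnitude reconstruction makes the
observed intensity Rician: y = √((x+ε₁)² + ε₂²), ε₁,ε₂ ~ N(0, σ²). The
simulator calibrates σ as 1/10 of the mean intensity of the central 25%×25%
window of the first b=0 volume (exposed as `center_fraction`); the sweep
harness scales the same base level to 5–20%.

The denoiser itself treats the noise as additive with standard deviation σ
inside its ℓ2 terms — the standard sparse-coding treatment — and applies no
Rician bias correction. At the simulated SNR (b=0 tissue ≈ 10σ) the residual
magnitude bias is visible mainly in the diffusion-weighted volumes; the FA
bias measurements quantify what remains after denoising.

## The denoising objective

For one group of L adjacent slices Y = [Y₁…Y_L]:

argmin_{α,X} λ‖Y−X‖² + Σ_{ijl}‖R_ijl X − Ψα_ijl‖² + Σ_{ijl} μ_ijl‖α_ijl‖₁

solved by block-coordinate relaxation with X initialized to Y:

1. **Coding.** Each patch solves min ‖α‖₁ s.t. ‖y−Ψα‖² ≤ C·n_pix·σ²
   (the Lagrangian form above with per-patch μ absorbed into the budget).
   The solver traces the LARS-lasso path on the dictionary Gram matrix; the
   squared residual is an explicit quadratic in the step along each path
   segment, so the budget crossing is found in closed form and the
   coefficients interpolated exactly. An optional support cap (default 5)
   freezes the active set once full, riding the restricted path toward
   λ→0; drops re-open the set. Patches that cannot meet the budget under
   the cap keep their best code and carry an explicit infeasibility flag.
2. **Dictionary update.** Sequential K-SVD: for atom m, the residual of the
   patches using m (with m's contribution removed) is rank-1 factorized
   (full SVD for few users, eigendecomposition of E·Eᵀ otherwise — the two
   agree to ~1e-12); the atom becomes the leading left singular vector and
   the using-patches' coefficients the scaled right singular vector. Signs
   are canonicalized (first nonzero entry of each atom positive) so runs
   are bit-reproducible. After each sweep, unused atoms and near-duplicates
   (|correlation| > 0.99) are replaced by the currently worst-represented
   patches; their codes are recomputed at the next coding pass.
3. **Reconstruction.** With codes fixed, X has the closed form
   x_l = (λI + Σ RᵀR)⁻¹(λy_l + Σ RᵀΨα). Σ RᵀR is diagonal (per-pixel patch
   cover counts), so this is a pixelwise ratio, computed without forming R.

Training starts from the overcomplete separable 2D-DCT dictionary (r=√k
mean-removed cosine atoms per axis, all outer products, unit-normalized;
the first atom is the constant patch, which absorbs the DC component — no
mean subtraction is applied to patches).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| patch_side | 8 | 8×8 patches for 256-scale images; 6×6 preset for small images (36×100 dictionary) |
| k | 256 | atoms; 4× overcomplete for n_pix=64 |
| C | 1.2 | budget constant in C·n_pix·σ² |
| max_nonzeros | 5 | sparsity cap per patch |
| L (group_size) | 5 | adjacent slices sharing one dictionary |
| n_iterations | 15 | maximum K-SVD rounds per group |
| λ | 30/σ | fidelity weight; the canonical K-SVD-denoising choice, 0 when σ=0 |
| stride | 1 | maximally overlapping patch grid (flush-to-border patches guarantee coverage when stride>1; stride ≤ patch_side enforced) |
| rel_tol | 1e-3 | early stop when a coding pass improves the representation error by <0.1% |
| train_subsample | 40000 | training-pool cap; the final coding pass always covers all patches |

λ, L and stride are declared package defaults — genuinely open design
choices, not values with an external referent. `learn_dictionary` itself
defaults to rel_tol=0 (exactly n_iterations rounds); the pipeline-level
early stop exists because warm-started volumes converge in 2–4 rounds
(the mechanism that motivates carrying dictionaries across volumes in the
first place), and a fixed 15 rounds everywhere adds cost without quality.

Warm starting: slice groups are fixed across volumes; the dictionary
learned for group g of volume v initializes group g of volume v+1, with
the DCT dictionary seeding volume 0. Volumes are otherwise denoised
independently, b=0 and b>0 alike, with one shared σ.

## Tensor fitting and FA metrics

Tensors are fit voxelwise by OLS on ln S = ln S0 − b gᵀDg (7 unknowns;
intensities floored at 1e-8 before the log; WLS with S² weights available
behind a flag, off by default). The tissue mask defaults to b=0 intensity
> 10% of the b=0 mean. FA = √(3/2)·‖λ−λ̄‖/‖λ‖ with eigenvalues clamped to
zero first, so FA ∈ [0,1] under noisy fits; colored FA is FA·|e₁| with
red/green/blue ↔ x/y/z. Error metrics over the mask: bias (mean FA error),
variance (of the FA error distribution), RMSE_FA = √(Σ(FA−F̂A)²/Q); these
satisfy rmse² = bias² + var·(Q−1)/Q.

## The phantom

`make_tensor_field` builds smooth parametric tensor fields on an elliptical
tissue mask over an isotropic low-diffusivity background: `uniform`
(isotropic 0.7e-3 mm²/s everywhere), `two_region` (a wavy boundary between
an anisotropic region, eigenvalues (1.7,0.3,0.3)e-3 with smoothly rotating
in-plane orientation, and a near-isotropic region), and `crossing` (two
oblique anisotropic stripes). Seeded smooth perturbations (±5% eigenvalue
jitter, small orientation jitter) avoid exactly-repeating patches.
Gradient schemes use a deterministic spherical-Fibonacci half-sphere
(quasi-uniform, well-conditioned design). Background voxels get a dim
unweighted amplitude (5% of S0) so intensity-based masking behaves as on
real magnitude images.

What the phantom reproduces: mixed high/low FA, smooth regions with sharp
boundaries, slice-to-slice redundancy, Rician statistics at a calibrated
SNR. What it does not: EPI/motion/coil artifacts, non-tensor (multi-
compartment) diffusion, anatomical texture richness, spatially varying
noise. Passing tests therefore demonstrate the mechanics and the
noise-reduction behavior of the method under its own assumptions, not
clinical performance.

## Problem sizes and numerical choices

The reference experiment runs at 64×64×5 voxels with 1 b=0 + 32 directions
(the full tensor-estimation design) so the complete 33-volume pipeline,
tensor fits and FA metrics execute in about a minute; the noise-level sweep
uses a 32×32×5 / 12-direction variant. Sparse coding is exact to the path
solution (cross-checked against sklearn's `lars_path` to ~1e-10 and an
independent SLSQP solve of the constrained program to 1e-4 on the ℓ1 norm);
the K-SVD update is checked against the full-SVD Eckart–Young optimum to
1e-9; aggregation is checked against an explicit dense solve of the normal
equations to 1e-8. Degenerate cases: a grazing budget crossing lost to
rounding is clamped; active-set solves carry a 1e-12 diagonal ridge;
reported residual norms are recomputed exactly after coding.

## Known limitations

- Greedy path selection under a tight support cap can lock onto a
  suboptimal support (no backtracking); with exactly-k-sparse synthetic
  data and a coherent dictionary a few percent of patches are affected.
  The error-budget formulation (cap as a secondary guard) is the primary
  operating mode and does not suffer from this.
- No Rician bias correction by default; the optional post-hoc magnitude
  correction x̂ ← √(max(x̂²−2σ², 0)) (`bias_correct=True`) reduces the
  background/diffusion-weighted bias but is deliberately off to match the
  additive-noise treatment of the objective.
- One σ for the whole sequence; spatially varying (parallel-imaging) noise
  is out of scope.
- Runtime grows linearly in volumes × patches × K-SVD rounds; no
  parallel/GPU execution.
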