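# Methods

This note records the models implemented in `guidedpet`, the numerical
conventions behind them, the defaults and why they were chosen, and what
the synthetic phantom does and does not emulate.

## Acquisition model

The forward model is `q(θ) = Aθ + b` for a nonnegative activity image θ on
a regular grid. `A` is a 2D parallel-beam projector assembled once as a
sparse matrix: every voxel center is projected onto the radial axis of
each view and its value split between the two nearest radial bins by
linear interpolation, scaled by the voxel side length so values
approximate line integrals. The backprojector is the exact matrix
transpose, so the adjoint identity holds to machine precision — every EM
update relies on this pairing. The default geometry uses one view per
degree over 180° and radial bins at the voxel pitch covering the grid
diagonal.

Resolution is modelled as an isotropic Gaussian applied in image space
before projection (and, adjointly, after backprojection), default FWHM
4.5 mm — a typical whole-body PET system resolution covering positron
range, acollinearity and detector width. The Gaussian uses zero-padding
boundaries, which keeps the symmetric kernel exactly self-adjoint.

The background `b` is randoms plus scatter: randoms are spatially uniform;
scatter is the true sinogram smoothed radially with a 40 mm FWHM Gaussian
(the fractions are physically specified quantities; the *spatial* shape of
scatter is a modelling choice, and a broad smooth halo of the trues is the
standard first-order approximation). Both are scaled so that randoms and
scatter are each a stated fraction (default 20% each) of total prompts,
with prompts = trues + background. The joint sinogram is then rescaled by
one common factor to the target prompt count, preserving the fractions
exactly, and Poisson noise is drawn per bin. Realization *r* uses seed
`base_seed + r`; index 0 is reserved for noiseless (expectation) runs.
`b` is treated as exactly known during reconstruction. Attenuation,
normalization, dead time and time-of-flight are out of scope.

Because the sinogram is rescaled to a count level, reconstructions live in
scaled units; the benchmark layer divides images by the recorded
`count_scale` before any comparison with the ground truth.

## Phantom

The phantom is procedural: a sinusoidally perturbed elliptical cortex
(gray matter ribbon) around a white-matter interior with a central
perturbed CSF ventricle, at 1 mm default voxels. PET activities follow
FDG-like uptake with gray:white = 4:1 (defaults 0.1 and 0.025 arbitrary
units) and cold CSF (0 — an assumption; low nonzero values are equally
plausible and configurable). The MR guidance image is T1-like over the
*same* labels (WM 1.0 > GM 0.6 > CSF 0.2, normalized scale), so the two
modalities share every boundary but no intensity ordering.

To avoid an overly piecewise-constant activity, the PET image is
multiplied by `1 + H(2·G(rand, σ_sm) − 1)` with `rand ~ U(0,1)` per voxel
and `G` Gaussian smoothing. `H` and `σ_sm` are not physically constrained;
the defaults `H = 0.1`, `σ_sm = 2` voxels give a gentle ±10% texture and
are documented guesses — both configurable, and the multiplier is clipped
at zero for extreme settings. The modulation is mean-one by construction.

Four tumors are inserted into the PET activity only (the MR is untouched):
two small lesions inside white matter and two larger ones straddling
tissue boundaries; two of the four sit at 3× the gray-matter intensity
with hard edges, the other two are Gaussian-profiled at lower contrast.
Centers and radii scale with the brain size so the same layout works at
any grid.

ROI masks are derived from the labels: whole brain, per-tissue masks, the
four tumor masks, and an eroded white-matter mask (one pass of a full 3×3
structuring element — the erosion depth is a convention, chosen as the
mildest mask that removes boundary voxels). The tissue masks exclude
lesion voxels so that the eroded-WM standard deviation measures noise
rather than lesion signal; erosion of the lesion-free WM mask then
automatically clears a one-voxel margin around each lesion.

What the phantom does *not* emulate: anatomical realism (gyri, vascular
structure, tissue heterogeneity beyond the random texture), MR intensity
non-uniformity or noise, registration error, and 3D scanner geometry.
Consequently, passing tests show that the methods behave as designed under
shared-boundary/discrepant-lesion conditions; they do not certify
performance on scanner data.

## Similarity structure

All six guided methods are parameterized by one construction: compare each
voxel with the voxels in its side-5 spatial neighborhood (24 neighbors in
2D, 124 in 3D) through a Gaussian in a feature space, optionally keep only
the k nearest neighbors *in that feature space*, and normalize. Per
method:

| method | Gaussian feature | kNN by | normalization |
|---|---|---|---|
| KEM | MR intensity | MR intensity | row (center incl.) |
| KEM-LVS | (MR/σ_MR, position/σ_s) | joint feature | row (center incl.) |
| HKEM | MR × current PET product | current PET value | row (center incl.) |
| Gaussian MR-guided | MR intensity | — (full) | neighborhood (center excl.) |
| Bowsher | binary | MR intensity | neighborhood (center excl.) |
| anato-functional | MR × current PET product | — (full) | neighborhood (center excl.) |

Conventions, all deliberate and test-pinned:

* **Sparsify, then normalize** — zeroed neighbors do not absorb mass.
* **Center voxel**: kernel rows include the center with self-similarity 1
  and always retain it (so even k=1 kernels can represent any image); MAP
  penalty neighborhoods exclude it (a voxel is not penalized against
  itself).
* **MR normalized to [0,1]** before any similarity, so σ_MR values are
  comparable across inputs; the PET iterate enters in raw activity units
  (σ_PET is therefore intensity-scale dependent, as its strong
  count-level sensitivity reflects).
* **Ties** in kNN selection break toward the lower voxel index
  (deterministic and platform-stable).
* **Boundaries**: neighborhoods truncate at image edges and k caps at the
  available candidates.
* Kernel symmetry is *not* enforced; kNN selection makes both K and the
  Bowsher weights asymmetric by construction.
* HKEM's kNN uses the PET value alone (the joint PET-MR variant is a
  known alternative but is not implemented).

## Reconstruction

All engines start from a uniform image inside the sensitivity support
(voxels with near-zero sensitivity are frozen at zero; ratio sinograms use
the convention 0/0 = 0, and measured counts in bins with zero expectation
raise an error rather than silently vanishing). Default 300 iterations, no
subsets.

**MLEM** is the standard multiplicative update
`θ' = θ/(Aᵀ1) · Aᵀ[m/(Aθ+b)]`. Post-reconstruction smoothing (for the
comparison baseline) is a Gaussian with stated FWHM, wide-kernel truncation
so the semigroup property holds to high accuracy.

**Kernel EM** iterates the coefficient update
`α' = α/(KᵀAᵀ1) · KᵀAᵀ[m/(AKα+b)]` and reports θ = Kα. For HKEM the
kernel is rebuilt from the current image before every update; from the
uniform start, iteration 1 is effectively MR-only.

**MAP-EM** takes one MLEM step to get θ_EM, then applies De Pierro's
separable surrogate maximizer in the root form
`θ' = 2B/(D + √(D² + 4CB))` with `D = s − (β/2)Σ_l w̃(θⱼ+θ_l)`,
`B = θ_EM·s`, `C = βΣ_l w̃`, `s = Aᵀ1`, which avoids the catastrophic
cancellation of the literal quotient form when D < 0. Two conventions
matter here:

* The update coefficients use the **symmetrized weights**
  `w̃ = (w + wᵀ)/2`. The quadratic penalty value depends only on the
  symmetric part of w — `(θⱼ−θ_l)²` is symmetric in (j,l) — so the
  objective is unchanged, and symmetrization is exactly what makes the
  surrogate inequality (hence monotone ascent) rigorous for asymmetric
  normalized or Bowsher weights.
* With the neighborhood sum counting each pair twice and the surrogate's
  ½ convention, this update ascends `Ω = L − (β/8) R` for
  `R = Σⱼ Σ_l w̃_jl (θⱼ−θ_l)²`; that is the penalized objective the
  package traces and the monotonicity test asserts. Equivalently, β as
  exposed here multiplies R/8 — a pure bookkeeping convention that leaves
  the method and its parameter sweeps unchanged.

The anato-functional weights are rebuilt each iteration from the previous
iterate. For the two adaptive methods (HKEM, anato-functional) no ascent
guarantee exists; empirically both settle at a fixed point — by 300
iterations the objective changes by less than 10⁻⁴ (relative) over ten
iterations while the residual image drift is comparable to plain MLEM's
own slow late-iteration drift, and the stabilization test asserts exactly
that.

## Metrics

* **SSIM** in the simplified single-number form
  `(2μ_gt μ + C1)(2σ_gtθ + C2) / ((μ² + μ_gt² + C1)(σ² + σ_gt² + C2))`.
  The default mode computes the moments once over the masked ROI; a
  local-Gaussian-window mode (maps averaged over the mask) is provided
  because region-wise and windowed conventions both exist — the global
  mode is the default since the statistic is reported as one number per
  ROI. Constants are `C = (K·L)²` with K1 = 0.01, K2 = 0.03 and L the
  ground-truth dynamic range over the mask (configurable).
* **Voxel statistics** across noise realizations: mean, bias = mean − GT,
  and the *population* (1/N) standard deviation. The 1/N divisor is used
  everywhere, including single-image ROI standard deviations, exactly as
  the printed definitions state — not the sample (1/(N−1)) form.
* **ROI percent metrics**: Bias_ROI = 100·√(Σ(θ̄−θᴳᵀ)²/Σ(θᴳᵀ)²),
  σ_ROI = 100·√(ΣₙΣⱼ(θ̄−θₙ)²/(N·Σ(θᴳᵀ)²)), and NRMSE = √(Bias² + σ²) —
  an exact identity, asserted to 10⁻¹⁰.
* **Resampling**: reconstructions on a coarser grid are linearly
  interpolated (pixel-center aligned) to the ground-truth grid before
  metric evaluation.
* **Parameter selection**: the operating point maximizing
  SSIM_unique² + SSIM_brain², with the unique-region SSIM averaged over
  the four tumor ROIs; ties prefer the smaller regularization. A separate
  utility picks, per method, the parameter nearest a target metric value
  (for matched-NRMSE image panels), with the same tie rule.

## Benchmark defaults and problem sizes

The benchmark layer sweeps one parameter per method — β for MAP methods
(log-spaced grid 0–10⁶), k for kernel methods (up to the full 24-neighbor
2D neighborhood, with 3D-derived k values mapped proportionally, e.g. the
Bowsher operating point 20/124 → 4/24), post-smoothing FWHM for MLEM —
over seeded Poisson realizations, and tabulates all metrics per scheduled
iteration. Default σ values per count level follow the operating points
discussed under parameter selection: σ_MR = 0.1 (high counts) or 0.5 (low
counts) for the MAP and HKEM methods, σ_MR = 1 (high) / 0.5 (low) for
KEM, σ_MR = 0.5 with σ_s = 40 for KEM-LVS, σ_PET = 0.01 (high) / 0.5
(low).

Problem sizes are chosen for desk-scale, repeatable runs: the default 2D
phantom is 128×128 at 1 mm with 180 views and prompts of 10⁶ (high) /
10⁵ (low) at the same 20%/20% background fractions; the test suite's
study conditions are 64×64 at 2 mm, 96 views, 2×10⁵ prompts, 3
realizations and 120 iterations. Count levels of 10⁸/10⁷ remain available
as explicit settings for full-scale 2D runs. End-to-end determinism under
a fixed configuration and seed is asserted in the tests.

## Known limitations

* The projector is 2D parallel-beam; scanner-accurate or 3D system models
  must be supplied as substitute operators (the reconstruction engines
  only require the project/backproject/sensitivity contract).
* Noiseless MLEM does *not* closely recover the phantom in 300
  iterations: with the 4.5 mm PSF modelled on both sides, whole-brain
  NRMSE plateaus near 27% (vs 8.6% with resolution modelling disabled),
  because EM recovers PSF-suppressed edge frequencies extremely slowly.
  This is a property of the inverse problem, not of the implementation —
  the corresponding acceptance test documents it by failing its <10%
  bound while the convergence-direction clause passes.
* The adaptive methods' fixed points depend on the iteration path; only
  stabilization, not uniqueness, is checked.
* σ_PET operates on raw activity units, so its useful range shifts with
  count level and scaling — as its documented count-level sensitivity
  implies.
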