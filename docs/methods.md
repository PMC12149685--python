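# Methods

`hectorvi` computes surrogate lung-ventilation maps from an inhale/exhale
CT pair by fusing two independent estimates — one derived from breathing
motion, one from tissue density — into a single hybrid map. This note
records the model, the numerical choices, and what the synthetic test bed
does and does not establish.

## Preprocessing

Both phases are cropped/padded so the inhale lung sits at a 10-voxel air
margin from every face, resampled trilinearly to one uniform cube
(128³ by default; the test suite uses 48³–64³ so a full case runs in
about a minute on one CPU core), and min–max normalized to [0, 1]. The
margin is guaranteed on the *final* grid: the original-space crop margin
is scaled per axis by the resampling factor, since a fixed 10-voxel crop
would shrink below 10 voxels whenever the thorax is downsampled. A copy
of the resampled exhale volume is kept in Hounsfield units, because the
density metric needs HU semantics that the normalization destroys. An
affine geometry record (crop offset + per-axis scale) maps processed
voxel coordinates back to the original grid exactly.

Masks are resampled trilinearly and thresholded at 0.5, which preserves
topology better than nearest-neighbour at factor-two grid changes.
Downstream computation treats voxels of the resampled grid as isotropic
units; anisotropic input spacing is absorbed by the resampling.

## Registration model

The exhale image M is registered to the inhale image F by minimizing,
over the lung domain Ω,

    E = D(F, M, u) + α₁⟨f₁²⟩ + α₂⟨|∇f₁|²⟩ + β⟨|∇(f₂,f₃,f₄)|²⟩,

where the primary variables are not the Cartesian components of the
displacement u but its divergence f₁ = ∇·u and curl (f₂,f₃,f₄) = ∇×u.
The divergence is, to first order, the local volume change — the
quantity of physiological interest — so estimating it directly avoids
differentiating a noisy displacement afterwards. Weights are
α₁ = 0.1 (volume-change magnitude), α₂ = 2 (spatial homogeneity of
volume change; breathing expansion is expected to be smooth), and
β = 0.05 (curl regularity, for numerically stable motion fields).
All four ⟨·⟩ averages are taken over the same integration domain as the
data term (the dilated lung mask), so the relative weighting of data and
penalties is independent of how much air padding surrounds the thorax —
with whole-grid averaging the effective regularization would shrink as
the padded volume grows, and the estimated divergence picks up
texture-scale noise.

The data term D is one minus the Ω-mean of a local squared correlation
coefficient computed under a Gaussian window of σ = 1.5 voxels, making
the similarity invariant to locally affine intensity changes. Windows
where either image is locally constant contribute zero. The mask used
for D is the inhale lung mask dilated by 3 voxels, so lung-boundary
contrast contributes to the match.

A hard physiological-plausibility constraint |f₁| ≤ 0.5 is enforced by
projection after every update; it suppresses the implausibly large local
expansions/contractions registration algorithms are prone to estimating
at artifacts.

### Displacement reconstruction

The displacement is recovered from the primary variables through
Helmholtz potentials: the scalar Poisson problem Δψ = f₁ and the vector
problem ΔA = −(f₂,f₃,f₄) are each solved spectrally with a type-I
discrete sine transform (homogeneous Dirichlet boundary, exact for the
7-point Laplacian), and u = ∇ψ + ∇×A. This satisfies the same continuum
identity Δu = ∇f₁ − ∇×(f₂,f₃,f₄) as solving the vector Poisson system
componentwise, but places the boundary condition on the potentials
rather than on u itself. That distinction matters: the gradient of a
potential does not vanish tangentially at the boundary, so pinning the
displacement components to zero there leaves a boundary layer that never
converges to an analytic potential-flow field; with Dirichlet
potentials, divergence/curl sources well inside the padded grid produce
displacements that decay toward the faces, and the reconstruction
reproduces the closed-form gradient of a sine-product potential with
second-order accuracy (error ratios ≈ 3.3–3.8 per grid doubling,
16³→64³). All spatial derivatives are central differences with
second-order one-sided stencils at the faces; their exact matrix
transposes are used in adjoint computations.

No solenoidality constraint is imposed on the curl variables; the
least-squares character of the reconstruction absorbs any inconsistency.

### Optimization

Projected gradient descent with backtracking, coarse-to-fine over a
3-level Gaussian-antialiased image pyramid (factor 2, fields upsampled
trilinearly between levels; the dimensionless f-values carry over
unchanged and the reconstructed displacement rescales automatically).
Gradients of the data term flow through the exact adjoint of the
reconstruction operator (the DST Poisson solver is self-adjoint); the
derivative of the warped image with respect to u uses the image gradient
sampled at the warped positions, a standard approximation that makes
the computed direction inexact by a few percent — harmless under a
backtracking scheme that only accepts strictly decreasing steps. The
step size grows by 1.25 after each accepted step and halves on
rejection (up to 25 times); a level stops early when the relative
energy decrease over 5 accepted iterations falls below 1e−5, or after
100 iterations. The energy trace is recorded per level (energies at
different pyramid levels are not comparable) and is non-increasing
within each level by construction. Nothing is randomized: results are a
deterministic function of inputs and configuration.

## Ventilation metrics

**Volume-based.** The specific volume change on the inhale anatomy is
read directly off the divergence variable, sVol\* = 1 − Jac ≈ −f₁
(first-order Jacobian approximation; truncating higher-order modes also
truncates their noise sensitivity). It is pushed forward to the exhale
anatomy by inverting y = x + u(x) per exhale voxel with a fixed-point
iteration (x ← y − u(x), at most 20 iterations, tolerance 0.01 voxel)
and sampling −f₁ trilinearly at the pre-image. Inverse-field transport
avoids the holes that scatter-splatting leaves in the target grid.
Exhale-mask voxels whose pre-image leaves the grid are filled from the
nearest valid voxel and a warning is logged (as it is when the fixed
point fails to converge on more than 5% of mask voxels).

**HU-based.** With ρ_air = −HU/1000 and ρ_tissue = (HU + 1000)/1000,
the map is the product ρ_air·ρ_tissue evaluated on the exhale HU
volume: gas exchange needs comparable proportions of air and perfused
tissue, so the model peaks (0.25) at HU = −500 and vanishes at pure air
(−1000) or pure tissue (0). HU outside [−1000, 0] (vessels,
calcifications) is clamped first so the product stays non-negative — a
convention for out-of-range values the density model itself does not
define. A 5-voxel cubic median filter suppresses noise; it runs on the
full grid before masking so mask-edge voxels see complete neighborhoods.

## Rank fusion

Maps computed in unrelated units can only be combined consistently if
the combination sees each map through its voxel ordering alone:
F(f(A), g(B)) = F(A, B) for any strictly increasing f, g. Each map is
converted to an ordering map — in-mask voxels ranked ascending — and
rescaled to [0, 1]. Ties receive fractional (mean) ranks, the choice
that keeps the invariance exact for weakly monotone transforms; the
rescaling divides by the attained rank extremes rather than (N − 1), so
the smallest value maps to exactly 0 and the largest to exactly 1 even
when the extremes are tied. The two ordering maps are fused voxelwise
with the smooth minimum

    Smin(a, b) = (a·e^{−a} + b·e^{−b}) / (e^{−a} + e^{−b}),

a differentiable soft minimum (temperature fixed at 1) that highlights
regions flagged as low-function by *either* component while avoiding
the discontinuities of a hard minimum. Smin is symmetric, equals its
arguments when they agree, and lies between min(a, b) and the mean.

## Evaluation

Against a reference ventilation image on the same exhale grid:
the voxelwise Spearman correlation (implemented as Pearson on
fractional ranks) and the Dice overlap of the 25% highest and lowest
functional regions, each map thresholded at its own within-mask
quartile. Quartile sets are selected by exact count (⌈N/4⌉ voxels, ties
broken by stable rank) so the Dice is well defined on maps with heavy
ties. All three scores are invariant to strictly monotone transforms of
either input.

## Synthetic test bed

The phantom emulates a thorax at CT resolution: two ellipsoidal lungs
(parenchyma −850 HU) carrying a band-limited pseudo-random texture
(wavelengths 2.5–7 voxels, ~64 HU standard deviation — the vessel- and
airway-scale structure a registration has to track), inside a 0 HU body
on a −1000 HU background, with interfaces smoothed over ~1.2 voxels.
Breathing motion is a potential flow, u = ∇φ with φ a sum of Gaussian
blobs, so the true divergence Δφ, displacement, and inverse map are all
closed-form and the curl is identically zero. One broad blob per lung
(σ = 0.85 of the mean lung radius; peak divergence 0.25 by default, a
typical tidal-breathing volume change) keeps healthy within-lung
ventilation fairly homogeneous, as in healthy physiology, with a mild
left/right amplitude asymmetry for global structure. The exhale scan is
the inhale anatomy advected through the analytic inverse map — evaluated
by fixed-point iteration on the closed-form field, never through the
pipeline's interpolators — with optional additive Gaussian HU noise
applied last from a seeded generator.

Defects emulate disease with cleanly separated signatures: a *motion*
defect adds a cancellation blob that scales the local divergence by
(1 − severity) while leaving HU untouched; a *density* defect shifts
parenchymal HU toward air by the severity while leaving the motion
untouched; *both* combines them. The default suite draws one defect per
case (radius 0.55 of the smallest lung semi-axis, severity 0.5–0.9,
position within ±0.35 of the lung radii) deterministically from a seed.

Because exhale synthesis is pure advection, the phantom deliberately
omits the density increase real parenchyma shows on exhale, as well as
airway trees, 4DCT binning artifacts, slab-correlated scanner noise,
and cross-phase segmentation inconsistencies. Passing tests therefore
establish that the estimator chain is correct and well conditioned on
smooth, noise-controlled anatomy with known truth — not that clinical
accuracy matches any particular cohort.

One consequence of a purely motion-defined ground truth: the HU
component's healthy-lung ordering is texture-driven and carries no
information about that truth, so on the phantom the fused map scores a
*lower* Spearman against the motion truth than the volume component
alone. Whether fusion helps or hurts global correlation depends on both
components tracking the reference — a property of real physiology the
phantom does not emulate; what the phantom does establish is the
defect-highlighting behavior of the fusion.

Defect-direction checks compare the defect region against a matched
defect-free twin (same seed and anatomy) rather than against the rest
of the lung: defects are placed in high-ventilation territory, so a
within-case comparison confounds the defect's effect with where it
sits. The fused-map check is within-case, since flagging the region
against its surroundings is exactly what the fusion is for.

## Problem sizes and tolerances

The test suite runs registrations at 32³–64³ with the default
configuration (the full-resolution default remains 128³); the five-case
recovery suite at 64³ yields voxelwise Spearman ≥ 0.8 between the
recovered and analytic negative divergence per case (measured
0.89–0.91), with the whole suite completing in minutes on one core.
Degenerate inputs fail loudly: constant volumes cannot be normalized or
rank-ordered, even median patches and non-positive spacings are
rejected, and a non-finite registration energy raises with its
level/iteration context rather than propagating NaNs.

## Known limitations

- The divergence bound, LCC scale, and regularization weights are tuned
  for human inhale/exhale CT at ~2 mm resampled voxels; other species,
  breath-hold protocols, or grid scales may need retuning.
- The first-order sVol\* ≈ −∇·u approximation biases large volume
  changes (|f₁| near the 0.5 bound) relative to the exact Jacobian.
- Fused values are rank-based and dimensionless; they order lung tissue
  by estimated function but carry no physical ventilation units.
- Fusion of more than two component maps is not supported.
- Reference ventilation images must already be aligned and resampled to
  the exhale grid; no rigid pre-registration is provided.
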