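# Methods

## Problem

Dynamic contrast-enhanced (DCE) breast MRI is read on subtraction images
(postcontrast minus unenhanced volumes). Patient motion between the six
acquisitions misaligns the series, producing subtraction artifacts that can
obscure lesions, and corrupts voxel-wise pharmacokinetic modeling.
`dce4dreg` implements a groupwise, four-dimensional registration that
aligns all timepoints simultaneously while preserving the physiological
enhancement signal, together with the quantitative machinery needed to
validate it: a ground-truth phantom simulator, extended Tofts fitting with
voxel-wise residual errors, motion grading, and paired nonparametric
statistics.

## Registration model

Each timepoint carries a cubic B-spline free-form deformation: a regular
grid of control-point displacement vectors (mm), interpolated by the
tensor-product cubic B-spline basis, giving a C²-smooth field. No timepoint
is a reference. The dissimilarity metric is computed from intensities
sampled at N spatial points through the current transforms, arranged as an
N×G matrix (G timepoints). With K the G×G correlation matrix of its
columns and λ₁ ≥ … ≥ λ_G its eigenvalues, the metric is

    D = Σ_{j=1..G} j · λ_j            ("PCA2" weighting).

Since trace(K) = G always, D is bounded by G ≤ D ≤ G(G+1)/2, with D = G in
the rank-one (perfectly compacted) limit. Contrast kinetics make the
temporal signal low-rank; motion disperses variance into trailing
eigenvalues, which the linearly increasing weights penalize. Minimizing D
therefore removes motion while retaining enhancement.

Key numerical choices:

- **Analytic gradient.** dD/dK = Σ_j j v_j v_jᵀ (first-order eigenvalue
  perturbation), chained through the per-column standardization and the
  B-spline transform. Intensities and their spatial gradients are evaluated
  from the *same* cubic B-spline volume interpolant (prefilter +
  analytic basis derivative), so the analytic gradient agrees with central
  finite differences of the cost to ~1e-5. When two non-negligible
  eigenvalues (> 1e-6) coincide within 1e-9, perturbation theory breaks
  down and a finite-difference fallback is used; near-zero eigenvalue pairs
  are exempt (their eigen-directions carry no sample variance).
- **Optimizer.** Adaptive-step gradient descent: fresh seeded random sample
  of N=2048 foreground points each iteration (foreground = temporal-mean
  intensity above 5% of range, with sub-voxel jitter), step length
  `step_size·√factor / (1 + k/A)^0.602` applied to the max-normalized
  gradient, 250 iterations per level. Samples warped outside any volume's
  domain are dropped for that evaluation. Stochastic sampling acts as a
  regularizer and keeps each iteration cheap.
- **Multi-resolution.** Pyramid factors 8/4/2/1 (Gaussian smoothing at
  σ = factor/2 voxels, then decimation), capped per axis so at least four
  voxels remain — thin slabs would otherwise lose all through-plane
  structure at coarse levels. Control-point spacing schedule 32/16/8/8 mm;
  consecutive levels are connected by exact cubic B-spline subdivision
  (Lane–Riesenfeld even/odd rules), which reproduces the coarse field
  exactly when the spacing halves.
- **Groupwise gauge.** Without a reference image the problem is determined
  only up to a common deformation; after every step the temporal mean
  displacement at every control point is projected to zero. The registered
  series therefore sits at the group-mean position, not at any input frame.
- **Interpolation.** Cubic B-spline during both optimization and final
  resampling; mirror boundary handling keeps the stencil accurate at the
  edge, and voxels whose source falls outside the domain get the volume's
  background (minimum) value.
- **Degenerate inputs.** Zero-variance sample columns (e.g. all-background
  samples) have their variance floored at 1e-12 with a warning rather than
  failing. A NaN metric aborts with a diagnostic; running out of iterations
  is not an error.

The metric reported for a whole series (`series_metric`) uses a fixed,
seeded, *content-independent* uniform sample of the image domain, so
unregistered and registered renderings are scored on identical points.

## Phantom simulator

The generator emulates the clinical protocol: six T1-weighted volumes at
0/90/160/230/300/370 s after injection, 0.7×0.7×2.0 mm voxels, on a
desk-scale 64×64×16 grid (full pipeline runs in about a minute per case,
rather than hours at the clinical 512×512 matrix; results are
qualitative properties, not grid-size-dependent constants). Two
ellipsoidal "breasts" carry a smooth multiplicative baseline texture (25%
amplitude, σ = 2.5 voxels — registration needs edges) and mild parenchymal
enhancement (Ktrans 0.01 min⁻¹); a 6 mm spherical lesion enhances with
Ktrans 0.103 min⁻¹, v_e 0.3, v_p 0.02 — magnitudes chosen to match
clinically reported means for malignant breast lesions.

- **Signal model.** Linear by default: S = S₀(1 + r·C_t) with r = 5 per mM,
  a realistic ~60% first-postcontrast lesion enhancement. The unenhanced
  frame is rendered pre-injection (C_t = 0); fitting uses the five
  postcontrast frames only. A spoiled-gradient-echo mode (flip 25°, TR
  7.5 ms, baseline T1 1 s, relaxivity 4.5 s⁻¹mM⁻¹) is available.
- **Motion.** A cubic B-spline field on a 22 mm control grid (deliberately
  unequal to the registration's schedule, avoiding an inverse crime), built
  from a spatially smoothed temporal random walk with the reference frame
  fixed at identity. Each postcontrast frame is rescaled so the *maximum
  displacement of its field* equals the configured amplitude (default
  4 mm ≈ 5.7 in-plane voxels — moderate motion); the walk supplies the
  smooth spatial/directional pattern, the amplitude sets the envelope.
  A rigid mode (uniform translation) is available.
- **Noise.** Additive Gaussian, SD 2% of the breast baseline by default,
  applied after motion (acquisition order: physiology → motion → noise);
  Rician optional.
- **Determinism.** Identical (config, seed) reproduces the phantom
  bit-for-bit; texture, motion and noise use separate seeded substreams.

What the phantom does *not* emulate: anatomy (ducts, vessels, chest wall),
coil/bias fields, k-space artifacts, fat signal, through-plane
discontinuous motion. Passing tests therefore demonstrate correctness of
the algorithmic chain and its behavior under controlled motion/noise, not
clinical performance.

## Extended Tofts modeling

C_t(t) = v_p·C_p(t) + Ktrans·∫₀ᵗ C_p(τ)e^(−k_ep(t−τ))dτ, k_ep = Ktrans/v_e.
The AIF is a Weinmann-type population biexponential
C_p(t) = D(a₁e^(−m₁t) + a₂e^(−m₂t)) (D = 0.1 mmol/kg, a₁ = 3.99,
a₂ = 4.78 kg/L, m₁ = 0.144, m₂ = 0.0111 min⁻¹); a user-sampled AIF with
linear interpolation is supported. For the biexponential the convolution
is evaluated in closed form (with the t·e^(−mt) limit when k_ep ≈ m); for
sampled AIFs a fine-grid trapezoid recursion (stable for large k_ep) is
used. Times are seconds at the interface, minutes internally, so Ktrans is
in conventional min⁻¹.

The fitted quantity is relative enhancement (S(t) − S(t₀))/S(t₀) of the
postcontrast frames, treated as proportional to concentration; without T1
mapping the proportionality constant is absorbed into AIF-normalized units
(for phantoms the known scale r converts back to true units). Voxel-wise
fitting is bounded trust-region least squares over Ktrans ∈ [0, 5] min⁻¹,
v_e ∈ (0.01, 1], v_p ∈ [0, 0.5], with a deterministic 3×3×2 multistart
grid (the best three starts by initial cost are refined; no RNG). The
per-voxel residual error is the RMSE of the fit over timepoints — the
objective motion surrogate. Percentiles over the lesion ROI use the linear
interpolation convention throughout.

A note on identifiability: with only five postcontrast samples the
three-parameter fit is ill-conditioned at moderate noise. At SNR 20
(noise SD = 5% of peak concentration) the Cramér–Rao bound already implies
a median relative Ktrans error around 30%, and both the multistart fit and
an exhaustive global variable-projection search over k_ep measure ≈19%.
Noiseless curves are recovered to well under 1%. This is a property of the
sparse clinical sampling, not of the optimizer.

## Segmentation

Lesions are segmented on subtraction images: the earliest timepoint with
adequate enhancement is chosen (the first postcontrast frame unless local
seed-neighborhood enhancement is below 50% of its value at the second —
markedly delayed enhancement), then voxels inside a spheroid brush
(mm-radius, anisotropy-aware) with intensity strictly above 0.1× the brush
maximum are kept, restricted to the seed's 26-connected component so
nearby bright structures cannot merge in. 3D morphological dilation and
erosion (ball element) provide adjustment; an erosion that empties the ROI
is an error. The fractional threshold makes the mask invariant to global
intensity scaling.

## Assessment

Subjective motion enters as numerical-ranking-scale (NRS) scores 0–10,
mapped to four clinical categories (0→0; 1–3→1; 4–7→2; 8–10→3). Objective
impact is the post-minus-pre difference (negative = improvement) of
residual-error percentiles and of Ktrans mean/SD over a shared ROI — for
phantoms, the ground-truth lesion mask is used in both arms; because the
registered series sits at the group-mean position, the mask can be offset
by the temporal-mean injected displacement, which is acceptable since
these statistics measure temporal consistency, not absolute position.
Paired statistics: exact-binomial sign test (ties dropped), Wilcoxon
signed-rank (exact enumeration for n ≤ 25 without ties, normal
approximation with tie correction otherwise), Spearman rank correlation of
pre values with deltas, and Kruskal–Wallis (the standard reading of a
nonparametric one-way ANOVA) for subgroup comparisons; all two-sided.

## Known limitations

- The B-spline transform lives in grid-world coordinates (world =
  index·spacing); oblique affines are carried through I/O but ignored by
  the registration geometry.
- The groupwise gauge makes recovered per-timepoint displacements
  comparable to injected truth only after projecting the truth to the same
  zero-mean gauge, and exactly only up to transform composition
  (first-order for smooth fields).
- Percentile-wise residual analysis assumes a reasonably sized ROI
  (hundreds of voxels); single-voxel ROIs yield degenerate percentiles.
- No rigid/affine pre-alignment: capture range is set by the coarsest
  pyramid level (≈ tens of mm for the default settings).
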