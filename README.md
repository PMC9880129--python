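# dce4dreg

Groupwise, four-dimensional, PCA-based registration for dynamic
contrast-enhanced (DCE) breast MRI, with the quantitative machinery to
validate it: a ground-truth phantom simulator, extended Tofts perfusion
fitting with voxel-wise residual errors, semiautomatic lesion
segmentation, motion grading, and paired nonparametric statistics.

## The problem

Breast DCE-MRI is read on subtraction images (postcontrast minus
unenhanced volumes). Patient motion between the six acquisitions produces
subtraction artifacts that can obscure lesions and corrupts voxel-wise
pharmacokinetic modeling. Conventional registration aligns one timepoint
to another and struggles with intensity changes caused by the contrast
agent itself. `dce4dreg` instead registers *all* timepoints
simultaneously — no reference volume — with a metric that separates
physiological enhancement from anatomical motion.

## The method

Each timepoint carries a cubic B-spline free-form deformation. Intensities
sampled at N spatial points through the current transforms form an N×G
matrix (G timepoints); with λ₁ ≥ … ≥ λ_G the eigenvalues of its G×G
column-correlation matrix, the dissimilarity is

    D = Σ_{j=1..G} j · λ_j ,       G ≤ D ≤ G(G+1)/2 ,

the "PCA2" eigenvalue-compaction metric. Contrast kinetics keep the
temporal signal low-rank (small D); motion disperses variance into
trailing eigenvalues, which the increasing weights penalize. D is
minimized by adaptive-step gradient descent (analytic eigenvalue-
perturbation gradient) over a 4-level multi-resolution pyramid
(8×/4×/2×/1× down-sampling, 32/16/8/8 mm control spacing), with a
zero-temporal-mean gauge so no frame is privileged.

Registration quality is quantified with the extended Tofts model
C_t = v_p·C_p + Ktrans·(C_p ⊛ e^(−k_ep t)), k_ep = Ktrans/v_e: per-voxel
RMSE residuals of the fit over the lesion ROI are an objective,
physiology-aware motion surrogate, analyzed percentile-wise (post − pre,
negative = improvement), alongside Ktrans mean/SD changes.

## Worked example

```python
import dce4dreg as d

series, truth = d.generate_phantom(d.PhantomConfig(seed=0))
result = d.GroupwiseRegistration(series, d.RegistrationConfig(seed=0)).fit()
print(result.summary())

fit_pre  = d.fit_roi(series, truth.lesion_mask,
                     enhancement_scale=truth.enhancement_scale)
fit_post = d.fit_roi(result.registered_series, truth.lesion_mask,
                     enhancement_scale=truth.enhancement_scale)
case = d.delta_assessment(fit_pre, fit_post)
```

Output:

```
Groupwise 4D PCA2 registration
==============================================
timepoints                 6
pyramid                    (8, 4, 2, 1)
control spacing (mm)       (32.0, 16.0, 8.0, 8.0)
PCA2 metric pre            7.1330
PCA2 metric post           6.1927
metric bounds              [6, 21]
max |displacement| (mm)    3.002
runtime (s)                31.4

residual percentile deltas (post - pre):
  p10  -0.0004
  p50  -0.0047
  p90  -0.0288
Ktrans mean: 0.118 -> 0.082
Ktrans SD:   0.110 -> 0.039
```

Reading this: the phantom injects smooth 4 mm patient motion into a
six-timepoint series with an enhancing 6 mm lesion (true
Ktrans = 0.103 min⁻¹). Registration compacts the eigenvalue spectrum
(D: 7.13 → 6.19, where 6 is the perfectly-aligned bound for G = 6), and
every residual percentile decreases — most strongly in the high-error
tail (p90: −0.029 vs p50: −0.005), i.e. exactly where motion hurt
perfusion modeling most. The Ktrans SD over the lesion drops by roughly
two thirds: quantification becomes markedly more consistent.

The same steps are available from a shell:

```bash
dce4dreg phantom --seed 0 --out-dir case0/
dce4dreg register --in case0/series.nii.gz --out registered.nii.gz \
    --transform-out motion.json --seed 0
dce4dreg subtract --in registered.nii.gz --out sub.nii.gz
dce4dreg segment --sub sub.nii.gz --seed 45,36,8 --brush-mm 12 --out roi.nii.gz
dce4dreg fit --in registered.nii.gz --roi roi.nii.gz --out-dir maps/
```

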