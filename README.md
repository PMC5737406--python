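# filmrecon

Volumetric reconstruction of historical thick-slice brain MR acquisitions
that survive only as photographic films.

Before digital archives, axial brain MR exams were printed slice-by-slice on
film and the original data was often lost. For longitudinal studies — e.g.
people followed for decades after a clinically isolated syndrome — those
films are the only record of the earliest time points. `filmrecon` rebuilds a
spatially and photometrically consistent 3D volume from scanned films: it
extracts each printed slice, recovers the lost geometry (in-plane spacing,
per-slice pose, orientation) with the help of a later 3D scan of the same
subject, harmonises intensities, and restores the slices by deconvolution.
It is aimed at neuroimaging groups digitising film archives; a synthetic film
generator makes every stage testable without clinical data.

## The model

Each extracted historical slice `y_k` is related to the true anatomy by an
unknown in-plane 2D affine map `T(θ_k, ·)` and a linear intensity distortion
`(α_k, β_k)`. With `r_k` the oblique slice of the later reference volume
resampled onto the stack grid, the joint motion + intensity correction solves

    min_Θ  λ_R Σ_k R_k(Θ_k)  +  λ_N Σ_{k<K} N_k(Θ_k, Θ_{k+1})  +  λ_P P(Θ − Θ_0)

    R_k = Σ_{ξ ∈ Ω_skull} ϱ_γ( α_k y_k(T(θ_k, ξ)) + β_k − r_k(ξ) )
    N_k = Σ_{ξ ∈ Ω}       ϱ_γ( α_k y_k(T(θ_k, ξ)) + β_k − α_{k+1} y_{k+1}(T(θ_{k+1}, ξ)) − β_{k+1} )

where `ϱ_γ(e) = sqrt(γ² + e²) − γ` is a smooth ℓ1 loss, `Ω_skull` is a
neighbourhood of the skull (the structure assumed most stable over decades,
hence robust to brain atrophy between the acquisitions), and the prior `P`
pins the in-plane scale, gain and offset near (1, 1, 0). Residuals are
weighted by their term's λ and passed through the solver's soft-ℓ1 loss, which
realises `γ_term = 1/λ_term` exactly; the defaults are λ_N = 1, λ_R = 10, and
λ_P = 10⁶ for the 4-parameter similarity stage (10 iterations) relaxed to
10³ for the full affine stage (20 iterations). The solver is trust-region
least squares with an analytic sparse Jacobian.

Each corrected slice is then restored independently by isotropic TVL2
deconvolution with non-negativity,

    min_x  ½‖y − A(σ²)x‖² + λ TV_iso(x)   s.t.  x ≥ 0,

solved by 10 iterations of scaled ADMM (λ = 5, ρ = 0.5, Gaussian blur
variance σ² = 0.25 px² on the 8-bit film intensity scale) with an L-BFGS-B
bound-constrained x-update and a vectorial soft-threshold v-update.

Before refinement, the pipeline recovers provisional metadata: per-slice
rigid alignment driven by the inter-slice term alone, a 5-parameter in-plane
3D similarity alignment (rotation about the slice normal, uniform in-plane
scale, 3D translation) of skull masks against the reference, left-right flip
detection, and a global intensity correction (subtract the pooled
20%-intensity percentile, clip at zero, then one linear map fitted to the
resampled reference).

## Worked example

`python examples/full_reconstruction.py` renders a synthetic study (15
five-millimetre slices of a textured head phantom printed on a film sheet
with per-slice rotations up to ±5°, translations up to ±4 px, scale 0.95–1.05,
gain 0.8–1.2, landmark jitter, blur and noise; the reference volume has 5%
brain atrophy and reduced axial coverage) and reconstructs it:

```
pose recovery against the rendered ground truth (modulo the global rigid frame):
  mean |translation| = 0.053 px
  mean |rotation|    = 0.786 deg
  mean |scale - 1|   = 1.66 %

variant quality over the ground-truth brain mask:
  Naively Scaled         NCC=0.388  SSIM=0.370  PSNR=15.41 dB  edge motion=3.18 vox
  MC                     NCC=0.808  SSIM=0.824  PSNR=20.31 dB  edge motion=1.75 vox
  Naively Scaled + IC    NCC=0.391  SSIM=0.383  PSNR=15.94 dB  edge motion=3.18 vox
  MC + IC                NCC=0.904  SSIM=0.831  PSNR=21.35 dB  edge motion=1.75 vox
  MC + IC + TVL2         NCC=0.900  SSIM=0.822  PSNR=21.30 dB  edge motion=1.73 vox
```

The five variants isolate each stage's contribution: motion correction (MC)
recovers per-slice geometry to a twentieth of a pixel, intensity correction
(IC) lifts the photometric agreement, and the deconvolved variant shows the
smallest brain-edge displacement against the truth. `examples/` holds two
further scripts: slice extraction from rendered films, and single-slice
deconvolution.

A thin CLI wraps the same pipeline for shell use:
`filmrecon simulate|extract|reconstruct|evaluate|all` (inputs: film scans as
PNG/TIFF, a JSON landmark sidecar, the reference as NIfTI; outputs: NIfTI
volumes plus JSON/CSV reports).

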