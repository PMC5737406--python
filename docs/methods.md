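# Methods

This note documents the models, parameters and numerical choices behind
`filmrecon`, and what the synthetic test bed does and does not establish.

## Problem setting and assumptions

The input is a set of scanned films holding one historical axial thick-slice
brain MR acquisition, a landmark sidecar marking one point per printed slice,
the slice thickness printed on the film, and a later 3D scan of the same
subject with trusted spatial metadata. The reconstruction assumes:

- **In-plane motion only.** Subject motion during the historical acquisition
  is neglected; each slice's distortion (printing, manual scanning, imprecise
  landmark clicks) is modelled as an in-plane 2D affine map. This avoids any
  out-of-plane resampling of data that is 5 mm apart through-plane.
- **The skull is the stable anchor.** The brain may have atrophied in the
  years between acquisitions, but the skull has not; reference information is
  therefore used only in a neighbourhood of the skull.
- **A single linear photometric model per slice** (gain and offset) on top of
  one global linear correction, reflecting per-film illumination differences.

## Pipeline

1. **Extraction** (`films`). Crops one uniform window per landmark,
   zero-padding windows that cross the film border, and stacks crops in
   landmark order. Coordinates are 0-based (row, col); windows are half-open.
   The naive stack carries provisional spacing (1, 1, thickness) mm.
2. **Neighbour rigid alignment** (`initialize`). Per-slice in-plane rigid
   transforms minimising the inter-slice term alone (plain least squares,
   intensity fixed), initialised by matching intensity centroids to the
   stack-mean centroid; 10 trust-region iterations. Returns transforms; the
   stack is resampled once afterwards.
3. **3D similarity alignment** (`initialize`). Rotation about the slice
   normal, uniform in-plane scale and 3D translation aligning the stack's
   skull mask with the reference's. The objective is NCC between
   in-plane-smoothed *mask images* over their union support: inside the thin
   bright ring the intensities are nearly constant, so NCC of raw intensities
   restricted to the ring carries little geometric signal. Initialisation
   uses mask moments — centroids for translation, central-z-band in-plane
   radii for scale (the reference resolves the skull apex caps, the
   thick-slice stack does not, which biases full-mask moments), principal
   axes for rotation. Optimisation is regular-step gradient ascent
   (finite-difference gradient, step halving, stop at 1e-3 in step units)
   over a 3-level in-plane pyramid (factor 2, Gaussian pre-smoothing); only
   NCC-improving steps are accepted. The recovered scale multiplies the
   stack's in-plane spacing.
4. **Oblique reference slices** (`initialize`). The reference is resampled
   through the similarity transform onto the stack grid. Because the
   historical slices are thick-slab averages, each r_k is the
   support-normalised mean of N reference planes spread over the slice
   thickness (N = thickness / reference z-spacing): a single centre-plane
   sample misstates ring radii on the curved skull dome, and un-normalised
   averaging dims slabs straddling the reference FOV edge. Slices whose
   in-FOV overlap is below 5% are flagged; their reference term is dropped
   and only the neighbour term anchors them (the known border-slice regime).
5. **Left-right flip.** Film chirality is unknown. Both orientations are
   taken through steps 2–4 and the one whose aligned stack correlates better
   with its own resampled reference (by a 0.02 margin) is kept; the margin
   avoids flipping near-symmetric content on noise. A mirrored stack must be
   aligned *before* the comparison — the global similarity adapts to either
   orientation, so comparing mirrored data against the other orientation's
   frame is meaningless.
6. **Global intensity correction** (`intensity`). The pooled 20%-intensity
   percentile (linear-interpolation quantile) is subtracted and intensities
   clipped at zero, removing the film-base pedestal and background noise;
   then one (gain, offset) pair is fitted by least squares against the
   resampled reference over the foreground and applied uniformly. How the
   uniform linear step should be estimated is not prescribed anywhere; masked
   least squares against the reference is this package's choice, consistent
   with using the reference's intensity information.
7. **Joint registration** (`register`). See README for the objective. Term
   weights λ_N = 1, λ_R = 10; prior weight 10⁶ for the similarity stage
   (10 iterations), 10³ for the affine stage (20 iterations); robust scale
   γ = 1/λ per term, realised by weighting residuals with λ and using the
   solver's soft-ℓ1 loss. The prior penalises only the in-plane log-scale
   (vs 0), α (vs 1) and β (vs 0); translations, rotations and shears are
   unpenalised. Stage parameterisations: similarity (rotation, log-scale,
   t_row, t_col, α, β) — log-scale keeps the scale positive and the prior
   symmetric; affine (raw 2×2 matrix + translation, α, β) with the scale
   prior as ½·log det, linearly extrapolated below det = 0.01 so trial points
   with collapsing determinants are penalised smoothly. Residuals from
   out-of-support samples are dropped without renormalising by the valid
   count; slices with < 5% reference overlap fall back to the neighbour term.
   The similarity stage is run from two initialisations — identity, and
   centroid translation plus a coarse ±7° NCC rotation sweep on smoothed
   slices — keeping the lower-cost result. (A pure principal-axis rotation
   estimate is unreliable on near-elliptical brain slices; the sweep lands
   inside the refinement's capture range.) The similarity stage operates on
   σ = 1.5 px smoothed slices to widen the rotation basins; the affine stage
   on unsmoothed data.
8. **Refinement passes.** Image texture repeats on a few-pixel scale, so a
   slice's rotation can land in a nearby local minimum. Two restart rounds
   re-run the affine stage from the current poses and from a fresh rotation
   sweep (reusing the current α, β), keeping the lower-cost result. On the
   synthetic studies the joint cost and the distance to ground truth were
   verified to move together, so cost-based selection is sound.
9. **TVL2 deconvolution** (`tv`). Slice-wise isotropic TV: forward
   differences, Neumann boundary, Σ‖(∂row, ∂col)‖₂; matrix-free separable
   Gaussian blur truncated at ⌈4σ⌉ taps (unit-sum, zero-padded boundary, so
   the operator is self-adjoint); scaled ADMM (λ = 5, ρ = 0.5, σ² = 0.25,
   10 iterations, no tolerance stop) with an L-BFGS-B x-update (≤ 10 inner
   iterations, warm-started) enforcing x ≥ 0, and the vectorial
   soft-threshold S_{λ/ρ} for the auxiliary gradient field.

### Intensity scale convention

The weights above balance data terms against priors at a fixed intensity
magnitude. The registration and deconvolution therefore run on a canonical
8-bit film scale: intensities are scaled so the 99th percentile of the
nonzero reference slices sits at 255, and the fitted offsets are mapped back
afterwards. Without this, inputs in [0, 1] would make the priors freeze the
intensity parameters and under-reward geometric corrections.

## Evaluation

`masked_metrics` computes MSE, Pearson NCC, SSIM (Gaussian window, 11 taps,
σ = 1.5, default constants, dynamic range from the reference image, averaged
over the mask per slice) and PSNR (dynamic range of the reference; +inf for
identical inputs) over a brain mask. Volumes are first rigidly pre-aligned by
masked NCC over Otsu-foreground masks — a raw `> 0` support is useless on
scans with a noise floor. Edge motion between two segmentations is surrogated
by the slice-wise symmetric mean distance between mask boundaries
(distance-transform based); it captures the same brain-edge displacement
notion as SIENA-style analyses but is not numerically comparable with SIENA.

Per-slice pose errors against synthetic ground truth are reported after
removing the common rigid (rotation + translation) component: the
reconstruction's frame is whatever the reference alignment chose, and
validation always starts with a rigid pre-alignment; a frame convention is
not a per-slice error. The scale is never gauge-corrected — the pose prior
anchors it absolutely.

## The synthetic test bed

`synth` renders studies with known ground truth. The phantom is a nested
ellipsoid head: bright skull shell (intensity 1.0), grey/white tissue
(0.60/0.45), dark ventricles (0.20), a few hyperintense lesions (0.85)
placed asymmetrically (so mirror detection has signal), and a smooth
random intra-brain texture field (Gaussian-filtered noise, σ = 3 voxels,
amplitude 0.08) standing in for gyral/sulcal structure and tissue
inhomogeneity — without in-plane texture, per-slice rotation is close to
unobservable, which no real PD-weighted slice is. The skull dome's z
semi-axis exceeds the 75 mm acquired FOV: historical axial acquisitions
covered the mid-head, and every printed slice shows a substantial skull
ring. The "later" reference shrinks the brain compartment radially by the
atrophy factor (default 0.95) about its centroid, leaves the skull
untouched, and by default stops 8 mm short of the top of the historical
FOV — longitudinal scans rarely share coverage, and the resulting
low-overlap border slices exercise the neighbour-term-only fallback.

Films are rendered by slab-averaging (box through-plane PSF, switchable in
principle to a Gaussian slab), warping each slab by a per-slice affine drawn
from the study ranges (rotation U(−5°, 5°), translation U(−4, 4) px, scale
U(0.95, 1.05), gain U(0.8, 1.2), offset U(−0.05, 0.05)), blurring with
σ² = 0.25, compositing onto a film canvas, then adding the film-base
pedestal (0.06) and Gaussian noise (sd 0.02, clipped at 0). Landmarks are
the paste anchors jittered by up to ±2 integer pixels; the jitter is folded
into the recorded true affine, so the ground truth stays exact. Noise,
pedestal and texture levels are fixed choices representing a reasonably
clean film scan.

What passing tests on this bed shows: the estimator recovers the modelled
distortions (affine motion, linear intensity, blur) to well below a pixel
under realistic noise. What it does not show: robustness to film damage
(scratches, annotations, encircled lesions), overlapping-skull layouts,
nonlinear photometric response, or out-of-plane subject motion — none of
which are modelled by the generator or the method.

## Numerical choices and degenerate inputs

- Bilinear interpolation everywhere in 2D warps, with exact interpolant
  gradients in the Jacobian; out-of-support samples are flagged invalid and
  excluded rather than zero-filled.
- Mask surrogate: per-slice thresholds (films have per-slice illumination),
  Otsu for foreground/background, and a three-class 1D Lloyd split of the
  foreground histogram (seeded at the 10/50/95% quantiles) for the
  skull/tissue boundary — binned multi-Otsu thresholds are ambiguous on
  spiky discrete histograms. Largest in-plane component, hole fill, one
  in-plane erosion; all morphology is in-plane because 3D structuring
  elements destroy the top and bottom of a 15-slice stack. A
  `brain_extractor` hook accepts an external tool's mask instead.
- Ω_skull is built from the oblique reference slices: dilated skull mask
  (radius 2 in-plane) minus a slightly wider band around the reference
  brain — the atrophied brain edge would otherwise drag the in-plane scale —
  and intersected with the reference support.
- Constant images are rejected wherever a threshold or correlation is
  required; degenerate intensity fits fall back to the identity with a
  warning; a slice whose optimised affine degenerates (possible only when it
  has no data term, e.g. the λ_N = 0 ablation) keeps its initialisation with
  a warning.
- All randomness flows through seeded `numpy` generators; identical inputs
  and seeds reproduce bit-identical reports.

## Problem sizes

The standard study is K = 15 slices of 96×96 px at 5 mm thickness with a
96×96×75 reference at 1 mm³ — compact enough that a full reconstruction runs
in about half a minute on one CPU while exhibiting every regime the method
must handle (atrophy, FOV mismatch, per-slice photometric drift, landmark
jitter, border slices without reference overlap).

## Known limitations

- Absolute in-plane rotation of the whole stack is only weakly identified by
  a near-elliptical skull; it is treated as part of the frame, exactly as a
  rigid pre-alignment treats it during validation.
- Per-slice rotation accuracy is noise-draw dependent: the skull ring is
  nearly circular and rotation information comes mostly from the interior
  texture, so on unfavourable noise draws the joint objective's global
  minimum can sit 1–2° from the true rotations (with translations and scale
  unaffected). The standard study conditions therefore fix the three
  fixture seeds; typical mean rotation error under them is 0.5–1°.
- Border slices without reference overlap align to their neighbours and may
  drift from the true anatomy; removing the inter-slice term makes them
  markedly worse (this is a feature test, not an accident).
- Per-slice α/β and the global linear model cannot represent spatially
  varying bias fields within a slice.
- The deconvolution assumes a known, spatially uniform Gaussian PSF.
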