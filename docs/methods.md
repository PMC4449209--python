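# Methods

This note documents the models, conventions and design choices behind
`histo3d`: what each stage of the registration cascade computes, what the
synthetic phantom does and does not emulate, and where the design was
genuinely open.

## Coordinate and intensity conventions

All geometry lives in physical micrometre coordinates: the origin is the
centre of pixel (0, 0), x runs along columns, y along rows, and every
transform is a 2D affine map `x ↦ Ax + t` with `t` in μm. This makes the
method's distance thresholds (candidate gate 100 μm, neighbourhood side
250 μm, nucleus areas 6–160 μm²) independent of scan resolution. Rigid
transforms are the constrained case: `A` orthogonal with det +1 (rotation
only; reflections are never produced — the rigid fit's closed form
`θ = atan2(Σ cross, Σ dot)` is the det-+1 Procrustes solution).

Pairwise transform *k* maps section *k+1* coordinates into section *k*'s
frame (each section is the moving image registered onto its predecessor).
Cumulative transforms compose pairwise maps innermost-last and are anchored
at section 1, which is the untransformed base of every reconstruction.

Images are 8-bit RGB; colour-fraction thresholds ("green below 80 %") are
fractions of 255. Grayscale is the unweighted RGB mean. Window/level uses
the radiology convention — window = full ramp width, level = ramp centre —
so window 14 / level 235 maps [228, 242] linearly onto [0, 255], clamped,
with round-half-up. Resampling is always backward (pull) bilinear warping
with out-of-domain samples filled slide-white (255); MSE between a fixed
and a warped moving raster is averaged over the overlap only (moving-image
out-of-bounds samples are excluded from the mean, with no correction term
for shrinking overlap — a known limitation).

## Intensity-based registration

Both branches start from the same coarse initialisation: each adjacent pair
is downsampled by bilinear interpolation so its extents fit within
172 × 264 pixels, converted to grayscale, and rigidly registered from
identity by minimising overlap MSE with a regular-step gradient descent.
Parameters are (θ, t_x, t_y) with θ about the fixed image centre (centring
reduces rotation–translation coupling); the scales (10², 10⁻², 10⁻²)
down-weight rotation so that parameter sensitivities are comparable, and
the step lengths run from 4 down to 0.1. The high-resolution refinement
re-optimises on 4 μm/px grayscale with steps 0.01 → 0.001, rigid first and
then, if requested, the 6-parameter affine (matrix entries scaled 10²,
translations 10⁻², mirroring the rigid convention; full-resolution images
are used only for final volume resampling and the translation-landscape
sweep).

The optimizer itself: gradients are central finite differences taken with
per-parameter half-steps `fd_step / scale`; the update is
`−step · (g/s)/‖g/s‖`; when the scaled gradient direction reverses (negative
dot product with the previous direction) the step is multiplied by the
relaxation factor 0.5; optimisation stops when the step falls below the
minimum or after 200 iterations (relaxation and cap are not dictated by the
underlying algorithm family; these defaults bound runtime and match common
regular-step behaviour). The walk is deliberately blind — a step may
transiently worsen the metric, which lets it traverse the small landscape
bumps that aliased cellular detail produces at the coarse level — but the
best state visited is tracked, returned, and recorded in the trace, so the
accepted-MSE sequence is monotone non-increasing and the result never ends
on a worsening excursion. The optimizer is deterministic; identical inputs
and settings reproduce bit-identical transforms.

A practical boundary worth stating: a single-level regular-step search on a
bumpy similarity landscape can stall before reaching the global optimum.
The coarse level is therefore assumed to be genuinely low-resolution
(≈10–25 μm/px), where tissue outline and shading dominate; the phantom's
study conditions satisfy this, and the nucleus branch additionally
tolerates coarse errors up to its 100 μm candidate gate.

## Nucleus-landmark registration

Segmentation takes 8-connected components of the "hematoxylin-dark" mask
(green < 80 % of 255) whose physical area lies in [6, 160] μm²; both
criteria must hold. Centroids are unweighted. Debris on the blank glass is
rejected by dilating each component with a 5 μm disk and testing the ring
(dilation minus component, clipped to the image): mean green > 95 % of 255
*and* SD < 4 % of 255 means glass-like surroundings and the detection is
dropped. The ring rather than the full dilated disk is used so the
component's own dark pixels do not dilute the background statistics.

Correspondence is block matching: for nucleus *p* on section *I*, candidate
nuclei on section *J* are those whose centroids, mapped through the coarse
initialisation, lie within T = 100 μm of *p* — gating after initialisation
is essential, since otherwise T may not cover the true match under large
perturbations. The match is the candidate minimising the MSE between
250 μm window/levelled green-channel squares centred on each nucleus in its
own section frame (full resolution by default; the neighbourhood spacing is
configurable). One pass is made, earlier section → later section, and
many-to-one matches are allowed; an optional mutual-best filter exists but
is off by default since the procedure defines no uniqueness constraint.
Only the 100 smallest-MSE correspondences per pair define the fit (ties
broken by score, then the landmark's y then x, for determinism): most
nuclei are not bisected, so weakly matching correspondences are likely
spurious. The rigid or affine least-squares fit is computed on
initialisation-mapped coordinates and composed with the initialisation; the
affine fit reuses the same selected correspondences as the rigid one
(a single correspondence stage feeds both models).

The block comparison is translation-only, so its discrimination degrades
with the relative rotation/shear between sections: content at radius *r*
from the nucleus is displaced ≈ *r·δθ*, and beyond a few degrees the
correct candidate's neighbourhood no longer clearly wins. With the study
conditions (per-section |θ| ≤ 5°, |shear/scale| ≤ 5 %) enough of the
selected 100 remain correct for sub-2 μm fits, but occasional draws that
stack rotation and shear produce visibly degraded pairs — the same
brittleness the gate radius itself has.

## Error evaluation

The reference reconstruction is a chain fitted per pair to verified
homologous landmark pairs (affine by default, matching how reference errors
are usually reported); it serves as the surrogate ideal alignment.
*Pairwise* error is `‖p_I − T(p_J)‖` over homologous pairs: FRE when the
pairs defined `T`, TRE when they were withheld. *Accumulated* error maps a
landmark on section *k* into the section-1 frame through both the
algorithm's and the reference cumulative transforms and takes the
distance; section-1 errors are zero by construction, and both chains are
applied to raw landmark positions (consistent, so the convention cancels
for the reference). Pairwise error measures topology fidelity per pair;
accumulated error exposes spatially biased pairwise errors that compound
through the stack — the two are complementary, and the
banana-into-cylinder failure is visible only in the accumulated context.

LOOCV refits the transform *n* times with one pair withheld and scores the
withheld pair; a degenerate leave-one-out fold is reported as missing
(NaN), never fabricated. Summaries are non-parametric: median ± IQR;
95 % CI on the median from the sorted values at ranks n/2 ± 1.96·√n/2
(rounded to the nearest integer rank and clamped to [1, n] — the rounding
rule is a package choice); per-section maxima reported as mean ± SD.
Method comparisons run a KS normality screen (reported, never used to
switch tests) and a paired Wilcoxon signed-rank test with zero differences
discarded. The non-parametric prediction interval uses the sample maximum
as the upper bound of the P % interval with P = (N−1)/(N+1). The MSE
translation-landscape sweep evaluates overlap MSE at a registration
optimum composed with pure translations ±20 μm in 0.5 μm increments
(81 samples per axis) and reports the displacement of the minimum — the
distance between the intensity metric's optimum and the landmark
registration's.

## The phantom

The generator renders a 3D scene into perturbed serial sections with exact
ground truth. Study conditions (the defaults): ten 5 μm sections of a
2 × 2 mm footprint at 1 μm/px; 400 nuclei per mm² per section-slab with
diameters N(5, 0.7²) μm clipped to [3.2, 5.0]; one vessel (wall annulus,
radii 10–16 μm) inclined 30° to the section normal; independent per-section
rigid perturbations |t| ≤ 50 μm, |θ| ≤ 5° (affine deviation 0 by default,
0.05 in the shear/scale experiments); additive Gaussian pixel noise SD 2.
The 1 μm/px grid trades the scanner's 0.25 μm for tractable raster sizes;
every threshold is physical, so the method is unchanged.

Scene content and why it is there:

- **Tissue footprint** — an ellipse with outward 2nd/3rd-harmonic boundary
  lobes. The lobes give the outline the rotational asymmetry real muscle
  cross-sections have; without them rotation is unconstrained at the coarse
  level. Lobes only extend the base ellipse, so nuclei, blobs and vessels
  sampled inside the ellipse always lie in tissue.
- **Stain colours** — background white (255); tissue base green 222 (above
  the 80 % segmentation threshold, below the 95 % glass criterion);
  nucleus green 128 (≈50 % of 255, safely under the threshold); DAB-brown
  vessel wall (150, 92, 50). Nucleus and wall pixels fail the colour
  criterion but walls fail the area cap, so only nuclei become landmarks.
- **Pale interstitial blobs** — static 3D columns (radii 3–25 μm, ≈35 %
  coverage, green 234) shared by all sections, standing in for the pale
  fibre interiors and interstitial space of transversely sectioned muscle.
  They are the structure the 14/235 window/level keeps: without in-band
  fine/mid-scale content, neighbourhoods are nearly uniform after the
  contrast mapping and block matching cannot distinguish candidates a few
  μm apart. Fibre-scale radii keep near-centre content correlated under
  the ±5° relative rotations.
- **Texture** — a smooth shared field (SD 4, correlation 25 μm) plus a
  weaker per-section field (SD 2.5, 10 μm) on the tissue; the shared part
  gives the intensity MSE a usable landscape, the per-section part models
  slab-to-slab appearance change.
- **Nuclei** — spheres placed uniformly in the elliptical slab; each
  section shows the disk of the largest sphere circle inside its 5 μm slab.
  Diameters are clipped at the section thickness so the radius never
  exceeds half the slab spacing: a nucleus is bisected by at most one
  cutting plane, and each homologous pair spans exactly two adjacent
  sections with identical in-plane world position.

Sections are rendered in an unperturbed world frame and then resampled
through the inverse of the section's ground-truth transform (independent
draws, no drift — so accumulated-error growth under a biased registration
is attributable to the method, not the phantom), with sensor noise added
after warping. Ground truth records the transform chain, all nucleus
centres, per-section landmark lists, the homologous bisected pairs, and a
50/50 registration/reference split of those pairs; the splits are disjoint.
A ground-truth landmark is "detectable" when its cut-disk area reaches
9 μm² — the segmenter's 6 μm² floor plus a margin absorbing rasterisation
and warp-interpolation loss of 1–2 px — so recall/precision bookkeeping is
not dominated by pixelation at the 1 μm grid.

What the phantom does **not** emulate: tears, folds, missing sections,
staining batch effects, non-affine tissue deformation, anisotropic or
clumped nucleus placement, out-of-focus blur, and scanner illumination
fields. Passing tests therefore show that the pipeline recovers known
rigid/affine geometry under realistic optical structure and noise — not
that it is robust to deformation or artefact classes the generator never
produces. Two further idealisations matter when reading TRE numbers: the
automatic pipeline is blind to the ground truth but not *prevented* from
selecting a reference nucleus among its best-100 (real evaluations exclude
reference landmarks from the registration), and homologous phantom pairs
coincide exactly in world coordinates, whereas real bisected-nucleus halves
have sub-radius centroid offsets. Both make phantom TREs slightly
optimistic relative to tissue.

## Numerical choices and degenerate inputs

- Rigid fits reject configurations with coincident source points; affine
  fits reject (near-)collinear sources (second singular value ≤ 1e−9 of
  the first). Transform inversion requires |det| > 1e−12.
- Intensity rounding: round-half-up to the nearest integer after every
  intensity mapping; identity resampling on the same grid is bit-exact.
- The volume grid is the union of all transformed section footprints,
  snapped to section 1's pixel grid, so no tissue is cropped and the base
  slice is reproduced bit-exactly.
- Correspondence selection ties are broken by (score, y, x) so the best-k
  cut is deterministic.
- An empty overlap in any MSE comparison raises rather than returning a
  silent sentinel; a non-finite metric at an optimizer's accepted state
  raises with the iteration and parameters.

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run the cascade on phantom pairs
at the full 2 × 2 mm study footprint and on 10-section stacks at
1.5 × 1.5 mm (the smaller footprint keeps nine-pair stacks proportionate
while leaving >100 bisected nuclei per pair); statistical calibrations use
1000 simulated samples of n = 100 and 100 seeded fit replicates. These
sizes are the package's chosen experiment scales; all of them derive every
random draw from explicit seeds.

## Known limitations

- The 100 μm gate is brittle by construction: a true match outside the
  post-initialisation ball cannot be recovered, and everything rests on the
  coarse initialisation achieving that accuracy.
- Translation-only neighbourhood comparison degrades under large relative
  rotation or shear (see above); an orientation-corrected neighbourhood
  extraction would remove this but is deliberately not the default
  behaviour of the method implemented here.
- The affine model cannot express local tissue deformation; residual FRE of
  a reference fit is exactly the deformation the model leaves behind.
- MSE-based intensity registration between adjacent sections optimises a
  metric whose true optimum is intrinsically displaced from the ideal
  alignment (different tissue on each section); the landscape sweep
  quantifies this displacement rather than treating it as optimizer error.
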