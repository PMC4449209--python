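# histo3d

Fully automatic 3D reconstruction of serial brightfield histology sections,
built around registration of **bisected cell nuclei** — with a complete
registration-error evaluation framework and a synthetic serial-section
phantom generator.

## The problem

Conventional 2D histology of microvasculature (arterioles and venules in
muscle, here DAB-stained smooth-muscle walls with hematoxylin-counterstained
nuclei) gives no 3D context: vessel connectivity, orientation and diameter
are easily misread from single sections. Stacking serial 5 μm sections back
into a volume requires registering each section to its neighbour — but
adjacent sections sample *different* tissue, and aligning salient structures
(e.g. vessel cross-sections) pairwise straightens obliquely oriented vessels
into section-orthogonal cylinders. This is the **"banana-into-cylinder"**
artifact: topology is preserved, geometry is destroyed.

Cell nuclei are ≈5 μm in diameter — about one section thickness — so a
nucleus bisected by the microtome blade appears at homologous positions on
exactly two adjacent sections, with no orientation bias. Registering on
such landmarks preserves geometry.

## The method

For each adjacent section pair (moving section *J* onto fixed section *I*):

1. **Coarse initialisation** — rigid intensity registration on low-resolution
   grayscale images (extents ≤ 172 × 264 px) minimising the overlap MSE with
   a regular-step gradient-descent optimizer (scales 10² / 10⁻² for
   rotation / translation, step lengths 4 → 0.1).
2. **Nucleus landmarks** — segment nuclei as 8-connected components with
   green channel < 80 % of 255 and area in [6, 160] μm²; reject debris whose
   5 μm-dilated surroundings look like blank glass (mean green > 95 %,
   SD < 4 %).
3. **Block-matching correspondence** — for each nucleus *p* on *I*, the
   candidates are nuclei *q* on *J* whose initialisation-mapped centroids lie
   within *T* = 100 μm of *p*:

   p′ = argmin over q with D(p, q) < T of MSE(I(p), J(q))

   where I(p), J(q) are 250 μm window/levelled (14/235) green-channel
   squares centred on the nuclei.
4. **Fit** — keep the 100 correspondences with the smallest MSE and fit the
   least-squares rigid (or affine) transform; compose with the
   initialisation, then compose all pairwise transforms into cumulative
   transforms anchored at section 1 and resample the RGB sections into a
   stacked volume (voxels e.g. 0.25 × 0.25 × 5 μm).

A conventional high-resolution intensity-based branch (rigid then affine MSE
refinement on 4 μm/px grayscale) is included for comparison.

**Evaluation:** pairwise and accumulated target/fiducial registration error
(TRE/FRE) against a reference reconstruction fitted from withheld landmark
pairs, leave-one-out cross-validation, rank-based 95 % CIs on medians
(ranks n/2 ± 1.96·√n/2), Wilcoxon signed-rank comparisons, non-parametric
prediction intervals with level P = (N−1)/(N+1), and MSE translation-
landscape sweeps (±20 μm at 0.5 μm steps).

**Phantom:** a seeded generator renders serial sections of a 3D scene —
lobed tissue footprint, pale fibre-scale interstitial blobs, a vessel wall
annulus following an inclined 3D centerline, and spherical nuclei cut into
per-section disks — applies known rigid/affine perturbations per section,
and reports exact ground truth (transforms, nucleus positions, homologous
bisected pairs split into registration/reference sets).

## Worked example

```python
import numpy as np
import histo3d as h3

# a 2 x 2 mm two-section phantom, 1 μm/px, rigid jitter |t| ≤ 50 μm, |θ| ≤ 5°
spec = h3.PhantomSpec(n_sections=2, seed=11)
stack, truth = h3.generate_phantom(spec)

result = h3.reconstruct(stack, method="nucleus_rigid")
print(result.summary())

# held-out TRE against withheld bisected-nucleus pairs
p_i, p_j = h3.ground_truth_pairs(truth, "reference")[1]
tre = h3.pairwise_error(result.chain.pairwise[0], p_i, p_j)
print(f"held-out TRE: median {np.median(tre):.2f} um over {len(tre)} pairs")
```

Output:

```
histo3d reconstruction (nucleus_rigid)
  sections: 2
  voxel spacing: (1.0, 1.0, 5.0) um
  pair 2->1: rot -4.26 deg, t (-85.5, +106.5) um
  pair 2->1: 1188/1223 landmarks, 1188 matched, 100 selected (mean MSE 2327.5)
held-out TRE: median 0.50 um over 278 pairs
```

The recovered pairwise transform (−4.26°, ≈(−86, +107) μm) undoes the known
perturbation; the withheld homologous nucleus pairs land within half a
micrometre of each other — an order of magnitude below the section
thickness, i.e. a geometrically faithful reconstruction. A volume can then
be written with `h3.render_volume` / `h3.write_volume` (multipage TIFF plus
a JSON sidecar with voxel spacing), or from the shell:

```bash
histo3d phantom --out demo/ --seed 11 --sections 10
histo3d reconstruct demo/section_*.tiff --spacing-um 1 --method nucleus_affine \
    --out demo/volume.tiff --save-transforms demo/chain.json
histo3d evaluate --chain demo/chain.json --reference demo/reference_pairs.csv \
    --report demo/report.json
```

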