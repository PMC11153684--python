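# lungmet

Predicting *where* lung cancer will seed its next metastases, from a single 3D
chest CT volume.

Small pulmonary metastases (≲ 2 mm) sit below the detection limit of routine
CT/PET-CT, yet their locations drive treatment decisions. `lungmet` implements
a bioclinical pipeline for radiology researchers and modellers that converts a
CT-like volume into an L1-normalized 3D probability heatmap of likely
colonization sites, by combining classical image analysis with a three-layer
biophysical model of metastatic spread.

## What it computes

**Initial condition from the image.** The primary tumor (location τ_l ∈ ℝ³,
radius τ_s) is taken from a clinician tag or detected by recursive upper-tail
Otsu thresholding. Healthy lung tissue is segmented slice-by-slice: adaptive
Canny edges (hysteresis thresholds at (1 ± k)·median), a discretized Hough
search for the two lung-boundary ellipses, accretion and morphological closure
of connected edges into two filled regions, stacking, and shrink-compensated
Laplacian smoothing of the 3D shape. Blood vessels are cylinder-fit segments
b = (c, h, r, o_xy, o_xz) with start/end locations

    sl = c − h/2 · u,  el = c + h/2 · u,  u = [cos o_xy, cos(π/4 − o_xy), cos o_xz],

recovered from a skeletonized vessel mask. A flow graph G = (B, E) is built by
an iteratively growing search radius (R ← R + δ_R) over segment endpoints and
reduced to the **maximum-radius spanning tree** (edge weight = the smaller
incident radius — the hemodynamically limiting bore).

**Seeding model.** For each query location τ: the tumor grows by Gompertz
kinetics until its radius reaches the nearest vessel, then sheds d cells/hour
into the bloodstream; cells ride the unique tree path toward the vessel
nearest τ with transit times from a steady Hagen–Poiseuille network solve,
dying at rate λ and going extinct below a threshold ξ; survivors extravasate
and settle in the surrounding healthy tissue with saturating kinetics and a
Gaussian falloff in distance from the serving vessel. Settled counts over a
sampled grid Ω (strides α_x, α_y, α_z) are L1-normalized into the heatmap
P(I).

**Scoring.** Predictions are compared with a binary truth image I₁ by the
soft classifier d_s(I₁, I₂) = 1 − Σ(I₁ − I₂)²/(x·y·z) and the hard classifier
d_h(I₁, I₂, ζ) = d_s on the prediction binarized at α > ζ, with cohort
MEAN ± STD summaries.

Because clinical volumes cannot be redistributed, the package ships a
first-class **phantom generator**: seeded synthetic volumes with ellipsoidal
lungs, a branching cylindrical vessel tree (Murray-rule radii), a spherical
tumor and planted ground-truth metastasis sites that are *not* painted into
the image — they emulate lesions below imaging resolution, which is exactly
the regime the heatmap addresses.

## Worked example

```python
import numpy as np
from lungmet import (PhantomSpec, generate_phantom, detect_primary_tumor,
                     segment_lungs, detect_vessels, build_graph,
                     max_radius_spanning_tree, GraphBuildParams,
                     generate_heatmap, GridSpec, ModelParams,
                     dice, soft_score, hard_score)
from lungmet.evaluation import metastasis_truth_mask, default_zeta

volume, truth = generate_phantom(PhantomSpec(seed=1))
tumor = detect_primary_tumor(volume)
lung = segment_lungs(volume, tumor=tumor)
segments = detect_vessels(volume, lung)
tree = max_radius_spanning_tree(build_graph(segments, GraphBuildParams()))
heatmap = generate_heatmap(volume, tumor, lung, tree, GridSpec((4, 4, 4)),
                           ModelParams())

print(f"tumor at {np.round(tumor.location, 1)} mm, radius {tumor.size:.2f} mm")
print(f"lung mask Dice vs ground truth: {dice(lung.mask, truth.lung_mask):.3f}")
print(f"{len(segments)} vessel segments, spanning tree with {len(tree.edges)} edges")
i1 = metastasis_truth_mask(truth.metastasis_mask)
zeta = default_zeta(len(heatmap.grid_points))
print(f"soft score {soft_score(i1, heatmap.values):.4f}, "
      f"hard score {hard_score(i1, heatmap.values, zeta):.4f} (zeta={zeta:.2e})")
```

prints

```
tumor at [17. 36. 20.] mm, radius 3.94 mm
lung mask Dice vs ground truth: 0.982
8 vessel segments, spanning tree with 7 edges
soft score 0.9995, hard score 0.9986 (zeta=2.44e-04)
```

The detected tumor matches the planted one (true center (17, 36, 20) mm,
radius 4 mm); the lung mask overlaps the ground-truth lungs at Dice 0.98; the
eight detected segments are a merged-but-connected rendering of the planted
15-segment tree (branches overlap near junctions, as in real vasculature);
and the heatmap scores near 1 against the sparse truth because both soft and
hard errors are normalized by the full voxel count.

A command-line interface mirrors the library
(`lungmet phantom | segment | graph | heatmap | score | run | show-config`);
`lungmet run config.yaml` executes the whole pipeline from a single YAML file
and writes a manifest with SHA-256 hashes of every artifact (identical
config + seed ⇒ identical hashes).

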