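# Methods

This note documents the model implemented by `lungmet`, the defaults it
ships with, the numerical choices behind them, and what the synthetic
phantoms do and do not establish about behavior on clinical data.

## The seeding model

The pipeline evaluates, for every sampled location τ in the lungs, the
expected number of tumor cells that settle there by stop time T, and
normalizes those counts into a probability field. Three sub-models are
composed; each sits behind its own function so a more detailed model can be
swapped in.

**Primary growth (Gompertz).** The tumor's cell count follows
N(t) = K·exp(ln(N₀/K)·e^(−a·t)), with N₀ set from the tagged radius via a
cell density ρ (cells/mm³) and the equivalent-sphere relation. Growth
proceeds until the equivalent radius reaches the surface of the nearest
vessel (bisection, tolerance 1e−7 h); from that contact time t_c the tumor
sheds cells into the bloodstream at a constant rate d, so the shed total is
d·max(0, T − t_c). If even the carrying-capacity radius cannot reach a
vessel, nothing is shed and the prediction is zero. Shedding is modeled as a
single release at the source ("batch" semantics); continuous pipelining
through the network would only rescale counts that the final L1
normalization removes.

**Bloodstream transport (steady Poiseuille network with extinction).** The
vessel tree carries a steady flow solved from node pressures: each edge has
conductance min(r_i, r_j)⁴ / L (Hagen–Poiseuille with constants absorbed; L
is the endpoint gap plus the mean of the incident heights), unit pressure at
the inlet (the widest segment), zero at the leaves. Mass balance at interior
nodes holds to < 1e−9 relative. Edge velocity is flow/(πr²). The full
unsteady network problem is deliberately avoided — it is expensive and
numerically fragile — and a steady solve preserves the feature that matters
here: the *relative* distribution of flow and transit time over the tree.
Circulating cells decay exponentially at rate λ over the summed edge transit
times; a population arriving below the extinction threshold ξ is set to
zero. This rule implicitly bounds the survivable transit time at
ν_t = ln(N_in/ξ)/λ, which the tests verify against the empirical extinction
onset. Path length for explicit path enumeration is the sum of traversed
segment heights (the source excluded — cells enter at its end) plus
inter-endpoint gaps, so the ν cutoff has consistent mm units.

**Colonization (saturating, vessel-proximal).** Arrivals extravasate near
the target vessel and settle in surrounding healthy tissue:
settled = round(C·f_eff·(1 − e^(−p·arrived/C))), capped by the arrivals so
conservation (settled ≤ arrived ≤ shed) holds exactly. f_eff is the
healthy-tissue fraction in a 3 mm ball around τ (zero if τ is outside the
lung mask), multiplied by a Gaussian falloff exp(−(d_v/σ)²) in the distance
d_v between τ and the serving vessel's surface. The falloff encodes that
cells leave the bloodstream into the tissue *around* the vessel rather than
anywhere in the lung; without it, every location served by the same nearest
vessel would score identically regardless of its distance to that vessel,
and the heatmap would not localize.

All semantics are expected-value (deterministic): extravasation
probabilities become expected settled counts. This keeps the heatmap
reproducible and testable; a seeded stochastic mode was considered and
rejected as adding variance without information.

### Model parameters

| parameter | default | units | rationale |
|---|---|---|---|
| d (shedding rate) | 1e6 | cells/h | order of magnitude for a vascularized ~cm tumor; only relative counts matter after normalization |
| λ (bloodstream death) | 2.0 | 1/h | circulating tumor cells clear within hours |
| ξ (extinction threshold) | 100 | cells | small populations fail to survive transit |
| T (stop time) | 720 | h | a 30-day horizon between scans |
| a (Gompertz rate) | 0.01 | 1/h | months-scale doubling at small sizes |
| K (carrying capacity) | 1e12 | cells | classical ~1 kg lethal burden |
| ρ (cell density) | 1e6 | cells/mm³ | standard tissue packing |
| p (extravasation scale) | 1e−3 | — | small per-arrival settlement probability |
| C (colonization capacity) | 1e6 | cells | local niche saturation |
| colonization radius | 3 | mm | tissue ball for the healthy fraction |
| σ (extravasation spread) | 5 | mm | perivascular settlement range; wider than the grid stride so lattice sampling does not alias it |
| inlet velocity | 50 | mm/h | *effective* advection rate of the stand-in flow, not an instantaneous blood speed: it folds recirculation and re-trapping into one rate so that bloodstream residence times are commensurate with the clearance rate λ and path-dependent extinction is meaningful at organ scale. With literal mm/s velocities the transport layer would be spatially uniform and the model would reduce to geometry. |

None of these are fitted; all are exposed in configuration and recorded in
the run manifest.

## Initial-condition construction

**Tumor.** Otsu's threshold applied recursively to the upper intensity tail
(three levels) isolates the brightest tissue class even though it occupies a
tiny volume fraction; the brightest connected component (≥ 8 voxels) gives
τ_l (centroid) and τ_s (equivalent-sphere radius). A manual tag bypasses
detection. The tumor sphere is excluded from the healthy-tissue mask:
settlement targets must be healthy tissue.

**Lungs (per axial slice).** Canny edges with hysteresis thresholds at
(1 ± k)·median(slice), k = 0.33, σ = 1. The two boundary ellipses come from
a bounded accumulator over a discretized (center, semi-axes) grid (stride 2,
axis stride 2, rotation 0 by default), scored by perimeter coverage on the
1-px-dilated edge map and ranked by absolute votes (coverage × perimeter
length), with three safeguards that matter in practice: a descending
coverage hierarchy (0.9 → 0.45) so that near-perfect boundary fits are
claimed before partially-fitting large contours that can span both lungs; a
nearly-edge-free-interior check that rejects such spanning contours
outright; and an eccentricity bound (3:1) excluding sliver fits. Candidates
are refined by a ±2 px sub-lattice search scored against the *raw* edge map
(the dilated map plateaus within a pixel of the true contour and biases the
fit one pixel outward). Edges 8-connected to each ellipse's rasterization
are accreted, the contour is closed with a growing disk (bounded at radius
4) and hole-filled; the boundary band's outer half (contour pixels outside
the fitted ellipse) is trimmed so the region area tracks the enclosed
analytic area πab instead of inflating by a pixel all around.

**3D reconstruction.** Per-slice regions are stacked; failed slices between
successes copy their nearest successful neighbor, failures beyond the
first/last success stay empty (pole cross-sections smaller than the
accumulator's minimum axis are undetectable by design). The stack is
smoothed by Taubin's shrink-compensated Laplacian relaxation (alternating
weights +0.5/−0.52, 10 iterations, 6-neighbor mean, re-binarized at 0.5).
The plain Laplacian scheme acts as curvature flow and measurably eroded the
organ ~5 % by volume; the compensated scheme halves the boundary bias and
raises phantom Dice from ~0.97 to ~0.98–0.99.

**Vessels.** In-lung voxels above the Otsu split of in-lung intensities are
skeletonized (3D); the skeleton is split at junction voxels (≥ 3 neighbors)
into simple branches (≥ 4 voxels, junction voxels re-attached). Each branch
is fit by a cylinder: centroid, principal axis (SVD), height from the axial
extent minus one voxel per end (the discrete skeleton overshoots into the
rounded caps), radius from the mean Euclidean distance transform along the
branch. Fitted cylinders have no intrinsic direction, but the graph
construction keys on start locations, so segments are oriented
*root-outward*: starting from the widest segment, segments are claimed in
order of endpoint proximity to the already-oriented structure and their
start put on the proximal side — the direction blood actually flows.
Orientation angles then come from inverting the endpoint parametrization.

The endpoint direction vector u = [cos o_xy, cos(π/4 − o_xy), cos o_xz] is
used exactly as defined even though it is not unit-norm and cannot represent
near-vertical directions (its in-plane norm is bounded below by ~0.54);
phantom trees are generated in the same (o_xy, o_xz, h) parameter space, so
generation, fitting and evaluation stay mutually consistent, and fitting
clamps cos o_xz into [−1, 1] for marginally unrepresentable axes.

**Graph.** Each segment's start is tested against spheres of radius R around
every other segment's endpoints; it links to the closest candidate it is not
already linked to. A round adding nothing grows R by δ_R (defaults R₀ = 2 mm,
δ_R = 1 mm). The process halts once the graph is connected *and* a round at
the final radius adds nothing more: detected junction attach points cluster
within a couple of voxels, so stopping at first connectivity would freeze an
essentially random sibling-vs-parent wiring, whereas saturating the radius
completes the local junction triangles and leaves the choice to the
maximum-radius spanning tree (Kruskal on weight = min incident radius,
equal-weight ties taken in ascending index order — which prefers the taller,
earlier-sorted parent). On noise-free phantoms with well-separated branches
this recovers a tree isomorphic to the generating one.

## Heatmap

The volume is sampled on a lattice with voxel strides α (default (4, 4, 4)
for 64³ volumes; points ordered z-major). Grid points outside the lung mask
get probability 0 without a model evaluation. Per-point evaluation reuses a
prepared model context (flow solve, contact time, per-target-segment
survival cache), which is bit-identical to independent single-point calls.
Counts are L1-normalized whenever any count is positive; an all-zero map is
returned un-normalized with a warning. Values live on the lattice; the value
"at" an arbitrary voxel is taken at its nearest lattice point.

## Phantoms: what they emulate, and what passing tests show

Phantoms have two axis-aligned ellipsoidal lungs (semi-axes (11, 16, 22) mm
in a 64³ mm volume), a binary vessel tree grown in angle space (root radius
2.5 mm, depth 4, Murray-rule child radii r_p/2^(1/3), heights decaying by
0.78, branch angles 0.35–0.7 rad, children re-sampled up to ten times to stay
inside the lung), a 4 mm spherical tumor touching the root region, and three
metastasis sites planted at vessel endpoints at least 10 mm from the tumor,
sampled with probability proportional to vessel radius. Intensities are
four-level piecewise-constant (background 0.1, lung 0.3, vessel 0.7, tumor
0.9) with additive Gaussian noise (σ = 0.02); ground truth is noise-free and
exact, and planted metastases are invisible in the intensity volume.

What phantoms do **not** emulate: Hounsfield calibration, breathing/cardiac
motion, airways and lobar fissures, non-elliptical lung cross-sections,
vessel curvature and caliber noise, parenchymal texture. Segmentation and
detection results on phantoms are therefore upper bounds on clinical
performance; the biophysics and scoring layers are exercised exactly as they
would be on clinical inputs.

A deliberate, documented coupling: metastasis placement is radius-weighted,
so a transport model that prefers wide, well-perfused vessels is correlated
with the planted truth *by construction*. Localization tests measure whether
the pipeline recovers that coupling through the full image-analysis chain,
not whether the biology is true.

## Evaluation

d_s and d_h implement the exact arithmetic contracts (1 − mean squared voxel
difference; strict α > ζ thresholding), cohort summaries use the sample
(n−1) standard deviation, and ζ defaults to the uniform baseline 1/|Ω|. The
classifier truth image dilates planted voxels by one voxel to absorb
rasterization; localization metrics use the raw planted voxels. Localization
is summarized two ways over a phantom cohort: the mean heatmap value at
planted voxels against the 80th-percentile value of the pooled nonzero grid
values (an enrichment statement; the assertion used in acceptance testing),
and the mean percentile rank of planted-voxel values. Under the default
conditions the enrichment passes (~1.1–1.2×) while the mean rank sits near
70: planted sites are sampled distally while exponential transit extinction
favors proximal, short-transit sites, and grid-lattice snapping at the lung
boundary charges segmentation rasterization against the model. Both effects
are structural and reported as limitations rather than hidden by metric
choice.

## Problem sizes

Tests and the acceptance script run on 64³ phantoms (voxel 1 mm), ~8–15
vessel segments, 4096-point grids, and cohorts of 10 (acceptance) or 20
(localization test) phantoms — sizes chosen so a full cohort evaluates in
well under a minute per case on one CPU while every stage operates far from
degenerate limits.

## Known limitations

- The printed endpoint parametrization cannot represent near-vertical
  vessels; steeply rising branches are fitted with a clamped polar angle.
- Junction topology recovery depends on endpoint localization at ~1 voxel
  accuracy; heavily overlapping sibling branches merge into single segments
  (counted, logged, and tolerated by the transport layer).
- The flow stand-in is steady and non-pulsatile; its velocity scale is an
  effective parameter, not a measurement.
- Colonization ignores cell-cell interaction, immune clearance and mutation;
  the distance falloff is isotropic.
- Per-slice ellipse search assumes two roughly elliptical, mutually exterior
  lung cross-sections; pathologies that merge or occlude them will fail
  slices (interpolated when possible, reported otherwise).
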