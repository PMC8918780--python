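# Methods

This note documents the measurement models, conventions, defaults and
known limitations of `pancshell`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Coordinate and unit conventions

Arrays are stored `(z, y, x)` with per-axis voxel spacing `(dz, dy, dx)` in
µm; the default phantom spacing is (2, 1, 1) µm, a typical light-sheet
configuration with ~2× coarser optical sectioning than in-plane sampling.
Voxel centers sit at `index × spacing` (0-based). All public coordinates,
lengths, areas and volumes are µm-valued; tables report positions as
`(x, y, z)`. A mask's volume is its voxel count times the voxel volume;
its surface is the boundary between mask and background voxels.

## Distance model

The reference structure (epithelial bud or endocrine cluster) defines an
anisotropic Euclidean distance transform of the background
(`scipy.ndimage.distance_transform_edt` with physical sampling). Voxels
inside the reference are 0: in a branched organ, non-epithelial cells that
appear "inside" the reference volume sit between branches and are in
direct contact, so contact and interiority are deliberately conflated at
distance 0. Spot distances are read at the nearest voxel center (not
interpolated) — simpler, consistent with the 0-inside rule, and bounded by
one voxel; the EDT itself agrees with analytic slab/sphere distances to
within `max(spacing)` (verified in the acceptance suite). Whether the
original interactive workflow measured to the mask or to the rendered mesh
is not reconstructible; the mask EDT is our documented choice.

Distance bands are half-open and shared by the 3D and 2D pipelines: first
cell layer `[0, 7.5)` µm (≈ one cell layer, a proxy for direct contact),
analysis band `[0, 15)` µm (≈ two cell layers), distant band `[15, 50)` µm.
Records beyond 15 µm are kept but flagged `excluded`, because the
cluster-microenvironment analyses reuse the 15–50 µm band. Both boundaries
are parameters, not constants.

## Reference segmentation

`segment_reference`: Gaussian smoothing (µm-scaled, anisotropy-aware) →
threshold → morphological closing → cavity filling → small-component
removal; components are labeled by descending volume and the epithelium is
the largest. Cavity filling is on for the epithelium: the marker labels a
monolayer around lumens, and lumens must not contribute "surface" to
distance measurements. It is off for vessels and endocrine clusters.

Three threshold modes: Otsu (general default), an explicit intensity, and
`"half-max"` — half the smoothed channel's 99.9th-percentile maximum. For
*membrane* markers (Ecad, VEcad) the signal is a rim, not a filled body; a
low Otsu cut places the boundary on the rim's blurred outer tail and
dilates the mask by roughly a micron, which would systematically shift
every distance and inflate first-layer fractions by several percentage
points. The half-maximum contour tracks the membrane crest, which is the
standard edge-localization convention for symmetric blur; the 3D and 2D
pipelines therefore use `half-max` for the epithelial reference and keep
Otsu elsewhere. Residual surface bias measured on phantoms is a few tenths
of a µm.

`mask_to_mesh` triangulates the 0.5-level isosurface (marching cubes on
the zero-padded mask, spacing-aware). Sphere-phantom mesh area agrees with
4πr² within 15 % at r = 20 µm, and mesh-enclosed volume (divergence
theorem) with voxel volume within 10 %.

## Nuclear spots

Preprocessing follows the two standard steps for crowded epithelia:
`subtract_membrane` computes `max(nuclear − α·membrane, 0)` with α matching
the two channels' 99.9th-percentile maxima — a high percentile tracks the
peak structures (blob cores, membrane crests) regardless of how much of
the volume they cover, so the membrane is cancelled rather than under- or
over-subtracted; `invert_cellbody` blurs and inverts a membrane channel
into a filled-cell image.

`detect_spots` is a multiscale Laplacian-of-Gaussian detector with
per-axis scales from the nuclear prior (5 µm xy, 7 µm z — the axial
elongation of a PSF-blurred ~6 µm nucleus), evaluated at 0.8/1.0/1.25× the
base scale, with sub-voxel refinement by response-weighted centroid.
A candidate maximum must exceed both

* `threshold × robust max` of the response (relative cut, default 0.1 —
  the interactive tools' "quality" cut-off is unpublished, so this is a
  free parameter), and
* a noise floor of 5 σ of the background response, computed as the image
  noise (gradient-MAD estimator, robust to structure) times the filter's
  white-noise gain (L2 norm of the scale-normalized kernel).

When preprocessing has rectified the image (the zero-clipping in the
membrane subtraction), the internal noise estimate is biased low; the
pipeline therefore estimates noise on the raw nuclear channel and
propagates it through the subtraction as `σ·√(1+α²)`.

`deduplicate_spots` greedily suppresses, by descending peak intensity
(ties to the lower id), any detection within `min_separation` of a kept
one; the pipeline default of 3 µm ≈ one nuclear radius removes duplicate
detections inside a single large cell without merging genuinely adjacent
nuclei. The operation is idempotent.

`classify_spots` partitions nuclei: epithelial if the center lies in the
epithelium mask (sub-voxel trilinear occupancy ≥ 0.5), else endothelial if
within 3.5 µm (half the axial spot diameter) of an ERG detection — or
above an ERG intensity cut when only a raw channel is available — else
mesenchymal. The epithelial test wins on conflicts; conflicts are counted
and reported. On phantoms at peak SNR ≈ 10 the full
detection+classification chain reaches F1 ≥ 0.95 (≥ 8 µm separations) and
~99 % class accuracy.

## Vessels

`segment_vessels` is the reference segmentation without cavity filling,
keeping all components ≥ 250 µm³. `build_vessel_graph` thins the mask
(`skimage.morphology.skeletonize`), builds the 26-connected voxel graph,
merges adjacent non-degree-2 voxels into junction/endpoint nodes, traces
degree-2 chains into polyline segments, then iteratively prunes terminal
twigs shorter than `prune_length` (default 5 µm — sub-cellular twigs are
thinning artifacts of surface roughness), shortest-twig-per-junction
first; nodes left with exactly two incident segments (pruned junctions,
diagonal-run artifacts) are dissolved by merging their segments.

`segment_diameters` sets each segment's mean diameter to twice the mean
interior-EDT radius along its path, excluding samples within one node
radius of either end, where merging lumens inflate the EDT. For straight
tubes of radius 3–10 µm at (2, 1, 1) µm spacing the recovered diameter is
within one voxel (≤ max spacing) of 2r. Note the estimate carries a small
positive bias (≈ half a voxel) because the EDT measures to background
voxel *centers*; it is inside the stated tolerance and left uncorrected.

Proximity filtering keeps segments whose *minimum* path distance to the
reference is below the cut — a vessel "in proximity" touches the band; no
averaging rule is implied. Diameter histograms use 2 µm bins from 0 and
weight by segment count (a per-length weighting flag exists; which of the
two the original analysis used is not documented). The vascular volume
fraction is the exact voxel-count ratio |vessel ∩ shell| / |shell|.

## Endocrine clusters

Glucagon⁺ clusters are segmented, labeled, and filtered with a strict
`volume > 67,700 µm³` rule — the published eight-cell cutoff; a cluster at
exactly the threshold is removed. Each surviving cluster is profiled
independently against its own distance map (per-cluster shells may
overlap; aggregation across clusters is left to the caller): vascular
volume fraction and mesenchymal density in the 0–15 and 15–50 µm shells.
Densities are reported per 10⁵ µm³ (the source figures give no unit; the
choice is stated in output headers), computed as spot count over shell
volume.

## 2D sections

Sections are analyzed like the 3D volume but in-plane: watershed nuclear
segmentation seeded at smoothed-intensity maxima (nuclei are intensity
blobs, so touching nuclei keep distinct peaks even when their thresholded
footprints merge), classification by the *median* marker intensity in the
nuclear footprint (robust to bright membrane spill at a footprint's edge)
with Ecad precedence, a half-max epithelium profile with a 15 µm EDT
shell (a manual ROI polygon can be imported instead), per-class contact
fractions (`d < 7.5` among `d < 15`), and abundance pooled over sections
taken every 30 µm. On a phantom, pooled 2D composition agrees with the 3D
shell composition within 5 pp and the 2D contact fraction with the 3D
first-layer fraction within 4 pp — the package's cross-modality
consistency check. The residual discrepancy is real and explained by
geometry: the in-plane distance to the sectioned epithelium profile can
only overestimate the 3D distance.

## Synthetic phantoms

The generator is first-class code and defines the validation conditions:

* **Geometry** — a capsule-tree bud (trunk along the optical axis, default
  radius 40 µm and length 260 µm with four branches of radius 25 µm at
  25–50° polar angle) inside a 300 µm cube ROI, so the bud occupies ~10 %
  of the ROI, a plausible scale for an early bud in such a field of view.
  Vessels are constant-radius tubes (radii 3–10 µm) laid along random
  smooth paths on iso-distance surfaces `radius + 3 µm` off the bud (so
  tube and bud never overlap), plus straight free-space tubes. Endocrine
  clusters are spheres of requested volume seated on the bud surface.
* **Nuclei** — epithelial nuclei uniform inside the bud with centers at
  least one nuclear radius (3 µm) deep; endothelial/mesenchymal nuclei
  placed by rejection sampling against the *true* distance map so that
  each accepted center's recorded distance falls in its drawn shell
  (`[0,7.5)/[7.5,15)/[15,50)` µm mixture weights per class) — shell
  membership is exact by construction; centers keep ≥ 1 µm from the bud
  surface (a touching cell's center cannot sit on the boundary) and a
  global pairwise separation of 2 nuclear radii ≈ one cell diameter, the
  packing limit of adjacent cells. Without weights, endothelial nuclei sit
  on vessel walls and mesenchymal nuclei are uniform within 50 µm.
* **Rendering** — nuclei are isotropic-in-µm Gaussian blobs
  (σ = radius/1.5, i.e. FWHM ≈ nuclear diameter); membrane markers light
  the mask boundary at full amplitude and the interior at 40 % (membranes
  below the resolution limit make epithelium quasi-filled at tissue
  scale); every channel is blurred by an anisotropic PSF (σ = 2, 1, 1 µm —
  reproducing the 5 µm xy / 7 µm z nuclear appearance) and degraded with
  Poisson shot noise plus Gaussian read noise. Defaults give peak
  SNR ≈ 10. The noiseless signal depends only on the truth; the noise only
  on the seed.
* **Sectioning** — planes every 30 µm; a nucleus appears on its nearest
  plane (ties to the lower one) when the plane passes within half a
  nuclear radius of its center, emulating a physical section sampling
  only nuclei it cuts near their equator (~10 % of the population per
  30 µm spacing).

Identical spec + seed → bit-identical volume and truth (per-stage
independent `numpy` generator streams).

What the phantom does **not** emulate: light-sheet stripe artifacts,
scattering and clearing inhomogeneity, per-cell membrane honeycombs,
nuclear size/intensity variability, vessel lumens and diameter tapering,
or anisotropic cell shapes. Passing the phantom suite therefore shows the
measurement chain is correct under idealized image formation; it does not
certify segmentation robustness on real tissue, where thresholds and spot
quality cuts are expected to need adjustment.

## Validation problem sizes

Test and acceptance runs use 300 µm-cube phantoms at (2, 1, 1) µm
(13.5 M voxels): 2 000 shell-structured nuclei for layer-fraction
recovery (±3 pp), 1 500 nuclei at 66/7/27 % for composition recovery
(±3 pp per class), 200 nuclei at ≥ 8 µm separation for detection
(F1 ≥ 0.95), and a denser 5 500-nucleus phantom for the 2D/3D concordance
(±5 pp composition, ±4 pp contact fraction). Analytic oracles (slab and
sphere EDT, cylinder diameters, tube-in-shell volume fractions, exact
voxel-count cluster volumes) cover the geometric operations. These sizes
make the whole suite run in a few minutes on one core while keeping the
binomial sampling error of each recovery check at roughly half its
tolerance.

## Statistics

Two groups are compared with the two-sided Mann–Whitney U (the reported U
is `min(U₁, U₂)`, the classic tabled statistic); three or more with
Kruskal–Wallis followed by Dunn's pairwise z-tests on pooled mid-ranks
with tie correction. Dunn p-values are Holm-adjusted by default (the
source analyses name only "Dunn's multiple comparisons"; Holm dominates
Bonferroni uniformly, and a Bonferroni flag is provided). `density_check`
is the plain count/volume ratio per 10⁵ µm³.

## Known limitations

* Spot detection resolves nuclei down to ≈ 6 µm separation at the default
  optics; closer pairs merge along z and are counted once — matching the
  physical limit the original interactive workflow also faced.
* Diameter estimates assume locally cylindrical vessels; irregular lumens
  bias the inscribed-sphere radius low.
* The 2D pipeline classifies from marker intensity only; it has no notion
  of 3D continuity across sections.
* `run_pipeline`'s section analysis currently requires a phantom input;
  real section images are analyzed through the `sections2d` API directly.
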