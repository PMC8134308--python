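# Methods

This note records the models, conventions and design decisions behind
`contraplane`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the synthetic experiments do
and do not demonstrate.

## Coordinates and frames

Voxel indices are 0-based `(x, y, z)` in on-disk NIfTI array order; the
world coordinate of a voxel is its **center**, `world(v) = origin + v ∘
spacing`, all distances in mm. Only axis-aligned grids are supported —
oblique NIfTI affines are rejected rather than silently resampled.

A standard-plane frame is an intersection point plus unit normals of the
sagittal, axial and coronal planes. Independent per-plane estimates are
generically not orthogonal; they are reconciled by projecting the 3×3
normal matrix onto the nearest orthogonal matrix (SVD polar factor). This
treats the three planes symmetrically, unlike Gram–Schmidt, which would
privilege whichever plane is listed first. Inputs within 30° of a
degenerate (near-parallel) configuration are rejected.

Sign convention: the axial normal points from the plafond toward the
proximal tibia; sagittal points medially, coronal toward the fibula. With
these conventions a right ankle assembles a right-handed frame
(determinant +1) and a left ankle a left-handed one, so handedness *is*
laterality. Because a segmented cylinder is symmetric under flipping its
normal, signs cannot come from the masks; they are anchored to the image
by first intensity moments (below). The error metrics therefore also
offer sign-invariant angles.

## Artificial segmentation targets

* Sphere landmark: radius 5 mm around the plateau center; a hard binary
  mask rather than a Gaussian heatmap — with the combined CE + soft-Dice
  loss the binary target handles the extreme class imbalance well.
* Plane cylinders: per plane, voxels within `height/2` of the plane and
  within `radius` of the intersection point axis-distance-wise. Defaults
  radius 25 mm, height 2 mm (the configuration of the main accuracy
  experiment; 20/30 mm and 3 mm are supported variants). Any voxel
  belonging to two or more cylinders is demoted to background, whether
  the overlap is pairwise or triple — the omitted bars are symmetric
  about each plane, so they bias neither the per-class PCA nor the
  centroid (verified to <1° / <0.5 mm in the tests).
* Membership boundaries are inclusive (`≤`), making masks deterministic
  and exactly reproducible by enumeration.

## Synthetic phantom

The phantom stands in for non-public clinical C-arm data. Its canonical
right-ankle template (canonical frame = identity, intersection at the
origin) is deliberately minimal:

| structure | surrogate | role |
| --- | --- | --- |
| tibia shaft | tube r=9 mm along +ŷ, intensity 1.0 | axial normal / proximal cue |
| tibial plafond | disc r=12 mm, y∈[0,3], intensity 1.4 | intersection point |
| fibula | tube r=4 mm at z=+16 mm, intensity 1.0 | coronal-side cue |
| talus | ellipsoid (10,6,10) at y=−9, intensity 0.8 | distal mass |
| medial malleolus | knob r=5 mm at x=+13, intensity 1.2 | chirality cue |

The knob makes the template chiral: without it a mirrored (left) ankle
would be indistinguishable from a right one and laterality could not be
image-determined. A left ankle is the reflection of the template across
the canonical x–y plane, which flips the coronal normal and the
handedness. Each ankle is scaled (uniform in [0.8, 1.2]), rotated per
axis (uniform in ±45°, Euler order x-then-y-then-z — composition order
changes the distribution, so it is fixed and documented), translated with
a ≥20 mm margin of the intersection from the volume boundary, and overlaid
with additive Gaussian noise (default sd 0.05 ≈ 5% of tube intensity).
Bilateral samples hold one left and one right ankle in opposite x-halves
with >60 mm center separation; a `symmetric` switch renders the second
ankle as the exact mirror of the first for comparison-view validation.
Ground-truth frames are the exactly transformed canonical frames, never
measured from voxels. All randomness flows from the single spec seed.

Desk-scale default grids: 64³ at 1.5 mm (unilateral), 72³ at 2.0 mm
(bilateral), 32³ at 2.5 mm for training; the full-scale preprocessing
(512³ at 0.3 mm → 160³ at 0.96 mm, zero mean / unit variance) is the same
code path at different settings.

What the phantom does **not** emulate: bone texture, metal implants and
artifacts, fractures, beam hardening, or anatomical shape variability
beyond similarity transforms. Passing tests therefore demonstrate the
correctness of the geometric pipeline and the learnability of the task —
not clinical accuracy.

## Localization stage

Sliding-window patches tile the stride lattice with the final patch per
axis clamped flush to the boundary (all predictions on real content, no
padding). Fusion is the per-voxel arithmetic mean of covering patches,
accumulated with compensated summation in a canonical patch order, so the
fused map is exactly permutation invariant. Weighted k-means runs on
world coordinates of voxels with fused probability above 0.05 (the
clustering needs some threshold; 0.05 discards fusion noise while keeping
partial-coverage sphere voxels), with deterministic farthest-point
initialization from the weight maximum — determinism is worth more here
than the marginal robustness of random restarts. Two detections closer
than 40 mm (less than any plausible ankle separation) are merged into one
with a warning rather than reported as two ankles.

## Plane-estimation stage

ROIs are cropped on the voxel lattice with exact world bookkeeping and
zero padding recorded in a mask. PCA runs on world-mm coordinates (for
isotropic grids this equals index PCA up to scale). The plane normal is
the eigenvector of the smallest eigenvalue; a degeneracy warning fires
when the eigengap `(λ₂−λ₃)/λ₁ < 0.05`, e.g. when a crop truncates the
cylinders so strongly that disc and thickness directions blur. Classes
with fewer than 50 voxels (at 1 mm spacing) are treated as missing — PCA
on fewer voxels is statistically meaningless. The intersection point is
the unweighted mean of the three class centroids, which is robust to the
unequal class sizes the omission rule leaves behind; the pooled
all-foreground mean is available as a config switch. Default crop sizes
follow the published settings: 128 for unilateral runs, 80 for bilateral
runs (where the crop must not contain the second ankle); the desk-scale
tests use 48/32 on proportionally smaller volumes.

## Laterality and comparison views

Sign anchoring uses first intensity moments `Σ I·((w−p)·n̂)` in
anatomy-specific windows: a 45 mm sphere for the axial normal (shaft
mass), a ±12 mm near-plateau slab of radius 25 mm for the sagittal normal
(malleolus cue) and a ±18 mm slab of radius 35 mm for the coronal normal
(fibula cue). The slabs keep the laterally symmetric structures inside
the placement margin, so partial clipping at the volume boundary cannot
flip a sign (plain whole-volume moments can be fooled by an
asymmetrically clipped shaft).

Comparison slices sample each ankle in its *own* frame basis. For the
left-handed frame the in-plane axes form a reflected pair, which realizes
the "mirror to common laterality" step implicitly: a mirror-symmetric
pair yields pixel-matching slices without any explicit image flip.
`mirror_frame` (reflection through a world coordinate plane, handedness
flip) is provided for explicit conversions. Viewing levels are −6 / 0 /
+10 mm along each side's own axial normal — the published "approximately"
values, exposed in config — plus one signed correction applied to both
sides (deliberately not per side, matching the plus/minus correction-tool
semantics). Display convention: both ankles in right-ankle orientation.
Slices default to 60 mm at 0.5 mm/px, comfortably covering the 25 mm
cylinders.

## Evaluation metrics

`pos` is the Euclidean intersection-point error; `pos2Ax` its projection
onto the **true** axial normal — measured against the true plane because
that is the level the surgeon actually views (the predicted-plane variant
is a config switch). Angles are folded to [0°, 90°] by absolute dot
product, so `pos2Ax ≤ pos` and antiparallel normals score 0°. Summaries
report median, sd over all cases and sd over per-group medians (the
fold-wise convention), plus the maximum for localization audits.
Bilateral predictions are matched to truths by nearest intersection via
the Hungarian assignment; unmatched cases are counted, never dropped.

## Network and training

The segmentation network is a plain 3-level 3D U-Net: two conv(3³)–
instance-norm–ReLU blocks per level, 2× max-pool down, trilinear up with
skip concatenation, 1×1×1 output head; base width 8 at desk scale.
It is implemented directly on numpy — convolutions as one GEMM per kernel
offset on shifted views of the padded input (BLAS does the work), with
hand-derived backward passes for every layer, validated against float64
finite differences and exact adjoint identities in the test suite.

Loss: cross-entropy plus (1 − mean soft Dice over foreground classes),
ε = 1e-5, weighted 1:1. Optimizer: Adam. The full-scale recipes (learning
rate 3e-4; localizer: 64³ patches, batch 16, 1000 epochs; planes: batch
4, 300 epochs) are kept as configuration presets. The desk-scale recipe
that the tests exercise trains on 40 phantoms at 32³ (2.5 mm) for 20
epochs, and a short schedule behaves very differently from a long one:
with the conservative full-scale settings the run barely leaves the
background-prediction regime, and without any prior information the
network spends most of its updates collapsing onto, and digging out of,
the all-background solution. The desk recipe therefore (a) initializes
the output-head bias at the class-prior log-odds, the standard remedy for
extreme class imbalance, so the first updates refine shape rather than
prevalence; (b) uses batch size 1 (800 updates instead of 200) with a
40-step linear warmup to a 1.5e-3 peak and cosine decay; (c) applies
light augmentation (±5° rotation, scale 0.98–1.02) on top of the
phantoms' own ±45° pose variation; and (d) uses cylinder masks of radius
20 mm and three voxel layers' height (7.5 mm) — the proportional analogue
of the published 3 mm masks on the 1 mm grid; two-layer slabs put a hard
ceiling on the achievable Dice, and a 25 mm radius at this field of view
clips at the volume edge, both of which measurably degrade the recovered
normals. Online augmentation applies one sampled rotation/scale/
mirror/crop per draw, trilinear for images, nearest-neighbor for labels,
and analytic transforms for ground-truth frames. Training is bit-
reproducible given the seed (single-threaded numpy); divergence (NaN)
aborts with the epoch in the message. Plane decoding is per-voxel argmax
with no morphological cleanup — the PCA stage is the robustness
mechanism.

The oracle segmenters answer from exact ground truth rendered on the
query grid, optionally flipping a seeded fraction of labeled voxels to
background and switching on an equal count of background voxels within 3
voxels of the structure. Oracle noise rates are the dial for the
robustness experiments; at rate 0 the full pipeline reproduces phantom
ground truth to ≈0.15 mm / ≈0.05°, so any learned-route error is
attributable to the network.

## Numerical choices and degenerate inputs

* Inclusive mask boundaries; voxel-center sampling alignment throughout
  (`(i+0.5)·f−0.5` for resizing), which preserves physical extent and
  makes block-constant downsampling exact.
* Constant volumes cannot be variance-normalized: preprocessing returns
  zeros with a warning instead of dividing by zero.
* k-means ties (equidistant voxels) assign to the lower center index;
  duplicate detections merge below 40 mm separation.
* The mirror-symmetric comparison check uses noise sd 0.02: the two
  sides' noise realizations are independent, so at the default 0.05 the
  slice difference would measure noise, not alignment.
* Frame JSON is serialized at 9 significant digits and re-orthonormalized
  on load.

## Known limitations

* Axis-aligned geometry only; no DICOM ingestion.
* The number of ankles is operator-declared (as in the original tool);
  there is no automatic model selection for k.
* The numpy U-Net is desk-scale: full 160³ training would be impractical
  without GPU acceleration; the learning experiments show trainability of
  the representation, not clinical performance.
* Laterality anchoring assumes the template's anatomical asymmetries
  (shaft, fibula, malleolus) are visible in the ROI; heavily truncated
  fields of view could defeat the moment cues.
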