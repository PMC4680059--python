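# Methods

## The measurement model

The Cartilage Damage Index (CDI) is a rapid alternative to full cartilage
segmentation for the lateral tibiofemoral compartment. Instead of delineating
the whole cartilage plate, it samples cartilage thickness at a small set of
*informative locations* — points on the articular surface where full-thickness
cartilage loss (denudation) is most commonly observed across knees — and
aggregates them into a single height-normalized score per surface:

    CDI_surface = ( Σ_k  t_k · L_k · m ) / H

where, for each informative location k,

* `t_k` — cartilage thickness (mm) along the local surface normal;
* `L_k` — anterior–posterior extent (mm) of cartilage-bearing bone–cartilage
  boundary inside the location's partition cell on its sagittal slice;
* `m`   — the medial–lateral factor, by default the sagittal slice thickness
  (0.7 mm), so each term is a small volume in mm³;
* `H`   — subject height in meters.

The total CDI is the femoral plus tibial score (mm³/m). Lower values mean
more cartilage damage. The "voxel size" factor in this formula is ambiguous
in the literature this index descends from (in-plane dimension, slice
thickness, or voxel volume are all defensible); we fix it to the slice
thickness and note that absolute CDI magnitudes therefore carry a
convention-dependent scale — all validation statistics used here (rank
correlations, ICC, SRM, trend tests) are invariant to that scale.

## Universal surface coordinates

Each articular surface gets a rectangular 2D frame:

* `v ∈ [0, 1]` spans medial → lateral, anchored at the most medial and most
  lateral sagittal slices containing bone (slices with at least
  `min_bone_voxels` bone voxels, default 1, to guard against stray labels).
  `slice(v) = round(medial + v·(lateral − medial))`, ties rounding toward
  the lateral slice.
* `u ∈ [0, 1]` spans anterior → posterior along the bone–cartilage boundary
  of one slice. Each slice is normalized by **its own** anterior and
  posterior boundary extremes, not a global bounding box: per-slice scaling
  is robust to condyle curvature and matches the per-slice projection of the
  boundary onto the AP axis. Boundary extraction keeps the largest
  contiguous column run; the bone voxel facing the articular side (superior
  for the tibia, inferior for the femur) defines the boundary point.

Round-trip error is bounded by one grid step per axis (verified
exhaustively on phantoms), and whole-voxel translations of the volume leave
all (u, v) coordinates unchanged.

## Denudation atlas and informative-location selection

Denudation annotations are projected into (u, v) cells (default 100 × 100,
half-open binning, `u = 1` assigned to the last cell) and accumulated into a
per-cell count of affected knees. "Evenly select 9 locations in and around
the most frequently denuded region" is operationalized as an explicit,
parameterized procedure:

1. threshold the map at the `threshold_quantile` (default 0.75) of its
   **positive** cell values;
2. keep the 8-connected component with the largest total count (ties go to
   the more posterior component — larger mean `u` — since the lateral
   denudation region is posterior);
3. dilate its bounding box by `margin_uv` (default 0.05), clipped to [0,1]²;
4. tile the box with an even 3 × 3 partition and place one location at each
   cell center.

The partition cells double as the AP-length cells during measurement, so
the 9 locations never double-count anterior–posterior extent. Selection is
stable between 100 × 100 and 50 × 50 grids to within one cell width
(tested). All four knobs are configuration parameters; this is a
reproducible stand-in for what is, in practice, a judgment call by the
method developers.

## Thickness measurement and its resolution limit

Thickness at a location is read from the label volume by ray casting:
starting at the boundary voxel, stepping at 0.1 mm or finer (default
0.05 mm) along the outward surface normal (from the local boundary tangent
over ±3 boundary points), skipping bone, and measuring the cartilage run
length, capped at 15 mm to stop runaway rays through label noise. A ray
that steps off bone directly into background marks bare bone.

A single ray cannot resolve thickness below the row spacing (0.456 mm): the
label field is vertically quantized, so one ray's run length carries a
deterministic error of up to one voxel. We therefore average the run length
over a small window of parallel rays (default ±4 boundary columns). Where
the bone–cartilage interface is oblique to the voxel grid — everywhere on
the tilted tibial plateau, and on the posterior femoral condyle where the
informative locations live — the per-column quantization phases decorrelate
and the window mean is accurate to well under half a voxel (≤ 0.15 mm on
constant-thickness phantoms). Directly at the femoral apex, where the
interface is flat and grid-aligned, the phases lock and accuracy degrades
to about one voxel; this is a physical limit of label-based measurement,
not an implementation artifact, and the informative locations do not sit
there. A location reports 0.0 mm (denuded) when the majority of its rays
hit bare bone, which keeps full-thickness lesions exactly zero instead of
blurred.

The method's designed blind spot is inherited faithfully: a lesion disjoint
from every location cell does not change the CDI (asserted in tests), which
mirrors the known limitation that informative locations may not capture all
cartilage damage.

## Synthetic phantoms

Phantoms emulate the sagittal DESS geometry: 160 slices of 0.7 mm,
307 × 384 in-plane at 0.365 × 0.456 mm (defaults; tests use smaller
volumes with the same spacing). One analytic bone surface per volume:

* **femur** — a parabolic cylindrical cap, convex toward the tibia, apex
  placed anteriorly (35% of the AP extent) so the posterior region presents
  an oblique interface, as a flexed condyle does on sagittal slices;
* **tibia** — a shallow dish with an 8% posterior tilt.

Cartilage of prescribed normal thickness `t(u, v)` is rasterized as a
vertical extent `t·sqrt(1 + |∇h|²)` per surface column, so a normal ray
through the labels recovers `t`. Lesions are half-open rectangles in
(u, v) with a depth fraction (1 = denudation); ties at cell boundaries
belong to the lower-coordinate cell. Ground truth carries the exact
thickness grid and the analytic volume `∬ t·sqrt(1 + |∇h|²) dx dz`;
voxel-counted volume agrees within 5% at test resolution and improves with
refinement.

## Synthetic cohorts (fast mode)

Cohort-level experiments skip voxelization: each knee carries per-surface
(u, v) thickness grids (60 × 60) plus physical extents (femur 50 × 38 mm,
tibia 42 × 36 mm). This keeps a 100-knee, two-visit simulated study under a
second of compute; full rasterization is reserved for the coordinate /
measurement round-trip tests and the development-atlas stage.

Default study conditions mirror the validation design: 25 knees per lateral
JSN grade (0–3), with

* mean thickness decrement per grade (0, 0.3, 0.7, 1.1) mm from surface
  bases of 2.2 mm (femur) and 1.8 mm (tibia), between-subject SD 0.18 mm —
  producing roughly a halving of mean CDI from grade 0 to grade 3, the
  severity gradient reported for this compartment;
* denudation probability rising with grade (0.05, 0.3, 0.6, 0.9), lesions
  drawn inside a posterior hotspot u ∈ [0.55, 0.85], v ∈ [0.35, 0.65];
* 24-month progression per surface ~ Normal(0.12, 0.10) mm of thickness
  loss (≈ 3%/year, an OA-range rate; thickness floored at 0);
* intra-reader remeasurement noise SD 0.06 mm per location; the
  reliability subset is 5 knees per grade re-read twice;
* height ~ Normal(1.68, 0.09) m, drawn once per subject and reused at both
  visits to isolate cartilage change from normalization drift;
* covariate links from baseline true cartilage volume V (mm³):
  JSW = 0.8 + 0.6·V/1000 + N(0, 0.5) mm (mean ≈ 4.4 mm at grade 0, matching
  the reported cohort mean) and HKA = 7.0 − 1.0·V/1000 + N(0, 2.0) degrees
  (more valgus-to-varus with volume loss, mean ≈ 3°); KL grade is the JSN
  grade plus a Bernoulli(0.6) increment, clipped to 0–4.

What the generator does **not** emulate: MR intensities (labels only),
realistic anatomy (smooth analytic surfaces, rectangular footprints),
segmentation errors correlated along the surface, osteophytes or bone
attrition, and reader drift over time. Passing tests therefore demonstrate
that the algorithmic chain is correct and that the statistics recover known
effects under clean conditions — not that the index attains any particular
accuracy on clinical images.

## Statistics

* **ICC(3,1)** — two-way mixed, single-measure, *consistency* intraclass
  correlation, `(MS_subj − MS_err)/(MS_subj + (k−1)·MS_err)` from the
  subjects × measurements ANOVA; the standard Shrout–Fleiss reading of a
  "3,1 model" for intra-rater reliability. A numerically zero residual sum
  of squares (< 1e−12 of total) is snapped to zero so perfect or
  constant-offset agreement yields exactly 1.0.
* **SRM** — mean change / SD of change (n−1 denominator), sign preserved;
  negative = decline.
* **Spearman ρ** — tie-averaged ranks with the t-approximation p-value
  (n − 2 df), appropriate at the n ≈ 80–100 design sizes; an exact
  enumeration of pairings is available for n ≤ 10.
* **Trend test** — the named "test for trend" is not pinned down in this
  literature; we use Jonckheere–Terpstra (rank-based, built for ordered
  alternatives), with a seeded two-sided permutation p-value (default
  10,000 permutations; ties count ½; permutations are vectorized in
  chunks). A tie-corrected normal approximation is available as
  `mode="asymptotic"`. The statistic's null mean `(n² − Σ nᵢ²)/4` decides
  the reported direction.

The validation report bundles these with per-grade mean CDI tables and
rank pairs for rank–rank scatter plots, and records the permutation count
and seed used.

## Numerical and design choices

* 0-based slice/row/col indices; (u, v) continuous in the closed unit
  square; half-open cell binning with 1.0 in the last cell.
* `slice_for_v` ties round toward the lateral slice (documented,
  deterministic).
* Degenerate inputs raise typed errors: no bone ("empty volume"), bone in a
  single slice, boundaries under 3 points, all-zero frequency maps,
  zero-variance ratings or changes, locations off the surface. An empty
  denudation mask is *not* an error (an intact knee is valid data).
* Pipeline runs are reproducible byte-for-byte from config + seed: all
  randomness flows from a master `SeedSequence`, artifacts are stamped with
  a SHA-256 config hash, and JSON is written with sorted keys. Demo sizes
  (20 development knees, 10 validation knees per grade, reduced phantom
  volumes, 2,000 permutations) complete the full pipeline in seconds;
  the acceptance script scales up to 50 development knees and the full
  25-per-grade validation design.
* Configuration is YAML validated through typed pydantic models.

## Known limitations

* Absolute CDI values are convention-dependent (see the ml-factor note) and
  are not comparable across implementations without harmonizing that factor.
* Thickness accuracy degrades to ~1 voxel at flat, grid-aligned interface
  patches (femoral apex); irrelevant for posterior informative locations.
* The location-selection rule (quantile → largest component → dilated box →
  even grid) is an explicit substitute for a manual expert choice, not a
  reconstruction of any published coordinate set.
* Fast-mode cohorts share one lesion process across femur and tibia per
  knee (damage co-occurs within a joint); surfaces do not progress
  independently of that shared severity.
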