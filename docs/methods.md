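# Methods

This note records the models, conventions and numerical choices behind
`cscmorph`, in the order the pipeline runs them.

## Synthetic micrographs (synthgen)

The generator emulates how rosette CSCs appear on the protoplasmic
fracture face of a freeze-fracture replica: dark multi-lobed particles on
a lighter membrane background (replica polarity; black/white inversion is
an explicit downstream step), with an optional brighter "decoration"
annulus around each lobe mimicking preferential metal-grain accumulation,
and additive Gaussian noise.

Study conditions (the defaults of `SimulationConfig`):

| parameter | default | meaning |
|---|---|---|
| `ring_radius` | 8.5 nm | half the opposite-lobe spacing (17.0 nm mean) |
| `lobe_area_mean`, `lobe_area_sd` | 39.9, 6.5 nm² | per-lobe true area, Normal truncated to ±3 sd |
| `lobe_shape_mix` | 0.5 | fraction of lobes drawn triangular (visual assessments span ~30–70%) |
| `five_lobe_fraction` | 0.09 | minority of five-lobed/indistinct particles |
| `centroid_jitter_sd` | 0.35 nm | isotropic lobe-centroid jitter; reproduces the ~0.7 nm spacing sd |
| `pixel_size` | 0.25 nm/px | plausible sampling for film scanned at high resolution; the true value after digitization is not published, so this is a configurable package choice |
| `box_size` | 31.6 nm | particle box; configs whose particles cannot fit are rejected |
| `noise_sd`, `halo_strength` | 0.15, 0.08 | noise and decoration amplitudes (intensity units; lobes are 0.35 below a 0.55 background) |

Triangular lobes are equilateral triangles with corner-rounding radius
10% of the side (the Minkowski sum of an inner triangle with a disc),
one vertex pointing at the particle centre; round lobes are discs of
equal area.  The recorded "true area" is the exact analytic area of the
drawn shape.  Rasterization uses a 3×3 sub-pixel coverage test (a pixel
belongs to a lobe when ≥50% covered), which makes the rendered pixel
count an unbiased area estimate.  One seed drives a per-particle
sub-stream plus a noise stream, so micrograph and truth are bit-identical
for a fixed `(seed, config)` and stable under particle subsetting.

The truncation of lobe areas at mean ± 3 sd matches the spread of the
published per-lobe range at n = 300 and guarantees the box constraint.

**What the generator does not emulate:** metal-grain texture, shadowing
anisotropy, membrane curvature/tilt (elliptical particles), replica
cracks, or correlated (non-white) noise.  Tests passing on this generator
therefore validate the *measurement arithmetic and recovery behaviour*,
not robustness to every replica artefact; lobe tracing on real data
remains a manual or user-supplied step.

Toy atomic models are vertical pseudo-atom columns ("helices") spanning
the membrane slab, packed on tangent hexagonal-lattice sites — the
compact packing of a real transmembrane domain.  The default helix
cross-section radius 0.7463 nm gives a per-helix footprint of 1.75 nm²,
so an 8-helix monomer occupies ~14.0 nm², one third of the published
trimeric transmembrane footprints — a realistic packing density chosen
once from those published areas.

## Measurement protocol (metrology)

* **Circular geometry.**  The smallest enclosing circle (Welzl's
  algorithm; verified against a brute-force support-set oracle) over all
  lobe outline points gives `P_circ = 2πr` and `d_circ = P_circ/π`
  (an exact identity, asserted per particle).
* **Hexagonal geometry.**  The irregular hexagon through each lobe's
  outermost boundary point gives `P_hex`; the diameter uses the
  across-flats regular-hexagon relation `d_hex = (√3/6)·P_hex`.  The
  across-corners alternative (`P/3`) is inconsistent with the published
  perimeter/diameter pairs by ~16%, while across-flats agrees to ~1%;
  the residual ~1% presumably reflects per-particle irregular-hexagon
  conversions whose exact rule is not published.
* **Lobe areas** are absolute shoelace areas of simple polygons
  (self-intersections are an error naming the crossing segments).
* **Opposite-lobe spacings** pair centroids (i, i+3) after ordering by
  polar angle.
* **Summaries** report mean ± sample SD (n−1; absent for n = 1) per
  group; group-level and overall rows are *unweighted* means of member
  values/means — the only convention that reproduces the published
  summary rows (e.g. (39.9 + 39.1)/2 = 39.5).
* Particles without exactly six identifiable lobes are excluded from
  metrology but counted, mirroring the published 324-of-497 yield.

Coordinates live in a continuous nm plane; pixel (row, col) maps to nm
through its centre, origin top-left, y downward.

## Class averaging (classavg)

Alignment is iterative and reference-free: the reference starts as the
unaligned mean; each round estimates rotation by circular
cross-correlation of polar-resampled images (angle step 1° by default)
and translation by an upsampled correlation peak (search capped at ±25%
of the box), re-transforms the *original* images (no interpolation
accumulation), and re-averages.  Iteration stops at `n_iter` or when the
median shift update falls below 0.1 px.  Zero-variance images are
excluded with a warning.  The mean correlation to the reference is
tracked and non-decreasing in practice.

Classification is k-means (Euclidean distance on zero-mean/unit-SD pixel
vectors, removing per-image contrast scale) repeated over `n_trials = 5`
sub-seeded trials; trials are matched to the first by Hungarian
assignment on the class-membership Jaccard matrix, and a class is kept
when its mean matched Jaccard is ≥ `min_overlap = 0.5`.  This is an
explicit analogue of stability-filtered averaging ("classes reproducible
across classification trials"), not a replication of any program's
internal parameters.  Members of unstable classes stay unassigned.
Box sizes in nm round to the nearest odd pixel count so every box has a
centre pixel (31.6 nm → 127 px, 10.3 nm → 41 px at 0.25 nm/px).

**SNR convention.**  Wherever tests quote an SNR they use the
single-particle convention: signal variance over noise variance, so at
SNR 1 the added noise sd equals the sd of the noiseless image.

## Triangularity (lobeshape)

A lobe mask is the Otsu superlevel set, largest connected component,
holes filled.  The score is
`T = max_θ IoU(mask, T_θ) − IoU(mask, D)`, where `T_θ` is the equal-area
equilateral triangle rotated θ ∈ [0°, 120°) in 1° steps and `D` the
equal-area disc, both centred on the mask centroid.  Equal *area* (not
perimeter) references keep the score aligned with the pipeline's primary
measured quantity; the 120° search period exploits triangle symmetry;
IoU was preferred over moment-based descriptors because it maps directly
onto the visual "is it a triangle" judgement.  Masks touching the box
border are flagged low-confidence.  Population statements are a
non-increasing fraction-vs-threshold curve; no single "true" triangular
fraction is claimed, because strictness is exactly the free parameter in
the visual assessment.

## Footprints and assemblies (footprint)

Atoms within the membrane slab (midplane ± 2.0 nm by default — a typical
hydrophobic half-thickness; which atoms count as the transmembrane
region is not defined by any published rule, so the slab is configurable)
project to disks with fixed van der Waals radii
(C 0.170, N 0.155, O 0.152, S 0.180, H 0.120, P 0.180 nm; unknown
elements default to 0.170 nm with a warning; the slab interval is
closed).  PDB coordinates are read in ångströms and converted to nm.

* **Union areas** are rasterized (default grid 0.05 nm) with a linear
  edge-antialiasing ramp; agreement with a ≥10⁶-sample Monte-Carlo oracle
  is within 0.5% on random disk sets, including sub-nanometre disks.
* **Blurred isosurfaces.**  The density is the disk-indicator sum
  convolved with a Gaussian of FWHM `R` (default 2.5 nm).  The threshold
  is expressed relative to the analytic centre peak of an isolated
  average-radius disk and is auto-calibrated by default so the isosurface
  area equals the hard union area — the operational reading of rendering
  "to the edges of the van der Waals model"; the absolute threshold of
  the original rendering software is not portable.  The auto-calibrated
  relative threshold exceeds 1 when `R` is large compared to single
  disks; user-supplied thresholds must lie in (0, 1).
* **Cn oligomers** place n monomer copies on the smallest ring radius
  (bisection, 0.01 nm tolerance) at which adjacent-copy hard overlap is
  ≤ `contact_tolerance` × monomer area (default 0.01), with the Cn phase
  grid-searched (1° default).  Zero tolerance is resolved through
  analytic disk-pair penetration depths, making tangency exact and the
  oligomer area exactly additive.  This deterministic geometric packing
  replaces docking: the area comparison depends on footprint geometry,
  not interface energetics, which are out of scope.
* **Six-fold assemblies** put six oligomer copies at 60° spacing on
  `r_ring` (8.5 nm reproduces the 17.0 nm opposite-lobe spacing); the
  common per-lobe rotation is fixed or chosen to minimize adjacent-lobe
  clash.  Clash area is always reported, never forbidden — oversized
  oligomers are *supposed* to clash.

## Comparison and the stoichiometry call (compare)

`percent_excess(a, b) = 100(a−b)/b`.  The per-lobe call is
`argmin_n |A_n − Ā|` over n = 2..6 with ties to the smaller n (the
conservative reading of an upper-bound claim), and the complex-level
count is six times that.  The published oligomer-area tables and
dimension rows ship as TSV inputs (`cscmorph/data/`) because the raw
micrographs and refined models they derive from are not deposited; the
report labels them as published inputs and recomputes all arithmetic
from them.  One published comparison ("4% to 8% larger") is
normalization-ambiguous at its upper end; the report therefore prints
both denominators for both model comparisons.

Overlay fits threshold the class average (Otsu), centre the assembly
footprint on the mask centroid, render it as an area-preserving envelope
blurred to 2.5 nm (matching the published isosurface rendering; 0
disables), and optimize a global rotation for coverage.  Coverage is
relative to the mask, spill relative to the footprint, and inter-lobe
clash comes from the assembly geometry.

## Pipeline, problem sizes, determinism

`run_pipeline` chains simulate → measure → average → score-lobes →
footprint → compare, writing every intermediate to the run directory and
a JSON report with seed, config hash and package version.  A config
without a seed is rejected before any computation; a fixed seed gives a
bit-identical report.  Default test and demonstration runs use tens of
particles and a 5–15° oligomer phase grid: the toy monomer is nearly
isotropic, so coarse phase grids change its packed radius negligibly
while keeping runs interactive; cohort-level statistics in the
acceptance script use a 497-particle noiseless simulation (≥300 measured
six-lobed particles, mirroring the published yield).

## Known limitations

* Lobe segmentation from raw noisy micrographs is deliberately not
  automated beyond thresholding aids; the measurement stage consumes
  polygons from ground truth or user annotation, as the original
  protocol traced lobes by hand.
* The toy helix bundles are stand-ins for undeposited atomic models;
  their absolute areas are calibrated, so the synthetic stoichiometry
  call validates the *decision logic*, not any new structural claim.
* Alignment assumes roughly centred particles and in-plane rotation
  only; no CTF model, no 3D reconstruction.
* Rotational alignment of a six-fold-symmetric object is identifiable
  only modulo 60°; rotation-recovery guarantees are stated for
  asymmetric templates.
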