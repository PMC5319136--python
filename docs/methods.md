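# Methods

This note documents the models, numerical conventions and design choices
behind the `ctoam` package, and what the synthetic studies do and do not
demonstrate.

## Measurement model

Subchondral bone density is read off a CT volume `V` (HU) restricted to a
binary bone mask `M` supplied as input (segmentation is out of scope: in
practice the bone is outlined manually on transverse slices). Arrays are
indexed `(x, y, z)` = (medial–lateral, dorso-plantar, distal–proximal);
voxel `(i, j, k)` sits at `origin + (i, j, k)·spacing` mm.

### Views

A view is an orthographic frame: a unit sight direction `d` plus an
orthonormal in-plane basis `(e0, e1)`; image columns run along `e0`, rows
along `e1`. The proximal view looks down the slice axis
(`d = (0, 0, −1)`, `e0 = x̂`, `e1 = ŷ`); the dorsal view is the proximal
frame tilted backwards 90° about the medial–lateral axis (Rodrigues
rotation), giving `d = (0, 1, 0)`, `e1 = ẑ`. Arbitrary tilts are allowed;
the basis is re-orthonormalized by construction.

### Surface-anchored maximum intensity projection

Per pixel a ray is marched along `d` at step `min(spacing)/2` (sub-voxel
with respect to every axis). Membership is nearest-voxel: a sample belongs
to the bone iff its nearest voxel (per-axis `floor(i + 0.5)`, i.e. round
half up) is in `M`. The first in-bone sample anchors the articular
surface; from it a segment of length `mip_depth` (default 1.5 mm) extends
inward and the pixel value is the maximum HU over that segment. Pixels
whose ray never enters the mask are outside the joint surface and carry
NaN.

HU is sampled by **masked trilinear interpolation**: the eight surrounding
voxels are blended with trilinear weights, out-of-mask voxels receive zero
weight, and the weights are renormalized (coordinates clamped at the
grid). Two properties follow by construction: voxels outside the bone can
never influence any densitogram value (no soft-tissue dilution at the
surface), and pixel values are monotone in the volume's HU and in
`mip_depth`. Ray and pixel extents are restricted to the mask's bounding
box padded by one voxel — rays outside it cannot enter the mask, so this
is purely an optimization; it also anchors the pixel grid to the bone, so
whole-voxel translations of the content reproduce the identical
densitogram.

The default pixel size is the smallest in-plane voxel spacing (no
resolution loss); `mip_depth` smaller than the sampling step is rejected.
A deliberately slow per-pixel re-implementation of the same definitions
(`ctoam.reference.mip_bruteforce`, own nearest/trilinear code) serves as
an independent cross-check; on random ≤ 20³ volumes with random tilts the
two agree to well under 1 HU (the documented interpolation tolerance).

### Calibration

Density calibration is an OLS line through (mean ROI HU, nominal density)
over the phantom inserts: arithmetic mean, no HU thresholding inside an
ROI (an ROI is a defined region of homogeneous material — standard
quantitative-CT practice). At least two inserts with distinct densities
and disjoint ROIs are required; identical mean HU across inserts or a zero
slope raise a degenerate-fit error. Calibration is applied to densitogram
pixels *after* projection, so each joint carries both an HU and a
mg HA/cm³ densitogram; the maximum of an affine map equals the affine map
of the maximum (slope > 0), so the order does not change the statistics
while keeping raw-HU maps available.

### Quantization, maxima, MAR

Densitogram HU map to 8-bit levels over a fixed window (default
200–1200 HU, the same range as the false-colour display scale):
`level = clip(round(255·(HU − lo)/(hi − lo)), 0, 255)`, then
`bin = min(level // 32, 7) + 1` — 8 bins of exactly 32 levels, level 255
in bin 8. A fixed window (rather than per-image min–max) keeps bins
comparable across scans and time points, which is the point of phantom
calibration; it is configurable.

A density maximum is an 8-connected component of pixels with bin ≥ 7.
`min_area` defaults to 3 px to suppress single-pixel noise speckles
(1 restores the strict literal definition); connectivity is configurable
(4/8). Each region carries two locations:

* the **area centroid** — describes where the region lies, but the
  centroid of an absolute-threshold region shifts whenever the region
  grows, e.g. under a global density increase on a curved, obliquely
  viewed surface;
* the **peak** (highest-HU pixel) — invariant under any monotone
  rescaling of the densitogram, so it tracks the location of the
  underlying density maximum itself. Longitudinal location comparisons
  therefore use peaks; both locations are reported.

Locations are expressed on a fixed 30 × 30 unit grid spanned by the tight
bounding box of the joint-surface pixels (corner → (0,0), opposite corner
→ (30,30)); a degenerate zero-span axis maps to the grid midline. Because
the whole surface always spans 30 units, coordinates are invariant to
joint size and pixel scale. MAR is the union of all maximum-region pixels
over the surface pixel count, reported as a ratio and ×100; per-region
ratios are also emitted so single-region conventions can be compared.

### Paired statistics

Per view and metric (mean density, maximum density, MAR×100), paired
differences are tested with Shapiro–Wilk (the t-test's normality
assumption concerns the differences, not the margins) and a two-sided
paired Student's t-test, α = .05, no multiple-testing correction. Edge
cases: identical time points report t = 0, p = 1 (flag `identical`);
constant non-zero differences have zero variance and report NaN with flag
`zero_variance`. For locations, each subject's t2 maxima are matched to
its t1 maxima by greedy nearest-centroid pairing, matched displacements
are averaged per subject, and the per-subject (Δx, Δy) are tested per
coordinate (paired t) and jointly (one-sample Hotelling T², F-transformed)
— there is no single canonical way to combine x and y into one p-value,
so both are reported and the joint test is used as the headline location
test.

## Synthetic data

The generator emulates a trochlea-like tarsal bone:

* **Geometry** — two overlapping partial (upper-half) cylinders with
  medial–lateral axes stand in for the medial and lateral trochlear
  ridges (default radii 9 and 8 mm, length 14 mm, 40 × 32 × 55 mm volume
  at 0.5 × 0.5 × 1.25 mm voxels; the 1.25 mm slice spacing matches the
  collimation of the emulated protocol). The convex half faces the
  proximal and dorsal viewers simultaneously, which is the minimal
  geometry exhibiting the two-ridge maxima topology.
* **Density** — a subchondral shell (2.5 mm, 550 mg HA/cm³) over a
  trabecular interior (250 mg HA/cm³); every boundary of a ridge except
  its flat base counts as shell. Hotspots are isotropic Gaussian bumps
  (350 mg HA/cm³, σ = 2 mm) anchored on the shell surface — one per
  ridge, the medial placed proximally (40° from vertical), the lateral
  more distally (70°), so each view sees both at usable incidence.
* **Phantom** — five cylindrical inserts at 0/100/200/400/800 mg HA/cm³
  (the nominal ladder of a typical bone-density phantom; configurable)
  below the bone, ROIs eroded to avoid edge voxels (574 voxels each).
* **Signal chain** — bone/insert densities map to HU through the inverse
  of the configured true calibration (slope 0.8 mg HA/cm³ per HU,
  intercept −3), then additive Gaussian HU noise (default SD 10 HU) is
  applied to the whole volume. With zero noise the mapping is exact, so
  calibration recovery has a machine-precision oracle.
* **Cohorts** — per subject a recorded jitter factor `N(1, 0.04²)`
  (truncated at 0.5) scales all bone densities at both time points
  (between-subject variation), and the growth factor (default 1.15,
  matching the ~20% weight gain of a maturing large-breed dog as a
  density effect) multiplies bone — not phantom — densities at t2 before
  noise. Hotspot anchors never move: the simulated truth is "density
  grows, loading pattern fixed". Scans are seeded with structured keys
  `(root seed, subject, timepoint)`; an additive-offset scheme was
  rejected because sequential root seeds would make adjacent replicates
  share noise realizations.

What the generator does *not* model: real talus shape, cartilage, beam
hardening/scatter, partial-volume blur at the bone boundary, scanner
drift, repositioning error between time points, or spatially varying
growth. Passing tests therefore demonstrate that the *pipeline* measures
what it claims on known ground truth — not that real joints behave this
way.

## Simulation studies and problem sizes

All studies live in `ctoam.experiments`, are driven by explicit seeds,
and are sized to run on a single CPU in minutes:

* MIP cross-check: 20 random volumes ≤ 20³ voxels, random tilts 0–90°,
  random depths 1–3 mm, compared pixel-for-pixel with the brute-force
  reference (tolerance 1 HU; spacings are drawn as generic floats so
  nearest-voxel ties do not occur).
* Calibration: noise-free recovery (relative slope error < 0.1%,
  observed ~1e−14) and 20 noisy scans at 10 HU SD (slope error < 2%;
  with ≥ 500-voxel ROIs the ROI-mean standard error is ~0.4 HU, so the
  observed ~0.1% has comfortable margin).
* Localization: 10 seeds at default noise; every visible hotspot must be
  matched by a detected region whose grid centroid is within 2 units of
  the anchor mapped through the same grid frame.
* Growth: 20 cohorts of 10 subjects, growth 1.15, noise 5 HU — every
  subject must increase in all three metrics, paired tests must reject in
  ≥ 95% of cohorts, and the location test must reject at roughly the
  nominal rate (peaks are anchored).
* Type-I: 1000 null cohorts (growth 1.0) on a compact variant of the same
  anatomy (36 × 28 × 25 mm at 1 × 1 × 1.25 mm voxels, three inserts), one
  view, mean density — the rejection rate must fall in the 95% binomial
  interval around .05.

## Known limitations

* The MIP surface anchor is quantized to the ray step (≤ half the
  smallest voxel); very thin structures (< one voxel) can be missed by
  nearest-voxel membership.
* Oblique, strongly foreshortened hotspots (incidence cosine ≲ 0.25) may
  fall below `min_area` after projection; the ground truth only lists
  hotspots above that incidence.
* The statistics module implements exactly the paired design: unequal or
  unpaired groups are rejected rather than approximated.
* t1/t2 scans are compared in their own view frames (no inter-scan
  registration), which matches the intended acquisition protocol of
  standardized positioning.
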