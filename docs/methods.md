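# Methods

`fishct` quantifies musculoskeletal phenotypes of small fish from microCT
volumes: automatic tri-compartment tissue segmentation, lean-mass
morphometrics, a per-vertebra skeletal phenome, cohort statistics
(skeletal barcodes, a permutation global test, allometric normalization),
and mutation-efficiency-normalized screen scores.  Because raw fish scans
are rarely redistributable, the package ships a ground-truthed phantom
generator; every stage is validated against what the generator provably
constructed.

## Axis and unit conventions

Volumes are ordered (anteroposterior, dorsoventral, left–right) with index 0
anterior and dorsal; readers permute external data into this frame from a
user-declared orientation.  Lengths are micrometres, areas mm², volumes mm³,
mineral density mg HA/cm³.  Intensities stay in native reconstructed units —
all thresholds are data-driven, so no Hounsfield rescale is needed, and both
threshold algorithms are equivariant under positive affine intensity maps.

## Tissue segmentation

Two thresholds are selected automatically on a single transverse slice
(default: the stack midpoint, which in a typical fish sits adjacent to the
posterior swim-bladder chamber; a landmark override exists).  A
``slice_halfwidth`` option widens the histogram source to a thin slab
around the midpoint: the protocol's operator picked a representative slice
by eye, and a strict single slice can fall in an intervertebral gap and
contain no bone at all, leaving the upper threshold without a bone mode —
the pipeline scripts use a half-vertebral-pitch slab for this reason, while
the faithful single-slice behaviour remains the default.

* **Lower threshold — isodata ("Default").**  The intermeans update
  `g(t) = round((mean_{<=t} + mean_{>t})/2)` is scanned exhaustively from the
  lowest bin; the threshold is the first split with `g(t) <= t`.  On clean
  histograms this is exactly the smallest fixed point; on noisy histograms,
  where the iteration oscillates between adjacent bins, it is the lower bin
  of the first oscillation — the basin an ascending iteration converges
  into.  Rounding is half-up.
* **Upper threshold — Kapur maximum entropy.**  The split maximizing the sum
  of Shannon entropies of the two renormalized class distributions; ties
  (within 1e-10, absorbing float summation order) go to the smallest split.

Histograms use native one-unit bins for integer volumes and 256 equal bins
for floats.  Voxels are classified: below lower = presumptive adipose,
within `[lower, upper]` = lean, strictly above upper = bone.  The boundary
convention (bone strictly above the upper threshold) matters: the
maximum-entropy tie rule returns exactly the lean-class intensity on
noiseless class-pure histograms, so an upper-inclusive bone class would
misclassify all lean tissue in the noiseless limit.

**Body mask.**  Presumptive adipose and background air are indistinguishable
by intensity, so a body mask separates them: the largest 26-connected
component of voxels at or above the lower threshold, plus every enclosed
cavity (hole filling).  A Euclidean-ball closing (default radius 3 voxels)
is used only to *seal* thin channels before hole finding; the fillet voxels
the closing itself would add at concave corners (e.g. where an arch meets
the body wall) are not part of the mask.  This keeps the mask exactly equal
to the true body on noiseless phantoms while remaining robust to
channel-connected cavities.

**Adipose is folded into lean** for all lean-volume quantities, since the
intensity criterion cannot reliably separate adipose from lean tissue; the
adipose class is still reported separately.

## Lean morphometrics

Per-slice cross-sectional areas give the AP lean profile.  The
anterior/posterior swim-bladder boundary is the slice of maximal lean CSA in
the gap between the two largest internal air cavities (in-mask voxels below
half the lower threshold, ≥50 voxels).  Regional lean volumes integrate the
profile anterior/posterior of the boundary over a configurable trunk range
(default: the full body extent — the anatomical anterior cut of the trunk is
a configuration landmark, deliberately not auto-detected).  Standard length
is the AP extent of the body mask; dorsoventral height is the maximal
per-slice DV extent; fineness ratio = SL / height.

## Vertebral phenome

Bone voxels are opened by one voxel (removing the speckle that any
threshold sitting ~2σ into the soft-tissue tail produces), labelled by
26-connected components, size-filtered, and ordered by AP centroid; voxels
the opening shaved off fine structures are re-attached face-adjacent.
A component whose AP extent exceeds 1.8× the median spans more than one
expected vertebra.  Because two coincident noise voxels can bridge the
narrow intervertebral gap (a single speckle face-propping a surface voxel
survives the gentle opening, and a stronger opening would sever thin arch
laminae), such components are first inspected along AP: near-empty slices
(below 5% of the component's median slice count) between substantial blocks
identify a noise bridge and the component is split there.  A component with
no such slice — a substantial, genuinely mineralized bridge — raises a
fusion error carrying the component ids rather than being silently split.

The body axis is fitted through per-vertebra *centrum footprints*: grid
columns whose AP bone count is near-maximal trace the centrum disc, whose
centroid is unbiased by unequal neural/haemal arches (a whole-component
centroid is demonstrably pulled dorsally).  The centrum radius per vertebra
comes from the area-weighted radial occupancy integral
(``r² = Σ occ_k·Δ(e²)`` over annuli out to the first annulus under 50%
occupancy, plus half a voxel of guard) — occupancy of a partially covered
annulus equals its covered area fraction, so this is phase-stable where a
plain "last annulus over 50%" rule is not.  Voxels within that cylinder are
centrum, the rest split dorsal/ventral into neural and haemal arch.

Measures per element: volume (voxel count), TMD (mean of linearly calibrated
intensities; identity calibration by default because hydroxyapatite
calibration constants are scanner-specific), and local thickness — the
maximal-inscribed-sphere (Hildebrand) definition computed by sphere-painting
the Euclidean distance transform, exact for element-sized structures and
anchored in tests to an O(n²) brute-force oracle.  Note the Hildebrand mean
of a short cylinder is genuinely below its diameter (end faces limit the
spheres).  Centrum length is the speckle-trimmed AP extent (0.5% of voxel
mass trimmed per tail — inert on clean structures, immune to single
reattached noise voxels).  Neural arch length is the trimmed DV extent;
the arch angle is measured at the dorsal apex between rays to the left and
right hemi-arch centroids taken from a mid-leg window (65–85% of the DV
extent): mid-leg row centroids lie exactly on the leg midlines, whereas rows
at the centrum junction are clipped by the centrum and bias the rays
outward.  The phenome matrix covers the 20 anterior-most vertebrae:
{centrum, neural arch, haemal arch} × {volume, thickness, TMD} plus centrum
length, with arch length/angle as auxiliary myomere correlates.

## Cohort statistics

* **Skeletal barcodes**: per-(measure, vertebra) standard scores against the
  control cohort (mean/SD per cell, ddof=1); per-fish or group-mean mode —
  both exist because published figures show per-fish barcodes while group
  summaries drive ranking.
* **Global test**: per measure, the 20-vertebra block is standardized per
  vertebra and the score statistic `Q = ||X'(y − ȳ)||²` is referred to its
  label-permutation distribution: `p = (1 + #{Q_perm ≥ Q_obs})/(B + 1)`,
  B = 10 000 by default, seeded.  A permutation null was chosen over the
  original asymptotic null because cohorts of 6–10 fish per group are far
  from asymptotia; the permutation version is assumption-free and exact in
  expectation (p can never undercut 1/(B+1)).  No multiple-testing
  correction is applied across the ten measures by default, matching
  per-measure reporting practice; a Benjamini–Hochberg option would be a
  caller-side one-liner on the returned table.
* **Allometry**: `m = a·SL^b` fitted on controls by OLS on logs;
  normalization rescales every fish to the control mean SL via
  `m* = m·(SL_ref/SL)^b`, removing body-size-driven differences.

## Screen scoring

Per gene: `z_m = (mean_mutant − mean_control)/SD_control` per measure (with
an unpaired t-test p-value alongside), `mean|z|` over the panel, and the
prioritization score `mean|z| / efficiency`, where mutation efficiency is
`1 − %WT/100` from sequence-trace decomposition of the somatic pool.  The
normalization extrapolates the diluted phenotype of a mosaic pool to full
editing.  The measure panel is configurable; the default covers skeletal
myomere correlates (centrum length, neural arch length/angle), soft-tissue
morphology (trunk/anterior/posterior lean volumes, chamber lengths) and
standard length.  Reported scores are rounded to two significant figures.

## Synthetic phantom: the stated world

The default phantom is a small adult zebrafish-like body at the 21 µm in
vivo voxel size: standard length 12.6 mm, maximal height 2.55 mm (fineness
≈ 4.9), width 0.62× height under an elliptical height profile; 24 vertebrae
(378 µm solid-cylinder centra of radius 160 µm at a 462 µm pitch — both
exact voxel multiples so digitization is identical across vertebrae);
neural and haemal arches as paired straight laminae attaching at ±50° on
the centrum surface with a 30° apex angle and 84 µm band thickness,
extruded over 168 µm AP; two air-filled swim-bladder chambers (2.2/2.9 mm,
340 µm radius) separated by a 63 µm septum at 45% of SL; ~1.5% of body
volume as internal adipose pockets (120–280 µm radius, fully enclosed in
soft tissue).  Intensities are air 0, adipose 60, soft tissue 120, bone =
inverse TMD calibration of the per-vertebra density (default 900 mg
HA/cm³ → 900 under identity calibration): free parameters of the stated
world, chosen once so that the two automatic thresholds separate the
intended classes on a mid-body slice histogram (verified by hand before any
test existed).  Noise is additive Gaussian, *unclipped* (volumes are signed
integers, as real reconstructed exports are): clipping at zero would bias
the air-class mean upward and destabilize the lower threshold at moderate
noise.  Noise tiers: low = 8, moderate = 12 native units against the
60-unit adipose/soft separation.

Every truth value is computable from the spec before voxelization: centrum
volume/thickness/length analytically (πr²L, 2r, L), arch voxel counts by
closed-form per-row grid arithmetic (counts of grid planes in intervals),
lengths as the continuous generative values.  Arch volumes exclude cells
inside the centrum disc, matching the measurement convention.

Cohorts apply multiplicative effects to named quantities — centrum length,
TMD, lean volume (via a body-width rescale that corrects for the fixed
bone/air inclusions; width rather than height so the dorsoventral clearances
between arches and swim bladder are preserved), and standard length (a true
isotropic body-size effect) — plus mean-one lognormal between-fish
variation; all per-fish randomness derives from one master seed.

**What a green phantom test does not establish.**  The phantom has uniform
class intensities (no partial-volume gradients, beam hardening or ring
artifacts), perfectly separated chordacentrum-like vertebrae (no fusions,
ribs or fin rays), straight arches and a straight body axis.  Green tests
establish that the algorithms recover what they claim from geometry they
can in principle recover it from — not scanner-grade robustness.

## Numerical choices and known limitations

* Thresholds come from one slice and apply globally (protocol fidelity); a
  whole-volume histogram option exists but is off by default.
* At noise sd ≳ 15 (2.5σ of the class gap) the single-slice intermeans
  crossing becomes seed-dependent on the phantom's near-delta trimodal
  histogram and can jump to the soft/bone valley; real histograms, with
  partial-volume spread, are less brittle.  Documented, not tuned away.
* The upper threshold inevitably sits ~2σ into the soft-tissue tail, so a
  percent-scale speckle of false bone voxels is expected at any noise; the
  vertebra labeller's opening/reattach and the trimmed extents make the
  phenome robust to it, and noisy-phantom bone *volumes* remain biased by
  the surface speckle halo at the few-percent level.
* Ties: equal-entropy splits take the smallest threshold; AP ordering ties
  are broken by centroid; the boundary slice takes the first argmax in the
  inter-chamber gap.
* DICOM series reading requires the optional `pydicom` dependency; NIfTI
  and TIFF are first-class.  Two-fish acquisitions must be split upstream.
* The trunk's anterior anatomical cut and the neural-arch-angle convention
  are declared configuration, not inferences — the underlying field
  protocols leave both open.
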