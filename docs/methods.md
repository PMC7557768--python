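# Methods

## Scope and model of the data

The package analyses structural connectivity between the pedunculopontine
nucleus (PPN) and the internal/external globus pallidus (GPi/GPe) from
per-subject tractography inputs: an orientation field on a voxel grid, ROI
masks (pallidal segments, PPN, six exclusion nuclei per hemisphere, a
midsagittal slab, functional-territory subdivisions) and a rigid
subject-to-template transform. Acquisition, preprocessing, tissue
segmentation and spherical deconvolution are out of scope: the phantom
module supplies orientation fields directly, and registration is emulated by
ground-truth rigid transforms rather than estimated nonlinear warps. Whether
nonlinearity of real registrations would alter group-map topography cannot
be assessed in this setting and is simply noted as untested.

## Coordinate conventions

Streamlines are stored in world millimetres (TCK convention). Voxel
ownership is half-open — voxel *i* owns continuous indices in
[i − 0.5, i + 0.5) per axis, with centers at integer indices — and indexing
is 0-based. Binary masks are resampled by nearest neighbour (pull-back of
the target voxel center), which preserves {0, 1} semantics for label maps;
linear interpolation plus rethresholding was deliberately avoided.

## Tracking

The tracker is an arc-step probabilistic propagator over *discrete lobe
mixtures*: each voxel holds a set of (unit direction, amplitude) lobes with
antipodal symmetry, rather than a spherical-harmonic fODF. This preserves
the contract of second-order FOD integration — amplitude-weighted direction
sampling, curvature bounded per step, circular-arc geometry, amplitude
cutoff for termination — without re-implementing spherical deconvolution; it
is an approximation of that family of algorithms, not a re-implementation.
Specifics:

* step = 1.25 × voxel size (1.5625 mm at the default 1.25 mm voxels);
  maximum angle per step = 30° × step/voxel = 37.5°, independent of voxel
  size; amplitude cutoff 0.025; these are the standard parameters for deep,
  curved bundles.
* Direction sampling is exact categorical sampling proportional to amplitude
  over the lobes that pass the cutoff and lie within the curvature cone
  (antipodal sign resolved toward the incoming tangent). With a finite lobe
  set this is distribution-identical to rejection sampling and cannot
  exhaust trials; termination occurs exactly when no lobe qualifies.
* Each step advances along a circular arc of fixed arc-length whose initial
  tangent is the incoming direction and final tangent the sampled one; the
  chord is 2(step/θ)sin(θ/2) along the tangent bisector, a straight step
  when θ = 0.
* Tracking is bidirectional (two half-tracks with opposite initial signs
  sharing the seed point), the common default when seeding inside gray-matter
  ROIs where either direction may lead to the target. The per-streamline
  length budget is split evenly between the halves.
* Field lookup is nearest-voxel; lobes are not interpolated between voxels
  (interpolating discrete mixtures is ill-defined). This is a deviation from
  samplers operating on continuous spherical-harmonic fields.
* Seeds are drawn uniformly inside each seed voxel's cube; the default 10
  seeds per voxel is a desk-scale reduction of the full-scale 1000, which
  remains available through configuration.

Because seeding is bidirectional, the seed point is an interior vertex of
the emitted streamline. Bundle selection therefore treats "seeded in the
ROI" as *emanates from the seed mask* (first vertex inside it, or course
passing through it) rather than literally "first vertex inside": with
interior seeds the literal reading would misclassify roughly half of all
genuinely seeded streamlines whose distal half happens to be written first.

## Bundle selection

Selection follows seed/include/exclude semantics: an include region must be
intersected anywhere along the course (not terminated in); touching any
exclude region rejects the streamline outright, and exclusion takes
precedence over a missed include in the rejection tallies. Streamline–voxel
membership is decided on the polyline densified at half-voxel spacing so
that thin masks — in particular the one/two-slice midline slab that blocks
ipsilateral tracts from crossing over — cannot be tunnelled through between
vertices.

Per hemisphere three bundles are defined: GPi→ipsilateral PPN (excluding
GPe, the six ipsilateral nuclei — caudate, putamen, accumbens, STN, SNc,
SNr — and the midline slab), GPe→ipsilateral PPN (pallidal roles swapped),
and GPi→contralateral PPN (slab not excluded, contralateral nuclei
excluded). No GPe–contralateral bundle is defined. Whether ipsilateral
exclusion lists should additionally contain contralateral nuclei is left as
a configuration switch (off by default).

## Density maps, group maps, topography

A track-density map counts *distinct* streamlines per voxel (each
streamline contributes at most one per voxel), matching NOS-style counting;
segment-length weighting would be erased by the subsequent binarization
anyway. Two group products are built:

* **Tract MPMs**: per-subject density maps are registered to the template,
  binarized (strictly positive) and summed; the retention threshold keeps
  voxels covered in at least ceil(0.5 N) subjects, exact at even and odd N.
* **PPN connectivity clusters**: the density map is first multiplied by the
  pallidal ROI, thresholded at 25% *of the per-map maximum density* (the
  referent of the relative threshold is configurable; the maximum is the
  common choice in track-density thresholding), and registered afterwards;
  cluster MPMs are then binarize-and-sum aggregates with the same retention
  rule. The two step orders are deliberately distinct and each is tied to
  its product.

Topography is quantified as percentage overlap 100·|A∩B|/|B| between a
cluster MPM (A) and a territory MPM (B). The statistic is normalized by the
territory and is therefore asymmetric by design.

## Statistics

NOS comparisons use the two-sided Wilcoxon signed-rank test: zero
differences dropped (the common convention), midranks for ties, W = sum of
positive-difference ranks. For ≤ 12 effective pairs the two-sided p is
computed by full enumeration of the 2^n sign assignments (doubling the
smaller tail, capped at 1); 2^12 is enumerable instantly, and beyond that a
normal approximation with tie-corrected variance and a 0.5 continuity
correction is accurate to well under the decision margin. Seven paired
comparisons are run (GPi vs GPe per side, ipsi vs contra per side, left vs
right per bundle family) at uncorrected α = 0.05, matching the uncorrected
design; a Holm adjustment is available but off by default. The "standard
error" reported with per-bundle means is sample SD / √n.

## The phantom

The phantom emulates the *inputs* the analysis consumes, not diffusion
physics. On a 40×48×32 grid of 1.25 mm voxels (template world origin at the
grid center):

* **ROIs.** PPN and the exclusion nuclei are spheres; the pallidal segments
  are ellipsoids elongated anteroposteriorly (semi-axes 2.6 × 5.5 × 2.6 mm),
  mirror-symmetric about a 2-voxel midsagittal slab. Elongation matters:
  the territory terciles must be wide relative to the bundle tube for
  topography to be resolvable at this grid scale.
* **Territories.** Each pallidal ROI is split into exact rank-based
  terciles along the anteroposterior axis (ties broken by the dorsoventral
  coordinate, then lexicographic index): posterior = sensorimotor, central
  = associative, anterior = limbic. A mixed anteroposterior/dorsoventral
  ranking was rejected because a dorsoventrally-oriented entry column would
  smear across all three terciles; the overlap statistic only requires a
  disjoint partition, and the anteroposterior ordering preserves the
  anatomical labels' sense.
* **Bundles.** Six true bundles (cubic splines through 5 control points)
  run from each pallidal segment through a peduncle-like waypoint down to
  the PPN; contralateral bundles cross the midline at a decussation-like
  point. Entry into the pallidum is dorsoventral at the ROI's central
  anteroposterior level, i.e. endpoints are planted in the associative
  tercile. Distractor bundles (pallidum → caudate / putamen) terminate in
  exclusion nuclei and must never survive selection.
* **Counts and effects.** Realized per-bundle ground-truth counts are
  Poisson draws around n_true × multiplier, with base n_true = 200 for true
  bundles (100 for distractors) and multipliers composing: GPi/GPe ratio
  2.0, right/left ratio 1.25, contralateral factors 1.25 (left) and 0.85
  (right). These defaults reproduce the qualitative ordering of the real
  cohort: GPi > GPe everywhere, rightward lateralization of ipsilateral
  tracts, left-contra > left-ipsi but right-contra < right-ipsi. Poisson
  noise emulates between-subject NOS variability (means are reported with
  standard errors); overdispersion is deliberately not modeled.
* **Orientation field.** Every voxel within a bundle's tube holds one lobe
  per overlapping bundle: the tangent of the nearest centerline point, with
  amplitude uniform in [0.3, 1.0]; overlap voxels are genuine crossing-fiber
  configurations. Background voxels are isotropic at amplitude 0.01, below
  the 0.025 cutoff, so tracking terminates there. Tube radius is 1.5 voxels
  × √multiplier: since the expected tracked count scales with the tube
  cross-section covered by seed voxels, the *tracked* NOS inherit the same
  effect ordering as the ground-truth Poisson counts. (The tracker seeds
  per ROI voxel and cannot observe the ground-truth counts directly; scaling
  the tube cross-section is what transports the effect into tracking.)
* **Subject variability.** A rigid jitter (translation ≤ 2 mm per axis,
  rotation ≤ 3° about a random axis through the grid center) maps the whole
  template scene into subject space; its exact inverse is stored as the
  subject→template transform. Anatomy variation and registration error are
  thus collapsed into one rigid perturbation plus Poisson count noise —
  richer noise models (local deformation, per-bundle shape variation) are
  left open. A jitter large enough to push an ROI off the grid raises an
  error instructing a smaller bound.
* **Reproducibility.** Everything derives from (master seed, subject id)
  through named seed sequences; cohorts are bit-reproducible.

What passing tests on the phantom do *not* show: robustness to fODF
estimation error, partial-volume and crossing-fiber ambiguity beyond the
synthetic two-lobe case, nonlinear registration error, or realistic
anatomical variability. The phantom validates the pipeline's logic and
calibration, not tractography's fidelity to tissue.

## Numerical and design choices

* Relative density threshold referent: fraction of the per-map maximum
  (configurable); binarization of registered density maps uses strictly
  positive values.
* MPM retention: count ≥ ceil(fraction × N).
* "At desk scale": the default cohort is 20 subjects at 10 seeds/voxel
  (the full-scale design — 100 subjects, 1000 seeds/voxel — is reachable by
  configuration); a full default run takes on the order of a minute on one
  CPU.
* Degenerate inputs: empty tractograms yield zero density maps and empty
  clusters; an all-zero density map thresholds to an empty mask; percentage
  overlap against an empty reference raises (undefined); a signed-rank test
  with all-zero differences raises (undefined).
* Writers are deterministic (no timestamps); identical inputs give
  byte-identical TCK/NIfTI/CSV outputs.

## Known limitations

* Discrete lobe fields cannot express within-voxel orientation dispersion;
  tracked streamline attrition along a corridor therefore depends mainly on
  tube curvature and width, and tracked NOS are systematically lower than
  ground-truth counts (selection-stage recovery of *ground-truth* bundles
  is ≥ 99%, by contrast).
* Rigid-only inter-subject geometry; no anisotropic reorientation of
  orientation fields is implemented (transforms rotate bundle centerlines
  before field construction instead).
* Streamline-count measures inherit all the usual caveats of NOS as a
  connectivity proxy; the package reproduces the measure, it does not
  endorse it.
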