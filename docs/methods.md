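# Methods

## Measurement model

The package simulates an MR texture acquisition that samples the magnitude of
single points of k-space over a selected tissue volume, rather than
reconstructing an image. The simulated observable for a prism of tissue is
the magnitude of the 1D discrete Fourier transform of its cross-section-
averaged occupancy signal. Assumptions baked into this model:

- **Magnitude only, phases discarded.** Each k-value is acquired in a single
  excitation, so magnitudes from different prisms and excitations can be
  averaged without phase coherence. The pipeline therefore averages
  *magnitude* spectra across prisms; per-prism phase never enters. A
  corollary (asserted as a property test): rigid translation of the
  structure leaves every simulated measurement unchanged.
- **No sequence physics.** Relaxation, noise, crusher gradients, excitation
  profiles and acquisition timing are out of scope; the simulation maps
  binary microstructure directly to ideal spectral magnitudes.
- **Binary tissue.** Bone/marrow is a two-phase medium; grayscale volumes
  are thresholded first (see below).

DFT convention: magnitudes are normalised by the sample count N, one-sided,
DC excluded; harmonic n corresponds to spatial frequency n/(N·d) mm⁻¹ for
sample spacing d. Under this convention a pure cosine of amplitude A with an
integer period count puts A/2 at its harmonic, and Parseval's identity holds
exactly against the mean-removed signal (tested to 1e-10 relative). No
windowing or detrending is applied: DC exclusion plus the band placement
already make the ratio metric offset- and scale-invariant.

## Band bookkeeping

Bands are fixed physical windows: low [1.0, 1.8] mm⁻¹ (trabecular-spacing
scale), high [3.8, 7.4] mm⁻¹ (trabecular-thickness scale), narrow-high
[3.8, 5.6] mm⁻¹. Membership is resolved in the harmonic-index space of the
*nominal* analysis length L: a band [lo, hi] selects harmonics
round(lo·L)..round(hi·L). This is deliberate: on the realised grid of a
near-nominal window (e.g. a 5 mm window that is 555 voxels of 9 µm), a
literal inclusive frequency comparison can drop an edge point, whereas
index-space resolution keeps the counts stable at 5 / 19 / 10 points for
L = 5 mm. The band mean is the arithmetic mean of magnitudes at those
harmonics, taken on the prism-averaged spectrum (a per-prism-then-average
variant is exposed but not the default). One caveat, discovered and pinned
by test: at analysis lengths far from nominal the rounded edge can admit a
frequency slightly outside the physical band, so sweep comparisons across
lengths should use lengths where the rounded edges stay interior.

## Preprocessing operators

- **Thresholding**: per-slice 2D Otsu. For each slice the joint histogram
  of (intensity, 3×3 local mean) — 64 bins per axis — is scanned for the
  threshold pair maximising the trace of the between-class scatter of the
  two diagonal quadrants; the final assignment is by the intensity
  threshold alone. The local-mean axis makes the threshold choice robust to
  pixel noise without letting isolated bright/dark pixels leak across phase
  boundaries. Constant slices fall back to a volume-wide 1D Otsu split;
  `bright_is_bone=False` inverts contrast symmetrically.
- **Despeckle**: connected foreground components smaller than
  `min_component_vox` (default 125 voxels) are removed, then undersized
  background components are filled; 26-neighbourhood for bone,
  6-neighbourhood for void (the standard complementary pair). The operation
  is idempotent. The 125-voxel default corresponds to a (5-voxel)³ blob —
  a sub-resolution fragment at micro-CT scale; it is a config knob, since
  no canonical value exists.
- **Erosion**: binary erosion with a centred cubic structuring element of
  side 2r+1 (r = 0 is the identity), equivalent to r iterations of the 3³
  cube and to a Chebyshev-distance criterion (brute-force-verified in
  tests). The odd, centred kernel is chosen over an even uncentred one as
  the standard symmetric reading of "remove r voxel layers from every free
  surface". Voxels beyond the array border count as bone, so only real
  bone/void interfaces erode — a 5-voxel slab at r = 2 leaves exactly a
  1-voxel slab. Disease simulation runs threshold → despeckle → erode →
  despeckle; the trailing pass removes fragments created when thin
  trabeculae split.

## Histomorphometry

Local thickness is the largest-inscribed-sphere definition: the value at a
voxel is the diameter of the largest sphere lying entirely in the phase and
containing the voxel. Implementation: Euclidean distance transform, then for
each integer radius r (largest first) the voxels covered by spheres of
radius r centred where the EDT exceeds r receive diameter 2r+1; exact up to
the integer-radius discretisation (one voxel), verified against an O(n²)
all-spheres oracle. The array border is treated as phase continuation
("extension" semantics), matching the infinite-slab idealisation; the plate
phantom is therefore phased so the volume boundary cuts a plate through its
centre voxel, making border structures read their infinite-pattern value.

Tb.Th (Tb.Sp) is the mean foreground (background) local thickness over the
phase's voxels; BV/TV is the foreground fraction; Tb.N defaults to the
plate-model convention BV/TV / Tb.Th, switchable to 1/(Tb.Th + Tb.Sp).
Commercial histomorphometry tools implement proprietary variants of these
definitions, so agreement is expected at the index level, not per-sample
equality.

## Synthetic microstructure

Real vertebral micro-CT is the intended input, but the pipeline is validated
on a generator: white noise smoothed with a per-axis Gaussian kernel
(σ = correlation length / voxel size, in voxels) and thresholded at the
empirical quantile that yields exactly the target bone volume fraction.
Defaults: BV/TV 0.16, correlation length 0.08 mm, voxel 0.02 mm. The
correlation length was set by measuring Tb.Th on generated volumes
(0.08 mm → Tb.Th ≈ 0.17 mm, inside the 0.10–0.20 mm window of healthy human
vertebrae; Tb.Sp ≈ 0.44 mm, at the low end of the reported range). The
0.02 mm voxel keeps a (5 mm)³ VOI at 250³ voxels so full studies run in
minutes; all geometry is physical, so results are robust to the voxel size.
Anisotropy is available through unequal per-axis correlation lengths and
produces strongly direction-dependent metrics (tested).

**Cohorts.** Study cohorts draw per-volume BV/TV ~ N(0.16, 0.02) (clipped to
[0.10, 0.22]) and correlation length ~ N(0.08, 0.01) mm, emulating the
regional heterogeneity of real trabecular bone, whose BV/TV spans several
percentage points between vertebrae and regions. The osteoporotic-like
operating point shifts to BV/TV ~ N(0.105, 0.01) and 0.55× the correlation
length (halved trabecular thickness at two-thirds the bone fraction — the
published signature of osteoporotic vertebrae) and is generated
independently, *not* by eroding healthy volumes.

**What the generator does not emulate.** Gaussian excursion sets are
blob-like, not a connected plate-and-rod network; they have no cortical
shell, no marrow-phase signal, no preferential resorption of unloaded
trabeculae (disease is uniform erosion), and no imaging noise or partial-
volume blur. Passing tests therefore demonstrate that the *pipeline*
responds to thickness/spacing changes as designed — not that real
osteoporotic bone will separate with the same margins. One consequence
observed consistently: on this microstructure erosion shifts the ratio
metric *down*, whereas on real bone images it shifts up. The classifier is
direction-agnostic (the fitted boundary records which side is diseased), so
all classification results are unaffected; the direction is pinned in a
regression test rather than asserted as a universal.

## Classification

The ratio metric is the sole feature, so the linear max-margin classifier
reduces to a threshold. `fit_boundary` z-scores the feature on the training
data, fits a hinge-loss SVM at unit regularisation (C = 1), and maps the
threshold back to metric units; standardisation makes the objective
scale-free (without it, a feature whose spread is far below the unit margin
scale collapses to a degenerate w ≈ 0 fit). For separable data this yields
the midpoint of the inner class extremes; the non-separable optimum is
cross-checked against an independent multi-start optimiser in tests. Ties at
the threshold go to the healthy side — conservative, since deliberately
biasing toward fewer false negatives is an explicit, separate move (the
monotone sensitivity/specificity trade-off of shifting the boundary is
tested).

Evaluation: stratified k-fold (default 5) cross-validation, re-partitioned
and repeated (default 50×); per repeat, held-out predictions are pooled
across folds before computing sensitivity (diseased correctly flagged) and
specificity (healthy correctly cleared); a per-fold-averaged variant is
switchable. Reported ± is the sample standard deviation over repeats. All
partitioning derives from one seed; identical seeds give identical reports.
Stratification is used because with ~6 per class per fold an unstratified
split can leave a fold single-class.

The cross-section sweep recomputes the metric from the first m prisms
(row-major grid order from the VOI corner, m = 1..25, i.e. 1–25 mm² of
acquired cross-section) and re-runs the CV per m. Metrics that are undefined
for a prism subset (zero band mean, e.g. an all-void prism on heavily eroded
bone) are excluded with a logged count.

## Replication study (`trabspec.study`)

`run_replication_study(seed)` executes the whole design: 30 healthy cohort
volumes; mild (r = 1 voxel ≈ 20 µm) and strong (r = 2 ≈ 40 µm) erosion —
the same physical severities as 2-/4-voxel erosion of 9 µm data; Mann-
Whitney location-shift tests; CV reports for both severities; the
cross-section sweep (m = 1, 3, 5, 10, 25) and narrow-band variant; a
13-volume osteoporotic-like cohort classified by the boundary trained on
baseline + strongly eroded volumes; Tb.N and BV/TV versus erosion radius
(10 volumes at 96³); and histomorphometry of one cohort member (on a 160³
central crop — the background local-thickness pass is the one expensive
step). These problem sizes keep a full run near three minutes on one core
while providing ≥ 30 VOIs per condition for the distribution tests.

Typical behaviour at these conditions: baseline and strongly eroded metric
distributions separate at p < 1e-8 with CV sensitivity/specificity around
0.85–0.97 depending on the cohort draw; mild erosion is consistently and
strictly harder; the narrow high band costs ≲ 0.04 accuracy; accuracy
degrades sharply at 1 mm² of acquired cross-section and the
accuracy-versus-area curve flattens by ~5 mm², though on this synthetic
microstructure a small residual gain above 5 mm² remains (cohort prisms are
more independent than prisms of real, spatially correlated bone); Tb.N and
BV/TV fall monotonically with erosion radius.

## Numerical and interface choices

- Geometry in mm, frequencies in mm⁻¹, voxel conversions by rounding
  (edge_vox = round(edge_mm / voxel_size)); VOI tiling is greedy from the
  mask bounding-box minimum corner, and a VOI is kept only if entirely
  inside the mask. Delineating the usable trabecular interior (excluding
  cortical shell) is the caller's responsibility: masks are explicit
  inputs, never inferred.
- I/O: TIFF slice-stack directories (lexicographic order, axis0 = slice),
  single multi-page TIFF, and NIfTI; voxel size from metadata with an
  explicit override; CSV records at full float precision. Axis names are
  user labels only — no anatomical orientation inference.
- Bands may optionally be re-derived from measured Tb.Sp/Tb.Th as
  (1 ± 0.3)/mean — a rough heuristic, off by default; the fixed default
  bands are the reference configuration.
- Degenerate inputs fail loudly: constant images (thresholding), empty
  phases (histomorphometry), all-bone VOIs (undefined metric), single-class
  or too-small classes (classifier).

## Known limitations

- The Gaussian-field generator's realism limits are listed above; margins
  measured here should not be read as clinical performance.
- The erosion disease model is spatially uniform; real resorption is
  preferential. Non-uniform erosion is an extension hook, not implemented.
- Local thickness at cut structures on the volume boundary inherits the
  extension assumption; structures lacking an in-volume centre voxel can
  read up to two voxels thin.
- The 2D Otsu variant assigns by intensity only; a full quadrant-based
  assignment would differ on heavy-tailed noise.
- NRRD input, DICOM, registration and visualisation are out of scope.
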