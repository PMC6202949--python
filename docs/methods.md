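# Methods

This note documents the models, conventions and numerical choices behind
`epival`: what the synthetic data emulate, how each pipeline stage
works, which parameters matter, and where the design was genuinely open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate conventions

The room frame is IEC-style with origin at the isocenter: x lateral
(+ patient left, head-first supine), y longitudinal (+ superior),
z vertical (+ anterior).  The gantry rotates about y; at gantry 0 the
source is at (0, 0, +SAD) and increases clockwise viewed from the foot
of the couch.  Couch and collimator angles are fixed at 0.  Portal-image
coordinates (u, v) are in mm **at isocenter scale**: the pin-hole
projection onto the detector is divided by the magnification SDD/SAD, so
any point in the isocenter plane perpendicular to the beam maps to its
in-plane coordinates exactly, and all reported errors live on the same
mm scale as prostate motion.  SAD = 1000 mm and SDD = 1600 mm are
configuration parameters; with the 41 cm / 1024 px panel they give the
0.25 mm isocenter-scale pixel.  Pixels use 0-based indices addressing
pixel centers; the image center ((N−1)/2, (N−1)/2) is the beam axis
before flex; +u is +columns, +v is −rows.

The monitor's translation estimates are treated as room-frame
displacements of the monitored volume's center of mass, including couch
shifts (the trace is referenced to the position at CBCT time); rotation
estimates are carried through the logs but deliberately ignored in the
comparison, which is between marker centers of mass.

## Synthetic sessions: what they emulate

One session = one treatment fraction, written as plain-text logs plus
one 16-bit TIFF per field.  The generator's defaults are the study
conditions; per-component seeds fan out from a single seed through
`numpy` `SeedSequence` spawn keys, so identical configurations produce
byte-identical sessions.

* **Prostate motion** is a 3D random walk: each translation component
  accumulates independent Gaussian steps of SD `walk_step_sd · √dt`
  (default 0.3 mm/√s on a 0.1 s grid), so positional variance grows
  linearly with time.  This reproduces the stochastic drift character of
  intrafraction prostate motion and makes multi-millimeter excursions
  possible within a fraction; it does not model rectal-gas transients,
  periodic components, or couch-correction feedback.
* **Monitoring** resamples the true motion at 3 Hz and adds i.i.d.
  Gaussian estimation noise per axis (`us_noise_sd`, default 0.3 mm,
  inside the in vitro 0.2–0.7 mm range reported for such systems).  The
  vendor's confidence formula is proprietary, so confidence is a
  declared surrogate: C = clip(baseline − slope·|displacement| +
  jitter, 0, 1) with baseline 0.9, slope 0.005/mm, jitter SD 0.05.  The
  slope is mild because the reported displacement includes the 8–15 mm
  couch correction and normal fractions should sit near the clinically
  typical C ≈ 0.85–0.9; only the threshold behavior matters downstream
  — a `poor_probe` fraction draws C uniformly in [0.05, 0.45] and must
  trip the persistent-low-confidence exclusion.
* **Session timeline** (linac clock): t = 0 is the CBCT reference where
  the initial marker positions are recorded (including a setup error of
  8–15 mm in a random direction); monitoring starts at 5 s; the couch
  corrects the setup error at 30 s as a constant-speed ramp of 1 s
  (8–15 mm/s, the speed class of auto-correction couch drives — the
  sync precision depends directly on this speed, see below); fields
  follow at 45 s spacing, each with two 8 s segments.  The monitor log's
  clock runs ahead of the linac clock by `clock_offset_s` (drawn in
  ±120 s when unset; constant within a fraction — clock drift is out of
  scope).
* **Portal frames**: in-aperture intensity 3000, out-of-field 500,
  markers as negative Gaussian blobs of FWHM 1.5 mm (iso scale) and
  depth 1500, aperture = beveled 40×40 mm MLC polygon rasterized with
  4× supersampling (anti-aliased edges carry sub-pixel information for
  the flex match), rigid panel flex drawn uniformly in ±1.8 mm per axis
  per field, additive Gaussian detector noise (SD 30).  The three
  1×3 mm marker cylinders are treated as points at their centroids;
  extent enters only through the blob width, because the analysis
  compares centers of mass.  No scatter, energy response, or
  leaf-by-leaf transmission is modeled.
* **Guide-vs-CBCT mismatch**: `reference_time_offset_s` offsets the
  monitoring reference from the CBCT time, reproducing the error source
  where motion during the CBCT acquisition is invisible to the monitor.
  Default 0.

Because the generator and analyzer share the gantry/axis conventions,
those conventions cancel in E; passing tests therefore validate the
pipeline's internal consistency and noise response, not any one
vendor's axis labels.  Equally, the synthetic conditions are cleaner
than patient data (no deformation, no CBCT localization uncertainty, no
observer bias), so absolute error magnitudes here are a floor, not a
reproduction of the clinical values.

## Localization chain

* **LoG enhancement**: the stated 3.5 mm kernel with SD 1.0 mm is read
  as truncation extent 3.5 mm / Gaussian SD 1.0 mm (the only
  self-consistent reading), both converted to pixels via the
  isocenter-scale pixel size.  The discrete kernel is the sampled
  analytic LoG with its truncation-induced mean subtracted, so constant
  regions map exactly to zero (scipy's `gaussian_laplace` at this
  truncation has a −3% DC response, which would offset the whole
  field).  Markers are rendered dark, so they appear as positive LoG
  extrema.
* **Detection** searches only the aperture interior eroded by 5 mm (iso
  scale) so field-edge responses cannot win; candidates must clear a
  robust threshold (6 × 1.4826·MAD of the in-region response) and be
  ≥ 2 mm apart; each peak is refined by an intensity-weighted centroid
  in a 7×7 px window.  Fewer than two detections is the single-marker
  exclusion.
* **Observers** are detection replicates with independent Gaussian
  perturbations (SD 0.3 mm per axis) — enough structure to exercise the
  interobserver rule (> 1.5 mm disagreement drops the marker; fewer
  than two survivors drops the image).  Forced-outlier fields (one
  replicate offset by 2.5 mm) reproduce image-level exclusions at
  configured positions in a study.
* **Obscured-marker inference** applies only when a marker was never
  detected (MLC/bony occlusion), not when observers dropped it: the
  missing marker's offset from the visible pair's center of mass in the
  projected CBCT constellation is added to the imaged pair's center of
  mass.  Exact under pure translation in the unit-magnification plane;
  rotations of the constellation leak in proportionally to the offset
  times the rotation angle.
* **Flex** is estimated by normalized cross-correlation between the
  planned aperture template and the softly thresholded image (midpoint
  of the in/out-field intensity modes, with a ±15% soft ramp that keeps
  edge coverage sub-pixel informative), over shifts within ±5 mm, with
  3-point parabolic refinement per axis; a peak below 0.5 flags the
  estimate unreliable and the field proceeds uncorrected.  Whether the
  original procedure shifted the image or the localizations is
  immaterial for a rigid shift; localizations are corrected here (flex
  × SAD/SDD converts panel-scale shift to isocenter scale).

## Clock synchronization

The couch correction appears in both logs.  Detection in the monitor
trace uses a sustained level-shift statistic (3-sample means on either
side of each inter-sample boundary, norm > 2 × the configured 1 mm
jump threshold) rather than raw consecutive-sample jumps: at 0.3 mm
estimation noise, raw per-axis differences have SD ≈ 0.46 mm and
produce ~8% false flags, whereas level shifts separate a couch move
from reverting noise spikes cleanly.  The flagged activity is
rasterized at the 0.1 s resolution, cross-correlated against the linac
couch intervals, and the lag of the maximum gives the coarse offset
(robust to multiple moves).  Because a ~3 Hz trace cannot place a step
below its 0.33 s sampling grid from the argmax alone, the coarse lag is
refined by fitting the known constant-speed ramp (magnitude and
duration from the linac log) plus a local linear baseline to the
monitored displacement projected on the couch direction, scanning the
ramp timing on a 0.01 s grid.  The achievable precision scales with
couch speed: at the default 8–15 mm/s, recovery is within ±0.1 s; a
several-times slower couch would carry proportionally less timing
information, which is the quantitative form of the "indirect
synchronization" uncertainty the clinical workflow could not measure.

Motion lookup at a field time is hold-last-sample (zero-order hold,
right-continuous), matching clinical display behavior; a gap over 2 s
is a stale estimate and excludes the field as a sync failure.

## Exclusions and aggregation

Every field ends in exactly one state: included, `interobserver`,
`single_marker`, `low_confidence`, or `sync_failure`.  "Consistently
below C < 0.5" is operationalized as > 90% of beam-on samples below
threshold (the clinical rule is fraction-level but unquantified).
Per-fraction E_f averages the included fields' |E| (the 2D magnitude;
whether the original aggregated magnitudes or per-axis errors is
unstated — magnitude is the conservative choice and is documented in
the output schema).  C_f averages confidence over the whole trace.
Marker-group, image-quality and feature-count labels on fractions are
pass-through simulation metadata; the human observer study they came
from is out of scope.

## Statistics

Nonparametric limits of agreement use empirical quantiles with linear
interpolation between order statistics: equal-tailed two-sided
intervals for signed per-axis errors, one-sided upper limits for
non-negative magnitudes; levels 25/50/75/95 are nested by construction
and validated as such.  The KS normality test estimates mean and SD
from the sample, so its p-value comes from a seeded Monte-Carlo
(Lilliefors) null of 10⁴ replicates, cached per sample size; a plain-KS
flag is not offered because fitted parameters always invalidate the
plain null here.  Kruskal–Wallis uses the tie-corrected H with a χ²
(k−1) p-value; R² is ordinary least squares.  No multiple-testing
correction is applied across the exploratory group comparisons.

## Problem sizes

Study-scale computations (the 80-fraction exclusion study, noise
sweeps, the phantom protocol) render frames on a 256×256 grid at the
native 0.4004 mm/px pitch — a central panel crop that comfortably
contains the 40 mm aperture plus motion — keeping a full study run in
the minutes range; single sessions default to the full 1024×1024 panel.
The exclusion study uses 56 five-field + 24 three-field fractions
(352 first-segment images), 17 forced interobserver outlier fields and
one poor-probe five-field fraction, matching the clinical cohort's
bookkeeping.

## Known limitations

* The confidence surrogate shares only the threshold phenomenology of
  the real score; relationships between C and image content are not
  modeled, so the no-relationship null results here are built in rather
  than discovered.
* Marker identity matching (nearest-assignment to the predicted
  constellation) can mislabel under motion comparable to the ~8 mm
  inter-marker projected spacing; at the simulated motion scale this is
  not reached.
* Occasional genuine interobserver drops occur by chance at the default
  replicate noise (the per-marker disagreement tail crosses 1.5 mm with
  probability ≈ 0.5%), mirroring the clinical exclusion mechanism;
  forced outliers are additive to this background.
* The walk's variance growth is unbounded; sessions are short enough
  (minutes) that the prostate stays inside the aperture margin in all
  default configurations.
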