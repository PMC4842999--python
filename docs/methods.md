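# Methods

`nanopsd` quantifies the nanoscale organisation of PSD95 — the major
postsynaptic scaffold protein — in two orthogonal super-resolution
modalities: gated-STED-like pixel images (confocal channel ~240 nm lateral
resolution, STED channel ~85 nm, 20 nm pixels) and PALM-like single-molecule
localisation tables (~40 nm localisation precision).  The pipeline detects
postsynaptic densities (PSDs) and the PSD95 nanoclusters (NCs) inside them,
measures their morphometry, classifies synapses by their NC count
(1NC / 2NC / 3+NC), and aggregates the measurements into cohort statistics.
Because no raw brain images are distributed with the package, a synthetic
scene generator supplies ground-truth fields with the statistical structure
the analysis assumes; it doubles as the Monte-Carlo robustness harness for
the segmentation parameters.

## Scene model

A scene is a rectangle (nm coordinates, origin at the top-left corner,
x rightward, y downward).  The PSD count is Poisson with mean
`psd_density x area / 20 um^2` (default 19.2 per 20 um², the measured
density 20 um from the CA1 soma layer).  Each PSD draws its NC count from a
subtype mixture; the default (63.7 / 24.3 / 9.0 / 2.9 % for 1-4 NCs) matches
the CA1 stratum oriens population, with the open "3+" class split between 3
and 4 NCs as a decaying tail.  NC centres within a PSD are placed by
sequential rejection sampling so that **every** pairwise separation lies in
the spacing interval (default 100–300 nm, the reported inter-NC distance
range); an unsatisfiable request fails loudly naming the PSD.  NC short/long
axes are log-normal with configurable log-scale spread (default 0.25) around
medians of 86 × 189 nm, so the configured medians are preserved exactly;
orientations are uniform.  Each NC carries a Poisson molecule count
(default mean 150) that sets both its rendered brightness and its expected
localisation yield.

Draws are made with `numpy.random.default_rng(seed)`; identical
(config, seed) pairs reproduce scenes, images and localisation tables
byte-for-byte.  PSDs are kept at least `edge_margin_nm` (default 600 nm,
more than 3 PSF sigma) from the field border so the noiseless rendering
conserves total intensity to 1e-6.

## Rendering

* **Pixel images.**  Each NC is a uniform-intensity filled ellipse (a
  Gaussian profile is config-selectable) whose integrated intensity equals
  its molecule count, painted at 4x supersampling, convolved with an
  isotropic Gaussian PSF parameterised by its FWHM (FWHM = 2√(2 ln 2)·σ),
  then block-summed onto the pixel grid.  `psf_fwhm = 0` renders the exact
  ellipse masks — the configuration used for PSF-free morphometry checks.
  Optional noise: Poisson shot noise at a configurable gain and additive
  Gaussian read noise (both off by default; recovery analyses are run
  noiseless so they isolate the segmentation operator itself).
* **Localisation tables.**  Per NC, Poisson(events) positions are drawn
  uniformly inside the ellipse and displaced by isotropic Gaussian error
  with σ = precision / 2.355 (precision is quoted as a FWHM-like width).
  Uniform false localisations are added at `background_rate` per um²
  (default 0.1).  Every event records its true parent NC for recovery
  scoring.
* **Two-channel fields.**  For juxtaposition analysis, channel B receives a
  punctum at an exact-fraction subset of channel-A centres plus a
  fixed-length offset in a random direction, and sparse unpaired puncta
  elsewhere.  The paired subset has a deterministic size (round(f·n)) so the
  realised pairing fraction carries no extra binomial noise.

## Segmentation

Both modalities share one engine: Gaussian prefilter (0.04 um), local
background subtraction, thresholding, 8-connected labelling, seeded
watershed splitting, minimum-size filtering (30 px for PSDs, 10 px for NCs)
and border exclusion.

* **Background subtraction.**  The commercial tool's "background subtraction
  with a diameter" is not publicly specified; here the local background is a
  Gaussian low-pass with σ = diameter / 2.355 and the clipped difference is
  kept.  This removes structure above the stated scale and is analytically
  testable.
* **Threshold.**  The original analysis used an interactive threshold.  The
  default here is 10% of the robust image maximum (99.9th percentile of the
  background-subtracted image), exposed in config; an absolute threshold can
  be set instead.
* **Watershed seeds.**  Seeds are local maxima of a copy smoothed to a
  *total* Gaussian level of one quarter of the seed-point diameter (any
  smoothing already applied, e.g. the prefilter, is discounted in
  quadrature rather than stacked), with maxima closer than **half** the
  seed-point diameter merged to the brighter one.  The half-diameter rule is
  deliberate: with a full-diameter exclusion a 160 nm seed setting cannot
  split NCs 150 nm apart even when the image shows two clear peaks, and on
  synthetic fields the NC-count confusion-matrix diagonal collapses below
  30% at 150 nm separations while the 1NC fraction inflates by ~9 points.
  With the half-diameter rule the diagonal exceeds 90% for separations above
  ~155 nm and field-level subtype fractions are recovered within ~1 point.
* **Morphometry support.**  A 10% global threshold admits a skirt of
  partial-coverage pixels around every object, inflating circle-equivalent
  diameters by 10–15%.  Object statistics (area, equivalent diameter,
  ellipse axes, centroid) are therefore measured on the fragment's
  *half-maximum support* — pixels at or above 50% of the fragment's own peak
  — which is the 2D analogue of FWHM sizing and is unbiased on uniform
  ellipses.  The full watershed partition is retained for assignment and
  for the partition invariant (fragments tile their component exactly).
  `support_fraction=None` restores full-fragment measurement.
* **Intensity statistics** are computed on the original (pre-subtraction)
  channel, since cross-region intensity comparisons would otherwise be
  distorted by the high-pass.
* **Assignment.**  Each NC joins the PSD whose mask contains its centroid
  (fallback: largest mask overlap, ties to the lower PSD label).  PSDs with
  no NC are excluded and their fraction reported; orphan NCs are counted.

The STED workflow segments PSDs on the confocal channel (seed 0.4 um) and
NCs on the STED channel (seed 0.16 um), both with 0.14 um background
subtraction.

## PALM pipeline

Raw frames can be localised by least-squares 2D Gaussian fitting (free
amplitude, position, σ, offset; precision from the fit covariance), but the
standard entry point is a localisation table.  PSD-scale clusters are
defined by DBSCAN in nm space; ε = 100 nm (≈ 2.5× the localisation
precision) and min_points = 10 are package defaults, echoed into output
metadata, since the source protocol does not print them.  Clustered events
are rendered as 40 nm discs (the average fitting precision) whose amplitude
is a nearest-neighbour density weight: the inverse mean distance to the
k = 5 nearest within-cluster neighbours, median-normalised per cluster
(global normalisation is available; singletons weight 1; noise events are
not rendered).

The PSD channel is this NN image blurred by a large 0.25 um Gaussian kernel.
The kernel width is read as a FWHM (σ ≈ 106 nm): the blur must fuse the NCs
of one PSD (≤ 300 nm apart) into a single blob *without* fusing neighbouring
PSDs ~0.5 um apart, and a σ = 250 nm reading demonstrably merges 40% of
neighbouring PSDs on synthetic fields at the measured density.  The NC
channel is the NN image smoothed at 0.04 um with 0.07 um background
subtraction; because that high-pass retains only a residual of the NC
envelope, the half-maximum support is measured on the smoothed
pre-subtraction channel.  Seed diameters are 0.25 / 0.07 um.  An optional
watershed-dynamics merge step (`merge_saddle_fraction`) can collapse
fragments separated by shallow valleys; it is off by default.

## Spatial statistics

The pair-correlation function g(r) is estimated on 10 nm annuli out to 1 um
with translation edge correction, normalised by n(n−1)/|W|².  A binned
(not kernel-smoothed) estimator was chosen because the Monte-Carlo envelope
logic takes pointwise extrema per radius, and because it admits an exact
O(n²) brute-force oracle (the package ships one; the two agree to machine
precision).  Envelopes are the per-radius min/max over 49 simulations of
exactly n uniform points in the same window (a binomial process,
conditioning on the observed count); g above the upper envelope flags
significant clustering at that radius, a pointwise ~1/50 test.  Both the
peak radius and the span of significant radii are reported, since "maximal
g(r) range" can denote either.

Juxtaposition follows the object-based rule: an A-punctum is juxtaposed when
a B centre lies within 600 nm (centre to centre).  The chance level is
estimated by rotating channel B 90° clockwise (image convention, y down)
about the field centre, clipping rotated coordinates back into the window,
and repeating the measurement.

## Cohort statistics

The statistical unit is the mouse: per-structure measures reduce to one
median per mouse and groups are summarised as the mean ± SD of those medians
(a single-mouse summary reports SD 0 and a flag).  Subtype fractions are
computed per mouse then averaged, so their SD is an across-mice spread.
Group comparisons use one-way ANOVA with post-hoc Tukey HSD on the per-mouse
values (per-structure ANOVA is available but not the default).
Distance-from-soma gradients bin structures in seven 20 um steps over
20–140 um and correlate per-image means against bin distance (Pearson);
per-bin means are available behind a flag, and the observation level used is
recorded in the result.  The subtype-weighted consistency check — the
fraction-weighted mean of per-subtype diameters, rounded to the nearest nm —
ties the per-subtype measurements to the whole-population median.

## Problem sizes and numerical choices

Recovery analyses in the test suite and acceptance script use 10 × 10 um
fields (≈ 96 PSDs each): 22 fields (≈ 2100 PSDs) for subtype-fraction
recovery, 4 fields for diameter recovery per modality, 20 fields for
juxtaposition, and 100 random instances (≤ 500 points) for the DBSCAN
oracle comparison — sizes chosen so each suite completes in minutes while
keeping Monte-Carlo error well inside the tolerances tested.  Peak fits
iterate to 1e-10 relative tolerance with at most 1000 function evaluations;
profile FWHM fits flag r² < 0.5 as invalid; degenerate (collinear) masks
floor the short ellipse axis at one pixel; ellipse moments add the 1/12
uniform-pixel variance before eigendecomposition.

## What the simulator does and does not emulate

The generator reproduces the densities, subtype mixtures, NC geometry,
spacing statistics, PSF widths, localisation precision and background rates
reported for hippocampal tissue, so passing recovery tests shows the
pipeline is unbiased *under the stated generative model*.  It does not
emulate tissue autofluorescence, labelling stoichiometry or maturation
gradients, fluorophore blinking kinetics (no duplicate-emitter merging is
performed), depth-dependent aberrations, or 3D structure (scenes are 2D, as
in the source analyses).  Conclusions about real tissue therefore rest on
the published validation against manual quantification, not on these tests.

## Known limitations

* NC pairs closer than ~150 nm are usually merged at STED resolution — an
  intrinsic resolution limit also present in the original analysis, which
  the subtype-mixture recovery partially compensates because PSD-level
  fusion biases the opposite way.
* The PALM NC diameter runs ~5–7% high at default settings (disc rendering
  plus 40 nm smoothing broadens the half-max support); this is within the
  tolerance the recovery tests assert but is a known systematic.
* DBSCAN border points may legally attach to different adjacent clusters
  than a reference implementation; equivalence is asserted on core points
  and the noise set.
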