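# Methods

## Measurement model

The analysis operates on aligned 2D intensity grids: a nucleus channel
(DAPI), a mitochondrial-marker channel (Tom70) and a potential-reporter
channel (MitoTracker CMX ROS), with a known pixel size in µm. All
quantities are computed per cell; the cell is the unit of analysis for
group statistics, matching the usual ≥35-cells-per-condition design of this
assay.

Three readouts are defined over the mitochondrial compartment restricted to
a region (whole cell or ring):

* `ratio_potential_marker` = Σ potential / Σ marker (potential per unit
  mitochondrial mass — the Δψ_m proxy);
* `potential_per_area` = Σ potential / mitochondrial area (a.u./µm²);
* `marker_per_area` = Σ marker / mitochondrial area (a.u./µm²).

Ratios aggregate as ratios of sums rather than means of pixelwise ratios:
dim pixels then contribute proportionally to their signal instead of adding
high-variance quotients. A `ratio_mode="pixel_mean"` option provides the
pixelwise alternative for sensitivity checks. Empty intersections yield an
invalid record (NaN ratios), never zeros, and excluded cells are counted in
the QC report so that analyzed + excluded = segmented.

## Preprocessing and segmentation

Background is a per-image scalar. The default estimator is the **mode** of
the integer-rounded intensity histogram: with most of the field occupied by
background, the histogram peak estimates the background plateau without
bias under symmetric noise. A low-percentile estimator (the conventional
1st percentile) is also available but systematically undershoots the
background by ~2.3 noise SDs, leaving a positive residual on both channels
that biases ratio metrics at low signal; it is therefore not the default.
Corrected intensities are clipped at zero.

Nuclei: Otsu threshold on the corrected DAPI channel, hole filling, and
removal of components below `min_nucleus_area_um2` (default 20 µm²).
Cell territories: every pixel is assigned to the nucleus with the smallest
Euclidean distance (computed by the exact distance transform with nearest-
feature indices), so territories partition the field. Mitochondria: Otsu on
the corrected marker channel, by default per cell territory (robust to
per-cell marker abundance differences; a global variant is available),
excluding nucleus pixels and objects below `min_object_area_um2` (default
0.1 µm², removing single-pixel noise). Otsu is scale-covariant, so
segmentation is invariant to multiplying a channel by a positive constant.
Cells whose nucleus touches the field border are flagged and can be
excluded by configuration; by default they are retained.

## Ring geometry

Distance from the nucleus is defined with a half-pixel boundary correction:

    d = max(EDT(nucleus complement) − 0.5 px, 0) · pixel_size

The boundary of a pixelated region runs midway between the outermost region
pixel centers and their neighbors; the raw EDT (distance to the nearest
nucleus pixel *center*) is never smaller than one pixel outside the region,
which would leave the innermost ring empty whenever the ring width does not
exceed the pixel size. With the correction, a pixel adjacent to the nucleus
sits at d = 0.5 px, ring 1 always touches the nucleus, and all rings have
the same effective radial width. Ring k is the half-open band
(k−1)·w ≤ d < k·w (w = 1 µm, 4 rings by default), intersected with the
cell's territory by default so rings of neighboring cells never overlap.
Rings reaching the field border are truncated and flagged.

Ring **membership** is a pixel-level rule and is what all intensity metrics
use. Ring **areas** are additionally reported by a supersampled quadrature
(`RingSet.ring_areas_um2`, 4× by default): the same distance rule is
evaluated on a finer grid restricted to the nucleus neighborhood, excluding
the nucleus pixel footprint. Counting member pixels quantizes ring areas by
tens of percent when rings are only one or two pixels wide (the set of
attainable pixel-center distances is discrete near a boundary); the
quadrature measures the geometric area of the ring region to a few percent
even at 1 µm pixels.

Profiles are normalized per cell to ring 1. Cells whose ring 1 holds no
mitochondrial signal are excluded from profile averaging and logged.

## Statistics

Group summaries are mean ± SEM (sample SD with n−1 over √n; undefined and
reported as missing for n = 1). Control normalization divides every value
by its experiment's control-group mean, making the control exactly 1.0
within each experiment before averaging across experiments. Two groups are
compared with the two-tailed Student t-test (pooled variance by default,
Welch optional); three or more with one-way ANOVA followed by pairwise
t-tests with Bonferroni correction. The comparison family is a required
parameter — `vs_reference` (family size g−1; e.g. rings 2–4 against the
perinuclear ring 1) or `all_pairs` (g(g−1)/2) — because the appropriate
family depends on the design and silently defaulting would mis-state
adjusted p-values. Significance is α = 0.05 on the adjusted p-value.
Degenerate inputs (identical groups) return t = 0, p = 1 rather than
failing. The t-test's null rejection rate over 1000 simulated replicates
sits inside the 99% binomial band [0.035, 0.065] around α; individual
seeds can honestly fall outside this band about 3% of the time.

## Synthetic scenes

The generator emulates a 63× confocal field of adherent epithelial cells:
512×512 px at 0.2 µm/px (a 102 µm field), four cells per field by default.
Nuclei are randomly rotated ellipses with 4–6.5 µm semi-axes, placed
without overlap (≥3 µm apart; placement failure after bounded retries is an
explicit error). Mitochondria are persistent random walks seeded
preferentially near the nucleus with outward drift, dilated to ~0.5 µm
width, ~4 µm mean length, 20 objects per cell, confined to the owning
cell's territory and kept ≥2 px apart so the programmed object count is
recoverable by connected components. Intensities follow the linear distance
laws stated in the README with defaults m0 = 150 a.u., b = 1.5,
s_p = +0.05/µm (potential-per-marker rising away from the nucleus, as in
control cells), s_m = −0.03/µm (marker density declining outward). Noise is
Poisson on the full signal (scaling 1.0) plus additive Gaussian (SD 6 a.u.)
over a 50 a.u. background, giving a marker SNR near 10. Equal parameters
and seed reproduce scenes and renders bitwise.

Treatment scenarios are parameter overrides of the vehicle condition, with
magnitudes chosen as plausible design values (they are not measurements):
`hyperpolarized_fragmented` raises the polarization base 1.3× and doubles
the object count at half the object length; `marker_up_gradient_steep`
raises marker density 1.25× and steepens the gradient to +0.10/µm;
`gradient_flattened` reduces the gradient to +0.005/µm.

The truth table records, per cell, the programmed object count, mitochondrial
area, and per-ring potential/marker ratios computed from the programmed
intensities with the same distance convention and binning as the analysis.

What the generator does **not** model: point-spread-function blur,
photobleaching, stage drift, 3D structure, mitochondrial dynamics, or
intensity distributions of any real instrument. Passing recovery tests
therefore demonstrates the correctness of the measurement pipeline on data
satisfying its geometric assumptions, not performance on real micrographs —
in particular, real images with overlapping organelle blur would stress
segmentation in ways these scenes do not.

## Validation scales and numerical choices

Validation experiments are sized to run on one CPU in minutes: gradient and
effect recovery use ~13 fields (≥50 cells) per group; fragmentation uses 3
fields per condition; the t-test calibration uses 1000 replicates of two
n=35 groups. Recovery accuracy observed at these scales: noiseless ring
profiles match pixel-level truth to <1%; the mean normalized ring-4 ratio
at default noise is within ~1% of truth; programmed whole-cell effects of
10/25/50% are recovered within one percentage point; programmed object
counts are recovered exactly in gap-enforced scenes at default noise.

Tie-breaking and degenerate cases: territory assignment at exactly equal
distances follows the distance transform's nearest-feature choice (stable
for a fixed input); a flat gradient yields unit-normalized profiles; an
all-zero marker channel yields an empty compartment with a warning, not an
error; rendering raises if programmed slopes drive any pre-noise intensity
negative over the placed mitochondria. All seeds are integers below 2³¹;
every stochastic step derives its generator from the experiment seed, so
saved configurations reproduce all outputs byte for byte.
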