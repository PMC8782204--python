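# Methods

This note documents what the package computes, the choices made where the
design was open, and what the synthetic validation does and does not show.

## Coordinate and signal conventions

Voxel indices are 0-based; every user-facing coordinate is in mm scanner
space through the volume's affine. All signal segments are half-open sample
intervals `[start, end)`. Recordings are channels × samples in µV.
Threshold comparisons are strict (`>`) everywhere — a sample equal to a
threshold is sub-threshold — so the ictal onset rule and the interictal
event rule behave consistently at boundaries.

## Electrode localization

### Voxel extraction

The default `bright` rule sets the threshold halfway between the median of
the nonzero voxels (the brain parenchyma level in a skull-stripped scan)
and their 99.999th percentile (the metal level). Electrode voxels occupy
only ~0.01–0.05 % of a head volume, which is exactly the regime where
Otsu's method fails: with such an unbalanced mixture the between-class
variance is maximized by splitting the dominant brain/noise mode, not by
separating metal from brain (on our synthetic volumes Otsu lands at ~123
in units where the true separatrix is ~550, extracting hundreds of
thousands of voxels). Otsu remains available as an explicit override
(`otsu`), alongside percentile (`p99.9`) and absolute (`abs:V`) rules, for
images where the bright class is a sizable fraction.

### 3D line Hough transform

Directions are the 321 sign-deduplicated vertices of a three-times
subdivided icosahedron (~4° bin half-width); each point votes, per
direction, into a 1-voxel 2D grid over the plane orthogonal to that
direction. Peaks are extracted iteratively: take the global accumulator
maximum, claim the points near that line, remove them, re-vote. Stopping is
vote-based — `min_votes = max(10, 25 % of the first peak)` — so no
electrode count is needed, with `--n-electrodes` as an override.

Two refinements matter in practice:

* **Claim–refit to stability.** The discrete direction of a peak is a few
  degrees off the true shaft, so a single tight claim covers only part of
  it. The claim radius is widened slightly, the axis refit by a
  total-least-squares (principal-axis) line through the claimed points, and
  the cycle repeated until the claimed set stabilizes, before a final tight
  claim.
* **Contiguous-support restriction.** A detected line extends infinitely,
  and beyond the shaft it can pass straight through another electrode.
  Claims are therefore restricted to the contiguous run of axial
  projections (gaps ≤ 5 voxels) around the median; without this, stolen
  points starve the other shaft's own Hough peak below `min_votes` and an
  electrode disappears.

### Mixture clustering

One full-covariance Gaussian component per Hough line, with means, weights
and covariances initialized from each line's inliers (`reg_covar` 1e-3, a
single initialization, fixed seed): the geometric prior replaces random
restarts entirely, which is the point of running the Hough transform first.
Because full covariances of long thin clusters overlap near shaft
crossings, the mixture responsibilities occasionally hand a few voxels to
the wrong electrode; two rounds of k-lines refinement (refit each cluster's
axis, re-assign every point to its nearest axis) restore the geometrically
correct partition. Components that collapse below 4 members raise a named
error.

### Contact segmentation

Per cluster: the shaft axis is a total-least-squares line (rotation
invariant, unlike coordinate-pair regressions; fit after discarding
perpendicular outliers > 3 voxels). The head is the extreme axial
projection nearer the brain's center of intensity mass, with ties broken
toward the lower flattened voxel index. Contact 1 is found by center-of-mass
convergence from the head; each subsequent start steps one pitch (3.5 mm
default) outward along the axis.

Center-of-mass convergence resamples a 2×2×2 mm cube (9³ trilinear
samples) around the current point and moves to its intensity-weighted
centroid; voxels inside the cluster's region get double weight. The doubled
region is the cluster's member voxels **dilated by 2 voxels** so that it
covers whole contact blobs: doubling only the supra-threshold subset biases
each centroid toward an arbitrary, noise-dependent voxel set (measured on
synthetic batches: 95th-percentile axis distance 0.10 mm undilated vs
0.05 mm dilated). Iteration stops when the displacement falls below 0.05
voxel or after 10 iterations; a detected two-point oscillation — two bright
regions competing — returns the candidate with the higher interpolated
intensity. The 0.05-voxel tolerance leaves a worst-case residual of ~0.08
voxel at the observed contraction rate of ~0.6 per iteration; a looser
0.25-voxel rule would leave up to 0.36 voxel.

The walk stops at `max_contacts` (16), when the stepped point leaves the
cluster's axial extent dilated by one pitch, or when the converged point's
interpolated intensity falls below the extraction threshold. Finally an end
contact whose spacing to its neighbor deviates from the pitch by more than
1 mm is dropped as a phantom: such contacts arise when stray cluster voxels
inflate the axial extent toward a crossing shaft (measured phantoms sit
4.4–6.1 mm from their neighbor, genuine spacings within ±0.3 mm).

### Geometric QC

Axis–contact distances are measured against a line re-regressed through the
**final contact coordinates**, not the voxel cloud, because the metric
validates the contacts themselves. Adjacent-spacing errors are Euclidean
spacing minus the configured pitch. Single-contact electrodes contribute an
axis distance of 0 by convention and no spacing pairs.

## Epileptogenicity Index

Both filters are applied zero-phase (forward–backward): a causal filter's
group delay would bias every onset time, and onset order is the quantity of
interest. The notch Q of 30 is shared with the interictal path. The
smoothing window shrinks at the recording edges (mean over the in-bounds
part). The threshold uses the sample standard deviation (ddof = 1). Tied
onsets share the earlier rank while consuming rank slots (onsets at samples
{5, 5, 9} give ranks 1, 1, 3), so with distinct onsets the TC multiset over
m onset channels is exactly {1, 1/2, …, 1/m}. The EC window is anchored at
the globally earliest onset for all channels and truncated (with a warning)
if it runs past the recording. EC uses the normalized energy (NHFE), which
makes every EI invariant to rescaling the raw recording. Channels without
an onset keep TC = 0 and EI = 0 rather than being dropped, so outputs
always align with the channel list.

## High-Frequency Events Index

The ripple envelope is the magnitude of the analytic signal after notch and
band-pass, smoothed by a 10 ms centered moving average. The smoothing is an
energy-envelope estimate in the spirit of the short RMS windows standard in
high-frequency-oscillation detection: it leaves the envelope of any
sustained oscillation unchanged (a 150 Hz tone of amplitude A still reads
A) but suppresses the millisecond-scale excursions of a stochastic
background. This matters quantitatively: a Rayleigh-distributed raw
envelope spends 2⁻⁴ ≈ 6 % of its time above 2× its median, and the 20 ms
merge rule chains those excursions into spurious events that pass the 50 ms
duration filter at ~7–13 events/channel/min on a pure pink-noise input;
with the 10 ms smoothing the spurious rate drops to ~0/min at unchanged
recall of planted ripples. The window is configurable
(`envelope_smooth_ms`), as is the band.

Event extraction order is fixed and pinned by test: extract strict
supra-threshold runs → merge gaps < 20 ms (a 60/10/60 ms pattern becomes
one 130 ms event) → drop events < 50 ms (a lone 40 ms burst is discarded;
a 40 ms burst 10 ms from a 60 ms burst survives via the merge). Channels
with a degenerate zero threshold (flat-zero envelope) emit no events.
Recordings are processed in memory; zero-phase filtering and the Hilbert
transform are not exactly chunk-invariant, so no chunked mode is offered
and multi-hour files should be windowed by the caller if memory demands it.

Note that the per-channel event count is *not* monotone in the threshold in
full generality: raising a threshold can split one long merged event at a
≥ 20 ms saddle into two events that each pass the duration filter. The
tests therefore assert monotonicity only where it genuinely holds (isolated
single-lobe bursts, and total supra-threshold time at the raw run level).

## Evaluation

AUC is the all-pairs concordance probability (ties 1/2), which equals
trapezoidal integration of the tie-handled ROC curve; the curve points come
from scikit-learn and the two are cross-checked in tests. Contact matching
is greedy nearest-pair one-to-one with a default tolerance of 1.75 mm —
half the pitch — so a found contact can never be credited to an adjacent
true contact.

## Synthetic data: what it emulates, and what it does not

* **Volumes**: a smooth ellipsoidal brain plateau at 10 % of the blob peak
  (so thresholding has something to reject), additive Gaussian noise at
  10 % of the blob peak, and contacts rendered as isotropic Gaussian blobs
  (FWHM = 2 mm contact diameter) that partially merge at 3.5 mm pitch —
  deliberately reproducing the hard case where adjacent contacts blur
  together. Shafts are straight by default, with an optional parabolic-arc
  bend (`bend_amplitude_mm`) to exercise the bent-electrode failure mode,
  and are placed with ≥ 2 contact diameters of clearance. Not emulated:
  skull/teeth/support artifacts (assumed removed by skull-stripping), beam
  hardening and metal streaks, anisotropic voxels in the defaults (the code
  handles general affines; the generator defaults to 1 mm isotropic).
* **Ictal recordings**: 1/f-amplitude ("pink") noise baselines at 50 µV;
  from each SOZ channel's onset, band-limited 60–140 Hz noise whose
  amplitude rises with a 0.5 s saturating-exponential ramp to `snr` × the
  channel's own in-band baseline deviation. Not emulated: DC shifts,
  propagation patterns, artifacts, non-stationary baselines.
* **Interictal recordings**: the same noise floor with Tukey-windowed
  (α = 0.2) ripple bursts of 60–150 ms at known times, ≥ 100 ms apart,
  scaled so the mean in-event envelope is ≥ `event_snr` × the channel's
  envelope median (a 15 % headroom factor covers taper and band-edge
  losses). Not emulated: spike-and-wave morphology, fast ripples > 250 Hz,
  movement artifacts, mains harmonics.

Passing the synthetic validation therefore demonstrates the internal
consistency and numerical behavior of the pipeline under controlled noise —
it does not certify clinical accuracy on real CT or SEEG, where artifact
structure, electrode bending and non-Gaussian backgrounds are harsher.

## Validation batch sizes

The geometric validation uses 20 seeded volumes of 8 electrodes with 8–16
contacts each (~1 900 contacts, ~1 800 adjacent pairs per batch) — enough
that the reported percentages are stable to a few tenths of a point across
batches. Signal-side property checks use 20–40 seeded recordings at 512–1000
Hz and 30–60 s duration.

## Known limitations

* Electrode shafts are assumed predominantly straight; strongly bent
  electrodes widen both QC distributions (by design, the bend generator
  reproduces this) and can truncate the contact walk.
* The vote-based electrode-count rule can miss a shaft whose contacts are
  unusually few and dim when a much larger shaft dominates the first peak;
  `--n-electrodes` overrides it.
* The Hough accumulator assumes near-isotropic voxels; strongly anisotropic
  volumes should be resampled first.
* EI depends on a manually chosen baseline and target window, as intended;
  no automatic seizure detection is provided.
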