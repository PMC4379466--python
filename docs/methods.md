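# Methods

## Scope and coordinate conventions

The package analyses 2D single-molecule localization microscopy (SMLM) data
acquired on resin sections and correlates them with electron-microscopy (EM)
images of the same field. All SMLM coordinates are continuous nanometres,
x rightward, y downward, with camera pixel (0, 0) spanning [0, pixel) on each
axis; EM images are addressed in pixels. The two modalities are calibrated
independently, so the control-point transform is the only bridge between
them — tables never store EM pixels and EM images never carry nm metadata.

## Forward model

**Structures.** Ground truth is a point set decorating a parametrized
geometry: two parallel lines at an exact spacing (membrane pair), a single
line, a ring, Gaussian nuclear clusters, or a uniform field. Counts are
Poisson in the structure measure (length x linear density or area x areal
density), so replicate simulations carry realistic counting noise.

**Photo-switching.** Each switching fluorophore cycles
dark -> on -> (bleached | dark) in continuous time: exponential dark
intervals at the recovery rate, exponential on-times (default mean 60 ms),
and an irreversible bleaching probability per burst. Detected photons per
burst are drawn uniformly in 100–1000 (only the range of this quantity is
known, not its shape) and split across camera frames in proportion to the
overlap of the on-interval with each frame's 50 ms integration window at
17 fps; photons emitted in the 8.8 ms dead time per frame are lost. A
configurable fraction of emitters never switches and instead fluoresces
continuously until an exponential bleaching time — this is the population
that raises the background early in an acquisition.

**Camera.** The EMCCD chain is simplified to
counts = Poisson(QE·(signal+background))·gain + N(0, read noise) + offset.
The full electron-multiplying register cascade (excess noise factor ~sqrt(2))
is deliberately omitted: the downstream estimators are validated against the
variance structure this model produces, and adding the cascade would only
rescale the effective gain. Defaults: 80 nm back-projected pixel (a typical
EMCCD pixel behind a 100x objective), gain 30, read noise 20 counts, offset
100, QE 0.9.

**PSF.** A Gaussian with sigma = 0.25·lambda/NA (the standard Gaussian
match to the Airy profile), 91 nm for lambda = 510 nm and NA = 1.4. Spots
are rendered as pixel-integrated Gaussians (difference of error functions),
truncated at 5 sigma (mass error < 1e-6).

**Dense non-switching background.** At realistic labeling densities the
non-switching population's overlapping PSFs blur into a spatially uniform
glow. Simulating it as thousands of individually rendered bright spots is
both slow and misleading at the emitter counts a test movie can afford — a
few hundred resolvable constant spots bias nearby fits through PSF overlap,
an artifact of under-sampling the population rather than a property of the
data being emulated. `render_movie` therefore also accepts a per-frame
background array, and the canonical scenario
(`scenarios.bleaching_background_movie`) uses an exponentially decaying
uniform background (default 43 -> 2 photons/px/frame at 0.06 s^-1) over a
sparse switching population. The emitter-level non-switching model remains
available and its summed intensity is verified to decay at the configured
bleaching rate.

**EM images.** The same ground-truth structure is rendered as dark Gaussian
ridges (sigma 1.5 px) on a bright background — heavy-metal-stained membranes
in bright-field TEM — in a coordinate system related to the SMLM frame by a
known, invertible similarity or affine transform, with optional Gaussian
noise. These are synthetic stand-ins for micrographs, used as registration
fixtures with exact ground truth.

## Localization

1. **Background subtraction.** Per pixel, the temporal median over a sliding
   window of ±10 frames (truncated at the edges) is subtracted. The median
   is robust to bursts up to ~1/2 the window length, so single-molecule
   signal survives while the slowly bleaching background is removed.
   Residuals are kept signed; detection clamps them at zero.
2. **Detection.** The signed residual frame is convolved with a Gaussian
   matched to the PSF width, which suppresses single-pixel shot-noise spikes
   (EMCCD Poisson-times-gain noise is heavier-tailed than Gaussian).
   Candidates are 3x3 local maxima exceeding
   median + 4 x (1.4826·MAD) of the smoothed frame, greedily thinned to a
   2 px minimum separation in order of decreasing intensity (ties: smaller
   row, then column).
3. **Fitting.** Each candidate's 7x7 ROI (raw counts converted to
   photo-electrons; the fit does not use the residual, whose signed values
   are incompatible with a Poisson likelihood) is fit by maximizing the
   Poisson likelihood of mu_i = N·G_i(x0, y0, sigma) + b with an analytic
   gradient (L-BFGS-B). sigma is free within [0.5, 2] x the nominal PSF
   sigma to absorb section-induced aberrations. Flat ROIs and
   non-convergent fits return a failure flag.
4. **Merging.** Localizations in consecutive frames within 50 nm are merged
   into one record at the photon-weighted mean position (photons summed,
   `n_merged` counting the chain length); with 60 ms on-times and 50 ms
   integration, two-frame bursts are the norm. Records below 100 detected
   photons are then dropped — 100 photons is the lower edge of the detected
   single-molecule range, and sub-100 fits are dominated by noise peaks
   (this floor is also what holds the noise-only false-localization rate at
   or below 1 per 100 frames).
5. **Persistent-signal removal.** `remove_persistent` traces
   consecutive-frame chains on an unmerged table and discards chains longer
   than 5 frames: signals present at one position for many frames are
   non-switching molecules, not single-molecule detections.

## Accuracy estimation (NeNA)

For every localization in frame t, the distance to its nearest neighbor in
frame t+1 within a 200 nm search radius is collected. Same-molecule pairs —
two independent localizations of one fluorophore whose burst spans the frame
boundary — follow a Rayleigh distribution of scale sigma·sqrt(2) in distance,
p(d) = (d/2 sigma^2)·exp(−d^2/4 sigma^2), truncated and renormalized on
[0, R]; spurious pairs contribute a linear term 2d/R². The mixture is fit by
bounded maximum likelihood on binned counts (200 bins, two weight starts to
avoid the degenerate all-background optimum); the reported accuracy is the
per-axis sigma, consistent with the FWHM = 2.35·sigma convention used in the
structural-resolution formula. A confidence half-width is derived from the
numerical curvature of the binned likelihood at the optimum.

The estimator requires at least 50 pairs and must run on **unmerged**
tables: burst merging deletes exactly the adjacent-frame repeats it
measures. `accuracy_trend` splits the acquisition into epochs of equal frame
count (not equal localization count, so epochs map to wall-clock acquisition
time) and estimates each epoch independently, marking under-populated epochs
invalid rather than failing.

By construction the estimate uses only (frame, x, y); it is exactly
invariant to the photon column, which is what makes it an independent check
on photon-based accuracy predictions.

## Density and resolution

The mean distance d̄ from a point to its K = 20 nearest neighbors is
converted to a local density via rho = (c_K/d̄)², where
c_K = (1/(K·sqrt(pi)))·sum_{k=1..K} Gamma(k+1/2)/Gamma(k)
is the expectation factor for a uniform Poisson process (c_1 = 1/2 recovers
the classic nearest-neighbor result; c_20 ≈ 1.7134, verified against Monte
Carlo to < 1%). The factor corrects for the fact that 20 neighbors cannot
all sit at the single-neighbor distance — they cannot be arranged with
circular symmetry.

Two numerical details:

- **Border correction.** A point whose 20th neighbor is farther than its
  distance to the field border has part of its neighborhood outside the
  field; such points are flagged and excluded from summaries.
- **Pooled summary density.** The pointwise mean of (c_K/d̄_i)² is biased
  ~6% high on uniform fields because squaring amplifies the sampling noise
  of d̄ (Jensen's inequality). Summaries therefore report the pooled
  estimate (c_K / mean(d̄))², which is unbiased within the tested 5% across
  1,000–40,000 points/μm²; the pointwise mean is kept under a separate key.

Exact duplicate points (zero distance) are excluded with a warning, not
jittered. The Nyquist-limited resolution is R_N = 2/rho^(1/2) (twice the
mean sampling interval in 2D), and the structural resolution combines the
localization FWHM and the sampling term in quadrature:
R = sqrt((2.35 sigma)^2 + R_N^2). This form reproduces the canonical
triplet: sigma = 17 nm at 22,000/μm² (R_N = 13.5 nm) gives R ≈ 42 nm.
Molecule counts per diffraction-limited area use a circle of 250 nm
diameter, the conventional lateral resolution of high-NA visible-light
imaging; the same convention gives ~1,080 molecules at 22,000/μm² and
~1,963 at 40,000/μm².

## Rendering

Each localization is drawn as a unit-mass pixel-integrated Gaussian of
sd = max(sigma_loc, R_N,i/2.35, floor) on a 5 nm (default) grid: blur
degrades exactly where sampling is sparse, so the image never shows detail
the local density cannot support. The color raster maps the
intensity-weighted mean local density per pixel through a colormap on a log
scale between configurable bounds; the same scale can be labeled in Nyquist
nm, giving the dual density/resolution legend. The wide-field reference
renders the same positions with a fixed 250 nm-FWHM kernel. Mass is
conserved by both renderers (sum of raster = record count), and with the
kernel floor raised to the wide-field sd the two renderers agree to
floating-point precision.

## Registration and profiles

Similarity ("linear conformal": rotation + uniform scale + translation,
reflections excluded by default) is estimated by orthogonal Procrustes with
scale; affine by least squares. Preconditions: ≥ 2 pairs (similarity),
≥ 3 non-collinear pairs (affine). The tool always reports the control-point
residual RMS and never auto-selects between the two models — what counts as
"significant shrinkage" of a section is the operator's call, so both
residuals are exposed instead. Rasters are resampled by inverse mapping with
bilinear interpolation; overlays composite the resampled SR image over the
normalized EM image with a user alpha, leaving EM untouched outside the SR
support.

Line profiles average `width` perpendicular bilinear samples at evenly
spaced positions along a segment; TEM profiles are inverted (max − value) so
dark membranes compare directly with bright fluorescence ridges.

**Resolvability criterion.** A 300 nm line pair blurred with a 250 nm-FWHM
Gaussian retains a shallow (~29%) dip, so a bare local-maximum count would
call it "resolved". `count_resolved_peaks` instead requires a dip of at
least 50% prominence (a Rayleigh-style contrast criterion) for maxima to
count as separate structures; under it the wide-field profile of the 300 nm
pair is single-peaked while the SMLM and inverted-EM profiles are
two-peaked.

## Validation scenarios and problem sizes

Tests validate each stage against independent oracles: a brute-force
continuous-time switching simulation (burst discretization), exhaustive
grid search of the Poisson likelihood and a numerical Cramér–Rao bound
(fitting), an O(n²) all-pairs sort (neighbor search), Monte-Carlo Poisson
fields (c_20 and density recovery), and closed-form transforms
(registration). Simulated movies use 32–48 px fields with 300–1,000 frames
and a few hundred emitters — small enough for the suite to run in about a
minute while leaving each estimator several hundred events per assertion.
The bleaching-background scenario (1,000 frames, ~700 emitters, background
45 -> 2 photons/px) yields ~300–450 NeNA pairs per epoch, enough for the
~17 -> ~12 nm accuracy trend to be strictly monotone across three epochs.

What the synthetic data do not emulate: stage drift, astigmatism or any 3D
PSF structure, spatially varying illumination, EM-register excess noise,
section wrinkles or stain granularity in the EM images, and multi-emitter
(overlapping-burst) events beyond what random coincidence produces. Passing
tests therefore demonstrate correctness of the estimators under the stated
model, not robustness to these real-data effects; drift correction and
multi-emitter fitting are explicit non-goals.

## Known limitations

- The localization chain fits one emitter per ROI; fields above a few
  active emitters per 1,000 px² start to lose precision to overlap.
- The NeNA mixture assumes spurious pairs are uniform in area; on strongly
  clustered data within the search radius the background weight absorbs
  some same-structure pairs and sigma is biased slightly upward. Reducing
  the search radius mitigates this.
- Density estimation assumes local uniformity at the 20-neighbor scale; on
  1D structures (membranes) the returned "areal density" is an effective
  value whose Nyquist interpretation is approximate.
- The EM synthesizer produces idealized ridge images; registration accuracy
  on real micrographs is limited by feature identification, not by the
  estimator.
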