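# Methods

This note documents the models, conventions and design choices behind
`larvalight`: what the quantification stages assume, what the phantom
simulator does and does not emulate, and the numerical details a user needs
to interpret (or distrust) the outputs.

## Imaging model and flat-field correction

A light sheet is thin at its focus and diverges away from it. Along the
propagation axis *x* the illumination intensity follows a Lorentzian centred
on the sheet focus; along the vertical axis *y* it is Gaussian:

I(x, y) = I₀ · [1 + ((x − x_c)/x_R)²]⁻¹ · exp(−(y − y_c)²/(2σ_y²))

with I₀ the peak intensity (a.u.), x_c the focus position and x_R the
Lorentzian half-width (both px), y_c the vertical sheet centre and σ_y the
vertical width (px). The fit (`fit_sheet_field`) is nonlinear least squares
with an analytic initialisation — I₀ and (x_c, y_c) from the image maximum,
x_R and σ_y from half-max widths — applied to an average of images of a
uniform fluorophore solution. On noiseless synthetic fields the five
parameters are recovered to better than 1e-6 relative error.

Correction divides each plane by the fitted field **normalised to its own
peak**, so intensities in the well-illuminated region are unchanged and the
field periphery is brightened. Whether to divide by the raw or normalised
field is a genuine convention choice; normalised-to-peak was chosen so that
corrected and uncorrected intensities are directly comparable near the
sheet focus. Where the normalised model falls below a floor ε (default
0.05) the divisor is clamped at ε to avoid noise blow-up; engaging the
floor on more than 10% of pixels logs a warning. An optional crop fraction
removes low-intensity rows at the top and bottom of the frame before
correction (default 0).

Tile fusion pastes tiles at their stage coordinates rounded to the nearest
voxel (no subpixel interpolation or cross-correlation refinement — stage
coordinates are trusted) and resolves overlaps by the arithmetic mean of
contributing tiles. Dual-illumination exposures are combined by a plain
voxelwise average.

## Single-cell quantification

Reporter intensity is summed within a discrete circle (pixels whose centre
lies within `radius_px` of the centre pixel; default 6 px) around each
provided cell centre on a 2D maximum-intensity projection. Cell centres are
supplied as tables — the package deliberately does not segment fat-body
cells from a membrane marker. Circles clipped by the image border are
flagged rather than silently truncated. Endpoint analyses use the circle
**sum**; time-lapse traces use the circle **mean** (which is robust to the
tracked centre drifting within the cell). No local background is
subtracted by default; the option exists because whether the original
measurements subtracted background is not determinable, and the phantom's
recovery tests are exact without it.

Response classification works on per-larva median single-cell intensity.
Larvae at or below a background gate are non-responders; the gate defaults
to the largest per-larva median over a small cohort of mock (zero
expression) phantoms, mirroring the use of mock-injected animals to bound
background fluorescence. Above-gate larvae are split into partial and
complete responders by an exhaustive 1D Otsu threshold on log medians. The
split is accepted only when the two groups' mean log medians differ by at
least log(3): responding cohorts separate by roughly an order of magnitude,
and without this guard a unimodal cohort would always be split on noise.
Unsplittable cohorts are all called partial, with a logged note.

Nuclear factor levels (e.g. a tagged transcription factor) are quantified
in 3D: Gaussian blur of the nuclei channel, threshold (Otsu by default),
connected components, removal of components below a size floor (default
half the median component volume — hemocyte nuclei are markedly smaller
than fat-body nuclei), and per-nucleus signal Σ(I − mean(shell)) where the
shell is the mask dilated by 2 px minus the mask. Negative totals are
clipped to zero by default (configurable).

## A-P profiling

Tissue-scale profiles need no cell marker. The projection is log(1 + I)
transformed (log1p admits zero pixels), and two Otsu thresholds are
computed on a 256-bin histogram, separating dim background, bright tissue
background, and strong reporter signal; the mask keeps the top class.
Because the thresholds returned by the histogram implementation are bin
centres, classification compares histogram **bin indices**, so pixel values
sharing the threshold bin are never split — this makes the three-level
worked example exact. Masked intensity is summed along the short axis and
accumulated into equal-width bins over the fat-body extent (x₀, x₁), which
is supplied by configuration or the truth manifest (no automatic outline
detection). Every masked pixel lands in exactly one bin, so the
unnormalised profile conserves total masked intensity exactly. The default
is 14 bins, i.e. a bin width of ~0.07 of the fat-body length; bins are
equal-width in length fraction, not pixels.

Per-larva profiles are normalised to their own maximum and averaged; the
error band is the per-bin **sample** standard deviation (ddof = 1, zero for
a single larva). Profiles with an all-zero maximum are excluded with a
warning.

Regional statistics use boundaries at 0.25 and 0.65 of the fat-body length
(anterior | middle | posterior). The boundaries are a documented convention;
they are configurable everywhere they appear. When region ratios are
computed from a binned profile, the profile should be finely binned so that
region boundaries fall between bins — the pipeline uses column-resolution
bins for ratios (and 14 bins for display), because with 14 bins a boundary
falls mid-bin and the straddling bin mixes anterior and middle signal,
biasing the anterior/middle ratio by almost a factor of two. Undefined
ratios (zero middle mean) are reported as NaN, never infinity.

Transcript profiles average per-cell frequency (gene count / total count)
within each A-P bin; error bars are the standard deviation of that mean
over 100 within-bin resamples with replacement, seeded. Single-cell bins
have exactly zero bootstrap error; empty bins are NaN.

## Bacteria segmentation and counting

Segmentation is two-phase: a difference of Gaussians (σ₁ = expected
bacterium radius, default 2 px; σ₂ = 1.6σ₁) thresholded by Otsu catches
single cells and small clusters, and a Gaussian blur (σ₃ = 6 px) thresholded
catches large diffuse clusters; the union is labelled with 8-connectivity in
2D, 26 in 3D. The large-cluster threshold defaults to **twice the median
blurred peak of the DoG-phase detections**: any superposition of two nearby
single cells reaches at most twice a single's blurred response, while a
cluster of three or more exceeds it, so the blur phase cannot bridge
neighbouring singles into spurious clusters (an Otsu default here sits just
above background and does exactly that). Both thresholds are overridable.

Object intensity is measured over labels expanded by 4 px into unclaimed
background (aperture completion): the raw mask hugs the bright core of a
spot and captures a size-dependent fraction of its flux, which would bias
counts upward for large clusters. Counts are ceil(intensity / unit) with
the unit the **median of per-object summed intensities** (most objects are
single cells, so the median is a single-cell intensity; a per-pixel median
would not yield per-object counts near 1). A relative noise tolerance
(default 0.1) is subtracted from the ratio before rounding up: the median
normalisation pins single-cell ratios exactly at 1, where any measurement
noise would otherwise push half of them over the rounding edge to 2. Exact
integer multiples still map to themselves, the estimator remains
scale-invariant, and ceil(2.5) = 3. The median is computed after the mask
union, over all objects. Planktonic objects are those with estimated count
1 or 2; A-P density sums estimated counts per bin.

## Expression dynamics

Traces are assembled from per-frame tracked centres (long-format tables;
missing frames leave gaps, centres drifted out of frame drop that frame
with a log entry). The initial rise is fit by ordinary least squares from
the first frame until the trace first reaches halfway between its initial
and final values, with a minimum of 3 points and a fall-back to the full
trace — "initial rise" needs an operational definition and this one is
insensitive to late-time saturation. Slopes may optionally be clipped at
zero. No photobleaching detrend is applied: the GFP readout is assumed
stable, so intensity integrates production. Regional statistics are
medians and quartiles of fitted slopes per region and ratios of medians;
the rate-level correlation is the R² of a regression of intensity at a
reference time (default 6 h) on fitted initial rate.

## The phantom simulator

The phantom provides every input the analyses need, with complete ground
truth. One larva is a field (default 220 x 900 px at 2 µm/px, so the fat
body spans ~1.4 mm; 2D by default, 3D supported with cells in a monolayer
plane) containing:

- an outside-larva background level (default 5 a.u.) and a brighter larva
  body band (default 20 a.u.) — the "dim background" and "bright
  background" classes the multi-Otsu stage expects;
- `n_cells` (default 180) fat-body cells in four bilaterally symmetric
  rows along the A-P axis, rendered as hard discs of constant intensity
  (radius 4 px) composited with the body by per-pixel maximum. Hard discs,
  not PSF-convolved blobs, are deliberate: the circle-sum operator assumes
  compact support, and this makes recovery exact and testable. Per-cell
  mean intensities are drawn log-normally (CV 0.35) around region means —
  log-normal keeps intensities positive and reproduces a broad continuous
  single-cell distribution; the true distribution shape is not known
  beyond that, so this is a modelling choice. Region means encode the
  measured contrasts: middle 100 a.u., anterior 14x, posterior 5x, and the
  control marker channel 1.3x in the anterior only. `allele_copies`
  multiplies the drawn values, so two-copy phantoms are exactly twice
  one-copy phantoms at fixed seed;
- optional multiplicative sheet field (peak-normalised) and additive
  Gaussian noise (default sd 5 a.u., 5% of the middle-region mean). The
  noise model is additive Gaussian on noise-free signal — no camera model
  is asserted;
- for time series, per-cell linear accumulation value = intercept +
  slope·t with slopes drawn log-normally per region (medians: middle 20
  a.u./h, anterior 2.0x, posterior 1.6x; CV 0.4) and the intercept at the
  body level;
- bacteria as discretely normalised Gaussian spots of integrated intensity
  count x unit (default unit 2000 a.u., σ = 2·count^⅓ px), placed along a
  mild "U" A-P density with a minimum separation (default 14 px) enforced
  by rejection sampling, and per-object intensity scatter off by default;
- transcript tables with Poisson totals and Binomial gene counts whose
  true frequency follows a flat, anterior-step or U-shaped profile.

Anterior is at low x; A-P positions are fractions of the fat-body extent
in [0, 1]; coordinates are 0-based pixel indices at pixel centres. All
generators are deterministic given (seed, config).

What the phantom does **not** emulate — and hence what passing recovery
tests do not establish about real data: optical PSFs and depth-dependent
blur, larval motion and tissue deformation, hemolymph autofluorescence
structure beyond a uniform body level, realistic anatomy beyond the lobed
band geometry, overlapping or touching cells, and bacteria—host-cell
colocalisation. Recovery on phantoms validates the computational chain,
not the microscope.

## Cohorts and problem sizes

The shipped default cohort (`configs/default_cohort.yaml`) is 10
partial-response larvae, seeds 0–9, default contrasts, imaged under a
gentle default sheet field and flat-fielded against five simulated uniform
reference images (fit on their average). The cohort analysis runs in
seconds; time-series rate fitting uses one phantom of 200 cells sampled at
13 frames over 6 h, enough that regional medians are estimated to a few
percent. The heterogeneous cohort used for the contrast-bound metric draws
per-larva anterior and posterior contrasts uniformly from [2.5, 10]
(12 larvae).

## Known limitations

- The partial/complete split method (1D Otsu with a 3-fold separation
  guard, k-means not provided) is one of several defensible choices; on
  cleanly separated cohorts they agree.
- Region ratios from coarsely binned profiles are biased when boundaries
  straddle bins; use cell tables or fine bins (the pipeline does).
- The bacteria count estimator assumes most objects are single cells; in
  fields dominated by clusters the median unit — and therefore every
  count — is wrong.
- Tile fusion is mean-blend only; seams are not corrected.
- `read_image` recovers the pixel size only from OME-TIFF metadata or the
  zarr attribute written by this package.
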