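# larvalight

Whole-larva light-sheet image quantification for spatially patterned immune
responses in the *Drosophila* larval fat body.

After systemic bacterial infection, larval fat-body cells express
antimicrobial-peptide (AMP) reporters such as DptA-GFP in a stereotyped
spatial pattern: expression is high in the anterior and posterior lobes and
low in the middle of the tissue (a "U-shaped" profile along the
anterior-posterior axis), and individual cells accumulate reporter at
approximately constant, region-specific rates. `larvalight` implements the
full quantification chain needed to measure this from light-sheet
fluorescence microscopy data, together with a phantom-larva simulator so
every stage can be validated by parameter recovery without any raw imaging
data.

## What it computes

- **Fusion and flat-fielding** (`larvalight.fusion`) — averaging of
  dual-illumination exposures, stitching of tiles by stage coordinates, and
  correction of the light-sheet illumination field, modelled as a
  Lorentzian along the propagation axis times a Gaussian vertically:

  I(x, y) = I₀ · [1 + ((x − x_c)/x_R)²]⁻¹ · exp(−(y − y_c)²/(2σ_y²))

  The five parameters (I₀, x_c, x_R, y_c, σ_y) are fit by nonlinear least
  squares to an image of uniform fluorophore solution, and every plane is
  divided by the fitted field normalised to its peak.
- **Single-cell quantification** (`larvalight.cells`) — reporter intensity
  summed within a circle of radius 6 px around provided cell centres;
  larva-level classification into none / partial / complete responders from
  per-larva median cell intensity (background gate, then a 1D Otsu split on
  log medians); nuclear factor levels by 3D nucleus segmentation with
  2-px-shell local background subtraction and size-based removal of the
  smaller hemocyte nuclei.
- **A-P profiling** (`larvalight.profile`) — three-class multi-Otsu
  thresholding of log-transformed projections isolates strong reporter
  signal from dim and bright background; masked intensity is summed along
  the short axis, binned along the A-P axis (14 bins ≈ 0.07 of the fat-body
  length each), normalised per larva to its maximum, and averaged across
  larvae. Regional contrast ratios (anterior/middle, posterior/middle) and
  bootstrap transcript-frequency profiles (100 within-bin resamples) are
  computed here.
- **Bacteria** (`larvalight.bacteria`) — two-phase segmentation
  (difference-of-Gaussians for single cells, blur-and-threshold for large
  clusters), per-object cell counts by ceil(intensity / median object
  intensity), planktonic filtering (count < 3), and A-P density profiles.
- **Dynamics** (`larvalight.dynamics`) — per-cell intensity traces from
  tracked centres, ordinary-least-squares fits to the initial linear rise,
  regional rate medians/quartiles and their ratios, and the R² between
  initial rate and later expression level.
- **Phantom simulator** (`larvalight.phantom`) — synthetic larvae with known
  per-cell intensities, accumulation slopes, bacterial objects, transcript
  tables, and sheet fields, each with a complete truth manifest. Defaults
  encode the measured effect sizes: 14× anterior/middle reporter contrast,
  5× posterior/middle, 1.3× anterior enhancement of a uniform control
  marker, anterior rate median 2.0× and posterior 1.6× the middle, and 2×
  intensity for two reporter copies.

## Worked example

Analyze the shipped default cohort: 10 partial-response phantom larvae
(seeds 0–9) imaged under the default sheet field, flat-fielded against a
simulated uniform-fluorescence reference, masked, profiled and quantified:

```python
from larvalight import pipeline as pl

cfg = pl.default_cohort_config()
res = pl.run_snapshot_cohort(cfg)
s = res["summary"]
print(f"mean anterior/middle reporter ratio: {s['anterior_middle'].mean():.2f}")
print(f"mean anterior/middle marker ratio:   {s['marker_anterior_middle'].mean():.3f}")
print(f"background gate: {res['background_gate']:.0f} a.u.")
print("responses:", res["classification"]["response"].value_counts().to_dict())
```

prints

```
mean anterior/middle reporter ratio: 14.70
mean anterior/middle marker ratio:   1.304
background gate: 2149 a.u.
responses: {'partial': 10}
```

The recovered reporter contrast (14.70) matches the generating 14-fold
anterior/middle contrast to within 5%, the control marker channel recovers
its small 1.3-fold anterior enhancement, the background gate (the largest
per-larva median over mock, zero-expression phantoms) sits far below every
infected larva's median, and all ten larvae are called partial responders.
The averaged normalised A-P profile in `res["average_profile"]` is U-shaped:
close to 1 in the anterior bins, ≈ 0.06 in the middle, ≈ 0.33 in the
posterior.

The same driver exposes `run_timeseries` (rate fitting),
`run_bacteria` (segmentation and counting) and `run_transcripts`
(bootstrap profiles), and the `larvalight` command line wraps each stage
(`larvalight simulate`, `larvalight flatfield`, `larvalight quantify-cells`,
`larvalight profile`, `larvalight bacteria`, `larvalight run`, ...).

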