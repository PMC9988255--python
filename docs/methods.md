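# Methods

## Fiber detection

`fiberdens` quantifies the areal fraction of darkly stained, thin,
elongated structures (DAB-visualised DBH- or TH-positive axons) in
calibrated RGB brightfield ROIs. The conventional ROI is a 300×300 µm²
window sampled at 1320×1320 px (0.227 µm/px); any size and calibration is
accepted.

The per-ROI pipeline, with every constant on `QuantParams`:

1. **Channel combination.** gray = 1·blue − 0.25·red − 0.25·green.
   DAB's brown reaction product absorbs strongly in the blue band, so the
   blue channel carries stain contrast while red/green supply a background
   reference; the result is a signed plane (white → 127.5, typical tissue
   background ≈ 105, stained fibers ≈ −10). Channels are addressed by
   name, never by array position.
2. **Median denoising.** Disk neighborhood of radius 3 px (29 pixels,
   reflective borders). The odd count makes the output an order statistic
   of the input, removing shot-like noise without shifting edges. Planes
   whose values lie on the quarter-integer grid (anything derived from
   8-bit data) are filtered by an exact sliding-histogram (Huang) kernel;
   general floats fall back to `scipy.ndimage.median_filter`. Both paths
   return identical values.
3. **High-pass.** The plane minus its Gaussian blur (σ = 8 px,
   reflective borders) isolates fiber-scale spatial frequencies. With the
   default `stain_dark` polarity the sign is flipped so stained elements
   come out positive. The plane's scalar median is subtracted before
   smoothing; this leaves the result unchanged mathematically (a constant
   passes through Gaussian smoothing) but makes the computation exactly,
   bit-for-bit, invariant to constant intensity offsets for
   dyadic-rational inputs — a property the test suite asserts.
4. **Large-stain exclusion.** On the denoised (pre-high-pass) plane,
   pixels whose stain-relative intensity (background median minus value,
   for dark stains) reaches 60 are candidates; connected components
   (8-connectivity) of area ≥ 2000 px are kept, dilated by 5 px, and
   excluded from the detection *numerator only* — the denominator remains
   the full ROI, preserving "proportion of detected pixels in the ROI"
   literally. Fiber traces are thin and never reach the area cutoff.
5. **Fixed threshold.** A pixel is detected iff its polarity-corrected
   high-pass value is ≥ 11 (gray levels on the 0–255 scale) and is not
   inside the stain mask. The comparison is inclusive (a pixel at exactly
   11 is detected); this is a declared convention, tested as such.
6. **Volume fraction.** detected pixels / ROI pixels; reported as
   `volume_percent = 100 × fraction_hp`, the depletion readout.
7. **Focus QC.** The ROI is re-analysed with σ = 20 px, which lets lower
   spatial frequencies through the subtraction. Defocus destroys
   fine-scale energy first, so the ratio `fraction_hp / fraction_lowfreq`
   drops for blurry images; ROIs with ratio < 0.5 (repository default —
   no published value exists) fail QC. A zero low-frequency fraction
   makes the ratio undefined and fails QC with a logged reason.

Open conventions resolved here (all configurable): "Gaussian radius" is
interpreted as σ in pixels; the threshold is applied to positive
(stain-dark) deviations; the median neighborhood is ImageJ's disk, not a
square. All arithmetic is double precision; nothing clips to [0, 255]
inside the analysis path.

## Synthetic micrographs

`generate_fiber_scene` renders ground-truth-bearing stand-ins for the
real ROIs: persistent random walks (wrapped-normal step angles, SD
`tortuosity` = 0.25 rad) rendered 2 px wide in DAB brown (120, 80, 40) on
a pale background (230, 225, 220), plus optional large dark stains
(default one disk of radius ≈ 35 px — deliberately far above the
2000-px exclusion cutoff, since the algorithm's premise is that large
stains are unambiguously large), Gaussian sensor noise (SD 3), optional
defocus blur, and 8-bit quantization. Walk length shrinks as the mask
approaches the target density, keeping the realized density within 20% of
target down to 0.005. The truth mask is exact and pre-noise.

At the default calibration a 2-px fiber is ≈ 0.45 µm — the thin-axon
regime in which the radius-3 median filter passes only a fraction of
fiber pixels. Detected fractions are therefore a fraction of true density
(the readout is relative, and rank correlation with ground truth exceeds
0.95 across 0.005–0.05), and per-scene detection has substantial variance;
cohort simulations average several ROIs per subject × region, as a real
study does across hemispheres and sections. The generator does not model
optics (no PSF beyond Gaussian defocus), uneven illumination, staining
gradients, varicosities, or fiber bundling — passing tests show the
detector recovers density ordering and rejects defocus for this scene
family, not that it is optimal on real tissue.

Default scenes are 660×660 px; cohort simulations use 330×330 px scenes
with 4 ROIs per subject × region and 10 subjects per group — sizes chosen
so a full 50-cohort simulation study runs on a laptop while keeping the
subject-level effect sizes in the regime the study design targets.

`generate_behavior_table` draws lever-press rates for mixed factorial
designs as baseline (12 presses/min) + subject effect (SD 3) + residual
(SD 3), with the devaluation effect subtracted from the devalued-lever
response in designated cells and rates truncated at 0 (counts logged).
Gaussian rates match the ANOVA assumptions of the planned-contrast
analysis; `simulate_training_sessions` is the separate point-process
variant (Poisson pressing thinned by the FR1/RR5/RR10/RR20 schedule
probability, 10-min and 20-outcome caps, 2.5-min ITIs, each lever
presented twice).

## Planned orthogonal contrasts

All analyses are sets of 1-df planned contrasts with the error rate
controlled **per contrast** at α = 0.05, with no familywise correction —
this follows the analysis tradition the package reimplements and differs
deliberately from omnibus-ANOVA practice.

The univariate reduction: a within-subject contrast is applied to each
subject's responses, yielding one score per subject; the between-weighted
combination of cell means of scores is tested against the pooled
within-cell variance of scores, F(1, N − J) with J between-cells (so a
57-subject, 4-cell design reports F(1, 53) throughout). Pure between
contrasts use subject means as scores. With two-level within factors no
sphericity question arises. For 2^k designs the full orthogonal set
(every main effect and interaction, 2^m − 1 contrasts) is built by ±1
product coding and verified orthogonal. Trend-over-days questions use
centered linear weights over the ordered sessions
(`linear_trend_weights`), the only 1-df reading consistent with the
F(1, N − J) convention.

Simple effects decompose a significant interaction by re-testing one
factor inside each level of the other **against the pooled error term and
df from the full design** (chosen to match the constant df2 convention;
the level-specific alternative is available by slicing the table).
Unbalanced cells use unweighted (cell-mean) contrast estimates with
1/n_j-weighted precision. Zero error variance yields F = +∞, p = 0 and a
degeneracy warning rather than an exception.

Calibration is verified by simulation: per-contrast type-I error falls in
[0.04, 0.06] under the null, F equals the squared pooled-variance t for
two-group contrasts to 1e−8, between-contrast sums of squares partition
the between-cells SS on balanced data, and the engine's F values match an
independent mixed-ANOVA implementation (pingouin) to machine precision.

## Numerical and degenerate-input choices

- Intensities are float64 on a 0–255 scale regardless of on-disk depth;
  16-bit inputs are rescaled by 255/65535.
- Reflective ("symmetric") borders everywhere in filtering.
- Ties at the detection threshold are included (≥).
- The QC ratio for an ROI with an empty low-frequency detection is NaN
  and fails QC; an all-QC-failed subject × region cell is reported as
  missing, never imputed.
- Scene and table generators are deterministic given their seed; cohort
  and dataset seeds are spawned from a single master seed.

## Known limitations

- Only 2-level factors are supported in automatic contrast-set
  construction; >2-level within factors (beyond linear trend) and
  sphericity corrections are out of scope.
- The stain detector assumes stains are darker than tissue background by
  a configurable margin on the combined plane; pale artifacts (bubbles,
  tears) are not modeled.
- The blur criterion's 0.5 cutoff was set against the synthetic scene
  family; real-microscope defocus may need a recalibrated cutoff.
- Colocalization counting and fiber tracing/length statistics are
  explicitly out of scope.
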