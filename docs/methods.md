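# Methods

This note documents the models behind `erythroquant`, the defaults that
matter, what the synthetic scenes do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Optical model of the red cell at 415 nm

Haemoglobin absorbs strongly at 415 nm (the Soret band) and is distributed
uniformly through the red-cell cytoplasm, so the optical density of a cell
at a point is proportional to the haemoglobin thickness along the beam
path.  The generator models an intact cell as a biconcave disc with the
classic polynomial-in-r² thickness profile

    t(ρ) = √(1 − ρ²) (c₀ + c₁ρ² + c₂ρ⁴),   ρ = r/R ∈ [0, 1]

with (c₀, c₁, c₂) = (0.81, 7.83, −4.39), normalized to a maximum of 1.
Absorbance is A(r) = A_peak · t(r/R) (default A_peak = 0.8 OD) and
transmitted intensity follows Beer–Lambert, I = I_bg · 10^(−A).  The result
is the field-standard discocyte appearance: a dark absorbing ring with a
brighter centre and outer edge.  Intact cells additionally carry a thin
additive bright halo just outside their boundary (amplitude 0.10 · I_bg,
width 2 px, linearly tapered), the visual hallmark of a live cell in
absorbance imaging.  A lysed cell has released its haemoglobin: it renders
as background-level interior plus a faint 1-px membrane outline at 25% of
the intact peak absorbance.

A `center_boost` parameter adds a Gaussian bump (σ = 0.35 R) of extra
central absorbance to an intact cell, emulating the central swelling that a
membrane-damaging treatment produces; it is the ground-truth effect that
the morphology comparison is designed to detect.

**Noise and SNR.** Noise is additive Gaussian, clipped at zero, applied
after rendering.  "SNR" always means peak signal amplitude over per-pixel
noise SD: for absorbance fields the amplitude is I_bg(1 − 10^(−A_peak));
for fluorescence scenes it is the cell (or luminal-surface) amplitude.
Clipping at zero is negligible for the default offsets chosen below.

## Segmentation pipeline

1. **Scale estimation.** The scale-normalized Laplacian-of-Gaussian
   response −σ²∇²G∗I is computed over a σ grid (default 2–10 px, step 0.5)
   on the inverted image; the strongest peak selects σ*, and the cell
   radius estimate is √2 σ*.  A featureless image (no response above a
   floor) raises a no-scale error.
2. **Rolling-ball background.** The background is the grayscale opening of
   the (inverted) image with an exact ball structuring element of radius
   3× the estimated cell radius — the envelope traced by a ball rolled
   under the intensity surface, with replicate-padding at the borders.
   This is computed with nonflat grey erosion/dilation and verified in the
   tests against a brute-force loop oracle (agreement to 1e-9).
3. **Thresholding.** Otsu's threshold is computed by exhaustive vectorized
   maximization of the between-class variance over every distinct pixel
   value (classes ≤ t vs > t, smallest value on ties).  This matches an
   exhaustive-search oracle exactly on arbitrary-valued images, which a
   256-bin histogram implementation does not.
4. **Watershed splitting.** Markers are the regional maxima of the
   Euclidean distance transform after h-maxima suppression (depth 1 px),
   labelled in raster order (ties break to the smallest (row, col)); the
   watershed floods the negated distance transform within the mask.
   Foreground pixel count is conserved.
5. **Size filter.** Regions outside [0.4, 2.5] × πR̂² are discarded
   (brackets singlets; rejects debris and clumps), labels renumbered.

Before thresholding, the background-corrected image is smoothed with a
Gaussian of σ = 0.25 R̂; the rolling ball itself is noise-sensitive and the
smoothing stabilizes both the Otsu split and the watershed markers at low
SNR.  Foreground is 8-connected, background 4-connected.

**Local background.**  Each cell's local background is the median intensity
in a 2-px-wide annulus starting 2 px outside the region, excluding pixels
of any other region, measured on the original (uninverted) image.

## Radial profiles

A pixel's radius bin is the nearest integer to its Euclidean distance from
the region's geometric centroid; when the centroid falls between pixel
centres the four adjacent pixels (d ≤ √½) are assigned to bin 0 so the
centre bin is never empty.  The bin value is the mean of
(local background − intensity), i.e. absorbance-positive; the intensity
convention is available for display.  The conservation identity
Σ(mean·n_pixels) = Σ(background − I) over the region holds exactly by
construction.  Profiles truncate at the first empty bin.

Population profiles average per-cell profiles unweighted (each cell counts
once per bin it covers).  The pre/post comparison runs one Welch t-test per
bin where both arms have ≥ 2 cells, corrects across bins with Holm–Šidák,
and reports a centre verdict: significant if any corrected bin within
±5 px of the centre rejects.  By default at least 10 cells per arm are
required.

## Ratiometric dipole-potential measurement

The membrane dipole potential is read out with a two-channel ratiometric
dye.  Channel semantics are deliberately abstract ("A"/"B"): the per-cell
ratio is mean background-subtracted A over mean background-subtracted B,
and a linear calibration ratio = intercept + slope·MDP(mV) converts to
millivolts.  The default calibration is an identity-like placeholder
(slope 1, intercept 1); real millivolt output requires a supplied
calibration, and no literature constants are hard-coded.

The fluorescence background annulus is wider (gap 2 px, width 6 px) than
the absorbance pipeline's, with *all* segmented regions excluded from
every annulus.  Rationale: the background estimate dominates the ratio
error budget — at SNR 5 the irreducible pixel-noise error on a ~200-px
cell is ≈ 10 mV, and a 2-px annulus median adds ≈ 12 mV more, while a 6-px
annulus adds only ≈ 8 mV.  Cells whose denominator channel does not exceed
its background are excluded and logged.

Group procedures: the donor screen runs one unpaired Welch t-test per
donor (control vs treated), Holm–Šidák-corrected across donors, requiring
50 cells per arm by default; multi-condition single-donor designs use
one-way ANOVA with Dunnett's many-to-one comparison against the control
(100 cells per condition by default).

## Haemolysis

The intact/lysed call is a thresholded contrast score: fractional interior
absorbance (background − mean interior intensity)/background, where the
interior is the filled disc of radius 0.6× the region's maximal extent
around its centroid.  The disc — not the region's member pixels — matters
because a lysed cell segments as a thin rim whose member pixels exclude
the diagnostic empty interior.  The threshold is self-calibrating: Otsu on
the score histogram when the scores are genuinely bimodal (Otsu classes
separated by ≥ 4 pooled within-class SDs), otherwise a fixed absorbance
floor of 0.3 (an interior absorbing < 30% of the background light has lost
its haemoglobin).  The guard prevents a unimodal all-intact population
from being split down the middle.

Percent lysis follows the counting protocol: all non-border cells are
counted before incubation; after incubation only detections classified
intact are counted, so cells that lysed beyond the detection limit are
correctly counted as lysed.  Cells touching the image border are excluded
(partial interiors bias the score).  The MDP–lysis association compares
pre-treatment MDP between intact and lysed cells per donor (Welch t,
Holm–Šidák across donors, 20 cells per donor by default); the generator
can couple lysis probability logistically to the true MDP, with the
intercept solved by bisection so the population lysed fraction matches the
requested value.

## Vessel-wall permeability

Ground truth: intima fluorescence I(d) = I₀·exp(−d/λ) + offset, with d the
Euclidean distance to the nearest lumen pixel, λ = 10 px by default, and
lumen pixels at I₀ (tracer-filled).  The analysis assigns each intima
pixel its distance-transform value, bins at 1 px (nearest integer), and
reports mean ± SEM per bin over intima pixels only; lumen pixels are
excluded, so the closest occupied bin is 1.  The µm axis uses the default
calibration 0.5 µm/px.

The decay fit is I₀·exp(−d/λ) + C by weighted nonlinear least squares
(weights √n_pixels, log-linear initialization).  The constant baseline is
essential: without it, any rectified noise floor in the dim outer wall
biases λ upward by tens of percent.  For the same reason the synthetic
sections carry a detector offset (default 300) so additive noise does not
clip at zero.

Condition comparison: per-arm mean ± SEM profiles with equal weight per
image, and a two-tailed Welch t-test on a per-image summary — the mean
intensity over intima pixels within 40 px (20 µm) of the lumen.  The
summarized quantity is a package choice; the near-lumen band is where a
permeability change concentrates.

## Statistics layer

* **Welch t** from the closed form, with Welch–Satterthwaite df; two-tailed
  throughout.  Zero-variance degeneracies: equal means give p = 1, unequal
  means give p → 0 with a warning.
* **Holm–Šidák**: step-down adjusted p at rank k is
  max_{j≤k} 1 − (1 − p_(j))^(m−j+1), capped at 1; rejection while the
  adjusted value is below α (default 0.05).  Adjusted values are monotone
  along the sorted order and permutation-consistent.
* **ANOVA + Dunnett**: ordinary one-way F; Dunnett adjusted p-values from
  the exact pooled-MSE multivariate-t routine, with the randomized
  quadrature stream pinned so identical inputs give identical p-values
  (reproducible to ~1e-4, well inside the documented ±0.002 tolerance).
  The two-group case reduces to the pooled two-sided t-test.

Error control is verified by simulation in the test suite: type-I error of
Welch's test under unequal variances, and familywise error of Holm–Šidák
and Dunnett under global nulls, each within the binomial 95% interval of
α = 0.05 at 10 000 replicates.

## What the synthetic scenes do not emulate

No optical point-spread function, no defocus, no 3-D structure, no
photobleaching, no flow or time-lapse, no white cells, platelets or
debris, no spatially correlated noise, and no uneven illumination beyond
what the rolling-ball step is tested on separately.  Cell placement is
hard-core (non-overlapping by default), cells are perfectly circular in
projection, and fluorescent cells are uniform discs.  Passing the recovery
tests therefore demonstrates correctness of the measurement chain under
the stated image-formation model, not robustness to every artefact of real
microscopy; the statistics layer's guarantees, by contrast, are
model-free.

## Default study conditions and problem sizes

Scenes use radius-8 px cells (4 µm at 0.5 µm/px) at I_bg = 1000.  Recovery
checks run at peak SNR 5: detection on 50-cell fields, lysis on 200-cell
populations with lysed fraction 0.43, ratiometric recovery on 100-cell
scenes with between-cell MDP spread 50 mV (the tens-of-mV per-cell
heterogeneity that ratiometric imaging resolves), treatment shifts of
2 SD (100 mV) in 2 of 9 screened donors, and λ = 10 px over 10 vessel
sections per arm.  Null-calibration simulations use 1 000 replicates for
the donor screen and 10 000 for the statistics layer.  These sizes are the
package's standard benchmark conditions; all are reproducible from fixed
seeds.

## Known limitations

* The scale estimator returns a single global cell size; strongly
  polydisperse fields would need per-blob scales.
* The contrast-score threshold's bimodality guard assumes roughly
  homogeneous intact-cell absorbance within a field.
* Welch tests treat cells (or images) as independent; within-field
  correlations are not modelled.
* The decay fit assumes a single exponential; layered walls with two
  transport regimes would need a mixture model.
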