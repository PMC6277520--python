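# erythroquant

Quantitative microscopy of red blood cells and vessel walls: single-cell
segmentation of 415 nm absorbance images, radial morphology profiles,
ratiometric membrane-dipole-potential (MDP) measurement, haemolysis
counting, and tracer-penetration profiling of the vascular intima — with a
seeded synthetic-scene generator providing full ground truth for every
stage.

## Who this is for

Groups studying membrane-active agents (immunotoxins, pore formers,
amphiphiles) on red cells and endothelium, who image:

* **morphology** — haemoglobin's Soret-band absorbance at 415 nm maps cell
  thickness, so a discocyte appears as a dark ring with a brighter centre
  and edge; treatment-induced central swelling shows up as increased
  central absorbance;
* **membrane dipole potential** — a ratiometric voltage-sensitive dye whose
  two-channel ratio shifts linearly with the potential at the membrane
  surface;
* **haemolysis** — a lysed cell loses its interior absorbance, leaving a
  faint membrane outline, so % lysis can be counted image by image;
* **vascular permeability** — fluorescent tracer penetrating the vessel
  wall, quantified as mean intensity versus distance from the lumen.

## The measurements

**Segmentation.** Cell scale from the strongest scale-space peak of the
scale-normalized Laplacian of Gaussian (radius = √2 σ*); rolling-ball
background subtraction (exact ball opening, radius 3R̂); Otsu threshold by
exhaustive between-class-variance search; marker-based watershed on the
Euclidean distance transform to split touching cells; size filtering.

**Radial profile.** For cell c with centroid x_c and local background b_c,
bin k collects pixels with round(‖x − x_c‖) = k and reports
mean(b_c − I(x)) — absorbance-positive — with the exact conservation
identity Σ_k mean_k·n_k = Σ_region (b_c − I).  Populations are compared
per bin (Welch t, Holm–Šidák across bins) with a verdict for the centre
band |r| ≤ 5 px.

**MDP.** Per cell, ratio = mean(A − bg_A)/mean(B − bg_B) over the cell's
pixels; MDP(mV) = (ratio − intercept)/slope from a supplied linear
calibration.  Donor screens run one unpaired Welch t-test per donor with
Holm–Šidák correction; multi-condition designs use one-way ANOVA with
Dunnett's test against control.

**Haemolysis.** contrast = (b_c − mean interior I)/b_c, thresholded by
Otsu-on-scores with a bimodality guard; % lysis = 100 × (n_before −
n_intact_after)/n_before from before/after counts.

**Permeability.** Each intima pixel gets its distance-transform distance
to the lumen; mean ± SEM per 1-px bin (0.5 µm/px), decay fitted as
I₀e^(−d/λ) + C, arms compared by Welch's t on per-image near-lumen means.

**Statistics.** Welch's t (Welch–Satterthwaite df), Holm–Šidák step-down
(adjusted p = max_{j≤k} 1 − (1 − p_(j))^(m−j+1)), ANOVA + Dunnett — all
two-tailed, error control verified by simulation.

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

`examples/` holds one short script per capability.  Detection:

```bash
$ python examples/segment_field.py
estimated cell radius: 7.78 px (true 8.0)
detected 50 of 50 cells
detection F1 = 1.000, mean centroid error = 0.19 px
F1 of 1.0 means every cell was found once, with no false detections.
```

The scale-space estimate lands within a quarter pixel of the true radius
grid point, and at peak SNR 5 all 50 cells are recovered with sub-pixel
centroid accuracy.  The donor screen:

```bash
$ python examples/mdp_screen.py
donor_id  mean_control  mean_treated  p_adj  significant
  donor0      285.3673      297.3397 0.6173        False
  ...
  donor2      286.9839      199.8493 0.0000         True
  ...
  donor6      300.6831      203.3429 0.0000         True

flagged donors: ['donor2', 'donor6'] (true shifted donors: donor2, donor6)
```

Nine donors, 50 cells per arm; only the two donors carrying a true 100 mV
treatment shift survive the familywise correction.  And permeability:

```bash
$ python examples/vessel_permeability.py
fitted decay: I0 = 991, lambda = 10.31 px (5.16 um at 0.5 um/px; true lambda = 10 px)
Welch t = 165.76, df = 14.0, p = 1.92e-24
direction: treated > control, significant: True
```

λ is the 1/e penetration depth of the tracer; doubling the surface
intensity in the treated arm is detected with the correct direction.

## Command line

A thin CLI wraps the library for batch runs:

```bash
erythroquant simulate rbc --seed 3 --n-cells 50 --snr 5 --out scene/
erythroquant morphology --pre pre.tif --post post.tif --out run/
erythroquant mdp --manifest donors.csv --cal-slope 2e-3 --cal-intercept 0.4 --out run/
erythroquant lysis --before before.tif --after after.tif --out run/
erythroquant permeability --manifest vessels.csv --out run/
```

Each run writes CSV tables, a `summary.json`, and a
`resolved_config.json`; reruns with the same seed and config are
byte-identical.

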