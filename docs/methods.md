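# Methods

## The mixing model

Every analysis in this package rests on the linear mixing model (LMM). A
1 m hyperspectral pixel in a semi-arid grassland rarely contains a single
cover type; its observed reflectance r ∈ R^B (B valid bands) is modelled
as a convex combination of K class *endmember* spectra E = [e_1 … e_K]:

    r = E a + ε,    a_i ≥ 0,    Σ_i a_i = 1,

where a is the vector of sub-pixel *fractional abundances* and ε is
residual noise. Unmixing solves the least-squares problem min ‖E a − r‖²
per pixel under one of four constraint regimes:

| mode   | constraints          | solver                                   |
|--------|----------------------|------------------------------------------|
| `ols`  | none                 | `numpy.linalg.lstsq`                     |
| `sto`  | Σ a = 1              | closed-form KKT system                   |
| `nnls` | a ≥ 0                | Lawson–Hanson (`scipy.optimize.nnls`)    |
| `fcls` | both                 | exact active-set QP on the unit simplex  |

`fcls` (fully constrained least squares) is the production mode: its
output is a proper composition, which is what makes the downstream area
and change arithmetic exact. The active set starts from the
equality-constrained solution, clamps the most negative coordinate to
zero, re-solves on the support, and re-admits clamped coordinates whose
KKT multiplier turns negative; for K ≤ 6 it converges in a handful of
iterations. Whole-cube runs vectorise the first equality-constrained
solve (one shared KKT factorisation for all pixels) and fall back to the
per-pixel active set only where that solution leaves the feasible region,
which keeps a 100×100×426 cube under a second on one CPU.

Numerical choices: rank tolerance 1e-10 relative to the largest singular
value of E (a rank-deficient library raises an error naming the closest
pair of classes rather than returning an arbitrary split); sum-to-one
tolerance 1e-6; post-convergence clamping absorbs only floating-point
dust (≤ 1e-9), never real violations.

`brute_force_unmix` is a test oracle, not a solver: it enumerates the
simplex lattice of spacing `step` (guarded to K ≤ 4) and returns the
residual-minimising point. Agreement between the active set and this
oracle is limited by lattice quantisation: along the least-curved
eigendirection of EᵀE (grass vs. forb spectra are similar) the
lattice-optimal point can sit one objective-equivalent neighbour beyond
the nearest rounding, so the tests assert agreement within two lattice
spacings with the large majority of pixels within one.

## Endmembers and separability

Endmembers are supervised ROI means: the per-band arithmetic mean over
the valid pixels of labelled polygons, pooling multiple regions per label
at the pixel level (equivalently, the pixel-count-weighted mean of region
means). Per-class provenance records pixel counts and per-band standard
deviations; no numeric homogeneity threshold is enforced — ROI quality is
the analyst's responsibility. Separability is quantified by the spectral
angle, arccos of the normalised inner product over valid bands
(scale-invariant, in [0, π/2] for non-negative spectra), reported as a
diagnostic without a default acceptance threshold.

## Preprocessing

Three operations, all of which flip validity flags and never alter
reflectance values:

* `mask_invalid` — a pixel is invalid if any *currently valid* band holds
  the no-data sentinel (−9999 in scaled-integer storage, i.e. −0.9999
  reflectance) or falls below `min_valid` (default 0: negative surface
  reflectance is physically invalid). Restricting the scan to valid bands
  matters: water-absorption bands legitimately contain garbage, including
  negatives, and must not condemn the pixel. Consequently band exclusion
  should run before pixel masking; masking is idempotent and commutes
  with clipping, but not with band exclusion.
* `exclude_bands` — 1-based inclusive ranges at the configuration surface
  (matching how band windows are quoted in the hyperspectral literature),
  converted internally to 0-based half-open. Bands are masked, never
  deleted, so the wavelength axis is stable. The default water-absorption
  preset (bands 192–212 and 282–314) leaves 372 of 426 bands; an
  alternate preset (190–211, 281–314) ships as a named option.
* `clip_to_polygon` — pixel-centre containment (strict interior) against
  a single AOI polygon, optional window crop, retained area reported in
  hectares. Point-to-pixel lookup is half-open: a point on a shared edge
  belongs to the cell to its south-east.

## Change and summary statistics

With two acquisition dates the per-pixel least-squares slope reduces
exactly to (f₂ − f₁)/(t₂ − t₁) in fraction units per year; the
denominator is the calendar-year difference (4 for 2018→2022), which is
what bounds slopes to ±0.25 for fractions in [0, 1] and matches the
published trend-legend bounds. Default trend breaks (−0.085, −0.036,
0.037) partition the slope axis into four lower-inclusive intervals
(decline / moderate decline / moderate gain / gain); breaks are fully
configurable.

Abundance histograms use ten equal-width bins on [0, 1], left-closed
right-open with the last bin closed; abundance categories low/medium/high
break at 0.3 and 0.6, lower-inclusive throughout. The histogram summary
deliberately carries *two* medians under distinct names — the median of
pixel fractions and the median of the ten bin tallies — because published
summary tables conflate them (the tallies' median is what their "Median"
row contains). Weighted area is Σ fraction × pixel area / 10⁴ ha; for a
sum-to-one stack the K class areas tile the valid AOI area exactly, a
conservation law the tests assert on every scene.

## Accuracy assessment

A reference point is predicted as the class whose fraction at its pixel
reaches the threshold τ (0.5 and 0.75 by default); among multiple
qualifiers the largest fraction wins with a lexicographic tie-break, and
points with no qualifier are "unclassified" — counted but excluded from
the matrix. Metrics follow the source tables' convention by default:
user's accuracy = diagonal / reference-row total, producer's = diagonal /
predicted-column total, which is the reverse of the textbook assignment;
`convention="standard"` swaps them. Values are returned unrounded.

The packaged 75 %-threshold validation matrix prints cells summing to 154
although the campaign declared 150 points (50 per class); its published
overall accuracy is trace/150. `ConfusionMatrix` therefore carries an
optional declared reference total used for overall accuracy when present;
per-class accuracies always derive from the printed cells.

## Paired change tests

The change question is answered on paired per-bin pixel tallies (ten
pairs per cover class: the 2018 histogram against 2022). Differences are
screened with the Shapiro–Wilk test (Royston's AS R94 approximation via
`scipy.stats.shapiro`; valid for 3 ≤ n ≤ 5000) and Q–Q points using
Blom-type plotting positions (i − 0.375)/(n + 0.25). Because the
differences are heavily non-normal, the test of record is the Wilcoxon
signed-rank test, implemented exactly: zero differences dropped
(Wilcoxon's original treatment), average ranks for tied magnitudes,
V = sum of positive-difference ranks, and — when |d| is tie-free and
n ≤ 25 — the exact two-sided p from the full 2ⁿ sign distribution built
by integer polynomial convolution, p = min(1, 2·min(P(V ≤ v), P(V ≥ v))).
Ties or n > 25 fall back to a normal approximation with continuity and
tie corrections, flagged in the result's `method` field. The convolution
is cross-checked in the tests against explicit 2¹⁰ enumeration and
against `scipy.stats.wilcoxon`.

## The synthetic scene generator

Real NEON tiles cannot ship with a package, so every stage is exercised
against seeded synthetic scenes with known ground truth, emulating the
NEON AOP Level-3 geometry: 1 m pixels, 426 bands at 5 nm spacing on the
grid 380 + 5k nm (the published band count and printed wavelength range
are mutually inconsistent; the band count is privileged), reflectance
stored as scaled integers (factor 10 000, sentinel −9999).

* **Endmember spectra** are smooth analytic archetypes — vegetation with
  a green bump, red trough, sigmoid red edge, declining SWIR with liquid-
  water dips; soil as a monotone bright ramp with a clay feature — plus a
  small seeded band-correlated perturbation that individualises classes.
  Generation fails if any pair falls below a configurable minimum
  spectral angle.
* **Fraction fields** are per-pixel Dirichlet draws, Gaussian-smoothed
  per layer and renormalised, which preserves exact simplex membership.
  Default concentrations (0.15, 0.12, 0.10) for 2018 and (0.10, 0.13,
  0.13) for 2022 with 0.3 px smoothing reproduce the strongly bimodal
  abundance histograms real rangeland cover shows (most pixels near 0 or
  1) and the herbaceous-decline / bare-soil-gain direction of change,
  while leaving enough ≥0.95-purity pixels for ROI extraction and
  ≥0.75-purity pixels for validation points. Heavier smoothing of i.i.d.
  draws collapses the distribution toward 1/K and destroys purity, so
  smoothing is deliberately mild; spatial autocorrelation is therefore
  short-range only.
* **Rendering** applies the LMM forward (the same model the unmixer
  inverts), adds i.i.d. Gaussian noise per band (default sd 0.01
  reflectance), overwrites the water-absorption windows with
  high-variance garbage, and injects no-data and negative-band defect
  pixels so preprocessing is exercised. At the stressed noise condition
  (sd 0.02) roughly a third of pixels legitimately trip the negativity
  mask in some band; they are excluded from analysis exactly as real
  invalid pixels would be.
* **Reference points** are purity-thresholded stratified samples of the
  ground truth (default 50 per class at ≥ 0.75), mirroring a manual
  validation campaign against recent imagery.

What passing synthetic tests does **not** show: the noise model has no
band correlation, no within-class spectral variability (each class is one
exact spectrum), no BRDF/illumination structure, no flightline seams and
no nonlinear mixing. Parameter-recovery results on these scenes are
therefore an upper bound on what identical settings would achieve on real
tiles.

## Pipeline, sizes, determinism

`run_pipeline` executes simulate → preprocess → endmembers → unmix →
trend → summarize → validate → stats from one TOML configuration
(strict-keys), writing a JSON manifest with a SHA-256 per artifact. All
randomness descends from one integer seed through named
`numpy.random.SeedSequence` spawns; identical configuration and seed
reproduce identical manifests bit for bit. The pipeline's endmember stage
stands in for manual ROI delineation by placing one-pixel square ROIs on
the highest-purity ground-truth pixels of each class.

Default problem sizes — 100×100 pixels × 426 bands × 2 years for the
full pipeline, 100×100 for recovery checks, smaller scenes for unit
tests — were chosen so the whole suite and the acceptance script each run
in well under a minute on one CPU while still exercising the full NEON
band geometry.

## Known limitations

* ENVI support is BSQ/int16 only; no HDF5 AOP tiles, no reprojection, no
  mosaicking of flightlines.
* No MESMA or nonlinear mixing; endmembers are fixed per scene.
* Two-date trends only; no multi-date regression or per-pixel
  significance.
* The exact Wilcoxon path requires tie-free absolute differences; tied
  counts fall back to the normal approximation (flagged).
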