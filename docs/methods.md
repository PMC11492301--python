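# Methods

## Problem and pipeline

The package predicts the mean absolute MLC positional deviation of a VMAT
delivery from pre-delivery information, and relates that deviation to
delivery quality. One *file* is the delivery log of one bank (A or B) of
one field; its deviation is the mean of |actual − planned| over every
0.05 s sample and every leaf, taken as absolute values because leaves
reciprocate and signed errors cancel. A *treatment record* is one delivery
of a two-field plan and contributes four files; its deviation is their
unweighted mean.

The pipeline is: (1) integrate each beam's control points into an
MU-weighted, edge-enhanced fluence and extract GLCM texture features and
the adjacent-aperture Dice; (2) reduce same-day MLC self-check records to
per-bank wear covariates; (3) screen all candidate factors by Spearman
rank correlation and summarize with the multiple-correlation coefficient;
(4) fit a random-forest regressor against a linear baseline; (5) correlate
treatment deviations with gamma passing rates.

## Fluence construction

Apertures are rasterized in collimator-fixed (MLC) coordinates: a pixel is
open iff its center lies strictly between its leaf row's two bank tips and
inside the jaw rectangle. The common beam grid is the bounding box of all
jaw-clipped apertures plus a one-pixel margin. The collimator angle is
kept as metadata rather than rotating the image: the GLCM features are
computed over the four-direction set {0°, 45°, 90°, 135°} and averaged, so
they are covariant under the rotations that matter, and resampling a
rotated binary mask would only add aliasing.

Per-CP monitor units are beam MU × the cumulative-meterset-weight
increment; the first CP delivers nothing but still participates in the
Dice chain. Edge enhancement multiplies each CP mask's boundary pixels
(4-connectivity; 8 available) by 2 before summation, so a stack of small
apertures remains distinguishable from one large one. With edge weight 1
the construction satisfies, exactly, total fluence × pixel area = Σ ΔMU ×
aperture area — the bookkeeping identity used as a machine-precision test.

Default pixel pitch is 0.25 mm (the quarter-leaf projected width) for
standalone fluence export; the analysis pipeline uses 1.25 mm, which
changes feature values by far less than their between-field spread while
keeping a full study cheap. Pitch is rejected when it exceeds the smallest
leaf width (quarter leaves would vanish).

## Texture and Dice features

Fluence is linearly quantized into k = 16 gray levels (binning [min, max];
a constant image maps to level 0). k is unstated in the defining study;
16 is the common texture-analysis default, and features are k-dependent so
k is carried in metadata. GLCMs are symmetric, distance 1, four
directions, features averaged across directions (single values per field
are reported, so an aggregation must exist; the mean is canonical).
Entropy uses log base 2; 0·log 0 ≡ 0.

Two correlation variants are computed. `correlation_paper` reproduces the
defining form Σ (i−Mean)(j−Mean)p(i,j)²/Variance with Mean/Variance the
gray moments of the quantized *image* — unconventional (squared
probability, image-level moments) but consistent with the reported
magnitude of the statistic, so it is the pipeline default;
`correlation_standard` is the textbook GLCM correlation from the marginal
moments of p, cross-checked against scikit-image in the tests.

Dice of two apertures is 2|A∩B|/(|A|+|B|) on the shared raster, with the
0/0 case (both apertures closed) defined as 1 — no shape change. A
raster-free per-leaf interval-overlap oracle cross-checks the rasterized
value. The field Dice is the mean over adjacent CP pairs and is
order-sensitive by construction.

## Wear covariates

Self-check records carry ME, BL, MSC, PWM, LG, LO, CO per leaf ("SC" is
accepted as an alias for MSC). Units of the device-internal quantities are
arbitrary; only ranks and ratios are used. Records are averaged per bank,
and session series are normalized to the first session per parameter;
a zero first-session value leaves that normalized series NaN rather than
fabricated. Repair resets pass through as mutation points. Dynalog files
are matched to wear records of the same calendar date and bank — no
interpolation across dates.

## Screening, multi-correlation, models

Spearman screening uses average ranks and two-sided p-values with
p < 0.05 as the effectiveness criterion (deviations are not normally
distributed); a constant factor yields NaN and is never effective. No
multiple-testing correction is applied by default (matching the screening
convention this pipeline follows); Benjamini–Hochberg is available behind
a flag. The multiple-correlation coefficient is the Pearson correlation
between y and its OLS fit (√R²), with the overall F-test p-value; rank
deficiency is reported with the offending columns named.

Preprocessing is fit on training rows only: z-score by training mean/sd,
then min–max to [0, 1] by the z-scored training extrema; test rows may
fall outside [0, 1] and are not clipped. The forest uses 200 trees, 6
predictors tried per split, minimum leaf size 5 (the regression default),
and variance-reduction splitting — the regression analogue of the Gini
criterion named in the defining text. "Node's number of 6" is read as
mtry because it is tied to the number of inputs. Evaluation: a seeded
0.7:0.3 split; 5-fold CV *inside* the training set with the scaler re-fit
per fold (a leakage test asserts that perturbing held-out rows cannot
change fold scalers); MSE and variance explained per fold; held-out MSE
for both RF and LM on the scaled and raw (mm²) deviation scales, both
reported because the scale of the published MSEs is ambiguous. Both the
OOB pseudo-R² and the CV-fold variance explained are computed, since which
one was reported is unstated. Impurity importances are normalized to sum
to 100%.

## Gamma and delivery quality

The gamma index is globally normalized: dose criterion as a percentage of
the reference maximum, search over a disk of radius 3×DTA sampled at
pitch/3 with bilinear interpolation of the evaluated plane, low-dose
exclusion below 10% of the maximum (TG-218 convention; all three
configurable). Planes on different pitches are commensurated by bilinear
resampling; an optional detector-array resampler (7.62 mm spacing) mimics
a 32×32 ion-chamber array. Pass rates are invariant under joint rescaling
of both planes and monotone under tightening of either criterion.

## The synthetic study

The generator emulates the study conditions rather than any deposited
data (none exists): a balanced crossed design in which every treatment
plan is delivered at every wear session, 2 fields × 2 banks per record.
Defaults: 5 treatments × 10 sessions (200 files) at desk scale; recovery
experiments and the acceptance script use 8 × 16 (512 files, the cohort
scale of ~500–750 files). Dynalogs carry 120 samples (6 s) per file — a
deliberate scale-down from full arc durations that leaves the per-file
sampling error of the mean absolute deviation below 1%.

*Plans.* Sliding apertures on the HD120 geometry whose center
reciprocates sinusoidally: the oscillation frequency scales with a
per-field jitter knob (so zero jitter freezes the aperture and field Dice
is exactly 1) while the swept amplitude is drawn independently — this
decouples temporal variability (Dice) from fluence texture. A roughness
knob shapes static leaf-edge irregularity; aperture height, width scale,
MU and collimator angle vary per field. Resulting field Dice averages
≈0.90, matching observed VMAT values.

*Wear.* Per-parameter linear drifts (BL, MSC, LO, CO up; ME, PWM down; LG
flat — the planted null) with relative session noise 0.035 and a static
leaf pattern; the noise deliberately dominates the slow trends so that
different parameters are not trend-collinear. Optional repair resets
restart the drift clock for BL/MSC/PWM, appearing as mutation points in
the normalized series. Banks differ in baseline.

*Planted deviation model.* Each file's target deviation is
μ = 0.41 − 0.035·z(dice) − 0.035·z(homogeneity) − 0.035·z(PWM)
[+ 0.025·z(dice)z(PWM) + 0.02·(z(homogeneity)²−1) when nonlinear]
+ N(0, 0.012²), floored at 0.05 mm, where z(·) are within-study z-scores
of the *measured* covariates (within-bank for PWM — the banks have
distinct mechanical states and are analyzed separately). The intercept is
the clinically typical cohort mean; the slopes were chosen once so the
planted Spearman magnitudes land in the 0.3–0.5 band reported for real
cohorts and deviations stay in the plausible 0.3–0.6 mm range. Leaf noise
is half-normal in magnitude with random sign (i.e. Gaussian), scaled so
E|actual − planned| equals μ — matching the absolute-deviation statistic
directly.

*Dose pairs.* A smooth reference dome plus a spatially correlated
perturbation of amplitude 6 cGy per mm of deviation on a 61×61, 4 mm
plane (24.4 cm square, the usual QA plane), giving 2%/2 mm passing rates
in the low-90s at typical deviations.

What the generator does *not* emulate: leaf-velocity limits and beam
holds, transmission/leakage and tongue-and-groove effects, dose engines,
or physically modeled motor aging. Passing recovery tests therefore shows
that the pipeline identifies planted covariate structure of realistic
magnitude at realistic sample sizes — not that any specific clinical
coefficient is reproduced.

A structural caveat: GLCM entropy, energy and (standard) correlation are
intrinsically collinear with homogeneity (|r| ≈ 0.85–0.95 in any
aperture-fluence family) and are driven by the same latent plan knobs as
the planted features. They act as *confounded surrogates*: screening
flags them as effective (as real cohorts do) and the forest shares
importance with them. Recovery tests therefore compare planted importances
against the causally null covariates (ME, BL, MSC, LO, CO — the LG
analogues among the model inputs), not against these surrogates.

## Numerical and degenerate-input conventions

Strict pixel-center-in-open-interval rasterization (closed pairs
contribute nothing at any pitch); dynalog positions stored as integer
centi-millimeters, so writing is byte-stable and round-trips are exact at
file resolution; Spearman of a constant factor is NaN/ineffective rather
than an error; gamma requires a positive reference maximum and a search
radius of at least one DTA; RF results are deterministic given the seed,
and every generator is a pure function of (config, seed) with child
streams keyed by purpose, so regenerated studies are hash-identical.

The "forest reaches the Bayes floor" property is asserted at a noise
level (0.04 mm) where the irreducible noise dominates the unexplained
variance; as noise → 0 the floor vanishes while estimation error does
not, so no finite-sample learner can sit within a constant factor of it.

## Known limitations

DICOM-RT reading is a thin adapter for standard RT Plan objects (MLCX,
carried-forward attributes) and has been exercised against synthetic
datasets, not vendor exports. The gamma search is exhaustive over a disk
rather than adaptive, which is exact but O(offsets × pixels). The exact
pixel pitch and gray-level count of the original fluence analysis are
unpublished; ours are reasoned defaults, so absolute feature values are
comparable only within a fixed configuration.
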