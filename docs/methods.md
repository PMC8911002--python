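# Methods

This note documents the models, numerical choices and limitations behind
`ftirstress`. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Spectral model and preprocessing

Spectra live on the canonical ascending grid of integer wavenumbers
400–4000 cm⁻¹ (3601 points). Instrument displays often show the axis
descending; storage order is ascending so that index(ν) = ν − 400.

Preprocessing is a fixed two-step sequence:

1. **Baseline correction.** The straight line through (400, A(400)) and
   (4000, A(4000)) is subtracted, so both endpoints become exactly zero.
   The anchors are the single absorbance values at those wavenumbers — no
   window averaging. Interior values may become negative and are kept:
   clipping would destroy the linearity of the operator
   (correct(s₁+s₂) = correct(s₁)+correct(s₂)), which the tests rely on.
2. **Total-sum normalization.** The spectrum is rescaled so its signed sum
   equals 10⁶. The operation is idempotent and invariant to positive
   rescaling of the input; a nonpositive signed sum (an empty or
   pathological trace) is an error, optionally a drop at the set level.

The order baseline-then-normalize is fixed; reversing it would change the
result because the chord of a rescaled spectrum differs. Scale and offset
changes of a raw trace are absorbed completely by the two steps, which is
what makes downstream class predictions invariant to per-scan gain and
offset.

## Synthetic data generator

The generator emulates the study conditions the pipeline is meant for:
two classes (control / heat), 6 plants per class, 10 pressed-pellet disks
per plant, 3 repeat scans per disk, with one heat-class disk scanned only
once — 180 control and 178 heat raw spectra.

Each trace is a mixture of Gaussian bands: the twelve major leaf bands
(3293, 2960, 2925, 2852, 1651, 1541, 1385, 1241, 1158, 1106, 1055,
618 cm⁻¹), one broad envelope (center 3250 cm⁻¹, σ 230) spanning
2700–3700 cm⁻¹, and narrow "marker" bands at 1465, 1729, 1251, 576, 1502
and 482 cm⁻¹ (σ 3–6). Band widths and amplitudes are synthetic choices
shaped to the qualitative morphology of a dried-leaf KBr-pellet spectrum.

**Class effects** are multiplicative factors on the amplitude of the band
nearest the stated effect wavenumber, applied in the heat class only.
Multiplicative (not additive) effects survive total-sum normalization as
relative compositional shifts. The default recovery conditions implant
three effects: ×1.30 at 1465, ×1.22 at 1729, ×0.75 at 1251. The published
six-marker pattern (up at 1465/1729, down at 1251/576/1502/482) is
available as `study_marker_effects()`. No quantitative effect sizes exist
for the real data; these magnitudes were chosen once so that the
generator's own recovery properties (≥ 95% test accuracy; ≥ 2 of 3
implanted wavenumbers recovered within ±10 cm⁻¹ with correct direction;
chance-level behavior under the null) hold with margin, and they are
documented here as synthetic choices.

**Noise** has four parts, with defaults in absorbance units:

| component | default | meaning |
|---|---|---|
| plant_sd / disk_sd / repeat_sd | 0.05 / 0.03 / 0.02 | log-scale sds of per-band log-normal amplitude factors at each hierarchy level (amplitudes are positive, hence log-normal) |
| baseline_slope_sd | 2×10⁻⁵ /cm⁻¹ | per-scan linear drift (removed exactly by baseline correction) |
| floor_sd | 0.004 | white detector-noise floor at every grid point |
| knurl_sd (405–480 cm⁻¹) | 0.004 | extra independent noise in the low-wavenumber knurl interval |

The white floor matters for realism and for the discriminant: without it,
wavenumbers far from every band have near-zero within-class variance, and
an unregularized Fisher solve amplifies chance class differences there by
1/variance, burying the real markers under noise-region extrema. Real
spectrometers always have a broadband noise floor; adding one restores the
expected behavior.

Every random draw uses a `numpy` SeedSequence keyed by
(seed, class, level-tag, plant[, disk[, repeat]]), so the draw for one
cell is independent of the design around it: shortening one disk to a
single repeat does not perturb any other spectrum.

**What the generator does not emulate:** physically meaningful band shapes
(Voigt profiles, self-absorption), KBr-matrix band shifts of up to
~15 cm⁻¹, correlated (non-white) detector noise, atmospheric CO₂/H₂O
features, or scatter effects. Passing tests on this generator therefore
demonstrate the correctness and statistical behavior of the pipeline under
the stated design, not the biological validity of any specific marker on
real leaves.

## PCA and the discriminant

PCA is centered but not scaled (covariance PCA): the spectra are already
total-sum normalized, and per-wavenumber scaling would inflate baseline
regions. Whether the original analysis used covariance or correlation PCA
is not stated; covariance is this package's choice.

The discrimination problem has p = 3201 features (400–3600 cm⁻¹) and only
~215 training spectra, so the within-class scatter matrix is singular in
the raw feature space and a direct Fisher solve does not exist. The
classifier therefore (a) reduces the training spectra to a
rank-`pca_rank` PCA subspace (default 40, configurable), (b) computes the
Fisher direction w = S_w⁻¹(μ_heat − μ_control) there, and (c)
back-projects w through the orthonormal PCA basis to a unit-norm loading
curve over wavenumbers. Because the basis is orthonormal, scoring a
spectrum against the back-projected loadings is exactly equivalent to
scoring its PCA coordinates against w (verified to 10⁻⁸ in the tests).
This PCA-LDA construction is the standard regularization for collinear
spectroscopic data; it is a documented divergence from applying a
canned LDA routine directly to all 3201 features.

Conventions: LD1 sign is fixed so the heat training mean is positive; the
decision threshold is the midpoint of the two training-class means (no
threshold is stated for the original analysis; histograms separate near
zero). The train/test split is stratified by class at
round(ratio·n_class) — 108 + 107 = 215 training spectra at 60:40 on
180/178 — with the rounding rule as this package's convention.

**Pseudo-replication.** The default split (`grouping="none"`) randomizes
at the spectrum level, matching the original analysis. Repeat scans of one
disk and disks of one plant are then shared between train and test, so
test accuracy partly reflects replicate memorization: each plant belongs
to exactly one class, and plant-level random effects are class-confounded.
`grouping="by_disk"` / `"by_plant"` are provided to avoid this leakage.
For the same reason the package's chance-level reference ("null design")
uses no class effects **and** only repeat-level iid noise: with per-plant
effects, a spectrum-level split would push no-signal test accuracy far
above 0.5 through leakage rather than signal, which would say nothing
about the classifier.

## Marker discovery

Targets are local extrema of the LD1 loading curve with |loading| > 0.15
(the published threshold), thinned so that extrema closer than
`min_separation` (default 10 cm⁻¹) keep only the larger magnitude.

Anchor candidates are restricted to *landmarks* of the pooled mean
spectrum — local maxima, minima, and inflection points (sign changes of a
Savitzky–Golay second derivative; window 11 points, polynomial order 3).
The landmark restriction makes the scan deterministic and matches the
stated intent that anchors sit at visually discernible features;
`anchor_mode="grid"` relaxes it to every grid point. For a target ν, a
candidate pair must lie within 150 cm⁻¹ on *opposite sides* of ν (every
published marker has opposite-side anchors). A pair is inadmissible if any
spectrum has |A_anchor2 − A_anchor1| < 10⁻¹², or if the two-sided pooled
Student's *t*-test on Fm values gives p ≥ 10⁻⁴ (Welch's test is available
via `equal_var=False`). Among admissible pairs the smallest p wins; ties
break by total anchor distance, then by the lower wavenumber pair.

Anchor orientation is not derivable from the published tables (neither
distance nor side order is consistent there), so this package fixes:
anchor1 is the anchor with the lower pooled-mean absorbance (the "0" end)
and anchor2 the higher (the "1" end). An increase in target absorbance
then increases Fm, which keeps marker direction aligned with the sign of
the LD1 loading.

No multiple-testing correction is applied in the scan — the 10⁻⁴
threshold is taken as given, as in the original procedure. With ~10–30
candidate pairs per target this inflates the per-target false-positive
rate above 10⁻⁴; the null-simulation tests bound the observed rate at the
target level (≤ 5% of probed targets over 20 seeds).

Diagnosis is deliberately simple plumbing: per marker, a spectrum votes
heat when its Fm lies on the heat side of the midpoint between the two
class medians; the overall verdict is the majority vote, abstaining on
ties (including an Fm exactly at a midpoint).

## Numerical and degenerate-input choices

- Normalization tolerance: preprocessed spectra sum to 10⁶ within 10⁻³
  absolute (floating-point headroom only).
- A singular within-class scatter at the requested PCA rank raises with
  advice to lower `pca_rank` rather than silently regularizing.
- `evaluate_marker` flags a zero control median (ratio undefined → NaN).
- CSV round-trips are bit-exact: values are written via shortest-repr
  and read with round-trip float parsing.
- Input grids finer than 1 cm⁻¹ are linearly interpolated onto the
  canonical grid; coarser or incomplete grids are rejected rather than
  extrapolated.

## Problem sizes

The test suite and acceptance script run the full 358-spectrum design end
to end (simulation, PCA, rank-40 PCA-LDA, marker scan) and repeat the
null design 20 times for the chance-level and false-positive properties;
these sizes match the study design exactly, so nothing is scaled down.

## Known limitations

- The measured spectra of the original study are not deposited, so
  data-dependent published numbers (e.g. the 81.1% PC1–PC2 variance or the
  exact Table of median Fm values) are not reproducible; the package
  reproduces the *procedures* and the published worked arithmetic, and
  validates statistical behavior on synthetic data.
- The Fm scan's tie-breaking and anchor-orientation rules are this
  package's conventions where the original procedure is silent.
- Fisher LDA assumes shared within-class covariance; the pooled t-test
  ignores the replicate hierarchy (as did the original analysis), so
  p-values on real nested data are anti-conservative.
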