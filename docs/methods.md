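# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic acquisition model

Every downstream stage is validated against cohorts from
`neuroraman.synthetic`, which emulates intracranial probe acquisition with
full ground truth.

**Spectral model.** A clean sample spectrum is
`y(ν) = Σᵢ cᵢ Kᵢ(ν) + b(ν)` on the fingerprint grid 600–1800 cm⁻¹ at
1 cm⁻¹ spacing (the full probe domain −200 to 3723 cm⁻¹ is available via
`full_probe_axis` but is not the default: every band the analysis interprets
lies in the fingerprint region). Component spectra `Kᵢ` are sums of
pseudo-Voigt bands — amplitude-normalised convex mixes of a Lorentzian and a
Gaussian of equal FWHM, the standard line shape for condensed-phase Raman;
the default Lorentzian fraction is 0.5 (0.6–0.7 for the heme bands, which
are typically broader-tailed). The five-component basis:

| component   | main bands (cm⁻¹, relative amplitude) | role |
|-------------|----------------------------------------|------|
| cardiolipin | 1266 (1.0), 1660 (0.95), 1440 (0.35), 1080 (0.2) | injury marker; carries the unsaturated-lipid bands |
| ganglioside | 1337 (0.8), 1447 (0.55), 1063 (0.3), 1656 (0.25) | CH deformation / carbohydrate region |
| hemoglobin  | 754 (0.8), 1337 (0.55), 1545 (0.45), 1620 (0.35) | blood contamination |
| cholesterol | 700 (0.65), 1440 (0.9), 1130 (0.3), 1672 (0.25) | sterol CH₂ bending |
| protein     | 1003 (1.0), 1447 (0.7), 1660 (0.55), 1240 (0.35) | phenylalanine marker, amide I/III |

Components are peak-normalised so mixing coefficients are comparable. Band
positions follow the published brain-tissue assignments (1003, 1266, 1337,
1447, 1660 cm⁻¹ as the diagnostic set); amplitudes and widths are plausible
stand-ins, not reproductions of any measured library — the reference lipid
library used in the original tissue work is not deposited, so this basis is
synthetic by construction.

**Cohort structure.** Default study conditions: two classes
(control / TBI), 20 samples per class, per-sample coefficients drawn from a
zero-truncated normal around the class means with coefficient of variation
0.15, TBI cardiolipin mean at 50 % of control. Moderate-injury cohorts are
produced by intermediate depletion factors. Each sample is emitted as 15
accumulations (the probe's acquisition setting) with i.i.d. Gaussian channel
noise (default sd 0.01 ≈ 1 % of a unit component peak; a Poisson option is
available but off by default, since at these count levels the Gaussian
approximation to detector noise is adequate) and Poisson-count cosmic-ray
spikes (default rate 0.2 per accumulation; 1–3 channels wide; amplitude
10–30× the spectrum's MAD-based robust scale, making detection well-posed).
The fluorescence background is
`A·exp(−(ν−ν₀)/τ) + A·κ·(1−u²)` with amplitude A = 5 (several times the band
amplitudes, as in real tissue fluorescence), decay τ = 800 cm⁻¹ and dome
curvature κ = 0.3. Cohorts are bit-reproducible from their seed.

**What the generator does not emulate:** instrument response and wavelength
calibration drift, quartz-window and dark-current contributions, detector
etaloning, spatial heterogeneity within a sample, and any physical optics of
the probe. Passing tests therefore demonstrate correctness of the analysis
chain under the stated statistical model, not instrument-level robustness.

## Preprocessing

**Cosmic-ray removal.** Spikes are uncorrelated across accumulations, so
each accumulation is compared channel-wise against the median over the stack
("nearest neighbours" in acquisition order). The deviation threshold is a
robust z-score: per-channel MAD·1.4826 across accumulations, floored by the
median per-channel scale so noise-free channels cannot produce zero
thresholds, with cutoff z = 8. Detection is one-sided (spikes are additive).
Flagged values are replaced by the median of the unflagged accumulations at
that channel; the despiked stack is then averaged. With a single
accumulation there is no neighbour stack and the function falls back to
second-difference-based within-spectrum interpolation, with a warning. The
operation is idempotent.

**Baseline subtraction.** The background is modelled as a cubic B-spline on
11 equally spaced nodes — the one parameter the underlying tissue study
states — and fitted by iteratively re-weighted penalised least squares.
After each pass, points far above the fit relative to the spread of the
negative residuals are down-weighted by a smooth logistic (the arPLS
weighting); points below keep weight one, so the spline settles onto the
lower envelope (the fluorescence) and ignores the bands. A second-difference
penalty on the spline coefficients (`smoothness`, default 1.0) keeps the fit
smooth across band-dense spans where almost no baseline-only channel
remains. Iteration stops when the fitted curve changes by less than
10⁻⁵·max|y| (typically 30–50 passes; cap 50, warning on non-convergence,
e.g. for peak-free inputs whose weights keep adapting at negligible fit
change). Binary asymmetric re-weighting was tried first and is numerically
unstable at small asymmetry weights; an unpenalised knot spline oscillates
across masked spans. Post-subtraction negatives are retained — clipping
would bias the NNLS step.

Known limitation: where pseudo-Voigt tails of neighbouring bands overlap
(1440–1680 cm⁻¹), the inter-band valleys never touch the true baseline, so
any envelope-tracking method sits slightly high there. On default cohorts
this costs up to ~5–6 % of the 1660 cm⁻¹ peak height in the
cardiolipin-depleted class (mean error across bands ≈ 2 %); on isolated
bands the error is within 5 %. The tests assert exactly these bounds.

**Resampling** is linear (cubic available) to avoid ringing at sharp bands,
and refuses to extrapolate. **Normalisation** is unit-L2 ("vector") for SOM
distances and off for NNLS — the underlying study does not state its
normalisation, so this is exposed in the config.

**Band metrics.** `peak_height` is the window maximum of the
baseline-corrected spectrum (default half-window 10 cm⁻¹);
`band_ratio(1447, 1660)` is the injury metric.

## SKiNET: hexagonal SOM with label vectors

The map is a pointy-top hexagonal grid in axial coordinates (odd-row offset
layout converted to axial; hex distance via the cube-coordinate formula).
Defaults: 10×10 neurons for cohorts of a few dozen spectra, online Kohonen
training for 100 epochs, learning rate decaying exponentially 0.5 → 0.01,
Gaussian neighbourhood kernel with radius decaying max(grid)/2 → 1,
initialisation by seeded random sampling of training spectra (plus 10⁻⁶
jitter so duplicate picks are not bit-identical; PCA-span initialisation
available). Distances are Euclidean on vector-normalised spectra (cosine
available). All ties break to the lowest linear index / first-listed class
for bit-reproducibility. These training choices are engineering defaults,
not reproductions — the original study states neither grid size nor
schedule.

Label vectors are co-trained: each neuron's label vector moves toward the
sample's one-hot class with the same kernel-weighted step as the weights.
Because the update is a convex combination starting from zero, label weights
stay in [0, 1] with row sums ≤ 1 throughout training — the supervised step
is integral to training rather than a post-hoc neuron labelling, which is
one admissible reading of the original description and is documented here as
this package's definition. Classification returns the BMU's label argmax
with confidence = that label weight normalised over classes.

**SOMDI.** For class c the discriminant vector is
`Σₙ (Lₙ,c − mean_{c'≠c} Lₙ,c') · Wₙ / Σₙ‖Wₙ‖`. The mass normalisation (not
unit norm) is deliberate: when the class distributions coincide the label
contrasts cancel and the discriminant magnitude collapses to the
label-permutation noise floor, which the tests exploit as a null control.
Positive peaks mark class-characteristic wavenumbers; fitting the component
library to the positive part by NNLS attributes the activation to
components.

Note that on vector-normalised spectra, depleting one component makes every
other component's bands *relatively* discriminative too: the generative
discriminant set of a cardiolipin-depletion cohort contains, beyond the five
diagnostic bands, weaker features at e.g. 700, 754 and 1081 cm⁻¹. The
validation therefore scores SOMDI peaks against the generator's own
discriminant band set — peaks of the noiseless normalised class-mean
difference above a conventional 10 % prominence floor — and additionally
requires the three strongest SOMDI features to come from that set's top
five, which are exactly 1266, 1660, 1447, 1337 and 1003 cm⁻¹.

## Unmixing and group statistics

NNLS (`scipy.optimize.nnls`) fits peak-normalised components, by default
with a constant offset column to absorb residual baseline; the offset
coefficient is constrained non-negative like the others. Fits are to
per-sample average spectra, not per accumulation. Optimality is checked in
the tests via the KKT conditions (zero gradient on active components,
non-negative gradient on bound components) and, on small problems, against
an exhaustive non-negative grid search at step 10⁻³. Group comparison is a
per-component one-way ANOVA with no multiple-testing correction by default
(Bonferroni by flag); zero between-group variance is reported as F = 0,
p = 1 rather than NaN.

## Pipeline, formats, determinism

The `run_pipeline` orchestration (also `neuroraman run`) chains
simulate/read → preprocess → stratified 70/30 split → SOM training →
classification → SOMDI → NNLS → ANOVA → JSON report, writing every artifact
plus a manifest of SHA-256 checksums. With identical config and seed, every
artifact is bit-identical (the manifest's wall-clock timestamp is outside
the checksum set). Spectra are read/written as two-column CSV (header
auto-detected, descending axes re-sorted with a warning) and minimal
JCAMP-DX `(XY..XY)`; configs are YAML with a mandatory seed; exit codes
distinguish config (2), parse (3) and numeric (4) errors.

## Problem sizes in tests and validation

Unit tests run on reduced grids (4×4–6×6 maps, 20–40 spectra, a few cohort
seeds); the validation script uses the full study conditions (20
samples/class, 15 accumulations, 10×10 map, 5 cohort seeds, 20
label-permutation replicates, exhaustive 2- and 3-component grid searches at
step 10⁻³). These sizes were chosen as the smallest that make each
statistical assertion stable across seeds.

## Known limitations

- Coefficients are concentration *proxies*: no absolute calibration is
  attempted, and the component basis is a synthetic stand-in.
- The baseline's valley-floor bias (above) is intrinsic to envelope methods
  under heavy band overlap; a joint baseline-plus-components fit would
  remove it but is out of scope for a standalone preprocessing step.
- The permutation-null confidence of the SOM classifier is the only
  uncertainty measure exposed; no calibration of label-weight confidences.
- Single-accumulation despiking is a best-effort fallback and cannot
  distinguish a genuine 1-channel band from a spike.
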