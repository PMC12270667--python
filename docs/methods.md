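# Methods

This note documents the models, default parameters, numerical choices, and
known limitations of the `lamline` package.

## Divisive-normalization pRF model

The spatial response of a cortical patch to a binary stimulus aperture S on
a raster covering the screen is

    R(S) = (amp_act · ⟨S, G1⟩ + b) / (amp_norm · ⟨S, G2⟩ + d) − b/d

with G1, G2 unit-amplitude isotropic Gaussians at the pRF position, widths
sigma1 (activation pool) and sigma2 ≥ sigma1 (normalization pool). The −b/d
term anchors the empty stimulus at exactly zero. Inner products are raster
sums at a configurable resolution (default 20 px/dva; desk-scale accuracy —
the encircled-energy error of a rasterized disc is below 1% at 50 px/dva and
around half a percent at small radii). Size-tuning curves use 101 radii
uniformly on [0, 10] dva; argmax ties break toward the smaller radius
(smallest maximal stimulus). On a finite screen the no-suppression curve
plateaus once the disc covers the raster, so "argmax at the largest radius"
holds in the sense that the last radius attains the maximum.

Checkerboard stimuli use 2 radial cycles per dva of radius and 1 angular
cycle per dva of outer radius; the angular cycle count is rounded to the
nearest integer ≥ 1 so the wedge pattern closes at the 2π wrap (a fractional
count would create a seam; the alternative — scaling angular frequency with
ring width instead of outer radius — is not implemented). The medium annulus
warns about spatial overlap only when its 2-dva ring does not fit strictly
between the center-disc edge and the large-annulus outer edge; by
construction a mid-way 2-dva ring usually touches the large annulus' inner
portion, which is tolerated ("preferably without overlap").

Candidate-patch selection keeps pRFs with eccentricity in [1.5, 3] dva, at
least 1 dva from the vertical meridian, variance explained r² > 0.55
(strict), and sigma1 > 0.50 dva (strict).

## Synthetic sessions

The generator defines the study conditions; its defaults are fixed:

- **Paradigm** — 3 conditions × 5 events per run, 2-s flicker presentations,
  onset-to-onset ISIs from min + truncated-exponential excess with
  min/max/mean = 14/24/18 s (the exponential scale is solved with Brent's
  method so the truncated mean is exact), preceded by 42 s dummy + 30 s
  baseline, all inside a 7-min run; two timing variants with different
  pseudorandom orders and ISIs, reproducible from (variant, seed).
- **Line geometry** — 16 voxels at 0.25 mm, TR = 0.105 s, gray-matter ribbon
  of 6–10 samples (default 7, indices 5–11, pial at the lower index);
  outside the ribbon, signal is attenuated to 5% to emulate outer-volume
  suppression.
- **Ground-truth laminar profiles** (percent signal change as a function of
  normalized depth d, 0 = pial): center = 1.5·(1 − d) + 0.4·N(d; 0.5, 0.1)
  — a superficial (draining-vein-like) gradient with a small middle-depth
  peak; large = 1.0·N(d; 0.25, 0.12) + 0.8·N(d; 0.75, 0.12) −
  0.5·N(d; 0.5, 0.12) — bimodal with a negative middle deflection; medium =
  equal mixture of the two. N is a unit-max Gaussian. Amplitudes are
  order-of-magnitude typical for event-related laminar BOLD (~1% signal
  change) and were chosen so the center stimulus produces the largest
  depth-averaged response, matching its role as the tuning-curve optimum.
  Because the mixture components overlap, the large profile's modes sit
  ~0.01 off the nominal 0.25/0.75 placements.
- **HRF** — two-gamma kernel sampled at TR with gamma shapes 7 and 17 (unit
  scale), i.e. positive-lobe mode exactly 6 s and undershoot mode 16 s,
  undershoot ratio 1/6, unit peak. A 2-s boxcar convolved with it peaks near
  7 s.
- **Noise** — AR(1) (ρ = 0.3, sd 0.8), white noise (sd 0.4), and
  participant-specific slow cosine drift (3 components), in raw units on a
  baseline of 100 (so sd 1 = 1% signal). The real data's drift and
  physiological spectra are unknown; these are stand-ins, configurable in
  `NoiseConfig`.
- **Leakage** — unidirectional carry model: each depth bin passes fraction
  λ (default 0.3) of its accumulated venous signal one step toward the
  surface, giving a lower-triangular matrix L[i,j] = λ^(i−j) in WM-first
  order. A constructor accepts a full published coefficient table from JSON
  instead; the parameterized model keeps tests self-contained.
- **Multi-echo** — optional: echoes at TE = 6, 14, 22, 30, 38 ms with
  mono-exponential decay (T2* = 33 ms in gray matter, 20 ms outside).

What the generator does **not** emulate: motion, cortical curvature and
partial-volume mixing, vessel-specific T2* heterogeneity, respiratory or
cardiac quasi-periodic noise, and nonlinear BOLD saturation. Passing tests
therefore demonstrate correctness of the analysis chain, not robustness to
every artifact of real line-scanning data.

## Preprocessing

- Percent signal change uses the per-depth temporal **median** as baseline
  (robust to sparse evoked excursions; whether the original analysis used
  mean or median is not determinable, and with < 50% of samples stimulated
  the median equals the true baseline exactly in the noiseless limit).
- Epochs span −2…14 s around onsets with a fixed length of
  round(16 s / TR) = 152 samples; starts align to the nearest sample at or
  before onset − 2 s with no temporal interpolation. Each epoch is
  baseline-corrected by its mean over the pre-onset samples. Averaging is
  within timing variant first, then across variants, so unbalanced epoch
  drops do not bias one event order.
- Re-gridding restricts to the gray-matter ribbon (bounds from the sidecar,
  standing in for manual boundary delineation) and linearly interpolates to
  20 evenly spaced normalized depths; nearest/cubic alternatives are not
  needed because interpolation choice only matters below the ribbon's
  sampling density.
- Inclusion QC: per-line-position r² from an OLS on the HRF-convolved
  center-event regressor; a session is included when the center peak-window
  response exceeds all other conditions and the center profile shows the
  draining-vein signature (superficial third > deep third). A ±2-sample
  ribbon shift maximizing mean in-ribbon r² is reported; the original
  procedure's shift rule is qualitative, so this is a deterministic
  stand-in.

## Depth profiles and laminar model

Template weighting divides by Σₜ h_T of the raw (not absolute) template
values, as the expression is written; a near-zero template sum raises rather
than returning unstable ratios. Participant normalization (subtract own
depth-mean, add grand mean) is idempotent and preserves the group mean.

The laminar design places unit-max Gaussians at 25% and 75% depth
(sigma_g = 0.12 normalized depth by default — FWHM ≈ 28% keeps the peaks
separable on 20 points; the design stays numerically full-rank for
sigma_g ∈ (0.05, 0.3)). Derivative regressors are analytic depth-derivatives
of each Gaussian scaled to unit max-absolute (the derivative-with-respect-
to-peak-position convention differs only in sign). The drain regressor is
1 − d (linear, maximal at the pial surface) or exp(−d/τ), τ = 0.25, both
zero-meaned so the intercept stays interpretable; whether the original
design zero-meaned its linear term is unknown, but β_context is invariant
to that choice since it excludes intercept and drain. β_context sums the
four contextual coefficients. Deconvolution solves the lower-triangular
system L·x = measured by forward substitution from the uncontaminated
deepest bin.

Fitting is OLS (`numpy.linalg.lstsq`); with 20 observations and 6 regressors
this is exactly determined and needs no regularization. Group comparison
uses pingouin's one-way ANOVA (partial η²) and Holm-corrected pairwise
t-tests with Cohen's d. With 11 synthetic participants the cohort sizes
match the original inclusion count; the linear mixed-effects variant is
deliberately replaced by participant-level tests, since the random-effects
structure of the original model is unspecified.

## Problem sizes and determinism

Monte-Carlo checks use 200 seeded replications (estimator calibration and
cohort-contrast direction), 100,000 draws for the ISI-mean check, and 1000
seeds for paradigm validity; these sizes give Monte-Carlo error well below
the tolerances tested. Every stochastic component takes a
`numpy.random.Generator` or integer seed, and full-pipeline outputs are
bit-reproducible given (config, seed).

## Known limitations

- The DN-model parameter values of real participants are unknown; defaults
  (amp_act = 1, amp_norm and d configurable) are placeholders that produce
  realistic size tuning, not participant estimates.
- β_context from template-weighted profiles is in arbitrary units that scale
  with generator amplitudes; only signs, orderings, and ratios are
  comparable across analyses.
- Exact noiseless round-trip recovery holds for single-condition runs; in
  mixed runs, epoch windows overlap the tail (undershoot) of preceding
  events of other conditions, which biases profiles at the fraction-of-a-
  percent level — a property of event-related designs, not of this
  implementation.
- Group inference assumes independent participants; run-level nesting is
  averaged out before testing.
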