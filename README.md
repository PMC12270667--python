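# lamline

Depth-resolved analysis of line-scanning fMRI responses to pRF-tailored
visual stimuli.

## The problem

Ascending (feedforward) and descending (contextual) cortical connections
terminate in different layers of primary visual cortex: feedforward input
from the thalamus arrives in the middle layers, while contextual input from
neighboring neurons and higher-order areas targets the superficial and deep
layers. Line-scanning fMRI samples a single cortical patch every 0.25 mm
along the cortical depth at TR ≈ 105 ms, giving 6–10 data points across gray
matter — enough to resolve these laminar signatures non-invasively. By
presenting stimuli tailored to a patch's population receptive field (pRF) —
a small disc in the pRF center versus large annuli in its surround — the
relative contribution of stimulus-driven and contextual processing can be
manipulated and read out as a profile of BOLD amplitude across cortical
depth.

This package implements that analysis chain end to end, together with a
synthetic session generator with known laminar ground truth so every stage
is testable without any scanner data:

1. **Stimulus design** (`lamline.prf`) — divisive-normalization (DN) pRF
   model. The response to a binary stimulus aperture S is

   R(S) = (a₁⟨S, G₁⟩ + b) / (a₂⟨S, G₂⟩ + d) − b/d,

   with G₁, G₂ isotropic Gaussians of widths σ₁ ≤ σ₂ (activation and
   normalization pools). Size-tuning curves over disc radii 0–10 dva pick
   the center stimulus; screen geometry fixes the largest 2-dva-wide
   annulus; the medium annulus sits halfway between.
2. **Synthetic sessions** (`lamline.simulate`) — event-related runs (five
   2-s presentations per condition per 7-min run, ISIs jittered 14–24 s with
   mean 18 s from a truncated negative exponential, ~42 s dummy + 30 s
   baseline), distinct ground-truth laminar profiles per condition, a
   unidirectional draining-vein leakage model, AR(1) + drift noise, and
   optional multi-echo output (TE = 6…38 ms).
3. **Preprocessing** (`lamline.preprocess`) — echo combination
   (sum-of-squares or T2*-weighted), Savitzky-Golay smoothing (31 samples,
   3rd order), percent signal change, epoching over −2…14 s with pre-onset
   baseline correction, and linear re-gridding of the gray-matter ribbon
   onto 20 evenly spaced depth points (0 = pial, 1 = white matter).
4. **Depth profiles** (`lamline.profiles`) — template weighting: the
   group-average center response collapses each depth's time course into a
   single amplitude, profile(d) = Σₜ h_d·h_T / Σₜ h_T.
5. **Laminar model** (`lamline.model`) — a 6-regressor GLM over depth
   [intercept, drain, G(0.25), G(0.75), G′(0.25), G′(0.75)]; the summary
   statistic **β_context** is the sum of the last four coefficients.
   Draining-vein effects are handled by the drain regressor (linear or
   negative-exponential) or by deconvolving profiles with a lower-triangular
   leakage matrix.
6. **Group statistics** (`lamline.pipeline`) — one-way ANOVA and
   Holm-corrected pairwise tests on β_context across conditions.

## Worked example

```bash
python analysis/01_design_stimuli.py
python analysis/02_run_cohort_pipeline.py
python analysis/03_vascular_robustness.py
```

`02_run_cohort_pipeline.py` simulates 11 participants (two timing-variant
runs each) and prints:

```
included 11 / 11 participants

beta_context by condition (mean +- SEM):
  center    -2.29 +- 0.28
  medium     8.77 +- 0.46
  large     19.78 +- 1.24

one-way ANOVA: F = 200.51, p = 4.36e-18, partial eta^2 = 0.93
```

The ordering is the package's core result on synthetic data: the large
annulus (contextual surround stimulation) yields strongly positive
β_context — a bimodal profile peaking at superficial and deep depths — while
the center stimulus (feedforward drive) yields negative β_context, its
profile being dominated by the draining-vein gradient with reduced
middle-depth bimodality. The medium annulus falls in between. Note that
β_context magnitudes are in template-weighted units and scale with the
generator's amplitudes; only the ordering and signs are meaningful.
`03_vascular_robustness.py` shows the ordering is preserved with either
drain regressor and with leakage deconvolution on or off (win rate 1.0 over
200 cohorts).

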