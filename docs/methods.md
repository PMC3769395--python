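# Methods

`deepmeg` implements a deep-brain MEG source-imaging analysis around a
synthetic replica of a 2×2 within-subject face-perception experiment
(emotion: fearful/neutral × gaze: direct/averted), with a per-subject
anxiety covariate. This note documents the models, the defaults and why
they were chosen, and what the synthetic data can and cannot establish.

## Coordinate and unit conventions

Right-handed RAS head frame (x right, y anterior, z superior), origin at
the single-sphere conductor centre. All internal distances are metres,
currents ampere-metres, fields tesla; reporting surfaces use mm, nAm, fT.

## Source model

Two source-space families are mixed, following the standard deep-brain
imaging construction:

* **Surface spaces** (neocortex, hippocampus): one equivalent current
  dipole per vertex, oriented along the outward vertex normal — the
  macrocolumn model for laminar grey matter.
* **Volume spaces** (amygdala): the structure is filled with an
  axis-aligned cubic lattice and an *orthogonal trihedron* of dipoles is
  placed at every node, leaving the local net-current orientation free.
  Estimated node amplitude is the Euclidean norm of the three component
  estimates; the per-hemisphere amygdala time course is the node-mean of
  these norms.

The synthetic template anatomy consists of two closed hemispheric
cortical shells built from Fibonacci point sets triangulated by their
convex hull. This achieves any requested vertex count exactly (the
default template reports 15 000 vertices) at the cost of realism: unlike
a folded cortex, the shells contain deep inward-facing vertices.
Amygdalae are ellipsoids of ≈ 2 cm³ centred at (±22, −4, −18) mm with
default lattice spacing 1.8 mm, chosen so the per-hemisphere node counts
(≈ 365) fall in the range reported for individually segmented amygdalae
(≈ 350–450). Trihedral frames default to the canonical axes; all derived
quantities (depth weights, norm time courses) are frame-rotation
invariant, so this choice is immaterial and is tested as such. Users can
substitute their own anatomy via Wavefront OBJ meshes and NIfTI masks.

## Forward model

The conductor is a spherically symmetric volume (single sphere by
default; per-channel overlapping spheres fitted to scalp points within a
60° angular window are supported). Dipole fields use the closed-form
solution for a current dipole in a spherical conductor; its two classic
consequences — radial dipoles are externally silent, and the radial field
component equals the free-space dipole field's — serve as independent
test oracles. Sensors are CTF-style axial gradiometers (151 channels,
helmet radius 11 cm, 5 cm baseline, radial orientation, Fibonacci cap
layout); coils are treated as point magnetometers, since coil-area
integration adds no behaviour observable at this modelling level. The
gain matrix concatenates per-structure blocks in input order: one column
per surface vertex, three per volume node.

## Inverse model

Depth-weighted minimum-norm estimation (wMNE):

    ĵ(t) = R Gᵀ (G R Gᵀ + λ² I)⁻¹ b(t)

* **Depth weights** R: w = (‖g‖²)^(−γ) with exponent γ = 0.4. A
  trihedral node's three columns share one weight computed from the
  summed squared norms of the triplet (frame-invariant; avoids the
  blow-up a per-column rule would suffer on the magnetically near-silent
  radial combination, which is retained in the gain). Squared norms are
  floored at 1e−6 of their maximum, and the final weights are capped at
  10× the smallest weight — the conventional depth-weighting limit. The
  cap matters here because the closed-shell template contains
  near-radial cortical columns whose uncapped weights would dominate the
  prior.
* **Regularization**: λ = 10 % of the largest singular value of the
  depth-weighted lead field G·R^{1/2}. Computing σ_max on the *weighted*
  lead field follows the convention of the toolboxes this estimator
  originates from; the unweighted reading is a config change away
  (`lambda_fraction` applies to whatever gain the weights produce).
* Noise covariance is identity-scaled; baseline-estimated covariance is
  a config hook, not implemented.
* The sensor-space system is solved by Cholesky factorization;
  operators are bit-reproducible for fixed inputs, and small systems are
  tested against dense closed-form and constrained-optimization oracles.

## Synthetic experiment

* **Design**: 6 blocks × 64 face trials; every block shows 16 identities
  × 4 conditions exactly once; 8–12 blue-dot target trials per block at
  random positions (expected 60 per session); fixation 0.7–0.9 s, face
  0.5 s, ISI 1–2 s. Sampling 1250 Hz; a 20 ms projector delay separates
  trigger and photodiode onset.
* **Anxiety**: STAI-state-like scores truncated to [20, 38] with
  target mean 26. The latent normal location is calibrated by
  root-finding so the *truncated* mean equals 26 (naive truncation of
  N(26, 5.2) would bias the mean to ≈ 27.1). The latent scale stays 5.2,
  giving an observed SD ≈ 4.4 — matching both observed mean and SD is
  infeasible within a truncated normal on this range. Anxiety acts as a
  pure amplitude gain, 1 + 0.02·(score − 26) per STAI unit, on all
  structures: an additive, condition-independent covariate effect.
* **Waveforms**: each structure's trace is a Gaussian early peak
  (latency 140 ms, σ 22 ms, unit height) plus a sustained component (a
  190–350 ms boxcar smoothed with a 20 ms Gaussian, 0.6 of the peak).
  Base amplitudes are order-of-magnitude choices — 10 nAm (amygdala),
  25 nAm (fusiform, lateral-occipital patches of 40 vertices) — since the
  emulated study reports no single-trial source amplitudes.
* **Effects are multiplicative** (fractional amplitude increases), wired
  to components: early emotion (+30 % fearful on the peak), late emotion
  (+30 % fearful on the sustained component *within 310–350 ms only*),
  sustained gaze (+18 % direct), right-lateralized fearful×direct
  interaction (+25 % on the sustained term). Cortical structures carry
  their own switches (e.g. fusiform: bilateral emotion×gaze interaction,
  +15 % right-hemisphere gain; no gaze main effect).
* **Trial noise**: per-trial amplitude jitter (lognormal-free normal
  multiplier, σ = 0.3, clipped at zero with a logged warning) and latency
  jitter (σ = 10 ms). Sensor noise is white and homoscedastic,
  default 50 fT per sample — single-trial amygdala evoked fields (~20 fT)
  sit below the noise floor while ~96-trial averages are clean, a
  realistic MEG regime. Blink artifacts are low-frequency frontal
  transients (amplitude 2 pT, default rate 5 %) with ground-truth flags.

## Preprocessing

Epochs span [−0.2, +0.6] s around the photodiode-corrected onset
(delays are rounded to the nearest sample and logged). Rejection is
automated peak-to-peak thresholding (default 1.5 pT, far above clean
synthetic trials), replacing the visual inspection of a human analyst.
Averages are low-pass filtered at 40 Hz with a zero-phase
(forward-backward) 4th-order Butterworth — zero-phase because the
analysis measures latencies — then baseline-corrected over [−200, 0) ms.
Filtering and baseline correction are linear and commute with averaging
(tested); correcting after filtering keeps the baseline-mean invariant
exact.

## Measurements and statistics

Analysis windows are half-open in seconds — [130, 170) ms and four
consecutive 40 ms windows over [190, 350) ms — mapped to samples by
index flooring, so window sample counts are exact at 1250 Hz. Cortical
ROIs are fixed-size geodesic neighbourhoods (77 fusiform, 82
lateral-occipital vertices) centred on the maximum of the grand-average
(across subjects and conditions) z-scored map in 130–170 ms, searched
within config-exposed coordinate boxes standing in for anatomical
delimitation; ties break to the lowest vertex id. The exact rule that
produced the original cluster sizes is unknowable from counts alone;
fixed-size neighbourhoods are the documented surrogate. k-means
(k-means++ with fixed seed, 10 restarts) partitions volume nodes for
control ROIs.

The **repeated-measures ANCOVA** uses the multivariate-contrast
formulation: per-subject contrast scores (orthonormal Helmert Kronecker
contrasts) are regressed on the mean-centred covariate. The effect F
tests the intercept, effect×covariate the slope, and the covariate main
effect the slope of per-subject grand means (subject-mean adjustment).
With n subjects this yields the (1, n−2) denominator df structure of a
15-subject cohort with one covariate, i.e. F(1, 13). Greenhouse–Geisser
ε comes from the covariance of covariate-residualized contrast scores
(the residualization choice is ours; the alternative differs only
through the covariate's 1 df); GG-adjusted p values use (qε, q(n−2)ε)
df. A constant covariate is dropped with a warning, reducing exactly to
RM-ANOVA (equal to the squared paired t for 2-level factors). Planned
comparisons run single cell contrasts through the same machinery. No
multiple-testing correction is applied across the late windows beyond
the interaction-then-simple-effects logic.

Note that finite-sample GG-adjusted null p values are *conservative*,
not uniform (the ε estimator is biased downward under sphericity); the
calibration tests assert uniformity for uncorrected p and
non-anticonservativeness for GG.

## Calibration and recovery studies

The type-I-error and power studies run at measurement level: the same
waveforms, condition multipliers, and subject gains produce noiseless
cell means, and the generator's trial amplitude jitter enters as
cell-mean noise with σ/√n_trials (latency jitter, sensor noise, and
inverse leakage are deliberately excluded at this level; the end-to-end
sensor-level path is exercised separately by the pipeline tests). Under
the null all 1-df effects reject at 5 % ± binomial noise; at the default
effect sizes the early emotion effect, the sustained gaze effect, and
the three-way interaction are detected in ≈ 100 % of 15-subject cohorts.

The localization study activates the centroid node of the right
amygdala grid (10 nAm, fixed tangential direction, early-peak waveform),
projects through the full default model (15 000-vertex cortex, both
amygdalae, both hippocampal shells), adds white noise at peak-amplitude
SNR 10, inverts, and measures the distance between the true node and the
amplitude-weighted centre of gravity of all deep-source (amygdala) node
norms at peak latency: ≈ 0.6 cm averaged over 100 noise seeds, inside
the ≤ 1 cm bound expected for isolated amygdala activations.

## Problem sizes

The full-scale configuration (151 channels, 15 000-vertex cortex, ~365
nodes per amygdala, 384 trials, 15 subjects) is used for the anatomy
constants and the localization study. The test suite and the example
cohort run reduced versions (32–151 channels, 200–3000 vertices, 1–2
blocks, 2–6 subjects) that exercise identical code paths; statistical
calibration uses the measurement-level fast path (2000 null and 200
effect cohorts), keeping the default suite under a minute.

## Known limitations

* Spherical conductors and shell anatomy: no realistic BEM/FEM geometry,
  no cortical folding, so absolute gain values and leakage patterns are
  only qualitatively representative.
* White homoscedastic sensor noise; no empty-room colored noise, no
  synthetic third-gradient reference correction, no head movement.
* Minimum-norm amplitude bias: estimated amygdala amplitudes are ~two
  orders of magnitude below planted values because energy spreads over
  ~17 000 components; condition *contrasts* and localization, the
  quantities analysed, are preserved.
* Cross-talk between structures is real and visible (e.g. cortical
  activity leaks into amygdala norms); the synthetic control analyses
  (hippocampus-body k-means clusters) exist precisely to characterize
  it, as in the emulated workflow.
* Passing tests demonstrate internal consistency and calibration of the
  method under the generator's assumptions — not that real amygdala
  responses are recoverable from real recordings.
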