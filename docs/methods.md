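# Methods

## Forward model of SERS mixture spectra

Each chemical species is a set of Lorentzian bands. A band with center
ν₀ and full width at half maximum w contributes a unit-height lineshape
`1 / (1 + ((ν − ν₀)/(w/2))²)`; Raman bands are near-Lorentzian and only
the band centers of the three target analytes are anchored by
measurement (uric acid 635 cm⁻¹, lactate 859 cm⁻¹, tyrosine
1353 cm⁻¹), so the default width (12 cm⁻¹) and the secondary bands are
configurable plausibilities, placed to create cross-analyte overlap
(e.g. a tyrosine band at 830 cm⁻¹ shoulders the lactate 859 cm⁻¹ band).
A species at concentration c contributes `response(c) · Σ_peaks
rel_amp · lineshape`, with `response(c) = sensitivity · c` by default or
the Langmuir form `sensitivity · s·c/(s + c)` when a saturation scale s
is set (off by default; offered because adsorption saturation is the
usual cause of high-level underestimation in SERS calibration).
Sensitivities are scaled so each analyte's physiological maximum (40 µM
uric acid, 20 mM lactate, 200 µM tyrosine) yields unit primary-peak
response, making the three analytes commensurate.

A fixed background component (broad substrate-like bands plus a sharp
urea-like feature, driven at "concentration" 1 by every design row)
plays two roles: it emulates the substrate/artificial-sweat matrix, and
it breaks the scale invariance of per-spectrum min–max normalization —
without an additive constant component, `c` and `2c` produce identical
normalized spectra and absolute concentration would be unidentifiable.

## Mixture design

The default design draws 41 distinct (uric acid, lactate, tyrosine)
tuples from the discrete level sets {0, 2.5, 5, 10, 20, 40} µM,
{0, 1, 2, 5, 10, 20} mM and {0, 50, 67, 100, 150, 200} µM with a fixed
internal seed, anchoring the all-zero and all-maximum corners; 36
replicates per combination give 1476 spectra. The exact combinations of
the reference corpus are not public, so this is a declared stand-in with
the same geometry; a design file (YAML/JSON) can override it.

## Noise model and its calibration

Per replicate: `spectrum = clip(clean · g + b(ν) + ε, 0)` with

- `g` log-normal with unit mean and coefficient of variation
  `amplitude_cv` (hotspot/enhancement variability). Note that
  per-spectrum min–max normalization deliberately removes most pure
  gain variation — that is the point of the normalization — so `g`
  matters mainly through its interaction with the additive terms;
- `b(ν)` a random polynomial of order `baseline_order` scaled by
  `baseline_scale` and shifted to be non-negative (fluorescence-like
  drift; strong signed drifts would clip whole spectra to zero);
- `ε` white Gaussian noise with SD `white_sigma`.

The defaults (cv 0.30, order 4, scale 0.80, σ 0.15, all relative to
unit peak response) were calibrated once so that cross-validated R²
on the default synthetic study lands inside the 0.65–0.92 band reported
for the real training corpus; at those settings the desk-scale study
gives per-metabolite mean R² ≈ 0.73–0.87 and RMSEs (≈ 7 µM uric acid,
≈ 3 mM lactate, ≈ 33 µM tyrosine) of the same order as the reference
values. The generator emulates level grids, replicate structure,
spectral overlap and measurement fluctuation; it does **not** emulate
chemical matrix effects (peak shifts, competitive adsorption),
instrument drift between sessions, or real sweat composition — so
passing tests demonstrate that the pipeline recovers concentrations
under the stated statistical structure, not performance on real sweat.

## Quantification model

A symmetric fully connected autoencoder: encoder = four equally sized
ReLU layers (width = input length, 1321 by default) followed by a
linear map to a 2-D latent layer; decoder mirrors it with a sigmoid
output (inputs live in [0, 1] after normalization). Prediction heads
are one logistic unit per metabolite on the latent code — this realizes
"concentration axes" in the latent plane as the heads' weight
directions. Labels are min–max scaled per metabolite over the training
split; predictions are inverse-scaled, so the sigmoid bounds them to
the training concentration range (documented saturation behavior).
Hidden activations (ReLU), the linear latent layer and the sigmoid
output are design choices; He/Glorot initialization is seeded. The
objective is `MSE(x̂, x) + λ·MSE(ŷ, y)` with λ = 1 by default.

Training: Adam with L2-style weight decay folded into the gradient,
(lr, decay) = (1e-4, 1e-5) through epoch 50 and (1e-5, 1e-6) after,
batch size 32, at most 150 epochs, early stopping on validation total
loss with patience 15 and best-checkpoint restore. Everything is
implemented in NumPy with analytic backprop; gradient correctness is
pinned by central-difference tests (note: the untrained network with
all-zero biases can place a ReLU pre-activation exactly at its kink for
a sample whose previous layer is fully inactive, where two-sided
differences and the one-sided analytic convention legitimately differ —
the tests randomize biases first).

### Shared vs per-metabolite models

With one shared model, three independently varying concentrations must
pass through the 2-D latent bottleneck, and each logistic head is an
affine function of that code: exact prediction would require the
(logit-scaled) label matrix to lie in a 2-D affine subspace, which a
3-D factorial-style design violates. Empirically the shared model tops
out around R² 0.55–0.85 even on noise-free data. Per-metabolite
training (the `metabolites` config field) removes the constraint — each
model embeds one concentration in its 2-D latent — and reaches
R² > 0.99 at zero noise. The package therefore keeps the shared
three-head model as the architectural default but uses per-metabolite
models as the evaluation protocol for parameter recovery, consistent
with quantifying sweat through "models for individual metabolites".
An ordinal-classification head (softmax over discrete levels) is a
conceivable alternative reading of the design and is not implemented.

### Desk-scale protocol

Tests, examples and the acceptance script run the study at desk scale:
200-point grid over the same 457–1674 cm⁻¹ range, 41 combinations × 12
replicates, hidden width = input length, and the training schedule
compressed to a 60-epoch budget (lr 1e-3 → 1e-4 at epoch 40, patience
10) — the same two-phase shape at one tenth the epochs, chosen so a
full 10-repeat cross-validation completes in minutes on one CPU. The
full-scale configuration (1321-point grid, four 1321-unit layers, the
1e-4/1e-5 schedule) remains the default `QuantifierConfig`.

## Feature attribution

SHAP values are estimated with an expected-gradients scheme: for each
sample, attributions average `∇f(b + α(x − b)) · (x − b)` over random
baselines b from a background set (up to 100 training spectra) and
α ~ U(0, 1), using the encoder's analytic input gradients (kernel-type
estimators are impractical at 1321 features). The attribution target is
each latent coordinate (encoder-only, making importance independent of
the sign/direction of the concentration effect), `latent_sum`, or a
head output. Per-sample values are squared and averaged across samples
into the non-negative importance profile; ties in `top_features` break
toward the lower wavenumber. Completeness (attributions summing to
`f(x) − E_b f(b)`) holds only up to Monte-Carlo error of the estimator
and is tested with loose tolerance on small examples.

## Evaluation statistics

R² is `1 − SS_res/SS_tot` about the mean of the true values; RMSE is
reported in physical units. Bland–Altman agreement uses differences
d = pred − true, bias = mean(d), limits bias ± 1.96·SD(d). Box
summaries use linear ("type 7") quantile interpolation with whisker
bounds at Q1 − 1.5·IQR and Q3 + 1.5·IQR; the interpolation rule is a
documented choice. Cross-validation keeps the full per-repeat metric
distribution because the reference results are reported as ranges
across 10 repeats (treated as min–max of the repeats).

## Chrono-sampling

Chamber fill interval = volume / flow rate (0.5 µL at 0.25 µL/min →
2 min); patch capacity = chambers × volume (17 × 0.5 µL → 8.5 µL). The
injection simulator labels each completely filled chamber with the
volume-weighted mean inlet concentration over its fill window, which
for a step input quantifies the dense-vs-sparse trade-off: smaller
chambers confine boundary mixing to one short window. Sweat rate is
volume collected per interval (default one interval per chamber, or
fixed windows with cumulative-volume interpolation); profiles timestamp
each chamber at its fill-window midpoint and report the replicate mean
± one standard deviation.

## Degenerate inputs and numerical choices

Constant spectra cannot be min–max normalized and are rejected;
constant training labels cannot be scaled and are rejected; SNR with
zero noise variance, empty designs/sets, and attribution of untrained
models fail with informative messages. All computation is float64;
training is single-threaded deterministic for a fixed seed (per-repeat
seeds derive from `numpy.random.SeedSequence` spawning).

## Known limitations

- The synthetic generator's secondary bands, background species stubs
  and noise decomposition are invented plumbing; only the three primary
  band centers, the level sets, the corpus geometry (41 × 36 × 1321)
  and the device timing figures are externally anchored.
- The shared three-head model is intrinsically R²-limited by the 2-D
  bottleneck (see above); raising `latent_dim` removes the limit but
  departs from the reference architecture.
- On-body validation against assay kits requires human sweat and is out
  of computational scope; Bland–Altman tooling supports such a
  comparison but is exercised here only on synthetic predictions.
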