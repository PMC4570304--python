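# Methods

This note documents the models implemented in `lcmcs`, the defaults and
numerical choices, what the synthetic data generator does and does not
emulate, and the design decisions taken where the method description left
room.

## Data model

Spectra are stored as samples × bands matrices on a strictly uniform
wavelength grid; the package convention is 350–2500 nm at 1 nm (2151
bands), the usual post-processed export of field spectroradiometers whose
native sampling (1.4/2 nm) is resampled upstream.  Original reflectance
must lie in (0, 1]; transformed or smoothed spectra are unconstrained
(wavelet smoothing may overshoot the physical range slightly, which is
numerically correct and deliberately not clipped).  Spectra and TN targets
are aligned by sample id, never by row position.  TN values must be
strictly positive because the mean relative error divides by them.

## Spectral transforms

Three standard chemometric transforms of reflectance R(λ):

* **log(1/R)** — absorbance-like; base-10 logarithm.  The base is a
  convention: correlations and every downstream quantity are invariant to
  it up to a positive scale.
* **FDR** — first derivative, computed as central differences at interior
  bands and one-sided differences at the two edges, in units of 1/nm.
  This stencil is exact for affine spectra and preserves the band grid, so
  band indices stay aligned with wavelengths.  (Differentiating over index
  rather than nm would change results by a constant factor only.)
* **(log[1/R])′** — the exact composition FDR ∘ log(1/R); the pipelines'
  default input.

## Local correlation maximization (LCM)

"Smoothing level k" means: discrete wavelet decomposition (sym8,
symmetric boundary extension) to depth k along the wavelength axis, all
detail coefficients at scales 1..k zeroed, inverse transform, trimmed to
the input length.  No coefficient thresholding is used — the ladder of
levels 0 (raw) through 5 is a ladder of low-pass approximations, which
matches the intended use: the per-band *choice* of level is the denoiser.
Level-k smoothing with sym8 requires roughly 16·2^k bands; the feasible
depth is checked and reported.

For each level the per-band Pearson correlation with TN is computed across
the **calibration samples only**; the learned level map is then applied
frozen to any new spectra (a `leaky_occ` flag reproduces the all-samples
variant for comparison, but leaks validation information and is off by
default).  Per band, the level with maximal |r| wins; ties break toward
the **lowest** level, i.e. the least smoothing, preserving detail.  Bands
with zero variance at some level are flagged incomputable at that level;
bands incomputable at every level are excluded from selection.  By
construction the OCC dominates every fixed level in mean |r| on the data
it was fitted to.

Level selection by argmax of an estimated correlation is subject to
selection bias: with six candidates per band, calibration |r| is slightly
inflated.  This is inherent to the method and visible in the synthetic
experiments as a calibration/validation gap; the frozen-map evaluation
reports it honestly.

## Band selection

Bands are kept when |r| exceeds a threshold: either a fixed value (e.g.
0.40) or the critical correlation of a two-sided significance test,
obtained by exact inversion of t = r·√((n−2)/(1−r²)) with n−2 degrees of
freedom (r* ≈ 0.2097 at n = 150, α = 0.01).  Thresholds are sign-agnostic.
No multiple-testing correction is applied across the 2151 bands — the
per-band p < 0.01 rule is reproduced as such, and its anti-conservatism
under 2151 tests is a property of the method, not of this implementation.

## Partial least squares

PLS1 via NIPALS: X and y are mean-centered; per component the weight
vector w ∝ Xᵀy, scores t = Xw, loadings p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then X
is deflated by t pᵀ (with a univariate response, deflating y as well is
algebraically redundant but kept for the residual diagnostics E, F, Ed).
The composite coefficient vector β = W(PᵀW)⁻¹q gives ŷ = (x − x̄)β + ȳ,
and R = W(PᵀW)⁻¹ projects centered spectra onto the latent scores passed
to the fuzzy regressor.  Successive scores are mutually orthogonal and the
implementation agrees with scikit-learn's reference PLS to 1e-8 and with
ordinary least squares in the full-component limit.

The latent-variable count can be fixed (the presets use 8 for the linear
models and 5 for the ANFIS models) or chosen from the calibration error:
components are added while calibration RMSE improves by more than a
relative tolerance (default 1e-6) times the target's standard deviation.
No cross-validation is used; with a coarser tolerance the rule stops early
on uninformative targets.

## ANFIS

First-order Takagi–Sugeno system on the PLS scores: 2 generalized bell
membership functions per input, full grid rule base (32 rules for 5
inputs), product firing, normalization (Σw̄ᵢ = 1 identically), linear
consequents, weighted sum output.  Initialization: centers spread evenly
over each input's training range, widths a = half the center spacing,
shape b = 2, optional seeded jitter.

Hybrid training alternates per epoch: (i) premises frozen, all consequent
parameters from one global least-squares solve; (ii) one full-batch
gradient step on (a, b, c) with analytic gradients, step-halving on loss
increase (the trace is non-increasing by construction), projection of a
and b onto [1e-6, ∞), early stop after 20 non-improving epochs (default
60 epochs, learning rate 0.01 on the normalized gradient).

**Consequent regularization.**  The grid design has 32·6 = 192 consequent
parameters against 150 calibration samples, so the plain least-squares
estimate interpolates the training data and generalizes poorly.  The solve
is therefore split: an unpenalized *global linear* stage (because Σw̄ᵢ = 1,
one shared consequent reproduces any linear map exactly — hence a linear
target is always fitted to machine precision by the first pass, a key
correctness check), followed by a ridge-penalized stage for the rule-wise
deviations that encode the nonlinearity.  The penalty is scaled to the
design (λ = 0.05 · tr(DᵀD)/q by default, configurable; 0 restores the raw
LSE with a tiny-ridge fallback only on numerical ill-conditioning).  This
shrinks the fuzzy model toward the global linear fit rather than toward
zero, which is the behavior a calibration scientist wants from a
small-sample neuro-fuzzy regressor.

## Pipelines and evaluation

The four presets share the (log[1/R])′ transform and differ in denoising
and regressor: PLS = level-5 smoothing + linear PLS (8 LVs, p < 0.01
bands); LCM = OSP + linear PLS (8 LVs, p < 0.01); CS = level-4 smoothing +
PLS(5 LVs, |r| > 0.40 bands) + ANFIS; LCMCS = OSP + PLS(5 LVs, p < 0.01) +
ANFIS.  All learned state — level map, band mask, PLS, ANFIS — is fitted
on the calibration split only.

The calibration/validation split is stratified by site; with the standard
three-site composition (100/95/85 samples) the calibration counts are
exactly 55/50/45 (validation 45/45/40).  Metrics: R² = 1 − SSres/SStot
about the evaluated split's own mean (also for validation), RMSE in
mg·kg⁻¹, MRE = 100·mean(|ŷ−y|/y).  Per-site blocks accompany the overall
numbers; sites with fewer than two samples are reported as unavailable
rather than silently dropped.  Reports serialize to JSON + CSV and round-
trip losslessly.

## Synthetic data generator

The generator emulates the features of field soil spectra that this
method stack exploits, with a known ground truth:

* smooth continuum rising from the visible into the NIR; three sites with
  small additive offsets (±0.012 reflectance);
* broad water/clay absorption features at 1400/1905/2200 nm (widths
  35–55 nm, max depths 0.08–0.14) whose depth increases with TN — so
  reflectance decreases with TN — through a saturating link
  g(u) = (1 − e^{−2.2u})/(1 − e^{−2.2}), u = scaled TN; the saturation is
  the nonlinearity the ANFIS stage exists to capture;
* fine-scale "burr" noise synthesized in the wavelet detail domain at
  scales 1–3 (amplitude 0.015), confined by an envelope around the broad
  features: at those bands the correct denoising level is known (≥ 3) and
  the level-map recovery rate is measurable;
* narrow TN-coupled features at 560/700/840/980 nm (widths 2.5–3 nm,
  depths ~0.03) in an otherwise clean window: their information lives at
  fine wavelet scales, so heavy smoothing destroys it — the correct level
  there is low, and a fixed-level pipeline must lose this signal;
* a correlated smooth baseline nuisance field (amplitude 0.004,
  correlation length 18 nm) that survives smoothing, which is what makes
  the smeared narrow features genuinely unrecoverable rather than merely
  attenuated;
* independent per-sample disturbances on the broad (σ = 0.10) and narrow
  (σ = 0.06) responses, so neither spectral window alone carries the full
  TN signal and combining them (what the OSP enables) is measurably
  better;
* TN uniform on 7–19 mg·kg⁻¹, 280 samples in site blocks 100/95/85, a
  small white-noise floor (3e-4), all driven by one seed.

These defaults define the study conditions for every end-to-end test and
for `scripts/acceptance.py`.  Under them the seed-averaged validation R²
ordering is LCMCS ≥ LCM ≥ PLS and LCMCS ≥ CS, with LCMCS above 0.85 —
the synthetic analogue of the field result the method was designed for.

**What passing these tests does not show.**  The generator's TN link is a
single monotone latent factor read through two windows; real soils have
correlated constituents (organic matter above all), instrument drift,
moisture and texture effects that are not independent of TN, and
between-site differences richer than an additive offset.  Success on the
synthetic design demonstrates that the implementation realizes the
intended mechanisms (per-band level selection recovers the injected noise
scales; the fuzzy stage captures the injected nonlinearity), not that the
method attains any particular accuracy on real soil archives.

## Problem sizes and determinism

Unit tests run on a 12 × 64 tiny configuration and a reduced 512-band
study; the acceptance checks use the full 280 × 2151 design with 10 seeds
for the four-model comparison and the level-map recovery rate, and 100 000
replicates for the Monte-Carlo check of the significance threshold.  Every
random draw flows from an explicit seed; repeating any pipeline run with
the same seed produces byte-identical artifacts.

## Known limitations

* The OCC/OSP construction optimizes each band independently; no spatial
  (across-wavelength) regularization of the level map is attempted.
* The per-band significance rule performs no false-discovery control.
* ANFIS is restricted to grid partitioning with bell memberships; rule
  generation by clustering is out of scope.
* The component-count rule uses calibration error only (by design), which
  overfits relative to cross-validation; the presets therefore pin the
  latent-variable counts.
* ASD binary formats, instrument calibration and radiance-to-reflectance
  conversion are out of scope; CSV is the only exchange format.
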