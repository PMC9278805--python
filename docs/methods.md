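# Methods

This note records the model, the choices made where the design was open,
what the synthetic generator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

A trial is an `m × t` real matrix with labelled rows (channel names), a
sampling rate, a subject identifier and either a 1–9 valence rating or a
±1 label. The reference pipeline downsamples to 128 Hz, band-passes
4–45 Hz and binarizes valence at 5.

* **Resampling** is polyphase and anti-aliased
  (`scipy.signal.resample_poly`, linear-extension padding). The common
  512→128 Hz case is an exact 4:1 ratio; arbitrary rational ratios are
  approximated to denominator ≤ 1000. Upsampling is refused.
* **Band-pass** is a 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`): zero phase, squared magnitude response. Standard EEG
  practice; no particular design is canonical for this pipeline, so the
  default is the most conventional one.
* **Valence ties**: a rating exactly at the threshold goes to the
  negative class (only strict inequalities are well defined; "high" is
  conventionally "> 5"). `binarize_valence` is monotone in the rating.
* **Region maps** are `region,channel` CSVs; within a region, channel
  order follows the map, not the recording, so every `X^j` is
  reproducible from the map alone. The packaged 32-channel map groups
  the standard 10/20 electrode names into 5 regions
  (9, 2, 7, 11, 3 channels).
* The optional reader for DEAP-style preprocessed MATLAB containers
  drops the 3 s pre-trial baseline by default (flag-controlled), since
  keeping it changes `t` and therefore the dense-layer geometry.

## Feature extractor

Per region (and once globally): temporal conv (1×25, 40 filters, valid,
stride 1) → spatial conv (m×1, 40) → batch norm → square → average pool
(1×75, stride 15) → log → flatten → dense to `d = 300`. The pooled length
is `⌊(t−99)/15⌋+1`, so trials need `t ≥ 99` samples.

Numerical and design choices:

* `z_j` is the 300-dimensional output of the first dense layer, not the
  raw flatten. Both readings are shape-consistent (the flatten length
  depends only on the shared `t`), but the dense-300 reading gives a
  `t`-independent feature dimension and matches the architecture table's
  placement of one dense layer before the K-way output.
* Batch norm is per feature map over (batch, time), biased variance,
  momentum 0.1, eps 1e−5; batch statistics in training, running averages
  in evaluation.
* The log layer clamps its input at `log_epsilon = 1e−6`: pooled squared
  activations can be exactly 0 (zero input), where log is undefined.
* Initialization is Glorot-uniform for conv/dense weights, zero biases,
  γ = 1, β = 0, all drawn from one seeded generator. No dropout.
* The two convolutions compose linearly (nothing between them), so the
  forward/backward passes evaluate them as one composite kernel
  `K[g,c,k] = Σ_f Ws[g,f,c] Wt[f,k]` applied to im2col windows. This is
  exact algebra, not an approximation; both parameter groups keep their
  own gradients via the chain rule through `K`. Note that batch norm
  absorbs per-map constant shifts, so the conv biases have exactly zero
  gradient; they are kept for interface completeness.
* Everything is float64 with hand-written backward passes; analytic
  gradients are verified against central differences in the test suite
  (tolerance 1e−4 relative, with a 0.01 absolute floor in the
  denominator so exact-zero gradients are compared on an absolute
  scale).

## Region attention

Squeeze: `s_j = mean(z_j)`. Excite: `u = σ(W₂ δ(W₁ s))` with hidden
width `max(1, ⌊(J+1)/2⌋)` and no biases (the gating equation has none).
`u` is computed per input sample, standard squeeze-and-excitation
semantics. Scale-and-stack produces `Ẑ` with rows `u_j z_j`, regions
first, global branch last. The ablation ("DNN") fixes `u ≡ 1` and drops
the gating parameters.

A structural caveat, observable in the attention experiments: the
square–pool–log features are approximately zero-mean after batch norm,
so the squeeze statistic starts near 0 and the gating output near 0.5;
and the hinge loss stops providing gradient once all margins are
satisfied. On strongly separable synthetic data the hinge saturates
within a few tens of epochs and the learned `u` stays close to 0.5 with
no reliable preference for the class-informative region — the classifier
matrix absorbs the discriminative signal instead. On barely separable
data (the realistic affective-EEG regime) margins stay active throughout
training and the gating continues to receive gradient. The test suite
states the attention-recovery property at the strongly separable
operating point and documents its outcome; see Limitations.

## Matrix classifier

Objective `½‖W‖_F² + τ‖W‖_* + C Σᵢ max(0, 1 − yᵢ(tr(WᵀẐᵢ) + b))` with
`W ∈ ℝ^{(J+1)×d}`.

* Subgradient of the nuclear term: `UVᵀ` from the thin SVD restricted to
  singular values above `1e−10 ×` the largest; at `W = 0` the zero
  matrix (a valid subdifferential element). At full rank with distinct
  singular values this is the exact gradient.
* Hinge-active branch when `H > 0`; samples exactly on the margin
  contribute nothing (valid, deterministic subgradient choice).
* Per-batch steps use `C × Σ` over the batch (a sum, not a mean), so the
  effective data-term step magnitude at batch 40 matches the stated
  learning rates.
* Prediction: label +1 iff `tr(WᵀẐ) + b ≥ 0` (deterministic tie-break).
* Effective rank (diagnostics) counts singular values ≥ 1 % of the
  largest.

## Training, model selection, evaluation

Plain SGD without momentum; learning rate `η_p = η₀/(1+αp)^β` with
`p` the fraction of optimizer *steps* completed (η₀ = 1e−3, α = 10,
β = 0.75); batch size 40. The reference budget is 1000 epochs; the
package default is 100, and the heavier test-suite experiments use
20–100 epochs — desk-scale budgets that suffice on the synthetic
datasets (the synthetic tasks converge within a few tens of epochs).

Hyperparameters `C ∈ {1e−2,…,1e2}` and `τ ∈ {1e−3,…,1e0}` are selected
by stratified 5-fold cross-validated accuracy on the training set only;
ties resolve toward smaller `C`, then smaller `τ` (stronger
regularization). A single-point grid short-circuits the CV. In
leave-one-subject-out evaluation the grid search runs inside each fold's
training portion, so the held-out subject never influences selection.
The package default when no search is requested is `C = 1`, `τ = 1e−2`
(the grid midpoints on a log scale).

Metrics: ACC, PPV, SEN, F1 from the confusion counts with +1 the
positive class; AUC is the rank statistic (ties ½), computed from the raw
decision score (AUC is invariant under monotone transforms, so no
probability calibration is needed); single-class folds report AUC as
undefined rather than a number. The paired two-tailed t-test compares
per-subject metric vectors; all-zero differences are an error,
zero-variance nonzero differences report p = 0 with a warning.

## Synthetic data generator

Emulates: several subjects; a fixed trial count per subject; a shared
montage; ±1 labels at a configurable balance (per-subject counts rounded,
then shuffled); a class-dependent sinusoidal carrier (default 10 Hz,
amplitude `effect_size × noise_sd`, random phase per trial) confined to
the channels of the informative regions; independent white Gaussian
noise everywhere; and a per-subject multiplicative gain
(`1 + N(0, shift_sd)`, magnitude) that makes cross-subject
generalization non-trivial. Randomness is counter-based: one seed spawns
per-subject and per-trial substreams, so generation is order-independent
and bit-reproducible.

Defaults — 4 subjects × 20 trials, 2 s at 128 Hz, effect size 4,
carrier 10 Hz, noise SD 1, gain jitter 0.1, balance 0.5, frontal region
informative — give a deliberately easy, analytically checkable task: the
oracle band power (periodogram energy within ±1 Hz of the carrier over
informative channels) separates the classes almost perfectly, so any
downstream failure indicts the pipeline, not the data.

Not emulated: 1/f spectral shape (a pink-noise option exists but is off
by default because band power is then less convenient to reason about),
volume conduction and realistic scalp topographies, artifacts,
non-stationarity, and realistic class overlap. Passing tests on this
generator therefore demonstrate mechanical and statistical correctness
of the pipeline, not expected performance on real affective EEG.

## Limitations

* Real-data performance claims are out of scope: the canonical emotion
  corpus is access-gated, and all end-to-end experiments here run on the
  synthetic testbed.
* The attention-recovery property (informative region ranked in the
  top 2 mean weights across seeds) does not hold reliably at the
  strongly separable operating point, for the saturation reasons above;
  the corresponding test states the property as such and fails honestly
  at that operating point. The ablation comparison (attention never
  materially hurts) does hold.
* Binary classification only; the multi-class extension is out of scope.
* The DEAP MATLAB reader is minimal and untested against the real files
  (no dataset available in this environment); it is a convenience, not a
  validated loader.
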