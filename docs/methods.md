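# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the package. It complements the README, which shows the
user-facing workflow.

## Problem setting

The task is binary classification of resting-state EEG epochs — major
depressive disorder (MDD) versus healthy control (HC) — under a
*subject-independent* protocol: all epochs of a subject fall entirely into
the training, validation or test side of a fold, never split across them.
The classification unit is a non-overlapping 2-s epoch; reported metrics
are epoch-level. Evidence in the literature points to delta (0.5–4 Hz) and
gamma (30–70 Hz) band power as the more discriminative features for MDD,
which is what the synthetic generator's default experiment encodes.

## Synthetic cohort generator

Each subject's recording is the sum of

- a 1/f ("pink") background, per-channel independent, RMS 3.5 µV, obtained
  by spectral shaping of white noise (amplitude ∝ 1/√max(f, 0.5));
- one narrowband stochastic oscillation per canonical band per channel:
  white noise restricted to the band's interior (5% edge margin) by
  spectral masking, RMS-normalized to `amp/√2` so a component of amplitude
  `A` carries the band power `A²/2` of a sinusoid of amplitude `A`. Base
  amplitudes are δ 11, θ 3.5, α 5.5, β 3, γ 5 µV with ±10% per-channel
  jitter.

Class effects multiply the band amplitudes of positive-class (MDD)
subjects, so `effect[b] = m` scales band-b power by `m²`. The defaults of
the recovery experiment double delta and gamma amplitudes (power ×4).

Two generator choices deserve explanation:

- **Narrowband noise rather than pure tones.** Real EEG rhythms wander
  within their band; a fixed sinusoid would give every subject a stable
  single-frequency fingerprint per channel. Such fingerprints are
  trivially memorizable by a sequence model and would turn a
  subject-independent benchmark into a memorization test. With stochastic
  band components, band *power* is the only class-informative statistic,
  which is the intended construct.
- **Amplitude budget.** Base amplitudes are set so that clean recordings —
  including doubled delta/gamma and Gaussian tails — stay essentially
  inside the ±100 µV artifact-rejection threshold (worst-case channel
  std ≈ 18 µV, 5.5 σ below the threshold). Rejection therefore only fires
  on injected artifacts (150 µV blink templates on the first 8 channels,
  Poisson-timed; optional 50 Hz line noise).

What the generator does **not** emulate: volume conduction and inter-channel
covariance, non-stationarity across minutes, realistic artifact
morphologies, medication or severity gradations. A model that passes the
recovery experiment has demonstrated correct plumbing (no leakage, working
optimization, band-power sensitivity), not clinical validity on real EEG.

## Preprocessing chain

Band-pass (0.5–70 Hz windowed-sinc FIR, zero-phase, MNE's default
transition widths `min(max(0.25·edge, 2 Hz), edge)`) and a 1 Hz-wide FIR
notch at 50 Hz are applied at the native rate (250 Hz), keeping the 70 Hz
upper edge below both the native and the post-resampling Nyquist. Then:
average reference, polyphase resampling to 150 Hz (exact 3/5 ratio),
channel standardization to 128 (truncate extras / zero-pad missing), 2-s
epoching (half-open windows, tail discarded), and amplitude rejection of
any epoch containing a sample beyond ±100 µV. The ordering of rejection
relative to referencing/resampling is a documented choice: rejection is
decided on the full-band conditioned epochs so that the keep-mask is
identical across band modes, which keeps per-band epoch sets aligned for
allbands stacking. ICA-style artifact removal is a manual step by nature
and is exposed only as a pluggable `cleaning_hook`.

Band modes: `fullband` (0.5–70 Hz, C = 128), one of `delta…gamma`
(band-pass to that band), or `allbands` (the five band-filtered copies
stacked along channels in the fixed order δ, θ, α, β, γ, C = 640). Band
filtering happens on the continuous signal before epoching to avoid
per-epoch edge transients.

Normalization is z-scoring per (channel, time) location across the epoch
dimension, with mean/std estimated **only** from training-fold epochs
(population std, σ floored at 1e-6) and applied unchanged to validation
and test epochs. Leak-freedom is asserted by tests that corrupt held-out
data and require bit-identical statistics and training histories.

## Network

Defaults: hidden size H = 64, vector dimension d = 16, output vector
dimension d′ = 16 (set equal to d; not independently motivated), K = 2
classes, r = 3 routing iterations, bidirectional, margin parameters
m⁺ = 0.9, m⁻ = 0.1, λ = 0.5 (the standard margin-loss convention), one
recurrent layer, no dropout.

The squash nonlinearity defaults to the *linear* form
`‖v‖ = ‖s‖/(1+‖s‖)`; the classic quadratic capsule form
`‖s‖²/(1+‖s‖²)` is available as `squash_variant="classic_quadratic"`.
The coupling softmax normalizes over the **lower units** (`Σ_i a_ij = 1`),
so the couplings of a class form a distribution over time steps — this is
also what the temporal attention curve exposes. Note this is the opposite
axis from classic capsule routing, where each lower unit distributes its
vote across classes; with per-class normalization the two class heads are
independent one-vs-rest readouts.

A learnable scalar (parameterized through `exp` to stay positive,
initialized at 1) scales norms into logits; since the margin loss is
defined on the norms themselves, the scale does not receive gradient under
the default objective and inference uses the norms directly (argmax is
invariant to positive scaling; ties resolve to the lower class index).

### Initialization

Two non-standard choices, both load-bearing for optimization and both
motivated by the geometry of the linear squash:

- `prim.c` (the vectorization bias) is initialized to a random **unit**
  vector instead of zero. With a zero bias all lower units start near the
  origin and epochs of different amplitude produce nearly *parallel*
  time-averaged representations, which a linear class transform cannot
  separate by norm in both directions; a fixed offset makes amplitude
  differences tilt the direction of `u_t`, not just its length.
- `route.W` is drawn uniform with limit `route_init_scale ·
  √(6/(d+d′))`, `route_init_scale = 3`. The linear squash needs
  pre-activation norms of order 1–10 to produce confidences in the
  responsive range between m⁻ and m⁺; at plain Glorot scale both class
  norms start collapsed near zero and the early gradient budget is spent
  on a shared scale climb rather than on discrimination.

LSTM weights use the standard uniform `±1/√H`; the dense/vectorization
weights use uniform `±1/√fan_in`.

### Ablation variants

`routing_only` feeds the per-time-step channel snapshot directly through
the vectorizing affine map (the T snapshots are the lower routing units);
`bilstm_only` mean-pools the hidden sequence and reads out two sigmoid
scores from a dense layer, trained with the same margin loss (the sigmoid
plays the role of the norm's [0, 1) range). The exact wiring of the
reduced variants is an interpretation — the reference experiments only
name them.

## Training and evaluation protocol

AdamW (lr 2e-3, β = (0.9, 0.999), decoupled weight decay 1e-2 on weight
matrices only), batch size 64, early stopping on validation loss with
patience 10 and restoration of the best-validation weights (monitoring
validation accuracy and keeping final weights are available as options).
Splitting: subjects are shuffled by seed, assigned to 5 grouped folds, and
20% of each fold's *training subjects* are held out as the inner
validation set — grouping the inner split preserves subject independence
of the early-stopping signal. Everything (generator, splits, batch order,
weight init) is driven by explicit seeds; full cross-validation runs are
bit-reproducible on a single CPU thread.

Metrics: epoch-level confusion matrix with MDD positive (precision/
recall/F1) and HC negative (specificity/FPR); rates as percentages rounded
to two decimals, with zero-denominator rates reported as undefined rather
than zero. ROC/AUC by trapezoidal integration over all thresholds (equal
to the Mann–Whitney pairwise probability, ties at ½), computed per fold
and pooled over all test epochs.

## The recovery experiment and its problem sizes

`eegroute.experiments.recovery_run` is the package's end-to-end
self-check: 10 subjects per class, 60 s each at 250 Hz, 128 channels,
doubled delta and gamma amplitudes; full-band preprocessing; a small
configuration (H = 16, d = d′ = 8, r = 3) trained for at most 30 epochs per
fold. These sizes give 600 test epochs pooled across folds and train in
roughly two minutes per cross-validation on one CPU; the headline numbers
are medians over three independent seeds. The null condition (all
multipliers 1) must collapse to chance — it is the negative control that
would catch subject leakage anywhere in the chain.

## Numerical choices

- float32 parameters and activations for training speed; float64 available
  through `ModelConfig(dtype=...)` and used by the finite-difference tests.
- squash guards the zero vector with ε = 1e-8 (squash(0) = 0 exactly).
- σ floor 1e-6 in normalization; constant (channel, time) locations
  normalize to zero rather than exploding.
- Epoch windows are 0-based half-open `[i·wT, (i+1)·wT)`; the trailing
  remainder is discarded.
- The LSTM recurrence runs in Numba-compiled kernels; gradients for every
  parameter and for the input (saliency) are analytic and tested against
  central differences at 1e-6 step.

## Interpretation tools

Saliency is the absolute input gradient of the winning class's norm —
deliberately the simplest attribution consistent with a per-(channel, time)
heat map. The temporal attention curve is the final-iteration routing
coupling of the predicted class: it is the only normalized per-time-step
weighting the architecture possesses, and it degenerates to the uniform
1/T curve when r = 1 (zero-initialized logits). Aggregation splits epochs
by prediction correctness and reports group means, with empty groups
flagged absent rather than zero-filled.

## Known limitations

- The synthetic construct validates machinery, not clinical claims; no
  real-EEG benchmark is bundled.
- EDF files can be read (via MNE) but not written; the npz + JSON bundle
  is the package's interchange format.
- The routing softmax axis follows the per-class (one-vs-rest) reading;
  with K = 2 this trains well, but it removes the inter-class competition
  of classic capsule routing and may behave differently for larger K.
- Margin parameters, d′, recurrent depth and the logit-scale treatment are
  convention-based defaults, configurable but not systematically tuned.
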