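# Methods

This note documents the models and procedures implemented in
`fallstream`, the assumptions behind them, and the choices made where the
design was genuinely open.

## Problem setting

Body-worn inertial sensors record tri-axial acceleration (units of g,
gravity included: a device at rest reads magnitude ≈ 1 g) and angular
velocity (deg/s). The task is binary classification of fixed-length
windows into *fall* vs *activity of daily living* (ADL), with the hard
cases being "fall-like" ADLs — sitting down heavily, bending over,
jumping — whose acceleration transients resemble impacts. A fall has a
characteristic four-phase signature that ADLs lack as a whole: ordinary
movement (*prefall*), a sub-1 g dip as support is lost (*falling*), a
short high-g spike (*impact*), and stillness on a rotated gravity axis
(*postfall*). The gyroscope adds the postural-rotation information that
acceleration alone cannot provide.

## The classifier

Two identical-architecture, independently weighted streams process the
accelerometer and gyroscope blocks of a segment (`LoS × 3` each, `LoS`
divisible by 4):

* **Encoders.** Three 1D convolutions, each 64 filters, kernel 3,
  stride 1, zero ("same") padding. Encoders 1–2 are followed by ReLU and
  max-pool of size 2; encoder 3 feeds global pooling directly (no
  activation). Same padding makes the pooled lengths exact halves, so
  the 64-D output holds for any admissible `LoS` (600, 400, 120, 60 …).
  Global pooling is average by default (`model.pooling: max` switches to
  max).

* **Self-attention.** The pooled 64-D vector `x` is projected by learned
  64×64 matrices into `q, k, v`. The default formulation is attention
  over the positions of the feature vector itself:
  `A[i, j] = softmax_j(q_i · k_j / τ)`, output `y = A v`, temperature
  `τ = √64` following scaled dot-product convention. This choice needs a
  justification: applied literally to a single pooled vector, token-wise
  attention is degenerate (the softmax of one scalar is 1 and the layer
  collapses to `y = v`). The outer-product form is the interpretation
  that keeps 64×64 query/key/value matrices meaningful, produces a
  nontrivial row-stochastic 64×64 attention map, and realizes
  "re-weighting the positions of the 1-D feature vector": each output
  coordinate is a convex combination of value entries. An alternative
  mode (`model.attention_mode: temporal`) applies standard scaled
  dot-product attention across the `LoS/4` temporal positions *before*
  global pooling; it is provided because the degeneracy argument cuts
  both ways and temporal attention is the more conventional reading.
  Whether the two streams share attention weights is another open point;
  the streams here are fully untied.

* **Head.** Concatenation to 128-D, batch normalization (batch statistics
  during training, running averages at evaluation), dropout 0.5, a 256-D
  ReLU hidden layer, and a 2-way softmax. Predicted label = argmax.

The network, backpropagation and Adam are implemented in numpy (float32).
Gradient correctness is verified in the test suite against central finite
differences with the module switched to float64. Total parameter count is
109,058, independent of `LoS`; a test pins this as a regression guard.

**Input standardization.** Accelerometer and gyroscope channels live on
very different numeric scales (O(1) g vs O(100) deg/s). Each channel is
z-scored with training-set statistics (stored in the checkpoint) before
the first convolution. This is a package design choice: batch
normalization deeper in the head does not compensate for a 100× input
scale mismatch at the first convolution, and convergence without it is
markedly slower.

**Initialization.** Kaiming-style uniform (bound `1/√fan_in`) for
convolutions and dense layers; N(0, 0.02²) for the attention matrices.
All seeds derive from the run's global seed.

## Signal conditioning

Pipeline order is fixed and tested: physical-unit conversion → zero-phase
low-pass → resample to the common rate → window.

* **Filter.** Order-4 Butterworth, 20 Hz cutoff (voluntary human movement
  lives below ~20 Hz), applied forward–backward (`sosfiltfilt`) so the
  filter is zero-phase and impact timing is preserved. Requires
  `fs > 2·cutoff`.
* **Resampling.** Target rate 50 Hz. Integer ratios decimate (the signal
  is already band-limited well below the new Nyquist); non-integer ratios
  (MobiFall's 87 → 50, 100 → 50) interpolate linearly onto a uniform
  grid, using native timestamps when present. Output length is
  `round(n·fs_out/fs_in)`. When the two sensors have different native
  rates they are interpolated onto one shared 50 Hz grid and truncated to
  their overlap before stacking.
* **Windowing.** Fall trials yield one window centered on the global
  acceleration-magnitude peak, clamped into bounds — this guarantees the
  impact phase is inside the window regardless of where it occurred in
  the trial. ADL trials are tiled with consecutive non-overlapping
  windows. Windows are half-open sample intervals `[start, start+LoS)`.
  Recordings shorter than one window are skipped with a logged warning so
  batch ingestion proceeds.
* **Unit conversion.** SisFall files are integer ADC counts; defaults
  follow the dataset's first accelerometer (±16 g, 13 bit) and gyroscope
  (±2000 deg/s, 16 bit), exposed as configuration because the choice of
  device/scaling is not fixed by the format itself. MobiFall rows are
  m/s² and rad/s with nanosecond timestamps, converted to g and deg/s.

## Training protocol

Cross-entropy loss, Adam (β₁ = 0.9, β₂ = 0.999), batch size 128, initial
learning rate 0.001 with step decay ×0.1 at epochs 100 and 200 — the
simplest monotone realization of a "gradually decreasing" schedule; both
the boundaries and factor are configurable. The training budget of 300 is
interpreted as *epochs* (a step-scale reading of the same number would
amount to only a handful of epochs); `epoch_unit: step` switches the
interpretation. Model selection: 10% of training *subjects* (at least
one) are held out as a validation set, and the checkpoint with the best
validation F1 is returned. Hyperparameter search draws uniformly without
replacement from the batch-size × learning-rate grid
({32, 64, 128} × {0.001, 0.005, 0.01}) and ranks draws by validation F1.
No class weighting is applied by default; inverse-frequency weights are
available behind `class_weighting` for imbalanced corpora (public fall
datasets run roughly 1 : 2.3 fall : ADL).

Determinism: given a seed, shuffling, dropout, initialization and
splits are all reproducible; training histories are bitwise repeatable
on the same platform/BLAS.

## Evaluation studies

* **Metrics** are percentages with fall as the positive class; zero
  denominators yield 0 with an `undefined` flag rather than an error.
  Values are reported to full precision and printed at 2 decimals;
  comparisons against 2-dp published tables tolerate ±0.01 for
  rounding-vs-truncation ambiguity.
* **Cross-validation** is subject-wise: subjects are shuffled once and
  split into k near-equal folds; each fold is the test group for a model
  trained from scratch on the rest. The reported average is the
  arithmetic mean of fold F1 scores. (Whether published CV protocols
  fold by subject or by segment is often unstated; subject-wise is the
  stricter and more deployment-relevant choice, consistent with the
  subject-wise train/test split.)
* **Sampling-rate ablation** retrains a model per rate (50/10/5 Hz) with
  a shared seed and subject split, rather than evaluating the 50 Hz model
  on decimated input — the question is what a system designed for the
  lower rate could achieve. Segments are anti-alias filtered (cutoff
  0.4 × rate) before decimation; a 12 s window becomes 120 samples at
  10 Hz and 60 at 5 Hz.
* **Attention-effect study.** `export_embeddings` emits per-segment,
  per-stream 64-D vectors before and after the attention module (the
  post vector is exactly `A·v`, and a test recomputes it from the
  diagnostics). Class separation is quantified with silhouette scores on
  the concatenated two-stream features; t-SNE visualization of the same
  table is left to standard libraries.
* **Streaming inference** classifies the most recent 8 s window
  (400 samples at 50 Hz) every 0.5 s; the first prediction is available
  at t = 8 s and any fall-labeled window is an alarm (no debouncing —
  mirroring an alert application that pages on first detection).

## The synthetic generator

The generator exists so the whole pipeline is testable without data
downloads; it emulates the statistical structure the classifier relies
on, not biomechanics.

Fall template (all configurable): prefall = 1 g plus a 0.3 g gait
oscillation at 2 Hz; falling = 0.4 s exponential decay of magnitude
toward 0.2 g; impact = 0.1 s half-sine whose maximum equals the profile's
`impact_peak` exactly in the noiseless case (drawn U(3, 6) g across
subjects); postfall = 1 g along an axis rotated by 90° by default.
Orientation switches from the resting axis to the rotated axis at
impact. The gyroscope carries a Gaussian rotation burst time-locked to
the falling/impact phases (peak U(150, 300) deg/s per subject) on a
random rotation axis. ADLs: rest (constant gravity), walking/jogging
(gait-frequency oscillation of the magnitude, mild limb rotation in the
gyro), sit-down/bend-down (a single 0.5 s half-sine transient up to
`transient_peak`, U(1.5, 2.5) g, with a transient — not sustained —
rotation). Per-axis Gaussian noise (default σ drawn U(0.01, 0.05) g per
subject; gyro noise floor 50× the acceleration σ in deg/s). Cohorts give
every subject an independent parameter draw so subjects differ
systematically, which is what makes subject-wise splitting meaningful;
trials are 12 s by default so a 12 s window yields exactly one segment
per trial.

What the generator does **not** emulate: device orientation drift,
soft-tissue and clothing artifacts, sensor bias/saturation, the
near-miss ADLs (stumbles, trampoline free-fall) that make real fall
detection hard, or realistic class imbalance. Consequently, passing the
synthetic end-to-end checks demonstrates that the implementation —
conditioning, architecture, gradients, training loop, splitting,
inference — is correct and that the model can exploit the fall
signature; it does not certify real-world detection accuracy, and
near-perfect synthetic scores are expected rather than impressive.

## Problem sizes used in tests and the acceptance script

Chosen as the package's own desk-scale defaults: the end-to-end study
uses the 10-subject cohort (50 falls + 50 ADLs per subject → 1000
segments of 600 samples) trained for 10 epochs; the ablation and
streaming studies use 8-subject cohorts (2 subjects held out) with
12/10-epoch budgets at batch 16, which probing showed is comfortably past
convergence for these sizes; directional claims (50 Hz ≥ 5 Hz accuracy,
post-attention silhouette ≥ pre) are decided by a 3-seed majority to
absorb single-draw subject effects.

## Numerical notes and limitations

* float32 throughout the network; eval-mode forward passes are
  deterministic and per-sample independent (batch-permutation
  equivariant), both under test.
* `MaxPool2` requires even temporal length, hence the `LoS` divisible-by-4
  precondition; ties in max-pooling resolve to the first position
  (argmax convention).
* Butterworth + decimation assumes the 20 Hz-filtered signal is
  band-limited below the target Nyquist (25 Hz at 50 Hz), which holds by
  construction; ablation rates below 50 Hz apply their own anti-alias
  filter.
* The metric helpers report undefined ratios as 0 with a flag; an
  all-zero confusion raises.
* Only binary fall/ADL classification is supported; multi-class activity
  recognition, multi-head attention, residual connections and positional
  encodings are out of scope.
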