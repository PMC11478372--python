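# Methods

This note documents the models, the numerical choices, and the limits of
what the package's tests demonstrate.

## Signal model and synthetic data

Each heartbeat class is rendered as a sum of Gaussian bumps, one per ECG
wave: amplitude (mV), width (Gaussian σ, seconds) and offset from the R
peak (seconds). The five templates encode the textbook discriminators —
sinus P/QRS/T for N; a taller, narrower, closer-coupled ectopic P′ for A;
a P-free wide QRS (σ_R = 32 ms, total width > 120 ms at a 0.05 mV
threshold) with discordant T for V; a broad notched R with discordant T
for L; an rsR′ complex for R. Records place beats at R-to-R intervals of
60/heart-rate seconds with ±5 % uniform jitter (enough to exercise the
detector's adaptive thresholds without pathological rhythms). Because
overlapping bumps can shift the rendered maximum a sample or two off the
R-bump center in the wide-QRS classes, the generator reports the actual
waveform peak (±10 ms search) as ground truth.

Segment-level generation renders the labeled beat at window offset 179
plus partially visible neighbours: preceding interval ≈ 0.62 s for the
premature classes (A, V), ≈ 0.8 s otherwise, and a compensatory ≈ 1.0 s
pause after V — the timing signature is part of what distinguishes these
classes clinically, and it carries class information here too.

Noise is additive: white Gaussian (default σ 0.03 mV for segments),
baseline wander (0.02 mV at 0.33 Hz) and powerline hum (0.01 mV at
50 Hz), all seeded. These defaults were fixed once so that the class
means are separated by more than 3× the additive-noise floor — the
generator is *designed* to be learnable. Consequently the end-to-end
accuracy the tests achieve (≥ 0.95, typically 1.0) demonstrates that the
pipeline is wired correctly and can fit its training signal; it says
nothing about accuracy on real recordings, where inter-patient morphology
variation, electrode artefacts and rhythm context dominate. What the
generator does **not** emulate: multi-lead morphology, fibrillation or
other rhythm-level arrhythmias, non-stationary noise, pacemaker beats.

## EEMD

EMD sifting uses cubic-spline envelopes through the local extrema
(plateau runs deduplicated), with the two nearest extrema mirrored about
each end of the signal to stabilize the splines. Sifting stops when the
envelope-mean energy ratio Σm²/Σh² falls below 0.2 (Cauchy-type
criterion) or after 50 sifting passes; mode extraction stops when the
residue has fewer than two maxima or minima, so the residue absorbs the
trend and `sum(imfs) + residue` reconstructs the input exactly by
construction.

EEMD defaults are the community-standard 100 trials at noise fraction
ε = 0.2 of the signal's standard deviation. Trials can yield different
mode counts; shorter trials are zero-padded at the tail before averaging
so the per-mode mean stays well defined. The averaged reconstruction
differs from the input by the ensemble-mean of the injected noise, which
shrinks as ε/√n — this is verified empirically at n ∈ {10, 40, 160}.
Degenerate inputs (constant signals, fewer than three extrema) raise a
dedicated error rather than returning an empty decomposition.

Denoising removes the leading (highest-frequency) mode by default
(`drop_leading=1`); the parameter is exposed because how many leading
modes to discard is signal-dependent. Metric conventions: a perfect
estimate reports SNR = +∞ (with RMSE 0 and correlation 1); a constant
reference makes the correlation undefined and raises. The correlation is
the standard Pearson coefficient. When a clean reference exists
(synthetic data) metrics are computed against it; for real signals the
only evaluable reference is the raw input, and both usages are supported.

## R-peak detection and windowing

The detector is the classic Pan–Tompkins chain with its published
constants: 5–15 Hz band-pass (order-2 Butterworth, zero-phase filtfilt),
five-point derivative, squaring, 150 ms moving-window integration, 200 ms
refractory period, running signal/noise peak estimates with the 0.125 /
0.875 update weights, threshold = noise + 0.25·(signal − noise), and an
RR-based search-back that accepts the best sub-threshold candidate above
half the threshold when 1.66× the average RR elapses without a beat.
Detections are refined to the local maximum of the band-passed signal
within ±75 ms. Records shorter than the 2 s learning phase are rejected.
On the synthetic fixture (60 s, 80 bpm, 20 dB SNR) sensitivity and
positive predictivity are both ≥ 0.99 at ±50 ms tolerance.

Windows take 179 samples before the R peak and 180 after (360 total, R at
offset 179). The window orientation is fixed here once; the total of 360
samples at 360 Hz (one second) is the constraint that matters. Boundary
beats without full context are dropped and counted. Z-scoring uses the
segment's own mean and population (n-denominator) standard deviation, per
segment rather than per record, so every training input is scale-free;
constant segments raise.

Class balancing equalizes class sizes by uniform undersampling without
replacement above the target and duplication-based oversampling below it
— sample values are never synthesized. Splitting is a stratified 70/30
train/test partition with a validation set carved from the training share
(default 10 % of it; the fraction is configurable).

## Network and training

The layer stack and its dimension chain are fixed by the architecture
configuration (table in the README). Numerical choices:

* Convolutions use 'same' padding, pooling 'valid' — the only
  combination that reproduces the documented chain (360→120 with k20/s3;
  120→40 with pool 2 stride 3). The first conv block and first pool block
  both use stride 3.
* Block order is conv → batch norm → ReLU (third conv block has no batch
  norm); the SE block sits after the third conv's ReLU, before the final
  pool.
* SE reduction r = 8 (bottleneck 4 for 32 channels), Swish in the
  bottleneck and sigmoid at the restore, so channel weights lie strictly
  in (0, 1). r is configurable since no single value is canonical.
* LSTM width 100, fused gate order (i, f, c̃, o), forget-gate bias
  initialized to 1, Glorot-uniform input weights and orthogonal recurrent
  weights. A standalone per-step reference cell written directly from the
  gate equations serves as the conformance oracle for the batched BPTT
  layer (agreement ≤ 1e−5 over 100+ random instances).
* Dense layers 20 and 10 with ReLU and L2 penalty λ = 1e−3 (λΣw²);
  dropout 0.1 before them; 5-way softmax output. Training computes
  logits and uses fused softmax cross-entropy for numerical stability.
* Batch-norm running statistics use momentum 0.9 (not the 0.99 common in
  large-scale training): with tens of optimizer steps per epoch the
  inference statistics must converge within a few hundred updates, and
  0.99 leaves them half-initialized for the first several epochs.
* Everything is float64 and seeded — weight init, shuffling, dropout —
  so identical seeds give bit-identical histories. Batch-norm statistics
  are saved and restored together with the weights (checkpoints and
  early-stopping restoration would otherwise evaluate with stale
  statistics).
* Adam uses the conventional β₁ = 0.9, β₂ = 0.999, ε = 1e−7.

Early stopping monitors validation loss with default patience 20 and
restores the best weights. The sweep harness retrains one freshly seeded
model per configuration on identical data; its table reports the mean
validation accuracy/loss over the full curve (the column mirroring the
published sweep tables) plus the final-20-epoch means, since the exact
averaging window behind such tables is ambiguous. The default grids are
learning rates {0.0006 … 0.002} at batch 150 and batch sizes {70 … 190}
at learning rate 0.001; the recommended operating point is 0.001 / 150.

## Problem sizes

The test suite and the acceptance checks run everything at desk scale,
chosen as the smallest sizes at which each property is meaningful:
training uses 500 segments per class (2 500 total, 70/30 split,
validation carved from training) for up to 12 epochs at the recommended
operating point — the model converges on the synthetic classes within ~5
epochs; EEMD checks use 2 s signals at up to 160 trials; detector scoring
uses one minute of signal. A full-scale run on the real database (tens of
thousands of beats, hundreds of epochs) uses the same code paths with
larger numbers.

## Known limitations

* EMD end effects are handled by mirror extension only; long slow trends
  can leak between the last mode and the residue.
* The detector is tuned for upright QRS morphology in an MLII-like lead;
  inverted-QRS leads would need the refinement step generalized to
  absolute value.
* Oversampling by duplication cannot add information; with severely
  skewed real data the minority-class metrics remain optimistic on the
  balanced set.
* The WFDB codec covers what the pipeline touches: header + signal
  formats 16 and 212, MIT beat annotations (including SKIP intervals;
  NUM/SUB/CHN/AUX modifiers are skipped). It is not a general WFDB
  implementation.
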