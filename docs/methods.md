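# Methods

This note records the modeling assumptions, the defaults chosen where the
model family leaves them open, and what the synthetic experiments do and do
not demonstrate.

## Synthetic data generator

Each trial consists of a stimulus segment and a resting baseline at 128 Hz.
A latent binary class per affect dimension is drawn balanced across trials
(±1 trial when odd); the class of the designated *signal dimension*
(default: valence) drives the physiology, the other dimensions' classes
affect only their ratings. Ratings are uniform on (threshold, max] for the
high class and [min, threshold] for the low class, so strict-threshold
binarization recovers the latent class exactly (threshold 5 on a 1–9 scale,
3 on a 1–5 scale).

EEG channels are sums of one sinusoid per band — delta 0.5–4, theta 4–8,
alpha 8–13, beta 13–30 Hz, with random frequency and phase per
channel/trial and base amplitudes 1.0 / 0.8 / 1.0 / 0.6 (arbitrary µV-like
units) — plus Gaussian noise of standard deviation `noise_sd` (default 1.0).
For the high class, alpha amplitude is multiplied by (1 + δ) on the first
⌈C/4⌉ channels and beta amplitude on the remaining channels, giving both a
localized and a distributed class signature, so the grid mapping and the
multi-scale kernels both matter. Baselines contain noise and base-amplitude
oscillations only.

EOG channels are a slow drift (0.05–0.3 Hz) plus 0.3-s biphasic blink
pulses (a Hann-windowed full sine period, amplitude 3) at a Poisson rate of
0.3 Hz, multiplied by (1 + δ) for the high class. ECG channels are a 0.08-s
triangular QRS train at 60–100 bpm (rate × (1 + δ) for the high class) with
small beat jitter and a respiratory-like wander. These templates are
deliberately simple and frequency-separated from the EEG bands.

What this emulates: trial/baseline structure, per-trial oscillatory
signatures, class-conditional band power, event-structured peripherals,
exact-by-construction labels, and bit-reproducibility from (config, seed).
What it does not: volume conduction and channel correlations from a head
model, non-stationarity within trials, artifacts other than blinks, 1/f
background spectra, or realistic effect sizes — δ is a knob, not an
estimate of any real dataset's separability. Passing recovery tests on this
generator therefore demonstrates that the implementation can extract the
kinds of features the model targets, not that it would reach any particular
accuracy on real recordings.

## Preprocessing

* **Baseline correction**: per channel, the mean of the baseline's full 1-s
  segment means is subtracted from the stimulus signal (the segment-mean
  convention of widely used DEAP pipelines). A missing baseline is a no-op;
  a sub-second baseline is a no-op with a warning (an error in strict mode).
* **Windowing**: 1-s windows with 1-s stride (non-overlapping), 0-based,
  half-open; ⌊(T_s − w)/s⌋ + 1 windows, zero if the trial is shorter than
  one window. Every window inherits its parent trial's binarized rating.
* **Binarization** is strict (score > threshold → 1) for both rating
  scales; a score equal to the threshold is "low".
* **Grid mapping**: channels are placed injectively on a 9×9 plane whose
  rows run anterior→posterior, preserving 10–20 neighbour relations; the
  default tables cover the 32-channel and 14-channel montages and can be
  replaced via a JSON layout file. Unplaced cells are exactly zero.
* **Noise injection**: additive zero-mean Gaussian noise with per-channel
  variance P/10^(SNR/10), where P is the channel's mean square; +∞ dB is
  the no-noise mode. By default only EEG channels are corrupted; a flag
  extends this to peripherals.
* No amplitude normalization is applied beyond baseline subtraction.

## Architecture defaults

Fixed by the model family: MSARB scales 3×3/5×5/7×7 with a 1×1 bottleneck
and residual connection; ECA constants t0 = 2, b1 = 1 with
k = ⌊|log2(C)/t0 + b1/t0|⌋ bumped to odd; DSANet kernels 1×50→1×10 and
1×5→1×3 with LSTM sizes 768/384; EEG-stream 3×3 convolutions with 64 and 32
maps; CBAM spatial kernel 7×7; softmax head with cross-entropy.

Chosen here (configurable in `ModelConfig`):

| parameter | default | note |
|---|---|---|
| temporal kernel k_t | 5 | per-electrode conv length, unspecified upstream |
| temporal / cross-channel filters | 64 / 64 | match the stated 64-map scale |
| DSANet conv filters | 32, 64 per branch | same rationale |
| dropout p | 0.5 | where dropout is named |
| peripheral projection F_e | 16 | channels after reshaping h_eog to the grid |
| CBAM reduction r | 8 | standard CBAM default |
| grid | 9×9 | smallest grid holding the 10–20 montage comfortably |
| init | seeded uniform ±1/√fan_in | reproducible from the model seed |

Shape reconciliation at the fusion input: the temporal stream's [F, 1, T]
map is adaptively average-pooled to the 9×9 plane; the peripheral vector is
linearly projected to F_e·H·W and reshaped. Convolutions that feed a
concatenation or residual use same padding; DSANet branch convolutions use
valid padding (nothing downstream constrains their length). LSTM branches
consume conv feature maps as L time steps of F·P-dimensional vectors and
return the final hidden state. No pooling between DSANet convolutions.

`ModelConfig.reduced()` (F0 = 8, LSTM 32/16, all widths shrunk) is the
preset for synthetic experiments and gradient checks.

## Training and evaluation

Full-scale protocol: SGD (momentum 0, no weight decay), learning rate 1e-5,
batch 64, 40 epochs (30 for the DREAMER-style preset), samples reshuffled
every epoch. The reduced preset uses lr 0.02, batch 32, 20 epochs: the
tiny-width models are stable at that step size and converge within the
small synthetic budgets.

Metrics come from the binary confusion table (positive class = high):
accuracy, SN = TP/(TP+FN), SP = TN/(TN+FP), P = TP/(TP+FP),
F1 = 2·P·SN/(P+SN). Zero-denominator metrics are reported as NaN with a
warning, never silently as 0. Kappa is reported in two forms because they
answer different questions: the uniform-chance form (N·p − 1)/(N − 1)
(exactly 2p − 1 for two classes) and the marginal Cohen form from the table
marginals; the marginal form is the default column.

Splits: `run_subject_cv` defaults to a window-level stratified shuffle
(k = 10), mirroring protocols that shuffle windows before folding.
**Caveat**: windows of one trial share both the label and the trial's
idiosyncratic signal signatures, so window-level splits let a model score
above chance by recognizing trials rather than classes — on this generator
the effect is directly measurable (held-out accuracy ≈ 0.65 at δ = 0). The
trial-grouped mode (`split="trial"`, stratified by class over whole trials)
removes this leakage and is what the parameter-recovery, null-calibration
and noise-sweep experiments use; at δ = 0 it scores ≈ 0.5 as it should.

The noise sweep retrains and tests at each SNR in {∞, 10, 0, −5} dB with
noise injected into the EEG of train and test data alike. Under the reduced
study conditions (one subject, 20 trials × 20 s → 400 windows, ~200 per
class, 14 EEG + 2 EOG channels) the δ = 1 task remains perfectly separable
down to −5 dB: the class signal is a doubling of narrowband power, which
survives broadband noise of 3× signal power at this window length, so the
sweep demonstrates *nonincreasing* accuracy rather than visible
degradation. Feature embeddings use seeded t-SNE (perplexity capped at
(n − 1)/3).

## Numerical choices

All computation is float64. The autodiff engine's primitives and every
assembled block are validated against central finite differences (worst
relative error on the full reduced model < 1e-4 with step 1e-5 and an
absolute floor of 1e-6 for negligible gradients). Batch normalization uses
ε = 1e-5 and momentum 0.1; training mode differentiates through the batch
statistics, inference mode uses running averages. Ties in max-pooling share
gradient equally. Cross-entropy on probabilities clips at 1e-12; the
training loss uses the max-shifted log-sum-exp form. The max subtraction in
softmax is treated as a constant, which is exact because softmax is
shift-invariant. Dropout is inverted (scaling by 1/(1−p) at train time) and
drawn from the model's own generator, so identical seeds give identical
training runs in single-threaded execution.

## Problem sizes

The test suite and the acceptance script run the structural checks at full
DEAP-like size (40 trials × 63 s × 34 channels) but train only reduced
models on the reduced study conditions above, and shorten DREAMER-like
trials to 20–40 s where only the window geometry matters — the row count of
a window is fixed by the montage, not the trial length. These sizes give
stable estimates (held-out n = 80 windows) at a few minutes per training
run on one CPU.

## Known limitations

* The 98%-level accuracies reported for this model family on the real DEAP
  and DREAMER datasets are not reproducible here: they require the
  controlled-access recordings and full-scale training. Nothing in this
  package asserts them.
* Adapters for the public DEAP/DREAMER release formats are out of scope of
  the test suite; the container formats documented in `synthetic.py` and
  `preprocessing.py` are the supported interchange.
* The engine is CPU-only and unoptimized for large widths; full-width
  (F0 = 64, LSTM 768/384) training is possible but slow, and is exercised
  only at forward-pass scale in the tests.
* Window-level CV remains the default for protocol fidelity despite the
  leakage discussed above; leakage-sensitive conclusions should use
  `split="trial"`.
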