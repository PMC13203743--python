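# Methods

This note records the model, the choices behind every tunable that the
package exposes, what the synthetic data does and does not emulate, and
the numerical conventions a maintainer needs.

## Signal model and preprocessing

Trials are cue-locked 4 s epochs of 3-channel EEG (C3, Cz, C4) at
250 Hz. The classification target is the imagined hand (left/right); the
physiological signal is event-related desynchronization (ERD): band-power
attenuation of the μ (8–13 Hz) and β (13–30 Hz) sensorimotor rhythms
contralateral to the imagined hand.

The time–frequency branch band-passes each trial to 4–40 Hz with a
4th-order Butterworth applied forward–backward (`sosfiltfilt`), i.e. a
zero-phase filter whose effective magnitude response is the squared
design response. The band is part of the method; the realisation
(Butterworth, order 4, zero-phase) is a package choice. When a continuous
recording is available the filter runs before epoching so edge
transients fall outside the epochs; epochs that exist on their own
(synthetic trials) are filtered directly, accepting small edge effects
inside the first/last slice.

Slicing cuts each trial into n = 8 contiguous, non-overlapping 0.5 s
slices of T = 125 samples. Slicing is an exact partition: lengths not
divisible by the slice length are an error, never padded.

## Time–frequency representation

Each slice channel is Hamming-windowed (w[k] = 0.54 − 0.46·cos(2πk/(T−1)))
and transformed with a complex Morlet wavelet

ψ(u) = (πB)^(−1/4) · exp(2πi·f_c·u) · exp(−u²/(2B)),

sampled at scale s = f_c·f_s/f for each of F = 125 analysis frequencies
linearly spaced over 4–40 Hz, L2-normalised (kernel divided by √s),
convolved with zero padding, magnitude kept. The three channel maps are
stacked (C3 ‖ Cz ‖ C4) into a 3×125×125 tensor per slice.

Parameters:

* **f_c = 0.8125** (normalised units): the center frequency of the
  conventional "morl" wavelet; fixed.
* **Bandwidth B = 4** (Gaussian time-variance; σ_t = 2): a package
  choice. The ridge of an L2-normalised scalogram of a pure tone is
  biased low by ≈ σ_f²/(2f); with the classic σ_t = 1 that bias reaches
  ~3 frequency bins at 35 Hz on this grid, with B = 4 it stays below one
  bin across the whole band. B is a `CWTConfig` field.
* **Boundary handling**: zero padding. The Hamming window already
  suppresses slice edges, so the padding choice is second-order.
* **Input scaling**: magnitudes enter the network standardised by a
  single mean/std estimated on the training set (`set_tfr_scale`).
  Per-map min–max scaling is used only for plotting.

The implementation is an FFT-accelerated bank of sampled kernels
(truncated at 5σ_t, where the envelope is ~4·10⁻⁶); the unit tests hold
it to ≤10⁻⁶ relative error against a direct time-domain convolution
oracle that re-derives the kernels from the formula above.

## Raw view and fusion

The raw branch takes the *unfiltered* slice, z-scores it per channel and
per slice (scale-invariant by construction; a per-trial variant is a
config option), and replicates it along the frequency axis so both views
share the 3×125×125 shape. Two independent 1×1 convolutions (3→3, with
bias) map the views and their outputs are added element-wise. The 3→3
width is forced by the 3-channel backbone stem.

Both gates are initialised at the identity. A "gated" scheme
(time–frequency gate at identity, raw gate near zero) is available but
not the default: with a near-zero raw gate, gradient descent fails to
recruit the raw view within desk-scale budgets — on data whose only class
cue is raw-view-only the fused model stays at chance — whereas the
identity initialisation lets either view be amplified or suppressed from
the first step. Freezing the raw gate at zero reduces the layer exactly
to the single-view time–frequency pipeline (the `tfr_only` ablation);
`raw_only` symmetrically freezes the time–frequency gate.

## Network

* **Backbone** (`shuffle_micro`, default): a reduced-depth
  ShuffleNet-style CNN — stem 3×3/2 convolution, four shuffle units
  (1×1 group convolution with g = 3, channel shuffle, depthwise 3×3,
  1×1 group convolution; stride-2 units concatenate a 3×3/2 average-pool
  shortcut, stride-1 units use residual addition), BatchNorm throughout,
  global average pooling, d = 48. A 2×2 average pool precedes the stem:
  the scalograms are smooth, so halving the spatial size costs little
  information and cuts compute ~4×. `cnn_micro` (three plain strided
  conv blocks, d = 48) exists for backbone-swap ablations. Depth and
  width are sized for CPU training on hundreds of trials; both are far
  smaller than published ImageNet backbones, which this environment
  cannot supply pretrained weights for. `pretrained=True` therefore
  loads a previously saved backbone checkpoint (transfer from another
  run) rather than ImageNet weights.
* **Transformer encoder**: 2 post-norm layers, 4 heads, model dim 48,
  feed-forward 4d, dropout 0.1, sinusoidal positions (learned positions
  and "none" are config options). Attention is softmax(QKᵀ/√d_k)V with
  d_k = 12. Disabling the positional encoding makes the pooled output
  permutation-invariant over slices (verified by test); removing the
  encoder entirely (`use_transformer=False`) mean-pools the slice
  embeddings directly.
* **Head**: temporal mean-pool over the n tokens → one linear layer →
  softmax over two classes.
* **Loss/optimiser**: mean cross-entropy; Adam with lr 0.002, batch 32,
  50 epochs by default, no schedule, no weight decay, no early stopping;
  the last-epoch model is evaluated (`eval_epoch="best"` switches to the
  lowest-training-loss epoch). One prediction per trial: the 8-slice
  sequence is a single sample, and train/test index sets are asserted
  disjoint.

All randomness (parameter init, batch order, dropout) derives from one
integer seed, so a training run is bit-reproducible on CPU.

### Autodiff runtime

`eegmvf.nn` is a small reverse-mode engine over numpy: convolutions via
im2col (recomputed in the backward pass instead of stored), a fused
BatchNorm backward, eager freeing of interior gradients, and an Adam
implementation. Every differentiable op is checked against central
finite differences in float64 in the unit tests. It exists because the
package targets plain scientific-Python environments; it is not a
general-purpose framework.

## Synthetic data

Each channel is 1/f-amplitude ("pink") noise — white noise shaped by
1/√f in the spectrum, unit RMS, scaled by `noise_level` (default 1.0)
relative to the oscillation RMS — plus one μ-band and one β-band
sinusoid (amplitudes 1.0 and 0.5, per-trial random frequency within the
band and random phase). For left-hand trials the C4 oscillations are
scaled by (1 − `erd_depth`); for right-hand trials, C3 (the contralateral
ERD convention); Cz is never modulated.

Two optional class-dependent cues support controlled experiments:

* `broadband_gain_delta`: multiplies whole left-class trials by
  (1 + δ). Note that per-channel z-scoring removes any trial-wide gain
  exactly, so this cue is invisible to both branch inputs as configured;
  it exists for pipelines that keep absolute amplitude.
* `highband_amp`: adds a 70 Hz sinusoid (random phase, all channels) to
  left-class trials. 70 Hz is far above the 4–40 Hz analysis band, so
  the bandpass erases it from the time–frequency view, while the
  z-scored raw waveform keeps it — a raw-view-only cue, the package's
  surrogate for the amplitude/phase information that time–frequency
  pipelines can lose. Whether real MI-EEG carries such cues is exactly
  the open empirical question; passing the ablation below shows the
  *mechanism* works, not that the cue exists in real recordings.

Not emulated: artifacts (EOG/EMG transients), volume conduction,
non-stationary rhythms, inter-subject variability. Consequently, passing
tests demonstrate pipeline correctness and the fusion mechanism, and say
nothing about accuracy on real EEG.

## Study conditions of the canned experiments

* **ERD separability** (`erd_separability_experiment`): erd_depth 0.9,
  100 trials/class training, 50/class held out, 10 epochs, random init.
  Expected: held-out accuracy ≥ 90 % (observed: 100 %). The chance-level
  control repeats the recipe with erd_depth 0 and 100/class held out;
  accuracy must stay inside the 95 % binomial interval around 50 %.
* **Fusion ablation** (`fusion_ablation_experiment`): erd_depth 0,
  highband_amp 1.0 (the only class cue), 40 trials/class train and test,
  three independent dataset seeds, fused / tfr_only / raw_only each
  trained 40 epochs. Metric: median margin over tfr_only. 40 epochs
  (vs. the default 50) is the point where recruitment of the raw view by
  the fused model is reliable across seeds; at 25 epochs it was
  seed-dependent. Problem sizes throughout are scaled so the whole suite
  trains on one CPU in minutes while leaving the training recipe
  (optimizer, lr, batch size) untouched.

## Known limitations

* No ImageNet pretraining path; the transfer-learning ablation of the
  original study design can only compare random init vs. a user-supplied
  checkpoint.
* The GDF reader handles the BCI IV 2b dialect (3 EEG + optional EOG
  channels, cue annotations 769/770); it is not a general GDF tool.
* BatchNorm statistics make eval-mode outputs depend on the training
  batch composition; with very small toy datasets (a handful of trials)
  train-mode loss and eval-mode accuracy can disagree noticeably.
* The engine is single-threaded numpy; wall-clock scales linearly with
  trials × epochs (~0.2 s per trial-epoch at default sizes).
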