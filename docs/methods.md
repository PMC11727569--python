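# Methods

## Signal model and preprocessing

Surface EMG is modelled here as band-limited (≈10–500 Hz),
microvolt-scale, channel-patterned activity superimposed on three noise
sources: broadband white noise, sinusoidal power-line interference, and
slow baseline drift. Preprocessing is therefore a 4th-order Butterworth
band-pass (10–500 Hz) followed by per-channel Z-scoring and sliding-window
segmentation into `L×T×1` images, `L = w·f/1000`.

Numerical and design choices:

* **Nyquist clamping.** At 1 kHz sampling the 500 Hz upper edge sits on
  Nyquist, where a digital band edge is ill-defined; the effective upper
  cutoff is `min(high_hz, 0.45·f)`, with a logged warning. The band-pass
  contract is otherwise unchanged.
* **Filter order.** "4th order" is passed directly as the Butterworth
  design order (`scipy.signal.butter(4, ..., btype="bandpass")`); scipy
  doubles the prototype order for a band-pass, which is the conventional
  reading of "4th-order Butterworth band-pass" in the EMG literature.
  The filter-quality checks (stop-band power ratio, mid-band RMS
  preservation) do not depend on this reading.
* **Zero-phase offline, causal online.** Training images are filtered
  forward–backward (no phase distortion); the streaming path applies the
  same coefficients causally with carried state, so chunked streaming
  output is bit-identical to a single causal pass.
* **Z-score.** Population (ddof = 0) standard deviation, fixed so the
  exact unit tests are well-defined; at window counts in the hundreds the
  sample/population difference is immaterial. A constant channel is a
  hard error naming the channel. Statistics are fitted on the samples
  outside the test repetitions by default ("train" scope), preventing
  test-set leakage through the normaliser; "all" scope is available for
  single-pass exploratory use. (Z-scoring yields mean 0 / unit variance,
  not values in [0, 1]; the implementation is the standard Z-score.)
* **Window labels.** A window spanning a label transition takes the
  majority per-sample label, ties broken toward the larger class index;
  windows whose majority is rest (label 0) are dropped by default, since
  the task is gesture classification, not onset detection. Windows are
  half-open `[start, start+L)` on 0-based samples, starting at multiples
  of the step `S = s·f/1000`; non-integer `L` or `S` is an error rather
  than a silent rounding.

## Synthetic sEMG generator

The generator emulates the acquisition protocol the method is designed
for: for each repetition `r = 1..reps`, every class contributes `rest_s`
seconds of baseline (label 0) followed by `active_s` seconds of activity
(label = class, repetition = r). Defaults: 5 s active / 3 s rest,
5 repetitions, 8 channels at 1000 Hz, 60 µV base amplitude (the 15–100 µV
range typical of surface electrodes), 50 Hz line interference at 2 µV,
5 µV RMS baseline drift, and 25 dB SNR.

Each gesture class is a `GestureProfile`: a per-channel gain vector built
from a distinct binary activation mask ("on" channels draw gains in
[0.7, 1], "off" in [0.05, 0.3]), guaranteeing any two classes differ by
≥ 0.4 in at least one channel — the separability the learning tests rely
on. The active signal is Gaussian noise band-passed to the profile's
burst band (default 20–450 Hz) and shaped by a plateau envelope with
100 ms raised-cosine ramps (avoiding step discontinuities the Butterworth
filter would ring on). The per-recording RNG stream derives from
`(seed, subject_index)`, so multi-subject datasets are reproducible
element-wise.

What it does **not** model: motor-unit action-potential trains and
recruitment, electrode shift, skin-impedance changes, fatigue,
inter-subject variability of any physiological kind. Passing tests
therefore demonstrate that the pipeline and network behave as specified
on band-limited channel-patterned signals — not that the reported
benchmark accuracies on real datasets are reproduced.

## Network

Implemented on a small reverse-mode autodiff engine (`myogest.nn`,
NHWC layout, float64), with gradients verified against central finite
differences in the test suite. Architecture constants follow the design:
per-branch multi-scale kernels (5×1, 8×1, 1×2) and (10×1, 20×1, 1×4),
8 kernels per arm (→ 32 concatenated channels), 2×2 pooling and spatial-
attention kernels, 128-dim fused step vectors, bidirectional LSTM hidden
size 128 (→ 256-dim output). Where the design is under-specified the
package makes these choices:

* **Same-padding, stride 1** in all multi-scale arms (and a stride-1
  2×2 max-pool with same padding in the pooled arm, whose "length-1
  kernel" is realised as a 1×1 conv to 8 channels): channel-axis
  concatenation forces equal spatial dims, and same-padding is the
  minimal way to get them.
* **Even 2×2 kernels** pad asymmetrically (one extra row/column at the
  trailing edge), preserving `L×T`.
* **Channel-attention reduction r = 8**: the CBAM default of 16 would
  leave a 2-unit bottleneck at 32 channels.
* **Residual unit**: conv 3×1 → batch-norm → ReLU → conv 3×1 →
  batch-norm with identity shortcut and a final ReLU — the shallowest
  standard residual block, keeping the shortcut while avoiding depth
  that overfits small sEMG datasets.
* **Sequence length τ = 8.** A strictly 1×128 front-end feature would
  leave the recurrent layer a single step and no temporal structure to
  model; the package keeps a short time axis (adaptive average pooling
  to τ = 8 steps, each honouring the 128-dim constraint) so the
  bidirectional LSTM sees a genuine sequence.
* **Dropout 0.5** before the classifier; **fan-in-scaled uniform** weight
  init from a seeded generator. Bitwise reproducibility is promised per
  platform/BLAS build, not across them.

Ablation ladder (used by the comparison tests): `bilstm` (three stacked
bidirectional LSTM layers on raw window rows, no convolutions),
`attn_cnn` (3×3 conv stem to 32 channels + residual attention + global
average pooling), `ms_attn_cnn` (multi-scale block + residual attention,
time-averaged fused features), `full` (the complete model). The conv
stem in `attn_cnn` is the package's choice — some stem is needed to meet
the attention block's 32-channel input contract.

## Training and evaluation

Adam (lr 1e-3, batch 64 — unstated by any benchmark protocol, standard
defaults), mean categorical cross-entropy with probabilities clamped at
1e-12, whole repetitions held out. One global seed fans out to weight
init, dropout masks and batch shuffling. Divergence (non-finite loss)
aborts with diagnostics rather than continuing.

### Desk-scale problem sizes

The stochastic end-to-end checks run on the generator's protocol
defaults with 4 classes, 8 channels, 5 repetitions, 35 dB SNR, 100 ms
windows with a 100 ms (non-overlapping) step — 1000 windows, 800 train /
200 test on the {1,2,4,5}/{3} repetition split. The full model trains
for 8 epochs in the learning check; the ablation comparison gives both
variants the same matched 8-epoch, identical-data budget. These sizes
are the package's chosen smoke-test scale: large enough that the fused
multi-scale features must actually be learned, small enough to run
routinely. They are not a reproduction of any published benchmark
figure, and the real-data benchmark accuracies are out of scope here
(training hyper-parameters for those runs were never published, so they
are not exactly reproducible even with the data).

## Streaming

Windows are emitted from a ring buffer the moment their last sample
arrives (starts at multiples of S); the causal filter carries state
across chunks, so streaming windows equal an offline causal-filtered
segmentation exactly — a property the tests assert. One vote per emitted
frame enters the FIFO buffer (capacity V, default 100); the modal label
is re-emitted every frame, ties breaking toward the most recent tied
label (favouring responsiveness). Rest participates in voting and maps
to `idle`; the command map covers the six manipulator gestures. Response
time and prediction speed are measured per window and reported for
information only — they are hardware-dependent and never asserted.

## Known limitations

* The synthetic generator's separability makes the learning tests easy
  relative to real inter-gesture confusion; accuracy numbers on it say
  nothing quantitative about real datasets. In particular, because class
  identity is carried by per-channel amplitude patterning (linearly
  separable from window RMS by construction), the stacked-Bi-LSTM
  baseline — which integrates per-channel magnitudes directly — can match
  or exceed the full model here, whereas on real sEMG the multi-scale
  convolutional features are what separate the architectures. The
  ablation comparison on synthetic data therefore probes wiring and
  budget parity, not the real-data ranking.
* The autodiff engine is single-threaded numpy: fine at the package's
  problem sizes, not a GPU training stack.
* The pure recurrent baseline reads raw 100-step windows and is the
  slowest variant by far; budget comparisons keep its epochs small.
* No artifact rejection beyond the band-pass; no electrode-shift or
  fatigue robustness.
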