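# Methods

`insound` classifies short insect-sound recordings by recasting them as
time-frequency images and training a small convolutional network on those
images. This note documents the models and procedures, the defaults that
matter, and what the bundled synthetic corpus does and does not demonstrate.

## Preprocessing

Insect sound energy is concentrated at low frequencies, so the pipeline
first removes everything above the band of interest and then lowers the
sampling rate.

**FIR low-pass (window design method).** The ideal low-pass impulse
response `h_ideal(n) = sin(2π f_n n) / (π n)` (normalized cutoff
`f_n = f_c / f_s`, limit value `2 f_n` at `n = 0`) is truncated to
`order + 1` taps by a Hamming window `w[n] = 0.54 − 0.46 cos(2πn/(N−1))`
and centered at `order/2`, giving an exactly linear-phase (type-I) filter.
Taps are rescaled to unit DC gain so constant signals pass unchanged. The
default order is 100 (101 taps), the reference setting for 16 kHz input.
The Hamming window is constructed half-and-mirror so tap symmetry holds to
the last bit, which makes the linear-phase property assertable exactly.
Application is plain convolution with the group delay (`order/2` samples)
compensated and zero-extension at the edges.

**Anti-aliased downsampling.** Band-limited interpolation
`y'(n) = Σ_k x(k) · sinc(n/R − k) · w(k)` with `R = f_t / f_s`, evaluated
with a Hamming-tapered sinc kernel of half-width 64 source samples
(configurable). Before interpolation an anti-alias FIR is applied. Its
*design* cutoff is shaded below `f_t/2` by half the Hamming transition
width (`3.3 f_s / taps`) so that the filter's **stopband edge** — not its
−6 dB point — lands on the new Nyquist frequency; with the cutoff placed
exactly at `f_t/2`, half of the transition band folds back on decimation
and about 1% of broadband energy aliases. With the shaded design, aliased
mass for white-noise input is far below 1% of the total. Output length is
`floor(n · f_t / f_s)`. Upsampling is out of scope. The fast implementation
is an exact evaluation of the windowed sum (verified against a naive all-k
reference at float precision); relative to the *ideal* unwindowed
interpolator the Hamming taper introduces ≈3·10⁻⁴ passband droop, which is
why the correctness contract is stated against the windowed sum.

## The PLMS feature

The patch-level log-scale mel spectrogram maps a preprocessed mono clip to
a 256×256×3 image:

1. **Patch framing.** The analysis window spans `Num` base hops (base hop
   10 ms, so `N = Num × round(0.01 f_t)` samples; 250 samples at the
   reference `Num = 10`, `f_t = 2500 Hz`). Consecutive patches overlap by
   half a window (`shift = N/2`). Under this mapping, doubling the patch
   size halves both the frame count and the STFT bin spacing — the
   time/frequency resolution trade-off the patch-size parameter is meant to
   steer. (The alternative fixed-shift reading would leave the frame count
   essentially independent of `Num`, which contradicts that trade-off, so
   the proportional-shift reading is used.)
2. **STFT.** Hamming-windowed `N`-point transform per patch, one-sided
   bins, power `P = |X|²`.
3. **Mel filterbank.** `M` triangular filters whose `M + 2` edge
   frequencies are uniform on the mel axis (`mel(f) = 2595 log10(1 +
   f/700)`) between 0 Hz and `f_t/2`, evaluated at the bin frequencies.
   Default `M = 128`; at the reference configuration the narrowest triangle
   spans 11.2 Hz against a 10 Hz bin grid, so every filter covers at least
   one bin. Configurations whose windows are too short for the requested
   band count (for example `Num = 5` at 2500 Hz with `M = 128`) raise a
   degenerate-filter error telling the user to lower `M`.
4. **Log scaling.** `10 log10(S / max S)` with the *global* maximum as the
   reference, clipped at −80 dB. Because the reference is the clip's own
   maximum, the image is exactly invariant to positive amplitude scaling of
   the waveform — loudness is deliberately not a feature.
5. **Log-frequency axis.** Band values, placed at their center
   frequencies, are linearly interpolated onto rows uniform in `log10(f)`
   between 20 Hz (the axis cannot start at 0) and `f_t/2`. This magnifies
   the low-frequency region where the discriminative structure lives.
6. **Rendering.** The dB range is mapped affinely (−80 dB → 0, 0 dB → 1),
   bilinearly resized to 256×256, and colormapped (viridis, 8-bit RGB),
   with low frequency at the bottom. Rendering is byte-deterministic.

## Baseline representations

Four classical comparisons are emitted through the same renderer: the
linear-axis STFT spectrogram; a Morlet scalogram (scales log-spaced over
[20 Hz, f_t/2]); the pseudo Wigner-Ville distribution (lag-windowed
instantaneous autocorrelation of the analytic signal by default — the raw
"pseudo" mode shows the classic midpoint cross-terms between component
pairs); and the generalized S-transform, computed in the frequency domain
with a Gaussian voice of width `σ(f) = 1/(γ f^p)` (`γ = p = 1` is the
standard S-transform; the f = 0 voice carries the signal mean). None of
these baselines' hyperparameters are standardized in the comparison
literature; the values here are package defaults chosen for desk-scale
cost.

## The classifier

An 11-stage network of about 1.54 million trainable parameters:

| stage | operator | width | notes |
|------:|----------|------:|-------|
| 1–2 | conv 3×3 /2 | 16, 32 | stride-2 downsampling |
| 3 | C3k2 | 64 | no residual, reduction 0.25 |
| 4 | conv 3×3 /2 | 64 | |
| 5 | C3k2 | 128 | no residual, reduction 0.25 |
| 6 | conv 3×3 /2 | 128 | |
| 7 | C3k2 | 128 | residual |
| 8 | conv 3×3 /2 | 256 | |
| 9 | C3k2 | 256 | residual |
| 10 | C2PSA | 256 | pyramid pooled-scale attention |
| 11 | classify | 12 | embed 384 → GAP → dropout → linear → softmax |

Every convolution is bias-free with batch normalization and SiLU. A C3k2
block splits the input into two half-width branches via 1×1 projections;
one passes through, the other goes through a 3×3/3×3 bottleneck at hidden
width `filters × reduction` (0.25 at stages 3/5, 0.5 with a residual add at
7/9); the halves are concatenated and fused 1×1. The C2PSA block splits
after a 1×1 mix and refines one half with a pyramid of average-pooled
contexts (scales 1/2/4, each re-projected 1×1 and summed back), a
per-channel squeeze gate (hidden width 32), a spatial gate built from the
channel mean/max maps (7×7 convolution), and a 3×3 fuse. Descriptions of
these CSP-attention blocks in the detection-network literature leave the
internal widths free; the three free widths here (head embedding 384,
squeeze hidden 32, pyramid scales 1/2/4) were fixed once so the total
lands on the reference 1.54 M parameter budget, and the count is verified
against independent per-layer arithmetic in the tests.

The network and its training loop run on an in-package reverse-mode
automatic-differentiation engine over NumPy arrays (`insound.nn`):
im2col convolutions, batch-norm with exact training-mode gradients, and a
fused softmax cross-entropy. Everything is float32 and deterministic under
explicit seeds — identical seed and data reproduce bit-identical weights.
FLOP accounting counts multiply-accumulates of one forward pass times two;
the convention is embedded in the report because published FLOP figures
for small classifiers rarely state theirs.

**Training protocol.** SGD (momentum 0.9) at learning rate 0.1, batch 32,
cross-entropy, no dropout, no early stopping — the reference settings. Adam,
dropout and patience-based early stopping are available for comparisons.
Augmentation (seeded random crop with scale in [0.8, 1], rotation ±10°,
brightness/contrast/saturation jitter ±0.2) is available but off by
default; the synthetic benchmark does not need it. Transfer learning is a
hook: load a checkpoint, freeze stages 1–6 (the default reading of
"lower feature layers"), fine-tune the rest.

## Evaluation

Confusion matrix, Accuracy@1 (argmax, ties to the lowest index), macro
recall, macro precision, macro F1 and macro one-vs-rest AUC (mid-rank tie
handling), reported as percentages to two decimals. Macro-F1 is the
harmonic mean of macro-precision and macro-recall; the per-class-average
convention is available behind a flag (both give 1.28% on the degenerate
balanced-12-class check). A class never predicted has precision 0; classes
with no true samples are excluded with a warning. On a balanced 12-class
set a constant predictor lands exactly at Accuracy@1 = macro-recall =
8.33%, macro-F1 = 1.28%, macro-AUC = 50.00% — useful analytic anchors that
the test suite asserts. Cross-validation summaries report mean ± unbiased
(n−1) standard deviation.

## Synthetic corpus

The generator emulates the reference recording format — four channels,
2500 ms at 16 kHz, twelve classes, loudness spanning 33 dB from very loud
to nearly inaudible — with signatures built from the physically meaningful
ingredients of insect sound: a 1/h-weighted harmonic stack at a jittered
fundamental (70–600 Hz), slow amplitude modulation (wingbeat envelope,
5–40 Hz), optional pulse-train gating (stridulation bursts), and white
noise at a class-specific SNR (10–30 dB). All partials stay below 1200 Hz
so the full discriminative band survives the 2500 Hz pipeline, mirroring
the low-frequency concentration of the target insects. Channels share one
source with gains in [0.7, 1] and sub-millisecond integer delays.

What the corpus does *not* emulate: real wing-kinematic waveforms,
enclosure acoustics and reverberation, microphone-array geometry, varying
clip onset/offset behavior, or non-stationary behavioral sequences. A
passing end-to-end benchmark therefore shows that the pipeline is wired
correctly and that the feature preserves class structure — not that the
reported real-data accuracy transfers to field recordings.

## Desk-scale problem sizes

The end-to-end benchmark trains from scratch on 40 clips per class
(480 clips, stratified 8:2), with feature images downscaled to 48×48 for
the network input and 30 training epochs, repeated over three seeds for
both the PLMS and the linear-axis STFT feature. These sizes are the
package's chosen desk-scale configuration: the corpus is small enough to
synthesize in seconds and the six training runs complete in CPU minutes,
while remaining far above chance difficulty (12 classes, chance 8.33%).
The model itself is identical to the full-resolution architecture — the
parameter count does not depend on input size.

## Numerical choices and edge cases

- All audio is float64 internally, [−1, 1]; PCM-16 files scale by 2¹⁵.
- Silent (all-zero) input: the PLMS dB normalization has no reference
  level and raises; the baseline image emitters render a uniform floor
  image instead, since "no energy anywhere" is a valid image statement.
- The resampler zero-extends at clip edges; the first/last few output
  samples carry edge ripple, which the amplitude checks exclude.
- Degenerate mel filters (no bin under a triangle) raise with guidance
  rather than silently emitting empty bands.
- Image resizing uses bilinear interpolation without anti-aliasing so that
  rendering is exactly reproducible across runs.
- Tie-breaks: argmax everywhere resolves to the lowest index; AUC uses
  mid-rank ties.

## Known limitations

- The CPU implementation is practical at desk scale (seconds per clip for
  features, minutes per training run) but not for corpus-scale studies
  with hundreds of thousands of clips.
- Upsampling, streaming capture and compressed codecs are out of scope.
- The learnable-frontend baseline from the comparison literature requires
  end-to-end training of a published trainable filterbank and is not
  included.
- Pretrained backbone weights are not shipped; the transfer-learning path
  is exercised with package-trained checkpoints only.
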