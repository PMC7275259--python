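# Methods

`apneaflow` classifies annotated sleep-apnea events as obstructive (OA) or
central (CA) from the motion visible in overhead infrared video. This note
documents the models, the synthetic data they are validated on, and the
numerical choices that were genuinely open.

## Physiological signal model

During normal breathing the chest and abdomen rise and fall together.
During an obstructive apnea, respiratory effort continues against a closed
airway: the rib cage and abdomen move **out of phase** (paradoxical
breathing) and the sum of the two displacements is close to zero. During a
central apnea the respiratory drive itself is absent and both compartments
are essentially motionless. These three regimes are what every classifier
in this package ultimately keys on.

## Motion front-end

Video (nominally 640×480 at 30 fps) is decimated to 2 Hz by keeping every
15th frame — sleep breathing is below 0.5 Hz, so 2 Hz sampling still
respects the Nyquist rate. Dense optical flow between retained frames
yields a 2-channel (x, y) px/frame field per frame pair. The flow backend
is pluggable; the default is scikit-image's iterative Lucas–Kanade
(`ilk`), with TV-L1 available. Both are classical, deterministic
estimators; a learned flow network could be dropped in behind the same
interface.

Units: flow is stored in px/frame; movement magnitudes d = √(x²+y²) are
converted to px/s before the 0.5 px/s cap is applied, so the cap means the
same thing at any frame rate. Position shifts are detected from the
frame-mean *uncapped* magnitude crossing a low threshold, with consecutive
loud frames merged into one shift.

## Windowing protocol

Apneas last at least 10 s. Each event is cut into 10-s windows (20 flow
frames at 2 Hz) starting 5 s before the event and ending 5 s after it.
Training strides are label-dependent — 1 s for CA, 5 s for OA — which
rebalances the window counts of the much rarer CA class. At test time the
stride is always 1 s and the event label is the majority vote over window
probabilities thresholded at 0.5. Ties are broken by the mean window
probability against 0.5, with OA on exact equality (deterministic, and it
uses the available confidence). Window and event times are snapped to the
frame grid by flooring.

## Networks

**Whole-body 3D-CNN.** A declarative layer specification (average pool
25×25/20×20 → five unpadded convolutions with interleaved batch norm,
max-pooling and dropout → 2880-wide flatten → dense 16 → 4 → 1, sigmoid)
from which layer output shapes and parameter counts are computed exactly:
95,649 total, 95,393 trainable, 256 non-trainable (the batch-norm running
means and variances over 16+64+32+16 channels). Where the printed kernel
sizes omit a temporal extent it is 1; both that and the unpadded
convolutions are forced jointly by the printed output shapes and the
parameter totals. A *desk preset* replaces the input with 48×64 frames and
a 3×3/2×2 first pool, which lands on the identical 23×31 pooled grid —
every later shape and all parameter counts are unchanged — and is what the
synthetic benchmark trains.

**Two-branch chest/abdomen network.** Two copies of the same stack, each
on a 100×100 crop around the (annotated or regressed) chest and abdomen
centers, with the first pool replaced by 10×10/5×5. Branch embeddings (16
each) are concatenated into a dense head emitting one probability. When a
kernel exceeds the available spatial extent of these smaller maps, it is
clamped to that extent (a 2×2 kernel on a 1-px map becomes 1×1); the
published description is silent on this and clamping keeps the stack
well-formed at any crop size. Crops that reach past the frame edge are
zero-padded rather than rejected — sleeping bodies do reach frame edges.

**Training loop (shared).** RMSProp (lr 0.001, ρ 0.9, ε 1e-8) on a
class-weighted binary cross-entropy with CA = 1 as the positive class;
weights are inverse class frequencies normalized to mean 1, so a 313:40
OA:CA training composition gives a CA:OA weight ratio of 7.825. Early
stopping maximizes the Matthews correlation coefficient on a validation
split, computed **window-level** (the event- vs window-level choice is not
pinned down anywhere; window-level is cheaper and monotone with the
event-level vote on this data), with best-weights restoration. Defaults:
1000 epochs, batch 32, patience 50; the synthetic benchmark uses much
smaller budgets (below). Dropout rate 0.3 and leaky-ReLU slope 0.01 are
unpublished; these are common defaults. The whole engine is plain NumPy
(im2col/shift-and-GEMM convolutions with explicit backprop), so runs are
bit-reproducible under a fixed seed and need no GPU.

## Baselines

1. **Autocorrelation.** m(t) = spatial mean of the capped magnitude image,
   per event; 4th-order Butterworth band-pass 0.05–0.5 Hz applied
   forward-backward (zero phase; the order and realization are
   unpublished); biased, mean-centered, variance-normalized
   autocorrelation up to a lag equal to the event duration (constant
   signals map to an all-zero series); heights of the first 10 strict
   local maxima with prominence ≥ 0.01 at lags ≥ 1, zero-padded to length
   10. Classifiers: linear SVM, logistic regression, random forest, each
   tuned by 3-fold cross-validation; the benchmark reports whichever wins
   on CV score (ties resolved in that fixed order).
2. **Movement histograms.** Per-frame 1000-bin histograms of the capped
   magnitudes over [0, 0.5] px/s (bin width 0.0005), averaged across the
   event; first 100 principal components (fit on training rows only);
   random forest. Histograms are computed over the whole capped frame — no
   region of interest — matching the whole-image averaging of baseline 1;
   capped input keeps all mass inside the binning range.
3. **2DFFT-CNN.** The per-frame histograms are stacked over time into an
   image, resized to 128×128 (resize-then-FFT; "constant size" most
   plausibly refers to the network input), 2-D FFT, log1p magnitude,
   zero-frequency centered. Anti-aliasing during the resize matters: the
   1000 narrow bins are decimated ~8× and alias badly otherwise. The
   classifier is a DarkNet19-style CNN adapted to 1-channel 128×128 input
   with a 0.25 width multiplier by default (full width by configuration),
   trained with the shared loop.

## Torso-box regression

Chest and abdomen are usually under a blanket, so they are regressed
rather than detected: a random forest maps (head box, BMI, weight, height,
one-hot head/body position) to the centers and sizes of both boxes. Head
detection itself and the body-position classifier are treated as inputs.
Detection is scored as the percentage of pairs with IoU strictly above 0.5.

## Synthetic data generator

No real recordings ship with the package; a seeded generator emulates the
signal model: textured scenes with chest/abdomen/head rectangles, vertical
region sinusoids with a shared phase-warped respiratory clock, Gaussian
"blanket" smearing of the displacement field beyond region borders, pixel
plus common-mode sensor noise, and abrupt position shifts. Key defaults
and why:

- breath rate uniform on [0.2, 0.42] Hz (12–25 breaths/min);
- OA phase offset π; CA `motion_scale` 0.05 — not exactly zero, mimicking
  residual tissue/sensor motion;
- amplitudes 0.35 px (chest) / 0.28 px (abdomen) at the 48×64 desk frame:
  sub-pixel motion that classical optical flow can recover from bilinear
  resampled texture, and mostly below the 0.5 px/s cap so the asymmetric
  velocity waveform survives capping;
- `speed_mod` 0.5: the peak inspiratory speed is about 3× the peak
  expiratory speed (realistic I:E asymmetry). This matters: a pure
  sinusoid's magnitude
  signal |v(t)| oscillates at twice the breath rate, which falls outside
  the 0.05–0.5 Hz analysis band for most sleep breathing rates; the
  asymmetry puts power at the fundamental. The warp is applied to a
  respiratory clock shared by both compartments, so the OA antiphase
  null (summed displacement ≡ 0 for equal amplitudes) holds exactly;
- sensor noise 0.05 px/frame per pixel, of which a 0.4 fraction is
  spatially coherent whole-frame jitter (a random-walk displacement).
  Purely i.i.d. pixel noise would vanish under spatial averaging and
  leave even a 5 % residual CA oscillation looking perfectly periodic —
  real camera noise is partly common-mode, and that is what makes CA's
  mean-movement signal aperiodic, as it is in practice;
- blanket smear: Gaussian blur of the displacement field with σ = 4 px,
  spreading region motion outward as a blanket does;
- apnea durations 15–28 s in the benchmark (clinically typical).

The generator does **not** model photorealistic appearance, hypopneas,
mixed apneas, cardiac micro-motions, illumination changes, or multiple
people. Passing the synthetic benchmark therefore demonstrates that the
pipeline's mechanics and learning dynamics are correct and that the
intended signal is recoverable end to end — not that real-world accuracy
matches any published figure.

## Benchmark problem sizes

The default benchmark (`evalharness.run_benchmark`) generates 40 OA + 40
CA events in a "training room" (10 synthetic subjects; 80/20 of subjects
held out as the early-stopping validation split) and 100 + 100 events in a
separate "test room", at 48×64 frames and 2 Hz. The CNNs train with batch
16, at most 10 epochs (patience 3) for the 3D-CNNs and 20 epochs
(patience 6) for the spectral CNN; the two-branch network uses 32×32
crops. These sizes keep a full five-method run around ten minutes on one
CPU core while leaving every method comfortably above 0.9 event accuracy.

## Numerical notes and limitations

- The band-pass upper edge is clamped to 0.999× Nyquist if it would meet
  or exceed it; at 2 Hz sampling the Nyquist frequency is 1 Hz, so the
  0.5 Hz edge is in fact unaffected.
- `filtfilt` padding is shortened for signals close to the minimum length
  (just above 3× the filter order).
- The confusion-matrix reconstruction tolerates ±0.06 percentage points
  so that both rounding and truncation of printed one-decimal values are
  admitted (357/374 = 95.45 % prints as 95.4 only under truncation).
- Whether the 3D-CNN consumed raw or capped flow is unspecified in the
  original description; here raw flow feeds the CNNs and capped
  magnitudes feed the baselines, both switchable.
- Degenerate metric ratios (zero denominators) are reported as 0 and
  flagged rather than raised.
- The NumPy engine is single-threaded-BLAS friendly but far slower than a
  GPU framework; full-resolution (480×640) training is supported in form
  but not a practical target.
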