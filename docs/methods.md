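# Methods

## Problem and pipeline

`respcam` estimates respiratory rate (RR, breaths/min) from RGB video of a
seated subject, without contact sensors. Two information channels exist in
such video: remote photoplethysmography (rPPG) — respiration- and
pulse-driven intensity modulation of skin reflectance, strongest in the
green channel — and mechanical chest motion. The pipeline is:

1. **ROI extraction.** A face box is detected per frame (pluggable
   detector), and a chest box is projected geometrically below it:
   vertically `[y+h, y+αh)` with α = 2.5, horizontally expanded by β = 0.2
   face widths on each side. Skin pixels are segmented by dual color-space
   thresholds — full-range YCrCb chrominance (Cr ∈ [133,173],
   Cb ∈ [77,127]) OR-ed with HSV hue/saturation (H ∈ [0,50], S ∈ [58,174]
   on a 0–255 scale) — then the binary mask is refined by Gaussian
   smoothing, re-thresholding at 0.5, and morphological opening/closing
   with disk elements.
2. **Preprocessing.** Temporal Gaussian smoothing (σ = 2 frames, half-width
   k = 6; unit-sum kernel, reflective boundaries) and per-frame photometric
   normalization `(I − μ_f)/σ_f`, with μ_f, σ_f the mean and population SD
   of all masked pixel values.
3. **Signal extraction.** Face/chest rPPG: masked green-channel mean,
   normalized per frame. Motion: global weighted Lucas–Kanade translation
   between consecutive grayscale ROI frames (normal equations on image
   gradients), rows weighted linearly 0.2→1.0 top-to-bottom to emphasize
   the thorax; vertical velocities are integrated into displacement.
   Each trace is conditioned by detrend → zero-phase 4th-order Butterworth
   bandpass 0.1–0.6 Hz → three-sigma normalization `(x − μ)/(3σ)`.
4. **Fusion / model.** The classical path fuses
   `S = 0.8·S_chest + 0.2·S_face` (chest motion and face rPPG). The learned
   path feeds overlapping T×4 windows (face rPPG, face motion, chest rPPG,
   chest motion; T = 256 frames, stride 32) to the waveform regressor.
5. **Rate estimation.** The (predicted or fused) waveform is detrended,
   bandpassed to 0.1–0.6 Hz, and its Welch PSD (Hamming taper, 50% segment
   overlap, zero-padded FFT) is searched for the in-band peak;
   RR = 60·f_peak.

## The waveform regressor

The network maps a T×4 window to a T-sample respiratory waveform:

- per-timestep affine embedding 4 → d_model (default 128);
- three 1-D convolution blocks with decreasing kernels 7, 5, 3 (conv →
  ReLU → batch norm → dropout 0.2; same-length zero padding, width kept at
  d_model);
- 8-head scaled-dot-product self-attention
  (`softmax(QKᵀ/√d_k)V`, d_k = d_model/8) with concatenation, output
  projection, residual connection and layer normalization;
- a two-layer bidirectional LSTM, per-direction width d_model/2, so the
  concatenated forward/backward states preserve d_model;
- a convolutional decoder d_model → 64 → 32 → 1 with kernels 5, 3, 1 (the
  final map is a 1×1 convolution).

Training minimizes MSE against the conditioned belt reference with AdamW
(lr 10⁻³, weight decay 10⁻⁴, batch 32) and a reduce-on-plateau schedule
(factor 0.5, patience 5 on validation loss); the best-validation weights
are kept. The loss choice is ours: the target is a bounded, normalized
waveform, and plain MSE is the simplest consistent regression loss (a
spectral loss was considered and left out of the default). All layers,
backpropagation and the optimizer are implemented in NumPy with
hand-derived gradients, verified against finite differences in the test
suite; evaluation-mode inference is a pure function (frozen batch-norm
statistics, dropout off), so fixed seeds give bit-identical runs.

Where the architecture leaves details open we chose: encoder channel width
constant at d_model (keeps the (batch, time, 128) contract at every
stage); residual connection only around the attention block; decoder
kernels 5/3/1 mirroring the encoder's decreasing-kernel design; the
block order is convolutions first, then attention.

## Synthetic data: what it emulates, and what it does not

No public dataset is required: the generator produces recordings with full
ground truth. A scene specifies duration (60 s), frame rate (30 fps), true
RR ∈ [6, 30] BPM, cardiac rate, a skin-tone profile, chest displacement,
noise levels, belt sampling (10 Hz) and a camera–belt clock offset
(0.5 s); everything is a pure function of the scene seed.

Rendered frames contain a skin-toned facial ellipse whose green channel
carries cardiac and respiratory modulation, a skin-toned chest rectangle
translating vertically with breathing (anti-aliased subpixel edges),
global multiplicative illumination drift, and per-pixel Gaussian noise.
A fast route synthesizes the four derived channels directly with the same
modulation model.

Realism choices, each with its rationale:

- **Rate variability** (default 4%): real quiet breathing is not
  isochronous. The instantaneous rate wanders as a sum of four random
  Fourier components below 0.05 Hz, giving a closed-form phase that the
  camera channels, the rendered video and the belt all share. References
  are therefore belt-derived (Welch peak of the conditioned belt), as in a
  real protocol.
- **Waveform morphology**: fundamental plus a 0.2-amplitude second
  harmonic. A proxy — subjects' true morphology is richer.
- **Skin-tone presets**: light (mean reflectance ≈ 197, respiratory
  green-channel amplitude 2.0) vs dark (≈ 118, amplitude 0.8), modeling
  melanin attenuation of the optical signal. These are artifact constants
  chosen so the darker preset has genuinely lower optical SNR, not
  measurements.
- **rPPG noise**: white sensor noise plus an *absolute* band-limited
  (0.08–0.7 Hz) illumination/perfusion noise floor. Because the floor does
  not scale with signal amplitude, the dark preset's weaker modulation
  sinks relative to it — the central fairness mechanism.
- **Motion-tracking noise**: white *velocity* noise integrated into a
  random walk, exactly what integrating noisy optical-flow velocities
  produces. Its magnitude scales inversely with figure/background
  contrast, so the dark preset tracks noisier against the green backdrop.
- **Movement artifacts**: occasional smooth bumps (Poisson, 2/min, ~0.8 s
  wide) on the chest channels only — optical flow's known weakness. They
  are what makes an intermediate chest/face fusion weight optimal in the
  weight-sweep experiment.
- **Chest displacement** (default 1.2 px): a 2–3 mm excursion scaled
  through the rendered geometry (face width 60 px ≈ 150 mm).

Default frames are 180×240 (all geometry resolution-relative); full-camera
6000×4000 frames would be pointless at test scale. Not emulated:
photorealistic appearance, head pose changes, clothing (the chest is
rendered skin-colored so the skin mask accepts it; a `mask_chest=False`
switch exists for clothed chests), compression artifacts, ambient light
spectra. Passing tests therefore demonstrate correct mechanics and the
intended orderings under this model, not field performance on real video.

## Desk-scale experiment sizes

Training experiments use 60-s recordings, non-overlapping 256-frame
training windows (overlapping windows are near-duplicates that add little
independent information), 40 training / 10 held-out subjects, 30 epochs,
and a width-64 instance of the architecture (heads 8, hidden 32, decoder
32/16/1); the full-width configuration stays the package default and is
exercised by the shape and contract tests. The skin-tone protocol
evaluates within-group errors classically on a 32-subject cohort and
cross-tone transfer (train on one tone, test on the other) with the
learned path on a 40-subject cohort at 10 epochs.

## Numerical choices and degenerate inputs

- Zero-phase filtering uses second-order sections with odd-reflection
  padding of 3/low_hz seconds — the 0.1 Hz corner settles slowly and the
  library default padding leaves visible startup transients.
- Welch defaults: 1024-sample segments (~34 s at 30 fps, ≥3 cycles of the
  slowest 6 BPM rate), Hamming taper, 50% overlap, nfft 8192 (grid step
  ≈ 0.0037 Hz ≈ 0.22 BPM). Shorter segments smear a slow fundamental into
  the band edge where it can lose the argmax to its own second harmonic.
  Signals shorter than one segment fall back to a single segment with a
  warning. Peak ties break toward the lower frequency.
- Synchronization: normalized cross-correlation over ±10 s; global peak
  wins, ties break toward smaller |lag|; a peak below 0.2 warns and applies
  zero lag. Positive lag means the belt started later than the camera.
- Population SD in the per-frame normalization and three-sigma rule;
  sample (n−1) SD and a 1.96 factor in Bland–Altman limits of agreement;
  differences are predicted − reference.
- Degenerate cases: constant signals raise explicit degenerate-signal
  errors; frames with empty or constant masks are skipped and filled by
  linear interpolation; a face lost mid-recording reuses the previous box
  (an unfound face in the first frame aborts); textureless motion pairs
  fall back to the intensity-centroid shift; multiple face detections
  resolve to the largest box.
- Per-frame smoothing/normalization is computed on aggregated traces
  (spatial mean, per-frame stats); smoothing commutes with spatial
  averaging by linearity, asserted in tests for fixed masks.

## Known limitations

- The face detector shipped for real video is a skin-blob heuristic
  (topmost large connected skin component) suited to cooperative frontal
  scenes; the detector interface accepts any external detector.
- Single global-translation Lucas–Kanade assumes rigid vertical chest
  motion within the ROI; large rotations or non-rigid clothing motion are
  out of scope.
- One rate per recording: no time-varying RR tracking.
- The skin-tone orderings are reproduced qualitatively on the synthetic
  model; absolute error levels on real populations cannot be inferred
  from them.
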