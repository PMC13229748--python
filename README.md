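# respcam

Non-contact respiratory-rate (RR) estimation from RGB video, for
physiological-monitoring researchers who need a complete, testable
camera-to-breaths-per-minute pipeline — including a skin-tone-aware
synthetic benchmark so everything runs without any external dataset.

Camera-based RR estimation reads two complementary cues from video of a
seated subject: remote photoplethysmography (rPPG) — subtle skin-color
modulation, strongest in the green channel — and mechanical chest motion.
Both are known to degrade for darker skin tones, where melanin absorption
attenuates the optical signal; this package reproduces and measures that
behavior on synthetic cohorts.

## Method

Per frame, a face box is detected and a chest box projected below it
(vertical extent α = 2.5 face heights, horizontal expansion β = 0.2 face
widths); skin pixels are segmented by YCrCb ∨ HSV thresholds and refined
morphologically. Four signals are extracted — face rPPG, face motion,
chest rPPG, chest motion (weighted Lucas–Kanade vertical flow) — and each
is conditioned by

```
x → detrend → zero-phase Butterworth bandpass 0.1–0.6 Hz (order 4) → (x−μ)/(3σ)
```

Two estimation paths share the spectral back end:

- **classical:** fuse `S(t) = 0.8·S_chest(t) + 0.2·S_face(t)`;
- **learned:** a hybrid sequence regressor — affine embedding 4→128, three
  1-D conv blocks (kernels 7, 5, 3) with ReLU/batch-norm/dropout, 8-head
  self-attention `softmax(QKᵀ/√d_k)V` with residual + layer norm, a
  two-layer BiLSTM (64 per direction), and a conv decoder 128→64→32→1 —
  trained with AdamW (lr 10⁻³, weight decay 10⁻⁴, batch 32, MSE against
  the synchronized, conditioned respiration-belt reference). The network
  and its backpropagation are implemented in NumPy and gradient-checked.

The rate is the Welch-PSD peak of the (predicted or fused) waveform in
the respiratory band: `RR = 60 · argmax_f P(f)`, Hamming-tapered segments
at 50% overlap, zero-padded to a ~0.22 BPM grid. Evaluation offers MAE,
RMSE, Bland–Altman limits of agreement, Pearson correlation,
cross-correlation camera–belt synchronization, and a skin-tone group
protocol (per-group and cross-tone transfer). See `docs/methods.md` for
every numerical choice.

## Worked example

Generate a 60 s synthetic recording (dark skin-tone preset, nominal
14 breaths/min, seeded) and estimate its rate through the full image
pipeline:

```bash
$ respcam synth --out demo --rr 14 --tone dark --duration 60 --seed 42
{"frames": 1800, "rr_bpm": 14.0, "out": "demo", ...}

$ respcam estimate demo --classical
{
  "rr_bpm": 13.623046875,
  "f_peak_hz": 0.22705078125,
  "band": [0.1, 0.6],
  ...
}
```

The estimate is 13.62 BPM, not 14.00, and that is correct: the generator
breathes with ~4% rate variability, so the *realized* mean rate differs
from the nominal one. The belt reference processed the same way gives
exactly 13.623 BPM — the camera pipeline matches the contact sensor to
the spectral grid's resolution. `demo/` also contains the ground-truth
`scene.json` and the belt recording `belt.csv` (which starts 0.5 s late,
recoverable by `respcam`'s cross-correlation synchronization).

Other commands: `respcam extract` (channel CSV dump), `respcam train`
(cohort training with checkpoint + loss log), `respcam evaluate`
(MAE/RMSE/Bland–Altman report and plots), `respcam sweep-fusion` (the
chest/face weight grid).

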