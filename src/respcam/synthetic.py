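"""Skin-tone-aware synthetic recordings with known respiratory ground truth.

The generator emulates a seated-subject acquisition: a skin-toned facial
ellipse whose green channel carries cardiac and respiratory intensity
modulation, a skin-toned chest rectangle translating vertically with
breathing, global multiplicative illumination drift, per-pixel sensor noise,
and a respiration-belt reference recorded as a time/value CSV with an
injected camera-belt clock offset.

Two output routes exist: :func:`render_frames`/:func:`render_video` produce
actual RGB frames for the full image pipeline, and
:func:`generate_channel_bundle` synthesizes the four derived channels
(face rPPG, face motion, chest rPPG, chest motion) directly for fast model
experiments. Both routes share the same modulation model, and both are pure
functions of the scene description (bit-identical output for equal seeds).

Skin-tone presets follow the optics of melanin absorption: the dark preset
has lower base reflectance and smaller pulse/respiratory intensity
amplitudes than the light preset, and its lower figure/background contrast
yields noisier motion tracking.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import signal as sps

from .roi import BoundingBox, project_chest_roi
from .signals import TemporalSignal

__all__ = [
    "ToneProfile",
    "SyntheticScene",
    "TONE_PRESETS",
    "get_tone",
    "default_scene",
    "generate_respiratory_waveform",
    "scene_waveform",
    "generate_channel_bundle",
    "render_frames",
    "render_video",
    "write_belt_csv",
    "make_belt_signal",
    "scene_to_dict",
    "scene_from_dict",
    "load_scene",
]

BACKGROUND_RGB = (45, 110, 60)  # uniform green backdrop; rejected by skin masks

# relative strengths of the secondary modulations, shared by both routes
CHEST_RPPG_GAIN = 1.5     # chest intensity modulation vs face resp_amp
CHEST_PULSE_GAIN = 0.5    # cardiac leakage into the chest intensity signal
FACE_MOTION_GAIN = 0.2    # respiratory head sway vs chest displacement
RPPG_NOISE_FRAC = 0.25    # white sensor noise on rPPG traces per unit pixel noise SD
RPPG_INBAND_FRAC = 0.5    # in-band illumination/perfusion noise floor (absolute,
                          # independent of skin tone: weak signals drown in it)
MOTION_VEL_NOISE_FRAC = 0.03   # chest flow-velocity noise (px/frame) per unit noise SD
FACE_MOTION_VEL_NOISE_FRAC = 0.06
BURST_WIDTH_S = 0.8       # movement-artifact bump width (Gaussian sigma)
BURST_AMP_FRAC = 1.0      # artifact amplitude scale vs chest displacement
DRIFT_FREQ_HZ = 0.02      # slow illumination drift
RATE_PROC_COMPONENTS = 4  # random Fourier components of the rate-variability process


@dataclass(frozen=True)
class ToneProfile:
    """Skin-tone rendering parameters.

    ``base_rgb`` is the mean skin reflectance; ``pulse_amp`` and ``resp_amp``
    are the cardiac and respiratory green-channel modulation amplitudes in
    8-bit intensity units.
    """

    name: str
    base_rgb: tuple[float, float, float]
    pulse_amp: float
    resp_amp: float

    def __post_init__(self):
        if self.pulse_amp < 0 or self.resp_amp < 0:
            raise ValueError("modulation amplitudes must be non-negative")

    @property
    def base_mean(self) -> float:
        return float(np.mean(self.base_rgb))


TONE_PRESETS = {
    "light": ToneProfile("light", (224.0, 196.0, 170.0), pulse_amp=1.0, resp_amp=2.0),
    "dark": ToneProfile("dark", (150.0, 110.0, 95.0), pulse_amp=0.4, resp_amp=0.8),
}


def get_tone(name: str) -> ToneProfile:
    try:
        return TONE_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown tone preset {name!r}; choose from {sorted(TONE_PRESETS)}")


@dataclass(frozen=True)
class SyntheticScene:
    """Full ground-truth description of one synthetic recording."""

    duration_s: float = 60.0
    fps: float = 30.0
    rr_bpm: float = 15.0
    hr_bpm: float = 72.0
    tone: ToneProfile = TONE_PRESETS["light"]
    # ~2-3 mm chest excursion scaled through the rendered geometry
    # (face width 60 px ~ 150 mm -> 0.4 px/mm)
    chest_disp_px: float = 1.2
    noise_sd: float = 2.0
    drift_amp: float = 0.02
    harmonic_frac: float = 0.2
    rr_variability: float = 0.04
    artifact_rate_per_min: float = 2.0
    belt_fs: float = 10.0
    belt_offset_s: float = 0.5
    seed: int = 0
    frame_w: int = 180
    frame_h: int = 240
    face_box: BoundingBox | None = None
    chest_box: BoundingBox | None = None

    def __post_init__(self):
        if not (6.0 <= self.rr_bpm <= 30.0):
            raise ValueError("rr_bpm must lie in the evaluated 6-30 BPM range")
        if self.fps <= 2.0 * self.rr_bpm / 60.0:
            raise ValueError("fps must exceed twice the respiratory frequency")
        for name in ("chest_disp_px", "noise_sd", "drift_amp", "artifact_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.face_box is None:
            side = int(round(min(self.frame_w, self.frame_h) / 3))
            fb = BoundingBox((self.frame_w - side) // 2,
                             int(round(0.1 * self.frame_h)), side, side)
            object.__setattr__(self, "face_box", fb)
        if self.chest_box is None:
            cb = project_chest_roi(self.face_box, frame_w=self.frame_w, frame_h=self.frame_h)
            object.__setattr__(self, "chest_box", cb)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def f_resp_hz(self) -> float:
        return self.rr_bpm / 60.0


def default_scene(**kwargs) -> SyntheticScene:
    """Scene with study-default acquisition parameters; kwargs override."""
    if isinstance(kwargs.get("tone"), str):
        kwargs["tone"] = get_tone(kwargs["tone"])
    return SyntheticScene(**kwargs)


def generate_respiratory_waveform(rr_bpm: float, duration_s: float, fs: float,
                                  harmonic_frac: float = 0.2,
                                  seed: int | None = None) -> TemporalSignal:
    """Reference respiratory waveform: unit fundamental plus one harmonic.

    ``r(t) = sin(2 pi f t) + harmonic_frac * sin(4 pi f t)`` with
    ``f = rr_bpm / 60``. The waveform is deterministic; ``seed`` is accepted
    for interface uniformity with the stochastic generators and ignored.
    """
    if rr_bpm <= 0 or fs <= 0 or duration_s <= 0:
        raise ValueError("rr_bpm, fs and duration_s must all be positive")
    if fs <= rr_bpm / 30.0:
        raise ValueError("fs must resolve the respiratory fundamental")
    if duration_s <= 2.0 * 60.0 / rr_bpm:
        raise ValueError("duration must cover at least two breathing cycles")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    f = rr_bpm / 60.0
    r = np.sin(2 * np.pi * f * t) + harmonic_frac * np.sin(4 * np.pi * f * t)
    return TemporalSignal(r, fs=fs, channel="reference")


def scene_waveform(scene: SyntheticScene, t: np.ndarray) -> np.ndarray:
    """The realized respiratory waveform of a scene at arbitrary times.

    Real quiet breathing is not isochronous: the instantaneous rate wanders
    by a few percent on a tens-of-seconds timescale. The rate-variability
    process is a small sum of random low-frequency (0.005-0.05 Hz) Fourier
    components with total relative amplitude ``rr_variability``, so the
    phase has a closed form and the same realization can be evaluated on
    the camera grid, the belt grid, or anywhere else. The camera channels,
    the rendered video, and the belt recording of one scene all share this
    waveform; all three routes are deterministic in the scene seed.
    """
    t = np.asarray(t, dtype=float)
    f0 = scene.f_resp_hz
    if scene.rr_variability > 0:
        rng = np.random.default_rng([scene.seed, 101])
        k = RATE_PROC_COMPONENTS
        amps = rng.normal(0.0, scene.rr_variability / np.sqrt(k), k)
        freqs = rng.uniform(0.005, 0.05, k)
        phases = rng.uniform(0.0, 2 * np.pi, k)
        # phase(t) = 2 pi f0 * (t + integral of the relative rate deviation)
        dev = np.zeros_like(t)
        for a, g, p in zip(amps, freqs, phases):
            dev += a / (2 * np.pi * g) * (np.sin(2 * np.pi * g * t + p) - np.sin(p))
        phi = 2 * np.pi * f0 * (t + dev)
    else:
        phi = 2 * np.pi * f0 * t
    return np.sin(phi) + scene.harmonic_frac * np.sin(2.0 * phi)


def _inband_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Band-limited (0.08-0.7 Hz) noise with the requested RMS amplitude."""
    if sd == 0.0 or n < 64:
        return np.zeros(n)
    sos = sps.butter(2, [0.08, 0.7], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, n))
    rms = float(np.sqrt(np.mean(x ** 2)))
    return x * (sd / rms) if rms > 0 else x


def _burst_train(rng: np.random.Generator, t: np.ndarray, scene: SyntheticScene) -> np.ndarray:
    """Smooth movement-artifact bumps contaminating the chest channels."""
    out = np.zeros_like(t)
    lam = scene.artifact_rate_per_min * scene.duration_s / 60.0
    n = rng.poisson(lam) if lam > 0 else 0
    for _ in range(n):
        center = rng.uniform(0.0, scene.duration_s)
        amp = rng.normal(0.0, BURST_AMP_FRAC * scene.chest_disp_px)
        out += amp * np.exp(-0.5 * ((t - center) / BURST_WIDTH_S) ** 2)
    return out


def generate_channel_bundle(scene: SyntheticScene) -> dict[str, TemporalSignal]:
    """Directly synthesize the four derived channels plus the clean reference.

    Returns a dict keyed by channel label (``face_rppg``, ``face_motion``,
    ``chest_rppg``, ``chest_motion``) plus ``reference``. Chest channels are
    stronger than their facial counterparts (higher physiological coupling),
    but carry occasional movement-artifact bursts; motion-tracking noise
    scales inversely with figure/background contrast, so the dark preset
    tracks slightly noisier.
    """
    n = scene.n_frames
    t = np.arange(n) / scene.fps
    r = scene_waveform(scene, t)
    cardiac = np.sin(2 * np.pi * scene.hr_bpm / 60.0 * t)
    drift = scene.drift_amp * np.sin(2 * np.pi * DRIFT_FREQ_HZ * t)
    tone = scene.tone
    base_g = tone.base_rgb[1]
    fs = scene.fps

    rng = np.random.default_rng(scene.seed)
    rppg_sd = RPPG_NOISE_FRAC * scene.noise_sd
    inband_sd = RPPG_INBAND_FRAC * scene.noise_sd
    # flow-gradient strength scales with figure/background contrast, so the
    # velocity noise scales with its inverse; darker skin against the green
    # backdrop has markedly lower contrast than the light preset
    bg_mean = float(np.mean(BACKGROUND_RGB))
    light_contrast = TONE_PRESETS["light"].base_mean - bg_mean
    contrast = light_contrast / max(tone.base_mean - bg_mean, 1.0)
    chest_vel_sd = MOTION_VEL_NOISE_FRAC * scene.noise_sd * contrast
    face_vel_sd = FACE_MOTION_VEL_NOISE_FRAC * scene.noise_sd * contrast

    face_rppg = (base_g * (1.0 + drift) + tone.resp_amp * r + tone.pulse_amp * cardiac
                 + rng.normal(0.0, rppg_sd, n) + _inband_noise(rng, n, fs, inband_sd))
    # displacement = integrated flow velocity, so velocity noise accumulates
    # into a random walk, exactly as in the tracking-based extraction
    face_motion = (FACE_MOTION_GAIN * scene.chest_disp_px * r
                   + np.cumsum(rng.normal(0.0, face_vel_sd, n)))
    chest_rppg = (base_g * (1.0 + drift) + CHEST_RPPG_GAIN * tone.resp_amp * r
                  + CHEST_PULSE_GAIN * tone.pulse_amp * cardiac
                  + rng.normal(0.0, rppg_sd, n)
                  + _inband_noise(rng, n, fs, inband_sd))
    chest_motion = (scene.chest_disp_px * r
                    + np.cumsum(rng.normal(0.0, chest_vel_sd, n)))
    bursts = _burst_train(rng, t, scene)
    chest_motion = chest_motion + bursts
    chest_rppg = chest_rppg + 0.5 * tone.resp_amp * bursts / max(scene.chest_disp_px, 1e-9)

    return {
        "face_rppg": TemporalSignal(face_rppg, fs, "face_rppg"),
        "face_motion": TemporalSignal(face_motion, fs, "face_motion"),
        "chest_rppg": TemporalSignal(chest_rppg, fs, "chest_rppg"),
        "chest_motion": TemporalSignal(chest_motion, fs, "chest_motion"),
        "reference": TemporalSignal(r, fs, "reference"),
    }


def _ellipse_mask(box: BoundingBox, frame_w: int, frame_h: int) -> np.ndarray:
    yy, xx = np.mgrid[0:frame_h, 0:frame_w]
    cx, cy = box.x + box.w / 2.0, box.y + box.h / 2.0
    return (((xx + 0.5 - cx) / (box.w / 2.0)) ** 2
            + ((yy + 0.5 - cy) / (box.h / 2.0)) ** 2) <= 1.0


def _chest_rect(scene: SyntheticScene) -> tuple[float, float, int, int]:
    """Static chest-rectangle geometry (y_top, y_bottom, x_left, x_right).

    Inset inside the projected chest box so that the +/- chest_disp_px
    vertical excursion never leaves the box.
    """
    cb = scene.chest_box
    margin_y = int(np.ceil(scene.chest_disp_px * (1 + scene.harmonic_frac))) + 8
    margin_x = max(4, cb.w // 12)
    return (float(cb.y + margin_y), float(cb.y + cb.h - margin_y),
            cb.x + margin_x, cb.x + cb.w - margin_x)


def render_frames(scene: SyntheticScene, quantize: bool = True) -> np.ndarray:
    """Render the full frame stack ``(N, H, W, 3)``.

    With ``quantize=True`` (default) frames are 8-bit as written to disk;
    ``quantize=False`` returns float frames, on which the modulation model
    holds exactly (no rounding).
    """
    n = scene.n_frames
    H, W = scene.frame_h, scene.frame_w
    t = np.arange(n) / scene.fps
    r = scene_waveform(scene, t)
    cardiac = np.sin(2 * np.pi * scene.hr_bpm / 60.0 * t)
    drift = 1.0 + scene.drift_amp * np.sin(2 * np.pi * DRIFT_FREQ_HZ * t)
    tone = scene.tone

    face_mask = _ellipse_mask(scene.face_box, W, H)
    y_top, y_bot, x_l, x_r = _chest_rect(scene)
    rows = np.arange(H, dtype=float)

    rng = np.random.default_rng(scene.seed)
    base = np.asarray(tone.base_rgb, dtype=np.float32)
    bg = np.asarray(BACKGROUND_RGB, dtype=np.float32)
    out = np.empty((n, H, W, 3), dtype=np.uint8 if quantize else np.float32)

    face_g = tone.base_rgb[1] + tone.pulse_amp * cardiac + tone.resp_amp * r
    chest_g = (tone.base_rgb[1] + CHEST_PULSE_GAIN * tone.pulse_amp * cardiac
               + CHEST_RPPG_GAIN * tone.resp_amp * r)
    dy = scene.chest_disp_px * r + _burst_train(np.random.default_rng([scene.seed, 7]),
                                                t, scene)

    for i in range(n):
        frame = np.broadcast_to(bg, (H, W, 3)).astype(np.float32).copy()
        face_rgb = np.array([base[0], face_g[i], base[2]], dtype=np.float32)
        frame[face_mask] = face_rgb
        # anti-aliased vertical coverage of the translated chest rectangle
        top, bot = y_top + dy[i], y_bot + dy[i]
        cov = np.clip(np.minimum(rows + 1.0, bot) - np.maximum(rows, top), 0.0, 1.0)
        chest_rgb = np.array([base[0], chest_g[i], base[2]], dtype=np.float32)
        band = frame[:, x_l:x_r, :]
        band[:] = band * (1.0 - cov[:, None, None]) + chest_rgb * cov[:, None, None]
        frame *= drift[i]
        if scene.noise_sd > 0:
            frame += rng.normal(0.0, scene.noise_sd, frame.shape).astype(np.float32)
        if quantize:
            out[i] = np.clip(np.round(frame), 0, 255).astype(np.uint8)
        else:
            out[i] = frame
    return out


def render_video(scene: SyntheticScene, out_dir: str | Path) -> SyntheticScene:
    """Write PNG frames plus a ground-truth metadata JSON and belt CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = render_frames(scene, quantize=True)
    for i, frame in enumerate(frames):
        iio.imwrite(out_dir / f"frame_{i + 1:06d}.png", frame)
    (out_dir / "scene.json").write_text(json.dumps(scene_to_dict(scene), indent=2))
    write_belt_csv(make_belt_signal(scene), scene.belt_offset_s, out_dir / "belt.csv")
    return scene


def make_belt_signal(scene: SyntheticScene) -> TemporalSignal:
    """The belt-sensor recording at the belt rate.

    The belt acquisition starts ``belt_offset_s`` seconds after the camera
    (an independent device), so its first sample measures the respiration at
    that absolute time; the offset is also carried in the CSV timestamps.
    """
    off = scene.belt_offset_s
    n = int(np.floor((scene.duration_s - off) * scene.belt_fs)) + 1
    t = off + np.arange(n) / scene.belt_fs
    return TemporalSignal(scene_waveform(scene, t), fs=scene.belt_fs,
                          channel="belt", t0=off)


def write_belt_csv(signal: TemporalSignal, offset_s: float, path: str | Path) -> Path:
    """Two-column ``time_s,respiration`` CSV with timestamps from offset_s."""
    path = Path(path)
    times = offset_s + np.arange(len(signal)) / signal.fs
    with open(path, "w") as fh:
        fh.write("time_s,respiration\n")
        for ts, v in zip(times, signal.samples):
            fh.write(f"{ts:.6f},{v:.9g}\n")
    return path


def scene_to_dict(scene: SyntheticScene) -> dict:
    d = dataclasses.asdict(scene)
    d["tone"] = dataclasses.asdict(scene.tone)
    d["face_box"] = dataclasses.asdict(scene.face_box)
    d["chest_box"] = dataclasses.asdict(scene.chest_box)
    return d


def scene_from_dict(d: dict) -> SyntheticScene:
    d = dict(d)
    tone = d["tone"]
    d["tone"] = ToneProfile(tone["name"], tuple(tone["base_rgb"]),
                            tone["pulse_amp"], tone["resp_amp"])
    d["face_box"] = BoundingBox(**d["face_box"])
    d["chest_box"] = BoundingBox(**d["chest_box"])
    return SyntheticScene(**d)


def load_scene(path: str | Path) -> SyntheticScene:
    return scene_from_dict(json.loads(Path(path).read_text()))
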