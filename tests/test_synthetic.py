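"""The synthetic generator must be deterministic, spectrally faithful, and
encode the skin-tone amplitude ordering it claims to emulate."""

import numpy as np
import pytest
from scipy import signal as sps

from respcam.io import read_belt_csv
from respcam.signals import TemporalSignal
from respcam.synthetic import (
    TONE_PRESETS,
    default_scene,
    generate_channel_bundle,
    generate_respiratory_waveform,
    make_belt_signal,
    render_frames,
    render_video,
    load_scene,
    scene_waveform,
    write_belt_csv,
)


def periodogram_peak_hz(x, fs):
    freqs, psd = sps.periodogram(x, fs=fs)
    sel = (freqs >= 0.05) & (freqs <= 1.0)
    return freqs[sel][np.argmax(psd[sel])]


class TestWaveform:
    def test_pure_sinusoid_at_quarter_hz(self):
        sig = generate_respiratory_waveform(15, duration_s=60, fs=30, harmonic_frac=0.0)
        assert len(sig) == 1800
        t = np.arange(1800) / 30.0
        np.testing.assert_allclose(sig.samples, np.sin(2 * np.pi * 0.25 * t), atol=1e-12)

    @pytest.mark.parametrize("rr", [6, 10, 15, 21.5, 30])
    def test_spectral_peak_matches_rate(self, rr):
        # FFT oracle: dominant frequency within one bin of rr/60
        sig = generate_respiratory_waveform(rr, duration_s=60, fs=30)
        peak = periodogram_peak_hz(sig.samples, 30.0)
        assert abs(peak - rr / 60.0) <= 1.0 / 60.0

    def test_band_edge_low_rate(self):
        sig = generate_respiratory_waveform(6, duration_s=60, fs=30, harmonic_frac=0.0)
        assert abs(periodogram_peak_hz(sig.samples, 30.0) - 0.1) <= 1.0 / 60.0

    @pytest.mark.parametrize("bad", [dict(rr_bpm=0), dict(fs=0), dict(duration_s=-1)])
    def test_invalid_parameters(self, bad):
        kwargs = dict(rr_bpm=15, duration_s=60, fs=30)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            generate_respiratory_waveform(**kwargs)

    def test_variable_rate_waveform_shared_across_grids(self):
        # belt and camera must see the same breathing realization
        scene = default_scene(rr_bpm=12, seed=3)
        t = np.arange(0, 10, 1 / 30)
        a = scene_waveform(scene, t)
        b = scene_waveform(scene, t[::3])
        np.testing.assert_allclose(a[::3], b, atol=1e-12)


class TestTonePresets:
    def test_dark_attenuated_relative_to_light(self):
        light, dark = TONE_PRESETS["light"], TONE_PRESETS["dark"]
        assert dark.base_mean < light.base_mean
        assert dark.pulse_amp < light.pulse_amp
        assert dark.resp_amp < light.resp_amp

    def test_face_respiratory_band_power_ordering(self):
        # melanin attenuation: dark face rPPG carries less respiratory power
        powers = {}
        for tone in ("light", "dark"):
            scene = default_scene(tone=tone, rr_bpm=15, noise_sd=0.0, drift_amp=0.0,
                                  artifact_rate_per_min=0.0, rr_variability=0.0, seed=5)
            x = generate_channel_bundle(scene)["face_rppg"].samples
            freqs, psd = sps.periodogram(x - x.mean(), fs=30.0)
            powers[tone] = psd[(freqs >= 0.1) & (freqs <= 0.6)].sum()
        assert powers["dark"] < powers["light"]


class TestBundle:
    def test_deterministic_for_fixed_seed(self):
        scene = default_scene(seed=11)
        a = generate_channel_bundle(scene)
        b = generate_channel_bundle(scene)
        for k in a:
            np.testing.assert_array_equal(a[k].samples, b[k].samples)

    def test_spectral_fidelity_noiseless(self, clean_scene, clean_bundle):
        f0 = clean_scene.f_resp_hz
        for ch in ("face_rppg", "chest_rppg", "chest_motion"):
            x = clean_bundle[ch].samples
            assert abs(periodogram_peak_hz(x - x.mean(), 30.0) - f0) <= 1.0 / 20.0

    def test_zero_face_amplitude_kills_face_band_power(self):
        from respcam.synthetic import ToneProfile

        tone = ToneProfile("custom", (224, 196, 170), pulse_amp=0.0, resp_amp=0.0)
        scene = default_scene(tone=tone, noise_sd=0.0, drift_amp=0.0,
                              artifact_rate_per_min=0.0, rr_variability=0.0, seed=2)
        b = generate_channel_bundle(scene)
        face = b["face_rppg"].samples
        chest = b["chest_motion"].samples
        freqs, psd_f = sps.periodogram(face - face.mean(), fs=30.0)
        _, psd_c = sps.periodogram(chest - chest.mean(), fs=30.0)
        band = (freqs >= 0.1) & (freqs <= 0.6)
        assert psd_f[band].sum() < 1e-12
        assert psd_c[band].sum() > 1.0


class TestRender:
    def test_face_green_mean_affine_in_modulation(self, clean_scene):
        frames = render_frames(clean_scene, quantize=False)
        ys, xs = clean_scene.face_box.slices
        # interior of the face ellipse: central region is pure skin
        cy, cx = ys.start + clean_scene.face_box.h // 2, xs.start + clean_scene.face_box.w // 2
        g = frames[:, cy - 5:cy + 5, cx - 5:cx + 5, 1].mean(axis=(1, 2))
        t = np.arange(clean_scene.n_frames) / clean_scene.fps
        r = scene_waveform(clean_scene, t)
        cardiac = np.sin(2 * np.pi * clean_scene.hr_bpm / 60.0 * t)
        tone = clean_scene.tone
        expected = tone.base_rgb[1] + tone.resp_amp * r + tone.pulse_amp * cardiac
        np.testing.assert_allclose(g, expected, atol=1e-4)

    def test_chest_centroid_tracks_displacement(self, clean_scene):
        # centroid row of the thresholded chest mask follows the injected
        # vertical displacement r(t)
        frames = render_frames(clean_scene, quantize=False)
        ys, xs = clean_scene.chest_box.slices
        gray = frames[:, ys, xs, :].mean(axis=-1)
        thresh = (clean_scene.tone.base_mean + np.mean([45, 110, 60])) / 2.0
        mask = gray > thresh
        rows = np.arange(gray.shape[1], dtype=float)
        centroid = (mask.sum(axis=2) * rows).sum(axis=1) / mask.sum(axis=(1, 2))
        t = np.arange(clean_scene.n_frames) / clean_scene.fps
        r = scene_waveform(clean_scene, t)
        assert np.corrcoef(centroid, r)[0, 1] > 0.95

    def test_same_seed_renders_identical_frames(self):
        scene = default_scene(duration_s=9.0, seed=4)
        np.testing.assert_array_equal(render_frames(scene), render_frames(scene))


class TestBeltCsv:
    def test_rows_start_at_offset(self, tmp_path):
        sig = TemporalSignal(np.arange(3, dtype=float), fs=10.0, channel="belt")
        p = write_belt_csv(sig, 0.0, tmp_path / "b.csv")
        lines = p.read_text().strip().splitlines()
        assert lines[0] == "time_s,respiration"
        times = [float(l.split(",")[0]) for l in lines[1:]]
        np.testing.assert_allclose(times, [0.0, 0.1, 0.2])

        p = write_belt_csv(sig, 0.5, tmp_path / "b2.csv")
        first = float(p.read_text().splitlines()[1].split(",")[0])
        assert first == pytest.approx(0.5)

    def test_roundtrip_preserves_samples(self, tmp_path):
        scene = default_scene(duration_s=30.0, seed=9)
        belt = make_belt_signal(scene)
        p = write_belt_csv(belt, scene.belt_offset_s, tmp_path / "belt.csv")
        back = read_belt_csv(p)
        assert back.fs == pytest.approx(scene.belt_fs)
        assert back.t0 == pytest.approx(scene.belt_offset_s)
        np.testing.assert_allclose(back.samples, belt.samples, atol=1e-8)


def test_render_video_writes_frames_and_ground_truth(tmp_path):
    scene = default_scene(duration_s=9.0, seed=1)
    out = tmp_path / "rec"
    render_video(scene, out)
    pngs = sorted(out.glob("frame_*.png"))
    assert len(pngs) == scene.n_frames
    assert pngs[0].name == "frame_000001.png"
    loaded = load_scene(out / "scene.json")
    assert loaded == scene
    assert (out / "belt.csv").exists()
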