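"""Runnable study protocols on synthetic cohorts.

These functions tie the generator, the classical spectral path and the
learned waveform regressor into the experiments reported for the method:
parameter recovery on held-out subjects, the chest/face fusion-weight sweep,
and the skin-tone group / cross-tone transfer protocol. All of them are
pure functions of their seeds.

Problem sizes are desk scale: recordings are 60 s at 30 fps, training uses
non-overlapping 256-frame windows (overlapping windows are near-duplicates
and add little training signal), and the default training network is a
width-64 instance of the architecture; the full-width configuration remains
the :class:`respcam.model.ModelConfig` default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import EvalReport, evaluate_rr, resample, synchronize
from .model import WaveformRegressor, stitch_windows
from .pipeline import estimate_rr_from_bundle, process_bundle
from .signals import CHANNELS, FilterSpec, FusionWeights, TemporalSignal, process_signal
from .spectral import WelchParams, estimate_rr
from .synthetic import SyntheticScene, default_scene, generate_channel_bundle, make_belt_signal

__all__ = [
    "SubjectRecording",
    "DESK_MODEL",
    "make_cohort",
    "build_training_set",
    "predict_recording_rr",
    "run_parameter_recovery",
    "run_fusion_sweep",
    "group_protocol",
]

# Reduced-width training configuration used by the desk-scale experiments.
DESK_MODEL = {
    "d_model": 64,
    "lstm_hidden": 32,
    "n_heads": 8,
    "decoder_channels": (32, 16, 1),
    "decoder_kernels": (5, 3, 1),
}


@dataclass(frozen=True)
class SubjectRecording:
    """One synthetic subject: scene ground truth plus the channel bundle.

    ``rr_ref`` is the belt-derived reference rate (Welch peak of the
    conditioned belt recording), the quantity a real protocol would compare
    against; ``scene.rr_bpm`` is the nominal generative rate.
    """

    subject_id: str
    scene: SyntheticScene
    bundle: dict[str, TemporalSignal]
    rr_ref: float

    @property
    def tone(self) -> str:
        return self.scene.tone.name

    @property
    def rr_true(self) -> float:
        return self.scene.rr_bpm


def reference_rr(scene: SyntheticScene, welch: WelchParams = WelchParams()) -> float:
    """Belt-derived reference rate: the belt resampled to the camera rate,
    conditioned like every other signal, then Welch peak."""
    belt = resample(make_belt_signal(scene), scene.fps)
    return estimate_rr(process_signal(belt), welch)["rr_bpm"]


def make_cohort(n_subjects: int, seed: int = 0, tones: tuple[str, ...] = ("light", "dark"),
                duration_s: float = 60.0, **scene_kw) -> list[SubjectRecording]:
    """Seeded cohort with alternating tone presets and uniform RR in 6-30 BPM."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        scene = default_scene(
            tone=tones[i % len(tones)],
            rr_bpm=float(rng.uniform(6.0, 30.0)),
            hr_bpm=float(rng.uniform(60.0, 100.0)),
            duration_s=duration_s,
            seed=int(rng.integers(2 ** 31)),
            **scene_kw,
        )
        out.append(SubjectRecording(f"S{i:03d}", scene, generate_channel_bundle(scene),
                                    rr_ref=reference_rr(scene)))
    return out


def _aligned_arrays(rec: SubjectRecording,
                    filter_spec: FilterSpec = FilterSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Conditioned channels and the synchronized conditioned belt target.

    The belt is resampled to the camera rate, conditioned with the same
    chain as the camera channels, and aligned by cross-correlation against
    the chest motion trace (the strongest camera channel); the recovered
    constant shift is then applied to every channel.
    """
    processed = process_bundle(rec.bundle, filter_spec)
    belt = make_belt_signal(rec.scene)
    belt_proc = process_signal(resample(belt, rec.scene.fps), filter_spec)
    _, _, lag_s = synchronize(processed["chest_motion"], belt_proc)
    lag = int(round(lag_s * rec.scene.fps))
    X = np.column_stack([processed[c].samples for c in CHANNELS])
    y = belt_proc.samples
    if lag >= 0:
        X = X[lag:]
    else:
        y = y[-lag:]
    n = min(len(X), len(y))
    return X[:n], y[:n]


def build_training_set(recordings, win_len: int = 256, stride: int = 256,
                       filter_spec: FilterSpec = FilterSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Stack belt-supervised windows of every recording into (n, T, 4)/(n, T)."""
    xs, ys = [], []
    for rec in recordings:
        X, y = _aligned_arrays(rec, filter_spec)
        for start in range(0, len(X) - win_len + 1, stride):
            xs.append(X[start:start + win_len])
            ys.append(y[start:start + win_len])
    if not xs:
        raise ValueError("no training windows; recordings too short?")
    return np.stack(xs), np.stack(ys)


def predict_recording_rr(model: WaveformRegressor, rec: SubjectRecording,
                         win_len: int = 256, stride: int = 32,
                         welch: WelchParams = WelchParams(),
                         return_details: bool = False):
    """Learned-path rate for one recording.

    Conditioned channels are windowed, each window is regressed to a
    waveform, overlapping predictions are averaged sample-wise, and the
    stitched waveform goes through the spectral output stage. With
    ``return_details`` the per-window rates (a diagnostic for rate
    stability across the recording) are returned alongside.
    """
    processed = process_bundle(rec.bundle)
    X = np.column_stack([processed[c].samples for c in CHANNELS])
    starts = list(range(0, len(X) - win_len + 1, stride))
    wins = np.stack([X[s:s + win_len] for s in starts])
    preds = model.predict(wins)
    waveform = stitch_windows(preds, starts, starts[-1] + win_len)
    sig = TemporalSignal(waveform, fs=rec.scene.fps, channel="predicted")
    rr = estimate_rr(sig, welch)["rr_bpm"]
    if not return_details:
        return rr
    fps = rec.scene.fps
    wp = WelchParams(seg_len=win_len, overlap_frac=welch.overlap_frac,
                     window_fn=welch.window_fn, nfft=max(welch.nfft, win_len),
                     band=welch.band)
    per_window = [
        estimate_rr(TemporalSignal(p, fs=fps, channel="predicted"), wp)["rr_bpm"]
        for p in preds
    ]
    return {"rr_bpm": rr, "per_window_rr": per_window, "window_starts": starts}


def _fit_model(X, y, epochs: int, batch_size: int, seed: int,
               model_kwargs: dict | None) -> WaveformRegressor:
    kwargs = dict(DESK_MODEL if model_kwargs is None else model_kwargs)
    model = WaveformRegressor(epochs=epochs, batch_size=batch_size,
                              random_state=seed, **kwargs)
    return model.fit(X, y)


def run_parameter_recovery(n_train: int = 40, n_test: int = 10, epochs: int = 30,
                           batch_size: int = 32, seed: int = 0, win_len: int = 256,
                           train_stride: int = 256, eval_stride: int = 32,
                           model_kwargs: dict | None = None) -> dict:
    """Train on synthetic subjects, recover RR on held-out subjects.

    Returns the held-out report plus the per-subject table and the trained
    model. The reference rate is belt-derived, as in a real protocol.
    """
    cohort = make_cohort(n_train + n_test, seed=seed)
    train, test = cohort[:n_train], cohort[n_train:]
    X, y = build_training_set(train, win_len=win_len, stride=train_stride)
    model = _fit_model(X, y, epochs, batch_size, seed, model_kwargs)
    rows = []
    for rec in test:
        rr_hat = predict_recording_rr(model, rec, win_len=win_len, stride=eval_stride)
        rows.append({"subject": rec.subject_id, "tone": rec.tone,
                     "rr_true": rec.rr_true, "rr_ref": rec.rr_ref, "rr_est": rr_hat})
    table = pd.DataFrame(rows)
    report = evaluate_rr(table["rr_ref"], table["rr_est"], group="heldout")
    return {"report": report, "mae": report.mae, "rmse": report.rmse,
            "table": table, "model": model, "n_train_windows": len(X)}


def run_fusion_sweep(weights=(0.5, 0.6, 0.7, 0.8, 0.9, 1.0), n_subjects: int = 16,
                     seed: int = 0) -> pd.DataFrame:
    """Classical-path MAE as a function of the chest fusion weight.

    Re-runs the chest/face weighting ablation on a synthetic cohort: chest
    channels carry occasional movement artifacts while the face channel is
    noisy but artifact-free, so intermediate weights trade the two error
    sources off against each other.
    """
    cohort = make_cohort(n_subjects, seed=seed)
    rows = []
    for w in weights:
        fw = FusionWeights(w_chest=float(w), w_face=float(1.0 - w))
        for rec in cohort:
            rr = estimate_rr_from_bundle(rec.bundle, fw)["rr_bpm"]
            rows.append({"w_chest": float(w), "subject": rec.subject_id,
                         "tone": rec.tone, "rr_ref": rec.rr_ref, "rr_est": rr,
                         "abs_err": abs(rr - rec.rr_ref)})
    df = pd.DataFrame(rows)
    return (df.groupby(["w_chest", "tone"])["abs_err"].mean().unstack("tone")
            .rename(columns=lambda c: f"mae_{c}")
            .join(df.groupby("w_chest")["abs_err"].mean().rename("mae_all"))
            .reset_index())


def _classical_rrs(recordings) -> pd.DataFrame:
    rows = [{"subject": r.subject_id, "tone": r.tone, "rr_ref": r.rr_ref,
             "rr_est": estimate_rr_from_bundle(r.bundle)["rr_bpm"]}
            for r in recordings]
    return pd.DataFrame(rows)


def _learned_rrs(model, recordings) -> pd.DataFrame:
    rows = [{"subject": r.subject_id, "tone": r.tone, "rr_ref": r.rr_ref,
             "rr_est": predict_recording_rr(model, r)} for r in recordings]
    return pd.DataFrame(rows)


def group_protocol(recordings, path: str = "classical", seed: int = 0,
                   cross: bool = True, within: bool = True, epochs: int = 15,
                   batch_size: int = 32, test_fraction: float = 0.25,
                   model_kwargs: dict | None = None) -> dict[str, EvalReport]:
    """Skin-tone evaluation protocol: per-group and cross-tone reports.

    Classical path: every recording is estimated directly; per-group reports
    (no training, ``cross`` is ignored). Learned path: within each tone
    group the subjects are split (seeded, subject-exclusive) into train and
    test; cross mode trains on all subjects of one tone and tests on all
    subjects of the other (``cross_light_to_dark``, ``cross_dark_to_light``).
    """
    groups: dict[str, list[SubjectRecording]] = {}
    for rec in recordings:
        groups.setdefault(rec.tone, []).append(rec)
    for tone, members in groups.items():
        if not members:
            raise ValueError(f"group {tone!r} is empty")
    reports: dict[str, EvalReport] = {}

    if path == "classical":
        df_all = _classical_rrs(recordings)
        for tone, sub in df_all.groupby("tone"):
            reports[tone] = evaluate_rr(sub["rr_ref"], sub["rr_est"], group=tone)
        reports["all"] = evaluate_rr(df_all["rr_ref"], df_all["rr_est"], group="all")
        return reports

    if path != "learned":
        raise ValueError("path must be 'classical' or 'learned'")

    rng = np.random.default_rng(seed)
    models = {}
    for tone, members in sorted(groups.items()) if within else []:
        order = [members[i] for i in rng.permutation(len(members))]
        n_test = max(1, int(round(test_fraction * len(order))))
        test, train = order[:n_test], order[n_test:]
        if not train:
            raise ValueError(f"group {tone!r} too small to split")
        X, y = build_training_set(train)
        model = _fit_model(X, y, epochs, batch_size, int(rng.integers(2 ** 31)),
                           model_kwargs)
        models[tone] = model
        df = _learned_rrs(model, test)
        reports[tone] = evaluate_rr(df["rr_ref"], df["rr_est"], group=tone)

    if cross and len(groups) >= 2:
        tones = sorted(groups)
        for src in tones:
            for dst in tones:
                if src == dst:
                    continue
                # retrain on the full source group for the transfer test
                X, y = build_training_set(groups[src])
                model = _fit_model(X, y, epochs, batch_size, seed + 1, model_kwargs)
                df = _learned_rrs(model, groups[dst])
                reports[f"cross_{src}_to_{dst}"] = evaluate_rr(
                    df["rr_ref"], df["rr_est"], group=f"cross_{src}_to_{dst}")
    return reports
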