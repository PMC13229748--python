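"""Readers and writers for frame directories, video containers and belt CSVs."""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .signals import TemporalSignal

__all__ = ["read_video", "read_belt_csv", "write_signals_csv", "read_frames_dir"]


def read_frames_dir(path: Path) -> np.ndarray:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
    if not files:
        raise IOError(f"no PNG frames found in {path}")
    frames = []
    for i, f in enumerate(files):
        try:
            img = iio.imread(f)
        except Exception as exc:  # re-raise with frame context
            raise IOError(f"failed to read frame {i} ({f.name}): {exc}") from exc
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        frames.append(img[..., :3])
    return np.stack(frames)


def read_video(path: str | Path, fps: float | None = None) -> tuple[np.ndarray, float]:
    """Read an RGB frame stack from a PNG directory or a video container.

    For a frame directory the frame rate cannot be inferred and must be
    given (directly, or via a ``scene.json`` ground-truth file next to the
    frames); a missing rate is an explicit error, never a silent default.
    """
    path = Path(path)
    if path.is_dir():
        frames = read_frames_dir(path)
        if fps is None:
            meta = path / "scene.json"
            if meta.exists():
                import json

                fps = float(json.loads(meta.read_text())["fps"])
            else:
                raise ValueError("frame directories carry no frame rate; pass fps")
        return frames, float(fps)
    if not path.exists():
        raise IOError(f"no such video: {path}")
    frames = np.asarray(iio.imread(path))
    if frames.ndim == 3:  # single frame container
        frames = frames[None]
    if fps is None:
        meta = iio.immeta(path)
        fps = meta.get("fps")
        if fps is None:
            raise ValueError(f"container {path} has no fps metadata; pass fps")
    return frames[..., :3], float(fps)


def read_belt_csv(path: str | Path, jitter_tol: float = 0.01) -> TemporalSignal:
    """Read a two-column ``time_s,respiration`` belt recording.

    The sampling rate is the reciprocal median timestamp spacing. Spacing
    jitter above ``jitter_tol`` (relative) triggers linear resampling onto a
    uniform grid with a warning.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise IOError(f"malformed belt CSV {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise IOError(f"belt CSV {path} needs two columns (time_s, respiration)")
    t = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    v = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy(dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        bad = int(np.argmax(~(np.isfinite(t) & np.isfinite(v))))
        raise IOError(f"non-numeric belt row at line {bad + 2} of {path}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise IOError(f"non-increasing timestamps in {path}")
    med = float(np.median(dt))
    fs = 1.0 / med
    if np.max(np.abs(dt - med)) > jitter_tol * med:
        warnings.warn("belt timestamps are non-uniform; resampling to the median rate",
                      RuntimeWarning)
        n = int(np.floor((t[-1] - t[0]) / med)) + 1
        tu = t[0] + np.arange(n) * med
        v = np.interp(tu, t, v)
    return TemporalSignal(v, fs=fs, channel="belt", t0=float(t[0]))


def write_signals_csv(signals, path: str | Path) -> Path:
    """Dump channels to CSV with a time column (equal lengths and rates)."""
    signals = list(signals)
    df = pd.DataFrame({"time_s": signals[0].times})
    for s in signals:
        df[s.channel] = s.samples
    df.to_csv(path, index=False)
    return Path(path)
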