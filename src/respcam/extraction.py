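"""Derive rPPG and motion traces from masked ROI frame sequences.

rPPG: per frame, the mean green intensity over skin pixels is standardized
by the frame's masked all-channel mean and standard deviation (photometric
normalization), and the per-frame traces are Gaussian-smoothed in time.
Smoothing the aggregated traces is equivalent to smoothing every pixel
sequence first and then averaging, because both operations are linear.

Motion: frame-to-frame global translation by weighted Lucas-Kanade least
squares over the ROI (image-gradient normal equations), with row weights
increasing linearly from 0.2 at the top to 1.0 at the bottom to emphasize
the thoracic region. Inter-frame displacements here are far below a pixel,
which is exactly the regime where single-level Lucas-Kanade is valid; the
cumulative sum of vertical velocities yields the displacement trace. A
degenerate (textureless) pair falls back to the vertical intensity-centroid
shift.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .preprocess import SmoothingParams, temporal_gaussian_smooth
from .signals import TemporalSignal

__all__ = [
    "extract_rppg",
    "extract_motion",
    "lucas_kanade_translation",
    "row_weights",
    "NoSignalError",
]


class NoSignalError(RuntimeError):
    """No usable frames (all degenerate, or no trackable structure)."""


def _interp_nan(values: np.ndarray) -> np.ndarray:
    """Fill NaN entries by linear interpolation from valid neighbors."""
    bad = np.isnan(values)
    if not bad.any():
        return values
    if bad.all():
        raise NoSignalError("every frame is degenerate; no signal to extract")
    idx = np.arange(values.size)
    values = values.copy()
    values[bad] = np.interp(idx[bad], idx[~bad], values[~bad])
    return values


def extract_rppg(roi_frames: Sequence[np.ndarray] | np.ndarray,
                 masks: Sequence[np.ndarray] | np.ndarray, fs: float,
                 smoothing: SmoothingParams | None = SmoothingParams(),
                 channel: str = "face_rppg") -> TemporalSignal:
    """Photometrically normalized, smoothed green-channel skin average.

    ``roi_frames`` is an (N, H, W, 3) stack (or a sequence of RGB frames) and
    ``masks`` the matching binary skin masks. Degenerate frames (empty mask
    or zero variance) are filled by linear interpolation from neighbors.
    """
    n = len(roi_frames)
    g_mean = np.full(n, np.nan)
    mu = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    for i in range(n):
        m = np.asarray(masks[i]) > 0
        if m.sum() < 2:
            continue
        frame = np.asarray(roi_frames[i], dtype=float)
        vals = frame[m]
        s = vals.std()
        if s == 0.0:
            continue
        g_mean[i] = frame[..., 1][m].mean()
        mu[i] = vals.mean()
        sd[i] = s
    g_mean, mu, sd = _interp_nan(g_mean), _interp_nan(mu), _interp_nan(sd)
    if smoothing is not None and n > 2 * smoothing.half_width_k:
        g_mean = temporal_gaussian_smooth(g_mean, smoothing)
        mu = temporal_gaussian_smooth(mu, smoothing)
        sd = temporal_gaussian_smooth(sd, smoothing)
    trace = (g_mean - mu) / np.maximum(sd, 1e-12)
    return TemporalSignal(trace, fs=fs, channel=channel)


def row_weights(height: int, top: float = 0.2, bottom: float = 1.0) -> np.ndarray:
    """Linear top-to-bottom row weighting emphasizing the lower (thoracic) rows."""
    if height == 1:
        return np.array([bottom])
    return np.linspace(top, bottom, height)


def lucas_kanade_translation(prev: np.ndarray, curr: np.ndarray,
                             weights: np.ndarray | None = None,
                             min_det: float = 1e-6) -> tuple[float, float] | None:
    """Global (dx, dy) translation between two grayscale frames.

    Solves the weighted Lucas-Kanade normal equations
    ``[sum w Ix^2, sum w Ix Iy; ., sum w Iy^2] d = -[sum w Ix It; sum w Iy It]``.
    Returns None when the structure matrix is (near-)singular.
    """
    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    Iy, Ix = np.gradient(prev)
    It = curr - prev
    w = np.ones_like(prev) if weights is None else weights
    a = (w * Ix * Ix).sum()
    b = (w * Ix * Iy).sum()
    c = (w * Iy * Iy).sum()
    det = a * c - b * b
    scale = max(a + c, 1e-12)
    if det < min_det * scale ** 2 / 4.0:
        return None
    gx = (w * Ix * It).sum()
    gy = (w * Iy * It).sum()
    dx = -(c * gx - b * gy) / det
    dy = -(a * gy - b * gx) / det
    return float(dx), float(dy)


def _centroid_row(frame: np.ndarray, weights: np.ndarray) -> float | None:
    dev = np.abs(frame - frame.mean())
    mass = (dev * weights[:, None]).sum(axis=1)
    total = mass.sum()
    if total <= 0:
        return None
    return float((np.arange(frame.shape[0]) * mass).sum() / total)


def extract_motion(roi_frames: Sequence[np.ndarray] | np.ndarray, fs: float,
                   top_weight: float = 0.2, channel: str = "chest_motion") -> TemporalSignal:
    """Vertical displacement trace of an ROI from weighted optical flow.

    ``roi_frames`` is an (N, H, W) grayscale stack cropped at a fixed box
    (tracking inside a moving box would cancel the very motion of interest).
    """
    n = len(roi_frames)
    if n < 2:
        raise ValueError("motion extraction needs at least two frames")
    h = np.asarray(roi_frames[0]).shape[0]
    w_rows = row_weights(h, top=top_weight)
    weights = np.broadcast_to(w_rows[:, None], np.asarray(roi_frames[0]).shape)
    velocity = np.zeros(n)
    any_flow = False
    prev = np.asarray(roi_frames[0], dtype=float)
    for i in range(1, n):
        curr = np.asarray(roi_frames[i], dtype=float)
        d = lucas_kanade_translation(prev, curr, weights)
        if d is not None:
            velocity[i] = d[1]
            any_flow = True
        else:  # centroid fallback for textureless pairs
            c_prev = _centroid_row(prev, w_rows)
            c_curr = _centroid_row(curr, w_rows)
            if c_prev is not None and c_curr is not None:
                velocity[i] = c_curr - c_prev
                any_flow = True
        prev = curr
    if not any_flow:
        raise NoSignalError("no trackable structure in the ROI sequence")
    return TemporalSignal(np.cumsum(velocity), fs=fs, channel=channel)
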