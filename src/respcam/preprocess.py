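"""Temporal denoising and per-frame photometric normalization of masked ROIs.

Temporal smoothing uses a unit-sum Gaussian kernel (half-width ``k``, scale
``sigma`` in frames) with reflective boundaries; at 30 fps the default
``sigma = 2`` keeps the 0.1-0.6 Hz respiratory band essentially untouched
while suppressing frame-rate noise. Frame normalization standardizes every
frame by the mean and standard deviation of its masked pixel values (all
color channels pooled), removing inter-subject brightness and tone offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "SmoothingParams",
    "gaussian_kernel",
    "temporal_gaussian_smooth",
    "normalize_frame",
    "DegenerateFrameError",
]


class DegenerateFrameError(ValueError):
    """Frame has an empty mask or zero variance and cannot be normalized."""


@dataclass(frozen=True)
class SmoothingParams:
    """Gaussian temporal-smoothing parameters (both in frames)."""

    sigma: float = 2.0
    half_width_k: int = 6

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.half_width_k < math.ceil(3 * self.sigma):
            raise ValueError("half_width_k must be at least ceil(3*sigma)")


def gaussian_kernel(params: SmoothingParams = SmoothingParams()) -> np.ndarray:
    """Sampled Gaussian of half-width k, normalized to unit sum.

    Unit-sum normalization makes the filter preserve constants (DC gain 1).
    """
    tau = np.arange(-params.half_width_k, params.half_width_k + 1)
    kern = np.exp(-tau ** 2 / (2.0 * params.sigma ** 2))
    return kern / kern.sum()


def temporal_gaussian_smooth(series: np.ndarray,
                             params: SmoothingParams = SmoothingParams()) -> np.ndarray:
    """Convolve along axis 0 with the unit-sum Gaussian kernel.

    Accepts a 1-D trace or any array whose leading axis is time (e.g. a
    per-pixel T x H x W stack). Boundaries are handled by reflection.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] <= 2 * params.half_width_k:
        raise ValueError("series shorter than the smoothing kernel")
    return ndimage.convolve1d(series, gaussian_kernel(params), axis=0, mode="reflect")


def normalize_frame(frame: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Standardize a frame by its masked mean and population SD.

    Statistics pool every color channel of the masked pixels; masked-out
    pixels stay zero. Raises :class:`DegenerateFrameError` when fewer than
    two pixels are masked or the masked region is constant.
    """
    frame = np.asarray(frame, dtype=float)
    m = np.asarray(mask) > 0
    if m.shape != frame.shape[:2]:
        raise ValueError("mask shape must match the frame grid")
    vals = frame[m]
    if vals.size < 2:
        raise DegenerateFrameError("mask selects fewer than two pixels")
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd == 0.0:
        raise DegenerateFrameError("masked region has zero variance")
    out = (frame - mu) / sd
    sel = m if frame.ndim == 2 else m[..., None]
    return np.where(sel, out, 0.0)
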