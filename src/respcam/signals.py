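"""Temporal signal container and the respiratory signal-conditioning chain.

The processing order used throughout the package is detrend -> zero-phase
Butterworth bandpass (0.1-0.6 Hz) -> three-sigma normalization, applied to
both camera-derived signals and the belt reference so that the two live on
a comparable scale before fusion, windowing, or model training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

RESP_BAND = (0.1, 0.6)  # Hz, respiratory band: 6-36 breaths/min

CHANNELS = ("face_rppg", "face_motion", "chest_rppg", "chest_motion")

__all__ = [
    "RESP_BAND",
    "CHANNELS",
    "TemporalSignal",
    "FilterSpec",
    "FusionWeights",
    "MultiChannelWindow",
    "detrend",
    "bandpass",
    "three_sigma_normalize",
    "process_signal",
    "compute_snr",
    "fuse_signals",
    "make_windows",
    "stack_channels",
    "DegenerateSignalError",
]


class DegenerateSignalError(ValueError):
    """Raised when a signal has no variance and cannot be normalized."""


@dataclass(frozen=True)
class TemporalSignal:
    """A uniformly sampled 1-D physiological signal.

    Parameters
    ----------
    samples : array of float
    fs : sampling rate in Hz
    channel : semantic label (``face_rppg``, ``chest_motion``, ``belt``, ...)
    t0 : start time in seconds of the first sample
    """

    samples: np.ndarray
    fs: float
    channel: str = "unknown"
    t0: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def with_samples(self, samples: np.ndarray, channel: str | None = None) -> "TemporalSignal":
        return replace(self, samples=np.asarray(samples, dtype=float),
                       channel=self.channel if channel is None else channel)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass specification (band edges in Hz, filter order)."""

    low_hz: float = RESP_BAND[0]
    high_hz: float = RESP_BAND[1]
    order: int = 4

    def __post_init__(self):
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class FusionWeights:
    """Chest/face fusion weights; must be non-negative and sum to one."""

    w_chest: float = 0.8
    w_face: float = 0.2

    def __post_init__(self):
        if self.w_chest < 0 or self.w_face < 0:
            raise ValueError("fusion weights must be non-negative")
        if abs(self.w_chest + self.w_face - 1.0) > 1e-9:
            raise ValueError("fusion weights must sum to 1")


@dataclass(frozen=True)
class MultiChannelWindow:
    """A fixed-length T x 4 slice of the four conditioned channels.

    Channel order is ``face_rppg, face_motion, chest_rppg, chest_motion``.
    """

    values: np.ndarray
    start_index: int
    fs: float

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(CHANNELS):
            raise ValueError(f"window must be T x {len(CHANNELS)}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("window values must be finite")
        object.__setattr__(self, "values", arr)

    @property
    def length(self) -> int:
        return self.values.shape[0]


def detrend(signal: TemporalSignal) -> TemporalSignal:
    """Subtract the least-squares linear trend."""
    if len(signal) < 3:
        raise ValueError("detrend requires at least 3 samples")
    return signal.with_samples(sps.detrend(signal.samples, type="linear"))


def bandpass(signal: TemporalSignal, spec: FilterSpec = FilterSpec()) -> TemporalSignal:
    """Zero-phase (forward-backward) Butterworth bandpass filter.

    Applying the filter in both directions squares the magnitude response and
    cancels the phase response, so in-band sinusoids come through with no lag.
    """
    nyq = signal.fs / 2.0
    if not spec.high_hz < nyq:
        raise ValueError(f"band edge {spec.high_hz} Hz outside Nyquist {nyq} Hz")
    if len(signal) <= 3 * spec.order:
        raise ValueError("signal too short for the requested filter order")
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                     fs=signal.fs, output="sos")
    # generous odd-reflection padding: the 0.1 Hz corner has settling times
    # of several seconds, far beyond sosfiltfilt's default pad length
    padlen = min(len(signal) - 1, int(round(3.0 * signal.fs / spec.low_hz)))
    return signal.with_samples(sps.sosfiltfilt(sos, signal.samples, padlen=padlen))


def three_sigma_normalize(signal: TemporalSignal) -> TemporalSignal:
    """Center the signal and scale by three population standard deviations.

    After normalization roughly 99.7% of samples of a Gaussian signal fall in
    [-1, 1], giving the model a bounded, subject-independent amplitude scale.
    """
    x = signal.samples
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateSignalError("constant signal cannot be three-sigma normalized")
    return signal.with_samples((x - np.mean(x)) / (3.0 * sd))


def process_signal(signal: TemporalSignal, spec: FilterSpec = FilterSpec()) -> TemporalSignal:
    """The standard conditioning chain: detrend -> bandpass -> three-sigma."""
    return three_sigma_normalize(bandpass(detrend(signal), spec))


def compute_snr(signal: TemporalSignal, f_ref: float, half_band_hz: float = 0.05,
                noise_band: tuple[float, float] = (0.05, 1.0)) -> float:
    """Spectral SNR in dB around a reference respiratory frequency.

    Ratio of periodogram power within ``f_ref +/- half_band_hz`` to the power
    in ``noise_band`` excluding that signal band.
    """
    if not (0.05 < f_ref < signal.fs / 2):
        raise ValueError("f_ref must lie in (0.05, fs/2)")
    freqs, psd = sps.periodogram(signal.samples, fs=signal.fs, detrend="constant")
    sig_sel = np.abs(freqs - f_ref) <= half_band_hz
    noise_sel = (freqs >= noise_band[0]) & (freqs <= noise_band[1]) & ~sig_sel
    p_sig = float(np.sum(psd[sig_sel]))
    p_noise = float(np.sum(psd[noise_sel]))
    if p_noise == 0.0:
        import warnings

        warnings.warn("zero out-of-band power; SNR is +inf", RuntimeWarning)
        return float("inf")
    return 10.0 * np.log10(p_sig / p_noise)


def fuse_signals(chest: TemporalSignal, face: TemporalSignal,
                 w: FusionWeights = FusionWeights()) -> TemporalSignal:
    """Weighted fusion ``w_chest * chest + w_face * face`` of the two regions."""
    if len(chest) != len(face):
        raise ValueError("chest and face signals must have equal length")
    if chest.fs != face.fs:
        raise ValueError("chest and face signals must share a sampling rate")
    fused = w.w_chest * chest.samples + w.w_face * face.samples
    return TemporalSignal(fused, fs=chest.fs, channel="fused", t0=chest.t0)


def make_windows(signals: Sequence[TemporalSignal], win_len: int = 256,
                 stride: int = 32) -> list[MultiChannelWindow]:
    """Slice four equal-length channels into overlapping T x 4 windows.

    Window starts are 0, stride, 2*stride, ... while ``start + win_len`` fits,
    giving ``floor((L - win_len) / stride) + 1`` windows.
    """
    if len(signals) != len(CHANNELS):
        raise ValueError(f"expected {len(CHANNELS)} channels, got {len(signals)}")
    lengths = {len(s) for s in signals}
    if len(lengths) != 1:
        raise ValueError("all channels must have equal length")
    L = lengths.pop()
    if L < win_len:
        raise ValueError(f"signals of length {L} are too short for win_len={win_len}")
    if not (0 < stride <= win_len):
        raise ValueError("need 0 < stride <= win_len")
    fs = signals[0].fs
    stacked = stack_channels(signals)
    out = []
    for start in range(0, L - win_len + 1, stride):
        out.append(MultiChannelWindow(stacked[start:start + win_len], start_index=start, fs=fs))
    return out


def stack_channels(signals: Sequence[TemporalSignal]) -> np.ndarray:
    """Stack the four channels into an L x 4 array in canonical channel order."""
    by_label = {s.channel: s for s in signals}
    if set(by_label) == set(CHANNELS):
        ordered = [by_label[c] for c in CHANNELS]
    else:  # fall back to given order when labels are not canonical
        ordered = list(signals)
    return np.column_stack([s.samples for s in ordered])
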