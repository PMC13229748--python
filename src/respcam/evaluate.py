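"""Camera-belt synchronization, error metrics, and agreement analyses.

Conventions: differences are predicted minus reference; Bland-Altman limits
of agreement use the sample (n-1) standard deviation and a 1.96 factor;
the synchronization lag is positive when the belt recording lags (starts
later than) the camera-derived signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps, stats

from .signals import TemporalSignal

__all__ = [
    "EvalReport",
    "BlandAltman",
    "resample",
    "synchronize",
    "mae",
    "rmse",
    "bland_altman",
    "pearson_r",
    "evaluate_rr",
    "run_group_protocol",
    "plot_bland_altman",
    "plot_scatter",
]


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False, default=None)
    diffs: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class EvalReport:
    """Per-group evaluation summary (all rate quantities in BPM)."""

    mae: float
    rmse: float
    n: int
    bland_altman: BlandAltman | None
    pearson_r: float | None
    group: str = "all"

    def to_dict(self) -> dict:
        d = {"mae": self.mae, "rmse": self.rmse, "n": self.n, "group": self.group,
             "pearson_r": self.pearson_r}
        if self.bland_altman is not None:
            d["bland_altman"] = {"mean_diff": self.bland_altman.mean_diff,
                                 "loa_low": self.bland_altman.loa_low,
                                 "loa_high": self.bland_altman.loa_high}
        return d


def resample(signal: TemporalSignal, fs_target: float) -> TemporalSignal:
    """Linear interpolation onto a uniform grid over the original time span."""
    if fs_target <= 0:
        raise ValueError("fs_target must be positive")
    if fs_target == signal.fs:
        return signal
    t_old = signal.times
    n_new = int(np.floor((t_old[-1] - t_old[0]) * fs_target)) + 1
    t_new = t_old[0] + np.arange(n_new) / fs_target
    return TemporalSignal(np.interp(t_new, t_old, signal.samples), fs=fs_target,
                          channel=signal.channel, t0=signal.t0)


def synchronize(camera: TemporalSignal, belt: TemporalSignal,
                max_lag_s: float = 10.0, min_peak: float = 0.2,
                ) -> tuple[TemporalSignal, TemporalSignal, float]:
    """Align a camera-derived signal with the belt by cross-correlation.

    The belt is resampled to the camera rate if needed, the normalized
    cross-correlation is searched over lags within ``+/- max_lag_s`` (global
    maximum; ties broken toward smaller absolute lag), and a constant shift
    is applied. Returns ``(camera_aligned, belt_aligned, lag_s)`` over the
    overlapping region. ``lag_s`` is the belt acquisition-start delay:
    positive when the belt started later than the camera, i.e. belt sample i
    matches camera sample ``i + lag``. Both inputs are expected already
    bandpassed to the respiratory band. A correlation peak below
    ``min_peak`` triggers a warning and zero applied lag.
    """
    if belt.fs != camera.fs:
        belt = resample(belt, camera.fs)
    c = camera.samples - camera.samples.mean()
    b = belt.samples - belt.samples.mean()
    denom = np.linalg.norm(c) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("cannot synchronize constant signals")
    # corr[k] = sum_n c[n + s] b[n] with s = k - (len(b) - 1)
    corr = sps.correlate(c, b, mode="full") / denom
    lags = np.arange(-len(b) + 1, len(c))
    max_lag = int(round(max_lag_s * camera.fs))
    sel = np.abs(lags) <= max_lag
    corr_w, lags_w = corr[sel], lags[sel]
    order = np.lexsort((np.abs(lags_w), -corr_w))  # max corr, then smaller |lag|
    best = order[0]
    peak, lag = float(corr_w[best]), int(lags_w[best])
    if peak < min_peak:
        warnings.warn(f"synchronization peak {peak:.2f} < {min_peak}; applying zero lag",
                      RuntimeWarning)
        lag = 0
    if lag >= 0:  # belt started late: camera[lag + i] pairs with belt[i]
        cam_a = camera.samples[lag:]
        belt_a = belt.samples
    else:
        cam_a = camera.samples
        belt_a = belt.samples[-lag:]
    n = min(len(cam_a), len(belt_a))
    fs = camera.fs
    return (TemporalSignal(cam_a[:n], fs, camera.channel),
            TemporalSignal(belt_a[:n], fs, belt.channel), lag / fs)


def _pair(ref, pred):
    ref = np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if ref.shape != pred.shape or ref.size == 0:
        raise ValueError("reference and prediction must be equal-length, non-empty")
    return ref, pred


def mae(ref, pred) -> float:
    """Mean absolute error."""
    ref, pred = _pair(ref, pred)
    return float(np.mean(np.abs(ref - pred)))


def rmse(ref, pred) -> float:
    """Root mean squared error."""
    ref, pred = _pair(ref, pred)
    return float(np.sqrt(np.mean((ref - pred) ** 2)))


def bland_altman(ref, pred) -> BlandAltman:
    """Agreement statistics on predicted-minus-reference differences."""
    ref, pred = _pair(ref, pred)
    if ref.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    diffs = pred - ref
    means = (pred + ref) / 2.0
    md = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(mean_diff=md, loa_low=md - 1.96 * sd, loa_high=md + 1.96 * sd,
                       means=means, diffs=diffs)


def pearson_r(ref, pred) -> float:
    """Product-moment correlation between reference and predicted rates."""
    ref, pred = _pair(ref, pred)
    if np.std(ref) == 0 or np.std(pred) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(ref, pred)[0])


def evaluate_rr(ref, pred, group: str = "all") -> EvalReport:
    """Full report: MAE, RMSE, Bland-Altman and correlation where defined."""
    ref, pred = _pair(ref, pred)
    ba = bland_altman(ref, pred) if ref.size >= 2 else None
    try:
        r = pearson_r(ref, pred)
    except ValueError:
        r = None
    return EvalReport(mae=mae(ref, pred), rmse=rmse(ref, pred), n=int(ref.size),
                      bland_altman=ba, pearson_r=r, group=group)


def run_group_protocol(recordings, path: str = "classical", seed: int = 0,
                       cross: bool = True, **kwargs) -> dict[str, EvalReport]:
    """Skin-tone group evaluation: per-group reports and optional cross-tone
    transfer (train on one tone group, test on the other).

    ``recordings`` is a list of subject recordings as produced by
    :func:`respcam.experiments.make_cohort`; ``path`` selects the classical
    spectral pipeline or the learned waveform regressor. Delegates the heavy
    lifting to :mod:`respcam.experiments`.
    """
    from . import experiments  # local import to avoid a module cycle

    return experiments.group_protocol(recordings, path=path, seed=seed,
                                      cross=cross, **kwargs)


def plot_bland_altman(ba: BlandAltman, path, title: str = "Bland-Altman") -> None:
    """Write a Bland-Altman agreement plot to ``path`` (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=18, alpha=0.7)
    for y, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("Mean of reference and estimate (BPM)")
    ax.set_ylabel("Estimate - reference (BPM)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scatter(ref, pred, path, title: str = "Estimated vs reference RR") -> None:
    """Write a reference-vs-estimate scatter plot to ``path`` (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = np.asarray(ref)
    pred = np.asarray(pred)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(ref, pred, s=18, alpha=0.7)
    lo, hi = min(ref.min(), pred.min()) - 1, max(ref.max(), pred.max()) + 1
    ax.plot([lo, hi], [lo, hi], "k--", linewidth=1)
    ax.set_xlabel("Reference RR (BPM)")
    ax.set_ylabel("Estimated RR (BPM)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
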