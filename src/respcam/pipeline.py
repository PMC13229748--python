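"""End-to-end pipelines from frames (or channel bundles) to a rate estimate.

The classical path mirrors the non-learned analysis route: per-frame face
detection with chest projection, skin masking, rPPG and motion extraction,
the detrend -> bandpass -> three-sigma conditioning chain, weighted
chest/face fusion, and Welch spectral peak estimation. The chest signal in
the fusion is the chest motion trace and the face signal is the facial
rPPG trace — the two modalities with the strongest and the complementary
respiratory coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .extraction import extract_motion, extract_rppg
from .preprocess import SmoothingParams
from .roi import (
    BoundingBox,
    SkinBlobDetector,
    SkinThresholds,
    compute_skin_mask,
    project_chest_roi,
    track_faces,
)
from .signals import (
    CHANNELS,
    FilterSpec,
    FusionWeights,
    TemporalSignal,
    fuse_signals,
    process_signal,
)
from .spectral import WelchParams, estimate_rr

__all__ = ["PipelineResult", "analyze_video", "estimate_rr_classical",
           "process_bundle", "fuse_bundle", "estimate_rr_from_bundle"]


@dataclass
class PipelineResult:
    """Raw and conditioned channels plus the per-frame geometry."""

    raw: dict[str, TemporalSignal]
    processed: dict[str, TemporalSignal]
    face_boxes: list[BoundingBox]
    chest_boxes: list[BoundingBox]
    fps: float


def _grayscale(frames: np.ndarray) -> np.ndarray:
    return np.asarray(frames, dtype=float) @ np.array([0.299, 0.587, 0.114])


def analyze_video(frames, fps: float, detector=None,
                  thresholds: SkinThresholds = SkinThresholds(),
                  alpha: float = 2.5, beta: float = 0.2,
                  smoothing: SmoothingParams | None = SmoothingParams(),
                  filter_spec: FilterSpec = FilterSpec(),
                  mask_chest: bool = True) -> PipelineResult:
    """Extract and condition the four channels from an RGB frame sequence.

    Boxes are detected per frame (tracking-by-persistence on dropouts); the
    motion traces use a fixed median box so that box jitter does not cancel
    the chest displacement being measured. ``mask_chest=False`` skips skin
    masking on the chest region (useful when the chest is clothed).
    """
    frames = np.asarray(frames)
    n, H, W = frames.shape[:3]
    if detector is None:
        detector = SkinBlobDetector(thresholds)
    face_boxes = track_faces(frames, detector)
    chest_boxes = [project_chest_roi(b, alpha, beta, W, H) for b in face_boxes]

    def median_box(boxes: Sequence[BoundingBox]) -> BoundingBox:
        xs = int(np.median([b.x for b in boxes]))
        ys = int(np.median([b.y for b in boxes]))
        ws = int(np.median([b.w for b in boxes]))
        hs = int(np.median([b.h for b in boxes]))
        return BoundingBox(xs, ys, ws, hs).clip(W, H)

    face_fixed = median_box(face_boxes)
    chest_fixed = median_box(chest_boxes)

    face_stack = np.stack([face_fixed.crop(f) for f in frames])
    chest_stack = np.stack([chest_fixed.crop(f) for f in frames])
    face_masks = np.stack([compute_skin_mask(f, thresholds) for f in face_stack])
    if mask_chest:
        chest_masks = np.stack([compute_skin_mask(f, thresholds) for f in chest_stack])
    else:
        chest_masks = np.ones(chest_stack.shape[:3], dtype=np.uint8)

    raw = {
        "face_rppg": extract_rppg(face_stack, face_masks, fps, smoothing, "face_rppg"),
        "face_motion": extract_motion(_grayscale(face_stack), fps, channel="face_motion"),
        "chest_rppg": extract_rppg(chest_stack, chest_masks, fps, smoothing, "chest_rppg"),
        "chest_motion": extract_motion(_grayscale(chest_stack), fps, channel="chest_motion"),
    }
    processed = {k: process_signal(v, filter_spec) for k, v in raw.items()}
    return PipelineResult(raw=raw, processed=processed, face_boxes=face_boxes,
                          chest_boxes=chest_boxes, fps=fps)


def estimate_rr_classical(frames, fps: float, weights: FusionWeights = FusionWeights(),
                          welch: WelchParams = WelchParams(), **analyze_kw) -> dict:
    """Classical spectral path: analyze, fuse chest motion with face rPPG,
    Welch peak, rate in BPM. Returns the rate plus intermediate results."""
    result = analyze_video(frames, fps, **analyze_kw)
    fused = fuse_signals(result.processed["chest_motion"],
                         result.processed["face_rppg"], weights)
    out = estimate_rr(fused, welch)
    out["pipeline"] = result
    out["fused"] = fused
    return out


def process_bundle(bundle: dict[str, TemporalSignal],
                   filter_spec: FilterSpec = FilterSpec()) -> dict[str, TemporalSignal]:
    """Condition every camera channel of a synthetic bundle."""
    return {k: process_signal(bundle[k], filter_spec) for k in CHANNELS}


def fuse_bundle(bundle: dict[str, TemporalSignal],
                weights: FusionWeights = FusionWeights(),
                filter_spec: FilterSpec = FilterSpec()) -> TemporalSignal:
    processed = process_bundle(bundle, filter_spec)
    return fuse_signals(processed["chest_motion"], processed["face_rppg"], weights)


def estimate_rr_from_bundle(bundle: dict[str, TemporalSignal],
                            weights: FusionWeights = FusionWeights(),
                            welch: WelchParams = WelchParams()) -> dict:
    """Classical spectral path applied to a directly synthesized bundle."""
    return estimate_rr(fuse_bundle(bundle, weights), welch)
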