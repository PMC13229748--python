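"""Face/chest region-of-interest detection and skin segmentation.

The face box is found per frame by a pluggable detector; the chest box is
projected geometrically below the face (vertical extent ``alpha`` face
heights, horizontal expansion ``beta`` face widths on both sides). Skin
pixels are segmented by dual color-space thresholding (YCrCb chrominance OR
HSV hue/saturation), then the binary mask is refined with Gaussian smoothing
and morphological opening/closing.

Color conventions: frames are 8-bit RGB. YCrCb uses the full-range (JPEG)
transform so the classic Cr in [133, 173], Cb in [77, 127] skin bounds apply;
HSV components are scaled to 0-255.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "BoundingBox",
    "HaarSpec",
    "SkinThresholds",
    "haar_feature",
    "detect_face",
    "track_faces",
    "project_chest_roi",
    "skin_mask_ycrcb",
    "skin_mask_hsv",
    "combine_masks",
    "refine_mask",
    "compute_skin_mask",
    "apply_mask",
    "rgb_to_ycrcb",
    "oracle_detector",
    "SkinBlobDetector",
    "FaceNotFoundError",
    "ChestOutOfFrameError",
]


class FaceNotFoundError(RuntimeError):
    """No face detection in a frame."""


class ChestOutOfFrameError(RuntimeError):
    """The projected chest region is empty after clipping to the frame."""


@dataclass(frozen=True)
class BoundingBox:
    """Integer pixel rectangle, half-open extent [x, x+w) x [y, y+h).

    Origin is the top-left corner of the frame with y increasing downward.
    """

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("bounding box must have positive width and height")

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.h), slice(self.x, self.x + self.w)

    def clip(self, frame_w: int, frame_h: int) -> "BoundingBox":
        x0 = max(self.x, 0)
        y0 = max(self.y, 0)
        x1 = min(self.x + self.w, frame_w)
        y1 = min(self.y + self.h, frame_h)
        if x1 <= x0 or y1 <= y0:
            raise ChestOutOfFrameError("box is empty after clipping to the frame")
        return BoundingBox(x0, y0, x1 - x0, y1 - y0)

    def iou(self, other: "BoundingBox") -> float:
        ix = max(0, min(self.x + self.w, other.x + other.w) - max(self.x, other.x))
        iy = max(0, min(self.y + self.h, other.y + other.h) - max(self.y, other.y))
        inter = ix * iy
        return inter / (self.area + other.area - inter) if inter else 0.0

    def crop(self, frame: np.ndarray) -> np.ndarray:
        ys, xs = self.slices
        return frame[ys, xs]


@dataclass(frozen=True)
class HaarSpec:
    """White/black rectangle lists of a Haar-like kernel within a window."""

    white_rects: tuple[BoundingBox, ...]
    black_rects: tuple[BoundingBox, ...]

    def __post_init__(self):
        if not self.white_rects or not self.black_rects:
            raise ValueError("HaarSpec needs at least one white and one black rectangle")


def haar_feature(image: np.ndarray, spec: HaarSpec) -> float:
    """Haar-like feature: intensity sum over white rects minus black rects.

    Uses an integral image; equivalent to direct double-loop summation.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    ii = np.zeros((H + 1, W + 1))
    ii[1:, 1:] = image.cumsum(axis=0).cumsum(axis=1)

    def rect_sum(b: BoundingBox) -> float:
        if b.x < 0 or b.y < 0 or b.x + b.w > W or b.y + b.h > H:
            raise ValueError(f"rectangle {b} outside image {W}x{H}")
        return float(ii[b.y + b.h, b.x + b.w] - ii[b.y, b.x + b.w]
                     - ii[b.y + b.h, b.x] + ii[b.y, b.x])

    return sum(rect_sum(b) for b in spec.white_rects) - sum(rect_sum(b) for b in spec.black_rects)


@dataclass(frozen=True)
class SkinThresholds:
    """Skin-color bounds in YCrCb chrominance and HSV hue/saturation (8-bit)."""

    cr_min: int = 133
    cr_max: int = 173
    cb_min: int = 77
    cb_max: int = 127
    h_min: int = 0
    h_max: int = 50
    s_min: int = 58
    s_max: int = 174

    def __post_init__(self):
        for lo, hi in ((self.cr_min, self.cr_max), (self.cb_min, self.cb_max),
                       (self.h_min, self.h_max), (self.s_min, self.s_max)):
            if lo > hi:
                raise ValueError("threshold min must not exceed max")


_YCRCB = np.array([  # rows: Y, Cr, Cb coefficients on RGB (full-range JPEG)
    [0.299, 0.587, 0.114],
    [0.713 * (1 - 0.299), -0.713 * 0.587, -0.713 * 0.114],
    [-0.564 * 0.299, -0.564 * 0.587, 0.564 * (1 - 0.114)],
]).T


def rgb_to_ycrcb(frame: np.ndarray) -> np.ndarray:
    """Full-range 8-bit YCrCb: Y in [0,255], Cr/Cb centered on 128."""
    out = np.asarray(frame, dtype=float) @ _YCRCB
    out[..., 1:] += 128.0
    return out


def skin_mask_ycrcb(frame: np.ndarray, thr: SkinThresholds = SkinThresholds()) -> np.ndarray:
    ycrcb = rgb_to_ycrcb(frame)
    cr, cb = ycrcb[..., 1], ycrcb[..., 2]
    return ((cr >= thr.cr_min) & (cr <= thr.cr_max)
            & (cb >= thr.cb_min) & (cb <= thr.cb_max)).astype(np.uint8)


def rgb_to_hs(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hue and saturation on the 0-255 scale (standard hexcone HSV model)."""
    f = np.asarray(frame, dtype=float)
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = maxc - minc
    s = np.where(maxc > 0, delta / np.where(maxc > 0, maxc, 1.0), 0.0)
    d = np.where(delta > 0, delta, 1.0)
    h = np.where(maxc == r, ((g - b) / d) % 6.0,
                 np.where(maxc == g, (b - r) / d + 2.0, (r - g) / d + 4.0))
    h = np.where(delta > 0, h / 6.0, 0.0)
    return h * 255.0, s * 255.0


def skin_mask_hsv(frame: np.ndarray, thr: SkinThresholds = SkinThresholds()) -> np.ndarray:
    h, s = rgb_to_hs(frame)
    return ((h >= thr.h_min) & (h <= thr.h_max)
            & (s >= thr.s_min) & (s <= thr.s_max)).astype(np.uint8)


def combine_masks(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise logical OR of two binary masks."""
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    return ((a > 0) | (b > 0)).astype(np.uint8)


def _disk(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1), dtype=bool)
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius ** 2


def refine_mask(mask: np.ndarray, blur_sigma: float = 1.0, open_radius: int = 1,
                close_radius: int = 2) -> np.ndarray:
    """Gaussian-smooth, re-threshold at 0.5, then open and close with disks."""
    m = ndimage.gaussian_filter(mask.astype(float), sigma=blur_sigma) > 0.5
    if open_radius > 0:
        m = ndimage.binary_opening(m, structure=_disk(open_radius))
    if close_radius > 0:
        m = ndimage.binary_closing(m, structure=_disk(close_radius))
    return m.astype(np.uint8)


def compute_skin_mask(frame: np.ndarray, thr: SkinThresholds = SkinThresholds(),
                      refine: bool = True, **refine_kw) -> np.ndarray:
    """Full skin-mask chain: YCrCb OR HSV threshold, then refinement."""
    m = combine_masks(skin_mask_ycrcb(frame, thr), skin_mask_hsv(frame, thr))
    return refine_mask(m, **refine_kw) if refine else m


def apply_mask(frame: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out non-skin pixels (elementwise product with the binary mask)."""
    frame = np.asarray(frame)
    if mask.shape != frame.shape[:2]:
        raise ValueError("mask shape must match the frame grid")
    m = (mask > 0)
    if frame.ndim == 3:
        m = m[..., None]
    return frame * m


# --- face detection -------------------------------------------------------

Detector = Callable[[np.ndarray], Sequence[BoundingBox]]


def oracle_detector(face_box: BoundingBox) -> Detector:
    """Detector returning a known ground-truth box (for synthetic scenes)."""

    def detect(frame: np.ndarray) -> list[BoundingBox]:
        return [face_box]

    return detect


class SkinBlobDetector:
    """Heuristic face detector: topmost large connected skin component.

    A stand-in for a boosted-cascade detector on cooperative frontal scenes:
    the face is the topmost skin blob covering at least ``min_area_frac`` of
    the frame (the chest, if skin-toned, lies below it).
    """

    def __init__(self, thr: SkinThresholds = SkinThresholds(), min_area_frac: float = 0.005):
        self.thr = thr
        self.min_area_frac = min_area_frac

    def __call__(self, frame: np.ndarray) -> list[BoundingBox]:
        mask = compute_skin_mask(frame, self.thr, refine=False)
        labels, n = ndimage.label(mask)
        if n == 0:
            return []
        # pixel-count area filter doubles as speck suppression
        counts = np.bincount(labels.ravel())[1:]
        min_area = self.min_area_frac * mask.size
        keep = np.flatnonzero(counts >= min_area) + 1
        if keep.size == 0:
            return []
        objects = ndimage.find_objects(labels)
        candidates = []
        for lab in keep:
            ys, xs = objects[lab - 1]
            candidates.append(BoundingBox(xs.start, ys.start,
                                          xs.stop - xs.start, ys.stop - ys.start))
        return [min(candidates, key=lambda b: b.y)]


def detect_face(frame: np.ndarray, detector: Detector) -> BoundingBox:
    """Run the detector on one frame; largest-area box wins on multiples."""
    if frame.size == 0:
        raise ValueError("empty frame")
    boxes = list(detector(frame))
    if not boxes:
        raise FaceNotFoundError("no face detected in frame")
    return max(boxes, key=lambda b: b.area)


def track_faces(frames: Sequence[np.ndarray], detector: Detector) -> list[BoundingBox]:
    """Per-frame detection with tracking-by-persistence on dropouts.

    A frame with no detection reuses the previous frame's box; failure on the
    very first frame aborts, since there is nothing to fall back to.
    """
    boxes: list[BoundingBox] = []
    for i, frame in enumerate(frames):
        try:
            boxes.append(detect_face(frame, detector))
        except FaceNotFoundError:
            if not boxes:
                raise FaceNotFoundError("face not found in the first frame")
            boxes.append(boxes[-1])
    return boxes


def project_chest_roi(face: BoundingBox, alpha: float = 2.5, beta: float = 0.2,
                      frame_w: int | None = None, frame_h: int | None = None) -> BoundingBox:
    """Project the chest box below a face box.

    Vertical extent ``[y + h, y + alpha*h)``; horizontal extent expanded by
    ``beta * w`` on each side: ``[x - beta*w, x + (1 + beta)*w)``. With frame
    dimensions given the result is clipped to the frame (the unclipped
    projection is translation-equivariant with the face box); an empty
    clipped box raises :class:`ChestOutOfFrameError`.
    """
    y0 = face.y + face.h
    y1 = face.y + int(round(alpha * face.h))
    x0 = face.x - int(round(beta * face.w))
    x1 = face.x + int(round((1 + beta) * face.w))
    if y1 <= y0 or x1 <= x0:
        raise ChestOutOfFrameError("projected chest region is empty")
    box = BoundingBox(x0, y0, x1 - x0, y1 - y0)
    if frame_w is None or frame_h is None:
        return box
    return box.clip(frame_w, frame_h)
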