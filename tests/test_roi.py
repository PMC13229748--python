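"""ROI geometry, Haar features, skin segmentation, and face detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.color import rgb2hsv

from respcam.roi import (
    BoundingBox,
    ChestOutOfFrameError,
    FaceNotFoundError,
    HaarSpec,
    SkinBlobDetector,
    SkinThresholds,
    apply_mask,
    combine_masks,
    compute_skin_mask,
    detect_face,
    haar_feature,
    oracle_detector,
    project_chest_roi,
    refine_mask,
    rgb_to_hs,
    rgb_to_ycrcb,
    skin_mask_hsv,
    skin_mask_ycrcb,
    track_faces,
)


def brute_force_haar(image, spec):
    image = np.asarray(image, dtype=float)

    def s(b):
        total = 0.0
        for yy in range(b.y, b.y + b.h):
            for xx in range(b.x, b.x + b.w):
                total += image[yy, xx]
        return total

    return (sum(s(b) for b in spec.white_rects) - sum(s(b) for b in spec.black_rects))


class TestHaar:
    def test_two_by_two_column_contrast(self):
        img = np.array([[5.0, 1.0], [2.0, 2.0]])
        spec = HaarSpec((BoundingBox(0, 0, 1, 2),), (BoundingBox(1, 0, 1, 2),))
        assert haar_feature(img, spec) == 4.0

    def test_constant_image_balanced_kernel_is_zero(self):
        img = np.full((4, 4), 3.7)
        spec = HaarSpec((BoundingBox(0, 0, 2, 4),), (BoundingBox(2, 0, 2, 4),))
        assert haar_feature(img, spec) == pytest.approx(0.0)

    def test_matches_brute_force_on_random_kernels(self, rng):
        img = rng.normal(size=(8, 8))
        for _ in range(20):
            def rand_rect():
                x, y = rng.integers(0, 6, 2)
                w = rng.integers(1, 8 - x + 1)
                h = rng.integers(1, 8 - y + 1)
                return BoundingBox(int(x), int(y), int(w), int(h))

            spec = HaarSpec((rand_rect(), rand_rect()), (rand_rect(),))
            assert haar_feature(img, spec) == pytest.approx(brute_force_haar(img, spec))

    def test_out_of_bounds_rect_rejected(self):
        img = np.zeros((4, 4))
        spec = HaarSpec((BoundingBox(2, 2, 4, 4),), (BoundingBox(0, 0, 1, 1),))
        with pytest.raises(ValueError):
            haar_feature(img, spec)


class TestChestProjection:
    def test_printed_defaults(self):
        box = project_chest_roi(BoundingBox(100, 50, 80, 100), 2.5, 0.2, 640, 480)
        assert (box.x, box.x + box.w) == (84, 196)
        assert (box.y, box.y + box.h) == (150, 300)

    def test_zero_beta_keeps_face_x_extent(self):
        face = BoundingBox(30, 10, 40, 40)
        box = project_chest_roi(face, 2.5, 0.0, 640, 480)
        assert (box.x, box.w) == (face.x, face.w)

    def test_clipping_at_frame_bottom(self):
        box = project_chest_roi(BoundingBox(0, 400, 50, 60), 2.5, 0.2, 640, 480)
        assert (box.y, box.y + box.h) == (460, 480)

    def test_fully_out_of_frame_raises(self):
        with pytest.raises(ChestOutOfFrameError):
            project_chest_roi(BoundingBox(0, 440, 50, 40), 2.5, 0.2, 640, 480)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(x=st.integers(0, 200), y=st.integers(0, 200), dx=st.integers(-50, 50),
           dy=st.integers(-50, 50))
    def test_translation_equivariance(self, x, y, dx, dy):
        face = BoundingBox(x, y, 40, 50)
        shifted = BoundingBox(x + dx, y + dy, 40, 50)
        a = project_chest_roi(face)  # unclipped (huge frame)
        b = project_chest_roi(shifted)
        assert (b.x - a.x, b.y - a.y, b.w, b.h) == (dx, dy, a.w, a.h)


class TestSkinMasks:
    def test_ycrcb_in_range_skin_pixel(self):
        # a known skin-like triple lands inside the chrominance bounds
        px = np.array([[[200, 140, 120]]], dtype=np.uint8)
        ycrcb = rgb_to_ycrcb(px)[0, 0]
        assert 133 <= ycrcb[1] <= 173 and 77 <= ycrcb[2] <= 127
        assert skin_mask_ycrcb(px)[0, 0] == 1

    def test_pure_blue_rejected(self):
        px = np.array([[[0, 0, 255]]], dtype=np.uint8)
        assert rgb_to_ycrcb(px)[0, 0, 1] < 133  # Cr below the skin range
        assert skin_mask_ycrcb(px)[0, 0] == 0

    def test_collapsed_threshold_range_empty_mask(self, rng):
        frame = rng.integers(0, 256, (6, 6, 3)).astype(np.uint8)
        thr = SkinThresholds(cr_min=200, cr_max=200, cb_min=0, cb_max=0)
        assert skin_mask_ycrcb(frame, thr).sum() == 0

    def test_hsv_matches_skimage_transform(self, rng):
        frame = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        h, s = rgb_to_hs(frame)
        ref = rgb2hsv(frame) * 255.0
        np.testing.assert_allclose(h, ref[..., 0], atol=1e-9)
        np.testing.assert_allclose(s, ref[..., 1], atol=1e-9)

    def test_hsv_examples(self):
        skin = np.array([[[200, 140, 120]]], dtype=np.uint8)
        assert skin_mask_hsv(skin)[0, 0] == 1
        gray = np.array([[[128, 128, 128]]], dtype=np.uint8)
        assert skin_mask_hsv(gray)[0, 0] == 0  # zero saturation
        thr = SkinThresholds(h_min=0, h_max=255, s_min=0, s_max=255)
        frame = np.random.default_rng(0).integers(0, 256, (5, 5, 3)).astype(np.uint8)
        assert skin_mask_hsv(frame, thr).all()

    def test_combine_is_elementwise_or(self, rng):
        a = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        b = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(combine_masks(a, b), (a | b))
        np.testing.assert_array_equal(combine_masks(a, a), a)
        np.testing.assert_array_equal(combine_masks(a, b), combine_masks(b, a))
        with pytest.raises(ValueError):
            combine_masks(a, b[:5])


class TestRefineAndApply:
    def test_opening_removes_isolated_speck(self):
        m = np.zeros((15, 15), dtype=np.uint8)
        m[7, 7] = 1
        assert refine_mask(m, blur_sigma=0.5, open_radius=1, close_radius=0).sum() == 0

    def test_closing_fills_pinhole(self):
        m = np.ones((20, 20), dtype=np.uint8)
        m[10, 10] = 0
        out = refine_mask(m, blur_sigma=0.5, open_radius=0, close_radius=1)
        assert out[10, 10] == 1

    def test_solid_mask_interior_preserved(self):
        m = np.ones((20, 20), dtype=np.uint8)
        out = refine_mask(m)
        assert out.dtype == np.uint8
        assert set(np.unique(out)) <= {0, 1}
        assert out[4:16, 4:16].all()

    def test_apply_mask_identity_and_annihilation(self, rng):
        frame = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
        ones = np.ones((8, 8), dtype=np.uint8)
        zeros = np.zeros((8, 8), dtype=np.uint8)
        np.testing.assert_array_equal(apply_mask(frame, ones), frame)
        assert apply_mask(frame, zeros).sum() == 0
        mask = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(apply_mask(frame, mask),
                                      frame * mask[..., None])
        with pytest.raises(ValueError):
            apply_mask(frame, ones[:4])


class TestDetection:
    def test_oracle_detector_returns_ground_truth(self, clean_scene, clean_frames):
        det = oracle_detector(clean_scene.face_box)
        box = detect_face(clean_frames[0], det)
        assert box == clean_scene.face_box
        assert box.iou(clean_scene.face_box) == 1.0

    def test_largest_area_tie_break(self):
        small, big = BoundingBox(0, 0, 10, 10), BoundingBox(20, 20, 20, 20)
        box = detect_face(np.zeros((64, 64, 3), np.uint8), lambda f: [small, big])
        assert box == big

    def test_blank_frame_raises(self):
        det = SkinBlobDetector()
        with pytest.raises(FaceNotFoundError):
            detect_face(np.zeros((64, 64, 3), np.uint8), det)

    def test_blob_detector_finds_synthetic_face(self, clean_scene, clean_frames):
        box = detect_face(clean_frames[0], SkinBlobDetector())
        assert box.iou(clean_scene.face_box) > 0.9

    def test_persistence_on_dropout(self, clean_frames):
        blank = np.zeros_like(clean_frames[0])
        det = SkinBlobDetector()
        boxes = track_faces([clean_frames[0], blank, clean_frames[2]], det)
        assert boxes[1] == boxes[0]
        with pytest.raises(FaceNotFoundError):
            track_faces([blank], det)

    def test_skin_mask_covers_face_and_chest_only(self, clean_scene, clean_frames):
        mask = compute_skin_mask(clean_frames[0])
        ys, xs = clean_scene.face_box.slices
        assert mask[ys, xs].mean() > 0.5  # ellipse fills ~78% of its box
        assert mask[:clean_scene.face_box.y - 2, :].mean() < 0.01  # background
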