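"""Segmentation: averaging, ONH and vessel masks, dilation, ROI merge."""

import numpy as np
import pytest

from onhpleth.phantom import MotionArtifactSpec, render_video
from onhpleth.segmentation import (
    MaskKind,
    MaskProvenance,
    ROIMask,
    average_frames,
    dilate_vessels,
    make_onh_roi,
    segment_onh,
    segment_vessels,
)
from onhpleth.video import FrameFlag, VideoSequence


def brute_force_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    """Offset-set dilation oracle: union of the disk's translates."""
    out = np.zeros_like(mask)
    rr, cc = np.nonzero(mask)
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr * dr + dc * dc <= radius * radius:
                r, c = rr + dr, cc + dc
                keep = (r >= 0) & (r < mask.shape[0]) & (c >= 0) & (c < mask.shape[1])
                out[r[keep], c[keep]] = True
    return out


class TestAverageFrames:
    def test_identical_frames_average_to_any_frame(self, still_video):
        video, _ = still_video
        sub = VideoSequence(frames=np.repeat(video.frames[:1], 5, axis=0), fps=video.fps)
        np.testing.assert_allclose(average_frames(sub), video.frames[0])

    def test_noise_reduction_follows_square_root_law(self, phantom_scene):
        video, _ = render_video(
            phantom_scene, np.zeros(250), MotionArtifactSpec.still(250, noise_sd=8.0, seed=2)
        )
        avg = average_frames(video)
        flat = np.zeros(video.frame_shape, dtype=bool)
        flat[5:20, 5:20] = True  # background corner, no structure
        residual = (avg - video.frames.mean(axis=0))  # zero by construction
        noise = avg[flat] - phantom_scene.static_scene()[flat]
        assert 0.3 < noise.std() < 0.8  # 8 / sqrt(250) = 0.51

    def test_blink_frames_excluded_from_average(self, phantom_scene):
        art = MotionArtifactSpec(
            dx=np.zeros(40), dy=np.zeros(40), theta=np.zeros(40), blink_frames=frozenset({3, 4})
        )
        video, _ = render_video(phantom_scene, np.zeros(40), art)
        clean, _ = render_video(phantom_scene, np.zeros(40), MotionArtifactSpec.still(40))
        from onhpleth.registration import flag_artifacts

        video.flags[:] = flag_artifacts(video)
        np.testing.assert_allclose(average_frames(video), average_frames(clean), atol=1e-9)

    def test_zero_ok_frames_errors(self, phantom_scene):
        video, _ = render_video(phantom_scene, np.zeros(5), MotionArtifactSpec.still(5))
        video.flags[:] = [FrameFlag.BLINK] * 5
        with pytest.raises(RuntimeError, match="no ok-flagged"):
            average_frames(video)


class TestSegmentONH:
    def test_manual_mask_returned_unchanged(self, phantom_scene, still_video):
        video, truth = still_video
        avg = average_frames(video)
        manual = ROIMask(truth.onh_mask, MaskKind.ONH, MaskProvenance.MANUAL)
        out = segment_onh(avg, manual_mask=manual)
        assert out.provenance == MaskProvenance.MANUAL
        np.testing.assert_array_equal(out.mask, truth.onh_mask)

    def test_automatic_segmentation_dice_against_truth(self, still_video):
        video, truth = still_video
        avg = average_frames(video)
        # the phantom disc fills ~38 % of the frame (a real ONH is a much
        # smaller fraction of the field of view), so the brightness
        # quantile is set from the disc fraction rather than the default
        disc_fraction = truth.onh_mask.mean()
        out = segment_onh(avg, threshold_quantile=1.0 - 0.9 * disc_fraction)
        inter = (out.mask & truth.onh_mask).sum()
        dice = 2 * inter / (out.mask.sum() + truth.onh_mask.sum())
        assert out.provenance == MaskProvenance.AUTOMATIC
        assert dice >= 0.95

    def test_empty_manual_mask_rejected(self, still_video):
        video, _ = still_video
        avg = average_frames(video)
        empty = ROIMask(np.zeros_like(avg, dtype=bool), MaskKind.ONH, MaskProvenance.MANUAL)
        with pytest.raises(ValueError, match="empty"):
            segment_onh(avg, manual_mask=empty)

    def test_multi_blob_manual_mask_rejected(self, still_video):
        video, _ = still_video
        avg = average_frames(video)
        m = np.zeros_like(avg, dtype=bool)
        m[5:10, 5:10] = True
        m[50:60, 50:60] = True
        with pytest.raises(ValueError, match="single blob"):
            segment_onh(avg, manual_mask=ROIMask(m, MaskKind.ONH, MaskProvenance.MANUAL))


class TestSegmentVessels:
    def test_vessel_recall_on_phantom_tree(self, still_video):
        from skimage.morphology import dilation, disk

        video, truth = still_video
        out = segment_vessels(average_frames(video))
        # recall within 1 px tolerance: a hit counts if detected within 1 px
        hits = (dilation(out.mask, disk(1)) & truth.vessel_mask).sum()
        assert hits / truth.vessel_mask.sum() >= 0.8

    def test_vessel_free_scene_gives_near_empty_mask(self, phantom_scene):
        from dataclasses import replace

        bare = replace(phantom_scene, vessel_tree=[])
        video, _ = render_video(bare, np.zeros(3), MotionArtifactSpec.still(3))
        out = segment_vessels(average_frames(video))
        assert out.mask.mean() < 0.005

    def test_constant_image_gives_empty_mask(self):
        out = segment_vessels(np.full((64, 64), 100.0))
        assert not out.mask.any()


class TestDilateVessels:
    def test_single_pixel_becomes_13_pixel_disk(self):
        m = np.zeros((21, 21), dtype=bool)
        m[10, 10] = True
        out = dilate_vessels(ROIMask(m, MaskKind.VESSELS, MaskProvenance.AUTOMATIC))
        assert out.n_pixels == 13
        np.testing.assert_array_equal(out.mask, brute_force_dilate(m, 2))

    def test_empty_mask_stays_empty(self):
        m = np.zeros((16, 16), dtype=bool)
        out = dilate_vessels(ROIMask(m, MaskKind.VESSELS, MaskProvenance.AUTOMATIC))
        assert not out.mask.any()

    def test_library_dilation_equals_offset_set_oracle_on_random_masks(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            m = rng.random((64, 64)) < 0.05
            out = dilate_vessels(ROIMask(m, MaskKind.VESSELS, MaskProvenance.AUTOMATIC))
            np.testing.assert_array_equal(out.mask, brute_force_dilate(m, 2))

    def test_dilation_is_extensive_and_monotone(self):
        rng = np.random.default_rng(23)
        a = rng.random((48, 48)) < 0.04
        b = a | (rng.random((48, 48)) < 0.04)
        da = dilate_vessels(ROIMask(a, MaskKind.VESSELS, MaskProvenance.AUTOMATIC)).mask
        db = dilate_vessels(ROIMask(b, MaskKind.VESSELS, MaskProvenance.AUTOMATIC)).mask
        assert (a <= da).all()  # extensive
        assert (da <= db).all()  # monotone

    def test_even_diameter_rejected(self):
        m = np.zeros((8, 8), dtype=bool)
        with pytest.raises(ValueError, match="odd"):
            dilate_vessels(ROIMask(m, MaskKind.VESSELS, MaskProvenance.AUTOMATIC), diameter_px=4)


class TestMakeONHROI:
    def _masks(self, phantom_scene):
        onh = ROIMask(phantom_scene.onh_mask(), MaskKind.ONH, MaskProvenance.MANUAL)
        vessels = ROIMask(phantom_scene.vessel_mask(), MaskKind.VESSELS, MaskProvenance.AUTOMATIC)
        return onh, dilate_vessels(vessels)

    def test_set_arithmetic_oracle(self, phantom_scene):
        onh, vd = self._masks(phantom_scene)
        roi = make_onh_roi(onh, vd, min_pixels=100)
        expected = np.zeros_like(onh.mask)
        for r in range(onh.mask.shape[0]):
            for c in range(onh.mask.shape[1]):
                expected[r, c] = onh.mask[r, c] and not vd.mask[r, c]
        np.testing.assert_array_equal(roi.mask, expected)

    def test_empty_vessels_gives_roi_equal_onh(self, phantom_scene):
        onh, _ = self._masks(phantom_scene)
        empty = ROIMask(np.zeros_like(onh.mask), MaskKind.VESSELS_DILATED, MaskProvenance.AUTOMATIC)
        roi = make_onh_roi(onh, empty, min_pixels=100)
        np.testing.assert_array_equal(roi.mask, onh.mask)

    def test_vessels_covering_disc_is_hard_failure(self, phantom_scene):
        onh, _ = self._masks(phantom_scene)
        full = ROIMask(np.ones_like(onh.mask), MaskKind.VESSELS_DILATED, MaskProvenance.AUTOMATIC)
        with pytest.raises(RuntimeError, match="noise-dominated"):
            make_onh_roi(onh, full, min_pixels=100)

    def test_roi_disjoint_from_vessels_and_inside_onh(self, phantom_scene):
        onh, vd = self._masks(phantom_scene)
        roi = make_onh_roi(onh, vd, min_pixels=100)
        assert not (roi.mask & vd.mask).any()
        assert (roi.mask <= onh.mask).all()
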