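"""Contour tracing, distance profile, finger webs and ROI construction."""

import math

import numpy as np
import pytest

from palmfuse import synth_hands as sh
from palmfuse.errors import HandNotOutstretchedError, PalmFuseError, RoiOutOfFrameError
from palmfuse.roi_locator import (
    ContourPath,
    DistanceProfile,
    build_roi_quad,
    crop_quad,
    distance_profile,
    extract_roi,
    locate_finger_webs,
    rotation_angle,
    trace_contour,
    transform_points,
)
from palmfuse.segmentation import segment_palm_region


class TestTraceContour:
    def test_square_block_visits_border_cells_once(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[3:7, 3:7] = 1
        path = trace_contour(m).points
        assert len(path) == 12
        border = {(r, c) for r in range(3, 7) for c in range(3, 7)
                  if r in (3, 6) or c in (3, 6)}
        assert {tuple(p) for p in path} == border
        # closed: last point 8-adjacent to first
        assert max(abs(path[0][0] - path[-1][0]), abs(path[0][1] - path[-1][1])) == 1

    def test_starts_at_bottom_left_and_runs_up_the_left_side(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[3:7, 3:7] = 1
        path = trace_contour(m).points
        assert tuple(path[0]) == (6, 3)
        assert tuple(path[1]) == (5, 3)  # counterclockwise as displayed

    def test_full_frame_is_border_ring(self):
        m = np.ones((6, 9), dtype=np.uint8)
        path = trace_contour(m).points
        assert len(path) == 2 * (6 + 9) - 4
        assert all(r in (0, 5) or c in (0, 8) for r, c in path)

    def test_empty_mask_rejected(self):
        with pytest.raises(PalmFuseError, match="no region"):
            trace_contour(np.zeros((5, 5), dtype=np.uint8))

    def test_synthetic_hand_path_length_matches_perimeter(self, palm_capture):
        img, gt = palm_capture
        mask = segment_palm_region(img)
        path = trace_contour(mask)
        # Euclidean path length vs the generator's Crofton perimeter of its
        # own silhouette: independent discretizations, a few percent apart
        assert path.euclidean_length == pytest.approx(gt.perimeter, rel=0.05)


class TestDistanceProfile:
    def test_three_four_five_triangle(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[-1, 0] = 1  # wrist run = single pixel at (9, 0)
        contour = ContourPath(points=np.array([[6, 4]]))
        prof = distance_profile(contour, m)
        assert prof.wrist_mid == (9.0, 0.0)
        assert prof.values[0] == pytest.approx(5.0)

    def test_semicircle_is_constant(self):
        m = np.zeros((40, 40), dtype=np.uint8)
        m[-1, 18:23] = 1  # wrist midpoint at (39, 20)
        ang = np.linspace(math.pi, 2 * math.pi, 50)
        pts = np.column_stack([39 + 15 * np.sin(ang), 20 + 15 * np.cos(ang)])
        prof = distance_profile(ContourPath(points=pts), m)
        assert np.allclose(prof.values, 15.0, atol=1e-9)

    def test_no_wrist_raises(self):
        with pytest.raises(PalmFuseError, match="wrist"):
            distance_profile(ContourPath(points=np.array([[1, 1]])),
                             np.zeros((5, 5), dtype=np.uint8))

    def test_profile_maximum_at_middle_finger_tip(self, palm_capture):
        img, gt = palm_capture
        mask = segment_palm_region(img)
        contour = trace_contour(mask)
        prof = distance_profile(contour, mask)
        peak_pt = contour.points[int(np.argmax(prof.values))]
        middle_tip = gt.tips[2]  # longest finger
        assert np.linalg.norm(peak_pt - middle_tip) < 6


class TestLocateFingerWebs:
    def test_webs_near_ground_truth_zero_jitter(self, palm_capture):
        img, gt = palm_capture
        mask = segment_palm_region(img)
        contour = trace_contour(mask)
        webs = locate_finger_webs(distance_profile(contour, mask), contour)
        assert webs.webs.shape == (4, 2) and webs.tips.shape == (5, 2)
        err = np.linalg.norm(webs.webs - gt.webs, axis=1)
        assert (err < 5).all()

    def test_rotation_does_not_change_web_count(self, identity):
        img, _ = sh.generate_palm_image(
            identity, sh.CaptureJitter(rotation_deg=10.0), seed=11)
        mask = segment_palm_region(img)
        contour = trace_contour(mask)
        webs = locate_finger_webs(distance_profile(contour, mask), contour)
        assert len(webs.webs) == 4 and len(webs.tips) == 5

    def test_circle_profile_rejected(self):
        ang = np.linspace(0, 2 * math.pi, 200, endpoint=False)
        pts = np.column_stack([50 + 30 * np.sin(ang), 50 + 30 * np.cos(ang)])
        prof = DistanceProfile(values=np.full(200, 30.0), wrist_mid=(50.0, 50.0))
        with pytest.raises(HandNotOutstretchedError):
            locate_finger_webs(prof, ContourPath(points=pts))


class TestRotationAngle:
    @pytest.mark.parametrize(
        "fw2, fw4, expected",
        [
            ((0, 0), (4, 4), 45.0),
            ((7, 0), (7, 9), 0.0),
            ((0, 0), (1, math.sqrt(3)), 30.0),
            ((0, 0), (5, 0), 90.0),
        ],
    )
    def test_known_angles(self, fw2, fw4, expected):
        assert rotation_angle(fw2, fw4) == pytest.approx(expected)

    def test_degenerate_pair_rejected(self):
        with pytest.raises(PalmFuseError, match="degenerate"):
            rotation_angle((3, 3), (3, 3))


class TestBuildRoiQuad:
    def test_worked_construction(self):
        quad = build_roi_quad((100, 64), (100, 192))
        expected = np.array([[132, 32], [132, 224], [324, 224], [324, 32]], float)
        assert np.allclose(quad.corners, expected)

    @pytest.mark.parametrize("fw2_c, fw4_c, row", [(40, 140, 60), (10, 300, 0), (64, 192, 100)])
    def test_side_and_offset_ratios_exact(self, fw2_c, fw4_c, row):
        fw2, fw4 = (row, fw2_c), (row, fw4_c)
        d = abs(fw4_c - fw2_c)
        quad = build_roi_quad(fw2, fw4)
        assert quad.side / d == pytest.approx(1.5)
        assert (quad.corners[0][0] - row) / d == pytest.approx(0.25)
        # exact square: equal sides and equal diagonals
        c = quad.corners
        assert np.linalg.norm(c[1] - c[0]) == pytest.approx(np.linalg.norm(c[2] - c[1]), abs=1e-9)
        assert np.linalg.norm(c[2] - c[0]) == pytest.approx(np.linalg.norm(c[3] - c[1]), abs=1e-9)

    def test_degenerate_pair_rejected(self):
        with pytest.raises(PalmFuseError, match="degenerate"):
            build_roi_quad((5, 5), (5, 5))


class TestExtractRoi:
    def test_output_sizes(self, palm_roi, dorsum_roi):
        assert palm_roi.shape == (256, 256)
        assert dorsum_roi.shape == (64, 64)
        assert palm_roi.dtype == np.uint8

    def test_rotation_equivariance(self, identity, noiseless_palm):
        base_roi = extract_roi(noiseless_palm[0], "palm")
        for alpha in (-15, 10):
            img, _ = sh.generate_palm_image(
                identity, sh.CaptureJitter(rotation_deg=alpha, noise_sigma=0), seed=7)
            roi = extract_roi(img, "palm")
            mad = np.mean(np.abs(roi.astype(float) - base_roi.astype(float)))
            assert mad <= 5.0

    def test_quad_out_of_frame_detected(self):
        img = np.full((40, 40), 200, dtype=np.uint8)
        quad = build_roi_quad((20, 5), (20, 35))  # side 45 > image
        with pytest.raises(RoiOutOfFrameError):
            crop_quad(img, quad, 16)

    def test_transform_points_matches_rotation_inverse(self):
        pts = np.array([[10.0, 20.0], [33.0, 7.0]])
        fwd = transform_points(pts, 12.5, (16.0, 16.0))
        back = transform_points(fwd, -12.5, (16.0, 16.0))
        assert np.allclose(back, pts, atol=1e-9)
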