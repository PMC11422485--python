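"""Contour, end-detection, midline and curvature geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from matplotlib.path import Path as MplPath

from wormspaces import posture, synth
from conftest import match_head_first


def disk_image(size=64, center=(32, 32), radius=12):
    yy, xx = np.mgrid[0:size, 0:size]
    return (((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
            <= radius ** 2).astype(float)


class TestExtractContour:
    def test_disk_contour_encloses_all_foreground(self):
        img = disk_image()
        cf = posture.extract_contour(img)
        path = MplPath(cf.points)
        fg = np.column_stack(np.nonzero(img))
        # every strictly interior foreground pixel lies inside the polygon
        inside = path.contains_points(fg, radius=1e-9)
        dist_to_edge = np.hypot(fg[:, 0] - 32, fg[:, 1] - 32)
        assert inside[dist_to_edge < 11].all()
        assert cf.n_contours_detected == 1

    def test_largest_blob_selected(self):
        img = disk_image()
        img[2:6, 2:6] = 1.0          # small second blob
        cf = posture.extract_contour(img)
        assert cf.n_contours_detected == 2
        # contour belongs to the big disk, not the corner blob
        assert cf.points[:, 0].max() > 20

    def test_background_image_fails(self):
        with pytest.raises(posture.ContourError):
            posture.extract_contour(np.zeros((32, 32)), level=0.5)

    def test_orientation_is_ccw(self):
        cf = posture.extract_contour(disk_image())
        assert posture._signed_area(cf.points) > 0


class TestSmoothContour:
    def test_zero_sigma_is_identity(self):
        pts = np.random.default_rng(0).normal(size=(20, 2))
        np.testing.assert_allclose(posture.smooth_contour(pts, 0.0), pts)

    def test_square_symmetry_preserved(self):
        # 4-fold symmetric polygon stays 4-fold symmetric
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        r = 10 + np.cos(4 * t)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
        sm = posture.smooth_contour(pts, 2.0)
        # advancing a quarter of the indices equals rotating by 90 degrees
        shifted = np.roll(sm, -10, axis=0)
        rotated = np.column_stack([-sm[:, 1], sm[:, 0]])
        np.testing.assert_allclose(shifted, rotated, atol=1e-10)

    def test_matches_bruteforce_circular_convolution(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 2))
        sigma = 2.0
        radius = int(np.ceil(4 * sigma))
        offs = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (offs / sigma) ** 2)
        w /= w.sum()
        expected = np.zeros_like(pts)
        for i in range(len(pts)):
            for o, wt in zip(offs, w):
                expected[i] += wt * pts[(i + o) % len(pts)]
        np.testing.assert_allclose(posture.smooth_contour(pts, sigma),
                                   expected, atol=1e-12)


class TestContourCurvature:
    def test_collinear_points_zero(self):
        pts = np.column_stack([np.zeros(3), [0.0, 1.0, 2.0]])
        k = posture.contour_curvature(pts)
        assert abs(k[1]) < 1e-12

    @pytest.mark.parametrize("n", [8, 16, 64])
    def test_regular_polygon_closed_form(self, n):
        R = 10.0
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([R * np.sin(t), R * np.cos(t)])  # CCW in (x=col)
        k = posture.contour_curvature(pts)
        # turning angle 2*pi/n over half the neighbor chord R*sin(2*pi/n)
        expected = (2 * np.pi / n) / (R * np.sin(2 * np.pi / n))
        np.testing.assert_allclose(k, expected, rtol=1e-10)

    def test_dense_circle_limit(self):
        r = 7.0
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        pts = np.column_stack([r * np.sin(t), r * np.cos(t)])
        k = posture.contour_curvature(pts)
        np.testing.assert_allclose(k, 1 / r, rtol=1e-4)


class TestFindEnds:
    def test_ellipse_ends_at_major_axis(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        pts = np.column_stack([4 * np.sin(t), 20 * np.cos(t)])
        k = posture.contour_curvature(pts)
        # brute-force oracle: global curvature maxima of the sampled ellipse
        ends = posture.find_ends(k, pts)
        for e in (ends.end1, ends.end2):
            assert abs(abs(e[1]) - 20) < 0.5 and abs(e[0]) < 1.0

    def test_perfect_circle_has_no_strict_maxima(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([np.sin(t), np.cos(t)])
        k = np.ones(100)                  # exactly constant curvature
        with pytest.raises(posture.ContourError):
            posture.find_ends(k, pts)

    def test_rendered_worm_ends_at_tips(self, processed_worm):
        res, truth = processed_worm
        ok = ~res.failed
        tips = np.stack([truth["midlines"][:, 0, :],
                         truth["midlines"][:, -1, :]], axis=1)
        for t in np.flatnonzero(ok)[:20]:
            d1 = min(np.hypot(*(res.end1[t] - tips[t, 0])),
                     np.hypot(*(res.end1[t] - tips[t, 1])))
            d2 = min(np.hypot(*(res.end2[t] - tips[t, 0])),
                     np.hypot(*(res.end2[t] - tips[t, 1])))
            assert d1 < 4 and d2 < 4


class TestAlignEnds:
    def _pair(self, a, b):
        return posture.EndPair(np.asarray(a, float), np.asarray(b, float),
                               0, 1)

    def test_stationary_ratio_zero(self):
        prev = self._pair([0, 0], [10, 0])
        cur = posture.align_ends(prev, self._pair([0, 0], [10, 0]))
        assert cur.distance_ratio == 0.0 and not cur.labels_swapped

    def test_exact_exchange_swaps(self):
        prev = self._pair([0, 0], [10, 0])
        cur = posture.align_ends(prev, self._pair([10, 0], [0, 0]))
        assert cur.labels_swapped and cur.distance_ratio == 0.0
        np.testing.assert_allclose(cur.end1, [0, 0])

    def test_equidistant_configuration_ratio_one(self):
        # both ends move to the midpoint: either labeling travels the same
        prev = self._pair([0, 0], [10, 0])
        cur = posture.align_ends(prev, self._pair([5, 0], [5, 0]))
        assert cur.distance_ratio == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=8, max_size=8))
    def test_ratio_always_in_unit_interval(self, coords):
        a = np.asarray(coords[:4]).reshape(2, 2)
        b = np.asarray(coords[4:]).reshape(2, 2)
        cur = posture.align_ends(self._pair(*a), self._pair(*b))
        assert 0.0 <= cur.distance_ratio <= 1.0


class TestFrameQuality:
    def test_clean_sequence_empty_mask(self):
        T = 50
        mask = posture.frame_quality(
            n_contours=np.ones(T, int),
            distance_ratio=np.full(T, 0.05),
            area=np.full(T, 300.0), length=np.full(T, 150.0))
        assert not mask.omitted.any()

    def test_ratio_above_threshold_omitted(self):
        ratio = np.full(20, 0.1)
        ratio[7] = 0.25
        mask = posture.frame_quality(np.ones(20, int), ratio,
                                     np.full(20, 300.0), np.full(20, 150.0))
        assert mask.omitted[7] and mask.reasons["distance_ratio_gt"][7]
        assert mask.omitted.sum() == 1

    def test_single_missing_ratio_not_omitted_but_run_is(self):
        ratio = np.full(20, 0.1)
        ratio[3] = np.nan
        ratio[10:12] = np.nan
        mask = posture.frame_quality(np.ones(20, int), ratio,
                                     np.full(20, 300.0), np.full(20, 150.0))
        assert not mask.omitted[3]
        assert mask.reasons["missing_ratio_run"][10:12].all()

    def test_roundness_z_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        T = 200
        area = rng.normal(300, 5, T)
        length = np.full(T, 150.0)
        area[77] = 500.0                     # curled-up frame
        mask = posture.frame_quality(np.ones(T, int), np.full(T, 0.1),
                                     area, length, z_window=30)
        roundness = area / length
        for i in [0, 50, 77, 199]:
            w = roundness[max(0, i - 30):i + 31]
            sd = w.std()
            expected = (roundness[i] - w.mean()) / sd if sd > 0 else 0.0
            assert mask.roundness_z[i] == pytest.approx(expected, rel=1e-9)
        assert mask.omitted[77] and mask.reasons["round_shape"][77]


class TestMidline:
    def test_rectangle_worm_central_axis(self):
        img = np.zeros((40, 100))
        img[16:24, 10:90] = 1.0
        cf = posture.extract_contour(img)
        # smoothing wide enough to merge each short side's two corners into
        # a single end cap, so the caps are the two dominant peaks
        sm = posture.smooth_contour(cf.points, 4.0)
        ends = posture.find_ends(posture.contour_curvature(sm), sm)
        mid = posture.compute_midline(cf.points, ends)
        assert mid.shape == (41, 2)
        # central axis: row ~ 19.5, spanning the rectangle's length
        assert np.abs(mid[5:-5, 0] - 19.5).max() < 1.0
        assert mid[:, 1].max() - mid[:, 1].min() > 70

    def test_spacing_cv_below_tolerance(self, processed_worm):
        res, _ = processed_worm
        for t in np.flatnonzero(~res.failed)[:10]:
            seg = np.hypot(*np.diff(res.midlines[t], axis=0).T)
            assert seg.std() / seg.mean() < 0.01

    def test_rendered_worm_midline_rms_below_1px(self, processed_worm):
        res, truth = processed_worm
        errs = []
        for t in np.flatnonzero(~res.failed & ~res.quality.omitted):
            m = match_head_first(res.midlines[t], truth["midlines"][t])
            errs.append(np.sqrt(((m - truth["midlines"][t]) ** 2)
                                .sum(axis=1).mean()))
        assert np.mean(errs) < 1.0 and np.median(errs) < 1.0


class TestMidlineCurvature:
    def test_straight_midline_zero(self):
        mid = np.column_stack([np.zeros(41), np.linspace(0, 40, 41)])
        np.testing.assert_allclose(posture.midline_curvature(mid), 0.0,
                                   atol=1e-12)

    def test_counts_41_39_37(self, processed_worm):
        res, _ = processed_worm
        t = int(np.flatnonzero(~res.failed)[0])
        assert res.midlines[t].shape[0] == 41
        assert len(posture.midline_turning_angles(res.midlines[t])) == 39
        assert len(posture.midline_curvature(res.midlines[t])) == 37

    def test_circular_arc_closed_form(self):
        R, L = 30.0, 2.0
        dphi = 2 * np.arcsin(L / (2 * R))
        phi = dphi * np.arange(41)
        mid = R * np.column_stack([np.cos(phi), np.sin(phi)])
        k = posture.midline_curvature(mid)
        np.testing.assert_allclose(np.abs(k), dphi, rtol=1e-10)

    def test_rendered_curvature_rms_below_tolerance(self, processed_worm):
        res, truth = processed_worm
        errs = []
        for t in np.flatnonzero(~res.failed & ~res.quality.omitted)[:20]:
            m = match_head_first(res.midlines[t], truth["midlines"][t])
            err = (posture.midline_curvature(m)
                   - posture.midline_curvature(truth["midlines"][t]))
            errs.append(np.sqrt((err ** 2).mean()))
        assert np.mean(errs) < 0.05


class TestMirrorConvention:
    def test_mirrored_image_negates_curvature(self):
        frames, _ = synth.simulate_worm_frames(n_frames=3, seed=5)
        for img in frames:
            res = posture.process_frames([img])
            res_m = posture.process_frames([np.flip(img, axis=1).copy()])
            c, cm = res.curvature[0], res_m.curvature[0]
            # mirror negates; an end-label swap additionally reverses+negates
            assert (np.allclose(cm, -c, atol=1e-3)
                    or np.allclose(cm, c[::-1], atol=1e-3))


class TestInjectedCurlFrames:
    def test_curl_frames_are_omitted(self):
        frames, truth = synth.simulate_worm_frames(
            n_frames=80, seed=13, curl_frames=(30, 31))
        res = posture.process_frames(frames)
        assert res.quality.omitted[[30, 31]].all()
        assert res.quality.reasons["round_shape"][[30, 31]].any()
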