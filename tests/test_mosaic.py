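"""Pairwise registration, mosaic compositing and score-distance profiles."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from biopsyguide.exceptions import InputError
from biopsyguide.fusion import StreamAssociation
from biopsyguide.geometry import CalibrationModel
from biopsyguide.mosaic import build_mosaic, register_pair, score_profile
from biopsyguide.scoring import FrameScore, MicroFrame, fov_mask
from biopsyguide.tracking import ProbeTrack, TrackEntry


def texture_scene(h, w, seed=0, sigma=1.0):
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.uniform(0, 255, (h, w)), sigma)
    return 40.0 + (img - img.min()) / np.ptp(img) * 160.0


def crop_frame(scene, x0, y0, w=160, h=120, index=0):
    return MicroFrame(
        pixels=scene[y0 : y0 + h, x0 : x0 + w],
        frame_index=index,
        fov_center=(w / 2, h / 2),
        fov_radius=0.45 * h,
    )


class TestRegisterPair:
    def test_self_registration_zero_shift_high_peak(self):
        scene = texture_scene(200, 240)
        a = crop_frame(scene, 20, 20)
        dx, dy, peak = register_pair(a, a)
        assert dx == pytest.approx(0.0, abs=1e-6)
        assert dy == pytest.approx(0.0, abs=1e-6)
        assert peak > 0.9

    def test_circular_shift_recovered(self):
        scene = texture_scene(200, 240)
        a = crop_frame(scene, 20, 20)
        shifted = np.roll(a.pixels, (-3, 7), axis=(0, 1))  # content +7 x, -3 y
        b = MicroFrame(pixels=shifted, fov_center=a.fov_center, fov_radius=a.fov_radius)
        dx, dy, _ = register_pair(a, b)
        assert dx == pytest.approx(7.0, abs=0.5)
        assert dy == pytest.approx(-3.0, abs=0.5)

    def test_matches_independent_phase_correlation(self):
        from skimage.registration import phase_cross_correlation

        scene = texture_scene(260, 300, seed=3)
        a = crop_frame(scene, 40, 40)
        b = crop_frame(scene, 47, 43, index=1)  # camera moved (+7, +3)
        dx, dy, _ = register_pair(a, b)
        fov = fov_mask(a)

        def fill(frame):  # same boundary suppression; registration is skimage's
            img = frame.pixels.astype(float)
            img[~fov] = img[fov].mean()
            return img

        ref_shift = phase_cross_correlation(fill(a), fill(b), normalization="phase")[0]
        # skimage returns (row, col) shift registering b onto a
        assert dx == pytest.approx(-ref_shift[1], abs=0.5)
        assert dy == pytest.approx(-ref_shift[0], abs=0.5)

    def test_unrelated_frames_low_peak(self):
        rng = np.random.default_rng(0)
        a = MicroFrame(pixels=rng.uniform(0, 255, (120, 160)),
                       fov_center=(80, 60), fov_radius=54)
        b = MicroFrame(pixels=rng.uniform(0, 255, (120, 160)),
                       fov_center=(80, 60), fov_radius=54)
        _, _, peak = register_pair(a, b)
        assert peak < 0.2

    def test_antisymmetric_within_one_px(self):
        scene = texture_scene(260, 300, seed=5)
        a = crop_frame(scene, 40, 40)
        b = crop_frame(scene, 52, 45, index=1)
        fwd = register_pair(a, b)
        bwd = register_pair(b, a)
        assert fwd[0] == pytest.approx(-bwd[0], abs=1.0)
        assert fwd[1] == pytest.approx(-bwd[1], abs=1.0)


class TestBuildMosaic:
    def test_single_frame_reproduces_frame_inside_fov(self):
        scene = texture_scene(200, 240, seed=1)
        a = crop_frame(scene, 20, 20)
        canvas = build_mosaic([a])
        fov = fov_mask(a)
        np.testing.assert_allclose(canvas.image[fov], a.pixels[fov].astype(float),
                                   rtol=1e-6)
        assert not canvas.weight[~fov].any()

    def test_known_shifts_give_expected_extent(self):
        """Ten frames stepped +20 px in x span frame width + 180 px."""
        scene = texture_scene(260, 420, seed=2)
        frames = [crop_frame(scene, 20 + 20 * i, 60, index=i) for i in range(10)]
        canvas = build_mosaic(frames)
        assert canvas.image.shape[1] == pytest.approx(160 + 180, abs=2)
        assert all(p.chained_valid for p in canvas.placements)

    def test_overlap_is_feathered_weighted_average(self):
        scene = texture_scene(260, 420, seed=4)
        a = crop_frame(scene, 30, 60, index=0)
        b = crop_frame(scene, 50, 60, index=1)
        canvas = build_mosaic([a, b])
        from scipy.ndimage import distance_transform_edt

        feather = distance_transform_edt(fov_mask(a))
        # reconstruct expected canvas with the known integer offsets
        (ox_a, oy_a) = canvas.placements[0].offset
        (ox_b, oy_b) = canvas.placements[1].offset
        exp_sum = np.zeros_like(canvas.image)
        exp_w = np.zeros_like(canvas.weight)
        for frame, (ox, oy) in ((a, (ox_a, oy_a)), (b, (ox_b, oy_b))):
            x0, y0 = int(round(ox)), int(round(oy))
            exp_sum[y0 : y0 + 120, x0 : x0 + 160] += frame.pixels * feather
            exp_w[y0 : y0 + 120, x0 : x0 + 160] += feather
        rng = np.random.default_rng(0)
        ys, xs = np.nonzero(exp_w > 0)
        pick = rng.choice(len(ys), 20, replace=False)
        for y, x in zip(ys[pick], xs[pick]):
            assert canvas.image[y, x] == pytest.approx(exp_sum[y, x] / exp_w[y, x],
                                                       rel=1e-6)

    def test_low_peak_breaks_chain_but_keeps_frames(self):
        scene = texture_scene(260, 420, seed=6)
        rng = np.random.default_rng(1)
        frames = [crop_frame(scene, 30, 60, index=0),
                  crop_frame(scene, 50, 60, index=1)]
        noise = MicroFrame(pixels=rng.uniform(0, 255, (120, 160)), frame_index=2,
                           fov_center=(80, 60), fov_radius=54)
        canvas = build_mosaic(frames + [noise], min_peak=0.3)
        assert canvas.placements[1].chained_valid
        assert not canvas.placements[2].chained_valid
        assert canvas.placements[2].offset == canvas.placements[1].offset

    def test_physical_width_is_extent_times_pitch(self):
        scene = texture_scene(200, 240, seed=7)
        canvas = build_mosaic([crop_frame(scene, 20, 20)], um_per_px=1.1)
        assert canvas.physical_width_um == canvas.image.shape[1] * 1.1

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            build_mosaic([])


def track_line(n, step_px, y=50.0):
    return ProbeTrack(entries=[
        TrackEntry(frame_index=i, timestamp=i * 0.1, x=10.0 + step_px * i, y=y,
                   blob_area=5.0, valid=True)
        for i in range(n)
    ])


def cal_1mm_per_px():
    return CalibrationModel(mm_per_px_x=1.0, mm_per_px_y=1.0)


class TestScoreProfile:
    def test_static_probe_single_bin_at_zero(self):
        track = ProbeTrack(entries=[
            TrackEntry(frame_index=i, timestamp=i * 0.1, x=30.0, y=30.0,
                       blob_area=5.0, valid=True)
            for i in range(5)
        ])
        assoc = StreamAssociation(pairs={i: i % 5 for i in range(10)}, tolerance=0.1)
        scores = [FrameScore(0.7, i, "t") for i in range(10)]
        profile = score_profile(track, scores, assoc, cal_1mm_per_px())
        assert len(profile.bins) == 1
        arc, mean, n = profile.bins[0]
        assert arc == 0.0 and mean == pytest.approx(0.7) and n == 10

    def test_uniform_scores_along_12mm_line(self):
        track = track_line(13, step_px=1.0)  # 12 mm total at 1 mm/px
        assoc = StreamAssociation(pairs={i: i for i in range(13)}, tolerance=0.1)
        scores = [FrameScore(0.5, i, "t") for i in range(13)]
        profile = score_profile(track, scores, assoc, cal_1mm_per_px(), bin_width_mm=1.0)
        assert 12 <= len(profile.bins) <= 13
        assert all(m == pytest.approx(0.5) for _, m, _ in profile.bins)

    def test_regime_switch_recovered_within_one_bin(self):
        n = 40
        track = track_line(n, step_px=0.5)  # 0.5 mm per widefield frame
        assoc = StreamAssociation(pairs={i: i for i in range(n)}, tolerance=0.1)
        scores = [FrameScore(0.1 if i < 20 else 0.9, i, "t") for i in range(n)]
        profile = score_profile(track, scores, assoc, cal_1mm_per_px(), bin_width_mm=1.0)
        means = [m for _, m, _ in profile.bins]
        arcs = [a for a, _, _ in profile.bins]
        switch_arc = 20 * 0.5  # 10 mm along the path
        rise = next(a for a, m in zip(arcs, means) if m > 0.5)
        assert abs(rise - switch_arc) <= 1.0
        assert means[0] == pytest.approx(0.1) and means[-1] == pytest.approx(0.9)

    def test_frame_totals_conserved(self):
        track = track_line(10, step_px=2.0)
        assoc = StreamAssociation(pairs={i: i // 3 for i in range(30)}, tolerance=0.1)
        scores = [FrameScore(0.4, i, "t") for i in range(30)]
        profile = score_profile(track, scores, assoc, cal_1mm_per_px())
        assert sum(n for _, _, n in profile.bins) == 30
        assert all(0 <= m <= 1 for _, m, _ in profile.bins)

    def test_two_valid_entries_required(self):
        track = ProbeTrack(entries=[TrackEntry(0, 0.0, 1.0, 1.0, 5.0, True)])
        with pytest.raises(InputError):
            score_profile(track, [], StreamAssociation({}, 0.1), cal_1mm_per_px())
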