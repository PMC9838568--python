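"""Stream association, score accumulation and the dual-threshold guidance map."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biopsyguide.exceptions import InputError
from biopsyguide.fusion import (
    GuidanceThresholds,
    ScoreField,
    StreamAssociation,
    accumulate_scores,
    associate_frames,
    compute_guidance_map,
    disc_offsets,
    project_guidance,
    update_thresholds,
)
from biopsyguide.geometry import PlanarHomography
from biopsyguide.riskmap import MucosaMask, RiskMap
from biopsyguide.scoring import FrameScore
from biopsyguide.tracking import ProbeTrack, TrackEntry


def fs(i, score):
    return FrameScore(score=score, frame_index=i, scorer_id="test")


def track_at(positions):
    return ProbeTrack(entries=[
        TrackEntry(frame_index=i, timestamp=i * 0.05, x=float(x), y=float(y),
                   blob_area=10.0, valid=v)
        for i, (x, y, v) in enumerate(positions)
    ])


def toy_risk(h=20, w=20, seed=0, mask_p=0.8):
    rng = np.random.default_rng(seed)
    mask = rng.uniform(size=(h, w)) < mask_p
    rg = np.where(mask, rng.uniform(0, 3, (h, w)), np.nan)
    return RiskMap(rg=rg, mask=MucosaMask(mask), normalization_constant=1.0)


class TestAssociate:
    def test_identical_lists_identity_pairing(self):
        ts = [0.0, 0.1, 0.2, 0.3]
        assoc = associate_frames(ts, ts, 0.01)
        assert assoc.pairs == {i: i for i in range(4)}

    def test_dual_rate_matches_brute_force(self):
        """90 fps micro against 20 fps widefield over 1 s."""
        micro = np.arange(90) / 90.0
        wide = np.arange(20) / 20.0
        assoc = associate_frames(micro, wide, tolerance=0.05)
        # independent oracle: nearest neighbor with earlier-frame tie-break
        expected = {}
        for mi, t in enumerate(micro):
            deltas = np.abs(wide - t)
            wi = int(np.flatnonzero(deltas == deltas.min())[0])
            if deltas[wi] <= 0.05:
                expected[mi] = wi
        assert assoc.pairs == expected
        assert len(assoc.pairs) == 90
        counts = np.bincount(list(assoc.pairs.values()), minlength=20)
        # interior widefield frames receive 4-5 micro frames; the first and
        # last absorb the grid edges
        assert set(counts[1:-1].tolist()) <= {4, 5}

    def test_out_of_tolerance_dropped(self):
        assoc = associate_frames([0.0, 10.0], [0.0], tolerance=0.1)
        assert assoc.pairs == {0: 0}

    def test_tie_breaks_toward_earlier_frame(self):
        assoc = associate_frames([0.5], [0.0, 1.0], tolerance=1.0)
        assert assoc.pairs == {0: 0}

    def test_empty_inputs_rejected(self):
        with pytest.raises(InputError):
            associate_frames([], [0.0], 0.1)

    def test_unsorted_inputs_rejected(self):
        with pytest.raises(InputError):
            associate_frames([0.2, 0.1], [0.0], 0.1)


class TestAccumulate:
    def test_single_score_radius_zero(self):
        track = track_at([(5, 7, True)])
        assoc = StreamAssociation(pairs={0: 0}, tolerance=0.1)
        field = accumulate_scores(track, [fs(0, 0.8)], assoc, 0, (10, 12))
        assert field.count[7, 5] == 1
        assert field.mean()[7, 5] == pytest.approx(0.8)
        assert field.count.sum() == 1

    def test_two_scores_same_pixel_average(self):
        track = track_at([(5, 7, True)])
        assoc = StreamAssociation(pairs={0: 0, 1: 0}, tolerance=0.1)
        field = accumulate_scores(track, [fs(0, 0.2), fs(1, 0.6)], assoc, 0, (10, 12))
        assert field.mean()[7, 5] == pytest.approx(0.4)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(7)
        n_wide, n_micro = 6, 25
        positions = [(rng.uniform(5, 25), rng.uniform(5, 15), rng.uniform() < 0.8)
                     for _ in range(n_wide)]
        track = track_at(positions)
        pairs = {i: int(rng.integers(0, n_wide)) for i in range(n_micro)}
        assoc = StreamAssociation(pairs=pairs, tolerance=0.1)
        scores = [fs(i, float(rng.uniform())) for i in range(n_micro)]
        radius = 2
        field = accumulate_scores(track, scores, assoc, radius, (20, 30))

        exp_sum = np.zeros((20, 30))
        exp_cnt = np.zeros((20, 30), int)
        valid = {e.frame_index: e for e in track.entries if e.valid}
        for s in scores:
            wi = pairs[s.frame_index]
            if wi not in valid:
                continue
            cx, cy = round(valid[wi].x), round(valid[wi].y)
            for y in range(20):
                for x in range(30):
                    if (x - cx) ** 2 + (y - cy) ** 2 <= radius**2:
                        exp_sum[y, x] += s.score
                        exp_cnt[y, x] += 1
        np.testing.assert_allclose(field.sum, exp_sum, atol=1e-12)
        np.testing.assert_array_equal(field.count, exp_cnt)

    def test_count_conservation_interior_footprints(self):
        """Total count = scored-tracked-associated frames x footprint size."""
        radius = 3
        footprint = len(disc_offsets(radius))
        track = track_at([(20, 20, True), (25, 22, True), (30, 24, False)])
        pairs = {0: 0, 1: 0, 2: 1, 3: 2, 4: 99}  # 2 -> valid, 3 -> invalid, 4 -> missing
        assoc = StreamAssociation(pairs=pairs, tolerance=0.1)
        scores = [fs(i, 0.5) for i in range(5)]
        field = accumulate_scores(track, scores, assoc, radius, (50, 60))
        assert field.count.sum() == 3 * footprint

    def test_mean_nan_where_unvisited(self):
        field = ScoreField.zeros((4, 4))
        assert np.all(np.isnan(field.mean()))


class TestGuidance:
    def _field(self, h, w, seed=1):
        rng = np.random.default_rng(seed)
        count = (rng.uniform(size=(h, w)) < 0.6).astype(int) * rng.integers(1, 4, (h, w))
        mean = rng.uniform(0, 1, (h, w))
        return ScoreField(sum=mean * count, count=count)

    def test_zero_thresholds_recover_visited_mucosa(self):
        risk = toy_risk()
        field = self._field(20, 20)
        g = compute_guidance_map(risk, field, GuidanceThresholds(0.0, 0.0))
        np.testing.assert_array_equal(g.mask, risk.mask.mask & (field.count > 0))

    def test_unreachable_score_threshold_empty(self):
        risk = toy_risk()
        field = self._field(20, 20)
        g = compute_guidance_map(risk, field, GuidanceThresholds(0.0, 1.0))
        mean = field.mean()
        assert g.mask.sum() == (risk.mask.mask & (field.count > 0)
                                & (np.nan_to_num(mean) >= 1.0)).sum()

    def test_matches_per_pixel_conjunction(self):
        risk = toy_risk(seed=5)
        field = self._field(20, 20, seed=6)
        th = GuidanceThresholds(1.2, 0.4)
        g = compute_guidance_map(risk, field, th)
        mean = field.mean()
        for y in range(20):
            for x in range(20):
                expected = (
                    risk.mask.mask[y, x]
                    and field.count[y, x] > 0
                    and risk.rg[y, x] >= th.tau_rg
                    and mean[y, x] >= th.tau_mtn
                )
                assert g.mask[y, x] == expected

    def test_dim_mismatch_rejected(self):
        with pytest.raises(InputError):
            compute_guidance_map(toy_risk(10, 10), self._field(20, 20),
                                 GuidanceThresholds(0, 0))

    @settings(derandomize=True, max_examples=30)
    @given(tr1=st.floats(0, 3), tm1=st.floats(0, 1), dtr=st.floats(0, 1), dtm=st.floats(0, 0.5))
    def test_antitone_in_both_thresholds(self, tr1, tm1, dtr, dtm):
        risk = toy_risk(seed=9)
        field = self._field(20, 20, seed=10)
        g1 = compute_guidance_map(risk, field, GuidanceThresholds(tr1, tm1))
        g2 = compute_guidance_map(
            risk, field, GuidanceThresholds(tr1 + dtr, min(1.0, tm1 + dtm))
        )
        assert not (g2.mask & ~g1.mask).any()

    @settings(derandomize=True, max_examples=30)
    @given(tr=st.floats(0, 3), tm=st.floats(0, 1))
    def test_update_equals_recompute(self, tr, tm):
        risk = toy_risk(seed=11)
        field = self._field(20, 20, seed=12)
        th = GuidanceThresholds(tr, tm)
        np.testing.assert_array_equal(
            update_thresholds(risk, field, th).mask,
            compute_guidance_map(risk, field, th).mask,
        )

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(InputError):
            GuidanceThresholds(-0.1, 0.5)
        with pytest.raises(InputError):
            GuidanceThresholds(0.5, 1.5)


class TestProject:
    def _guidance(self, h=60, w=80, seed=2):
        rng = np.random.default_rng(seed)
        mask = np.zeros((h, w), bool)
        ys, xs = np.ogrid[:h, :w]
        mask[(xs - 40) ** 2 + (ys - 30) ** 2 <= 160] = True  # ~500 px blob
        from biopsyguide.fusion import GuidanceMap

        return GuidanceMap(mask=mask, thresholds=GuidanceThresholds(0, 0))

    def test_identity_unchanged(self):
        g = self._guidance()
        out = project_guidance(g, PlanarHomography.identity(), (80, 60))
        np.testing.assert_array_equal(out, g.mask)

    def test_translation_shifts_mask(self):
        g = self._guidance()
        out = project_guidance(g, PlanarHomography.translation(5.0, 0.0), (80, 60))
        np.testing.assert_array_equal(out[:, 5:], g.mask[:, :-5])

    def test_round_trip_agreement_on_blob(self):
        """Camera -> projector -> camera keeps >= 98% of blob pixels."""
        th = np.deg2rad(1.5)
        m = np.array([[np.cos(th), -np.sin(th), 4.0],
                      [np.sin(th), np.cos(th), -2.0],
                      [1e-5, 0.0, 1.0]])
        h = PlanarHomography(m)
        g = self._guidance()
        fwd = project_guidance(g, h, (80, 60))
        from biopsyguide.geometry import warp_binary_mask

        back = warp_binary_mask(h.inverse(), fwd, 80, 60)
        agree = (back & g.mask).sum() / g.mask.sum()
        assert agree >= 0.98
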