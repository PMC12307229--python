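"""Segmentation, tracking and shape/intensity descriptors."""

import numpy as np
import pytest

from pushscope.morphometry import (
    CellFrame,
    CellTrack,
    cell_speed,
    classify_orientation,
    default_lamellipodium_mask,
    integrated_intensity,
    lamellipodium_fraction,
    link_tracks,
    normalized_central_intensity,
    pool_retraction_events,
    protrusion_regions,
    segment_cell,
    velocity_axis,
)
from pushscope.synth import MigrationSceneParams, NoiseModel, generate_migration_movie


@pytest.fixture(scope="module")
def migration_scene():
    params = MigrationSceneParams(image_shape=(40, 96, 160), seed=9)
    stack, truth = generate_migration_movie(params, -0.8, 0)
    return params, stack, truth


def _disk(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _jaccard(a, b):
    return (a & b).sum() / max((a | b).sum(), 1)


class TestSegmentCell:
    def test_generator_cell_recovered(self, migration_scene):
        params, stack, truth = migration_scene
        actin = stack.channel_2d("actin")
        nucleus = stack.channel_2d("nucleus")
        for t in (0, 20, 39):
            cell_m, pool_m, nuc_m = segment_cell(actin[t], nucleus[t])
            assert _jaccard(cell_m, truth.cell_masks[t]) >= 0.8
            assert _jaccard(nuc_m, truth.nucleus_masks[t]) >= 0.5
            # the pool is the brightest interior structure
            assert pool_m.any()
            assert (pool_m & truth.pool_masks[t]).sum() / pool_m.sum() >= 0.5

    def test_blank_frame_empty_masks(self):
        cell_m, pool_m, nuc_m = segment_cell(np.zeros((64, 64)), np.zeros((64, 64)))
        assert not cell_m.any() and not pool_m.any() and not nuc_m.any()

    def test_external_masks_passthrough(self):
        ext = _disk((32, 32), 16, 16, 5)
        cell_m, pool_m, nuc_m = segment_cell(
            np.zeros((32, 32)), external_masks=(ext, None, ext)
        )
        assert np.array_equal(cell_m, ext)
        assert not pool_m.any()
        assert np.array_equal(nuc_m, ext)


class TestLinkTracks:
    def _label_movie(self, n_frames, step=3, r=6, start=(20, 15)):
        frames = []
        for t in range(n_frames):
            lab = np.zeros((64, 128), dtype=np.int32)
            lab[_disk((64, 128), start[0], start[1] + step * t, r)] = 1
            frames.append(lab)
        return frames

    def test_single_cell_tracked_full_length(self):
        tracks = link_tracks(self._label_movie(20))
        assert len(tracks) == 1
        assert len(tracks[0]) == 20

    @pytest.mark.parametrize("length,expected", [(10, 0), (11, 1), (12, 1)])
    def test_track_length_filter_is_strict(self, length, expected):
        tracks = link_tracks(self._label_movie(length))
        assert len(tracks) == expected

    def test_merging_cells_terminate_both_tracks(self):
        frames = []
        for t in range(20):
            lab = np.zeros((64, 128), dtype=np.int32)
            lab[_disk((64, 128), 32, 20 + 2 * t, 6)] = 1
            lab[_disk((64, 128), 32, 100 - 2 * t, 6)] = 2
            frames.append(lab)
        # blobs touch around frame 17 ((100-20-12)/4); both tracks must end there
        tracks = link_tracks(frames, min_track_length=10)
        assert len(tracks) == 2
        ends = sorted(tr.frames[-1].time_index for tr in tracks)
        assert ends[0] == ends[1] < 19
        merged_at = ends[0] + 1
        lab = frames[merged_at]
        assert (lab > 0).any()

    def test_gate_refuses_teleporting_cell(self):
        frames = self._label_movie(24, step=0)
        # teleport the blob far away at frame 12: link must break
        for t in range(12, 24):
            lab = np.zeros((64, 128), dtype=np.int32)
            lab[_disk((64, 128), 40, 100, 6)] = 1
            frames[t] = lab
        tracks = link_tracks(frames, max_step_px=20.0, min_track_length=10)
        assert len(tracks) == 2  # two separate 12-frame tracks


class TestSpeed:
    def _track(self, centroids, dt=30.0, px=0.5):
        frames = [
            CellFrame(time_index=i, cell_mask=np.ones((4, 4), bool),
                      centroid_px=c, area_px=16)
            for i, c in enumerate(centroids)
        ]
        return CellTrack(frames=frames, frame_interval_s=dt, pixel_size_um=px)

    def test_stationary_zero(self):
        _, mean = cell_speed(self._track([(5.0, 5.0)] * 6))
        assert mean == 0.0

    def test_known_arithmetic(self):
        """2 px/frame at 0.5 um/px and 30 s/frame is 2 um/min."""
        track = self._track([(10.0, 10.0 + 2 * i) for i in range(5)])
        speeds, mean = cell_speed(track)
        assert np.allclose(speeds, 2.0)
        assert mean == pytest.approx(2.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(10, 50, (8, 2))
        _, a = cell_speed(self._track([tuple(p) for p in pts]))
        _, b = cell_speed(self._track([tuple(p + 7.3) for p in pts]))
        assert a == pytest.approx(b)

    def test_single_frame_raises(self):
        with pytest.raises(ValueError):
            cell_speed(self._track([(5.0, 5.0)]))

    def test_generator_speed_recovered(self, migration_scene):
        params, stack, truth = migration_scene
        actin = stack.channel_2d("actin")
        labels = []
        for t in range(actin.shape[0]):
            cell_m, _, _ = segment_cell(actin[t])
            labels.append(cell_m.astype(np.int32))
        tracks = link_tracks(
            labels, frame_interval_s=params.frame_interval_s,
            pixel_size_um=params.pixel_size_um,
        )
        assert len(tracks) == 1
        _, mean = cell_speed(tracks[0])
        expected = params.cell_speed_um_per_s * 60.0
        assert mean == pytest.approx(expected, rel=0.05)


class TestProtrusion:
    def test_identical_masks_zero_areas(self):
        m = _disk((32, 32), 16, 16, 6)
        d = protrusion_regions(m, m)
        assert d.gained_area_um2 == 0 and d.lost_area_um2 == 0

    def test_translated_square_brute_force(self):
        m0 = np.zeros((32, 32), bool)
        m0[10:20, 10:20] = True
        m1 = np.roll(m0, 3, axis=1)
        d = protrusion_regions(m0, m1, pixel_size_um=1.0)
        assert d.gained_area_um2 == 30.0 and d.lost_area_um2 == 30.0
        # brute-force set differences as the oracle
        gained = {(y, x) for y, x in zip(*np.nonzero(m1 & ~m0))}
        assert gained == {(y, x) for y, x in zip(*np.nonzero(d.gained_mask))}

    def test_empty_previous_mask(self):
        m1 = _disk((32, 32), 16, 16, 5)
        d = protrusion_regions(np.zeros((32, 32), bool), m1)
        assert d.gained_area_um2 == m1.sum()
        assert d.lost_area_um2 == 0

    def test_area_conservation_on_random_masks(self):
        """area(t+1) - area(t) == gained - lost, exactly, for any mask pair."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.random((24, 24)) > 0.6
            b = rng.random((24, 24)) > 0.6
            d = protrusion_regions(a, b)
            assert (int(b.sum()) - int(a.sum())
                    == int(d.gained_mask.sum()) - int(d.lost_mask.sum()))
            assert not (d.gained_mask & d.lost_mask).any()
            assert not (d.gained_mask & a).any()
            assert not (d.lost_mask & b).any()


class TestIntensity:
    def test_uniform_background_zero(self):
        frame = np.full((32, 32), 5.0)
        mask = _disk((32, 32), 16, 16, 5)
        assert integrated_intensity(frame, mask, background_estimate=5.0) == 0.0

    def test_known_arithmetic(self):
        frame = np.full((32, 32), 8.0)
        mask = np.zeros((32, 32), bool)
        mask[:10, :10] = True
        assert integrated_intensity(frame, mask, background_estimate=3.0) == 500.0

    def test_offset_invariance_with_estimated_background(self):
        rng = np.random.default_rng(2)
        frame = rng.uniform(10, 20, (48, 48))
        mask = _disk((48, 48), 24, 24, 6)
        frame[mask] += 50
        a = integrated_intensity(frame, mask)
        b = integrated_intensity(frame + 13.0, mask)
        assert a == pytest.approx(b, rel=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            integrated_intensity(np.ones((8, 8)), np.zeros((8, 8), bool))

    def test_negative_total_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            v = integrated_intensity(np.full((8, 8), 1.0),
                                     np.ones((8, 8), bool),
                                     background_estimate=5.0)
        assert v == 0.0


class TestRatios:
    def _uniform_track(self, pool_level, cell_level, n=4):
        frames = []
        imgs = []
        cell = _disk((48, 48), 24, 24, 12)
        pool = _disk((48, 48), 24, 24, 4)
        for t in range(n):
            img = np.zeros((48, 48))
            img[cell] = cell_level
            img[pool] = pool_level
            frames.append(CellFrame(time_index=t, cell_mask=cell,
                                    centroid_px=(24.0, 24.0),
                                    area_px=int(cell.sum()),
                                    central_pool_mask=pool))
            imgs.append(img)
        return CellTrack(frames=frames), imgs

    def test_pool_equal_to_cell_mean_gives_one(self):
        track, imgs = self._uniform_track(10.0, 10.0)
        ratio, mean = normalized_central_intensity(track, imgs,
                                                   background_estimate=0.0)
        assert np.allclose(ratio, 1.0)
        assert mean == pytest.approx(1.0)

    def test_gain_invariance(self):
        track, imgs = self._uniform_track(30.0, 10.0)
        _, m1 = normalized_central_intensity(track, imgs, background_estimate=0.0)
        _, m2 = normalized_central_intensity(track, [2 * i for i in imgs],
                                             background_estimate=0.0)
        assert m1 == pytest.approx(m2)

    def test_lamellipodium_two_compartment_closed_form(self):
        """Band at 2x body density over 10% of the area: ratio 2/1.1."""
        cell = np.zeros((40, 100), bool)
        cell[:10, :100] = True  # 1000 px
        lam = np.zeros_like(cell)
        lam[:10, 90:100] = True  # 10% of the cell
        frame = np.zeros((40, 100))
        frame[cell] = 1.0
        frame[lam] = 2.0
        ratio = lamellipodium_fraction(frame, lam, cell, background_estimate=0.0)
        assert ratio == pytest.approx(2.0 / 1.1, rel=1e-9)

    def test_uniform_cell_ratio_one(self):
        cell = _disk((32, 32), 16, 16, 10)
        lam = _disk((32, 32), 16, 10, 3) & cell
        frame = np.where(cell, 7.0, 0.0)
        assert lamellipodium_fraction(frame, lam, cell, background_estimate=0.0) \
            == pytest.approx(1.0)

    def test_lamellipodium_outside_cell_rejected(self):
        cell = _disk((32, 32), 16, 16, 6)
        lam = _disk((32, 32), 2, 2, 2)
        with pytest.raises(ValueError, match="inside"):
            lamellipodium_fraction(np.ones((32, 32)), lam, cell)

    def test_default_lamellipodium_mask_in_cell(self):
        m0 = _disk((32, 32), 16, 14, 8)
        m1 = _disk((32, 32), 16, 18, 8)
        lam = default_lamellipodium_mask(m0, m1)
        assert lam.any()
        assert not (lam & ~m1).any()


class TestOrientation:
    def test_mtoc_ahead_positive_projection(self):
        call = classify_orientation((10.0, 15.0), (10.0, 10.0), (0.0, 1.0),
                                    pixel_size_um=0.5)
        assert call.value == "mtoc_first"
        assert call.projection_um == pytest.approx(2.5)

    def test_coincident_is_tie(self):
        call = classify_orientation((10.0, 10.0), (10.0, 10.0), (0.0, 1.0))
        assert call.tie and call.value == "nucleus_first"

    def test_axis_reversal_flips_call(self):
        a = classify_orientation((10.0, 15.0), (10.0, 10.0), (0.0, 1.0))
        b = classify_orientation((10.0, 15.0), (10.0, 10.0), (0.0, -1.0))
        assert a.value == "mtoc_first" and b.value == "nucleus_first"
        assert a.projection_um == pytest.approx(-b.projection_um)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            classify_orientation((1.0, 1.0), (0.0, 0.0), (0.0, 0.0))

    def test_velocity_axis_points_along_motion(self):
        frames = [CellFrame(time_index=i, cell_mask=np.ones((2, 2), bool),
                            centroid_px=(5.0, 10.0 + 3 * i), area_px=4)
                  for i in range(6)]
        axis = velocity_axis(CellTrack(frames=frames), frame_index=3)
        assert axis == pytest.approx([0.0, 1.0])


class TestRetractionPooling:
    def test_constant_events_pool_to_one(self):
        events = [(np.ones(10), 3), (np.ones(8), 2)]
        out = pool_retraction_events(events)
        lag0 = np.nonzero(out["lags"] == 0)[0][0]
        covered = out["n_events"] >= 2
        assert np.allclose(out["mean"][covered], 1.0)
        assert np.allclose(out["sem"][covered], 0.0)
        assert out["mean"][lag0] == pytest.approx(1.0)

    def test_two_event_mean(self):
        e1 = np.array([1.0, 1.2])
        e2 = np.array([2.0, 2.8])  # normalizes to 1.0, 1.4
        out = pool_retraction_events([(e1, 0), (e2, 0)])
        lag1 = np.nonzero(out["lags"] == 1)[0][0]
        assert out["mean"][lag1] == pytest.approx(1.3)

    def test_onset_normalization(self):
        rng = np.random.default_rng(3)
        events = [(rng.uniform(1, 5, 12), 4) for _ in range(5)]
        out = pool_retraction_events(events)
        lag0 = np.nonzero(out["lags"] == 0)[0][0]
        assert out["mean"][lag0] == pytest.approx(1.0)

    def test_zero_onset_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            out = pool_retraction_events([(np.array([0.0, 1.0]), 0),
                                          (np.ones(4), 1)])
        assert out["n_events"].max() == 1
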