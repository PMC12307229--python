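"""Bead detection and Z-edge tracking against constructed and generated truth."""

import numpy as np
import pytest

from pushscope.beads import (
    BeadRecord,
    Kymograph,
    detect_beads,
    extract_kymograph,
    max_displacement,
    track_edge,
)
from pushscope.synth import BeadSceneParams, NoiseModel, generate_bead_stack
from conftest import match_bead


def _single_bead_stack(t_n=6, z_n=20, yx=48, z_center=8.0, peak=100.0):
    """One static Gaussian bead in the middle of a quiet stack."""
    zz, yy, xx = np.mgrid[0:z_n, 0:yx, 0:yx]
    spot = peak * np.exp(
        -((zz - z_center) ** 2 / (2 * 3.0**2)
          + (yy - yx / 2) ** 2 / (2 * 1.2**2)
          + (xx - yx / 2) ** 2 / (2 * 1.2**2))
    )
    return np.broadcast_to(spot, (t_n, z_n, yx, yx)).astype(np.float32).copy()


class TestDetectBeads:
    def test_single_static_bead_found_at_centroid(self):
        stack = _single_bead_stack()
        recs = detect_beads(stack)
        accepted = [r for r in recs if r.accepted]
        assert len(accepted) == 1
        cy, cx = accepted[0].xy_centroid_px
        assert abs(cy - 24) <= 0.5 and abs(cx - 24) <= 0.5

    def test_fused_pair_rejected_as_aggregate(self):
        stack = _single_bead_stack()
        shifted = np.roll(stack, 3, axis=3)  # 3 px apart: one merged component
        recs = detect_beads(stack + shifted, max_area_px=20)
        assert len(recs) == 1
        assert recs[0].rejection_reason == "aggregate"

    def test_drifting_bead_rejected_as_nonstationary(self):
        p = BeadSceneParams(
            image_shape=(16, 28, 64, 96), n_beads=1, seed=3,
            bead_drift_px_per_frame=0.5,  # 7.5 px total drift
            noise_model=NoiseModel(gaussian_sd=5.0),
        )
        stack, _ = generate_bead_stack(p)
        # widen the area gate so the streak-shaped component reaches the
        # stationarity check rather than the aggregate filter
        recs = detect_beads(stack.channel("bead"), stationarity_max_shift_px=2.0,
                            max_area_px=300)
        assert recs, "drifting beads should still be segmented"
        assert all(r.rejection_reason == "nonstationary" for r in recs)

    def test_all_zero_channel_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="all zero"):
            recs = detect_beads(np.zeros((3, 5, 32, 32)))
        assert recs == []

    def test_scene_beads_all_recovered(self, bead_scene):
        params, stack, truth = bead_scene
        recs = detect_beads(stack.channel("bead"))
        accepted = [r for r in recs if r.accepted]
        assert len(accepted) == params.n_beads
        for r in accepted:
            _, dist = match_bead(r, truth)
            assert dist <= 1.0

    def test_record_invariant(self):
        with pytest.raises(ValueError):
            BeadRecord(id=1, xy_centroid_px=(5, 5), area_px=9, accepted=True,
                       rejection_reason="aggregate")


class TestKymograph:
    def test_constant_stack_gives_constant_kymograph(self):
        rec = BeadRecord(id=1, xy_centroid_px=(16.0, 16.0), area_px=9, accepted=True)
        kym = extract_kymograph(np.full((4, 6, 32, 32), 3.5), rec)
        assert kym.values.shape == (6, 4)
        assert np.allclose(kym.values, 3.5)

    def test_halfwidth_zero_single_pixel_column(self):
        stack = np.arange(4 * 6 * 32 * 32, dtype=float).reshape(4, 6, 32, 32)
        rec = BeadRecord(id=1, xy_centroid_px=(10.0, 20.0), area_px=9, accepted=True)
        kym = extract_kymograph(stack, rec, xy_halfwidth_px=0)
        assert kym.values.shape == (6, 4)
        assert np.allclose(kym.values, stack[:, :, 10, 20].T)

    def test_window_mean_not_sum(self):
        stack = np.full((2, 5, 32, 32), 7.0)
        rec = BeadRecord(id=1, xy_centroid_px=(16.0, 16.0), area_px=9, accepted=True)
        for h in (0, 2, 5):
            kym = extract_kymograph(stack, rec, xy_halfwidth_px=h)
            assert np.allclose(kym.values, 7.0)

    def test_window_out_of_bounds_raises(self):
        rec = BeadRecord(id=1, xy_centroid_px=(1.0, 16.0), area_px=9, accepted=True)
        with pytest.raises(ValueError, match="exceeds"):
            extract_kymograph(np.ones((2, 5, 32, 32)), rec, xy_halfwidth_px=2)

    def test_rejected_bead_refused(self):
        rec = BeadRecord(id=1, xy_centroid_px=(16.0, 16.0), area_px=900,
                         accepted=False, rejection_reason="aggregate")
        with pytest.raises(ValueError, match="rejected"):
            extract_kymograph(np.ones((2, 5, 32, 32)), rec)

    def test_noiseless_kymograph_argmax_matches_truth(self, noiseless_bead_scene):
        params, stack, truth = noiseless_bead_scene
        ch = stack.channel("bead")
        recs = [r for r in detect_beads(ch) if r.accepted]
        dz = params.voxel_size_um[0]
        for r in recs[:5]:
            b, _ = match_bead(r, truth)
            kym = extract_kymograph(ch, r, z_step_um=dz)
            z_meas = kym.values.argmax(axis=0) * dz
            assert np.all(np.abs(z_meas - truth.edge_z_um[b]) <= dz + 1e-9)


class TestTrackEdge:
    def test_static_noiseless_bead_zero_displacement(self):
        stack = _single_bead_stack()
        rec = detect_beads(stack)[0]
        kym = extract_kymograph(stack, rec, z_step_um=0.1)
        trace = track_edge(kym)
        assert trace.valid_frames.all()
        assert np.all(np.abs(trace.displacement_um) < 0.05)  # half a z-step

    def test_interpolation_contract_midpoint(self):
        """A step edge exactly between samples lands at k + 0.5 z-steps."""
        col = np.array([100.0] * 8 + [0.0] * 8)  # step between z=7 and z=8
        kym = Kymograph(values=np.tile(col[:, None], (1, 5)), z_step_um=1.0,
                        frame_interval_s=30.0, bead_id=0)
        trace = track_edge(kym, smooth_sigma_zt=(0.0, 0.0))
        assert np.allclose(trace.edge_z_um, 7.5, atol=0.01)

    def test_translation_equivariance(self):
        stack = _single_bead_stack(z_n=26, z_center=8.0)
        shifted = np.roll(stack, 4, axis=1)
        rec = detect_beads(stack)[0]
        e0 = track_edge(extract_kymograph(stack, rec, z_step_um=0.1))
        e1 = track_edge(extract_kymograph(shifted, rec, z_step_um=0.1))
        assert np.allclose(e1.edge_z_um - e0.edge_z_um, 0.4, atol=1e-3)
        assert np.allclose(e1.displacement_um, e0.displacement_um, atol=1e-3)

    def test_intensity_scale_invariance(self):
        stack = _single_bead_stack()
        rec = detect_beads(stack)[0]
        e0 = track_edge(extract_kymograph(stack, rec, z_step_um=0.1))
        e1 = track_edge(extract_kymograph(stack * 37.0, rec, z_step_um=0.1))
        assert np.allclose(e0.edge_z_um, e1.edge_z_um, atol=1e-4)

    def test_zero_dynamic_range_raises(self):
        kym = Kymograph(values=np.full((5, 4), 2.0), z_step_um=0.1,
                        frame_interval_s=30.0, bead_id=0)
        with pytest.raises(ValueError, match="dynamic range"):
            track_edge(kym)

    def test_edge_matches_halfmax_oracle_on_noiseless_scene(
        self, noiseless_bead_scene
    ):
        """Independent oracle: brute-force half-maximum crossing per column."""
        params, stack, truth = noiseless_bead_scene
        ch = stack.channel("bead")
        rec = [r for r in detect_beads(ch) if r.accepted][0]
        kym = extract_kymograph(ch, rec, z_step_um=params.voxel_size_um[0])
        trace = track_edge(kym, smooth_sigma_zt=(0.0, 0.0))
        v = kym.values
        for t in range(v.shape[1]):
            col = v[:, t]
            half = col.max() / 2
            above = np.nonzero(col >= half)[0]
            k = above[-1]
            oracle = k + (col[k] - half) / (col[k] - col[k + 1])
            assert abs(trace.edge_z_um[t] / params.voxel_size_um[0] - oracle) <= 1.0


class TestMaxDisplacement:
    def test_all_zero_trace(self):
        from pushscope.beads import DisplacementTrace

        tr = DisplacementTrace(edge_z_um=np.full(5, 1.0), baseline_um=1.0,
                               valid_frames=np.ones(5, bool))
        assert max_displacement(tr) == 0.0

    def test_definition_on_known_series(self):
        from pushscope.beads import DisplacementTrace

        tr = DisplacementTrace(edge_z_um=np.array([0.0, 0.2, 0.8, 0.3]),
                               baseline_um=0.0, valid_frames=np.ones(4, bool))
        assert max_displacement(tr) == pytest.approx(0.8)

    def test_no_valid_frames_raises(self):
        from pushscope.beads import DisplacementTrace

        tr = DisplacementTrace(edge_z_um=np.full(3, np.nan), baseline_um=0.0,
                               valid_frames=np.zeros(3, bool))
        with pytest.raises(ValueError):
            max_displacement(tr)

    def test_scene_amplitude_recovered_on_average(self, bead_scene):
        """Mean recovered maximum within 10% of the planted amplitude."""
        params, stack, truth = bead_scene
        ch = stack.channel("bead")
        recs = [r for r in detect_beads(ch) if r.accepted]
        maxima = []
        for r in recs:
            b, _ = match_bead(r, truth)
            trace = track_edge(extract_kymograph(
                ch, r, z_step_um=params.voxel_size_um[0]))
            none = np.array([l == "none" for l in truth.labels[b]])
            trace = trace.with_baseline(
                float(np.nanmean(trace.edge_z_um[none & trace.valid_frames]))
            )
            maxima.append(max_displacement(trace))
        assert np.mean(maxima) == pytest.approx(
            params.displacement_amplitude_um, rel=0.10
        )
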