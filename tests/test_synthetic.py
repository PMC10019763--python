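"""Generator contracts: winding by construction, texture determinism,
flow-fixture geometry, trajectories, FA blobs, nuclei point process."""

import numpy as np
import pytest

from nemadef.defects import boundary_winding, local_order_parameter, winding_number
from nemadef.fields import nematic_difference
from nemadef.synthetic import (
    TrajectorySpec,
    advect_texture_movie,
    make_defect_director,
    make_defect_flow,
    make_fa_image,
    make_nuclei_points,
    make_scene,
    make_tracks,
    random_scene,
    realized_axes,
    render_texture,
)

PX = 1.856


class TestDefectDirector:
    def test_single_plus_half_winding(self, comet_director):
        d, (cx, cy) = comet_director
        k = winding_number(d, (cx / PX, cy / PX), radius=10)
        assert k == 0.5

    def test_pair_winding_adds_to_zero(self):
        d = make_defect_director(
            [((150.0, 150.0), 0.5, 0.0), ((250.0, 250.0), -0.5, 0.0)],
            shape=(256, 256), pixel_size=PX,
        )
        # loop around both cores
        k = winding_number(d, (200.0 / PX, 200.0 / PX), radius=60)
        assert k == 0.0

    def test_empty_list_gives_uniform_field(self):
        d = make_defect_director([], background_angle=0.3, shape=(64, 64), pixel_size=PX)
        assert np.allclose(d.theta, 0.3)
        q = local_order_parameter(d, window_um=20.0)
        assert np.allclose(q.q, 1.0)

    def test_overlapping_cores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_defect_director(
                [((100.0, 100.0), 0.5, 0.0), ((101.0, 100.0), -0.5, 0.0)],
                shape=(128, 128), pixel_size=PX,
            )

    def test_non_half_integer_charge_rejected(self):
        with pytest.raises(ValueError):
            make_defect_director([((100.0, 100.0), 0.3, 0.0)], shape=(128, 128), pixel_size=PX)

    def test_charge_conservation_on_random_scenes(self):
        for seed in range(5):
            sc = random_scene(4, shape=(256, 256), pixel_size=PX, seed=seed)
            total = sum(k for _, k, _ in sc.truth_defects)
            assert boundary_winding(sc.director) == total

    def test_realized_axis_single_defect_is_exact(self):
        axes = realized_axes([((100.0, 100.0), 0.5, 1.3)])
        assert np.isclose(axes[0], 1.3)


class TestTexture:
    def test_deterministic_under_seed(self, comet_director):
        d, _ = comet_director
        t1 = render_texture(d, seed=7)
        t2 = render_texture(d, seed=7)
        np.testing.assert_array_equal(t1, t2)
        t3 = render_texture(d, seed=8)
        assert not np.array_equal(t1, t3)

    def test_uniform_director_gives_oriented_texture(self):
        from nemadef.orientation import structure_tensor_director

        d = make_defect_director([], background_angle=0.0, shape=(128, 128), pixel_size=PX)
        tex = render_texture(d, seed=3)
        est = structure_tensor_director(tex, pixel_size=PX)
        err = np.abs(np.degrees(nematic_difference(est.theta, 0.0)))
        assert np.mean(err < 3.0) >= 0.95

    def test_rotated_director_rotates_texture_orientation(self):
        from nemadef.orientation import structure_tensor_director

        d = make_defect_director([], background_angle=np.pi / 2, shape=(128, 128), pixel_size=PX)
        tex = render_texture(d, seed=3)
        est = structure_tensor_director(tex, pixel_size=PX)
        err = np.abs(np.degrees(nematic_difference(est.theta, np.pi / 2)))
        assert np.mean(err < 3.0) >= 0.95


class TestDefectFlow:
    def test_motile_core_flow_points_along_tail(self):
        fl = make_defect_flow("motile_contractile", axis_angle=0.0, v0=20.0,
                              decay_length=60.0, shape=(33, 33), grid_spacing=10.0)
        ic = 16
        assert fl.vx[ic, ic] > 0 and np.isclose(fl.vy[ic, ic], 0.0)
        assert np.isclose(fl.vx[ic, ic], 20.0)

    def test_motile_vorticity_antisymmetric_about_axis(self):
        fl = make_defect_flow("motile_contractile", axis_angle=0.0, v0=20.0,
                              decay_length=60.0, shape=(33, 33), grid_spacing=10.0)
        om = np.gradient(fl.vy, 10.0, axis=1) - np.gradient(fl.vx, 10.0, axis=0)
        np.testing.assert_allclose(om, -om[::-1, :], atol=1e-8)

    def test_stationary_zero_on_tail_side(self):
        fl = make_defect_flow("stationary_asymmetric", axis_angle=0.0, v0=20.0,
                              decay_length=60.0, shape=(33, 33), grid_spacing=10.0)
        ic = 16
        assert np.allclose(fl.vx[:, ic + 1:], 0.0) and np.allclose(fl.vy[:, ic + 1:], 0.0)
        head_speed = np.hypot(fl.vx[ic, :ic], fl.vy[ic, :ic])
        assert head_speed.max() > 1.0
        # head flow points toward the core: positive x-component on the head side
        assert np.all(fl.vx[ic, :ic] >= 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            make_defect_flow("sideways", axis_angle=0.0)

    def test_advected_movie_shapes_and_identity_frame(self):
        rng = np.random.default_rng(0)
        tex = rng.standard_normal((64, 64))
        fl = make_defect_flow("motile_contractile", v0=10.0, decay_length=30.0,
                              shape=(9, 9), grid_spacing=64 * PX / 9)
        movie = advect_texture_movie(tex, fl, n_frames=3, pixel_size=PX)
        assert movie.shape == (3, 64, 64)
        np.testing.assert_array_equal(movie[0], tex)


class TestTracksAndPoints:
    def test_static_zero_jitter_track_is_constant(self):
        pf = make_tracks([TrajectorySpec((50.0, 60.0), (0.0, 0.0), 0.25, 10)], seed=0)
        pos = np.array([pf[t][0].position for t in range(10)])
        assert np.allclose(pos, pos[0])

    def test_constant_velocity_displacement(self):
        pf = make_tracks([TrajectorySpec((0.0, 0.0), (20.0, 0.0), 0.25, 10)], seed=0)
        pos = np.array([pf[t][0].position for t in range(10)])
        np.testing.assert_allclose(np.diff(pos[:, 0]), 5.0)

    def test_mean_speed_recovered_with_jitter(self):
        # Monte-Carlo: jittered 10 um/h tracks recover the nominal speed
        from nemadef.tracking import link_tracks, track_speed

        speeds = []
        for seed in range(50):
            pf = make_tracks(
                [TrajectorySpec((100.0, 100.0), (10.0, 0.0), 0.25, 20, jitter_sd=1.0)],
                seed=seed,
            )
            tr = link_tracks(pf, max_disp_per_frame=30.0)[0]
            speeds.append(track_speed(tr, 0.25, smoothing_window=5))
        assert abs(np.mean(speeds) - 10.0) / 10.0 < 0.15

    def test_fa_image_blob_count(self):
        img = make_fa_image(
            [((10.0, 10.0), 3.0, 1.0, 0.0), ((30.0, 30.0), 3.0, 2.0, 0.5),
             ((10.0, 40.0), 2.0, 1.5, 1.0), ((40.0, 10.0), 4.0, 3.0, 2.0),
             ((25.0, 45.0), 2.5, 1.0, 0.0)],
            shape=(256, 256), pixel_size=0.2, seed=0,
        )
        from nemadef.fa_morpho import segment_fas

        assert segment_fas(img)[0].max() == 5

    def test_empty_blob_list_segments_to_nothing(self):
        from nemadef.fa_morpho import segment_fas

        img = make_fa_image([], shape=(128, 128), pixel_size=0.2, seed=0)
        assert segment_fas(img)[0].max() == 0

    def test_nuclei_hotspot_density_ratio(self):
        from nemadef.defect_frame import density_map

        pts = make_nuclei_points(
            2000.0, area=(2000.0, 2000.0),
            hotspot=((1000.0, 1000.0), 300.0, 2.0), seed=5,
        )
        dm = density_map(pts, (2000.0, 2000.0), window_um=200.0)
        X, Y = np.meshgrid(dm["x_um"], dm["y_um"])
        inside = np.hypot(X - 1000, Y - 1000) < 200
        outside = (np.hypot(X - 1000, Y - 1000) > 500) & (X > 300) & (X < 1700) & (Y > 300) & (Y < 1700)
        ratio = dm["density_mm2"][inside].mean() / dm["density_mm2"][outside].mean()
        assert 1.7 < ratio < 2.3

    def test_zero_area_gives_empty_point_set(self):
        assert make_nuclei_points(1000.0, area=(0.0, 100.0), seed=0).size == 0
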