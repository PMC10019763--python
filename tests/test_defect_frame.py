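"""Defect-frame registration, ensemble averaging, profiles, contractility."""

import numpy as np
import pytest

from nemadef.defect_frame import (
    average_frames,
    axial_profile,
    contractility_sign,
    density_map,
    head_density_profile,
    register_observation,
)
from nemadef.fields import DefectObservation, VelocityField, nematic_difference
from nemadef.synthetic import make_defect_director, make_defect_flow, make_nuclei_points

PX = 1.856
SHAPE = (256, 256)
CENTER = ((SHAPE[1] - 1) * PX / 2, (SHAPE[0] - 1) * PX / 2)


def comet_with_flow(psi, kind="motile_contractile", v0=20.0):
    d = make_defect_director([(CENTER, 0.5, psi)], shape=SHAPE, pixel_size=PX)
    fl = make_defect_flow(kind, axis_angle=psi, v0=v0, decay_length=60.0,
                          shape=(31, 31), grid_spacing=SHAPE[0] * PX / 31, core=CENTER)
    obs = DefectObservation(position=CENTER, charge=0.5, axis_angle=psi)
    return d, fl, obs


class TestRegistration:
    def test_identity_registration_for_canonical_comet(self):
        d, fl, obs = comet_with_flow(0.0)
        p = register_observation(d, fl, obs, half_size_um=100.0, grid_step_um=PX * 2)
        # central crop of the lab field equals the patch where unmasked
        i0 = len(p.y) // 2
        assert p.dir_mask.all()
        assert np.isclose(p.theta[i0, -1], 0.0, atol=0.02)  # tail side along +x
        assert p.vx[i0, i0] > 0  # core flow toward tail

    def test_rotational_equivariance(self):
        patches = {}
        for psi in (0.0, np.radians(70.0)):
            d, fl, obs = comet_with_flow(psi)
            patches[psi] = register_observation(d, fl, obs, half_size_um=120.0,
                                                grid_step_um=PX * 2)
        p0, p1 = patches.values()
        m = p0.dir_mask & p1.dir_mask
        ang = np.degrees(nematic_difference(p1.theta[m], p0.theta[m]))
        assert np.sqrt(np.mean(ang**2)) < 3.0
        vm = p0.vel_mask & p1.vel_mask
        vrms = np.sqrt(np.mean((p1.vx[vm] - p0.vx[vm])**2 + (p1.vy[vm] - p0.vy[vm])**2))
        assert vrms / 20.0 < 0.10

    def test_non_plus_half_rejected(self):
        d, fl, obs = comet_with_flow(0.0)
        bad = DefectObservation(position=CENTER, charge=-0.5, axis_angle=0.0)
        with pytest.raises(ValueError):
            register_observation(d, fl, bad, half_size_um=50.0)

    def test_corner_core_is_masked_outside(self):
        d, fl, _ = comet_with_flow(0.0)
        obs = DefectObservation(position=(10.0, 10.0), charge=0.5, axis_angle=0.0)
        p = register_observation(d, fl, obs, half_size_um=100.0, grid_step_um=PX * 2)
        assert not p.dir_mask.all()
        # the quadrant beyond the image corner is fully masked
        n = len(p.y)
        assert not p.dir_mask[: n // 4, : n // 4].any()


class TestAveraging:
    def test_identical_patches_average_to_themselves(self):
        d, fl, obs = comet_with_flow(0.5)
        p = register_observation(d, fl, obs, half_size_um=100.0, grid_step_um=PX * 2)
        avg = average_frames([p, p, p])
        m = p.dir_mask
        assert np.allclose(
            nematic_difference(avg.theta[m], p.theta[m]), 0.0, atol=1e-9
        )
        vm = p.vel_mask
        np.testing.assert_allclose(avg.vx[vm], p.vx[vm])

    def test_opposite_velocities_cancel(self):
        d, fl, obs = comet_with_flow(0.0)
        p = register_observation(d, fl, obs, half_size_um=100.0, grid_step_um=PX * 2)
        import copy

        p2 = copy.deepcopy(p)
        p2.vx = -p2.vx
        p2.vy = -p2.vy
        avg = average_frames([p, p2])
        vm = p.vel_mask
        np.testing.assert_allclose(avg.vx[vm], 0.0, atol=1e-12)

    def test_noisy_ensemble_recovers_mean_director(self):
        """50 angle-noised copies of one comet average back to the clean
        director within 3 degrees."""
        rng = np.random.default_rng(11)
        d, fl, obs = comet_with_flow(0.0)
        clean = register_observation(d, None, obs, half_size_um=100.0, grid_step_um=PX * 2)
        noisy = []
        for _ in range(50):
            p = register_observation(d, None, obs, half_size_um=100.0, grid_step_um=PX * 2)
            dth = rng.normal(0.0, np.radians(10.0), size=p.cos2.shape)
            z = (p.cos2 + 1j * p.sin2) * np.exp(2j * dth)
            p.cos2, p.sin2 = z.real, z.imag
            noisy.append(p)
        avg = average_frames(noisy)
        m = clean.dir_mask
        err = np.degrees(nematic_difference(avg.theta[m], clean.theta[m]))
        assert np.sqrt(np.mean(err**2)) < 3.0

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            average_frames([])


class TestProfilesAndSign:
    def test_uniform_flow_gives_flat_profile(self):
        x = np.arange(21) * 10.0 - 100.0
        vf_patch = average_frames([_uniform_patch(x, u=7.0)])
        prof = axial_profile(vf_patch, band_halfwidth_um=30.0, n_bins=11)
        good = prof["n"] > 0
        np.testing.assert_allclose(prof["v_axial_umh"][good], 7.0)

    def test_zero_halfwidth_rejected(self):
        x = np.arange(21) * 10.0 - 100.0
        with pytest.raises(ValueError):
            axial_profile(average_frames([_uniform_patch(x)]), band_halfwidth_um=0.0)

    def test_stationary_profile_zero_tail_finite_head(self):
        d, fl, obs = comet_with_flow(0.3, kind="stationary_asymmetric")
        p = register_observation(d, fl, obs, half_size_um=140.0, grid_step_um=PX * 2)
        prof = axial_profile(average_frames([p]), band_halfwidth_um=30.0)
        x = prof["x_um"]
        v = prof["v_axial_umh"]
        tail = (x > 30.0) & np.isfinite(v)
        head = (x < -30.0) & np.isfinite(v)
        assert np.nanmax(np.abs(v[tail])) < 0.5
        assert np.nanmax(v[head]) > 2.0

    def test_contractile_extensile_and_zero(self):
        d, fl, obs = comet_with_flow(1.0)
        p = register_observation(d, fl, obs, half_size_um=140.0, grid_step_um=PX * 2)
        avg = average_frames([p])
        res = contractility_sign(avg)
        assert res["sign"] == "contractile"
        assert res["vorticity_antisymmetry"] > 0.9
        import copy

        p2 = copy.deepcopy(p)
        p2.vx, p2.vy = -p2.vx, -p2.vy
        assert contractility_sign(average_frames([p2]))["sign"] == "extensile"
        p3 = copy.deepcopy(p)
        p3.vx[:] = 0.0
        p3.vy[:] = 0.0
        assert contractility_sign(average_frames([p3]))["sign"] == "indeterminate"

    def test_global_rotation_leaves_average_unchanged(self):
        """Averaging scenes whose axes are rotated arbitrarily yields the
        same defect-frame field as the canonical one."""
        rng = np.random.default_rng(2)
        patches = []
        for psi in rng.uniform(0, 2 * np.pi, size=8):
            d, fl, obs = comet_with_flow(float(psi))
            patches.append(register_observation(d, fl, obs, half_size_um=120.0,
                                                grid_step_um=PX * 2))
        avg = average_frames(patches)
        d0, fl0, obs0 = comet_with_flow(0.0)
        ref = register_observation(d0, fl0, obs0, half_size_um=120.0, grid_step_um=PX * 2)
        m = ref.dir_mask & (avg.n_dir == len(patches))
        ang = np.degrees(nematic_difference(avg.theta[m], ref.theta[m]))
        assert np.sqrt(np.mean(ang**2)) < 3.0
        vm = ref.vel_mask & (avg.n_vel == len(patches))
        vrms = np.sqrt(np.mean((avg.vx[vm] - ref.vx[vm])**2 + (avg.vy[vm] - ref.vy[vm])**2))
        assert vrms / 20.0 < 0.10


class TestDensity:
    def test_homogeneous_poisson_mean(self):
        pts = make_nuclei_points(1000.0, area=(2000.0, 2000.0), seed=3)
        dm = density_map(pts, (2000.0, 2000.0), window_um=400.0)
        inner = dm["density_mm2"][2:-2, 2:-2]
        assert abs(inner.mean() - 1000.0) / 1000.0 < 0.1

    def test_no_points_zero_field(self):
        dm = density_map(np.empty((0, 2)), (500.0, 500.0), window_um=100.0)
        assert np.allclose(dm["density_mm2"], 0.0)

    def test_head_hotspot_ratio(self):
        """Nuclei excess at the head shows up as a head/tail density ratio
        near the prescribed fold."""
        defect = DefectObservation(position=(1000.0, 1000.0), charge=0.5, axis_angle=0.0)
        ratios = []
        for seed in range(8):
            pts = make_nuclei_points(
                3000.0, area=(2000.0, 2000.0),
                hotspot=((900.0, 1000.0), 100.0, 2.0),  # head side: x < core
                seed=seed,
            )
            prof = head_density_profile(pts, defect, half_size_um=150.0,
                                        band_halfwidth_um=50.0, n_bins=3)
            ratios.append(prof["density_mm2"][0] / prof["density_mm2"][2])
        assert abs(np.mean(ratios) - 2.0) < 0.35


def _uniform_patch(x, u=7.0):
    from nemadef.defect_frame import DefectFramePatch

    n = len(x)
    ones = np.ones((n, n))
    return DefectFramePatch(
        x=x, y=x, cos2=ones.copy(), sin2=np.zeros((n, n)),
        dir_mask=ones.astype(bool),
        vx=u * ones, vy=np.zeros((n, n)), vel_mask=ones.astype(bool),
    )
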