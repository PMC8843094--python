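"""Mask/angle synthesis: back-projection geometry, superposition, power law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from map3d import (
    IlluminationAngle,
    OpticalConfig,
    TargetSpot,
    aperture_center,
    power_radius,
    prune_rays,
    rasterize,
    synthesize_plan,
)
from map3d.patterns import OutOfRangeError, frame_azimuths


def ray_to_target_distance(disk, target, angle, cfg):
    """Oracle: lateral miss distance of the aperture-center ray at the
    target's depth (the ray shifts by z·tanθ·(cos ϕSM, sin ϕSM))."""
    x0, y0 = cfg.px_to_um(disk.center_col, disk.center_row)
    tan_t = math.tan(angle.theta)
    lx = x0 + target.z_um * tan_t * math.cos(angle.phi_sm)
    ly = y0 + target.z_um * tan_t * math.sin(angle.phi_sm)
    return math.hypot(lx - target.x_um, ly - target.y_um)


class TestApertureCenter:
    def test_in_focus_target_keeps_constant_aperture(self, cfg):
        t = TargetSpot(10.0, -20.0, 0.0, radius_px=5)
        centers = set()
        for phi in np.linspace(0, 2 * math.pi, 13, endpoint=False):
            d = aperture_center(t, IlluminationAngle(phi, cfg.theta), cfg)
            centers.add((round(d.center_col, 9), round(d.center_row, 9)))
            assert d.sweep_diameter_px == 0.0
        assert len(centers) == 1
        col, row = cfg.um_to_px(10.0, -20.0)
        assert centers == {(round(col, 9), round(row, 9))}

    def test_defocused_offset_and_sweep_diameter(self, cfg):
        # z = 100 µm, tanθ = 0.5, 1 µm/px: offset 50 px, sweep D = 100 px
        t = TargetSpot(0.0, 0.0, 100.0, radius_px=5)
        angle = IlluminationAngle(math.pi / 3, cfg.theta)
        d = aperture_center(t, angle, cfg)
        col0, row0 = cfg.um_to_px(0.0, 0.0)
        offset = math.hypot(d.center_col - col0, d.center_row - row0)
        assert offset == pytest.approx(50.0, abs=1e-9)
        assert d.sweep_diameter_px == pytest.approx(100.0, abs=1e-9)
        assert ray_to_target_distance(d, t, angle, cfg) < 1e-9

    def test_opposite_azimuths_mirror_about_target(self, cfg):
        t = TargetSpot(7.0, 11.0, 60.0, radius_px=3)
        phi = 1.1
        d1 = aperture_center(t, IlluminationAngle(phi, cfg.theta), cfg)
        d2 = aperture_center(t, IlluminationAngle(phi + math.pi, cfg.theta), cfg)
        col0, row0 = cfg.um_to_px(7.0, 11.0)
        assert d1.center_col - col0 == pytest.approx(-(d2.center_col - col0))
        assert d1.center_row - row0 == pytest.approx(-(d2.center_row - row0))

    def test_below_plane_aperture_sits_opposite_the_galvo_azimuth(self, cfg):
        # below-plane focus: phi_dmd = phi_sm + pi (first frame: phi_sm = pi,
        # aperture at phi_dmd = 0); above-plane: phi_dmd = phi_sm
        below = TargetSpot(0.0, 0.0, 50.0)
        above = TargetSpot(0.0, 0.0, -50.0)
        angle = IlluminationAngle(math.pi, cfg.theta)
        d_below = aperture_center(below, angle, cfg)
        d_above = aperture_center(above, angle, cfg)
        assert d_below.phi_dmd % (2 * math.pi) == pytest.approx(0.0, abs=1e-9) or (
            d_below.phi_dmd == pytest.approx(2 * math.pi, abs=1e-9)
        )
        assert d_above.phi_dmd == pytest.approx(math.pi, abs=1e-9)

    def test_out_of_range_error_names_target(self, cfg):
        t = TargetSpot(250.0, 0.0, 100.0, radius_px=20)
        with pytest.raises(OutOfRangeError, match="250"):
            aperture_center(t, IlluminationAngle(math.pi, cfg.theta), cfg)

    @settings(deadline=None, max_examples=200)
    @given(
        x=st.floats(-50, 50),
        y=st.floats(-50, 50),
        z=st.floats(-80, 80),
        phi=st.floats(0, 2 * math.pi),
        theta=st.floats(0.05, 1.0),
        um_per_px=st.floats(0.5, 3.0),
    )
    def test_ray_consistency_property(self, x, y, z, phi, theta, um_per_px):
        """Every back-projected aperture's ray passes through its target."""
        cfg = OpticalConfig(
            dmd_cols=1024, dmd_rows=1024, um_per_px=um_per_px, theta=theta
        )
        t = TargetSpot(x, y, z, radius_px=2)
        angle = IlluminationAngle(phi, theta)
        d = aperture_center(t, angle, cfg, check_bounds=False)
        assert ray_to_target_distance(d, t, angle, cfg) < 1e-6


class TestSynthesizePlan:
    def test_single_target_ten_frames_one_disk_each(self, cfg):
        plan = synthesize_plan([TargetSpot(0, 0, 30.0)], cfg)
        assert plan.n_frames == 10
        for f in plan.frames:
            assert len(f.disks) == 1

    def test_empty_target_list_gives_dark_masks(self, cfg):
        plan = synthesize_plan([], cfg)
        assert plan.n_frames == cfg.n_angles
        for f in plan.frames:
            assert not f.mask.any()

    def test_azimuths_evenly_spaced_starting_at_pi(self, cfg):
        plan = synthesize_plan([TargetSpot(0, 0, 10.0)], cfg)
        phis = np.array([f.angle.phi_sm for f in plan.frames])
        expected = frame_azimuths(cfg.n_angles)
        np.testing.assert_allclose(phis, expected)
        assert phis[0] == pytest.approx(math.pi)
        steps = np.diff(np.unwrap(phis))
        np.testing.assert_allclose(steps, 2 * math.pi / cfg.n_angles, atol=1e-12)

    def test_sweep_circle_law(self, cfg):
        """Aperture centers of a defocused target lie on a circle of
        diameter 2|Δz|tanθ/um_per_px centered at the target position."""
        t = TargetSpot(12.0, -8.0, -44.0, radius_px=4)
        plan = synthesize_plan([t], cfg)
        col0, row0 = cfg.um_to_px(t.x_um, t.y_um)
        radius = abs(t.z_um) * math.tan(cfg.theta) / cfg.um_per_px
        for f in plan.frames:
            d = f.disks[0][1]
            r = math.hypot(d.center_col - col0, d.center_row - row0)
            assert abs(r - radius) < 1e-6

    def test_superposition_of_disjoint_targets(self, cfg):
        a = TargetSpot(-60.0, -60.0, 20.0, radius_px=5)
        b = TargetSpot(70.0, 50.0, -30.0, radius_px=7)
        plan_a = synthesize_plan([a], cfg)
        plan_b = synthesize_plan([b], cfg)
        plan_ab = synthesize_plan([a, b], cfg)
        for fa, fb, fab in zip(plan_a.frames, plan_b.frames, plan_ab.frames):
            assert not (fa.mask & fb.mask).any()  # well separated
            np.testing.assert_array_equal(fab.mask, fa.mask | fb.mask)

    def test_dwell_splits_stimulation_time(self, cfg):
        plan = synthesize_plan([], cfg)
        assert plan.frames[0].dwell_us == pytest.approx(400.0)  # 4 ms / 10


class TestPowerRadius:
    @pytest.mark.parametrize(
        "base,factor,expected_rounded",
        [(10, 2, 14), (10, 1, 10), (5, 4, 10), (1, 1, 1)],
    )
    def test_quadratic_power_law(self, base, factor, expected_rounded):
        exact, rounded = power_radius(base, factor)
        assert rounded == expected_rounded
        assert exact == pytest.approx(base * math.sqrt(factor))

    def test_rasterized_area_ratio_tracks_factor(self, cfg):
        """Doubling radius quadruples delivered power (ON-pixel count)."""
        from map3d.patterns import ApertureDisk

        def count(r):
            d = ApertureDisk(256.0, 256.0, r, 0.0, 0.0)
            return rasterize([d], cfg).sum()

        exact, _ = power_radius(5, 4)
        assert exact == pytest.approx(10.0)
        assert count(exact) / count(5) == pytest.approx(4.0, rel=0.10)

    def test_too_dim_target_rejected(self):
        with pytest.raises(ValueError, match="too dim"):
            power_radius(1, 0.25)


class TestRasterize:
    def test_interior_disk_area_close_to_analytic(self, cfg):
        from map3d.patterns import ApertureDisk

        mask = rasterize([ApertureDisk(200.0, 200.0, 10.0, 0.0, 0.0)], cfg)
        assert mask.sum() == pytest.approx(math.pi * 100, rel=0.05)

    def test_empty_disk_list_all_dark(self, cfg):
        assert not rasterize([], cfg).any()

    def test_union_is_idempotent(self, cfg):
        from map3d.patterns import ApertureDisk

        d = ApertureDisk(100.0, 150.0, 8.0, 0.0, 0.0)
        one = rasterize([d], cfg)
        two = rasterize([d, d], cfg)
        assert one.sum() == two.sum()


class TestPruneRays:
    def test_zones_missing_all_rays_are_noop(self, cfg, single_target_plan):
        res = prune_rays(single_target_plan, [((500.0, 500.0, 50.0), 5.0)])
        assert all(v == 0 for v in res.removed.values())
        for f0, f1 in zip(single_target_plan.frames, res.plan.frames):
            np.testing.assert_array_equal(f0.mask, f1.mask)

    def test_sphere_on_one_beam_path_removes_exactly_that_disk(self, cfg):
        t = TargetSpot(0.0, 0.0, 60.0, radius_px=4)
        plan = synthesize_plan([t], cfg)
        # place a small sphere on frame 3's ray, halfway to the target
        f = plan.frames[3]
        d = f.disks[0][1]
        x0, y0 = cfg.px_to_um(d.center_col, d.center_row)
        mid = np.array([x0, y0, 0.0]) + 0.5 * (
            np.array([t.x_um, t.y_um, t.z_um]) - np.array([x0, y0, 0.0])
        )
        res = prune_rays(plan, [((mid[0], mid[1], mid[2]), 1.0)])
        assert res.removed[0] == 1
        assert len(res.plan.frames[3].disks) == 0
        for i, fr in enumerate(res.plan.frames):
            if i != 3:
                assert len(fr.disks) == 1

    def test_sphere_enclosing_target_prunes_everything(self, cfg):
        t = TargetSpot(0.0, 0.0, 60.0, radius_px=4)
        plan = synthesize_plan([t], cfg)
        with pytest.raises(OutOfRangeError, match="all rays pruned"):
            prune_rays(plan, [((0.0, 0.0, 60.0), 10.0)])

    def test_rebalance_grows_surviving_disks(self, cfg):
        t = TargetSpot(0.0, 0.0, 60.0, radius_px=4)
        plan = synthesize_plan([t], cfg)
        f = plan.frames[0]
        d = f.disks[0][1]
        x0, y0 = cfg.px_to_um(d.center_col, d.center_row)
        zone = ((x0, y0, 0.0), 0.5)
        res = prune_rays(plan, [zone], rebalance=True)
        surviving = res.plan.frames[1].disks[0][1]
        assert surviving.radius_px == pytest.approx(4 * math.sqrt(10 / 9))
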