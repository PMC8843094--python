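"""Forward simulator: shear rendering, FWHM, sectioning, misalignment."""

import math

import numpy as np
import pytest

from map3d import (
    BlurModel,
    MisalignmentSpec,
    OpticalConfig,
    TargetSpot,
    VolumeGrid,
    apply_scatter,
    axial_sectioning_curve,
    fwhm,
    render_volume,
    simulate_misalignment,
    synthesize_plan,
)
from map3d.optsim import IntensityVolume, ring_radius


def naive_render(plan, grid):
    """Oracle: per-voxel, per-frame ray-marching with hand-rolled bilinear
    interpolation of each sheared mask."""
    cfg = plan.config
    out = np.zeros((grid.nz, grid.ny, grid.nx))
    cx = (cfg.dmd_cols - 1) / 2.0
    cy = (cfg.dmd_rows - 1) / 2.0
    for f in plan.frames:
        mask = f.mask.astype(float)
        tan_t = math.tan(f.angle.theta)
        sx = tan_t * math.cos(f.angle.phi_sm)
        sy = tan_t * math.sin(f.angle.phi_sm)
        for iz, z in enumerate(grid.zs):
            for iy, y in enumerate(grid.ys):
                for ix, x in enumerate(grid.xs):
                    col = (x - z * sx) / cfg.um_per_px + cx
                    row = (y - z * sy) / cfg.um_per_px + cy
                    c0, r0 = int(math.floor(col)), int(math.floor(row))
                    fc, fr = col - c0, row - r0
                    val = 0.0
                    for dr, wr in ((0, 1 - fr), (1, fr)):
                        for dc, wc in ((0, 1 - fc), (1, fc)):
                            rr, cc = r0 + dr, c0 + dc
                            if 0 <= rr < cfg.dmd_rows and 0 <= cc < cfg.dmd_cols:
                                val += wr * wc * mask[rr, cc]
                    out[iz, iy, ix] += f.dwell_us * val
    return out


class TestRenderVolume:
    def test_focus_forms_at_the_target(self, cfg):
        t = TargetSpot(5.0, -3.0, 20.0, radius_px=3)
        plan = synthesize_plan([t], cfg)
        grid = VolumeGrid(nx=41, ny=41, nz=31, dx=1.0, dy=1.0, dz=2.0, center=(5, -3, 20))
        vol = render_volume(plan, grid)
        it = (15, 20, 20)  # index of (5, -3, 20)
        assert grid.zs[it[0]] == 20 and grid.ys[it[1]] == -3 and grid.xs[it[2]] == 5
        assert vol.data[it] == pytest.approx(vol.data.max(), rel=1e-9)
        # lateral argmax in the target plane is the target position
        plane = vol.data[15]
        iy, ix = np.unravel_index(np.argmax(plane), plane.shape)
        assert abs(grid.xs[ix] - 5.0) <= grid.dx and abs(grid.ys[iy] + 3.0) <= grid.dy

    def test_matches_naive_ray_marching_oracle(self, cfg):
        targets = [
            TargetSpot(0.0, 0.0, 24.0, radius_px=4),
            TargetSpot(-14.0, 10.0, -16.0, radius_px=6),
        ]
        plan = synthesize_plan(targets, cfg)
        grid = VolumeGrid(nx=24, ny=24, nz=9, dx=2.0, dy=2.0, dz=6.0)
        vol = render_volume(plan, grid, warn_uncovered=False)
        oracle = naive_render(plan, grid)
        scale = oracle.max()
        np.testing.assert_allclose(vol.data / scale, oracle / scale, atol=1e-9)

    def test_plane_energy_conservation_lossless_mode(self, cfg, rng):
        """With lateral voxel pitch equal to the DMD pixel pitch and full
        coverage, shear conserves each z-plane's summed intensity."""
        targets = [
            TargetSpot(float(rng.uniform(-20, 20)), float(rng.uniform(-20, 20)),
                       float(rng.uniform(-30, 30)), radius_px=int(rng.integers(2, 7)))
            for _ in range(3)
        ]
        plan = synthesize_plan(targets, cfg)
        grid = VolumeGrid(nx=512, ny=512, nz=5, dx=1.0, dy=1.0, dz=15.0)
        vol = render_volume(plan, grid, warn_uncovered=False)
        expected = sum(f.dwell_us * f.mask.sum() for f in plan.frames)
        np.testing.assert_allclose(vol.plane_sums(), expected, rtol=1e-6)

    def test_empty_plan_renders_zero_volume(self, cfg, coarse_grid):
        plan = synthesize_plan([], cfg)
        vol = render_volume(plan, coarse_grid)
        assert not vol.data.any()

    def test_single_frame_has_no_axial_sectioning(self, cfg):
        t = TargetSpot(0.0, 0.0, 0.0, radius_px=6)
        plan = synthesize_plan([t], cfg)
        plan.frames = plan.frames[:1]
        grid = VolumeGrid(nx=61, ny=61, nz=21, dx=1.0, dy=1.0, dz=3.0)
        vol = render_volume(plan, grid)
        zc, prof = vol.axial_max_profile()
        np.testing.assert_allclose(prof, prof[0], rtol=1e-9)
        with pytest.raises(ValueError, match="FWHM undefined"):
            fwhm(zc, prof)


class TestFwhm:
    def test_gaussian_closed_form(self):
        x = np.linspace(-60, 60, 1201)
        sigma = 10.0
        width = fwhm(x, np.exp(-(x**2) / (2 * sigma**2)))
        assert width == pytest.approx(2 * math.sqrt(2 * math.log(2)) * sigma, abs=0.05)

    def test_rectangular_profile(self):
        x = np.linspace(0, 100, 1001)
        v = ((x >= 30) & (x <= 70)).astype(float)
        assert fwhm(x, v) == pytest.approx(40.0, abs=0.2)

    def test_plateau_at_half_max_counts_as_crossing(self):
        # two-beam far field sits exactly at half max
        x = np.linspace(-10, 10, 201)
        v = np.where(np.abs(x) < 2, 2.0, 1.0)
        assert fwhm(x, v) == pytest.approx(4.0, abs=0.2)


class TestAxialSectioning:
    def test_more_beams_section_no_worse(self, cfg):
        grid = VolumeGrid(nx=72, ny=72, nz=81, dx=1.0, dy=1.0, dz=1.0)
        blur = BlurModel(sigma0_um=1.5)
        curve = axial_sectioning_curve([2, 4, 10], cfg, grid, radius_px=6, blur=blur)
        assert curve[10] <= curve[4] <= curve[2]
        assert curve[10] < curve[2]

    def test_single_beam_rejected(self, cfg, coarse_grid):
        with pytest.raises(ValueError, match="sectioning"):
            axial_sectioning_curve([1], cfg, coarse_grid)

    def test_two_opposed_beams_give_symmetric_profile(self):
        cfg = OpticalConfig(
            dmd_cols=256, dmd_rows=256, um_per_px=1.0, theta=0.4, n_angles=2
        )
        plan = synthesize_plan([TargetSpot(0.0, 0.0, 0.0, radius_px=5)], cfg)
        grid = VolumeGrid(nx=61, ny=61, nz=41, dx=1.0, dy=1.0, dz=1.0)
        vol = render_volume(plan, grid)
        _, prof = vol.axial_max_profile()
        np.testing.assert_allclose(prof, prof[::-1], rtol=1e-9)


class TestMisalignment:
    def test_identity_spec_reproduces_aligned_render(self, cfg, single_target_plan):
        grid = VolumeGrid(nx=41, ny=41, nz=11, dx=1.0, dy=1.0, dz=4.0, center=(5, -3, 20))
        v0 = render_volume(single_target_plan, grid)
        v1 = simulate_misalignment(single_target_plan, MisalignmentSpec(), grid)
        np.testing.assert_array_equal(v0.data, v1.data)

    def test_phase_offset_forms_ring_of_predicted_radius(self):
        cfg = OpticalConfig(
            dmd_cols=384, dmd_rows=384, um_per_px=1.0, theta=math.atan(0.4)
        )
        dz, tan_t = 40.0, 0.4
        plan = synthesize_plan([TargetSpot(0.0, 0.0, dz, radius_px=5)], cfg)
        grid = VolumeGrid(nx=120, ny=120, nz=5, dx=1.0, dy=1.0, dz=4.0, center=(0, 0, dz))
        dphi = math.pi / 2
        vol = simulate_misalignment(plan, MisalignmentSpec(phase_offset_rad=dphi), grid)
        predicted = 2 * dz * tan_t * math.sin(dphi / 2)
        assert ring_radius(vol, (0.0, 0.0), 2) == pytest.approx(predicted, abs=1.0)

    def test_amp_ratio_splits_focus_into_two_planes(self):
        """Elliptical galvo scan focuses x- and y-beam pairs at different
        depths (astigmatism): Δz for the x pair, Δz/ratio for the y pair."""
        cfg = OpticalConfig(
            dmd_cols=384, dmd_rows=384, um_per_px=1.0, theta=math.atan(0.4), n_angles=4
        )
        plan = synthesize_plan([TargetSpot(0.0, 0.0, 40.0, radius_px=2)], cfg)
        grid = VolumeGrid(nx=100, ny=100, nz=61, dx=1.0, dy=1.0, dz=1.0, center=(0, 0, 35))
        vol = simulate_misalignment(plan, MisalignmentSpec(amp_ratio=1.5), grid)
        ixc = int(np.argmin(np.abs(grid.xs)))
        iyc = int(np.argmin(np.abs(grid.ys)))
        prof = vol.data[:, iyc, ixc]

        def at(z):
            return prof[int(np.argmin(np.abs(grid.zs - z)))]

        z_x, z_y = 40.0, 40.0 / 1.5
        mid = (z_x + z_y) / 2
        assert at(z_x) > 2 * at(mid)
        assert at(z_y) > 2 * at(mid)


class TestScatter:
    def _focus_volume(self):
        grid = VolumeGrid(nx=81, ny=81, nz=5, dx=1.0, dy=1.0, dz=25.0, center=(0, 0, 50))
        xx, yy = np.meshgrid(grid.xs, grid.ys)
        data = np.stack([np.exp(-(xx**2 + yy**2) / (2 * 16.0)) for _ in grid.zs])
        return IntensityVolume(data=data, grid=grid)

    def test_disabled_or_zero_blur_is_identity(self):
        vol = self._focus_volume()
        out = apply_scatter(vol, BlurModel(sigma0_um=0.0, slope_um_per_um=0.0))
        np.testing.assert_array_equal(out.data, vol.data)

    def test_deeper_planes_broaden_more(self):
        vol = self._focus_volume()
        out = apply_scatter(vol, BlurModel(sigma0_um=1.0, slope_um_per_um=0.05))
        widths = [
            fwhm(vol.grid.xs, out.data[iz][40, :]) for iz in range(vol.grid.nz)
        ]
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_variance_addition_oracle(self):
        """Gaussian ⊛ Gaussian: FWHM² ≈ FWHM₀² + (2.355·σ_blur)²."""
        vol = self._focus_volume()
        sigma_blur = 3.0
        out = apply_scatter(
            vol, BlurModel(sigma0_um=sigma_blur, slope_um_per_um=0.0)
        )
        w0 = fwhm(vol.grid.xs, vol.data[0][40, :])
        w1 = fwhm(vol.grid.xs, out.data[0][40, :])
        predicted = math.sqrt(w0**2 + (2.3548 * sigma_blur) ** 2)
        assert w1 == pytest.approx(predicted, rel=0.02)

    def test_stronger_coefficient_broadens_strictly_more(self):
        vol = self._focus_volume()
        w1 = apply_scatter(vol, BlurModel(sigma0_um=0.0, slope_um_per_um=0.02))
        w2 = apply_scatter(vol, BlurModel(sigma0_um=0.0, slope_um_per_um=0.04))
        f1 = fwhm(vol.grid.xs, w1.data[-1][40, :])
        f2 = fwhm(vol.grid.xs, w2.data[-1][40, :])
        assert f2 > f1
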