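"""Geometric incoherent forward simulator for light-field plans.

The opsin integrates light over timescales much longer than one frame, so
the effective 3D illumination is the dwell-weighted, mutually incoherent sum
of every frame's tilted projection.  Under the package's geometric ray model
the intensity at a voxel is

    I(x, y, z) = Σ_f dwell_f · mask_f( (x, y) − z·tanθ·(cos ϕSM_f, sin ϕSM_f) )

i.e. each binary mask is sheared laterally in proportion to depth and
accumulated.  Shear is a lateral translation per z-plane, so in loss-less
mode (no blur, grid covering the sheared masks, lateral voxel pitch equal to
the DMD pixel pitch) every z-plane's summed intensity equals the
dwell-weighted ON-area of the masks.  Diffraction and tissue scattering are
not modeled physically; an optional depth-dependent Gaussian blur stands in
for the qualitative broadening trend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .patterns import LightFieldPlan, OpticalConfig, synthesize_plan

__all__ = [
    "VolumeGrid",
    "IntensityVolume",
    "MisalignmentSpec",
    "BlurModel",
    "render_volume",
    "fwhm",
    "axial_sectioning_curve",
    "simulate_misalignment",
    "apply_scatter",
    "ring_radius",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Regular voxel grid in sample coordinates, centered on a point.

    Axis coordinates are voxel centers: ``x_i = center_x + (i − (nx−1)/2)·dx``
    and similarly for y, z.
    """

    nx: int
    ny: int
    nz: int
    dx: float
    dy: float
    dz: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid dimensions must be positive")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel sizes must be positive")

    @property
    def xs(self) -> np.ndarray:
        return self.center[0] + (np.arange(self.nx) - (self.nx - 1) / 2) * self.dx

    @property
    def ys(self) -> np.ndarray:
        return self.center[1] + (np.arange(self.ny) - (self.ny - 1) / 2) * self.dy

    @property
    def zs(self) -> np.ndarray:
        return self.center[2] + (np.arange(self.nz) - (self.nz - 1) / 2) * self.dz

    def covers(self, x: float, y: float, z: float) -> bool:
        return (
            self.xs[0] <= x <= self.xs[-1]
            and self.ys[0] <= y <= self.ys[-1]
            and self.zs[0] <= z <= self.zs[-1]
        )


@dataclass
class IntensityVolume:
    """Simulated nonnegative intensity grid, stored z-major (nz, ny, nx)."""

    data: np.ndarray
    grid: VolumeGrid
    provenance: dict = field(default_factory=dict)

    def plane_sums(self) -> np.ndarray:
        return self.data.sum(axis=(1, 2))

    def axial_max_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(z coordinates, per-plane maximum intensity)."""
        return self.grid.zs, self.data.max(axis=(1, 2))

    def lateral_profile(self, axis: str, z_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Line profile through the plane's argmax along 'x' or 'y'."""
        plane = self.data[z_index]
        iy, ix = np.unravel_index(np.argmax(plane), plane.shape)
        if axis == "x":
            return self.grid.xs, plane[iy, :]
        if axis == "y":
            return self.grid.ys, plane[:, ix]
        raise ValueError("axis must be 'x' or 'y'")


@dataclass(frozen=True)
class MisalignmentSpec:
    """Phase/amplitude mismatch between DMD masks and scanning mirrors.

    ``phase_offset_rad`` (Δϕ) is added to the mask placement azimuth only;
    ``amp_ratio`` scales the y-galvo amplitude relative to x (1 = circular
    scan, else elliptical → astigmatism).
    """

    phase_offset_rad: float = 0.0
    amp_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not self.amp_ratio > 0:
            raise ValueError("amp_ratio must be > 0")


@dataclass(frozen=True)
class BlurModel:
    """Depth-dependent lateral Gaussian blur surrogate for scattering.

    σ(depth) = sigma0_um + slope_um_per_um · max(depth − entry, 0).
    """

    sigma0_um: float = 0.0
    slope_um_per_um: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.sigma0_um < 0 or self.slope_um_per_um < 0:
            raise ValueError("blur parameters must be >= 0")


def _render_frames(
    frames: list[tuple[np.ndarray, float, float, float]],
    cfg: OpticalConfig,
    grid: VolumeGrid,
    order: int,
) -> np.ndarray:
    """Accumulate sheared masks: frames are (mask, dwell_us, sx, sy) where
    (sx, sy) is the lateral shift in µm per µm of depth."""
    vol = np.zeros((grid.nz, grid.ny, grid.nx), dtype=np.float64)
    xs, ys, zs = grid.xs, grid.ys, grid.zs
    cx = (cfg.dmd_cols - 1) / 2.0
    cy = (cfg.dmd_rows - 1) / 2.0
    for mask, dwell, sx, sy in frames:
        m = mask.astype(np.float64)
        for iz, z in enumerate(zs):
            cols = (xs - z * sx) / cfg.um_per_px + cx
            rows = (ys - z * sy) / cfg.um_per_px + cy
            cc, rr = np.meshgrid(cols, rows)
            vol[iz] += dwell * ndimage.map_coordinates(
                m, [rr, cc], order=order, mode="constant", cval=0.0
            )
    return vol


def render_volume(
    plan: LightFieldPlan,
    grid: VolumeGrid,
    blur: BlurModel | None = None,
    *,
    order: int = 1,
    amp_ratio: float = 1.0,
    warn_uncovered: bool = True,
) -> IntensityVolume:
    """Render the 3D intensity volume produced by a plan.

    ``order`` selects the mask sampling during shear: 1 = bilinear
    (default, continuous sub-voxel shear), 0 = nearest neighbor.  An empty
    plan yields a zero volume.  Intensity units are dwell_us × mask value,
    so in loss-less mode each z-plane sums to Σ_f dwell_f·ON_count(mask_f).
    """
    import warnings

    cfg = plan.config
    if warn_uncovered:
        for t in plan.targets:
            if not grid.covers(t.x_um, t.y_um, t.z_um):
                warnings.warn(f"grid does not cover target {t}", stacklevel=2)
    frames = []
    for f in plan.frames:
        tan_t = math.tan(f.angle.theta)
        sx = tan_t * math.cos(f.angle.phi_sm)
        sy = amp_ratio * tan_t * math.sin(f.angle.phi_sm)
        frames.append((f.mask, f.dwell_us, sx, sy))
    data = _render_frames(frames, cfg, grid, order)
    vol = IntensityVolume(
        data=data,
        grid=grid,
        provenance={
            "n_frames": plan.n_frames,
            "order": order,
            "amp_ratio": amp_ratio,
            "blur": None if blur is None else vars(blur).copy(),
        },
    )
    if blur is not None and blur.enabled:
        vol = apply_scatter(vol, blur)
    return vol


def fwhm(coords: np.ndarray, values: np.ndarray) -> float:
    """Full width at half maximum of a 1D sampled profile, in coordinate
    units, with linear interpolation between bracketing samples.

    The half-maximum crossings are the outermost ones (plateaued maxima are
    spanned).  Reaching the half-maximum exactly counts as a crossing; if
    the profile stays strictly above half-maximum on either side the width
    is undefined (the single-beam, no-axial-sectioning case) and a
    ValueError is raised.
    """
    coords = np.asarray(coords, dtype=float)
    v = np.asarray(values, dtype=float)
    if coords.shape != v.shape or v.ndim != 1 or v.size < 3:
        raise ValueError("profile must be 1D with matching coordinates")
    half = v.max() / 2.0

    def crossing(idx_range) -> float:
        prev = None
        for i in idx_range:
            if v[i] > half:
                if prev is None:  # profile starts above half on this side
                    raise ValueError(
                        "profile never drops to half-maximum: FWHM undefined"
                    )
                if v[prev] == half:
                    return float(coords[prev])
                t = (half - v[prev]) / (v[i] - v[prev])
                return float(coords[prev] + t * (coords[i] - coords[prev]))
            prev = i
        raise ValueError("profile has no half-maximum crossing")

    left = crossing(range(v.size))
    right = crossing(range(v.size - 1, -1, -1))
    return abs(right - left)


def axial_sectioning_curve(
    n_beams: list[int],
    cfg: OpticalConfig,
    grid: VolumeGrid,
    *,
    radius_px: float = 10.0,
    blur: BlurModel | None = None,
) -> dict[int, float]:
    """Axial FWHM of a single centered focus versus the number of beams.

    For each n the single-target plan is rendered with n evenly spaced
    azimuths (same θ and aperture) and the FWHM of the max-intensity
    z-profile is measured.  More beams section more tightly; a single beam
    has no axial sectioning ability and is rejected.
    """
    out: dict[int, float] = {}
    from .patterns import TargetSpot

    for n in n_beams:
        if n < 2:
            raise ValueError("n = 1 has no axial sectioning ability")
        cfg_n = OpticalConfig(
            dmd_cols=cfg.dmd_cols,
            dmd_rows=cfg.dmd_rows,
            um_per_px=cfg.um_per_px,
            theta=cfg.theta,
            n_angles=n,
            stim_ms=cfg.stim_ms,
            wavelength_nm=cfg.wavelength_nm,
        )
        target = TargetSpot(
            x_um=grid.center[0],
            y_um=grid.center[1],
            z_um=grid.center[2],
            radius_px=radius_px,
        )
        plan = synthesize_plan([target], cfg_n)
        vol = render_volume(plan, grid, blur)
        zc, prof = vol.axial_max_profile()
        out[n] = fwhm(zc, prof)
    return out


def simulate_misalignment(
    plan: LightFieldPlan,
    spec: MisalignmentSpec,
    grid: VolumeGrid,
    *,
    order: int = 1,
) -> IntensityVolume:
    """Render a plan with DMD/galvo misalignment applied.

    The phase offset Δϕ rotates each aperture's placement azimuth on its
    sweep circle while the galvo angles are unchanged, so a defocused
    target's beams land on a ring of radius ``2·Δz·tanθ·sin(Δϕ/2)`` at the
    target plane instead of overlapping.  ``amp_ratio ≠ 1`` makes the scan
    elliptical, focusing x- and y-beam pairs at different depths
    (astigmatism).  Identity spec reproduces the aligned render exactly.
    """
    from dataclasses import replace as _dc_replace

    from .patterns import IlluminationAngle, PlanFrame, aperture_center

    cfg = plan.config
    frames = []
    for f in plan.frames:
        shifted = IlluminationAngle(
            phi_sm=(f.angle.phi_sm + spec.phase_offset_rad) % (2 * math.pi),
            theta=f.angle.theta,
        )
        disks = [
            (
                ti,
                aperture_center(
                    plan.targets[ti],
                    shifted,
                    cfg,
                    radius_px=d.radius_px,
                    check_bounds=False,
                ),
            )
            for ti, d in f.disks
        ]
        frames.append(
            PlanFrame(angle=f.angle, dwell_us=f.dwell_us, disks=disks, _cfg=cfg)
        )
    shifted_plan = _dc_replace(plan, frames=frames)
    return render_volume(
        shifted_plan,
        grid,
        order=order,
        amp_ratio=spec.amp_ratio,
        warn_uncovered=False,
    )


def ring_radius(vol: IntensityVolume, target_xy: tuple[float, float], z_index: int) -> float:
    """Intensity-weighted mean radial distance from ``target_xy`` in one
    z-plane; estimates the misalignment ring radius at the target plane."""
    plane = vol.data[z_index]
    total = plane.sum()
    if total <= 0:
        raise ValueError("plane carries no intensity")
    xx, yy = np.meshgrid(vol.grid.xs - target_xy[0], vol.grid.ys - target_xy[1])
    rr = np.hypot(xx, yy)
    return float((plane * rr).sum() / total)


def apply_scatter(
    vol: IntensityVolume, blur: BlurModel, tissue_entry_z: float | None = None
) -> IntensityVolume:
    """Depth-dependent lateral Gaussian smoothing of an intensity volume.

    Planes at or above the tissue entry depth get σ = σ₀; deeper planes get
    σ₀ plus the broadening slope times the traversed depth, so lateral FWHM
    grows monotonically with depth.  With σ₀ = slope = 0 this is the
    identity.
    """
    if not blur.enabled:
        return vol
    entry = vol.grid.zs[0] if tissue_entry_z is None else tissue_entry_z
    out = np.empty_like(vol.data)
    for iz, z in enumerate(vol.grid.zs):
        depth = max(z - entry, 0.0)
        sigma_um = blur.sigma0_um + blur.slope_um_per_um * depth
        if sigma_um == 0.0:
            out[iz] = vol.data[iz]
        else:
            out[iz] = ndimage.gaussian_filter(
                vol.data[iz], sigma=(sigma_um / vol.grid.dy, sigma_um / vol.grid.dx)
            )
    prov = dict(vol.provenance)
    prov["scatter"] = {"sigma0_um": blur.sigma0_um, "slope": blur.slope_um_per_um}
    return IntensityVolume(data=out, grid=vol.grid, provenance=prov)
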