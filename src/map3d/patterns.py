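"""Synthesis of synchronized (illumination angle, DMD mask) frame sequences.

A 3D multi-focus illumination pattern is executed as a short sequence of
frames.  Each frame pairs one illumination angle, set by a pair of scanning
mirrors, with one binary amplitude mask on a digital micromirror device
(DMD) that sits at an image-conjugate plane.  A target spot at defocus
``z_um`` is produced by opening, at every angle, a small circular aperture
displaced from the target's lateral position such that the tilted ray bundle
through the aperture passes through the 3D target point.  Over one sweep of
azimuths the apertures of a defocused target trace a circle of diameter
``D = 2|z| tanθ / um_per_px`` pixels; an in-focus target keeps a constant
aperture.  Superimposing the apertures of many targets in each frame yields
simultaneous multi-site illumination.

Geometry convention (canonical for the whole package): sample coordinates in
µm, right-handed, origin on the optical axis at the native focal plane, +z
pointing deeper into the sample.  A DMD point at lateral position ``p``
illuminates lateral position ``p + z·tanθ·(cos ϕSM, sin ϕSM)`` at depth
``z``, so the aperture center for a target at ``(x, y, z)`` is
``(x, y) − z·tanθ·(cos ϕSM, sin ϕSM)``.  The DMD grid is row-major and
0-based; pixel ``(row, col)`` has its center at
``x = (col − (cols−1)/2)·um_per_px``, ``y = (row − (rows−1)/2)·um_per_px``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OpticalConfig",
    "TargetSpot",
    "IlluminationAngle",
    "ApertureDisk",
    "PlanFrame",
    "LightFieldPlan",
    "PruneResult",
    "OutOfRangeError",
    "aperture_center",
    "frame_azimuths",
    "power_radius",
    "rasterize",
    "synthesize_plan",
    "prune_rays",
]


class OutOfRangeError(ValueError):
    """A target's aperture falls (partially) outside the DMD extent."""


@dataclass(frozen=True)
class OpticalConfig:
    """Static optical/rig parameters shared by all pattern computations.

    Parameters
    ----------
    dmd_cols, dmd_rows
        DMD mirror counts.
    um_per_px
        Size of one DMD pixel demagnified to the sample plane, in µm.
    theta
        Polar illumination half-angle θ in radians, constant across frames
        (all beams lie on one cone); 0 < θ < π/2.
    n_angles
        Number of illumination azimuths per volumetric pattern (default 10).
    stim_ms
        Stimulation dwell per volumetric pattern in ms (default 4); each
        frame dwells ``stim_ms / n_angles``.
    wavelength_nm
        Nominal excitation wavelength; metadata only (used by blur models).
    """

    dmd_cols: int
    dmd_rows: int
    um_per_px: float
    theta: float
    n_angles: int = 10
    stim_ms: float = 4.0
    wavelength_nm: float = 473.0

    def __post_init__(self) -> None:
        if self.dmd_cols < 1 or self.dmd_rows < 1:
            raise ValueError("DMD dimensions must be positive")
        if not self.um_per_px > 0:
            raise ValueError("um_per_px must be > 0")
        if not (0.0 < self.theta < math.pi / 2):
            raise ValueError("theta must satisfy 0 < theta < pi/2")
        if self.n_angles < 2:
            raise ValueError("n_angles must be >= 2")
        if not self.stim_ms > 0:
            raise ValueError("stim_ms must be > 0")

    @property
    def dwell_us(self) -> float:
        """Per-frame dwell time in µs (strictly positive by construction)."""
        return 1000.0 * self.stim_ms / self.n_angles

    @property
    def tan_theta(self) -> float:
        return math.tan(self.theta)

    # --- affine map between DMD pixel indices and sample-plane µm ---

    def px_to_um(self, col: float, row: float) -> tuple[float, float]:
        cx = (self.dmd_cols - 1) / 2.0
        cy = (self.dmd_rows - 1) / 2.0
        return (col - cx) * self.um_per_px, (row - cy) * self.um_per_px

    def um_to_px(self, x_um: float, y_um: float) -> tuple[float, float]:
        cx = (self.dmd_cols - 1) / 2.0
        cy = (self.dmd_rows - 1) / 2.0
        return x_um / self.um_per_px + cx, y_um / self.um_per_px + cy


@dataclass(frozen=True)
class TargetSpot:
    """One 3D illumination target.

    ``z_um`` is the signed defocus Δz: positive below the native focal plane
    (deeper), negative above.  ``radius_px`` is the aperture radius on the
    DMD; ``weight`` is a relative power factor realized by scaling the
    aperture area (power is quadratic in radius).
    """

    x_um: float
    y_um: float
    z_um: float = 0.0
    radius_px: float = 10.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ValueError("radius_px must be >= 1")
        if not self.weight > 0:
            raise ValueError("weight must be > 0")


@dataclass(frozen=True)
class IlluminationAngle:
    """One scanning-mirror pointing: azimuth ϕSM and polar angle θ.

    The equivalent spatial-frequency pair is
    ``(kx, ky) = tanθ·(cos ϕSM, sin ϕSM)`` so that kx² + ky² = tan²θ.
    """

    phi_sm: float
    theta: float

    @property
    def kx(self) -> float:
        return math.tan(self.theta) * math.cos(self.phi_sm)

    @property
    def ky(self) -> float:
        return math.tan(self.theta) * math.sin(self.phi_sm)


@dataclass(frozen=True)
class ApertureDisk:
    """A circular aperture on the DMD, in sub-pixel coordinates.

    ``phi_dmd`` is the disk's azimuth on its target's sweep circle and
    ``sweep_diameter_px`` that circle's diameter D = 2|Δz|·tanθ/um_per_px.
    """

    center_col: float
    center_row: float
    radius_px: float
    phi_dmd: float
    sweep_diameter_px: float


@dataclass
class PlanFrame:
    """One (angle, mask) pair of a plan.

    ``disks`` keeps (target index, disk) provenance so rays can be pruned
    per target after synthesis; ``mask`` is rasterized lazily.
    """

    angle: IlluminationAngle
    dwell_us: float
    disks: list[tuple[int, ApertureDisk]]
    _mask: np.ndarray | None = field(default=None, repr=False)
    _cfg: OpticalConfig | None = field(default=None, repr=False)

    @property
    def mask(self) -> np.ndarray:
        if self._mask is None:
            if self._cfg is None:
                raise ValueError("frame has neither a mask nor a config")
            self._mask = rasterize([d for _, d in self.disks], self._cfg)
        return self._mask


@dataclass
class LightFieldPlan:
    """Executable form of a 3D pattern: ordered (angle, mask) frames."""

    config: OpticalConfig
    targets: list[TargetSpot]
    frames: list[PlanFrame]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def masks(self) -> np.ndarray:
        """Stack of binary masks, shape (n_frames, rows, cols)."""
        return np.stack([f.mask for f in self.frames])


@dataclass
class PruneResult:
    plan: LightFieldPlan
    removed: dict[int, int]  # target index -> number of rays removed


def frame_azimuths(n_angles: int, start_phase: float = math.pi) -> np.ndarray:
    """Evenly spaced sweep azimuths ϕSM over [0, 2π), starting at π.

    The first frame's azimuth is π so that, for a below-plane focus, its
    aperture sits at ϕDMD = 0 (the worked hardware example).
    """
    return (start_phase + 2.0 * math.pi * np.arange(n_angles) / n_angles) % (
        2.0 * math.pi
    )


def aperture_center(
    target: TargetSpot,
    angle: IlluminationAngle,
    cfg: OpticalConfig,
    *,
    radius_px: float | None = None,
    check_bounds: bool = True,
) -> ApertureDisk:
    """Back-project a target along one illumination angle onto the DMD.

    The returned disk's center is the target's lateral DMD position
    displaced by ``|Δz|·tanθ/um_per_px`` pixels along ϕDMD, where
    ϕDMD = ϕSM + π for a below-plane focus (Δz > 0) and ϕDMD = ϕSM for an
    above-plane focus (the π-phase-shift case).  At Δz = 0 the center is
    the target position itself for every angle.
    """
    r = target.radius_px if radius_px is None else radius_px
    tan_t = math.tan(angle.theta)
    # center_um = target_lat − z·tanθ·u(ϕSM); ray through it hits the target.
    dx = -target.z_um * tan_t * math.cos(angle.phi_sm)
    dy = -target.z_um * tan_t * math.sin(angle.phi_sm)
    col, row = cfg.um_to_px(target.x_um + dx, target.y_um + dy)
    offset_px = abs(target.z_um) * tan_t / cfg.um_per_px
    if offset_px > 1e-12:
        phi_dmd = math.atan2(dy, dx) % (2.0 * math.pi)
    else:
        phi_dmd = angle.phi_sm % (2.0 * math.pi)
    disk = ApertureDisk(
        center_col=col,
        center_row=row,
        radius_px=r,
        phi_dmd=phi_dmd,
        sweep_diameter_px=2.0 * offset_px,
    )
    if check_bounds and not _disk_in_bounds(disk, cfg):
        raise OutOfRangeError(
            f"aperture for target ({target.x_um}, {target.y_um}, "
            f"{target.z_um}) µm at phi_sm={angle.phi_sm:.4f} rad falls "
            f"outside the DMD ({cfg.dmd_rows}x{cfg.dmd_cols})"
        )
    return disk


def _disk_in_bounds(disk: ApertureDisk, cfg: OpticalConfig) -> bool:
    return (
        disk.center_col - disk.radius_px >= 0
        and disk.center_col + disk.radius_px <= cfg.dmd_cols - 1
        and disk.center_row - disk.radius_px >= 0
        and disk.center_row + disk.radius_px <= cfg.dmd_rows - 1
    )


def power_radius(base_radius_px: float, factor: float) -> tuple[float, int]:
    """Aperture radius delivering ``factor`` times the power of the base.

    Delivered power scales with disk area, i.e. quadratically with radius,
    so the scaled radius is ``base·√factor``.  Returns ``(exact, rounded)``
    where ``rounded`` is the nearest integer pixel radius (half-up); the
    exact value is kept for simulation use.
    """
    if base_radius_px < 1:
        raise ValueError("base_radius_px must be >= 1")
    if not factor > 0:
        raise ValueError("factor must be > 0")
    exact = base_radius_px * math.sqrt(factor)
    if exact < 1.0:
        raise ValueError(
            f"scaled radius {exact:.3f} px < 1 px: target too dim to render"
        )
    return exact, int(math.floor(exact + 0.5))


def rasterize(disks: list[ApertureDisk], cfg: OpticalConfig) -> np.ndarray:
    """Binary DMD mask: a pixel is ON iff its center lies within any disk.

    Union semantics (no double counting); boundary ties count as ON.
    """
    mask = np.zeros((cfg.dmd_rows, cfg.dmd_cols), dtype=bool)
    for d in disks:
        r = d.radius_px
        c0 = max(0, int(math.floor(d.center_col - r)))
        c1 = min(cfg.dmd_cols - 1, int(math.ceil(d.center_col + r)))
        r0 = max(0, int(math.floor(d.center_row - r)))
        r1 = min(cfg.dmd_rows - 1, int(math.ceil(d.center_row + r)))
        if c1 < c0 or r1 < r0:
            continue
        cols = np.arange(c0, c1 + 1)
        rows = np.arange(r0, r1 + 1)
        cc, rr = np.meshgrid(cols, rows)
        inside = (cc - d.center_col) ** 2 + (rr - d.center_row) ** 2 <= r * r
        mask[r0 : r1 + 1, c0 : c1 + 1] |= inside
    return mask


def synthesize_plan(
    targets: list[TargetSpot],
    cfg: OpticalConfig,
    *,
    start_phase: float = math.pi,
) -> LightFieldPlan:
    """Build the n_angles-frame plan focusing on every target at once.

    Frame ``f`` has azimuth ``ϕSM(f) = π + 2πf/n_angles`` (mod 2π); its mask
    is the union of every target's back-projected aperture at that angle.
    Per-target power weighting is applied by scaling the aperture radius as
    ``radius·√weight`` (area ∝ power).  An empty target list yields all-dark
    masks.
    """
    azimuths = frame_azimuths(cfg.n_angles, start_phase)
    eff_radius = [power_radius(t.radius_px, t.weight)[0] for t in targets]
    frames: list[PlanFrame] = []
    for phi in azimuths:
        angle = IlluminationAngle(phi_sm=float(phi), theta=cfg.theta)
        disks = [
            (i, aperture_center(t, angle, cfg, radius_px=eff_radius[i]))
            for i, t in enumerate(targets)
        ]
        frames.append(
            PlanFrame(angle=angle, dwell_us=cfg.dwell_us, disks=disks, _cfg=cfg)
        )
    return LightFieldPlan(config=cfg, targets=list(targets), frames=frames)


def _ray_segment_hits_sphere(
    p0: np.ndarray, p1: np.ndarray, center: np.ndarray, radius: float
) -> bool:
    """True if the segment p0→p1 passes within ``radius`` of ``center``."""
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0.0:
        t = 0.0
    else:
        t = float(np.clip((center - p0) @ d / denom, 0.0, 1.0))
    closest = p0 + t * d
    return float(np.linalg.norm(center - closest)) <= radius


def prune_rays(
    plan: LightFieldPlan,
    exclusion_zones: list[tuple[tuple[float, float, float], float]],
    *,
    rebalance: bool = False,
) -> PruneResult:
    """Remove beams whose path crosses any exclusion sphere.

    For each (target, frame) pair, the beam is the cylinder of the target's
    aperture radius (in µm) running from the aperture at the native focal
    plane to the target point; it is removed from that frame's mask if it
    intersects any exclusion sphere ``((cx, cy, cz) µm, radius µm)`` over the
    z-range between the native plane and the target.  With ``rebalance``,
    each pruned target's surviving apertures grow by ``√(n/n_remaining)`` to
    restore its total delivered power.
    """
    cfg = plan.config
    removed: dict[int, int] = {i: 0 for i in range(len(plan.targets))}
    kept: list[list[tuple[int, ApertureDisk]]] = []
    for frame in plan.frames:
        kept_f: list[tuple[int, ApertureDisk]] = []
        for ti, disk in frame.disks:
            t = plan.targets[ti]
            x0, y0 = cfg.px_to_um(disk.center_col, disk.center_row)
            p0 = np.array([x0, y0, 0.0])
            p1 = np.array([t.x_um, t.y_um, t.z_um])
            beam_r = disk.radius_px * cfg.um_per_px
            hit = any(
                _ray_segment_hits_sphere(p0, p1, np.asarray(c, float), r + beam_r)
                for c, r in exclusion_zones
            )
            if hit:
                removed[ti] += 1
            else:
                kept_f.append((ti, disk))
        kept.append(kept_f)

    n = plan.n_frames
    unreachable = [i for i, k in removed.items() if k == n]
    if unreachable:
        tgts = ", ".join(str(plan.targets[i]) for i in unreachable)
        raise OutOfRangeError(f"all rays pruned for target(s): {tgts}")

    scale = {
        i: math.sqrt(n / (n - k)) if (rebalance and k) else 1.0
        for i, k in removed.items()
    }
    frames = []
    for frame, kept_f in zip(plan.frames, kept):
        disks = [
            (ti, replace(d, radius_px=d.radius_px * scale[ti]))
            for ti, d in kept_f
        ]
        frames.append(
            PlanFrame(
                angle=frame.angle, dwell_us=frame.dwell_us, disks=disks, _cfg=cfg
            )
        )
    pruned = LightFieldPlan(config=cfg, targets=list(plan.targets), frames=frames)
    return PruneResult(plan=pruned, removed=removed)
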