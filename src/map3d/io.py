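"""File formats: target lists, rig configs, plans, volumes, waveforms,
design matrices, measurements, and maps.

All formats are plain text or TIFF so experiment inputs and outputs
round-trip through the CLI.  Plans export as multi-page 1-bit TIFF (one
page per frame, page order = frame order) with a CSV sidecar
``frame,phi_sm_rad,theta_rad,dwell_us``; volumes as 32-bit float TIFF (one
page per z-plane, z ascending) with a JSON metadata sidecar; waveforms as
CSV and as raw little-endian float32 with a JSON header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .control import WaveformSet
from .netmap.design import ConnectivityMap, MeasurementVector, StimPatternMatrix
from .optsim import IntensityVolume, VolumeGrid
from .patterns import (
    IlluminationAngle,
    LightFieldPlan,
    OpticalConfig,
    PlanFrame,
    TargetSpot,
)

__all__ = [
    "read_targets",
    "write_targets",
    "read_optical_config",
    "save_plan",
    "load_plan",
    "save_volume",
    "load_volume",
    "save_waveforms",
    "save_design",
    "load_design",
    "save_measurements",
    "load_measurements",
    "save_map",
]

TARGET_COLUMNS = ["x_um", "y_um", "z_um", "radius_px", "weight"]


def read_targets(path: str | Path) -> list[TargetSpot]:
    """Target list from CSV (header x_um,y_um,z_um,radius_px,weight) or a
    JSON array of objects with the same keys."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    return [TargetSpot(**{k: float(r[k]) for k in TARGET_COLUMNS}) for r in rows]


def write_targets(targets: list[TargetSpot], path: str | Path) -> None:
    pd.DataFrame(
        [[t.x_um, t.y_um, t.z_um, t.radius_px, t.weight] for t in targets],
        columns=TARGET_COLUMNS,
    ).to_csv(path, index=False)


def read_optical_config(path: str | Path) -> OpticalConfig:
    """Rig configuration from YAML (keys mirror OpticalConfig fields)."""
    data = yaml.safe_load(Path(path).read_text())
    return OpticalConfig(**data)


def save_plan(plan: LightFieldPlan, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    masks = plan.masks().astype(np.uint8)
    tifffile.imwrite(out / "masks.tif", masks, photometric="minisblack")
    pd.DataFrame(
        {
            "frame": np.arange(plan.n_frames),
            "phi_sm_rad": [f.angle.phi_sm for f in plan.frames],
            "theta_rad": [f.angle.theta for f in plan.frames],
            "dwell_us": [f.dwell_us for f in plan.frames],
        }
    ).to_csv(out / "frames.csv", index=False)
    cfg = plan.config
    (out / "config.json").write_text(
        json.dumps(
            {
                "dmd_cols": cfg.dmd_cols,
                "dmd_rows": cfg.dmd_rows,
                "um_per_px": cfg.um_per_px,
                "theta": cfg.theta,
                "n_angles": cfg.n_angles,
                "stim_ms": cfg.stim_ms,
                "wavelength_nm": cfg.wavelength_nm,
            },
            indent=2,
        )
    )
    write_targets(plan.targets, out / "targets.csv")


def load_plan(plan_dir: str | Path) -> LightFieldPlan:
    """Rebuild a renderable plan from an exported plan directory."""
    d = Path(plan_dir)
    cfg = OpticalConfig(**json.loads((d / "config.json").read_text()))
    masks = tifffile.imread(d / "masks.tif").astype(bool)
    if masks.ndim == 2:
        masks = masks[None]
    frames_df = pd.read_csv(d / "frames.csv")
    targets = (
        read_targets(d / "targets.csv") if (d / "targets.csv").exists() else []
    )
    frames = [
        PlanFrame(
            angle=IlluminationAngle(
                phi_sm=float(r.phi_sm_rad), theta=float(r.theta_rad)
            ),
            dwell_us=float(r.dwell_us),
            disks=[],
            _mask=masks[int(r.frame)],
            _cfg=cfg,
        )
        for r in frames_df.itertuples()
    ]
    return LightFieldPlan(config=cfg, targets=targets, frames=frames)


def save_volume(vol: IntensityVolume, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, vol.data.astype(np.float32), photometric="minisblack")
    g = vol.grid
    meta = {
        "grid": {
            "nx": g.nx,
            "ny": g.ny,
            "nz": g.nz,
            "dx": g.dx,
            "dy": g.dy,
            "dz": g.dz,
            "center": list(g.center),
        },
        "provenance": vol.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def load_volume(path: str | Path) -> IntensityVolume:
    path = Path(path)
    data = tifffile.imread(path).astype(np.float64)
    meta = json.loads(path.with_suffix(".json").read_text())
    g = meta["grid"]
    grid = VolumeGrid(
        nx=g["nx"],
        ny=g["ny"],
        nz=g["nz"],
        dx=g["dx"],
        dy=g["dy"],
        dz=g["dz"],
        center=tuple(g["center"]),
    )
    return IntensityVolume(data=data, grid=grid, provenance=meta.get("provenance", {}))


def save_waveforms(ws: WaveformSet, out_dir: str | Path, stem: str = "waves") -> None:
    """CSV (t_s,galvo_x_V,galvo_y_V,dmd_trigger_V,laser_V) plus raw
    little-endian float32 with a JSON header; bit-exact across runs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "t_s": ws.t_s,
            "galvo_x_V": ws.galvo_x,
            "galvo_y_V": ws.galvo_y,
            "dmd_trigger_V": ws.dmd_trigger,
            "laser_V": ws.laser,
        }
    )
    df.to_csv(out / f"{stem}.csv", index=False)
    raw = np.stack([ws.galvo_x, ws.galvo_y, ws.dmd_trigger, ws.laser]).astype(
        "<f4"
    )
    raw.tofile(out / f"{stem}.bin")
    (out / f"{stem}.json").write_text(
        json.dumps(
            {
                "sample_rate_hz": ws.sample_rate_hz,
                "channels": ["galvo_x_V", "galvo_y_V", "dmd_trigger_V", "laser_V"],
                "dtype": "<f4",
                "layout": "channel-major",
                "n_samples": ws.n_samples,
                "epochs": ws.epochs,
            },
            indent=2,
        )
    )


def save_design(design: StimPatternMatrix, out_dir: str | Path) -> None:
    """Compressed sparse CSV (pattern_id,voxel_id) + JSON header."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, cols = np.nonzero(design.A)
    pd.DataFrame({"pattern_id": rows, "voxel_id": cols}).to_csv(
        out / "design.csv", index=False
    )
    (out / "design.json").write_text(
        json.dumps(
            {
                "P": design.P,
                "V": design.V,
                "V_pad": design.V_pad,
                "N": design.n_foci,
                "M": design.repeats,
                "grid_shape": list(design.grid_shape),
                "voxel_um": list(design.voxel_um) if design.voxel_um else None,
                "block_index": design.block_index.tolist(),
            },
            indent=2,
        )
    )


def load_design(in_dir: str | Path) -> StimPatternMatrix:
    d = Path(in_dir)
    hdr = json.loads((d / "design.json").read_text())
    df = pd.read_csv(d / "design.csv")
    A = np.zeros((hdr["P"], hdr["V_pad"]), dtype=np.uint8)
    A[df.pattern_id.to_numpy(), df.voxel_id.to_numpy()] = 1
    return StimPatternMatrix(
        A=A,
        n_foci=hdr["N"],
        repeats=hdr["M"],
        block_index=np.asarray(hdr["block_index"]),
        grid_shape=tuple(hdr["grid_shape"]),
        voxel_um=tuple(hdr["voxel_um"]) if hdr.get("voxel_um") else None,
        real_voxels=hdr["V"],
    )


def save_measurements(y: MeasurementVector, path: str | Path) -> None:
    pd.DataFrame(
        {"pattern_id": np.arange(len(y.y)), "peak_pA": y.y}
    ).to_csv(path, index=False)


def load_measurements(path: str | Path, polarity: str = "EPSC") -> MeasurementVector:
    df = pd.read_csv(path).sort_values("pattern_id")
    return MeasurementVector(y=df.peak_pA.to_numpy(), polarity=polarity)


def save_map(cmap: ConnectivityMap, out_dir: str | Path, stem: str = "map") -> None:
    """CSV of raster-order values plus a float32 TIFF volume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"voxel_id": np.arange(cmap.x.size), "x_pA": cmap.x}).to_csv(
        out / f"{stem}.csv", index=False
    )
    tifffile.imwrite(
        out / f"{stem}.tif",
        cmap.as_volume().astype(np.float32),
        photometric="minisblack",
    )
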