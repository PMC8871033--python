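"""Readers and writers for the pipeline's on-disk formats.

Volumes and solver states travel as NPZ; image stacks as numbered PNG
slices or one multi-page TIFF with a YAML sidecar; fields for external
viewers as legacy-ASCII VTK STRUCTURED_POINTS (readable by ParaView);
reports as JSON/CSV.  All writers are deterministic for fixed inputs so
manifests can hash their outputs.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .domain import ImageStack, PortSpec, VoxelMask

__all__ = [
    "save_mask", "load_mask",
    "write_image_stack", "read_image_stack",
    "save_ports", "load_ports",
    "save_state", "load_state",
    "write_vtk", "write_report",
    "load_config",
]


# ------------------------------------------------------------------- volumes

def save_mask(path, mask: VoxelMask) -> None:
    np.savez_compressed(path, fluid=mask.fluid,
                        periodic=np.array(mask.periodic))


def load_mask(path) -> VoxelMask:
    with np.load(path) as d:
        return VoxelMask(fluid=d["fluid"], periodic=tuple(d["periodic"]))


# -------------------------------------------------------------- image stacks

def write_image_stack(stack: ImageStack, out_dir, fmt: str = "png") -> Path:
    """Write one file per slice (PNG, 16-bit) or a multi-page TIFF
    (float32), plus a YAML sidecar with the spacings."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        for k, img in enumerate(stack.slices):
            data = np.round(img * 65535).astype(np.uint16)
            iio.imwrite(out_dir / f"slice_{k:04d}.png", data)
    elif fmt == "tiff":
        tifffile.imwrite(out_dir / "stack.tiff",
                         stack.slices.astype(np.float32))
    else:
        raise ValueError(f"unknown stack format {fmt!r} (png|tiff)")
    meta = {"pixel_spacing": float(stack.pixel_spacing),
            "slice_spacing": float(stack.slice_spacing),
            "n_slices": int(stack.n_slices), "format": fmt}
    (out_dir / "stack.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return out_dir


def read_image_stack(path) -> ImageStack:
    """Read a stack written by :func:`write_image_stack`, a directory of
    PNGs, or a single multi-page TIFF file."""
    path = Path(path)
    meta = {}
    if path.is_dir():
        sidecar = path / "stack.yaml"
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text())
        tiff = path / "stack.tiff"
        if tiff.exists():
            slices = tifffile.imread(tiff).astype(float)
        else:
            files = sorted(path.glob("slice_*.png")) or sorted(path.glob("*.png"))
            if not files:
                raise FileNotFoundError(f"no slices found under {path}")
            slices = np.stack([iio.imread(f).astype(float) / 65535.0
                               for f in files])
    elif path.suffix.lower() in (".tif", ".tiff"):
        slices = tifffile.imread(path).astype(float)
    else:
        raise ValueError(f"cannot read an image stack from {path}")
    return ImageStack(np.clip(slices, 0.0, 1.0),
                      pixel_spacing=meta.get("pixel_spacing", 1.0),
                      slice_spacing=meta.get("slice_spacing", 1.0))


# --------------------------------------------------------------------- ports

def save_ports(path, ports: dict[str, PortSpec]) -> None:
    doc = {"ports": [p.to_dict() for _, p in sorted(ports.items())]}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_ports(path) -> dict[str, PortSpec]:
    doc = yaml.safe_load(Path(path).read_text())
    return {d["name"]: PortSpec.from_dict(d) for d in doc["ports"]}


# -------------------------------------------------------------- solver state

def save_state(path, result) -> None:
    """Dump a SimulationResult's populations and metadata for restart."""
    np.savez_compressed(
        path,
        f=result.state.f, g=result.state.g,
        steps=result.steps, converged=result.converged,
        omega_f=result.params.omega_f, omega_g=result.params.omega_g,
        temperature=result.params.temperature, rho0=result.params.rho0,
        history=np.array(result.history, dtype=float).reshape(-1, 2),
        diagnostics=json.dumps(_jsonable(result.diagnostics)),
    )


def load_state(path, bmap):
    """Rebuild a SimulationResult against an existing BoundaryMap."""
    from .lbm import (DistributionField, FluidParams, SimulationResult,
                      moments)
    with np.load(path) as d:
        params = FluidParams(omega_f=float(d["omega_f"]),
                             omega_g=float(d["omega_g"]),
                             temperature=float(d["temperature"]),
                             rho0=float(d["rho0"]))
        state = DistributionField(f=d["f"], g=d["g"])
        return SimulationResult(
            fields=moments(state, bmap), state=state, params=params,
            steps=int(d["steps"]), converged=bool(d["converged"]),
            history=[tuple(r) for r in d["history"]],
            diagnostics=json.loads(str(d["diagnostics"])), bmap=bmap,
        )


# ----------------------------------------------------------------------- vtk

def write_vtk(path, fields: dict[str, np.ndarray], spacing: float = 1.0) -> None:
    """Legacy-ASCII VTK STRUCTURED_POINTS with point data.

    ``fields`` maps names to (nx, ny, nz) scalars or (nx, ny, nz, 3)
    vectors, all on one grid.
    """
    if not fields:
        raise ValueError("no fields to write")
    shapes = {v.shape[:3] for v in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one grid")
    nx, ny, nz = shapes.pop()
    lines = [
        "# vtk DataFile Version 3.0",
        "septalflow fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {spacing} {spacing} {spacing}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in sorted(fields.items()):
        # VTK expects x varying fastest
        flat = np.moveaxis(np.asarray(arr, dtype=float), (0, 1, 2), (2, 1, 0))
        if arr.ndim == 3:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(" ".join(f"{v:.9g}" for v in row.ravel())
                         for row in flat.reshape(-1, nx))
        elif arr.ndim == 4 and arr.shape[3] == 3:
            lines.append(f"VECTORS {name} double")
            lines.extend(" ".join(f"{v:.9g}" for v in row.ravel())
                         for row in flat.reshape(-1, nx * 3))
        else:
            raise ValueError(f"field {name!r} is neither scalar nor 3-vector")
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------- reports

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_report(report, out_dir) -> Path:
    """ComparisonReport -> report.json plus CSV tables of the PDFs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(_jsonable(report.to_dict()), indent=2, sort_keys=True))
    for tag, p_open, p_fill in (
        ("entropy", report.entropy_pdf_open, report.entropy_pdf_filled),
        ("speed", report.speed_pdf_open, report.speed_pdf_filled),
    ):
        with open(out_dir / f"pdf_{tag}.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["bin_lo", "bin_hi", "mass_open", "mass_filled"])
            for lo, hi, mo, mf in zip(p_open.edges[:-1], p_open.edges[1:],
                                      p_open.mass, p_fill.mass):
                wr.writerow([f"{lo:.9g}", f"{hi:.9g}",
                             f"{mo:.9g}", f"{mf:.9g}"])
    return out_dir


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
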