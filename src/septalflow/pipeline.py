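"""End-to-end orchestration: phantom -> render -> segment -> simulate
(defect open and filled) -> entropy -> compare.

One validated config drives every stage; every random stage receives an
explicit seed, and a manifest with config and artifact hashes makes reruns
checkable for bit-identity (NPZ/CSV/JSON artifacts are deterministic).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .domain import VoxelMask
from .entropy import compare_pre_post, entropy_of_result
from .geometry import build_boundary_map, classify_nodes
from .lbm import FluidParams, Simulation, SimulationResult, plane_flux
from .phantom import (PhantomConfig, PhantomSpec, make_two_chamber_phantom,
                      render_image_stack)
from .segmentation import segment_stack

__all__ = ["RunConfig", "run_pipeline", "simulate_phantom", "fill_defect",
           "seal_hull", "default_port_pressures"]

log = logging.getLogger("septalflow")

#: default inlet driving for phantom runs: the left (pulmonary-vein) side
#: at higher pressure than the right (vena-cava) side, outlets at the
#: reference density — the pressure ladder that makes blood leak
#: left-to-right through an open defect.
DEFAULT_PORT_PRESSURES = {
    "pulmonary_vein": {"density": 1.03},
    "vena_cava": {"density": 1.01},
}


def default_port_pressures() -> dict:
    return {k: dict(v) for k, v in DEFAULT_PORT_PRESSURES.items()}


@dataclass
class RunConfig:
    """Validated parameters for a full pipeline run."""

    phantom: dict = field(default_factory=dict)
    render: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    seed: int = 0
    simulate_on: str = "ground_truth"     # or "segmented"

    _RENDER_KEYS = {"lumen_intensity", "tissue_intensity", "blur_sigma",
                    "noise_sigma"}
    _SEG_KEYS = {"c1", "c2", "max_iter", "tol"}
    _SIM_KEYS = {"omega_f", "omega_g", "temperature", "rho0",
                 "ports", "max_steps", "conv_tol"}

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config sections: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(sio.load_config(path))

    def validate(self) -> None:
        for name, sect, allowed in (
            ("render", self.render, self._RENDER_KEYS),
            ("segmentation", self.segmentation, self._SEG_KEYS),
            ("simulation", self.simulation, self._SIM_KEYS),
        ):
            bad = set(sect) - allowed
            if bad:
                raise ValueError(f"unknown keys in config section "
                                 f"{name!r}: {sorted(bad)}")
        if self.simulate_on not in ("ground_truth", "segmented"):
            raise ValueError("simulate_on must be ground_truth|segmented")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if "ports" in self.simulation:
            ports = self.simulation["ports"]
            if not isinstance(ports, dict):
                raise ValueError("simulation.ports must map port name -> "
                                 "{speed|velocity|density}")
        # constructing these validates the numeric fields
        PhantomConfig(**{**self.phantom, "defect_open": True})
        self.fluid_params()

    def phantom_config(self, defect_open: bool) -> PhantomConfig:
        return PhantomConfig(**{**self.phantom, "defect_open": defect_open})

    def fluid_params(self) -> FluidParams:
        sim = self.simulation
        return FluidParams(
            omega_f=sim.get("omega_f", 1.0),
            omega_g=sim.get("omega_g", 1.6),
            temperature=sim.get("temperature", 310.0),
            rho0=sim.get("rho0", 1.0),
        )

    def port_config(self) -> dict:
        return self.simulation.get("ports", default_port_pressures())


def seal_hull(mask: VoxelMask, ports) -> VoxelMask:
    """Solidify hull fluid not covered by any port patch.

    Segmented masks reproduce the port openings only approximately; voxels
    that leak past the declared patches are trimmed so the domain closes.
    """
    fluid = mask.fluid.copy()
    keep = np.zeros(mask.shape, dtype=bool)
    for port in ports.values():
        vox = port.hull_voxels(mask)
        if len(vox):
            keep[tuple(vox.T)] = True
    for axis in range(3):
        if mask.periodic[axis]:
            continue
        for face in (0, mask.shape[axis] - 1):
            sl = [slice(None)] * 3
            sl[axis] = face
            layer = tuple(sl)
            fluid[layer] &= keep[layer]
    return VoxelMask(fluid, periodic=mask.periodic)


def fill_defect(mask: VoxelMask, phantom_config: PhantomConfig) -> VoxelMask:
    """Solidify the septum band of a (possibly segmented) mask — the
    surgical 'filling' of the defect."""
    nx = phantom_config.shape[0]
    t = phantom_config.septum_thickness
    x0 = nx // 2
    fluid = mask.fluid.copy()
    fluid[x0 - (t - 1) // 2: x0 + t // 2 + 1, :, :] = False
    return VoxelMask(fluid, periodic=mask.periodic)


def simulate_phantom(
    mask: VoxelMask,
    ports,
    params: FluidParams,
    port_config: dict | None = None,
    max_steps: int = 6000,
    conv_tol: float = 1e-6,
    septum_plane: int | None = None,
) -> SimulationResult:
    """Run one phantom geometry to its quasi-steady state.

    The oxygen field starts stratified by compartment (+1 left of the
    septum plane, -1 right of it) — the state the physiology maintains —
    so the run only has to resolve the flow and the defect-driven mixing,
    not a full washout from scratch.
    """
    bmap = build_boundary_map(classify_nodes(mask, ports))
    sim = Simulation(bmap, params, port_config or default_port_pressures())
    if septum_plane is None:
        septum_plane = mask.shape[0] // 2
    cb0 = np.where(bmap.positions[:, 0] < septum_plane, 1.0, -1.0)
    sim.set_state(rho=params.rho0, cb=cb0)
    return sim.run_to_steady(max_steps=max_steps, conv_tol=conv_tol)


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages and return the manifest (also written to disk).

    Artifacts land under ``out_dir``: the phantom ground truth, the
    rendered stack, the segmented mask, both simulation states, VTK field
    dumps and the comparison report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "artifacts": {}}

    def _register(path: Path) -> None:
        manifest["artifacts"][str(path.relative_to(out))] = _file_hash(path)

    # --- stage 1: phantom geometries -------------------------------------
    log.info("stage phantom: building open and filled geometries")
    ph_open = make_two_chamber_phantom(config.phantom_config(True))
    ph_fill = make_two_chamber_phantom(config.phantom_config(False))
    sio.save_mask(out / "phantom_open.npz", ph_open.ground_truth_mask)
    sio.save_mask(out / "phantom_filled.npz", ph_fill.ground_truth_mask)
    sio.save_ports(out / "ports.yaml", ph_open.port_labels)
    for name in ("phantom_open.npz", "phantom_filled.npz", "ports.yaml"):
        _register(out / name)

    # --- stage 2: render the CT-like stack --------------------------------
    log.info("stage render: seed=%d", config.seed)
    stack = render_image_stack(ph_open, seed=config.seed, **config.render)
    sio.write_image_stack(stack, out / "stack", fmt="tiff")
    _register(out / "stack" / "stack.tiff")

    # --- stage 3: segmentation -------------------------------------------
    log.info("stage segment")
    seg_mask = segment_stack(stack, **config.segmentation)
    sio.save_mask(out / "segmented.npz", seg_mask)
    _register(out / "segmented.npz")
    gt = ph_open.ground_truth_mask.fluid
    jaccard = float((gt & seg_mask.fluid).sum() / (gt | seg_mask.fluid).sum())
    manifest["segmentation"] = {"jaccard_vs_ground_truth": jaccard}
    log.info("segmentation Jaccard vs ground truth: %.4f", jaccard)

    # --- stage 4: simulations ---------------------------------------------
    params = config.fluid_params()
    ports_cfg = config.port_config()
    sim_kw = {
        "max_steps": config.simulation.get("max_steps", 6000),
        "conv_tol": config.simulation.get("conv_tol", 1e-6),
    }
    if config.simulate_on == "segmented":
        open_mask = seal_hull(seg_mask, ph_open.port_labels)
        fill_mask = fill_defect(open_mask, config.phantom_config(False))
    else:
        open_mask = ph_open.ground_truth_mask
        fill_mask = ph_fill.ground_truth_mask
    results = {}
    for tag, mask in (("open", open_mask), ("filled", fill_mask)):
        log.info("stage simulate (%s): %d max steps", tag, sim_kw["max_steps"])
        res = simulate_phantom(mask, ph_open.port_labels, params,
                               ports_cfg, **sim_kw)
        results[tag] = res
        sio.save_state(out / f"state_{tag}.npz", res)
        _register(out / f"state_{tag}.npz")
        fields = {
            "density": res.fields.rho_grid(),
            "velocity": res.bmap.to_grid(res.fields.u, fill=0.0),
            "oxygen": res.fields.cb_grid(),
            "entropy_rate": entropy_of_result(res).s,
        }
        sio.write_vtk(out / f"fields_{tag}.vtk", fields)
        log.info("  %s: steps=%d converged=%s flux_imbalance=%.3e",
                 tag, res.steps, res.converged,
                 res.diagnostics["flux_imbalance"])
        manifest.setdefault("simulation", {})[tag] = {
            "steps": res.steps,
            "converged": res.converged,
            "diagnostics": sio._jsonable(res.diagnostics),
        }

    # --- stage 5: entropy comparison --------------------------------------
    log.info("stage compare")
    report = compare_pre_post(results["open"], results["filled"])
    x0 = ph_open.orifice_plane()
    orifice = {tag: plane_flux(results[tag], 0, x0)
               for tag in ("open", "filled")}
    manifest["comparison"] = sio._jsonable(report.to_dict())
    manifest["comparison"]["orifice_flux"] = sio._jsonable(orifice)
    sio.write_report(report, out / "report")
    for p in sorted((out / "report").iterdir()):
        _register(p)

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
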