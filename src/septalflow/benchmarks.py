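"""Canonical validation runs used by the test suite and the acceptance
script: transport-coefficient recovery, the Poiseuille oracle,
segmentation recovery on the default phantom, and the defect-open vs
defect-filled pair."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .geometry import build_boundary_map, classify_nodes
from .lbm import FluidParams, Simulation
from .phantom import (make_duct, make_periodic_box, make_two_chamber_phantom,
                      render_image_stack)
from .pipeline import default_port_pressures, simulate_phantom
from .segmentation import segment_stack

__all__ = [
    "taylor_green_viscosity",
    "scalar_mode_diffusivity",
    "poiseuille_l2_error",
    "segmentation_recovery",
    "phantom_pair",
]


def taylor_green_viscosity(n=64, omega_f=1.0, u0=0.02, steps=400, every=20):
    """Fit the kinematic viscosity from the kinetic-energy decay of a
    Taylor-Green vortex: u ~ exp(-2 nu k^2 t), E ~ exp(-4 nu k^2 t)."""
    bmap = build_boundary_map(classify_nodes(make_periodic_box(n)))
    k = 2 * np.pi / n
    pos = bmap.positions.astype(float)
    x, y = pos[:, 0] * k, pos[:, 1] * k
    u = np.zeros((bmap.n_nodes, 3))
    u[:, 0] = u0 * np.sin(x) * np.cos(y)
    u[:, 1] = -u0 * np.cos(x) * np.sin(y)
    rho = 1.0 - (3 * u0**2 / 4) * (np.cos(2 * x) + np.cos(2 * y))
    sim = Simulation(bmap, FluidParams(omega_f=omega_f))
    sim.set_state(rho=rho, u=u)
    ts, energy = [], []
    for s in range(0, steps + 1, every):
        if s:
            sim.step(every)
        mac = sim.macroscopic()
        energy.append(float((mac.rho * (mac.u**2).sum(axis=1)).sum()))
        ts.append(s)
    # discard the initial acoustic transient
    slope = np.polyfit(ts[2:], np.log(energy[2:]), 1)[0]
    return -slope / (4 * k * k)


def scalar_mode_diffusivity(n=64, omega_g=1.0, steps=600, every=30):
    """Fit the scalar diffusivity from a decaying sinusoidal C_b mode in
    quiescent fluid: amplitude ~ exp(-alpha k^2 t)."""
    bmap = build_boundary_map(classify_nodes(make_periodic_box(n)))
    k = 2 * np.pi / n
    x = bmap.positions[:, 0].astype(float)
    basis = np.sin(k * x)
    sim = Simulation(bmap, FluidParams(omega_f=1.0, omega_g=omega_g))
    sim.set_state(rho=1.0, cb=0.5 * basis)
    ts, amps = [], []
    for s in range(0, steps + 1, every):
        if s:
            sim.step(every)
        amps.append(float(2 * np.mean(sim.macroscopic().cb * basis)))
        ts.append(s)
    slope = np.polyfit(ts, np.log(np.abs(amps)), 1)[0]
    return -slope / (k * k)


def poiseuille_l2_error(nx=40, ny=4, nz=19, omega_f=1.0, umax=0.03):
    """Steady parabolic-inlet channel vs the analytic profile."""
    mask, ports = make_duct(nx, ny, nz, wall_axis=2, flow_axis=0)
    bmap = build_boundary_map(classify_nodes(mask, ports))
    zc = (nz - 1) / 2
    half = (nz - 2) / 2
    b = bmap.ports["inlet"]
    z = bmap.positions[b.nodes][:, 2].astype(float)
    vel = np.zeros((len(b.nodes), 3))
    vel[:, 0] = umax * (1 - ((z - zc) / half) ** 2)
    sim = Simulation(bmap, FluidParams(omega_f=omega_f),
                     {"inlet": {"velocity": vel}})
    sim.set_state()
    res = sim.run_to_steady(max_steps=8000, conv_tol=1e-9)
    pos = bmap.positions
    sel = (pos[:, 0] == nx // 2) & (pos[:, 1] == 1)
    zl = pos[sel][:, 2].astype(float)
    ux = res.fields.u[sel, 0]
    ana = umax * (1 - ((zl - zc) / half) ** 2)
    return float(np.linalg.norm(ux - ana) / np.linalg.norm(ana))


def segmentation_recovery(seed=20, tol=0.10):
    """Segment the rendered default phantom (blur 1 voxel, noise 0.05)
    with C1 = 1, C2 = 0.7; return (Jaccard, mean symmetric surface
    distance in voxels) against the ground truth."""
    spec = make_two_chamber_phantom(defect_open=True)
    stack = render_image_stack(spec, blur_sigma=1.0, noise_sigma=0.05,
                               seed=seed)
    seg = segment_stack(stack, c1=1.0, c2=0.7, tol=tol)
    gt = spec.ground_truth_mask.fluid
    sf = seg.fluid
    jaccard = (gt & sf).sum() / (gt | sf).sum()

    def surface(m):
        return m & ~ndimage.binary_erosion(m)

    sg, ss = surface(gt), surface(sf)
    dg = ndimage.distance_transform_edt(~sg)
    ds = ndimage.distance_transform_edt(~ss)
    msd = (dg[ss].sum() + ds[sg].sum()) / (ss.sum() + sg.sum())
    return float(jaccard), float(msd)


def phantom_pair(max_steps=6000):
    """Defect-open and defect-filled runs on the default 48^3 phantom with
    identical driving (pressure-ladder inlets), compartment-stratified
    initial oxygen.  Returns {tag: (PhantomSpec, SimulationResult)}."""
    out = {}
    for tag, is_open in (("open", True), ("filled", False)):
        spec = make_two_chamber_phantom(defect_open=is_open, port_radius=5.0)
        res = simulate_phantom(
            spec.ground_truth_mask, spec.port_labels,
            FluidParams(omega_f=1.0, omega_g=1.6),
            default_port_pressures(), max_steps=max_steps, conv_tol=1e-9)
        out[tag] = (spec, res)
    return out
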