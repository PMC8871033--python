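"""Synthetic benchmark geometries and CT-like image stacks.

The central object is a two-chamber septal-defect phantom: two ellipsoidal
lumens separated by a planar septum, with a cylindrical orifice through the
septum that is either open (pre-operative defect) or filled (post-operative),
two inlet tubes (a low-oxygen "vena cava" and a high-oxygen "pulmonary
vein") and two outlet tubes reaching the domain hull.  It reproduces the
topology that matters for septal-defect hemodynamics — a jet through a hole
in the wall between a high-pressure and a low-pressure chamber — with none
of the anatomical detail of a real heart.

Simple all-fluid boxes and plane channels are provided as oracle fixtures
for the flow solver (equilibrium invariance, Taylor–Green decay, Poiseuille
profiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .domain import ImageStack, PortSpec, VoxelMask

__all__ = [
    "PhantomConfig",
    "PhantomSpec",
    "make_periodic_box",
    "make_channel",
    "make_duct",
    "make_two_chamber_phantom",
    "render_image_stack",
]


def make_periodic_box(n: int) -> VoxelMask:
    """All-fluid cube with full periodicity — the bulk-flow oracle fixture."""
    if n < 4:
        raise ValueError(f"periodic box needs n >= 4, got {n}")
    return VoxelMask(np.ones((n, n, n), dtype=bool), periodic=(True, True, True))


def make_channel(nx: int, ny: int, nz: int, wall_axis: int = 2) -> VoxelMask:
    """Plane channel: 1-voxel solid walls on both faces normal to
    ``wall_axis``, periodic along the other two axes."""
    shape = (nx, ny, nz)
    if wall_axis not in (0, 1, 2):
        raise ValueError("wall_axis must be 0, 1 or 2")
    if shape[wall_axis] < 5:
        raise ValueError(
            f"channel needs >= 5 voxels along the wall axis (got {shape[wall_axis]}): "
            "two walls plus at least three fluid layers"
        )
    fluid = np.ones(shape, dtype=bool)
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[wall_axis] = 0
    hi[wall_axis] = shape[wall_axis] - 1
    fluid[tuple(lo)] = False
    fluid[tuple(hi)] = False
    periodic = tuple(a != wall_axis for a in range(3))
    return VoxelMask(fluid, periodic=periodic)


def make_duct(
    nx: int, ny: int, nz: int, wall_axis: int = 2, flow_axis: int = 0
) -> tuple[VoxelMask, dict[str, PortSpec]]:
    """Plane channel with velocity-inlet/outlet ports on the ``flow_axis``
    faces (periodic along the remaining axis).  Used for flux-balance and
    Poiseuille-profile runs driven through ports rather than periodicity."""
    if wall_axis == flow_axis:
        raise ValueError("wall_axis and flow_axis must differ")
    mask = make_channel(nx, ny, nz, wall_axis=wall_axis)
    periodic = [a not in (wall_axis, flow_axis) for a in range(3)]
    mask.periodic = tuple(periodic)
    shape = mask.shape
    # in-plane coords on a flow face are the two non-flow axes in sorted order
    inplane = tuple(a for a in range(3) if a != flow_axis)
    center = tuple((shape[a] - 1) / 2.0 for a in inplane)
    radius = float(np.hypot(*[shape[a] for a in inplane])) + 1.0  # whole face
    ports = {
        "inlet": PortSpec("inlet", "inlet", "free", flow_axis, 0, center, radius),
        "outlet": PortSpec("outlet", "outlet", "free", flow_axis, 1, center, radius),
    }
    return mask, ports


@dataclass
class PhantomConfig:
    """Geometry of the two-chamber phantom, all lengths in voxels.

    Defaults define a 48^3 domain with chamber semi-axes (12, 15, 15),
    a 4-voxel septum and a radius-3 orifice — a lumped stand-in for an
    atrial/ventricular septal defect at a resolution a desktop run resolves.
    The septum is kept at least 4x the default rendering blur so the wall
    survives partial-volume smearing in the synthetic CT stack.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    chamber_semi_axes: tuple[float, float, float] = (12.0, 15.0, 15.0)
    chamber_offset: float = 10.0       # chamber centres at x0 -/+ offset
    septum_thickness: int = 4
    orifice_radius: float = 3.0
    orifice_center: tuple[float, float] | None = None   # (y, z); default mid
    defect_open: bool = True
    port_radius: float = 4.0

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        if min(self.shape) < 16:
            raise ValueError("phantom domain must be at least 16 voxels per axis")
        if self.septum_thickness < 1:
            raise ValueError("septum_thickness must be >= 1 voxel")
        _, by, bz = self.chamber_semi_axes
        if self.orifice_radius >= min(by, bz):
            raise ValueError(
                "orifice_radius must be smaller than the septum in-plane extent"
            )
        if self.orifice_radius < 0:
            raise ValueError("orifice_radius must be >= 0")


@dataclass
class PhantomSpec:
    """A realized phantom: ground-truth mask, port patches and provenance."""

    config: PhantomConfig
    ground_truth_mask: VoxelMask
    port_labels: dict[str, PortSpec]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.config.shape

    @property
    def defect_open(self) -> bool:
        return self.config.defect_open

    def orifice_plane(self) -> int:
        """x-index of the septum mid-plane (where orifice flux is measured)."""
        return self.config.shape[0] // 2


def _cylinder(shape, axis: int, c1: float, c2: float, radius: float,
              lo: int, hi: int) -> np.ndarray:
    """Solid cylinder along ``axis`` between indices [lo, hi], in-plane
    centre (c1, c2) over the two remaining axes in sorted order."""
    grids = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    inplane = [a for a in range(3) if a != axis]
    r2 = (grids[inplane[0]] - c1) ** 2 + (grids[inplane[1]] - c2) ** 2
    along = grids[axis]
    return (r2 <= radius**2) & (along >= lo) & (along <= hi)


def make_two_chamber_phantom(config: PhantomConfig | None = None, **kwargs) -> PhantomSpec:
    """Build the two-chamber septal-defect phantom.

    With ``defect_open=False`` the orifice voxels are solid (the defect is
    "filled") and the two lumens form separate fluid components; with the
    defect open and ``orifice_radius >= 1`` the lumen is a single component.
    """
    if config is None:
        config = PhantomConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a PhantomConfig or keyword fields, not both")
    nx, ny, nz = config.shape
    x0 = nx // 2
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    ax, by, bz = config.chamber_semi_axes
    xl, xr = x0 - config.chamber_offset, x0 + config.chamber_offset

    X, Y, Z = np.ogrid[0:nx, 0:ny, 0:nz]
    left = ((X - xl) / ax) ** 2 + ((Y - cy) / by) ** 2 + ((Z - cz) / bz) ** 2 <= 1.0
    right = ((X - xr) / ax) ** 2 + ((Y - cy) / by) ** 2 + ((Z - cz) / bz) ** 2 <= 1.0
    fluid = left | right

    # planar septum: a solid slab of the requested thickness centred on x0
    t = config.septum_thickness
    band_lo = x0 - (t - 1) // 2
    band_hi = x0 + t // 2
    fluid[band_lo:band_hi + 1, :, :] = False

    # cylindrical orifice through the septum (one voxel of overlap each side
    # so the hole actually joins the chambers)
    oy, oz = config.orifice_center if config.orifice_center else (cy, cz)
    if config.defect_open and config.orifice_radius >= 0.5:
        hole = _cylinder(config.shape, 0, oy, oz, config.orifice_radius,
                         band_lo - 1, band_hi + 1)
        fluid |= hole

    # port tubes: inlets along -y reaching the y=0 face, outlets along +z
    # reaching the z top face; one pair per chamber
    rp = config.port_radius
    fluid |= _cylinder(config.shape, 1, xl, cz, rp, 0, int(cy))       # pulmonary vein
    fluid |= _cylinder(config.shape, 1, xr, cz, rp, 0, int(cy))       # vena cava
    fluid |= _cylinder(config.shape, 2, xl, cy, rp, int(cz), nz - 1)  # aorta
    fluid |= _cylinder(config.shape, 2, xr, cy, rp, int(cz), nz - 1)  # pulmonary artery

    # the septum seals the slab again (tubes must not pierce it)
    fluid[band_lo:band_hi + 1, :, :] = False
    if config.defect_open and config.orifice_radius >= 0.5:
        fluid |= hole

    # closed hull except the port openings
    fluid[0, :, :] = fluid[-1, :, :] = False
    fluid[:, -1, :] = False
    fluid[:, :, 0] = False

    ports = {
        "pulmonary_vein": PortSpec("pulmonary_vein", "inlet", "high", 1, 0, (xl, cz), rp),
        "vena_cava": PortSpec("vena_cava", "inlet", "low", 1, 0, (xr, cz), rp),
        "aorta": PortSpec("aorta", "outlet", "free", 2, 1, (xl, cy), rp),
        "pulmonary_artery": PortSpec("pulmonary_artery", "outlet", "free", 2, 1, (xr, cy), rp),
    }
    mask = VoxelMask(fluid, periodic=(False, False, False))
    spec = PhantomSpec(config=config, ground_truth_mask=mask, port_labels=ports)
    _validate_phantom(spec)
    return spec


def _validate_phantom(spec: PhantomSpec) -> None:
    mask = spec.ground_truth_mask
    cfg = spec.config
    labels, n = mask.fluid_components()
    expected = 1 if (cfg.defect_open and cfg.orifice_radius >= 0.5) else 2
    if n != expected:
        raise ValueError(
            f"phantom has {n} fluid components, expected {expected} "
            f"(defect_open={cfg.defect_open}, orifice_radius={cfg.orifice_radius})"
        )
    seen: set[tuple[int, int, int]] = set()
    for port in spec.port_labels.values():
        vox = port.hull_voxels(mask)
        if len(vox) == 0:
            raise ValueError(f"port {port.name} does not touch the fluid hull")
        keys = set(map(tuple, vox.tolist()))
        if keys & seen:
            raise ValueError(f"port {port.name} overlaps another port")
        seen |= keys


def render_image_stack(
    phantom: PhantomSpec,
    lumen_intensity: float = 0.9,
    tissue_intensity: float = 0.1,
    blur_sigma: float = 1.0,
    noise_sigma: float = 0.05,
    seed: int = 0,
) -> ImageStack:
    """Render a CT-like grayscale stack of the phantom.

    The binary ground truth is mapped to the two intensities, blurred with an
    isotropic Gaussian (partial-volume effect) and perturbed with clipped
    additive Gaussian noise from a seeded generator, so identical seeds give
    byte-identical stacks.
    """
    for name, v in (("lumen_intensity", lumen_intensity),
                    ("tissue_intensity", tissue_intensity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if lumen_intensity == tissue_intensity:
        raise ValueError("lumen and tissue intensities must differ")
    if blur_sigma < 0 or noise_sigma < 0:
        raise ValueError("blur_sigma and noise_sigma must be >= 0")

    vol = np.where(phantom.ground_truth_mask.fluid, lumen_intensity, tissue_intensity)
    if blur_sigma > 0:
        vol = ndimage.gaussian_filter(vol, sigma=blur_sigma, mode="nearest")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sigma, size=vol.shape)
    vol = np.clip(vol, 0.0, 1.0)
    return ImageStack(np.moveaxis(vol, 2, 0))
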