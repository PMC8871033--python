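"""Node classification and per-link boundary map for the D3Q19 solver.

A voxel mask plus port patches become (a) a per-voxel label (solid, fluid,
inlet, outlet) and (b) gather tables that express one full streaming step —
bulk propagation, half-way bounce-back for the flow population and
specular-adiabatic reflection for the scalar population — as a single
indexed gather per population.

Walls live mid-link (half-way bounce-back convention): the solid voxel
layer is the wall, which places the no-slip plane second-order accurately
half a spacing inside the last fluid node.

For the scalar population a wall link is reflected specularly: the
post-collision value travels one step along the tangential velocity
c_i* = (c_i + c_i')/2 and arrives in the wall-mirrored direction i'.  This
is only well defined where the wall is locally flat with an unambiguous
axis normal; links at corners, edges and other ambiguous configurations
fall back to plain bounce-back (c_i* = 0, i' = opposite), which is the
zero-flux rule for purely normal links anyway and conserves scalar mass.
A repair pass demotes any specular assignment that would collide with or
orphan another link's target, so that after construction every incoming
population at every fluid node has exactly one source — the property that
makes total scalar mass exactly conserved in closed domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain import PortSpec, VoxelMask
from . import lattice

__all__ = [
    "NodeClassification",
    "BoundaryMap",
    "PortBinding",
    "LeakyDomainError",
    "classify_nodes",
    "build_boundary_map",
]

SOLID, FLUID, INLET, OUTLET = 0, 1, 2, 3
_LABEL_NAMES = {SOLID: "solid", FLUID: "fluid", INLET: "inlet", OUTLET: "outlet"}


class LeakyDomainError(ValueError):
    """Fluid reaches the open hull outside any port patch."""


@dataclass
class NodeClassification:
    """Per-voxel label plus the port patches that produced it."""

    labels: np.ndarray                  # uint8 (nx, ny, nz)
    ports: dict[str, PortSpec]
    port_voxels: dict[str, np.ndarray]  # name -> (n, 3) coordinates
    periodic: tuple[bool, bool, bool]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def count(self, label: int) -> int:
        return int((self.labels == label).sum())


def classify_nodes(mask: VoxelMask,
                   ports: dict[str, PortSpec] | None = None) -> NodeClassification:
    """Label every voxel as solid, fluid, inlet or outlet.

    Fluid voxels on a non-periodic hull face must be covered by a port
    patch; any that are not make the domain leaky and raise
    :class:`LeakyDomainError` listing the offending voxels.
    """
    ports = dict(ports or {})
    if mask.n_fluid == 0:
        raise ValueError("mask has no fluid voxels")
    labels = np.where(mask.fluid, FLUID, SOLID).astype(np.uint8)
    port_voxels: dict[str, np.ndarray] = {}
    claimed = np.zeros(mask.shape, dtype=bool)
    for name, port in ports.items():
        vox = port.hull_voxels(mask)
        if len(vox) == 0:
            raise ValueError(
                f"port {name!r} does not intersect fluid on its hull face "
                "(is the patch off-hull or misplaced?)"
            )
        if claimed[tuple(vox.T)].any():
            raise ValueError(f"port {name!r} overlaps another port")
        claimed[tuple(vox.T)] = True
        labels[tuple(vox.T)] = INLET if port.role == "inlet" else OUTLET
        # every port voxel needs an interior fluid neighbour along the normal
        n = port.inward_normal().astype(int)
        inner = vox + n
        ok = mask.fluid[tuple(inner.T)]
        if not ok.all():
            raise ValueError(
                f"port {name!r}: {int((~ok).sum())} voxels have no interior "
                "fluid neighbour along the port normal"
            )
        port_voxels[name] = vox

    leaks = []
    for axis in range(3):
        if mask.periodic[axis]:
            continue
        for face_idx in (0, mask.shape[axis] - 1):
            sl = [slice(None)] * 3
            sl[axis] = face_idx
            layer = labels[tuple(sl)]
            bad = np.nonzero(layer == FLUID)
            for i, j in zip(*bad):
                coord = [0, 0, 0]
                coord[axis] = face_idx
                a, b = [x for x in range(3) if x != axis]
                coord[a], coord[b] = int(i), int(j)
                leaks.append(tuple(coord))
    if leaks:
        shown = ", ".join(map(str, leaks[:10]))
        more = f" (+{len(leaks) - 10} more)" if len(leaks) > 10 else ""
        raise LeakyDomainError(
            f"{len(leaks)} fluid voxels on the open hull are not covered by "
            f"any port: {shown}{more}"
        )
    return NodeClassification(labels=labels, ports=ports,
                              port_voxels=port_voxels, periodic=mask.periodic)


@dataclass
class PortBinding:
    """Solver-side view of one port: node ids and inward geometry."""

    spec: PortSpec
    nodes: np.ndarray        # flat node ids of the port voxels
    interior: np.ndarray     # flat node ids of the interior neighbours
    normal: np.ndarray       # inward unit normal (3,)


@dataclass
class BoundaryMap:
    """Streaming gather tables plus per-wall-link metadata.

    ``src_f[n*19 + i]`` (resp. ``src_g``) is the flat (node, direction)
    index whose post-collision value becomes population i of node n after
    streaming.  Wall-link arrays describe each fluid-to-solid link: the
    reflected index, the estimated axis normal (or -1 when ambiguous), the
    mirror index i' and the tangential velocity c_i* actually applied.
    """

    shape: tuple[int, int, int]
    node_index: np.ndarray       # int64 (nx,ny,nz), -1 at solid voxels
    positions: np.ndarray        # (Nn, 3) voxel coordinates per node
    labels_flat: np.ndarray      # per-node label (FLUID/INLET/OUTLET)
    src_f: np.ndarray            # int64 (Nn*19,)
    src_g: np.ndarray            # int64 (Nn*19,)
    link_node: np.ndarray        # wall links: fluid node id
    link_dir: np.ndarray         # wall links: direction i into the solid
    link_normal_axis: np.ndarray # axis of the snapped normal, -1 ambiguous
    link_normal_sign: np.ndarray # +1 wall on the high side, -1 low side, 0 n/a
    link_mirror: np.ndarray      # i' used for the scalar reflection
    link_specular: np.ndarray    # bool: specular applied (else bounce-back)
    ports: dict[str, PortBinding] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def n_wall_links(self) -> int:
        return self.link_node.shape[0]

    def tangential_velocity(self, k: int) -> np.ndarray:
        """c_i* of wall link k: (c_i + c_i')/2."""
        return (lattice.C[self.link_dir[k]] + lattice.C[self.link_mirror[k]]) // 2

    def to_grid(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter per-node values back onto the voxel grid."""
        out_shape = self.shape + values.shape[1:]
        out = np.full(out_shape, fill, dtype=float)
        out[tuple(self.positions.T)] = values
        return out


def _neighbor_ids(node_index: np.ndarray, pos: np.ndarray, c: np.ndarray,
                  periodic: tuple[bool, bool, bool]) -> np.ndarray:
    """Flat node id of pos + c per node (-1 if solid or out of bounds)."""
    shape = node_index.shape
    q = pos + c
    ok = np.ones(len(pos), dtype=bool)
    for a in range(3):
        if periodic[a]:
            q[:, a] %= shape[a]
        else:
            ok &= (q[:, a] >= 0) & (q[:, a] < shape[a])
    out = np.full(len(pos), -1, dtype=np.int64)
    out[ok] = node_index[tuple(q[ok].T)]
    return out


def build_boundary_map(cls: NodeClassification) -> BoundaryMap:
    """Construct gather tables and wall-link metadata from a classification."""
    labels = cls.labels
    shape = labels.shape
    nonsolid = labels != SOLID
    node_index = np.full(shape, -1, dtype=np.int64)
    pos = np.argwhere(nonsolid)
    node_index[tuple(pos.T)] = np.arange(len(pos))
    Nn = len(pos)
    labels_flat = labels[tuple(pos.T)]
    is_port = labels_flat != FLUID

    Q = lattice.Q
    # neighbour table: nbr[n, i] = node id of pos + c_i, -1 if solid/out
    nbr = np.stack(
        [_neighbor_ids(node_index, pos, lattice.C[i], cls.periodic)
         for i in range(Q)], axis=1)

    # in-domain tests for forward and backward steps on non-periodic axes
    in_domain_fwd = np.ones((Nn, Q), dtype=bool)
    in_domain_bwd = np.ones((Nn, Q), dtype=bool)
    for a in range(3):
        if not cls.periodic[a]:
            step = lattice.C[:, a][None, :]
            fwd = pos[:, a][:, None] + step
            bwd = pos[:, a][:, None] - step
            in_domain_fwd &= (fwd >= 0) & (fwd < shape[a])
            in_domain_bwd &= (bwd >= 0) & (bwd < shape[a])

    # bulk streaming (pull): population i of node n comes from upstream
    # node pos - c_i; a solid upstream marks a wall slot to be filled below,
    # an out-of-domain upstream can only occur at port voxels on the hull
    # (classify_nodes vetoes other hull fluid), whose populations are fully
    # rewritten each step anyway
    upstream = np.stack(
        [_neighbor_ids(node_index, pos, -lattice.C[i], cls.periodic)
         for i in range(Q)], axis=1)
    out_of_domain = ~in_domain_bwd
    if (out_of_domain & ~is_port[:, None] & (upstream < 0)).any():
        raise AssertionError("non-port node with out-of-domain upstream link")
    src = upstream * Q + np.arange(Q)
    self_src = np.arange(Nn)[:, None] * Q + np.arange(Q)[None, :]
    src[upstream < 0] = self_src[upstream < 0]
    src_f = src.copy()
    src_g = src.copy()

    # wall links: (node, i) with the c_i neighbour solid inside the domain
    wall = (nbr < 0) & in_domain_fwd
    wall[:, 0] = False
    link_node, link_dir = np.nonzero(wall)

    # axis-snapped normal: unambiguous iff exactly one of the six axis
    # neighbours is solid
    axis_dirs = np.array([lattice._index_of(v) for v in
                          ([1, 0, 0], [-1, 0, 0], [0, 1, 0],
                           [0, -1, 0], [0, 0, 1], [0, 0, -1])])
    solid_axis = wall[:, axis_dirs] | ((nbr[:, axis_dirs] < 0) & ~in_domain_fwd[:, axis_dirs])
    n_solid_axis = solid_axis.sum(axis=1)
    norm_axis = np.full(Nn, -1, dtype=np.int64)
    norm_sign = np.zeros(Nn, dtype=np.int64)
    unamb = n_solid_axis == 1
    which = np.argmax(solid_axis[unamb], axis=1)
    norm_axis[unamb] = which // 2
    norm_sign[unamb] = np.where(which % 2 == 0, 1, -1)  # +1: solid on high side

    # tentative assignment per link: specular where geometry allows
    nl = len(link_node)
    bb_slot = link_node * Q + lattice.OPP[link_dir]
    mirror = lattice.OPP[link_dir].copy()      # fallback: bounce-back
    specular = np.zeros(nl, dtype=bool)
    target = bb_slot.copy()

    la = norm_axis[link_node]
    ls = norm_sign[link_node]
    cdir = lattice.C[link_dir]                 # (nl, 3)
    diag = (cdir != 0).sum(axis=1) == 2
    # link must lean into the snapped wall: its normal component points at it
    into = np.zeros(nl, dtype=bool)
    valid = la >= 0
    into[valid] = cdir[valid, la[valid]] == ls[valid]
    cand = valid & diag & into
    if cand.any():
        idx = np.nonzero(cand)[0]
        mi = lattice.MIRROR[la[idx], link_dir[idx]]
        cstar = (lattice.C[link_dir[idx]] + lattice.C[mi]) // 2
        dest = np.full(len(idx), -1, dtype=np.int64)
        for k, (n_id, cs) in enumerate(zip(link_node[idx], cstar)):
            i_cs = _CSTAR_DIR.get(tuple(cs))
            dest[k] = nbr[n_id, i_cs] if i_cs is not None else -1
        ok = dest >= 0
        idx, mi, dest = idx[ok], mi[ok], dest[ok]
        specular[idx] = True
        mirror[idx] = mi
        target[idx] = dest * Q + mi

    # repair: demote specular links until every wall slot is filled exactly
    # once (overfull slots and orphaned bounce-back slots cascade)
    n_slots = Nn * Q
    for _ in range(1000):
        counts = np.bincount(target, minlength=n_slots)
        # port slots don't participate: they are rewritten by the port update
        bad_over = specular & (counts[target] > 1)
        bad_orphan = specular & (counts[bb_slot] == 0)
        bad = bad_over | bad_orphan
        if not bad.any():
            break
        specular[bad] = False
        mirror[bad] = lattice.OPP[link_dir[bad]]
        target[bad] = bb_slot[bad]
    else:
        raise AssertionError("boundary-map repair did not converge")

    # write wall sources; slots at port nodes may be imperfectly matched but
    # are overwritten every step, so they are excluded from the exactness check
    src_f[link_node, lattice.OPP[link_dir]] = link_node * Q + link_dir
    src_g.reshape(-1)[target] = link_node * Q + link_dir

    counts = np.bincount(target, minlength=n_slots)
    slot_is_wall = np.zeros(n_slots, dtype=bool)
    slot_is_wall[bb_slot] = True
    fluid_slot = np.repeat(~is_port, Q)
    check = slot_is_wall & fluid_slot
    if not (counts[check] == 1).all():
        raise AssertionError("scalar wall slots not perfectly matched")

    ports: dict[str, PortBinding] = {}
    for name, port in cls.ports.items():
        vox = cls.port_voxels[name]
        nodes = node_index[tuple(vox.T)]
        normal = port.inward_normal().astype(int)
        interior = node_index[tuple((vox + normal).T)]
        ports[name] = PortBinding(spec=port, nodes=nodes, interior=interior,
                                  normal=port.inward_normal())

    return BoundaryMap(
        shape=shape, node_index=node_index, positions=pos,
        labels_flat=labels_flat,
        src_f=src_f.reshape(-1), src_g=src_g.reshape(-1),
        link_node=link_node, link_dir=link_dir,
        link_normal_axis=la, link_normal_sign=ls,
        link_mirror=mirror, link_specular=specular,
        ports=ports,
    )


#: map a tangential velocity vector to its lattice direction index
_CSTAR_DIR = {tuple(lattice.C[i]): i for i in range(lattice.Q)}
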