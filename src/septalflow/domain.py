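"""Shared spatial containers: voxel masks, image stacks and port patches.

Conventions used throughout the package: volumes are indexed ``[x, y, z]``,
voxel-centred, 0-based; an image stack holds one 2-D slice per z-plane with
slice ``k`` equal to ``volume[:, :, k]``.  Lattice units (voxel spacing 1)
are used everywhere inside the solver; physical spacing only matters at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: 26-connectivity structuring element used for fluid connected components.
CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VoxelMask:
    """Binary flow domain: True = fluid (lumen), False = solid (tissue)."""

    fluid: np.ndarray
    periodic: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self) -> None:
        self.fluid = np.asarray(self.fluid, dtype=bool)
        if self.fluid.ndim != 3:
            raise ValueError("VoxelMask.fluid must be a 3-D boolean array")
        self.periodic = tuple(bool(p) for p in self.periodic)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fluid.shape

    @property
    def n_fluid(self) -> int:
        return int(self.fluid.sum())

    @property
    def n_solid(self) -> int:
        return int((~self.fluid).sum())

    def fluid_components(self) -> tuple[np.ndarray, int]:
        """Label fluid connected components with 26-connectivity."""
        labels, n = ndimage.label(self.fluid, structure=CONN26)
        return labels, int(n)


@dataclass
class ImageStack:
    """Grayscale slice stack, intensities in [0, 1].

    ``slices[k]`` is the 2-D image of z-plane ``k`` with shape (nx, ny).
    ``slice_spacing`` is expressed in units of the in-plane pixel spacing.
    """

    slices: np.ndarray
    pixel_spacing: float = 1.0
    slice_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3:
            raise ValueError("ImageStack.slices must be (n_slices, nx, ny)")
        if self.slices.min() < -1e-12 or self.slices.max() > 1 + 1e-12:
            raise ValueError("image intensities must lie in [0, 1]")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    def volume(self) -> np.ndarray:
        """Return the stack as an (nx, ny, nz) volume."""
        return np.moveaxis(self.slices, 0, 2)


# in-plane axes for a hull face normal to each axis
_INPLANE = {0: (1, 2), 1: (0, 2), 2: (0, 1)}


@dataclass
class PortSpec:
    """Circular inlet/outlet patch on one hull face of the domain.

    ``axis``/``side`` pick the face (side 0 → index 0, side 1 → last index);
    ``center`` and ``radius`` are in-plane voxel coordinates on that face.
    ``oxygen_class`` encodes the scalar boundary value: 'low' → C_b = -1
    (vena cava), 'high' → C_b = +1 (pulmonary vein), 'free' → zero-gradient.
    """

    name: str
    role: str                      # 'inlet' | 'outlet'
    oxygen_class: str              # 'low' | 'high' | 'free'
    axis: int                      # face normal axis (0, 1, 2)
    side: int                      # 0 = low face, 1 = high face
    center: tuple[float, float]    # in-plane coords on the face
    radius: float

    def __post_init__(self) -> None:
        if self.role not in ("inlet", "outlet"):
            raise ValueError(f"port {self.name}: role must be inlet|outlet")
        if self.oxygen_class not in ("low", "high", "free"):
            raise ValueError(f"port {self.name}: oxygen_class must be low|high|free")
        if self.axis not in (0, 1, 2) or self.side not in (0, 1):
            raise ValueError(f"port {self.name}: invalid face")

    @property
    def cb_value(self) -> float | None:
        return {"low": -1.0, "high": 1.0, "free": None}[self.oxygen_class]

    def inward_normal(self) -> np.ndarray:
        n = np.zeros(3)
        n[self.axis] = 1.0 if self.side == 0 else -1.0
        return n

    def face_index(self, shape: tuple[int, int, int]) -> int:
        return 0 if self.side == 0 else shape[self.axis] - 1

    def hull_voxels(self, mask: VoxelMask) -> np.ndarray:
        """(n, 3) integer coordinates of fluid voxels inside the patch."""
        a, b = _INPLANE[self.axis]
        k = self.face_index(mask.shape)
        face = [slice(None)] * 3
        face[self.axis] = k
        layer = mask.fluid[tuple(face)]
        ii, jj = np.nonzero(layer)
        r2 = (ii - self.center[0]) ** 2 + (jj - self.center[1]) ** 2
        ii, jj = ii[r2 <= self.radius**2], jj[r2 <= self.radius**2]
        out = np.empty((len(ii), 3), dtype=np.int64)
        out[:, self.axis] = k
        out[:, a] = ii
        out[:, b] = jj
        return out

    def to_dict(self) -> dict:
        return {
            "name": self.name, "role": self.role,
            "oxygen_class": self.oxygen_class, "axis": int(self.axis),
            "side": int(self.side), "center": [float(c) for c in self.center],
            "radius": float(self.radius),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PortSpec":
        return cls(
            name=d["name"], role=d["role"], oxygen_class=d["oxygen_class"],
            axis=int(d["axis"]), side=int(d["side"]),
            center=tuple(d["center"]), radius=float(d["radius"]),
        )
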