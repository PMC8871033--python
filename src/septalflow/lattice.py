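"""D3Q19 lattice constants.

The velocity set has one rest vector, six face vectors of squared length 1
and twelve edge vectors of squared length 2, with weights 1/3, 1/18 and 1/36
respectively and lattice sound speed ``cs^2 = 1/3`` (lattice units,
``dx = dt = 1``).  Index tables for the opposite direction (bounce-back) and
for mirroring about an axis-aligned wall plane (specular reflection of the
scalar population) are precomputed here.
"""

from __future__ import annotations

import numpy as np

Q = 19
CS2 = 1.0 / 3.0

# rest; 6 face; 12 edge — order fixed so tests and dumps are reproducible.
C = np.array(
    [
        (0, 0, 0),
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        (1, 1, 0), (1, -1, 0), (-1, 1, 0), (-1, -1, 0),
        (1, 0, 1), (1, 0, -1), (-1, 0, 1), (-1, 0, -1),
        (0, 1, 1), (0, 1, -1), (0, -1, 1), (0, -1, -1),
    ],
    dtype=np.int64,
)

W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)


def _index_of(v: np.ndarray) -> int:
    hits = np.where((C == v).all(axis=1))[0]
    if len(hits) != 1:
        raise ValueError(f"{v} is not a D3Q19 velocity")
    return int(hits[0])


#: OPP[i] is the direction with c = -c_i.
OPP = np.array([_index_of(-C[i]) for i in range(Q)], dtype=np.int64)

#: MIRROR[a, i] is the direction obtained by flipping component ``a`` of c_i
#: — the reflection of direction i about a wall plane normal to axis ``a``.
MIRROR = np.empty((3, Q), dtype=np.int64)
for _a in range(3):
    for _i in range(Q):
        _v = C[_i].copy()
        _v[_a] = -_v[_a]
        MIRROR[_a, _i] = _index_of(_v)


def tangential_velocity(i: int, axis: int) -> np.ndarray:
    """c_i* = (c_i + c_i')/2 for a wall with normal along ``axis``.

    This is the in-plane component of c_i; for D3Q19 it is itself a lattice
    vector (zero for purely normal links).
    """
    return (C[i] + C[MIRROR[axis, i]]) // 2
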