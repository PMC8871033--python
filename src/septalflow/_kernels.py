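"""Numba inner loops for the D3Q19 double-distribution solver.

Kept deliberately tiny: one fused BGK collision over both populations and
one indexed gather that realizes streaming plus all wall reflections (the
gather tables are precomputed in :mod:`septalflow.geometry`).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def bgk_collide(f: np.ndarray, g: np.ndarray,
                cx: np.ndarray, cy: np.ndarray, cz: np.ndarray,
                w: np.ndarray, omega_f: float, omega_g: float) -> None:
    """In-place BGK relaxation of f (flow) and g (scalar) toward the
    second-order Maxwell equilibria."""
    n_nodes = f.shape[0]
    q = f.shape[1]
    for n in range(n_nodes):
        rho = 0.0
        mx = 0.0
        my = 0.0
        mz = 0.0
        gs = 0.0
        for i in range(q):
            fi = f[n, i]
            rho += fi
            mx += fi * cx[i]
            my += fi * cy[i]
            mz += fi * cz[i]
            gs += g[n, i]
        ux = mx / rho
        uy = my / rho
        uz = mz / rho
        usq = ux * ux + uy * uy + uz * uz
        for i in range(q):
            cu = cx[i] * ux + cy[i] * uy + cz[i] * uz
            com = 1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq
            feq = w[i] * rho * com
            geq = w[i] * gs * com        # gs = rho * C_b
            f[n, i] += omega_f * (feq - f[n, i])
            g[n, i] += omega_g * (geq - g[n, i])


@njit(cache=True)
def gather(src: np.ndarray, fin: np.ndarray, fout: np.ndarray) -> None:
    """fout.flat[k] = fin.flat[src[k]] — streaming as one indexed gather."""
    a = fin.reshape(-1)
    b = fout.reshape(-1)
    for k in range(src.shape[0]):
        b[k] = a[src[k]]
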