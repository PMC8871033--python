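"""Reaction-diffusion boundary extraction from grayscale slice stacks.

An indicator field R in [0, 1] grows out of seed points by grayscale-gated
diffusion,

    dR/dt = max{0, C1 (I - 1) + 1} * laplacian(R),

where I in [0, 1] is the local image intensity.  With the default C1 = 1 the
growth factor is simply I: the front races through bright lumen, slows
through the blurred wall and crawls in dark tissue.  After each explicit
step every voxel with R above the acceleration threshold C2 (default 0.7)
is set to 1 and stays there, so the extracted region grows monotonically.

Evolution stops once the largest diffusion update max|dR| (measured before
thresholding, over not-yet-extracted voxels) stays below ``tol`` for
``window`` consecutive iterations, or at ``max_iter``.  The update at the
front scales with the local growth factor, so ``tol`` is effectively a
brake tied to intensity: with the defaults the front halts where I has
fallen to roughly half the lumen level — the blurred half-intensity
surface, which is the boundary being sought.  The persistence window
bridges the bursty quiet intervals of threshold-accelerated growth.

The object boundary is then read off as the 0.5 level set of R per slice,
and the per-slice contours are fused into a 3-D voxel mask via signed
distance fields, inter-slice linear interpolation and a 3x3x3 median filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw, filters, measure

from .domain import ImageStack, VoxelMask

__all__ = [
    "SegmentationState",
    "ExtractedContour",
    "evolve_region",
    "extract_contours",
    "integrate_stack",
    "find_seeds",
    "segment_stack",
]

#: explicit pseudo-time step; < 1/4 stability bound of the 5-point
#: unit-spacing 2-D Laplacian with a growth factor <= 1.
DT = 0.2


@dataclass
class SegmentationState:
    """Result of one slice evolution."""

    R: np.ndarray
    c1: float
    c2: float
    iterations: int
    converged: bool
    dt: float = DT


@dataclass
class ExtractedContour:
    """Closed 0.5-level polylines of one slice, in continuous pixel coords
    (row, col) as produced by marching squares."""

    slice_index: int
    polylines: list[np.ndarray]
    shape: tuple[int, int]

    @property
    def n_contours(self) -> int:
        return len(self.polylines)


def evolve_region(
    image: np.ndarray,
    seeds,
    c1: float = 1.0,
    c2: float = 0.7,
    max_iter: int = 2000,
    tol: float = 0.10,
    window: int = 40,
    seed_radius: int = 2,
) -> SegmentationState:
    """Grow the indicator field R from ``seeds`` over one 2-D slice.

    ``seeds`` is either a boolean mask or an (n, 2) array of (row, col)
    pixel indices; seed pixels are held at R = 1 throughout.  Point seeds
    are dilated to disks of ``seed_radius`` pixels — an isolated pinned
    pixel feeds the diffusion too slowly to ever launch a front.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("evolve_region expects a single 2-D slice")
    if image.min() < -1e-12 or image.max() > 1 + 1e-12:
        raise ValueError("image must be normalized to [0, 1]")
    if c1 < 0:
        raise ValueError("C1 must be >= 0")
    if not 0.0 < c2 < 1.0:
        raise ValueError("C2 must lie in (0, 1)")

    seed_mask = np.zeros(image.shape, dtype=bool)
    seeds = np.asarray(seeds)
    if seeds.dtype == bool:
        if seeds.shape != image.shape:
            raise ValueError("boolean seed mask must match the image shape")
        seed_mask |= seeds
    else:
        pts = np.atleast_2d(seeds)
        if pts.size == 0:
            raise ValueError("seeds must be nonempty")
        if (pts < 0).any() or (pts[:, 0] >= image.shape[0]).any() or (
            pts[:, 1] >= image.shape[1]
        ).any():
            raise ValueError("seed points fall outside the image")
        seed_mask[pts[:, 0].astype(int), pts[:, 1].astype(int)] = True
        if seed_radius > 0:
            seed_mask = ndimage.binary_dilation(
                seed_mask, iterations=seed_radius)
    if not seed_mask.any():
        raise ValueError("seeds must be nonempty")

    factor = np.maximum(0.0, c1 * (image - 1.0) + 1.0)
    R = np.zeros_like(image)
    R[seed_mask] = 1.0
    fixed = seed_mask.copy()   # seeds plus every voxel accelerated to 1

    converged = False
    it = 0
    quiet = 0                  # consecutive iterations with max|dR| < tol
    for it in range(1, max_iter + 1):
        lap = ndimage.laplace(R, mode="nearest")
        step = DT * factor * lap
        step[fixed] = 0.0
        delta = float(np.max(np.abs(step)))
        R = np.clip(R + step, 0.0, 1.0)
        fixed |= R > c2
        R[fixed] = 1.0
        quiet = quiet + 1 if delta < tol else 0
        if quiet >= window:
            converged = True
            break
    return SegmentationState(R=R, c1=c1, c2=c2, iterations=it, converged=converged)


def extract_contours(R: np.ndarray, level: float = 0.5,
                     slice_index: int = 0) -> ExtractedContour:
    """Marching-squares isolines of R at ``level``.

    Saddle cells are resolved with scikit-image's ``fully_connected='high'``
    rule: ambiguous cells are connected through the above-level (object)
    side.  A constant field yields an empty contour set.
    """
    R = np.asarray(R, dtype=float)
    if R.min() < -1e-12 or R.max() > 1 + 1e-12:
        raise ValueError("R must lie in [0, 1]")
    if R.min() >= level or R.max() <= level:
        # the level is never crossed (e.g. constant fields): no contours
        return ExtractedContour(slice_index=slice_index, polylines=[],
                                shape=R.shape)
    # pad below-level so regions touching the image border still close
    padded = np.pad(R, 1, mode="constant", constant_values=0.0)
    polylines = [
        c - 1.0
        for c in measure.find_contours(padded, level=level, fully_connected="high")
        if len(c) >= 3 and np.allclose(c[0], c[-1])
    ]
    return ExtractedContour(slice_index=slice_index, polylines=polylines,
                            shape=R.shape)


def _rasterize(contour: ExtractedContour) -> np.ndarray:
    """Fill closed polylines to a binary slice (even-odd rule via XOR, so
    nested contours produce holes)."""
    m = np.zeros(contour.shape, dtype=bool)
    for poly in contour.polylines:
        m ^= draw.polygon2mask(contour.shape, poly)
    return m


_FAR = 1e6


def _signed_distance(m: np.ndarray) -> np.ndarray:
    """Positive inside, negative outside; large sentinels for empty/full."""
    if not m.any():
        return np.full(m.shape, -_FAR)
    if m.all():
        return np.full(m.shape, _FAR)
    inside = ndimage.distance_transform_edt(m)
    outside = ndimage.distance_transform_edt(~m)
    return inside - outside


def integrate_stack(
    contours: list[ExtractedContour],
    slice_spacing: float = 1.0,
    median_size: int = 3,
) -> VoxelMask:
    """Fuse per-slice contours into a watertight 3-D fluid mask.

    Each slice is rasterized and converted to a signed distance field;
    fields are linearly interpolated between slices onto unit-spaced
    z-planes, thresholded at zero and median-filtered.
    """
    if len(contours) < 2:
        raise ValueError("need at least 2 slices to integrate a stack")
    if not any(c.n_contours for c in contours):
        raise ValueError("all slices are empty — nothing to integrate")
    shape2d = contours[0].shape
    if any(c.shape != shape2d for c in contours):
        raise ValueError("all slices must share one shape")
    if slice_spacing <= 0:
        raise ValueError("slice_spacing must be positive")

    sdf = np.stack([_signed_distance(_rasterize(c)) for c in contours])
    k = np.arange(len(contours)) * slice_spacing
    nz = int(round(k[-1])) + 1
    z = np.arange(nz, dtype=float)
    # linear interpolation of the sdf stack along z
    idx = np.clip(np.searchsorted(k, z, side="right") - 1, 0, len(k) - 2)
    w = (z - k[idx]) / (k[idx + 1] - k[idx])
    interp = sdf[idx] * (1.0 - w)[:, None, None] + sdf[idx + 1] * w[:, None, None]
    fluid = np.moveaxis(interp > 0.0, 0, 2)
    if median_size > 1:
        fluid = ndimage.median_filter(fluid, size=median_size)
    return VoxelMask(fluid, periodic=(False, False, False))


def find_seeds(stack: ImageStack, min_area: int = 9,
               core_depth: float = 2.0) -> list[np.ndarray]:
    """Automatic per-slice seeding masks.

    The whole stack is thresholded with Otsu; per slice, each bright
    component of at least ``min_area`` pixels is seeded on its interior
    core — pixels at least ``core_depth`` inside the component (always
    including its single most interior point, so thin structures are kept).
    Seeding the whole core instead of one centre point launches the growth
    front near the boundary everywhere at once, which keeps evolution
    times, and hence slow leakage into tissue, uniform across structures
    of very different size.
    """
    thr = filters.threshold_otsu(stack.slices)
    seeds_per_slice: list[np.ndarray] = []
    for img in stack.slices:
        bright = img > thr
        labels, n = ndimage.label(bright)
        mask = np.zeros(img.shape, dtype=bool)
        for lab in range(1, n + 1):
            comp = labels == lab
            if comp.sum() < min_area:
                continue
            d = ndimage.distance_transform_edt(comp)
            core = d >= core_depth
            if not core.any():
                core = d == d.max()
            mask |= core
        seeds_per_slice.append(mask)
    return seeds_per_slice


def segment_stack(
    stack: ImageStack,
    c1: float = 1.0,
    c2: float = 0.7,
    max_iter: int = 2000,
    tol: float = 0.10,
    seeds: list[np.ndarray] | None = None,
    tol_window: int = 40,
) -> VoxelMask:
    """End-to-end slice-stack segmentation: seed, evolve, contour, fuse."""
    if seeds is None:
        seeds = find_seeds(stack)
    if len(seeds) != stack.n_slices:
        raise ValueError("need one seed array per slice")
    contours: list[ExtractedContour] = []
    for k, img in enumerate(stack.slices):
        sk = np.asarray(seeds[k])
        empty = not sk.any() if sk.dtype == bool else sk.size == 0
        if empty:
            contours.append(ExtractedContour(k, [], img.shape))
            continue
        state = evolve_region(img, sk, c1=c1, c2=c2,
                              max_iter=max_iter, tol=tol, window=tol_window)
        contours.append(extract_contours(state.R, level=0.5, slice_index=k))
    return integrate_stack(contours, slice_spacing=stack.slice_spacing)
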