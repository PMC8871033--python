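import numpy as np
import pytest
from scipy import ndimage

from septalflow.domain import ImageStack
from septalflow.segmentation import (ExtractedContour, evolve_region,
                                     extract_contours, find_seeds,
                                     integrate_stack, segment_stack)


def _disk_image(n=64, r=20.0, lumen=0.9, background=0.1):
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    disk = (xx - c) ** 2 + (yy - c) ** 2 <= r * r
    return np.where(disk, lumen, background), c, disk


class TestEvolveRegion:
    def test_uniform_bright_image_fills_the_whole_domain(self):
        """Growth factor 1 everywhere: diffusion plus acceleration sweep R
        to 1 over the connected domain."""
        img = np.ones((24, 24))
        st = evolve_region(img, np.array([[12, 12]]), max_iter=5000, tol=1e-9)
        assert np.allclose(st.R, 1.0)

    def test_uniform_dark_image_freezes_outside_the_seeds(self):
        """I = 0 with C1 = 1 gives growth factor max(0, 0) = 0: nothing
        evolves away from the seed disk."""
        img = np.zeros((24, 24))
        st = evolve_region(img, np.array([[12, 12]]), max_iter=200)
        seeded = st.R == 1.0
        assert seeded.sum() <= 13  # the dilated seed disk only
        assert np.all(st.R[~seeded] == 0.0)

    def test_disk_contour_lands_on_the_true_boundary(self):
        """On a bright disk over dark background the final 0.5 contour lies
        within one pixel of the analytic circle."""
        img, c, _ = _disk_image()
        st = evolve_region(img, np.array([[int(c), int(c)]]))
        cont = extract_contours(st.R)
        assert cont.n_contours == 1
        d = np.hypot(cont.polylines[0][:, 0] - c, cont.polylines[0][:, 1] - c)
        assert np.abs(d - 20.0).max() < 1.0 + 0.15  # sub-pixel + rasterization

    def test_indicator_stays_in_unit_interval_and_grows_monotonically(self):
        img, c, _ = _disk_image(n=48, r=12)
        rng = np.random.default_rng(0)
        img = np.clip(img + rng.normal(0, 0.05, img.shape), 0, 1)
        seeds = np.array([[24, 24]])
        short = evolve_region(img, seeds, max_iter=40, window=10**9)
        long_ = evolve_region(img, seeds, max_iter=160, window=10**9)
        for st in (short, long_):
            assert st.R.min() >= 0.0 and st.R.max() <= 1.0
        # the extracted set {R = 1} never shrinks with more iterations
        assert ((short.R == 1.0) <= (long_.R == 1.0)).all()

    def test_input_validation(self):
        img = np.ones((8, 8))
        with pytest.raises(ValueError):
            evolve_region(img, np.empty((0, 2)))
        with pytest.raises(ValueError):
            evolve_region(img, np.array([[20, 2]]))
        with pytest.raises(ValueError):
            evolve_region(img * 2.0, np.array([[4, 4]]))
        with pytest.raises(ValueError):
            evolve_region(img, np.array([[4, 4]]), c1=-1.0)


class TestExtractContours:
    def test_binary_disk_gives_one_closed_contour_of_right_length(self):
        _, c, disk = _disk_image()
        cont = extract_contours(disk.astype(float))
        assert cont.n_contours == 1
        poly = cont.polylines[0]
        assert np.allclose(poly[0], poly[-1])
        # binary input: marching squares cuts every boundary cell at its
        # midpoints, overshooting a smooth circle's length by a few percent
        length = np.sum(np.hypot(*np.diff(poly, axis=0).T))
        assert abs(length - 2 * np.pi * 20.0) / (2 * np.pi * 20.0) < 0.08

    @pytest.mark.parametrize("value", [0.0, 1.0])
    def test_constant_fields_have_no_interior_contours(self, value):
        R = np.full((16, 16), value)
        assert extract_contours(R).n_contours == 0


class TestIntegrateStack:
    def _disk_contour(self, r, n=40, k=0):
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        disk = ((xx - c) ** 2 + (yy - c) ** 2 <= r * r).astype(float)
        return extract_contours(disk, slice_index=k)

    def test_identical_disks_integrate_to_a_cylinder(self):
        n_slices, r = 12, 10.0
        contours = [self._disk_contour(r, k=k) for k in range(n_slices)]
        mask = integrate_stack(contours)
        expect = np.pi * r * r * n_slices
        assert abs(mask.n_fluid - expect) / expect < 0.05

    def test_shrinking_disks_give_monotone_cross_sections(self):
        radii = np.linspace(14, 4, 11)
        contours = [self._disk_contour(r, k=k) for k, r in enumerate(radii)]
        mask = integrate_stack(contours, median_size=1)
        areas = mask.fluid.sum(axis=(0, 1))
        assert (np.diff(areas.astype(int)) <= 0).all()

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            integrate_stack([self._disk_contour(5.0)])

    def test_all_empty_rejected(self):
        empty = [ExtractedContour(k, [], (16, 16)) for k in range(4)]
        with pytest.raises(ValueError):
            integrate_stack(empty)


class TestStackSegmentation:
    def test_recovers_a_blurred_noisy_sphere(self):
        """End-to-end on a synthetic ball: auto-seeding, evolution, contour
        fusion recover the volume with high overlap."""
        n, r = 40, 13.0
        x, y, z = np.mgrid[0:n, 0:n, 0:n]
        c = (n - 1) / 2
        gt = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= r * r
        rng = np.random.default_rng(5)
        vol = np.where(gt, 0.9, 0.1)
        vol = ndimage.gaussian_filter(vol, 1.0)
        vol = np.clip(vol + rng.normal(0, 0.05, vol.shape), 0, 1)
        stack = ImageStack(np.moveaxis(vol, 2, 0))
        seeds = find_seeds(stack)
        assert any(np.asarray(s).any() for s in seeds)
        mask = segment_stack(stack)
        jac = (gt & mask.fluid).sum() / (gt | mask.fluid).sum()
        assert jac > 0.88
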