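"""Box counting, dimension fitting, and regime segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hydrofractal as hf
from hydrofractal.boxcount import dyadic_sizes
from hydrofractal.relaxation_models import DomainError

from conftest import brute_force_box_count


class TestCounts:
    def test_full_image_exact_tiling(self):
        img = hf.make_box_model("full", 256)
        res = hf.box_count(img, sizes=[1, 4, 64, 256])
        assert res.counts[0] == 65536
        assert res.counts[-1] == 1
        np.testing.assert_array_equal(res.counts, (256 / res.box_sizes) ** 2)

    def test_size_one_counts_occupied_cells(self):
        rng = np.random.default_rng(2)
        occ = rng.random((40, 40)) < 0.2
        res = hf.box_count(hf.BinaryImage2D(occupancy=occ), sizes=[1, 2])
        assert res.counts[0] == occ.sum()

    def test_matches_brute_force_on_random_3d_grid(self):
        rng = np.random.default_rng(3)
        occ = rng.random((32, 32, 32)) < 0.02
        res = hf.box_count(hf.VoxelGrid3D(occupancy=occ), sizes=[1, 2, 4, 8, 16, 32])
        for s, n in zip(res.box_sizes, res.counts):
            assert n == brute_force_box_count(occ, int(s))

    def test_non_dyadic_size_with_ceiling_tiling(self):
        occ = np.ones((10, 10), dtype=bool)
        res = hf.box_count(hf.BinaryImage2D(occupancy=occ), sizes=[1, 3, 7])
        assert res.counts[1] == 16  # ceil(10/3)^2
        assert res.counts[2] == 4   # ceil(10/7)^2

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_nesting_bound(self, seed):
        """N(s) <= N(s/2) <= 2^dim N(s) on random 2-D and 3-D grids."""
        rng = np.random.default_rng(seed)
        ndim = 2 if seed % 2 else 3
        shape = (32,) * ndim
        occ = rng.random(shape) < 0.1
        if not occ.any():
            occ.flat[0] = True
        grid = hf.BinaryImage2D(occupancy=occ) if ndim == 2 else hf.VoxelGrid3D(occupancy=occ)
        res = hf.box_count(grid, sizes=[1, 2, 4, 8, 16])
        for i in range(len(res.counts) - 1):
            assert res.counts[i + 1] <= res.counts[i] <= 2**ndim * res.counts[i + 1]

    def test_default_sizes_stop_below_grid_size(self):
        assert dyadic_sizes((512, 512)) == [1, 2, 4, 8, 16, 32, 64, 128, 256]
        assert dyadic_sizes((160, 160, 457)) == [1, 2, 4, 8, 16, 32, 64, 128, 256]

    def test_offset_averaging_is_monotone(self):
        rng = np.random.default_rng(4)
        occ = rng.random((64, 64)) < 0.05
        res = hf.box_count(hf.BinaryImage2D(occupancy=occ), origin_policy="averaged")
        assert np.all(np.diff(res.counts) <= 0)
        assert res.grid_origin_policy == "averaged"

    def test_input_errors(self):
        empty = np.zeros((8, 8), dtype=bool)
        with pytest.raises(DomainError):
            hf.box_count(hf.BinaryImage2D(occupancy=empty))
        occ = np.ones((8, 8), dtype=bool)
        with pytest.raises(DomainError):
            hf.box_count(hf.BinaryImage2D(occupancy=occ), sizes=[0, 2])
        with pytest.raises(DomainError):
            hf.box_count(hf.BinaryImage2D(occupancy=occ), sizes=[2, 16])


class TestFitDimension:
    def test_full_box_dimension_exact(self):
        res = hf.box_count(hf.make_box_model("full", 256))
        D, err = hf.fit_dimension(res)
        assert D == pytest.approx(2.0, abs=1e-12)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_half_box_shifts_line_not_slope(self):
        full = hf.box_count(hf.make_box_model("full", 512))
        half = hf.box_count(hf.make_box_model("half", 512))
        D_full, _ = hf.fit_dimension(full)
        D_half, _ = hf.fit_dimension(half)
        assert abs(D_half - 2.0) <= 0.1
        assert D_half == pytest.approx(D_full, abs=0.1)
        # the count line is shifted down by exactly the area ratio
        np.testing.assert_allclose(half.counts / full.counts, 0.5)

    def test_single_occupied_row_is_one_dimensional(self):
        occ = np.zeros((256, 256), dtype=bool)
        occ[17, :] = True
        D, _ = hf.fit_dimension(hf.box_count(hf.BinaryImage2D(occupancy=occ)))
        assert D == pytest.approx(1.0, abs=1e-12)

    def test_size_range_restriction_and_min_points(self):
        res = hf.box_count(hf.make_box_model("full", 256))
        D, _ = hf.fit_dimension(res, size_range=(4, 64))
        assert D == pytest.approx(2.0, abs=1e-12)
        with pytest.raises(DomainError):
            hf.fit_dimension(res, size_range=(64, 128))


class TestSegmentRegimes:
    def test_thin_line_two_regimes(self, line_image):
        reg = hf.segment_regimes(hf.box_count(line_image))
        assert reg.slope_small == pytest.approx(2.0, abs=1e-9)
        assert reg.slope_large == pytest.approx(1.0, abs=1e-9)
        assert reg.breakpoint_size == pytest.approx(2.0, abs=1e-6)
        assert not reg.single_regime

    def test_thin_line_grid_method_agrees(self, line_image):
        reg = hf.segment_regimes(hf.box_count(line_image), method="grid")
        assert reg.breakpoint_size == 2
        assert reg.slope_small == pytest.approx(2.0, abs=1e-9)
        assert reg.slope_large == pytest.approx(1.0, abs=1e-9)

    def test_sphere_chain_regimes(self, chain_counts):
        """Volume scaling below the sphere radius, line scaling above the
        rod diameter, breakpoint near the diameter (80 voxels)."""
        reg = hf.segment_regimes(chain_counts)
        assert reg.slope_small == pytest.approx(3.0, abs=0.15)
        assert reg.slope_large == pytest.approx(1.0, abs=0.15)
        assert 40 <= reg.breakpoint_size <= 160

    def test_full_box_single_regime(self):
        reg = hf.segment_regimes(hf.box_count(hf.make_box_model("full", 256)))
        assert reg.single_regime
        assert reg.slope_small == pytest.approx(2.0, abs=1e-9)

    def test_scale_direction_contrast(self, line_image, blob_image):
        """Thin line: small-box slope above large-box slope.  Sparse blob
        image (micrograph-like): the opposite ordering."""
        line = hf.segment_regimes(hf.box_count(line_image))
        blob = hf.segment_regimes(hf.box_count(blob_image))
        assert line.slope_small > line.slope_large
        assert blob.slope_small < blob.slope_large
        assert blob.slope_large == pytest.approx(2.0, abs=0.1)

    def test_too_few_sizes_rejected(self):
        res = hf.box_count(hf.make_box_model("full", 256), sizes=[1, 2, 4, 8])
        with pytest.raises(DomainError):
            hf.segment_regimes(res)


class TestDottedChain:
    def test_intermediate_regime_slope_below_0p3(self):
        """Spheres smaller than their spacing: between the sphere size and
        the spacing the count is locked to the number of spheres, so the
        local dimension is near zero."""
        grid = hf.make_sphere_chain(hf.SphereChainSpec(100, 1.5, 0.05, 0.02))
        res = hf.box_count(grid)
        # 2R = 5 voxels, d = 75 voxels at voxel size 0.02
        D, _ = hf.fit_dimension(res, size_range=(5, 75))
        assert D < 0.3
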