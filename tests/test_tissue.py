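"""Tissue grid: masks, source mapping, and geometry rescaling."""

import numpy as np
import pytest

from chemocycle.tissue import (
    TissueGrid,
    build_domain,
    map_vessel_sources,
    rasterize_segments,
    update_geometry_after_cycle,
)
from chemocycle.vasculature import INLET, OUTLET, VascularNetwork


class TestBuildDomain:
    def test_tumor_cell_count_matches_disc_area(self):
        grid = build_domain(tumor_radius=0.005, extent=0.02, h=1e-4)
        expected = np.pi * 0.005**2 / 1e-4**2
        assert grid.tumor_mask.sum() == pytest.approx(expected, rel=0.02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_domain(tumor_radius=0.0, extent=0.02, h=1e-4)
        with pytest.raises(ValueError):
            build_domain(tumor_radius=0.01, extent=0.02, h=1e-4)  # R = extent/2
        with pytest.raises(ValueError):
            build_domain(tumor_radius=0.005, extent=0.02, h=3e-4)  # h !| extent

    def test_determinism(self):
        a = build_domain(0.005, 0.02, 1e-4)
        b = build_domain(0.005, 0.02, 1e-4)
        assert np.array_equal(a.tumor_mask, b.tumor_mask)

    def test_region_fields_follow_masks(self, small_grid):
        assert np.all(small_grid.L_p[small_grid.tumor_mask] == small_grid.params.tumor.L_p)
        assert np.all(small_grid.L_p[small_grid.normal_mask()] == small_grid.params.normal.L_p)
        assert np.all(small_grid.lymph_coeff[small_grid.tumor_mask] == 0.0)


def _one_segment_network(p0, p1, d_um=10.0):
    return VascularNetwork(
        positions=np.array([p0, p1], dtype=float),
        kinds=np.array([INLET, OUTLET]),
        edges=np.array([[0, 1]]),
        diam_um=np.array([d_um]),
        hematocrit=np.array([0.45]),
    )


class TestSourceMapping:
    def test_single_cell_segment(self, small_grid):
        h = small_grid.h
        net = _one_segment_network([0.1 * h, 0.5 * h], [0.9 * h, 0.5 * h])
        sv = map_vessel_sources(net, small_grid, depth=1.0)
        expected = np.pi * 10e-6 * (0.8 * h) / (h * h * 1.0)
        assert sv[0, 0] == pytest.approx(expected, rel=1e-12)
        assert np.count_nonzero(sv) == 1

    def test_total_wall_area_conserved(self, small_grid, default_network):
        sv = map_vessel_sources(default_network, small_grid, depth=1.0)
        total_mapped = sv.sum() * small_grid.cell_area * 1.0
        assert total_mapped == pytest.approx(default_network.wall_areas().sum(), rel=1e-6)

    def test_midpoint_crossing_splits_evenly(self, small_grid):
        h = small_grid.h
        # segment centered on a vertical cell boundary
        net = _one_segment_network([0.6 * h, 0.5 * h], [1.4 * h, 0.5 * h])
        seg, ix, iy, ln = rasterize_segments(small_grid, net.positions, net.edges)
        assert sorted(zip(ix, iy)) == [(0, 0), (1, 0)]
        assert ln[0] == pytest.approx(ln[1], rel=1e-12)

    def test_network_outside_domain_rejected(self, small_grid):
        net = _one_segment_network([0.0, 0.0], [3 * small_grid.extent, 0.0])
        with pytest.raises(ValueError):
            map_vessel_sources(net, small_grid)


class TestGeometryUpdate:
    def test_identity(self, small_grid):
        out = update_geometry_after_cycle(small_grid, 1e9, 1e9)
        assert out.tumor_radius == pytest.approx(small_grid.tumor_radius)
        assert np.array_equal(out.tumor_mask, small_grid.tumor_mask)

    def test_cube_root_law(self, small_grid):
        out = update_geometry_after_cycle(small_grid, 1e9 / 8.0, 1e9)
        assert out.tumor_radius == pytest.approx(small_grid.tumor_radius / 2.0, rel=1e-12)

    def test_chained_updates_compose(self):
        grid = build_domain(0.6e-3, 2e-3, 2e-3 / 32)
        two_step = update_geometry_after_cycle(
            update_geometry_after_cycle(grid, 0.7e9, 1e9), 0.5e9, 0.7e9
        )
        one_step = update_geometry_after_cycle(grid, 0.5e9, 1e9)
        assert two_step.tumor_radius == pytest.approx(one_step.tumor_radius, rel=1e-12)

    def test_monotone_in_cell_count(self, small_grid):
        shrunk = update_geometry_after_cycle(small_grid, 0.5e9, 1e9)
        grown = update_geometry_after_cycle(small_grid, 1.5e9, 1e9)
        assert shrunk.tumor_radius < small_grid.tumor_radius < grown.tumor_radius

    def test_nonpositive_counts_rejected(self, small_grid):
        with pytest.raises(ValueError):
            update_geometry_after_cycle(small_grid, 0.0, 1e9)
        with pytest.raises(ValueError):
            update_geometry_after_cycle(small_grid, 1e9, -1.0)

    def test_mask_area_tracks_radius(self):
        grid = build_domain(0.5e-3, 2e-3, 2e-3 / 64)
        area = grid.tumor_mask.sum() * grid.cell_area
        exact = np.pi * grid.tumor_radius**2
        band = 2 * np.pi * grid.tumor_radius * grid.h  # one-cell annulus
        assert abs(area - exact) < band
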