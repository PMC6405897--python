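"""Fractal habitat maps and disk landscapes."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fragsim import (
    Window, midpoint_displacement, threshold_to_habitat, make_disk_landscape,
    is_habitat, HabitatMap, DiskLandscape,
)
from fragsim.landscapes import (
    patch_count, write_ascii_grid, read_ascii_grid,
    write_disk_landscape, read_disk_landscape, rasterize_disks,
)


class TestMidpointDisplacement:
    def test_grid_size(self):
        assert midpoint_displacement(0.5, 7, 0).values.shape == (129, 129)
        assert midpoint_displacement(0.5, 3, 0).values.shape == (9, 9)

    def test_determinism(self):
        a = midpoint_displacement(0.4, 6, 42).values
        b = midpoint_displacement(0.4, 6, 42).values
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("hurst", [-0.1, 0.0, 1.0, 1.5])
    def test_invalid_hurst(self, hurst):
        with pytest.raises(ValueError):
            midpoint_displacement(hurst, 5, 0)

    def test_smoothness_increases_with_hurst(self):
        # mean |difference| between horizontally adjacent cells, 100 reps each
        def roughness(h, seed):
            v = midpoint_displacement(h, 5, seed).values
            return np.abs(np.diff(v, axis=1)).mean()
        rough_high = np.mean([roughness(0.9, s) for s in range(100)])
        rough_low = np.mean([roughness(0.1, s) for s in range(100)])
        assert rough_high < rough_low

    def test_fractal_dimension_relation(self):
        assert midpoint_displacement(0.3, 4, 0).fractal_dimension == 2.7


class TestThreshold:
    def test_endpoints(self):
        surf = midpoint_displacement(0.5, 4, 1)
        assert threshold_to_habitat(surf, 0.0).n_habitat_cells == 0
        assert threshold_to_habitat(surf, 1.0).n_habitat_cells == surf.values.size

    def test_exact_counts_129(self):
        surf = midpoint_displacement(0.5, 7, 2)
        assert threshold_to_habitat(surf, 0.2).n_habitat_cells == 3328
        # round-half-up of 8320.5
        assert threshold_to_habitat(surf, 0.5).n_habitat_cells == 8321

    @given(st.floats(0.0, 1.0), st.integers(0, 10 ** 6))
    def test_exact_count_property(self, p, seed):
        surf = midpoint_displacement(0.5, 3, seed % 1000)
        m = threshold_to_habitat(surf, p, tie_seed=seed)
        assert m.n_habitat_cells == math.floor(p * 81 + 0.5)

    def test_habitat_cells_are_highest(self):
        surf = midpoint_displacement(0.7, 4, 3)
        m = threshold_to_habitat(surf, 0.3)
        v = surf.values
        assert v[m.grid].min() >= v[~m.grid].max()

    def test_tie_breaking_exact(self):
        # constant surface: every cell tied; count must still be exact
        surf = midpoint_displacement(0.5, 3, 4)
        flat = type(surf)(np.zeros_like(surf.values) + 1.0, 0.5, 3)
        m = threshold_to_habitat(flat, 0.25, tie_seed=7)
        assert m.n_habitat_cells == math.floor(0.25 * 81 + 0.5)


class TestFragmentationOrdering:
    def test_patch_count_higher_for_low_hurst(self):
        # H=0.1 (rugged) must fragment p=0.2 into more 4-connected patches
        # than H=0.9 (smooth), over replicate pairs
        wins = 0
        for seed in range(30):
            rough = threshold_to_habitat(
                midpoint_displacement(0.1, 7, seed), 0.2, seed)
            smooth = threshold_to_habitat(
                midpoint_displacement(0.9, 7, seed + 10_000), 0.2, seed)
            wins += patch_count(rough) > patch_count(smooth)
        assert wins == 30


class TestStationarity:
    def test_uniform_point_in_habitat_with_probability_p(self):
        # conditional on an exact-count map, a uniform point hits habitat
        # with probability exactly k/n_cells, independent of H
        p = 0.2
        rng = np.random.default_rng(5)
        for h in (0.1, 0.5, 0.9):
            hits = 0
            total = 0
            for seed in range(30):
                m = threshold_to_habitat(
                    midpoint_displacement(h, 7, 1000 + seed), p, seed)
                xy = rng.random((1200, 2))
                hits += is_habitat(m, xy[:, 0], xy[:, 1]).sum()
                total += 1200
            frac = hits / total
            se = math.sqrt(p * (1 - p) / total)
            assert abs(frac - p) < 4 * se


class TestDiskLandscape:
    def test_radius_single_disk(self):
        land = make_disk_landscape(1, 0.25, seed=0)
        assert land.radius == pytest.approx(math.sqrt(0.25 / math.pi))
        assert land.radius == pytest.approx(0.2821, abs=1e-4)

    def test_radius_four_disks(self):
        land = make_disk_landscape(4, 0.25, seed=0)
        assert land.radius == pytest.approx(0.1410, abs=1e-4)

    def test_single_disk_realized_equals_nominal(self):
        land = make_disk_landscape(1, 0.25, seed=1)
        assert land.realized_coverage(1024) == pytest.approx(0.25, abs=2e-3)

    def test_overlap_reduces_coverage(self):
        land = make_disk_landscape(10, 0.4, seed=2)
        assert land.realized_coverage(512) <= 0.4 + 1e-6

    def test_diameter_exceeds_window(self):
        with pytest.raises(ValueError):
            make_disk_landscape(1, 0.9, seed=0)

    def test_radial_membership(self):
        land = DiskLandscape(np.array([[0.5, 0.5]]), 0.1, habitat_amount=0.03)
        assert is_habitat(land, 0.5, 0.59)
        assert not is_habitat(land, 0.5, 0.61)

    def test_toroidal_membership(self):
        land = DiskLandscape(np.array([[0.02, 0.5]]), 0.1, habitat_amount=0.03)
        assert is_habitat(land, 0.97, 0.5)  # wraps across x=0


class TestIsHabitatRaster:
    def test_full_map(self):
        m = HabitatMap(np.ones((4, 4), bool), 1.0)
        xy = np.random.default_rng(0).random((50, 2))
        assert is_habitat(m, xy[:, 0], xy[:, 1]).all()

    def test_boundary_assigned_to_last_cell(self):
        grid = np.zeros((129, 129), bool)
        grid[128, 128] = True
        m = HabitatMap(grid, grid.mean())
        assert is_habitat(m, 1.0, 1.0)

    def test_cell_convention(self):
        # lower-left quadrant habitat on a 2x2 map
        grid = np.array([[True, False], [False, False]])
        m = HabitatMap(grid, 0.25)
        assert is_habitat(m, 0.1, 0.1)
        assert not is_habitat(m, 0.9, 0.1)
        assert not is_habitat(m, 0.1, 0.9)

    def test_outside_window_raises(self):
        m = HabitatMap(np.ones((4, 4), bool), 1.0)
        with pytest.raises(ValueError):
            is_habitat(m, 1.2, 0.5)


class TestIO:
    def test_ascii_grid_roundtrip(self, tmp_path):
        m = threshold_to_habitat(midpoint_displacement(0.5, 4, 9), 0.3)
        path = tmp_path / "map.asc"
        write_ascii_grid(m, path)
        back = read_ascii_grid(path)
        np.testing.assert_array_equal(back.grid, m.grid)
        head = path.read_text().splitlines()[:6]
        assert head[0].split() == ["ncols", "17"]
        assert head[4].split()[0] == "cellsize"

    def test_disk_roundtrip(self, tmp_path):
        land = make_disk_landscape(5, 0.2, seed=3)
        path = tmp_path / "disks.csv"
        write_disk_landscape(land, path)
        back = read_disk_landscape(path)
        np.testing.assert_allclose(back.centres, land.centres)
        assert back.radius == pytest.approx(land.radius)

    def test_rasterize_matches_is_habitat(self):
        land = make_disk_landscape(3, 0.15, seed=4)
        g = rasterize_disks(land, 64)
        xs = (np.arange(64) + 0.5) / 64
        gx, gy = np.meshgrid(xs, xs, indexing="xy")
        direct = is_habitat(land, gx.ravel(), gy.ravel()).reshape(64, 64)
        assert (g.astype(bool) == direct).mean() > 0.999
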