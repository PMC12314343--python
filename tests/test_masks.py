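"""Kernel-density fields, enrichment masks and distance statistics."""

import numpy as np
import pytest

from rsnmap.masks import (
    DensityMask,
    ZoneGateConfig,
    border_distance,
    density_mask_from_points,
    distance_to_mask,
    fraction_within,
    kde_density,
    make_mask,
)
from rsnmap.neighborhoods import build_raster_grid


def _brute_force_kde(points, grid, h, reflect):
    xmin, ymin, xmax, ymax = grid.bbox
    pts = list(map(tuple, points))
    if reflect:
        pts = pts + [(2 * xmin - x, y) for x, y in pts] \
                  + [(2 * xmax - x, y) for x, y in pts] \
                  + [(x, 2 * ymin - y) for x, y in pts] \
                  + [(x, 2 * ymax - y) for x, y in pts]
    out = np.zeros(len(grid.centers))
    for i, (gx, gy) in enumerate(grid.centers):
        s = 0.0
        for x, y in pts:
            s += np.exp(-((gx - x) ** 2 + (gy - y) ** 2) / (2 * h * h))
        out[i] = s / (2 * np.pi * h * h * len(points))
    return out.reshape(grid.shape)


class TestKde:
    def test_peak_value_closed_form(self):
        """Single point, no boundary: peak = 1 / (2 pi h^2)."""
        h = 100.0
        grid = build_raster_grid((0, 0, 1000, 1000), 10.0)
        pt = np.array([[grid.centers[0, 0], grid.centers[0, 1]]])
        d = kde_density(pt, grid, bandwidth=h, boundary="none")
        assert d[0, 0] == pytest.approx(1.0 / (2 * np.pi * h * h), rel=1e-12)
        assert d[0, 0] == pytest.approx(1.5915e-5, rel=1e-3)

    def test_on_edge_reflection_doubles_density(self):
        """A point on a bbox edge contributes twice via its mirror image."""
        grid = build_raster_grid((0, 0, 200, 200), 10.0)
        pt = np.array([[0.0, 100.0]])  # exactly on the left edge
        plain = kde_density(pt, grid, bandwidth=20.0, boundary="none")
        refl = kde_density(pt, grid, bandwidth=20.0, boundary="reflect")
        # near the left edge the far-edge and y-mirrors are negligible at h=20
        j = 10
        assert refl[j, :10] == pytest.approx(2.0 * plain[j, :10], rel=1e-6)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(0)
        grid = build_raster_grid((0, 0, 200, 200), 10.0)
        pts = rng.uniform(0, 200, size=(50, 2))
        for reflect in (False, True):
            got = kde_density(pts, grid, bandwidth=40.0,
                              boundary="reflect" if reflect else "none")
            expect = _brute_force_kde(pts, grid, 40.0, reflect)
            assert got == pytest.approx(expect, rel=1e-9)

    def test_mass_conservation_with_reflection(self):
        """Reflection restores the mass plain truncation loses (interior
        points; corners are not double-mirrored)."""
        rng = np.random.default_rng(1)
        pts = rng.uniform(400, 1600, size=(100, 2))
        grid = build_raster_grid((0, 0, 2000, 2000), 10.0)
        d = kde_density(pts, grid, bandwidth=100.0, boundary="reflect")
        mass = d.sum() * 10.0 * 10.0
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_contract_errors(self):
        grid = build_raster_grid((0, 0, 100, 100), 10.0)
        with pytest.raises(ValueError):
            kde_density(np.empty((0, 2)), grid)
        with pytest.raises(ValueError):
            kde_density(np.array([[1.0, 1.0]]), grid, bandwidth=0.0)


class TestMask:
    def test_relative_max_extremes(self):
        d = np.array([[0.0, 0.5], [1.0, 2.0]])
        empty, _ = make_mask(d, "relative_max", 1.0)
        assert not empty.any()
        allpos, _ = make_mask(d, "relative_max", 0.0)
        assert allpos.sum() == 3  # strictly positive entries only

    def test_absolute_matches_elementwise(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 1, size=(30, 30))
        mask, thr = make_mask(d, "absolute", 0.4)
        assert thr == 0.4
        assert np.array_equal(mask, d > 0.4)

    def test_quantile_mode(self):
        d = np.linspace(0, 1, 101).reshape(1, -1)
        mask, thr = make_mask(d, "quantile", 0.5)
        assert thr == pytest.approx(np.quantile(d[d > 0], 0.5))

    def test_invalid_values(self):
        d = np.ones((2, 2))
        with pytest.raises(ValueError):
            make_mask(d, "relative_max", 1.5)
        with pytest.raises(ValueError):
            make_mask(d, "nonsense", 0.5)

    def test_mask_area_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 500, size=(60, 2))
        areas = []
        for v in (0.05, 0.2, 0.5, 0.8):
            dm = density_mask_from_points(pts, (0, 0, 500, 500),
                                          threshold_value=v)
            areas.append(dm.area)
        assert areas == sorted(areas, reverse=True)


class TestDistances:
    def _mask(self, bbox=(0, 0, 200, 200), spacing=10.0, true_box=(50, 50, 100, 100)):
        grid = build_raster_grid(bbox, spacing)
        x0, y0, x1, y1 = true_box
        inside = (
            (grid.centers[:, 0] > x0) & (grid.centers[:, 0] < x1)
            & (grid.centers[:, 1] > y0) & (grid.centers[:, 1] < y1)
        ).reshape(grid.shape)
        density = inside.astype(float)
        return DensityMask(grid=grid, density=density, bandwidth=100.0,
                           threshold_mode="absolute", threshold_value=0.5,
                           resolved_threshold=0.5, mask=inside)

    def test_inside_is_zero_and_outside_positive(self):
        dm = self._mask()
        d = distance_to_mask(np.array([[75.0, 75.0], [75.0, 120.0]]), dm)
        assert d[0] == 0.0
        # mask tiles span 50..100; 7 µm beyond the last tile edge
        assert d[1] == pytest.approx(20.0, abs=dm.spacing)

    def test_empty_mask_rejected(self):
        dm = self._mask()
        dm.mask = np.zeros_like(dm.mask)
        with pytest.raises(ValueError):
            distance_to_mask(np.array([[0.0, 0.0]]), dm)

    def test_matches_brute_force_tile_distance(self):
        """Random masks and points vs exhaustive distance to tile squares."""
        rng = np.random.default_rng(4)
        grid = build_raster_grid((0, 0, 150, 150), 10.0)
        mask = rng.uniform(size=grid.shape) < 0.15
        mask[0, 0] = True
        dm = DensityMask(grid=grid, density=mask.astype(float), bandwidth=1.0,
                         threshold_mode="absolute", threshold_value=0.5,
                         resolved_threshold=0.5, mask=mask)
        pts = rng.uniform(-20, 170, size=(100, 2))
        got = distance_to_mask(pts, dm)
        centers = grid.centers[mask.ravel()]
        s = grid.spacing
        for p, g in zip(pts, got):
            dx = np.maximum(np.abs(p[0] - centers[:, 0]) - s / 2, 0)
            dy = np.maximum(np.abs(p[1] - centers[:, 1]) - s / 2, 0)
            assert g == pytest.approx(np.hypot(dx, dy).min(), abs=1e-9)

    def test_fraction_within(self):
        assert fraction_within(np.array([0.0, 5.0, 12.0]), 10.0) == pytest.approx(200 / 3)
        assert fraction_within(np.zeros(5), 10.0) == 100.0
        with pytest.raises(ValueError):
            fraction_within(np.array([]))

    def test_fraction_within_monotone_in_distance(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(0, 50, 200)
        fracs = [fraction_within(d, x) for x in (5, 10, 20, 40)]
        assert fracs == sorted(fracs)


class TestBorderDistance:
    def _disc_mask(self, radius=1000.0, bbox=(0, 0, 4000, 4000), spacing=10.0):
        grid = build_raster_grid(bbox, spacing)
        cx = (bbox[0] + bbox[2]) / 2
        cy = (bbox[1] + bbox[3]) / 2
        inside = (
            np.hypot(grid.centers[:, 0] - cx, grid.centers[:, 1] - cy) <= radius
        ).reshape(grid.shape)
        return DensityMask(grid=grid, density=inside.astype(float), bandwidth=100.0,
                           threshold_mode="absolute", threshold_value=0.5,
                           resolved_threshold=0.5, mask=inside), (cx, cy)

    def test_disc_geometry(self):
        dm, (cx, cy) = self._disc_mask()
        pts = np.array([[cx, cy], [cx + 1000.0, cy], [cx + 1500.0, cy]])
        d, zone = border_distance(pts, dm)
        assert d[0] == pytest.approx(-1000.0, abs=2 * dm.spacing)
        assert zone[0] == "inside"
        assert abs(d[1]) <= dm.spacing
        assert zone[1] == "border"
        assert d[2] == pytest.approx(500.0, abs=2 * dm.spacing)
        assert zone[2] == "outside"

    def test_matches_contour_sampling(self):
        """Signed distances agree with dense contour sampling within one
        grid spacing."""
        dm, (cx, cy) = self._disc_mask(radius=300.0, bbox=(0, 0, 1000, 1000))
        rng = np.random.default_rng(6)
        pts = rng.uniform(100, 900, size=(50, 2))
        d, _ = border_distance(pts, dm)
        r = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        expect = r - 300.0  # exact signed distance to the circle
        assert np.all(np.abs(d - expect) <= dm.spacing + 1e-9)

    def test_degenerate_masks_rejected(self):
        dm, _ = self._disc_mask(radius=300.0, bbox=(0, 0, 1000, 1000))
        dm.mask = np.zeros_like(dm.mask)
        with pytest.raises(ValueError):
            border_distance(np.array([[1.0, 1.0]]), dm)
        with pytest.raises(ValueError):
            ZoneGateConfig(border_gate=0.0)
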