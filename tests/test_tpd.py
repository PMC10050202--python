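"""Trait probability density: bandwidth, grid, kernels, HDR thresholding."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from lhspectra.tpd import (
    Bandwidth,
    build_grid,
    density_from_kernels,
    hdr_threshold,
    hotspot_summary,
    kernel_matrix,
    quantile_contours,
    richness,
    select_bandwidth,
    tpd_density,
)


class TestBandwidth:
    def test_isotropic_normal_matches_reference_scaling(self, rng):
        """For standard-normal data the optimal h is ~ n^(-1/6)."""
        n = 1000
        Z = rng.standard_normal((n, 2))
        H = select_bandwidth(Z).H
        href = n ** (-1.0 / 6.0)
        for h in np.sqrt(np.diag(H)):
            assert abs(h - href) / href < 0.25
        assert abs(H[0, 1]) < 0.1 * H[0, 0]

    def test_scale_equivariance(self, rng):
        Z = rng.standard_normal((500, 2))
        H1 = select_bandwidth(Z).H
        H2 = select_bandwidth(4.0 * Z).H
        assert np.allclose(H2, 16.0 * H1, rtol=1e-8)

    def test_rotation_equivariance(self, rng):
        Z = rng.standard_normal((500, 2)) * np.array([2.0, 0.5])
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        H_rot = select_bandwidth(Z @ R.T).H
        assert np.allclose(H_rot, R @ select_bandwidth(Z).H @ R.T, rtol=1e-6)

    def test_collinear_fallback(self, rng):
        x = rng.standard_normal(100)
        pts = np.column_stack([x, 2.0 * x])
        H = select_bandwidth(pts).H  # Silverman fallback, still PD
        assert np.all(np.linalg.eigvalsh(H) > 0)

    def test_non_pd_matrix_rejected(self):
        with pytest.raises(ValueError):
            Bandwidth(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestGrid:
    def test_default_resolution_gives_40000_cells(self, rng):
        pts = rng.standard_normal((30, 2))
        bw = Bandwidth(0.1 * np.eye(2))
        x_edges, y_edges = build_grid(pts, bw, cells_per_dim=200)
        assert (len(x_edges) - 1) * (len(y_edges) - 1) == 40_000

    def test_zero_pad_hits_data_range_exactly(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        x_edges, y_edges = build_grid(pts, None, cells_per_dim=10, pad=0.0)
        assert x_edges[0] == 0.0 and x_edges[-1] == 1.0
        assert y_edges[0] == 0.0 and y_edges[-1] == 1.0

    def test_degenerate_range_rejected(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError, match="degenerate"):
            build_grid(pts, None, pad=0.0)

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError):
            build_grid(rng.standard_normal((5, 2)), None, cells_per_dim=1)


class TestDensity:
    def test_matches_direct_gaussian_mixture(self, rng):
        """Grid density equals brute-force mixture evaluation, then scaled."""
        pts = rng.standard_normal((50, 2))
        bw = select_bandwidth(pts)
        grid = build_grid(pts, bw, cells_per_dim=40)
        tg = tpd_density(pts, bw, grid)
        xc, yc = tg.x_centres, tg.y_centres
        XX, YY = np.meshgrid(xc, yc)
        cells = np.column_stack([XX.ravel(), YY.ravel()])
        direct = np.zeros(len(cells))
        for p in pts:
            direct += multivariate_normal.pdf(cells, mean=p, cov=bw.H)
        direct /= len(pts)
        direct /= direct.sum() * tg.cell_area
        assert np.allclose(tg.density.ravel(), direct, rtol=1e-10)

    def test_integral_is_one(self, rng):
        pts = rng.standard_normal((25, 2))
        bw = select_bandwidth(pts)
        tg = tpd_density(pts, bw, build_grid(pts, bw, cells_per_dim=80))
        assert tg.total_mass() == pytest.approx(1.0, abs=1e-6)

    def test_point_reflection_symmetry(self):
        pts = np.array([[1.0, 0.5], [-1.0, -0.5]])
        bw = Bandwidth(0.2 * np.eye(2))
        grid = build_grid(pts, bw, cells_per_dim=50)
        D = tpd_density(pts, bw, grid).density
        assert np.allclose(D, D[::-1, ::-1], rtol=1e-8)

    def test_species_order_invariance(self, rng):
        pts = rng.standard_normal((20, 2))
        bw = select_bandwidth(pts)
        grid = build_grid(pts, bw, cells_per_dim=30)
        a = tpd_density(pts, bw, grid).density
        b = tpd_density(pts[::-1], bw, grid).density
        assert np.allclose(a, b, atol=1e-12)

    def test_kernel_matrix_subset_equals_direct_density(self, rng):
        pts = rng.standard_normal((15, 2))
        bw = select_bandwidth(pts)
        grid = build_grid(pts, bw, cells_per_dim=30)
        K = kernel_matrix(pts, bw, grid)
        sub = [0, 3, 7, 11]
        from_K = density_from_kernels(K, grid, subset=sub).density
        direct = tpd_density(pts[sub], bw, grid).density
        assert np.allclose(from_K, direct, rtol=1e-12)


class TestHDR:
    @pytest.fixture()
    def grid99(self, rng):
        pts = rng.standard_normal((60, 2))
        bw = select_bandwidth(pts)
        tg = tpd_density(pts, bw, build_grid(pts, bw, cells_per_dim=60))
        return tg

    def test_q1_keeps_all_positive_cells(self, grid99):
        thr = hdr_threshold(grid99, q=1.0)
        assert np.array_equal(thr.occupancy, grid99.density > 0)

    def test_renormalised_after_threshold(self, grid99):
        thr = hdr_threshold(grid99, q=0.99)
        assert thr.total_mass() == pytest.approx(1.0, abs=1e-6)
        assert thr.threshold_q == 0.99

    def test_uniform_density_takes_half_the_cells(self):
        D = np.zeros((10, 10))
        D[2:6, 2:6] = 1.0
        D /= D.sum() * 0.01
        from lhspectra.tpd import TPDGrid

        tg = TPDGrid(np.linspace(0, 1, 11), np.linspace(0, 1, 11), D, 0.01)
        thr = hdr_threshold(tg, q=0.5)
        assert thr.occupancy.sum() == 8  # ceil(16/2), ties by cell index

    def test_greedy_minimality(self, grid99):
        """The HDR holds >= q mass and dropping its last cell drops below q."""
        for q in (0.5, 0.9):
            thr = hdr_threshold(grid99, q=q)
            inside = grid99.density[thr.occupancy]
            mass = inside.sum() * grid99.cell_area
            assert mass >= q - 1e-9
            assert mass - inside.min() * grid99.cell_area < q

    def test_invalid_quantile_rejected(self, grid99):
        for q in (0.0, 1.2):
            with pytest.raises(ValueError):
                hdr_threshold(grid99, q=q)

    def test_contours_nested(self, grid99):
        masks = quantile_contours(grid99, qs=(0.5, 0.6, 0.7, 0.8, 0.9, 0.99))
        for small, big in zip(masks, masks[1:]):
            assert np.all(big[small])

    def test_concentric_masks_for_unimodal_density(self):
        pts = np.zeros((1, 2))
        bw = Bandwidth(np.eye(2))
        grid = build_grid(np.array([[-3.0, -3.0], [3.0, 3.0]]), None,
                          cells_per_dim=61, pad=0.0)
        tg = tpd_density(pts, bw, grid)
        masks = quantile_contours(tg, qs=(0.3, 0.6, 0.9))
        xc, yc = tg.x_centres, tg.y_centres
        XX, YY = np.meshgrid(xc, yc)
        R = np.hypot(XX, YY)
        for m in masks:
            if m.any() and (~m).any():
                assert R[m].max() <= R[~m].min() + np.hypot(0.1, 0.1) + 1e-9


class TestRichnessAndHotspot:
    def test_richness_is_occupied_area(self, rng):
        pts = rng.standard_normal((40, 2))
        bw = select_bandwidth(pts)
        tg = hdr_threshold(tpd_density(pts, bw, build_grid(pts, bw, cells_per_dim=50)))
        assert richness(tg) == pytest.approx(tg.occupancy.sum() * tg.cell_area)

    def test_unthresholded_grid_rejected(self, rng):
        pts = rng.standard_normal((40, 2))
        bw = select_bandwidth(pts)
        tg = tpd_density(pts, bw, build_grid(pts, bw, cells_per_dim=50))
        with pytest.raises(ValueError, match="hdr_threshold"):
            richness(tg)

    def test_resolution_stability(self, rng):
        pts = rng.standard_normal((200, 2))
        bw = select_bandwidth(pts)
        vals = []
        for cells in (100, 200):
            tg = hdr_threshold(
                tpd_density(pts, bw, build_grid(pts, bw, cells_per_dim=cells)))
            vals.append(richness(tg))
        assert abs(vals[1] - vals[0]) / vals[0] < 0.05

    def test_hotspot_fractions_for_separated_clusters(self, rng):
        """Two equal well-separated clusters split species evenly at q=0.5."""
        a = rng.normal(0, 0.3, size=(100, 2))
        b = rng.normal(8, 0.3, size=(100, 2))
        pts = np.vstack([a, b])
        bw = Bandwidth(0.01 * np.eye(2))  # kernel much tighter than spread
        tg = hdr_threshold(tpd_density(pts, bw, build_grid(pts, bw, cells_per_dim=150)))
        sp_frac, area_frac = hotspot_summary(tg, pts, q=0.5)
        assert 0.35 < sp_frac < 0.65
        assert area_frac < 0.7

    def test_hotspot_fraction_approaches_one(self, rng):
        pts = rng.standard_normal((80, 2))
        bw = select_bandwidth(pts)
        tg = hdr_threshold(tpd_density(pts, bw, build_grid(pts, bw, cells_per_dim=60)))
        sp_frac, _ = hotspot_summary(tg, pts, q=0.999)
        assert sp_frac > 0.95
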