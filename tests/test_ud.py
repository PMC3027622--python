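import numpy as np
import pandas as pd
import pytest

from brbud import (BridgeSpec, GridSpec, VarianceParams, compute_ud,
                   default_tau, export_ud, grid_for_plan,
                   integrated_bridge_density, isopleth_areas, isopleth_mask,
                   plan_interpolation, read_ud)
from brbud.ud import InterpolationPlan, UDRaster
from conftest import single_segment


def two_segment_run(params, T2=30.0):
    """Two contiguous included segments along the x axis."""
    a = single_segment((0.0, 0.0), (300.0, 0.0), T=30.0)
    b = single_segment((300.0, 0.0), (600.0, 0.0), T=T2, T_R=T2)
    b[["t0", "t1"]] = [30.0, 30.0 + T2]
    return pd.concat([a, b], ignore_index=True)


class TestPlanInterpolation:
    def test_equidistant_interior_locations(self, buffalo_params):
        seg = single_segment((0.0, 0.0), (30.0, 0.0), T=30.0)
        plan = plan_interpolation(seg, tau=10.0, params=buffalo_params)
        # n = 3: locations at m = 0, 1, 2 plus the terminal fix
        assert plan.n_locations == 4
        assert np.allclose(plan.points[:, 0], [0.0, 10.0, 20.0, 30.0])

    def test_one_minute_interpolation(self, buffalo_params):
        seg = single_segment((0.0, 0.0), (300.0, 0.0), T=30.0)
        plan = plan_interpolation(seg, tau=1.0, params=buffalo_params)
        assert plan.n_locations == 31
        assert plan.n_per_segment.iloc[0] == 30

    def test_recorded_locations_get_h_min(self, buffalo_params):
        seg = single_segment((0.0, 0.0), (300.0, 0.0), T=30.0)
        plan = plan_interpolation(seg, tau=1.0, params=buffalo_params)
        assert plan.h[0] == buffalo_params.h_min
        assert plan.h[-1] == buffalo_params.h_min
        assert plan.h[15] == plan.h.max() > buffalo_params.h_min

    def test_junctions_not_double_counted(self, buffalo_params):
        plan = plan_interpolation(two_segment_run(buffalo_params), tau=10.0,
                                  params=buffalo_params)
        # 3 + 3 interpolated + single shared junction + single terminal
        assert plan.n_locations == 7
        xs = plan.points[:, 0]
        assert np.count_nonzero(xs == 300.0) == 1

    def test_spacing_constraint_violation(self):
        params = VarianceParams(5.0, 440.0, 180.0)
        seg = single_segment((0.0, 0.0), (3000.0, 0.0), T=30.0)
        with pytest.raises(ValueError, match="tau"):
            plan_interpolation(seg, tau=10.0, params=params)

    def test_default_tau_honours_constraint(self, buffalo_params):
        seg = single_segment((0.0, 0.0), (3000.0, 0.0), T=30.0)
        tau = default_tau(seg, buffalo_params)
        plan = plan_interpolation(seg, tau, buffalo_params)  # no raise
        assert plan.n_locations >= 2

    def test_null_d_segment_keeps_h_min_everywhere(self, buffalo_params):
        seg = single_segment((0.0, 0.0), (40.0, 0.0), T=30.0)
        seg["null_d"] = True
        plan = plan_interpolation(seg, tau=5.0, params=buffalo_params)
        assert np.all(plan.h == buffalo_params.h_min)

    def test_excluded_segment_endpoints_become_plain_kernels(
            self, buffalo_params):
        seg = single_segment((0.0, 0.0), (300.0, 0.0), T=30.0)
        seg["included"] = False
        seg["reason"] = "exceeds_Tmax"
        plan = plan_interpolation(seg, tau=1.0, params=buffalo_params)
        assert plan.n_locations == 2
        assert np.all(plan.h == buffalo_params.h_min)


class TestComputeUd:
    def test_single_kernel_peak_height(self, buffalo_params):
        h = 100.0
        plan = InterpolationPlan(np.array([[0.0, 0.0]]), np.array([h]), 1.0)
        grid = GridSpec(-500.0, -500.0, 12.5, 80, 80)
        ud = compute_ud(plan, grid, truncate=6.0)
        assert ud.values.max() == pytest.approx(1 / (2 * np.pi * h**2),
                                                rel=0.01)

    def test_normalized_mass_across_resolutions(self, buffalo_params):
        seg = single_segment((0.0, 0.0), (300.0, 100.0), T=30.0)
        for cell in (buffalo_params.sigma_min / 2,
                     buffalo_params.sigma_min / 4):
            plan = plan_interpolation(seg, 1.0, buffalo_params)
            grid = grid_for_plan(plan, cell, buffalo_params)
            ud = compute_ud(plan, grid)
            assert ud.mass == pytest.approx(1.0, abs=1e-3)
            assert ud.raw_mass == pytest.approx(1.0, abs=5e-3)

    def test_matches_time_integral_oracle(self, buffalo_params):
        # kernel sum over interpolated locations vs midpoint quadrature of
        # the time-averaged bridge density, typical 30-min segment
        T, z1 = 30.0, (300.0, 0.0)
        seg = single_segment((0.0, 0.0), z1, T=T)
        plan = plan_interpolation(seg, T / 64, buffalo_params)
        grid = grid_for_plan(plan, buffalo_params.sigma_min / 4,
                             buffalo_params)
        ud = compute_ud(plan, grid, truncate=6.0)
        xx, yy = np.meshgrid(grid.x_centers, grid.y_centers)
        oracle = integrated_bridge_density(
            np.stack([xx, yy], -1), BridgeSpec((0.0, 0.0), z1, T),
            buffalo_params, n_quad=256)
        rel = np.abs(ud.values - oracle).max() / oracle.max()
        assert rel < 0.03

    def test_mass_splits_between_disjoint_identical_bridges(
            self, buffalo_params):
        a = single_segment((0.0, 0.0), (300.0, 0.0), T=30.0)
        b = single_segment((10000.0, 0.0), (10300.0, 0.0), T=30.0)
        b[["t0", "t1"]] = [100.0, 130.0]
        seg = pd.concat([a, b], ignore_index=True)
        plan = plan_interpolation(seg, 1.0, buffalo_params)
        grid = grid_for_plan(plan, 50.0, buffalo_params)
        ud = compute_ud(plan, grid)
        left = ud.values[:, grid.x_centers < 5000.0].sum()
        assert left * grid.cell_area == pytest.approx(0.5, abs=0.01)

    def test_time_weighting_doubles_mass_for_double_activity(
            self, buffalo_params):
        # same geometry, activity times T and 2T: the slower segment gets
        # twice the interpolated locations, hence twice the UD mass
        a = single_segment((0.0, 0.0), (300.0, 0.0), T=30.0)
        b = single_segment((10000.0, 0.0), (10300.0, 0.0), T=60.0, T_R=60.0)
        b[["t0", "t1"]] = [100.0, 160.0]
        seg = pd.concat([a, b], ignore_index=True)
        plan = plan_interpolation(seg, 1.0, buffalo_params)
        grid = grid_for_plan(plan, 50.0, buffalo_params)
        ud = compute_ud(plan, grid)
        left = ud.values[:, grid.x_centers < 5000.0].sum() * grid.cell_area
        right = ud.values[:, grid.x_centers >= 5000.0].sum() * grid.cell_area
        assert right / left == pytest.approx(2.0, abs=0.05)

    def test_refinement_convergence_in_tau(self, buffalo_params):
        seg = single_segment((0.0, 0.0), (400.0, 150.0), T=30.0)
        plan1 = plan_interpolation(seg, 0.5, buffalo_params)
        grid = grid_for_plan(plan1, 25.0, buffalo_params)
        u1 = compute_ud(plan1, grid).values
        u2 = compute_ud(plan_interpolation(seg, 0.25, buffalo_params),
                        grid).values
        assert np.abs(u1 - u2).max() / u1.max() < 0.01

    def test_empty_plan_rejected(self, buffalo_params):
        with pytest.raises(ValueError):
            compute_ud(InterpolationPlan(np.empty((0, 2)), np.empty(0), 1.0),
                       GridSpec(0, 0, 10.0, 5, 5))


class TestIsopleths:
    def uniform_ud(self, n=10):
        grid = GridSpec(0.0, 0.0, 10.0, n, n)
        v = np.full((n, n), 1.0 / (n * n * grid.cell_area))
        return UDRaster(grid, v, True, 1.0)

    def test_uniform_density_cell_count(self):
        ud = self.uniform_ud(10)
        assert isopleth_mask(ud, 95.0).sum() == 95

    def test_areas_nest(self, buffalo_params):
        seg = single_segment((0.0, 0.0), (300.0, 0.0), T=30.0)
        plan = plan_interpolation(seg, 1.0, buffalo_params)
        ud = compute_ud(plan, grid_for_plan(plan, 50.0, buffalo_params))
        areas = isopleth_areas(ud, [50.0, 95.0])
        assert 0 < areas[50.0] < areas[95.0]

    def test_gaussian_one_sigma_level(self):
        # mass within one sigma of a circular Gaussian is 1 - exp(-1/2)
        h = 100.0
        plan = InterpolationPlan(np.array([[0.0, 0.0]]), np.array([h]), 1.0)
        grid = GridSpec(-800.0, -800.0, 10.0, 160, 160)
        ud = compute_ud(plan, grid, truncate=6.0)
        level = 100 * (1 - np.exp(-0.5))
        area = isopleth_mask(ud, level).sum() * grid.cell_area
        radius = np.sqrt(area / np.pi)
        assert radius == pytest.approx(h, abs=grid.cell)

    def test_bad_level_rejected(self):
        ud = self.uniform_ud()
        for level in (0.0, -5.0, 101.0):
            with pytest.raises(ValueError):
                isopleth_mask(ud, level)


class TestDegeneration:
    def test_all_excluded_equals_fixed_bandwidth_location_kde(
            self, buffalo_params):
        # every segment beyond T_max: the estimator must fall back to a
        # classical location KDE with constant bandwidth h_min
        pts = np.array([[0.0, 0.0], [400.0, 100.0], [150.0, 300.0]])
        rows = []
        for k in range(len(pts) - 1):
            s = single_segment(tuple(pts[k]), tuple(pts[k + 1]), T=200.0,
                               T_R=200.0)
            s[["t0", "t1"]] = [200.0 * k, 200.0 * (k + 1)]
            rows.append(s)
        seg = pd.concat(rows, ignore_index=True)
        seg["included"] = False
        seg["reason"] = "exceeds_Tmax"
        plan = plan_interpolation(seg, 1.0, buffalo_params)
        grid = grid_for_plan(plan, 50.0, buffalo_params)
        ud = compute_ud(plan, grid, truncate=6.0)
        lkde = compute_ud(
            InterpolationPlan(pts, np.full(3, buffalo_params.h_min), 1.0),
            grid, truncate=6.0)
        assert np.allclose(ud.values, lkde.values)

    def test_constant_weight_ud_invariant_to_tmax(self):
        seg = single_segment((0.0, 0.0), (300.0, 0.0), T=30.0)
        grid = GridSpec(-1500.0, -1500.0, 50.0, 70, 70)
        uds = []
        for tmax in (60.0, 180.0, 600.0):
            p = VarianceParams(100.0, 440.0, tmax, "constant_weight")
            uds.append(compute_ud(plan_interpolation(seg, 1.0, p), grid))
        assert np.allclose(uds[0].values, uds[1].values)
        assert np.allclose(uds[1].values, uds[2].values)


class TestExport:
    def test_ascii_roundtrip(self, tmp_path, buffalo_params):
        seg = single_segment((0.0, 0.0), (300.0, 0.0), T=30.0)
        plan = plan_interpolation(seg, 1.0, buffalo_params)
        ud = compute_ud(plan, grid_for_plan(plan, 50.0, buffalo_params))
        path = tmp_path / "ud.asc"
        export_ud(ud, path, "esri_ascii")
        back = read_ud(path)
        assert back.grid.same_geometry(ud.grid)
        assert np.abs(back.values - ud.values).max() < 1e-6 * ud.values.max()
        header = path.read_text().splitlines()[:6]
        assert header[4].split() == ["cellsize", "50.0"]

    def test_csv_export_shape(self, tmp_path, buffalo_params):
        seg = single_segment((0.0, 0.0), (300.0, 0.0), T=30.0)
        plan = plan_interpolation(seg, 1.0, buffalo_params)
        ud = compute_ud(plan, grid_for_plan(plan, 50.0, buffalo_params))
        path = tmp_path / "ud.csv"
        export_ud(ud, path, "csv")
        df = pd.read_csv(path)
        assert len(df) == ud.grid.n_cols * ud.grid.n_rows

    def test_unknown_format_rejected(self, buffalo_params):
        seg = single_segment((0.0, 0.0), (300.0, 0.0), T=30.0)
        plan = plan_interpolation(seg, 1.0, buffalo_params)
        ud = compute_ud(plan, grid_for_plan(plan, 50.0, buffalo_params))
        with pytest.raises(ValueError):
            export_ud(ud, "/tmp/x.bin", "geotiff")
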