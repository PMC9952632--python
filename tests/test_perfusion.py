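"""Outlet perfusion accounting and centerline curvature morphometry."""

import numpy as np
import pytest

from archflow.geometry import default_case_specs
from archflow.meshing import PatchSpec, straight_tube_mesh
from archflow.perfusion import (curvature_radius_profile, extract_centerline,
                                outlet_flow_rates)
from archflow.solver import solve_steady


class TestOutletFlows:
    def test_single_outlet_matches_inlet(self, small_tube):
        perf = outlet_flow_rates(small_tube["field"], small_tube["mesh"])
        assert perf.inlet_mean_m3s == pytest.approx(small_tube["Q"],
                                                    rel=1e-3)
        assert perf.fractions["descending"] == pytest.approx(1.0, abs=1e-3)

    def test_missing_outlet_reports_zero_with_note(self, small_tube):
        perf = outlet_flow_rates(small_tube["field"], small_tube["mesh"],
                                 expected_outlets=("LSA",))
        assert perf.outlet_mean_m3s["LSA"] == 0.0
        assert any("LSA" in n for n in perf.notes)

    def test_symmetric_branch_split(self, props):
        """Two mirror-image branches on a straight trunk: symmetry forces an
        equal split of the branch flow."""
        R, L = 0.005, 0.04
        ms = 0.0015  # branch outlets need a few cells across for the
        # surface-flux quadrature to conserve within 1%
        patches = [
            PatchSpec(name=side, s_center=0.02, half_width_s=0.004,
                      half_width_theta=0.8, direction_theta=th,
                      length=0.008, extension=0.008, mesh_size=ms)
            for side, th in (("left", np.pi / 2), ("right", -np.pi / 2))]
        mesh = straight_tube_mesh(R, L, ms, patches=patches)
        assert {"left", "right", "descending"} == set(mesh.outlet_names())
        U = 20 * props.dynamic_viscosity / (props.density * 2 * R)
        # per-step change of 1e-6 is orders below the 2% split tolerance
        field = solve_steady(mesh, U * np.pi * R ** 2, props, tol=1e-6)
        perf = outlet_flow_rates(field, mesh)
        ql, qr = perf.outlet_mean_m3s["left"], perf.outlet_mean_m3s["right"]
        assert ql / (ql + qr) == pytest.approx(0.5, abs=0.02)
        assert sum(perf.fractions.values()) == pytest.approx(1.0, abs=0.01)


class TestCurvature:
    def test_exact_on_circle(self):
        theta = np.linspace(0, 1.5 * np.pi, 100)
        R = 0.03
        pts = np.column_stack([R * np.cos(theta), R * np.sin(theta),
                               np.zeros_like(theta)])
        radius = curvature_radius_profile(pts)
        assert np.allclose(radius, R, rtol=0.005)

    def test_collinear_is_undefined(self):
        pts = np.column_stack([np.linspace(0, 1, 50), np.zeros(50),
                               np.zeros(50)])
        radius = curvature_radius_profile(pts)
        assert np.all(np.isinf(radius))

    def test_helix_curvature(self):
        r, c = 0.01, 0.005
        t = np.linspace(0, 4 * np.pi, 500)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), c * t])
        kappa_exact = r / (r ** 2 + c ** 2)
        radius = curvature_radius_profile(pts)
        assert np.allclose(1.0 / radius[5:-5], kappa_exact, rtol=0.02)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, np.pi, 120)
        pts = np.column_stack([0.02 * np.cos(t), 0.02 * np.sin(t), 0.003 * t])
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + np.array([0.4, -0.2, 1.0])
        r1 = curvature_radius_profile(pts)
        r2 = curvature_radius_profile(moved)
        assert np.allclose(r1, r2, rtol=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            curvature_radius_profile(np.zeros((2, 3)))


class TestCenterlines:
    @pytest.fixture(scope="class")
    def paths(self):
        return {k: extract_centerline(v)
                for k, v in default_case_specs().items()}

    def test_sampling_and_arc_length(self, paths):
        for p in paths.values():
            assert len(p.points) >= 200
            assert np.all(np.diff(p.arc_length) > 0)

    def test_arch_span_recovers_torus_radius(self, paths):
        specs = default_case_specs()
        for label, p in paths.items():
            assert p.min_curvature_radius == pytest.approx(
                specs[label].arch_curvature_radius, rel=0.01)

    def test_postop_curvature_ordering(self, paths):
        r = {k: p.min_curvature_radius for k, p in paths.items()}
        assert r["postop1w"] < r["postop6m"] <= r["normal"]
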