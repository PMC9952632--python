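"""Case presets, parametric meshing invariants, and synthetic WSS fixtures."""

import dataclasses

import numpy as np
import pytest

from archflow.geometry import (ArchCaseSpec, BranchSpec, SyntheticWssSeries,
                               build_case_geometry, default_case_specs,
                               load_spec, save_spec, spec_from_dict,
                               spec_to_dict, synthetic_wss_series)
from archflow.meshing import GeometryError, straight_tube_mesh


@pytest.fixture(scope="module")
def specs():
    return default_case_specs()


class TestCasePresets:
    def test_four_cases_with_morphological_orderings(self, specs):
        assert set(specs) == {"normal", "preop", "postop1w", "postop6m"}
        r = {k: v.arch_curvature_radius for k, v in specs.items()}
        # 1-week arch is the tightest; 6-month partially recovers
        assert r["postop1w"] < r["postop6m"] <= r["normal"]
        assert r["postop1w"] < r["normal"]

    def test_lsa_occluded_postop_only(self, specs):
        for label, spec in specs.items():
            lsa = next(b for b in spec.branch_specs if b.name == "LSA")
            assert lsa.present == (label in ("normal", "preop"))

    def test_aneurysm_only_preop(self, specs):
        assert specs["preop"].aneurysm_spec is not None
        for label in ("normal", "postop1w", "postop6m"):
            assert specs[label].aneurysm_spec is None

    def test_postop_ostia_more_proximal(self, specs):
        def ostium(label, name):
            return next(b.ostium_position for b in specs[label].branch_specs
                        if b.name == name)
        for name in ("IA", "LCCA"):
            for post in ("postop1w", "postop6m"):
                assert ostium(post, name) < ostium("preop", name)

    def test_branch_radii_within_lumen(self, specs):
        for spec in specs.values():
            for b in spec.branch_specs:
                assert 0 < b.radius < spec.lumen_radius

    def test_validation_rejects_postop_with_lsa(self, specs):
        bad = dataclasses.replace(
            specs["postop1w"],
            branch_specs=tuple(
                dataclasses.replace(b, present=True) if b.name == "LSA" else b
                for b in specs["postop1w"].branch_specs))
        with pytest.raises(ValueError, match="LSA"):
            bad.validate()

    def test_validation_rejects_arch_tighter_than_lumen(self, specs):
        bad = dataclasses.replace(specs["normal"], arch_curvature_radius=0.01)
        with pytest.raises(ValueError, match="arch_curvature_radius"):
            bad.validate()

    def test_yaml_roundtrip(self, specs, tmp_path):
        for label, spec in specs.items():
            path = tmp_path / f"{label}.yaml"
            save_spec(spec, path)
            assert load_spec(path) == spec

    def test_dict_roundtrip(self, specs):
        for spec in specs.values():
            assert spec_from_dict(spec_to_dict(spec)) == spec


class TestCaseMeshing:
    def test_normal_case_has_all_outlets(self, specs):
        mesh = build_case_geometry(specs["normal"])
        assert set(mesh.outlet_names()) == {"RSA", "RCCA", "LCCA", "LSA",
                                            "descending"}
        for name in mesh.outlet_names():
            assert len(mesh.facets_where(f"outlet:{name}")) > 0

    def test_postop_case_has_no_lsa_outlet(self, specs):
        mesh = build_case_geometry(specs["postop1w"])
        assert "LSA" not in mesh.outlet_names()
        assert len(mesh.facets_where("outlet:LSA")) == 0

    def test_watertight_and_positive_volumes(self, specs):
        mesh = build_case_geometry(specs["preop"])
        assert mesh.closure_defect() < 1e-10
        assert mesh.cell_volumes().min() > 0
        tags = mesh.facet_tags
        assert ((tags >= 0) & (tags < len(mesh.tag_names))).all()

    def test_deterministic_meshing(self, specs):
        a = build_case_geometry(specs["postop6m"])
        b = build_case_geometry(specs["postop6m"])
        assert np.array_equal(a.nodes, b.nodes)
        assert np.array_equal(a.cells, b.cells)
        assert np.array_equal(a.boundary_facets, b.boundary_facets)

    def test_overlapping_components_rejected_with_names(self, specs):
        spec = specs["normal"]
        ia = next(b for b in spec.branch_specs if b.name == "IA")
        clash = dataclasses.replace(
            spec, branch_specs=tuple(
                dataclasses.replace(b, ostium_position=ia.ostium_position)
                if b.name == "LCCA" else b for b in spec.branch_specs))
        with pytest.raises(GeometryError, match="IA|LCCA"):
            build_case_geometry(clash)

    def test_sac_region_marked_on_preop_wall(self, specs):
        mesh = build_case_geometry(specs["preop"])
        assert "aneurysm" in mesh.region_names
        assert len(mesh.facets_in_region("aneurysm")) > 0


class TestTubeFixtures:
    def test_cylinder_wall_area_closed_form(self):
        R, L = 0.005, 0.02
        mesh = straight_tube_mesh(R, L, 0.0015)
        wall = mesh.facets_where("wall")
        area = mesh.facet_areas[wall].sum()
        assert area == pytest.approx(2 * np.pi * R * L, rel=0.02)

    def test_refinement_doubles_cells_keeps_area(self):
        R, L = 0.005, 0.02
        coarse = straight_tube_mesh(R, L, 0.002)
        fine = straight_tube_mesh(R, L, 0.001)
        assert len(fine.cells) >= 2 * len(coarse.cells)
        a0 = coarse.facet_areas.sum()
        a1 = fine.facet_areas.sum()
        assert abs(a1 - a0) / a0 < 0.01

    def test_outward_area_vectors_sum_to_zero(self):
        mesh = straight_tube_mesh(0.004, 0.012, 0.0015)
        vec = (mesh.facet_normals * mesh.facet_areas[:, None]).sum(axis=0)
        assert np.linalg.norm(vec) < 1e-10 * mesh.facet_areas.sum()


class TestSyntheticWss:
    def test_constant_fixture_magnitude(self):
        wss = synthetic_wss_series(SyntheticWssSeries("constant", offset=2.0,
                                                      n_timesteps=32))
        mags = np.linalg.norm(wss.tractions, axis=2)
        assert np.allclose(mags, 2.0)

    def test_reversing_fixture_antisymmetric(self):
        wss = synthetic_wss_series(SyntheticWssSeries("reversing",
                                                      amplitude=1.0,
                                                      n_timesteps=64))
        assert abs(wss.tractions.sum()) < 1e-12
        assert np.allclose(np.abs(wss.tractions[:, 0, 0]), 1.0)

    def test_offset_sinusoid_time_average(self):
        fix = SyntheticWssSeries("offset_sinusoid", offset=1.0, amplitude=0.5,
                                 n_timesteps=1000)
        wss = synthetic_wss_series(fix)
        mean_vec = wss.tractions.mean(axis=0)
        assert np.linalg.norm(mean_vec) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("bad", [
        SyntheticWssSeries("constant", n_timesteps=3),
        SyntheticWssSeries("constant", period=0.0),
        SyntheticWssSeries("sawtooth"),
    ])
    def test_invalid_fixture_rejected(self, bad):
        with pytest.raises(ValueError):
            bad.validate()
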