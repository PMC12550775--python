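"""Virtual surgery: resection plane orientation, parametric implant
dimensions, cavity booleans with a voxel oracle, coverage checks."""

import numpy as np
import pytest

from stemfea.geometry import (IMPLANT_CATALOG, CoverageReport, GeometryError,
                              ImplantSpec, ResectionPlan, axis_extent,
                              build_implant, carve_cavity, check_coverage,
                              cut_face_of, resect_tibia, width_at)


def _measured_cut_normal(solid, anchor, normal):
    """Fit a plane to surface vertices lying on the resection face."""
    surf = solid.surface(pitch=0.8)
    d = (surf.vertices - anchor) @ normal
    on_plane = np.abs(d) < 1e-3
    pts = np.asarray(surf.vertices[on_plane])
    assert len(pts) > 30, "cut face not sampled"
    pts = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    n = vt[2]
    return n if n[2] > 0 else -n


class TestResection:
    @pytest.mark.parametrize("angle", [0.0, 3.0])
    def test_cut_face_orientation(self, small_solid, angle):
        plan = ResectionPlan(jlo_angle_deg=angle)
        cut = resect_tibia(small_solid, plan)
        n = _measured_cut_normal(cut, cut.cut_anchor, cut.cut_normal)
        measured = np.degrees(np.arccos(np.clip(n @ [0, 0, 1.0], -1, 1)))
        assert measured == pytest.approx(angle, abs=0.01)

    def test_resection_removes_volume(self, small_solid):
        cut = resect_tibia(small_solid, ResectionPlan())
        assert cut.volume(pitch=0.8) < small_solid.volume(pitch=0.8)

    def test_invalid_plans_rejected(self):
        with pytest.raises(GeometryError):
            ResectionPlan(depth_below_plateau=0.0)
        with pytest.raises(GeometryError):
            ResectionPlan(jlo_angle_deg=20.0)

    def test_plane_missing_solid_raises(self, small_solid):
        deep = ResectionPlan(depth_below_plateau=500.0, jlo_angle_deg=0.0)
        with pytest.raises(GeometryError):
            resect_tibia(small_solid, deep)


class TestImplant:
    def test_model1_extent_is_plate_thickness(self):
        spec = ImplantSpec.from_catalog(1)
        solid = build_implant(spec)
        lo, hi = axis_extent(solid, axis=2)
        assert hi - lo == pytest.approx(spec.plate_thickness, abs=0.01)

    def test_model6_stem_dimensions_read_back(self):
        spec = ImplantSpec.from_catalog(6)
        solid = build_implant(spec)
        lo, hi = axis_extent(solid, axis=2)
        assert hi - lo - spec.plate_thickness == pytest.approx(45.0, abs=0.01)
        z_mid = -spec.plate_thickness - 30.0   # below the fins
        assert width_at(solid, z_mid, axis=0) == pytest.approx(14.0, abs=0.01)
        assert width_at(solid, z_mid, axis=1) == pytest.approx(14.0, abs=0.01)

    def test_doubling_diameter_doubles_widths(self):
        s1 = ImplantSpec(model_id=9, stem_length=40, stem_diameter=6,
                         fin_count=0)
        s2 = ImplantSpec(model_id=9, stem_length=40, stem_diameter=12,
                         fin_count=0)
        z = -s1.plate_thickness - 25.0
        w1 = width_at(build_implant(s1), z, axis=0)
        w2 = width_at(build_implant(s2), z, axis=0)
        assert w2 / w1 == pytest.approx(2.0, rel=5e-3)

    def test_catalog_validation(self):
        with pytest.raises(GeometryError):
            ImplantSpec.from_catalog(7)
        with pytest.raises(GeometryError):
            ImplantSpec(model_id=1, stem_length=20.0, stem_diameter=9.0)
        with pytest.raises(GeometryError):
            ImplantSpec(model_id=2, stem_length=0.0)
        with pytest.warns(UserWarning):
            ImplantSpec(model_id=2, stem_length=33.0, stem_diameter=9.0)


class TestCavity:
    def _common_grid_volume(self, mask_fn, bounds, pitch=0.5):
        lo, hi = bounds
        axes = [lo[i] + (np.arange(int(np.ceil((hi[i] - lo[i]) / pitch)))
                         + 0.5) * pitch for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        return np.count_nonzero(mask_fn(grid)) * pitch ** 3

    def test_cavity_volume_against_voxel_oracle(self, small_solid):
        """volume(bone with cavity) = volume(cut bone) - volume(implant
        inside cut bone), measured on an independent voxel grid."""
        plan = ResectionPlan()
        cut = resect_tibia(small_solid, plan)
        face = cut_face_of(small_solid, plan)
        implant = build_implant(
            ImplantSpec.from_catalog(2, plate_width=30, plate_depth=22)
        ).translated(face.anchor)
        carved = carve_cavity(cut, implant)
        bounds = cut.bounds
        v_carved = self._common_grid_volume(carved.contains, bounds)
        v_cut = self._common_grid_volume(cut.contains, bounds)
        v_overlap = self._common_grid_volume(
            lambda p: cut.contains(p) & implant.contains(p), bounds)
        assert v_carved == pytest.approx(v_cut - v_overlap, rel=5e-3)

    def test_carving_is_idempotent(self, small_solid):
        plan = ResectionPlan()
        cut = resect_tibia(small_solid, plan)
        face = cut_face_of(small_solid, plan)
        implant = build_implant(
            ImplantSpec.from_catalog(2, plate_width=30, plate_depth=22)
        ).translated(face.anchor)
        once = carve_cavity(cut, implant)
        twice = carve_cavity(once, implant)
        v1, v2 = once.volume(pitch=0.8), twice.volume(pitch=0.8)
        assert abs(v2 - v1) <= 1e-6 * v1

    def test_disjoint_implant_raises(self, small_solid):
        cut = resect_tibia(small_solid, ResectionPlan())
        far = build_implant(
            ImplantSpec.from_catalog(1, plate_width=20, plate_depth=16)
        ).translated([0.0, 0.0, 500.0])
        with pytest.raises(GeometryError):
            carve_cavity(cut, far)


class TestCoverage:
    def test_footprint_inside_face(self, small_solid):
        plan = ResectionPlan()
        face = cut_face_of(small_solid, plan)
        implant = build_implant(
            ImplantSpec.from_catalog(1, plate_width=20, plate_depth=14)
        ).translated(face.anchor)
        rep = check_coverage(face, implant)
        assert isinstance(rep, CoverageReport)
        assert not rep.protrusion
        assert 0 < rep.coverage < 1

    def test_oversized_footprint_protrudes(self, small_solid):
        plan = ResectionPlan()
        face = cut_face_of(small_solid, plan)
        implant = build_implant(
            ImplantSpec.from_catalog(1, plate_width=80, plate_depth=60)
        ).translated(face.anchor)
        assert check_coverage(face, implant).protrusion

    def test_identical_footprint_full_coverage(self, small_solid):
        """Implant occupying exactly the bone cross-section covers it fully."""
        plan = ResectionPlan()
        face = cut_face_of(small_solid, plan)
        rep = check_coverage(face, small_solid)
        assert rep.coverage == pytest.approx(1.0, abs=1e-6)
        assert not rep.protrusion
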