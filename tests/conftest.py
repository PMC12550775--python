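"""Shared fixtures: a small, fast phantom and a fully prepared (meshed,
tagged, material-mapped) single-model assembly reused across test modules.

Everything is generated at test time; the small phantom keeps meshes at a
few thousand elements so the whole suite stays desk-scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from stemfea.geometry import (ImplantSpec, ResectionPlan, build_implant,
                              carve_cavity, cut_face_of, resect_tibia)
from stemfea.materials import (DensityCalibration, ImplantMaterial,
                               MaterialModel, assign_materials,
                               element_density)
from stemfea.meshing import (GeometryContext, MeshSettings, mesh_assembly,
                             tag_sets)
from stemfea.phantom import PhantomSpec, generate_phantom_surface, rasterize_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Noise-free reduced phantom: exact ground truth, fast rasterization."""
    return PhantomSpec(shaft_length=60.0, plateau_width=44.0,
                       plateau_depth=32.0, shaft_outer_radius=9.0,
                       cortical_thickness_proximal=1.5,
                       cortical_thickness_distal=4.0,
                       noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def small_solid(small_spec):
    return generate_phantom_surface(small_spec)


@pytest.fixture(scope="session")
def small_ct(small_spec):
    ct, gt = rasterize_phantom(small_spec, DensityCalibration(),
                               spacing=(1.0, 1.0, 1.0), margin=3.0)
    return ct, gt


@pytest.fixture(scope="session")
def coarse_settings() -> MeshSettings:
    return MeshSettings(global_size=4.0, contact_size=3.0)


@pytest.fixture(scope="session")
def assembly(small_spec, small_solid, small_ct, coarse_settings):
    """Meshed, tagged and material-mapped model-2 assembly on the small
    phantom (the most-reused expensive object of the suite)."""
    ct, _ = small_ct
    plan = ResectionPlan()
    bone_cut = resect_tibia(small_solid, plan)
    face = cut_face_of(small_solid, plan)
    spec = ImplantSpec.from_catalog(2, plate_width=34.0, plate_depth=24.0)
    a = np.deg2rad(plan.jlo_angle_deg)
    R = np.array([[np.cos(a), 0.0, np.sin(a)],
                  [0.0, 1.0, 0.0],
                  [-np.sin(a), 0.0, np.cos(a)]])
    implant = build_implant(spec).rotated(R).translated(face.anchor)
    bone = carve_cavity(bone_cut, implant)
    mesh = mesh_assembly(bone, implant, coarse_settings)
    ctx = GeometryContext(bone=bone, implant=implant,
                          plate_top_point=face.anchor,
                          load_normal=face.normal,
                          refine_offset=coarse_settings.refine_offset)
    tag_sets(mesh, ctx)
    rho = element_density(ct, mesh, DensityCalibration())
    materials = assign_materials(mesh, rho, MaterialModel(), ImplantMaterial())
    return {"mesh": mesh, "materials": materials, "bone": bone,
            "implant": implant, "face": face, "ct": ct, "plan": plan}
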