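"""Assembly and solve: stiffness invariants, consistent load application,
equilibrium, the closed-form prism patch test, and load-case linearity."""

import numpy as np
import pytest

from stemfea.materials import ElementMaterials
from stemfea.meshing import FEMesh, structured_box_mesh, _boundary_faces, _face6
from stemfea.solver import (BoundaryConditions, LoadCase, SolverError,
                            apply_loads, assemble, solve)


def _uniform_materials(mesh, E=5000.0, nu=0.3):
    m = mesh.n_elements
    return ElementMaterials(np.full(m, E), np.full(m, nu),
                            np.full(m, 1.0), np.ones(m, np.int8))


def _single_tet_mesh():
    nodes4 = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    from stemfea.meshing import _add_midside_nodes
    nodes, conn = _add_midside_nodes(nodes4, np.array([[0, 1, 2, 3]]))
    return FEMesh(nodes=nodes, elements=conn.astype(np.int32),
                  regions=np.zeros(1, np.int8))


class TestStiffness:
    def test_symmetry_and_rigid_body_null_space(self):
        mesh = _single_tet_mesh()
        K = assemble(mesh, _uniform_materials(mesh)).toarray()
        scale = np.abs(K).max()
        assert np.abs(K - K.T).max() < 1e-12 * scale
        # translations and linearized rotations produce zero force
        x = mesh.nodes
        rigid = [np.tile([1, 0, 0], (len(x), 1)),
                 np.tile([0, 1, 0], (len(x), 1)),
                 np.tile([0, 0, 1], (len(x), 1)),
                 np.cross(x, [0, 0, 1.0]),
                 np.cross(x, [1.0, 0, 0])]
        for mode in rigid:
            assert np.abs(K @ mode.ravel()).max() < 1e-8 * scale

    def test_linearity_in_modulus(self):
        mesh = _single_tet_mesh()
        K1 = assemble(mesh, _uniform_materials(mesh, E=1000.0))
        K2 = assemble(mesh, _uniform_materials(mesh, E=2000.0))
        assert abs(K2 - 2.0 * K1).max() < 1e-9 * abs(K1).max()

    def test_zero_modulus_rejected(self):
        mesh = _single_tet_mesh()
        mats = _uniform_materials(mesh)
        mats.modulus[0] = 0.0
        with pytest.raises(SolverError):
            assemble(mesh, mats)


class TestLoads:
    def test_case_totals(self):
        assert LoadCase("w", 3.0).total_force == pytest.approx(2250.0)
        assert LoadCase("s", 5.0).total_force == pytest.approx(3750.0)
        assert LoadCase("r", 12.0).total_force == pytest.approx(9000.0)

    def test_assembled_force_total_and_split(self, assembly):
        mesh = assembly["mesh"]
        case = LoadCase("walk", 3.0)
        bcs = apply_loads(mesh, case)
        total = np.linalg.norm(bcs.total_force())
        assert total == pytest.approx(2250.0, abs=1e-6)
        med = np.linalg.norm(bcs.forces[mesh.node_sets["medial_patch"]],
                             axis=1).sum()
        assert med / total == pytest.approx(0.600, abs=1e-9)
        # compressive: along the negative loading normal
        direction = bcs.total_force() / total
        assert direction @ mesh.meta["load_normal"] == pytest.approx(-1.0)

    def test_untagged_mesh_rejected(self):
        mesh = structured_box_mesh([4, 4, 4], 2.0)
        with pytest.raises(SolverError):
            apply_loads(mesh, LoadCase("w", 3.0))

    def test_even_split_symmetric_mesh(self):
        """medial_fraction = 0.5 on a mirror-symmetric box gives a force
        vector symmetric under x -> -x."""
        mesh = structured_box_mesh([10, 10, 10], 2.5)
        nodes = mesh.nodes
        faces, owners, locals_ = _boundary_faces(mesh)
        top = np.all(np.abs(nodes[faces][:, :, 2] - 10.0) < 1e-9, axis=1)
        xmid = 5.0
        med, lat = [], []
        for o, l, f in zip(owners[top], locals_[top], faces[top]):
            f6 = _face6(mesh, o, l)
            side = nodes[f6[:3], 0] - xmid
            if np.all(side > 0):
                med.append(f6)
            elif np.all(side < 0):
                lat.append(f6)
        mesh.face_sets["medial"] = np.array(med)
        mesh.face_sets["lateral"] = np.array(lat)
        mesh.node_sets["distal_fixed"] = np.flatnonzero(nodes[:, 2] < 1e-9)
        bcs = apply_loads(mesh, LoadCase("even", 3.0, medial_fraction=0.5),
                          direction=np.array([0.0, 0, -1.0]))
        mirrored = nodes.copy()
        mirrored[:, 0] = 10.0 - mirrored[:, 0]
        order = np.lexsort(mirrored.T)
        base = np.lexsort(nodes.T)
        assert np.allclose(bcs.forces[order], bcs.forces[base], atol=1e-12)


@pytest.fixture(scope="module")
def prism_solution():
    """Frictionless uniaxial compression of a 10x10x30 prism under uniform
    end pressure p: the exact solution is a constant stress state
    sigma_zz = -p."""
    E, nu, p = 5000.0, 0.3, 2.0
    mesh = structured_box_mesh([10, 10, 30], 2.5)
    mats = _uniform_materials(mesh, E=E, nu=nu)
    K = assemble(mesh, mats)
    nodes = mesh.nodes
    fixed = np.zeros((mesh.n_nodes, 3), bool)
    fixed[np.abs(nodes[:, 2]) < 1e-9, 2] = True
    i0 = int(np.argmin(np.linalg.norm(nodes, axis=1)))
    fixed[i0, :2] = True
    i1 = int(np.argmin(np.linalg.norm(nodes - [10, 0, 0], axis=1)))
    fixed[i1, 1] = True
    faces, owners, locals_ = _boundary_faces(mesh)
    top = np.all(np.abs(nodes[faces][:, :, 2] - 30.0) < 1e-9, axis=1)
    forces = np.zeros((mesh.n_nodes, 3))
    for o, l in zip(owners[top], locals_[top]):
        f6 = _face6(mesh, o, l)
        tri = nodes[f6[:3]]
        area = 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
        forces[f6[3:], 2] -= p * area / 3.0
    disp = solve(K, BoundaryConditions(fixed=fixed, forces=forces))
    return mesh, mats, disp, (E, nu, p)


class TestSolve:
    def test_zero_load_zero_displacement(self):
        mesh = structured_box_mesh([4, 4, 8], 2.0)
        K = assemble(mesh, _uniform_materials(mesh))
        fixed = np.zeros((mesh.n_nodes, 3), bool)
        fixed[mesh.nodes[:, 2] < 1e-9] = True
        bcs = BoundaryConditions(fixed=fixed,
                                 forces=np.zeros((mesh.n_nodes, 3)))
        disp = solve(K, bcs)
        assert np.abs(disp.u).max() == 0.0

    def test_unconstrained_rejected(self):
        mesh = structured_box_mesh([4, 4, 4], 2.0)
        K = assemble(mesh, _uniform_materials(mesh))
        bcs = BoundaryConditions(fixed=np.zeros((mesh.n_nodes, 3), bool),
                                 forces=np.zeros((mesh.n_nodes, 3)))
        with pytest.raises(SolverError):
            solve(K, bcs)

    def test_equilibrium(self, prism_solution):
        _, _, disp, (_, _, p) = prism_solution
        applied = np.array([0.0, 0.0, -p * 100.0])
        assert np.allclose(disp.reactions.sum(axis=0), -applied,
                           rtol=1e-6, atol=1e-6 * p * 100)

    def test_patch_test_recovers_constant_state(self, prism_solution):
        from stemfea.postprocess import recover_fields
        mesh, mats, disp, (E, nu, p) = prism_solution
        fld = recover_fields(mesh, disp, mats)
        szz = fld.stress[:, 2, 2]
        ezz = fld.strain[:, 2, 2]
        assert np.abs(szz + p).max() < 0.005 * p
        assert np.abs(ezz + p / E).max() < 0.005 * p / E

    def test_load_case_linearity(self, assembly):
        """Independent solves at 3 BW and 12 BW differ exactly by the load
        ratio: every derived field scales by 4."""
        mesh, mats = assembly["mesh"], assembly["materials"]
        K = assemble(mesh, mats)
        u3 = solve(K, apply_loads(mesh, LoadCase("w3", 3.0))).u
        u12 = solve(K, apply_loads(mesh, LoadCase("r12", 12.0))).u
        scale = np.abs(u3).max()
        assert np.abs(u12 - 4.0 * u3).max() < 1e-9 * scale
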