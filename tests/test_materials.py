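"""HU interpolation, Gauss-quadrature density integration (against exact and
Monte-Carlo oracles), the density-modulus laws and tissue classification."""

import numpy as np
import pytest

from stemfea.materials import (TISSUE_CORTICAL, TISSUE_IMPLANT,
                               DensityCalibration, ImplantMaterial,
                               MaterialModel, assign_materials,
                               density_to_modulus, element_density,
                               find_threshold, interpolate_hu)
from stemfea.meshing import structured_box_mesh
from stemfea.phantom import CTVolume


def _ct_from_fn(fn, shape=(12, 12, 12), spacing=(1.0, 1.0, 1.0),
                origin=(0.0, 0.0, 0.0)):
    axes = [origin[i] + np.arange(shape[i]) * spacing[i] for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return CTVolume(hu=fn(grid.reshape(-1, 3)).reshape(shape),
                    spacing=spacing, origin=origin)


class TestInterpolation:
    def test_voxel_center_identity(self):
        rng = np.random.default_rng(0)
        ct = _ct_from_fn(lambda p: rng.normal(size=len(p)))
        pts = np.array([[3.0, 4.0, 5.0], [0.0, 0.0, 0.0], [11.0, 11.0, 11.0]])
        idx = pts.astype(int)
        expected = [ct.hu[tuple(i)] for i in idx]
        assert np.allclose(interpolate_hu(ct, pts), expected, atol=1e-12)

    def test_constant_volume(self):
        ct = _ct_from_fn(lambda p: np.full(len(p), 321.0))
        pts = np.random.default_rng(1).uniform(0, 11, size=(50, 3))
        assert np.allclose(interpolate_hu(ct, pts), 321.0)

    def test_midpoint_mean(self):
        rng = np.random.default_rng(2)
        ct = _ct_from_fn(lambda p: rng.normal(size=len(p)))
        mid = np.array([[3.5, 4.0, 5.0]])
        expected = 0.5 * (ct.hu[3, 4, 5] + ct.hu[4, 4, 5])
        assert interpolate_hu(ct, mid)[0] == pytest.approx(expected, abs=1e-12)

    def test_out_of_bounds_background(self):
        ct = _ct_from_fn(lambda p: np.zeros(len(p)))
        assert interpolate_hu(ct, [[-50.0, 0.0, 0.0]])[0] == -1000.0


class TestElementDensity:
    def test_constant_field_exact(self):
        mesh = structured_box_mesh([4, 4, 4], 2.0)
        calib = DensityCalibration()
        ct = _ct_from_fn(lambda p: np.full(len(p), calib.hu(0.85)),
                         origin=(-2.0, -2.0, -2.0))
        rho = element_density(ct, mesh, calib)
        assert np.abs(rho - 0.85).max() < 1e-9

    def test_affine_field_equals_centroid_value(self):
        """The 4-point rule integrates affine fields exactly, so the element
        density equals the density at the centroid."""
        calib = DensityCalibration()
        g = np.array([0.02, -0.01, 0.015])

        def rho_fn(p):
            return 0.8 + p @ g

        ct = _ct_from_fn(lambda p: calib.hu(rho_fn(p)), shape=(16, 16, 16),
                         origin=(-4.0, -4.0, -4.0))
        mesh = structured_box_mesh([6, 6, 6], 2.0)
        rho = element_density(ct, mesh, calib)
        expected = rho_fn(mesh.element_centroids())
        assert np.abs(rho - expected).max() < 1e-9

    def test_smooth_field_against_monte_carlo_oracle(self):
        """Quadrature density within 1% of a dense per-element Monte-Carlo
        estimate on a smooth radial field."""
        calib = DensityCalibration()

        def rho_fn(p):
            r2 = ((p - 5.0) ** 2).sum(axis=1)
            return 0.5 + 0.4 * np.exp(-r2 / 40.0)

        ct = _ct_from_fn(lambda p: calib.hu(rho_fn(p)), shape=(15, 15, 15),
                         origin=(-1.0, -1.0, -1.0))
        mesh = structured_box_mesh([10, 10, 10], 2.5)
        rho = element_density(ct, mesh, calib)

        rng = np.random.default_rng(42)
        corners = mesh.corner_coords()
        # uniform barycentric samples via normalized exponentials
        w = rng.exponential(size=(10_000, 4))
        w /= w.sum(axis=1, keepdims=True)
        pts = np.einsum("qa,maj->mqj", w, corners)
        oracle = rho_fn(pts.reshape(-1, 3)).reshape(pts.shape[:2]).mean(axis=1)
        assert np.abs(rho / oracle - 1.0).max() < 0.01

    def test_element_outside_volume_floored(self):
        ct = _ct_from_fn(lambda p: np.zeros(len(p)), shape=(4, 4, 4))
        mesh = structured_box_mesh([2, 2, 2], 2.0)
        far = mesh.nodes + 1000.0
        mesh.nodes = far
        rho = element_density(ct, mesh, DensityCalibration(), density_floor=0.05)
        assert np.all(rho == 0.05)


class TestLaws:
    def test_unit_density_is_cancellous_coefficient(self):
        E, tissue = density_to_modulus(1.0, MaterialModel())
        assert E[0] == pytest.approx(6570.0)
        assert tissue[0] != TISSUE_CORTICAL

    def test_zero_density_floored(self):
        model = MaterialModel()
        E, _ = density_to_modulus(0.0, model)
        assert E[0] == model.modulus_floor

    def test_laws_agree_at_intersection(self):
        model = MaterialModel()
        rho = find_threshold(model)
        assert model.cortical(rho) == pytest.approx(model.cancellous(rho),
                                                    rel=1e-6)

    def test_negative_density_raises(self):
        with pytest.raises(ValueError):
            density_to_modulus(-0.1, MaterialModel())

    def test_threshold_near_published_value(self):
        assert find_threshold(MaterialModel()) == pytest.approx(1.68, rel=0.01)

    def test_threshold_closed_forms(self):
        m = MaterialModel(cortical_coeff=500.0, cortical_exp=2.0,
                          cancellous_coeff=500.0, cancellous_exp=1.2)
        assert find_threshold(m) == pytest.approx(1.0)
        swapped = MaterialModel(cortical_coeff=6570.0, cortical_exp=1.37,
                                cancellous_coeff=3890.0, cancellous_exp=2.39)
        assert find_threshold(swapped) == pytest.approx(
            find_threshold(MaterialModel()))
        with pytest.raises(ValueError):
            find_threshold(MaterialModel(cortical_exp=1.37))

    def test_law_monotone_in_density(self):
        model = MaterialModel()
        rho = np.linspace(0.0, 3.0, 2001)
        E, _ = density_to_modulus(rho, model)
        assert np.all(np.diff(E) >= 0)

    def test_classification_equals_larger_law(self):
        """Thresholding at the law intersection classifies each density by
        whichever law yields the larger modulus."""
        model = MaterialModel()
        rho = np.linspace(0.01, 3.0, 1000)
        _, tissue = density_to_modulus(rho, model)
        larger_is_cortical = model.cortical(rho) >= model.cancellous(rho)
        assert np.array_equal(tissue == TISSUE_CORTICAL, larger_is_cortical)


class TestAssignment:
    def test_implant_constants_and_bone_mapping(self, assembly):
        mesh, mats = assembly["mesh"], assembly["materials"]
        imp = mesh.regions != 0
        assert np.all(mats.modulus[imp] == 220_000.0)
        assert np.all(mats.poisson[imp] == 0.3)
        assert np.all(mats.tissue[imp] == TISSUE_IMPLANT)
        bone = ~imp
        assert np.all(mats.modulus[bone] >= MaterialModel().modulus_floor)
        assert np.all(mats.poisson[bone] == 0.3)

    def test_uniform_density_single_modulus(self):
        mesh = structured_box_mesh([4, 4, 4], 2.0)
        mats = assign_materials(mesh, np.full(mesh.n_elements, 1.8),
                                MaterialModel(), ImplantMaterial())
        assert len(np.unique(mats.modulus)) == 1
        assert np.all(mats.tissue == TISSUE_CORTICAL)  # 1.8 > threshold

    def test_incomplete_densities_rejected(self):
        mesh = structured_box_mesh([4, 4, 4], 2.0)
        with pytest.raises(ValueError):
            assign_materials(mesh, np.ones(3), MaterialModel(),
                             ImplantMaterial())
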