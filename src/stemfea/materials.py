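"""CT-based heterogeneous material assignment for bone finite-element models.

The chain is HU -> apparent density (linear calibration) -> elastic modulus
(piecewise power laws for cortical and cancellous bone).  Per-element density
is obtained by Gaussian-quadrature integration of the interpolated CT field
over each tetrahedron, so an element's modulus reflects the density averaged
over its actual volume rather than a single sampled voxel.

Units: densities in g/cm^3, moduli in MPa, lengths in mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "DensityCalibration",
    "MaterialModel",
    "ImplantMaterial",
    "ElementMaterials",
    "TISSUE_CANCELLOUS",
    "TISSUE_CORTICAL",
    "TISSUE_IMPLANT",
    "interpolate_hu",
    "element_density",
    "density_to_modulus",
    "find_threshold",
    "assign_materials",
]

TISSUE_CANCELLOUS = 1
TISSUE_CORTICAL = 2
TISSUE_IMPLANT = 3

#: Published density threshold separating cancellous from cortical bone,
#: the rounded intersection of the two default density-modulus laws.
PUBLISHED_TISSUE_THRESHOLD = 1.68

AIR_HU = -1000.0


@dataclass(frozen=True)
class DensityCalibration:
    """Linear HU -> apparent density map: ``rho = slope * HU + intercept``.

    QCT calibrations are scanner-specific; the default (0.001 g/cm^3 per HU,
    intercept 1.0 so water maps to ~1.0 g/cm^3) is a generic placeholder that
    places dense cortical bone at 1.8-2.0 g/cm^3.
    """

    slope: float = 0.001
    intercept: float = 1.0

    def __post_init__(self):
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero (not invertible)")

    def density(self, hu) -> np.ndarray:
        return self.slope * np.asarray(hu, dtype=float) + self.intercept

    def hu(self, rho) -> np.ndarray:
        return (np.asarray(rho, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class MaterialModel:
    """Density-modulus power laws and bone elastic constants.

    ``E_cortical = 3890 * rho^2.39`` and ``E_cancellous = 6570 * rho^1.37``
    (E in MPa, rho in g/cm^3).  The tissue threshold is the density at which
    the two laws intersect; with the default coefficients that is
    ~1.6715 g/cm^3, conventionally quoted rounded as 1.68 g/cm^3.  Pass an
    explicit ``tissue_threshold`` to override the computed intersection.
    """

    cortical_coeff: float = 3890.0
    cortical_exp: float = 2.39
    cancellous_coeff: float = 6570.0
    cancellous_exp: float = 1.37
    poisson_bone: float = 0.3
    density_floor: float = 0.05
    modulus_floor: float = 10.0
    tissue_threshold: float | None = None

    def __post_init__(self):
        if self.cortical_coeff <= 0 or self.cancellous_coeff <= 0:
            raise ValueError("law coefficients must be positive")
        if not (0.0 < self.poisson_bone < 0.5):
            raise ValueError("poisson_bone must lie in (0, 0.5)")
        if self.tissue_threshold is not None and self.tissue_threshold <= 0:
            raise ValueError("tissue_threshold must be positive")

    def cortical(self, rho) -> np.ndarray:
        return self.cortical_coeff * np.asarray(rho, dtype=float) ** self.cortical_exp

    def cancellous(self, rho) -> np.ndarray:
        return self.cancellous_coeff * np.asarray(rho, dtype=float) ** self.cancellous_exp

    @property
    def threshold(self) -> float:
        if self.tissue_threshold is not None:
            return self.tissue_threshold
        return find_threshold(self)


@dataclass(frozen=True)
class ImplantMaterial:
    """Cobalt-chrome-molybdenum implant elasticity (MPa)."""

    modulus: float = 220_000.0
    poisson: float = 0.3

    def __post_init__(self):
        if self.modulus <= 0:
            raise ValueError("implant modulus must be positive")


@dataclass
class ElementMaterials:
    """Per-element elastic constants, density and tissue class."""

    modulus: np.ndarray
    poisson: np.ndarray
    density: np.ndarray
    tissue: np.ndarray

    def __len__(self):
        return len(self.modulus)


# ---------------------------------------------------------------------------
# Sampling and integration
# ---------------------------------------------------------------------------

def interpolate_hu(ct, points, background: float = AIR_HU) -> np.ndarray:
    """Trilinear interpolation of the HU grid at physical coordinates (mm).

    Points beyond the volume extent return the background (air) HU; the count
    of such points is logged rather than raised, since resection planes may
    graze the field of view.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    idx = (pts - np.asarray(ct.origin)) / np.asarray(ct.spacing)
    shape = np.asarray(ct.hu.shape, dtype=float)
    oob = np.any((idx < 0) | (idx > shape - 1), axis=1)
    n_oob = int(oob.sum())
    if n_oob:
        logger.debug("interpolate_hu: %d of %d points outside volume -> background",
                     n_oob, len(pts))
    out = ndimage.map_coordinates(ct.hu, idx.T, order=1, mode="constant",
                                  cval=background)
    out[oob] = background
    return out


# Symmetric Gauss rules on the reference tetrahedron (barycentric points,
# weights summing to 1).  The 4-point rule is exact for quadratic integrands.
_A4, _B4 = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0, (5.0 - np.sqrt(5.0)) / 20.0
TET_GAUSS: dict[int, tuple[np.ndarray, np.ndarray]] = {
    1: (np.full((1, 4), 0.25), np.array([1.0])),
    4: (np.array([[_A4 if i == j else _B4 for j in range(4)] for i in range(4)]),
        np.full(4, 0.25)),
    5: (np.vstack([np.full((1, 4), 0.25),
                   [[0.5 if i == j else 1.0 / 6.0 for j in range(4)]
                    for i in range(4)]]),
        np.array([-0.8, 0.45, 0.45, 0.45, 0.45])),
}


def element_density(ct, mesh, calibration: DensityCalibration,
                    rule: int = 4, density_floor: float = 0.05) -> np.ndarray:
    """Per-element apparent density by Gauss integration of the CT field.

    ``rho_elem = sum_q w_q rho(x_q) / sum_q w_q`` over the tetrahedral rule
    (default 4-point); densities are floored at ``density_floor``.
    """
    if rule not in TET_GAUSS:
        raise ValueError(f"no {rule}-point tetrahedral Gauss rule (have {sorted(TET_GAUSS)})")
    bary, weights = TET_GAUSS[rule]
    corners = mesh.nodes[mesh.elements[:, :4]]            # (m, 4, 3)
    gauss_pts = np.einsum("qa,maj->mqj", bary, corners)   # (m, q, 3)
    hu = interpolate_hu(ct, gauss_pts.reshape(-1, 3)).reshape(gauss_pts.shape[:2])
    rho_q = calibration.density(hu)
    rho = rho_q @ weights / weights.sum()
    floored = rho < density_floor
    if floored.any():
        logger.info("element_density: floored %d of %d elements at %.3g g/cm^3",
                    int(floored.sum()), len(rho), density_floor)
    return np.maximum(rho, density_floor)


# ---------------------------------------------------------------------------
# Density -> modulus
# ---------------------------------------------------------------------------

def density_to_modulus(rho, model: MaterialModel):
    """Map density to Young's modulus (MPa) and tissue class.

    Densities at or above the tissue threshold follow the cortical law,
    below it the cancellous law; results are floored at ``modulus_floor``.
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    if np.any(rho < 0):
        raise ValueError("negative density")
    cortical = rho >= model.threshold
    E = np.where(cortical, model.cortical(rho), model.cancellous(rho))
    E = np.maximum(E, model.modulus_floor)
    tissue = np.where(cortical, TISSUE_CORTICAL, TISSUE_CANCELLOUS).astype(np.int8)
    return E, tissue


def find_threshold(model: MaterialModel) -> float:
    """Density at which the cortical and cancellous laws intersect.

    Solving ``c1 rho^e1 = c2 rho^e2`` gives ``rho* = (c2/c1)^(1/(e1-e2))``,
    the unique positive root when the exponents differ.
    """
    de = model.cortical_exp - model.cancellous_exp
    if de == 0:
        raise ValueError("equal exponents: the laws have no unique intersection")
    return float((model.cancellous_coeff / model.cortical_coeff) ** (1.0 / de))


def assign_materials(mesh, densities, model: MaterialModel,
                     implant_mat: ImplantMaterial) -> ElementMaterials:
    """Per-element constants: mapped bone laws for bone elements, fixed
    CoCrMo elasticity for baseplate/stem elements."""
    from .meshing import REGION_BONE

    regions = mesh.regions
    if np.any(regions < 0):
        bad = np.flatnonzero(regions < 0)
        raise ValueError(f"unlabeled elements: {bad[:10].tolist()} ...")
    densities = np.asarray(densities, dtype=float)
    if densities.shape[0] != len(regions):
        raise ValueError("densities must cover all elements")

    bone = regions == REGION_BONE
    E = np.full(len(regions), implant_mat.modulus, dtype=float)
    nu = np.full(len(regions), implant_mat.poisson, dtype=float)
    rho = np.full(len(regions), np.nan, dtype=float)
    tissue = np.full(len(regions), TISSUE_IMPLANT, dtype=np.int8)

    E_bone, tissue_bone = density_to_modulus(densities[bone], model)
    E[bone] = E_bone
    nu[bone] = model.poisson_bone
    rho[bone] = densities[bone]
    tissue[bone] = tissue_bone
    return ElementMaterials(modulus=E, poisson=nu, density=rho, tissue=tissue)
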