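"""Field recovery and the study's output quantities.

From the nodal displacements we recover element strain/stress tensors
(volume-averaged over the Gauss points, which for straight-sided TET10
elements equals the centroid value), then compute von Mises stress, the
von-Mises-type equivalent elastic strain, principal strains, a strain-based
periprosthetic fracture-risk percentage, and the region-of-interest
micro-strain percentiles that summarize load transfer at the bone-implant
interface.

Sign conventions: compression is negative; the "minimum principal strain" is
the most negative eigenvalue of the strain tensor; micro-strain = strain x 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meshing import REGION_BONE, FEMesh
from .solver import _W4, _gradients, _DNDL  # shared TET10 kernels

__all__ = [
    "TensorField",
    "FractureCriterion",
    "SummaryRow",
    "recover_fields",
    "von_mises",
    "equivalent_strain",
    "principal_strains",
    "fracture_risk",
    "summarize",
    "summarize_all",
    "summary_table",
    "summary_pivot",
    "mean_abs_strain_under_plate",
]


@dataclass
class TensorField:
    """Per-element symmetric strain (dimensionless) and stress (MPa) tensors."""

    strain: np.ndarray   # (m, 3, 3)
    stress: np.ndarray   # (m, 3, 3)

    def scaled(self, factor: float) -> "TensorField":
        return TensorField(strain=self.strain * factor,
                           stress=self.stress * factor)


@dataclass(frozen=True)
class FractureCriterion:
    """Ultimate-strain fracture criterion: the limit is a fixed fraction of
    the compressive yield strain of bone; risk is the peak principal-strain
    magnitude over that limit, in percent."""

    compressive_strain_limit: float = 0.0104
    fraction: float = 0.70

    @property
    def ultimate_strain(self) -> float:
        return self.fraction * self.compressive_strain_limit


@dataclass
class SummaryRow:
    """One study record: maxima over bone elements plus ROI micro-strain
    percentiles (median and 90th percentile of the compressive tail)."""

    model_id: int
    case: str
    max_von_mises: float
    max_equivalent_strain: float
    max_fracture_risk: float
    roi_median_microstrain: float
    roi_p90_microstrain: float


# ---------------------------------------------------------------------------
# Recovery
# ---------------------------------------------------------------------------

def recover_fields(mesh: FEMesh, displacements, materials) -> TensorField:
    """Element strain from shape-function gradients at the Gauss points,
    volume-averaged; stress via isotropic Hooke's law."""
    u = displacements.u if hasattr(displacements, "u") else np.asarray(displacements)
    ue = u[mesh.elements]                                    # (m, 10, 3)
    corners = mesh.corner_coords()
    grads, _ = _gradients(corners)                           # (4, m, 10, 3)
    # displacement gradient per gp, averaged with the (equal) weights
    H = np.einsum("q,qmai,mak->mik", _W4, grads, ue)
    eps = 0.5 * (H + H.transpose(0, 2, 1))

    E = np.asarray(materials.modulus, dtype=float)
    nu = np.asarray(materials.poisson, dtype=float)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    tr = np.trace(eps, axis1=1, axis2=2)
    sig = 2.0 * mu[:, None, None] * eps \
        + lam[:, None, None] * tr[:, None, None] * np.eye(3)
    return TensorField(strain=eps, stress=sig)


# ---------------------------------------------------------------------------
# Scalar invariants
# ---------------------------------------------------------------------------

def _as_batch(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return t[None] if t.ndim == 2 else t


def von_mises(stress) -> np.ndarray:
    """sqrt(1/2 [(s1-s2)^2 + (s2-s3)^2 + (s3-s1)^2]) on principal values (MPa)."""
    s = _as_batch(stress)
    p = np.linalg.eigvalsh(s)
    out = np.sqrt(0.5 * ((p[:, 0] - p[:, 1]) ** 2 + (p[:, 1] - p[:, 2]) ** 2
                         + (p[:, 2] - p[:, 0]) ** 2))
    return out if np.asarray(stress).ndim == 3 else float(out[0])


def equivalent_strain(strain, nu=0.3, convention: str = "deviatoric") -> np.ndarray:
    """Von-Mises-type equivalent elastic strain.

    The default convention applies the common FE-package factor 1/(1+nu) to
    the deviatoric principal-strain differences, so that in a uniaxial
    stress state the result equals sigma_vm / E exactly.
    """
    if convention != "deviatoric":
        raise ValueError("supported conventions: 'deviatoric' "
                         "(use von_mises(stress)/E for the stress-based form)")
    e = _as_batch(strain)
    nu = np.broadcast_to(np.asarray(nu, dtype=float), e.shape[0])
    p = np.linalg.eigvalsh(e)
    base = np.sqrt(0.5 * ((p[:, 0] - p[:, 1]) ** 2 + (p[:, 1] - p[:, 2]) ** 2
                          + (p[:, 2] - p[:, 0]) ** 2))
    out = base / (1.0 + nu)
    return out if np.asarray(strain).ndim == 3 else float(out[0])


def principal_strains(strain) -> np.ndarray:
    """Principal strains sorted descending (eps1 >= eps2 >= eps3)."""
    e = _as_batch(strain)
    p = np.linalg.eigvalsh(e)[:, ::-1]
    return p if np.asarray(strain).ndim == 3 else p[0]


def fracture_risk(strain, criterion: FractureCriterion | None = None,
                  signed: bool = False) -> np.ndarray:
    """Fracture-risk percentage per element.

    RF = 100 * |principal strain|_max / ultimate_strain.  The magnitude of
    the extreme principal strain is used (the limit derives from the
    compressive strength of bone while the loading here is compressive, so
    tensile and compressive peaks are treated symmetrically); ``signed=True``
    instead uses the algebraically largest principal strain.
    """
    criterion = criterion or FractureCriterion()
    p = principal_strains(_as_batch(strain))
    if signed:
        peak = p[:, 0]
    else:
        peak = np.abs(p).max(axis=1)
    out = 100.0 * peak / criterion.ultimate_strain
    return out if np.asarray(strain).ndim == 3 else float(out[0])


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _roi_bone_elements(mesh: FEMesh) -> np.ndarray:
    roi = mesh.element_sets.get("refined_roi")
    if roi is None:
        raise ValueError("mesh has no refined_roi element set; run tag_sets")
    return roi[mesh.regions[roi] == REGION_BONE]


def summarize(model_id: int, case: str, field: TensorField, mesh: FEMesh,
              materials, criterion: FractureCriterion | None = None) -> SummaryRow:
    """Collapse a solved load case into the study record.

    Maxima are taken over element-averaged values of bone elements only;
    the ROI percentiles (median, 90th) are of the magnitude of the minimum
    (most compressive) principal strain over the refined bone elements, in
    micro-strain, reported with the compressive sign.
    """
    criterion = criterion or FractureCriterion()
    bone = mesh.regions == REGION_BONE
    if not bone.any():
        raise ValueError("mesh has no bone elements")
    nu = np.asarray(materials.poisson, dtype=float)

    vm = von_mises(field.stress[bone])
    eqv = equivalent_strain(field.strain[bone], nu[bone])
    rf = fracture_risk(field.strain[bone], criterion)

    roi = _roi_bone_elements(mesh)
    if len(roi) == 0:
        raise ValueError("refined ROI contains no bone elements")
    eps3 = principal_strains(field.strain[roi])[:, 2]
    mag = np.abs(eps3) * 1e6
    med = -float(np.percentile(mag, 50.0))   # linear-interpolation estimator
    p90 = -float(np.percentile(mag, 90.0))

    return SummaryRow(model_id=model_id, case=case,
                      max_von_mises=float(vm.max()),
                      max_equivalent_strain=float(eqv.max()),
                      max_fracture_risk=float(rf.max()),
                      roi_median_microstrain=med,
                      roi_p90_microstrain=p90)


def summarize_all(results: dict[tuple[int, str], tuple[TensorField, FEMesh, object]],
                  expected: list[tuple[int, str]] | None = None,
                  criterion: FractureCriterion | None = None) -> list[SummaryRow]:
    """Summaries for every (model, case) combination; missing ones raise."""
    if expected is not None:
        missing = [k for k in expected if k not in results]
        if missing:
            raise ValueError(f"missing model/case combinations: {missing}")
    return [summarize(mid, case, fld, mesh, mats, criterion)
            for (mid, case), (fld, mesh, mats) in results.items()]


def summary_table(rows: list[SummaryRow]) -> pd.DataFrame:
    """Long-form study table, one row per (model, case)."""
    return pd.DataFrame([r.__dict__ for r in rows])


def summary_pivot(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-form study table: load cases as blocks of output rows,
    models as columns."""
    metrics = ["max_von_mises", "max_equivalent_strain", "max_fracture_risk",
               "roi_median_microstrain", "roi_p90_microstrain"]
    long = df.melt(id_vars=["model_id", "case"], value_vars=metrics,
                   var_name="metric")
    wide = long.pivot_table(index=["case", "metric"], columns="model_id",
                            values="value", sort=False)
    wide.columns = [f"model_{c}" for c in wide.columns]
    return wide.reset_index()


def mean_abs_strain_under_plate(mesh: FEMesh, field: TensorField,
                                depth: float = 5.0) -> float:
    """Mean equivalent-strain magnitude in bone directly beneath the
    baseplate, within ``depth`` mm of its inferior face — the region whose
    unloading signals stress shielding by a stem."""
    top = mesh.meta["plate_top_point"]
    n = mesh.meta["load_normal"]
    t = mesh.meta["plate_thickness"]
    cent = mesh.element_centroids()
    h = (cent - top) @ n
    bone = mesh.regions == REGION_BONE
    under = bone & (h < -t) & (h > -t - depth)
    if not under.any():
        raise ValueError("no bone elements under the baseplate")
    nu = np.full(int(under.sum()), 0.3)
    return float(np.mean(equivalent_strain(field.strain[under], nu)))
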