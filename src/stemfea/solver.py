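"""Linear-elastic TET10 assembly and solution.

Small-strain isoparametric elasticity on straight-sided quadratic tetrahedra.
Because midside nodes sit at edge midpoints, the element map is affine and
the Jacobian constant, so the 4-point Gauss rule integrates the stiffness
exactly.  Loads are uniform pressures on the medial/lateral baseplate
patches, converted to consistent nodal forces of the quadratic face shape
functions (for a straight 6-node triangle under uniform traction, each
midside node carries one third of the face load and the corners none).
Constraints are homogeneous Dirichlet (fully fixed nodes or selected
components), eliminated before a sparse direct factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .materials import ElementMaterials
from .meshing import FEMesh

__all__ = [
    "LoadCase",
    "BoundaryConditions",
    "DisplacementField",
    "SolverError",
    "DEFAULT_LOAD_CASES",
    "assemble",
    "apply_loads",
    "solve",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class LoadCase:
    """A physiological compressive load: a body-weight multiple at a fixed
    body weight, split medially/laterally over the two plateau patches."""

    name: str
    bw_multiple: float
    body_weight: float = 750.0
    medial_fraction: float = 0.60

    def __post_init__(self):
        if not (0.0 <= self.medial_fraction <= 1.0):
            raise ValueError("medial_fraction must lie in [0, 1]")

    @property
    def total_force(self) -> float:
        return self.bw_multiple * self.body_weight


#: walking (single-leg support), sit-to-stand / stairs, running
DEFAULT_LOAD_CASES = (
    LoadCase("walking_3BW", 3.0),
    LoadCase("stairs_5BW", 5.0),
    LoadCase("running_12BW", 12.0),
)


@dataclass
class BoundaryConditions:
    """Homogeneous constraints and consistent nodal forces (N)."""

    fixed: np.ndarray      # (n, 3) bool: constrained displacement components
    forces: np.ndarray     # (n, 3) float

    def total_force(self) -> np.ndarray:
        return self.forces.sum(axis=0)


@dataclass
class DisplacementField:
    """Nodal solution (mm), reactions at constrained dofs (N), residual."""

    u: np.ndarray
    reactions: np.ndarray
    residual: float


# ---------------------------------------------------------------------------
# TET10 shape functions (barycentric L0..L3; VTK node order)
# ---------------------------------------------------------------------------

_GP4 = np.array([(5.0 + 3.0 * np.sqrt(5.0)) / 20.0 if i == j
                 else (5.0 - np.sqrt(5.0)) / 20.0
                 for i in range(4) for j in range(4)]).reshape(4, 4)
_W4 = np.full(4, 0.25)

_EDGE_PAIRS = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]


def _dN_dL(L: np.ndarray) -> np.ndarray:
    """Derivatives of the 10 shape functions w.r.t. the 4 barycentric
    coordinates at one quadrature point L (4,) -> (10, 4)."""
    out = np.zeros((10, 4))
    for i in range(4):
        out[i, i] = 4.0 * L[i] - 1.0
    for k, (a, b) in enumerate(_EDGE_PAIRS):
        out[4 + k, a] = 4.0 * L[b]
        out[4 + k, b] = 4.0 * L[a]
    return out


_DNDL = np.stack([_dN_dL(L) for L in _GP4])   # (4 gp, 10, 4)


def _gradients(corners: np.ndarray):
    """Physical shape-function gradients per element and Gauss point.

    corners: (m, 4, 3).  Returns grads (gp, m, 10, 3) and volumes (m,).
    """
    A = corners[:, 1:] - corners[:, :1]                   # (m, 3 rows?, 3)
    # x = X0 + A^T xi  with A rows = (Xi - X0); grad xi = inv(A)^T? Use:
    # dxi/dx = inv(A) applied as: A (3,3) with A[k] = X_{k+1}-X_0 (row),
    # x = X0 + xi @ A  (xi row vector) -> dxi/dx = inv(A)
    det = np.linalg.det(A)
    invA = np.linalg.inv(A)                               # (m, 3, 3)
    # dL/dx: L_i (i=1..3) = xi_i -> rows of inv(A); L_0 = 1 - sum
    dLdx = np.empty((len(corners), 4, 3))
    dLdx[:, 1:, :] = np.transpose(invA, (0, 2, 1))
    dLdx[:, 0, :] = -dLdx[:, 1:, :].sum(axis=1)
    grads = np.einsum("qia,maj->qmij", _DNDL, dLdx)       # (4, m, 10, 3)
    return grads, det / 6.0


def assemble(mesh: FEMesh, materials: ElementMaterials) -> sp.csr_matrix:
    """Global stiffness (3n x 3n, N/mm) for isotropic heterogeneous elasticity.

    Uses the Lame form K_{ai,bj} = int lam dN_a/dx_i dN_b/dx_j
    + mu dN_a/dx_j dN_b/dx_i + mu delta_ij grad N_a . grad N_b.
    """
    E = np.asarray(materials.modulus, dtype=float)
    nu = np.asarray(materials.poisson, dtype=float)
    if np.any(E <= 0):
        bad = np.flatnonzero(E <= 0)
        raise SolverError(f"non-positive modulus on elements {bad[:10].tolist()}")
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))

    m = mesh.n_elements
    ndof = 3 * mesh.n_nodes
    rows_all, cols_all, vals_all = [], [], []
    chunk = max(1, 200_000 // 30)
    for s in range(0, m, chunk):
        sl = slice(s, min(s + chunk, m))
        corners = mesh.nodes[mesh.elements[sl, :4]]
        grads, vol = _gradients(corners)
        if np.any(vol <= 0):
            raise SolverError("element with non-positive Jacobian")
        mc = len(vol)
        Ke = np.zeros((mc, 10, 3, 10, 3))
        for q in range(4):
            g = grads[q]                                   # (mc, 10, 3)
            w = _W4[q] * vol
            gg = np.einsum("mai,mbj->maibj", g, g)
            Ke += (lam[sl] * w)[:, None, None, None, None] * gg
            Ke += (mu[sl] * w)[:, None, None, None, None] * gg.transpose(0, 1, 4, 3, 2)
            dots = np.einsum("mai,mbi->mab", g, g)
            eye = np.eye(3)
            Ke += np.einsum("m,mab,ij->maibj", mu[sl] * w, dots, eye)
        Ke = Ke.reshape(mc, 30, 30)
        edof = (3 * mesh.elements[sl][:, :, None]
                + np.arange(3)[None, None, :]).reshape(mc, 30)
        rows_all.append(np.repeat(edof, 30, axis=1).ravel())
        cols_all.append(np.tile(edof, (1, 30)).ravel())
        vals_all.append(Ke.ravel())
    K = sp.coo_matrix((np.concatenate(vals_all),
                       (np.concatenate(rows_all), np.concatenate(cols_all))),
                      shape=(ndof, ndof)).tocsr()
    return K


def apply_loads(mesh: FEMesh, case: LoadCase,
                direction: np.ndarray | None = None) -> BoundaryConditions:
    """Uniform compressive pressure per plateau patch, statically equivalent
    to ``medial_fraction * F`` medially and the remainder laterally.

    The traction acts opposite to the mesh's stored loading normal (the
    mechanical axis defined at resection) unless ``direction`` overrides it.
    """
    for name in ("medial", "lateral"):
        if name not in mesh.face_sets or len(mesh.face_sets[name]) == 0:
            raise SolverError(f"empty {name} patch; run tag_sets first")
    if direction is None:
        normal = mesh.meta.get("load_normal", np.array([0.0, 0.0, 1.0]))
        direction = -np.asarray(normal, dtype=float)
    direction = direction / np.linalg.norm(direction)

    forces = np.zeros((mesh.n_nodes, 3))
    shares = {"medial": case.medial_fraction, "lateral": 1.0 - case.medial_fraction}
    for name, share in shares.items():
        faces = mesh.face_sets[name]                       # (k, 6)
        tri = mesh.nodes[faces[:, :3]]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        total_area = areas.sum()
        if total_area <= 0:
            raise SolverError(f"degenerate {name} patch")
        pressure = share * case.total_force / total_area
        # consistent loads of a quadratic triangle under uniform traction:
        # corners 0, midsides A/3 each
        contrib = (areas / 3.0)[:, None] * (pressure * direction)[None, :]
        for k in range(3, 6):
            np.add.at(forces, faces[:, k], contrib)

    fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
    fixed[mesh.node_sets["distal_fixed"]] = True
    bc = BoundaryConditions(fixed=fixed, forces=forces)
    applied = bc.total_force()
    expect = case.total_force
    if abs(np.linalg.norm(applied) - expect) > 1e-9 * expect:
        raise SolverError("assembled load does not match the case total")
    return bc


def solve(K: sp.csr_matrix, bcs: BoundaryConditions,
          residual_tol: float = 1e-8) -> DisplacementField:
    """Sparse direct solve after eliminating constrained dofs."""
    n = bcs.fixed.shape[0]
    fixed = bcs.fixed.ravel()
    if not fixed.any():
        raise SolverError("no constraints: rigid motion is unremoved")
    free = np.flatnonzero(~fixed)
    f = bcs.forces.ravel()
    Kff = K[free][:, free].tocsc()
    try:
        lu = splu(Kff)
        u_free = lu.solve(f[free])
    except RuntimeError as exc:
        raise SolverError(f"singular system (insufficient constraints?): {exc}")
    if not np.all(np.isfinite(u_free)):
        raise SolverError("non-finite solution: system is singular "
                          "(insufficient constraints?)")
    u = np.zeros(3 * n)
    u[free] = u_free
    r = K @ u - f
    fnorm = np.linalg.norm(f)
    residual = float(np.linalg.norm(r[free]) / fnorm) if fnorm > 0 else 0.0
    if residual > residual_tol:
        raise SolverError(f"direct solve residual {residual:.3e} exceeds "
                          f"{residual_tol:.1e}")
    reactions = np.where(fixed, r, 0.0).reshape(n, 3)
    return DisplacementField(u=u.reshape(n, 3), reactions=reactions,
                             residual=residual)
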