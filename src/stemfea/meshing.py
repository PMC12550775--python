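"""Conformal TET10 meshing of the bone-implant assembly.

Strategy: a single Delaunay tessellation of a graded point set covering the
union of the resected bone (with its implant cavity) and the implant.  Points
come from three sources — samples of the boundary surfaces, a jittered
coarse lattice at the global element size, and a jittered fine lattice at the
contact element size inside a configurable offset of the bone-implant
interface.  Elements are classified bone/baseplate/stem by their centroid, so
the two bodies share interface nodes by construction: the bonded contact of
the model is rendered exactly by mesh conformity, with no constraint
equations.  Midside nodes are placed at edge midpoints (straight-sided
quadratic elements), which keeps every element's Jacobian constant and
positive after orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from .geometry import SolidModel

__all__ = [
    "MeshSettings",
    "FEMesh",
    "GeometryContext",
    "ConvergenceResult",
    "MeshingError",
    "mesh_assembly",
    "tag_sets",
    "convergence_study",
    "structured_box_mesh",
    "REGION_BONE",
    "REGION_BASEPLATE",
    "REGION_STEM",
]

REGION_BONE = 0
REGION_BASEPLATE = 1
REGION_STEM = 2

# VTK quadratic-tetra conventions
TET10_EDGES = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
TET_FACES = [(0, 1, 2), (0, 1, 3), (1, 2, 3), (0, 2, 3)]
_EDGE_MID = {frozenset(e): 4 + i for i, e in enumerate(TET10_EDGES)}


class MeshingError(RuntimeError):
    pass


@dataclass(frozen=True)
class MeshSettings:
    """Element sizing and the convergence protocol.

    ``global_size`` applies everywhere except within ``refine_offset`` mm of
    the bone-implant interface, where ``contact_size`` applies.  Elements are
    quadratic (TET10) throughout; ``quality_floor`` is the minimum scaled
    shape quality below which (boundary) slivers are discarded.
    """

    global_size: float = 1.0
    contact_size: float = 0.75
    convergence_tolerance: float = 0.05
    refine_offset: float = 3.0
    quality_floor: float = 0.05
    jitter: float = 0.15
    smooth_iters: int = 4

    def __post_init__(self):
        if not (0 < self.contact_size <= self.global_size):
            raise ValueError("require 0 < contact_size <= global_size")
        if not (0 < self.convergence_tolerance < 0.5):
            raise ValueError("convergence_tolerance must lie in (0, 0.5)")

    def scaled(self, size: float) -> "MeshSettings":
        """Same settings with the global size replaced (contact follows the
        same contact/global ratio)."""
        ratio = self.contact_size / self.global_size
        return MeshSettings(global_size=size, contact_size=ratio * size,
                            convergence_tolerance=self.convergence_tolerance,
                            refine_offset=self.refine_offset,
                            quality_floor=self.quality_floor,
                            jitter=self.jitter, smooth_iters=self.smooth_iters)


@dataclass
class FEMesh:
    """TET10 mesh with region labels and named node/element/face sets.

    ``elements[:, :4]`` are corner nodes, ``elements[:, 4:]`` midside nodes
    in VTK order.  ``regions`` holds REGION_BONE / REGION_BASEPLATE /
    REGION_STEM per element.  ``face_sets`` store 6-node boundary triangle
    connectivity (3 corners + 3 midsides) for load application.
    """

    nodes: np.ndarray
    elements: np.ndarray
    regions: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    face_sets: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def corner_coords(self) -> np.ndarray:
        return self.nodes[self.elements[:, :4]]

    def element_volumes(self) -> np.ndarray:
        x = self.corner_coords()
        a, b, c = (x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0])
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.corner_coords().mean(axis=1)

    def audit(self) -> dict:
        """Validity audit: positive Jacobians (signed volumes), 10 distinct
        nodes per element, and no orphan nodes.  Raises on failure."""
        vols = self.element_volumes()
        if not np.all(vols > 0):
            raise MeshingError(f"{int((vols <= 0).sum())} elements with "
                               "non-positive Jacobian")
        sorted_conn = np.sort(self.elements, axis=1)
        if np.any(sorted_conn[:, 1:] == sorted_conn[:, :-1]):
            raise MeshingError("element with repeated nodes")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.elements.ravel()] = True
        if not used.all():
            raise MeshingError(f"{int((~used).sum())} orphan nodes")
        return {"n_nodes": self.n_nodes, "n_elements": self.n_elements,
                "min_volume": float(vols.min()), "total_volume": float(vols.sum())}


# ---------------------------------------------------------------------------
# Point seeding
# ---------------------------------------------------------------------------

def _thin_by_voxel(points: np.ndarray, cell: float) -> np.ndarray:
    """Keep at most one point per cubic cell of size ``cell`` (deterministic:
    the first point in array order wins)."""
    if len(points) == 0:
        return points
    keys = np.floor(points / cell).astype(np.int64)
    _, idx = np.unique(keys, axis=0, return_index=True)
    return points[np.sort(idx)]


def _lattice(lo, hi, h, rng, jitter):
    axes = [lo[i] + (np.arange(int(np.ceil((hi[i] - lo[i]) / h)) + 1) + 0.5) * h
            for i in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if jitter > 0:
        pts = pts + rng.uniform(-jitter * h, jitter * h, size=pts.shape)
    return pts


def _surface_points(solid: SolidModel, pitch: float) -> np.ndarray:
    return np.asarray(solid.surface(pitch=pitch).vertices, dtype=float)


def mesh_assembly(bone: SolidModel, implant: SolidModel | None,
                  settings: MeshSettings) -> FEMesh:
    """Mesh the resected bone (cavity already carved) and, if present, the
    implant occupying that cavity, as one conformal TET10 tessellation."""
    h, hc, off = settings.global_size, settings.contact_size, settings.refine_offset
    rng = np.random.default_rng(0xC0FFEE)  # fixed: meshing is deterministic
    domain = bone.union(implant) if implant is not None else bone

    def near_interface(pts):
        if implant is None:
            return np.zeros(len(pts), dtype=bool)
        return np.abs(implant.sdf(pts)) <= off

    # --- boundary samples -------------------------------------------------
    pitch = max(0.35, min(1.0, 0.5 * hc))
    bone_surf = _surface_points(bone, pitch)
    fine_mask = near_interface(bone_surf)
    if implant is not None:
        # the cavity wall coincides with the implant surface: represent it
        # once, through the implant's own samples
        on_implant = np.abs(implant.sdf(bone_surf)) < 0.5 * pitch
        imp_surf = _surface_points(implant, pitch)
        imp_surf = imp_surf[np.abs(bone.sdf(imp_surf)) < 10 * off]  # near bone
        surf_fine = np.vstack([imp_surf,
                               bone_surf[fine_mask & ~on_implant]])
        surf_coarse = bone_surf[~fine_mask & ~on_implant]
    else:
        surf_fine = bone_surf[fine_mask]
        surf_coarse = bone_surf[~fine_mask]
    surf_fine = _thin_by_voxel(surf_fine, 0.7 * hc)
    surf_coarse = _thin_by_voxel(surf_coarse, 0.7 * h)
    surface = np.vstack([surf_fine, surf_coarse])

    # --- interior lattices ------------------------------------------------
    lo, hi = domain.bounds
    coarse = _lattice(lo, hi, h, rng, settings.jitter)
    keep = (domain.sdf(coarse) <= -0.45 * h) & ~near_interface(coarse)
    coarse = coarse[keep]
    if implant is not None:
        flo = np.maximum(lo, implant.bounds[0] - (off + hc))
        fhi = np.minimum(hi, implant.bounds[1] + (off + hc))
        fine = _lattice(flo, fhi, hc, rng, settings.jitter)
        keep = (domain.sdf(fine) <= -0.45 * hc) & near_interface(fine)
        fine = fine[keep]
    else:
        fine = np.empty((0, 3))

    # interior points too close to a surface sample would create slivers
    if len(surface):
        tree = cKDTree(surface)
        if len(coarse):
            d, _ = tree.query(coarse, k=1)
            coarse = coarse[d > 0.55 * h]
        if len(fine):
            d, _ = tree.query(fine, k=1)
            fine = fine[d > 0.55 * hc]

    points = np.vstack([surface, fine, coarse])
    is_interior = np.zeros(len(points), dtype=bool)
    is_interior[len(surface):] = True
    # collapse near-duplicates (e.g. doubly-sampled interface patches)
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=0.3 * hc, output_type="ndarray")
    if len(pairs):
        drop = np.zeros(len(points), dtype=bool)
        drop[pairs.max(axis=1)] = True
        points, is_interior = points[~drop], is_interior[~drop]
    if len(points) < 10:
        raise MeshingError("too few seed points; check solids and sizes")

    # --- tessellate, classify, filter ------------------------------------
    tri = Delaunay(points)
    conn = tri.simplices.astype(np.int64)
    cent = points[conn].mean(axis=1)

    regions = np.full(len(conn), -1, dtype=np.int8)
    if implant is not None:
        in_imp = implant.sdf(cent) <= 0.0
        regions[in_imp] = REGION_BASEPLATE  # refined to stem below (tag_sets)
        near = np.abs(implant.sdf(cent)) < max(1.0, hc)
        tol = np.where(near, 0.3 * hc, 0.0)
        in_bone = (bone.sdf(cent) <= tol) & ~in_imp
    else:
        in_bone = bone.sdf(cent) <= 0.0
    regions[in_bone] = REGION_BONE
    keep = regions >= 0
    conn, regions, cent = conn[keep], regions[keep], cent[keep]

    # orientation: positive signed volume
    x = points[conn]
    vol6 = np.einsum("ij,ij->i",
                     np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
                     x[:, 3] - x[:, 0])
    flip = vol6 < 0
    conn[flip, 1], conn[flip, 2] = conn[flip, 2].copy(), conn[flip, 1].copy()
    vol6 = np.abs(vol6)

    # quality floor: discard slivers (scaled volume quality in (0, 1])
    edges = points[conn][:, [e[1] for e in TET10_EDGES]] \
        - points[conn][:, [e[0] for e in TET10_EDGES]]
    lmax = np.linalg.norm(edges, axis=2).max(axis=1)
    quality = np.sqrt(2.0) * vol6 / lmax ** 3
    keep = (vol6 > 1e-9) & (quality >= settings.quality_floor)
    conn, regions = conn[keep], regions[keep]
    if len(conn) == 0:
        raise MeshingError("all elements eliminated by the quality floor")

    conn, regions = _largest_component(conn, regions, len(points))

    # compact node numbering, smooth, then promote to TET10
    used = np.unique(conn)
    remap = np.full(len(points), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    conn = remap[conn]
    nodes = points[used]
    nodes = _smooth_interior(nodes, conn, is_interior[used], domain,
                             settings.smooth_iters, settings.quality_floor)
    nodes10, conn10 = _add_midside_nodes(nodes, conn)

    mesh = FEMesh(nodes=nodes10, elements=conn10.astype(np.int32),
                  regions=regions,
                  meta={"settings": settings})
    mesh.audit()
    return mesh


def _element_quality(nodes, conn):
    """Scaled shape quality in (0, 1]: 1 for the regular tetrahedron."""
    x = nodes[conn]
    vol6 = np.einsum("ij,ij->i",
                     np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
                     x[:, 3] - x[:, 0])
    edges = x[:, [e[1] for e in TET10_EDGES]] - x[:, [e[0] for e in TET10_EDGES]]
    lmax = np.linalg.norm(edges, axis=2).max(axis=1)
    return np.sqrt(2.0) * vol6 / lmax ** 3


def _smooth_interior(nodes, conn, movable, domain, iters: int,
                     quality_floor: float, relax: float = 0.5):
    """Damped Laplacian smoothing of interior (lattice-seeded) corner nodes.

    Boundary samples stay put, so the discretized surface is unchanged;
    moves that would leave the domain or drop any adjacent element below the
    quality floor are reverted, so the floor enforced at element selection
    still holds on the delivered mesh.  Improves element quality and thereby
    the stability of recovered-field extrema between refinement levels."""
    if iters <= 0 or not movable.any():
        return nodes

    a = conn[:, [e[0] for e in TET10_EDGES] + [e[1] for e in TET10_EDGES]].ravel()
    b = conn[:, [e[1] for e in TET10_EDGES] + [e[0] for e in TET10_EDGES]].ravel()
    mov_idx = np.flatnonzero(movable)
    floor = quality_floor
    for _ in range(iters):
        sums = np.zeros_like(nodes)
        cnt = np.zeros(len(nodes))
        np.add.at(sums, a, nodes[b])
        np.add.at(cnt, a, 1.0)
        target = sums / np.maximum(cnt, 1.0)[:, None]
        new = nodes.copy()
        new[mov_idx] += relax * (target[mov_idx] - nodes[mov_idx])
        outside = domain.sdf(new[mov_idx]) > -1e-9
        new[mov_idx[outside]] = nodes[mov_idx[outside]]
        q_old = _element_quality(nodes, conn)
        for _ in range(8):
            q_new = _element_quality(new, conn)
            # an element may sit below the floor only if it was already
            # there and the move did not make it worse
            bad = (q_new < floor) & (q_new < q_old - 1e-12)
            if not bad.any():
                break
            revert = np.unique(conn[bad])
            new[revert] = nodes[revert]
        nodes = new
    return nodes


def _largest_component(conn, regions, n_points):
    """Keep the largest node-connected component of the element set."""
    parent = np.arange(n_points)

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for tet in conn:
        r0 = find(tet[0])
        for k in (1, 2, 3):
            rk = find(tet[k])
            if rk != r0:
                parent[rk] = r0
    roots = np.array([find(t) for t in conn[:, 0]])
    vals, counts = np.unique(roots, return_counts=True)
    main = vals[np.argmax(counts)]
    keep = roots == main
    return conn[keep], regions[keep]


def _add_midside_nodes(nodes, conn):
    """Promote linear tets to TET10 with midside nodes at edge midpoints."""
    m = len(conn)
    pairs = np.stack([conn[:, [a for a, _ in TET10_EDGES]],
                      conn[:, [b for _, b in TET10_EDGES]]], axis=-1)  # (m,6,2)
    pairs = np.sort(pairs.reshape(-1, 2), axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    mid = 0.5 * (nodes[uniq[:, 0]] + nodes[uniq[:, 1]])
    conn10 = np.empty((m, 10), dtype=np.int64)
    conn10[:, :4] = conn
    conn10[:, 4:] = len(nodes) + inverse.reshape(m, 6)
    return np.vstack([nodes, mid]), conn10


# ---------------------------------------------------------------------------
# Set tagging
# ---------------------------------------------------------------------------

@dataclass
class GeometryContext:
    """Geometric facts the mesher cannot know from connectivity alone: the
    solids, the implant frame (plate-top point, loading normal, in-plane
    axes), the sagittal split direction, and the distal fixation band."""

    bone: SolidModel
    implant: SolidModel | None = None
    plate_top_point: np.ndarray | None = None
    load_normal: np.ndarray | None = None       # unit, points proximally
    medial_direction: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    plate_thickness: float = 4.0
    distal_band: float = 1.0
    refine_offset: float = 3.0


def _boundary_faces(mesh: FEMesh):
    """(face corner triple, owner element, local face id) for faces used once."""
    conn = mesh.elements[:, :4]
    m = len(conn)
    faces = np.concatenate([conn[:, f] for f in TET_FACES])           # (4m, 3)
    owners = np.tile(np.arange(m), 4)
    locals_ = np.repeat(np.arange(4), m)
    key = np.sort(faces, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                  return_counts=True)
    boundary = counts[inv] == 1
    return faces[boundary], owners[boundary], locals_[boundary]


def _face6(mesh: FEMesh, owner: int, local: int) -> np.ndarray:
    """6-node connectivity (corners + midsides) of a tet's local face."""
    elem = mesh.elements[owner]
    tri = TET_FACES[local]
    mids = [elem[_EDGE_MID[frozenset((tri[i], tri[(i + 1) % 3]))]]
            for i in range(3)]
    return np.array([elem[tri[0]], elem[tri[1]], elem[tri[2]], *mids])


def tag_sets(mesh: FEMesh, ctx: GeometryContext) -> FEMesh:
    """Populate node/element/face sets: distal fixation, medial/lateral load
    patches on the superior baseplate face, interface nodes, refined ROI."""
    nodes = mesh.nodes
    contact = mesh.meta.get("settings", MeshSettings(3.0, 2.25)).contact_size

    z_min = nodes[:, 2].min()
    distal = np.flatnonzero(nodes[:, 2] <= z_min + ctx.distal_band)
    if len(distal) == 0:
        raise MeshingError("empty distal_fixed set: geometry misaligned")
    mesh.node_sets["distal_fixed"] = distal

    cent = mesh.element_centroids()
    if ctx.implant is not None:
        # split implant region into baseplate and stem by canonical height;
        # the tolerance absorbs centroid drift from mesh smoothing
        n = ctx.load_normal / np.linalg.norm(ctx.load_normal)
        height = (cent - ctx.plate_top_point) @ n
        imp = mesh.regions != REGION_BONE
        mesh.regions = mesh.regions.copy()
        spec = getattr(ctx.implant, "spec", None)
        stemless = spec is not None and getattr(spec, "stem_length", 0.0) == 0.0
        thr = -ctx.plate_thickness - 0.3 * contact
        mesh.regions[imp] = REGION_BASEPLATE
        if not stemless:
            mesh.regions[imp & (height < thr)] = REGION_STEM

        faces, owners, locals_ = _boundary_faces(mesh)
        plate_owner = mesh.regions[owners] == REGION_BASEPLATE
        d = (nodes[faces] - ctx.plate_top_point) @ n        # (k, 3)
        on_top = np.all(np.abs(d) <= 0.5 * contact, axis=1) & plate_owner
        # outward-facing check via face normal
        tri = nodes[faces]
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        fn /= np.linalg.norm(fn, axis=1, keepdims=True) + 1e-300
        on_top &= np.abs(fn @ n) > 0.7

        mdir = ctx.medial_direction / np.linalg.norm(ctx.medial_direction)
        side = (nodes[faces] - ctx.plate_top_point) @ mdir  # (k, 3)
        medial_f = on_top & np.all(side > 0, axis=1)
        lateral_f = on_top & np.all(side < 0, axis=1)
        for name, mask in (("medial", medial_f), ("lateral", lateral_f)):
            if not mask.any():
                raise MeshingError(f"empty {name} load patch: geometry misaligned")
            f6 = np.array([_face6(mesh, o, l)
                           for o, l in zip(owners[mask], locals_[mask])])
            mesh.face_sets[name] = f6
            mesh.node_sets[f"{name}_patch"] = np.unique(f6)

        bone_nodes = np.unique(mesh.elements[mesh.regions == REGION_BONE])
        imp_nodes = np.unique(mesh.elements[mesh.regions != REGION_BONE])
        mesh.node_sets["interface"] = np.intersect1d(bone_nodes, imp_nodes)

        roi = np.flatnonzero(np.abs(ctx.implant.sdf(cent)) <= ctx.refine_offset)
        if len(roi) == 0:
            raise MeshingError("empty refined ROI: geometry misaligned")
        mesh.element_sets["refined_roi"] = roi
        mesh.meta.update(plate_top_point=np.asarray(ctx.plate_top_point, float),
                         load_normal=np.asarray(n, float),
                         medial_direction=mdir,
                         plate_thickness=ctx.plate_thickness)
    return mesh


# ---------------------------------------------------------------------------
# Convergence protocol
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceResult:
    selected_size: float
    converged: bool
    table: pd.DataFrame


def convergence_study(run, sizes, tolerance: float = 0.05) -> ConvergenceResult:
    """Mesh-refinement protocol: run the pipeline at each (descending)
    element size and accept the first size at which every monitored output
    changes by less than ``tolerance`` relative to the previous size.

    ``run(size) -> dict[str, float]`` evaluates the monitored outputs.  If no
    size converges the finest one is returned with ``converged=False``.
    """
    sizes = list(sizes)
    if len(sizes) < 2:
        raise ValueError("need at least two mesh sizes")
    if any(b >= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly descending")

    rows = []
    prev = None
    selected, converged = None, False
    for size in sizes:
        out = run(size)
        row = {"size": size, **out}
        if prev is not None:
            rel = {f"delta_{k}": abs(out[k] - prev[k]) / (abs(prev[k]) or np.inf)
                   for k in out}
            row.update(rel)
            if selected is None and all(v < tolerance for v in rel.values()):
                selected, converged = size, True
        rows.append(row)
        prev = out
    if selected is None:
        selected = sizes[-1]
    return ConvergenceResult(selected_size=selected, converged=converged,
                             table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Structured reference meshes (patch tests, closed-form checks)
# ---------------------------------------------------------------------------

def structured_box_mesh(lengths, h) -> FEMesh:
    """Kuhn (6-tet) subdivision of a box into TET10 elements — a regular,
    conforming mesh for patch tests and closed-form comparisons."""
    lengths = np.asarray(lengths, dtype=float)
    n = np.maximum(1, np.round(lengths / h).astype(int))
    axes = [np.linspace(0, lengths[i], n[i] + 1) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    nodes = grid.reshape(-1, 3)
    idx = np.arange(nodes.shape[0]).reshape(n[0] + 1, n[1] + 1, n[2] + 1)

    c = np.stack(np.meshgrid(*[np.arange(k) for k in n], indexing="ij"),
                 axis=-1).reshape(-1, 3)
    corner = lambda dx, dy, dz: idx[c[:, 0] + dx, c[:, 1] + dy, c[:, 2] + dz]
    v = [corner(0, 0, 0), corner(1, 0, 0), corner(0, 1, 0), corner(1, 1, 0),
         corner(0, 0, 1), corner(1, 0, 1), corner(0, 1, 1), corner(1, 1, 1)]
    kuhn = [(0, 1, 3, 7), (0, 2, 3, 7), (0, 1, 5, 7),
            (0, 4, 5, 7), (0, 2, 6, 7), (0, 4, 6, 7)]
    conn = np.concatenate([np.stack([v[a], v[b], v[c_], v[d]], axis=1)
                           for a, b, c_, d in kuhn])

    x = nodes[conn]
    vol6 = np.einsum("ij,ij->i",
                     np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
                     x[:, 3] - x[:, 0])
    flip = vol6 < 0
    conn[flip, 1], conn[flip, 2] = conn[flip, 2].copy(), conn[flip, 1].copy()

    nodes10, conn10 = _add_midside_nodes(nodes, conn)
    mesh = FEMesh(nodes=nodes10, elements=conn10.astype(np.int32),
                  regions=np.zeros(len(conn10), dtype=np.int8))
    mesh.audit()
    return mesh
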