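"""Virtual surgery on implicit solids: resection, implant construction, cavity carving.

Solids are represented implicitly by an approximate signed-distance function
(negative inside), which makes boolean operations (min/max composition) exact
at the classification level and robust — no fragile surface-mesh booleans.
Triangulated surfaces are derived views extracted by marching cubes, and
volumes are measured by voxel counting, so every solid remains watertight by
construction.

Coordinate convention: right-handed, z proximal (up the shaft), units mm.
The +x half-space is the medial side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from skimage import measure

__all__ = [
    "SolidModel",
    "ResectionPlan",
    "ImplantSpec",
    "CutFace",
    "CoverageReport",
    "IMPLANT_CATALOG",
    "resect_tibia",
    "cut_face_of",
    "build_implant",
    "carve_cavity",
    "check_coverage",
    "axis_extent",
    "width_at",
]


class GeometryError(ValueError):
    """Raised for invalid geometric input or a failed geometric operation."""


class SolidModel:
    """A closed solid defined by an implicit function ``f(points) -> value``.

    ``f`` must be negative inside, positive outside, and approximately equal
    to the signed distance near the boundary (exactness away from the surface
    is not required).  ``bounds`` is a loose axis-aligned bounding box
    ``[[xmin, ymin, zmin], [xmax, ymax, zmax]]`` that fully contains the solid.
    """

    def __init__(self, fn, bounds, tag: str = "solid"):
        self._fn = fn
        self.bounds = np.asarray(bounds, dtype=float).reshape(2, 3)
        self.tag = tag

    # -- evaluation -----------------------------------------------------

    def sdf(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.asarray(self._fn(pts), dtype=float)

    def contains(self, points, tol: float = 0.0) -> np.ndarray:
        return self.sdf(points) <= tol

    # -- CSG ------------------------------------------------------------

    def union(self, other: "SolidModel", tag: str | None = None) -> "SolidModel":
        bounds = np.stack([
            np.minimum(self.bounds[0], other.bounds[0]),
            np.maximum(self.bounds[1], other.bounds[1]),
        ])
        return SolidModel(
            lambda p, a=self, b=other: np.minimum(a.sdf(p), b.sdf(p)),
            bounds, tag or f"{self.tag}|{other.tag}")

    def intersection(self, other: "SolidModel", tag: str | None = None) -> "SolidModel":
        bounds = np.stack([
            np.maximum(self.bounds[0], other.bounds[0]),
            np.minimum(self.bounds[1], other.bounds[1]),
        ])
        return SolidModel(
            lambda p, a=self, b=other: np.maximum(a.sdf(p), b.sdf(p)),
            bounds, tag or f"{self.tag}&{other.tag}")

    def difference(self, other: "SolidModel", tag: str | None = None) -> "SolidModel":
        return SolidModel(
            lambda p, a=self, b=other: np.maximum(a.sdf(p), -b.sdf(p)),
            self.bounds.copy(), tag or f"{self.tag}-{other.tag}")

    def translated(self, vector, tag: str | None = None) -> "SolidModel":
        v = np.asarray(vector, dtype=float).reshape(3)
        out = SolidModel(
            lambda p, a=self, v=v: a.sdf(p - v),
            self.bounds + v, tag or self.tag)
        if hasattr(self, "spec"):
            out.spec = self.spec
        return out

    def rotated(self, rotation, center=(0.0, 0.0, 0.0),
                tag: str | None = None) -> "SolidModel":
        """Rigidly rotate the solid by matrix ``rotation`` about ``center``."""
        R = np.asarray(rotation, dtype=float).reshape(3, 3)
        c = np.asarray(center, dtype=float).reshape(3)
        lo, hi = self.bounds
        grid = np.array(np.meshgrid(*zip(lo, hi), indexing="ij")).reshape(3, -1).T
        moved = (grid - c) @ R.T + c
        bounds = np.stack([moved.min(axis=0), moved.max(axis=0)])
        out = SolidModel(
            lambda p, a=self, R=R, c=c: a.sdf((p - c) @ R + c),
            bounds, tag or self.tag)
        if hasattr(self, "spec"):
            out.spec = self.spec
        return out

    # -- derived views --------------------------------------------------

    def surface(self, pitch: float = 0.6) -> trimesh.Trimesh:
        """Extract a watertight triangulated boundary surface (marching cubes)."""
        lo = self.bounds[0] - 2.0 * pitch
        hi = self.bounds[1] + 2.0 * pitch
        n = np.maximum(2, np.ceil((hi - lo) / pitch).astype(int) + 1)
        axes = [np.linspace(lo[i], lo[i] + (n[i] - 1) * pitch, n[i]) for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        vals = self.sdf(grid.reshape(-1, 3)).reshape(grid.shape[:3])
        if vals.min() > 0:
            raise GeometryError(f"solid '{self.tag}' is empty at pitch {pitch}")
        verts, faces, _, _ = measure.marching_cubes(
            vals, level=0.0, spacing=(pitch, pitch, pitch), allow_degenerate=False)
        verts = verts + lo
        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
        if mesh.volume < 0:
            mesh.invert()
        return mesh

    def volume(self, pitch: float = 0.5) -> float:
        """Solid volume by voxel counting (independent of any surface mesh)."""
        lo, hi = self.bounds
        n = np.maximum(1, np.ceil((hi - lo) / pitch).astype(int))
        axes = [lo[i] + (np.arange(n[i]) + 0.5) * (hi[i] - lo[i]) / n[i] for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        voxel = np.prod((hi - lo) / n)
        return float(np.count_nonzero(self.contains(grid)) * voxel)

    def to_stl(self, path, pitch: float = 0.6) -> None:
        self.surface(pitch=pitch).export(path)


# ---------------------------------------------------------------------------
# Primitive implicit shapes (canonical frames)
# ---------------------------------------------------------------------------

def _superellipse_prism(half_w, half_d, z_lo, z_hi, exponent=6.0, tag="prism"):
    """Prism with a superellipse cross-section, axis along z."""
    def fn(p):
        r = (np.abs(p[:, 0] / half_w) ** exponent
             + np.abs(p[:, 1] / half_d) ** exponent) ** (1.0 / exponent)
        lateral = (r - 1.0) * min(half_w, half_d)
        return np.maximum(lateral, np.maximum(z_lo - p[:, 2], p[:, 2] - z_hi))
    bounds = [[-half_w, -half_d, z_lo], [half_w, half_d, z_hi]]
    return SolidModel(fn, bounds, tag)


def _cylinder(radius, z_lo, z_hi, tag="cyl"):
    def fn(p):
        lateral = np.hypot(p[:, 0], p[:, 1]) - radius
        return np.maximum(lateral, np.maximum(z_lo - p[:, 2], p[:, 2] - z_hi))
    bounds = [[-radius, -radius, z_lo], [radius, radius, z_hi]]
    return SolidModel(fn, bounds, tag)


def _box(half, center, tag="box"):
    half = np.asarray(half, float)
    center = np.asarray(center, float)
    def fn(p):
        d = np.abs(p - center) - half
        return d.max(axis=1)
    return SolidModel(fn, [center - half, center + half], tag)


# ---------------------------------------------------------------------------
# Resection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResectionPlan:
    """Proximal tibial cut: ``depth_below_plateau`` mm below the highest point,
    tilted ``jlo_angle_deg`` (joint line obliquity) about the antero-posterior
    axis, i.e. in the coronal plane."""

    depth_below_plateau: float = 2.0
    jlo_angle_deg: float = 3.0

    def __post_init__(self):
        if self.depth_below_plateau <= 0:
            raise GeometryError("depth_below_plateau must be > 0")
        if abs(self.jlo_angle_deg) >= 15.0:
            raise GeometryError("jlo_angle_deg must satisfy |angle| < 15 deg")

    @property
    def normal(self) -> np.ndarray:
        a = np.deg2rad(self.jlo_angle_deg)
        return np.array([np.sin(a), 0.0, np.cos(a)])


def _top_of(solid: SolidModel, probe: float = 0.5) -> tuple[np.ndarray, float]:
    """Locate the centroid (x, y) near the top and the exact max-z of a solid."""
    lo, hi = solid.bounds
    n = np.maximum(4, np.ceil((hi - lo) / probe).astype(int))
    axes = [np.linspace(lo[i], hi[i], n[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    inside = solid.contains(grid)
    if not inside.any():
        raise GeometryError(f"solid '{solid.tag}' appears empty")
    pts = grid[inside]
    z_hi = pts[:, 2].max()
    top_slab = pts[pts[:, 2] > z_hi - 3.0 * probe]
    cx, cy = top_slab[:, 0].mean(), top_slab[:, 1].mean()
    # bisect along z through (cx, cy) for the exact surface height
    z_in, z_out = z_hi - probe, hi[2] + probe
    for _ in range(60):
        zm = 0.5 * (z_in + z_out)
        if solid.contains([[cx, cy, zm]])[0]:
            z_in = zm
        else:
            z_out = zm
    return np.array([cx, cy]), z_in


def resect_tibia(tibia: SolidModel, plan: ResectionPlan) -> SolidModel:
    """Remove the proximal cap above the resection plane.

    The plane passes ``depth_below_plateau`` mm below the proximal apex of the
    bone (along z) and its normal tilts ``jlo_angle_deg`` from the shaft axis
    in the coronal plane.
    """
    (cx, cy), z_top = _top_of(tibia)
    anchor = np.array([cx, cy, z_top - plan.depth_below_plateau])
    n = plan.normal
    if anchor[2] <= tibia.bounds[0, 2]:
        raise GeometryError("resection plane does not intersect the solid")

    def fn(p, base=tibia, a=anchor, n=n):
        return np.maximum(base.sdf(p), (p - a) @ n)

    out = SolidModel(fn, tibia.bounds.copy(), tag=f"{tibia.tag}_resected")
    out.cut_anchor = anchor
    out.cut_normal = n
    return out


@dataclass
class CutFace:
    """The planar resection face: plane (point, normal) plus an in-plane
    indicator for the bone cross-section."""

    anchor: np.ndarray
    normal: np.ndarray
    _bone: SolidModel = field(repr=False, default=None)

    def basis(self):
        n = self.normal / np.linalg.norm(self.normal)
        u = np.cross(n, [0.0, 1.0, 0.0])
        if np.linalg.norm(u) < 1e-8:
            u = np.cross(n, [1.0, 0.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def contains_inplane(self, uv) -> np.ndarray:
        """Indicator of the bone section for in-plane coordinates (n, 2)."""
        u, v = self.basis()
        uv = np.atleast_2d(uv)
        pts = self.anchor + uv[:, :1] * u + uv[:, 1:2] * v - 0.01 * self.normal
        return self._bone.contains(pts)


def cut_face_of(tibia: SolidModel, plan: ResectionPlan) -> CutFace:
    (cx, cy), z_top = _top_of(tibia)
    anchor = np.array([cx, cy, z_top - plan.depth_below_plateau])
    return CutFace(anchor=anchor, normal=plan.normal, _bone=tibia)


# ---------------------------------------------------------------------------
# Implant
# ---------------------------------------------------------------------------

#: Stem (length mm, diameter mm) per study configuration; model 1 has no stem.
IMPLANT_CATALOG: dict[int, tuple[float, float]] = {
    1: (0.0, 0.0),
    2: (20.0, 9.0),
    3: (45.0, 9.0),
    4: (70.0, 9.0),
    5: (45.0, 12.5),
    6: (45.0, 14.0),
}


@dataclass(frozen=True)
class ImplantSpec:
    """Parametric tibial component: rounded-rectangular baseplate, optional
    press-fit cylindrical extension stem with radial fins at the stem root.

    The commercial component's CAD is proprietary; every dimension here is a
    configurable approximation.  Canonical frame: baseplate superior face at
    z = 0, stem extending toward -z, footprint centered on the origin.
    """

    model_id: int = 1
    stem_length: float = 0.0
    stem_diameter: float = 0.0
    plate_width: float = 64.0
    plate_depth: float = 43.0
    plate_thickness: float = 4.0
    fin_count: int = 4
    fin_length: float = 10.0
    fin_thickness: float = 3.0
    fin_depth: float = 10.0

    def __post_init__(self):
        for name in ("plate_width", "plate_depth", "plate_thickness"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if (self.stem_length == 0) != (self.model_id == 1):
            raise GeometryError("stem_length == 0 if and only if model_id == 1")
        if self.stem_length > 0 and self.stem_diameter <= 0:
            raise GeometryError("stem_diameter must be > 0 when a stem is present")
        cat = IMPLANT_CATALOG.get(self.model_id)
        if cat is not None and self.model_id != 1:
            if (self.stem_length, self.stem_diameter) != cat:
                warnings.warn(
                    f"model {self.model_id}: stem ({self.stem_length}, "
                    f"{self.stem_diameter}) mm is off-catalog (expected {cat}); "
                    "proceeding", stacklevel=2)

    @classmethod
    def from_catalog(cls, model_id: int, **overrides) -> "ImplantSpec":
        if model_id not in IMPLANT_CATALOG:
            raise GeometryError(
                f"invalid model_id {model_id}; valid ids: {sorted(IMPLANT_CATALOG)}")
        length, diam = IMPLANT_CATALOG[model_id]
        return cls(model_id=model_id, stem_length=length, stem_diameter=diam,
                   **overrides)


def build_implant(spec: ImplantSpec) -> SolidModel:
    """Assemble the implant solid in its canonical frame (plate top at z=0)."""
    plate = _superellipse_prism(
        spec.plate_width / 2.0, spec.plate_depth / 2.0,
        -spec.plate_thickness, 0.0, exponent=5.0, tag="baseplate")
    solid = plate
    if spec.stem_length > 0:
        r = spec.stem_diameter / 2.0
        z_tip = -spec.plate_thickness - spec.stem_length
        # bullet-nosed press-fit stem: cylinder with a hemispherical tip
        # (exact capsule distance), avoiding the sharp tip-edge singularity
        z_center = z_tip + r

        def stem_fn(p, r=r, zc=z_center):
            dz = np.minimum(p[:, 2] - zc, 0.0)
            lateral = np.sqrt(p[:, 0] ** 2 + p[:, 1] ** 2 + dz ** 2) - r
            return np.maximum(lateral, p[:, 2] - 0.0)

        stem = SolidModel(stem_fn, [[-r, -r, z_tip], [r, r, 0.0]], "stem")
        solid = solid.union(stem)
        fin_depth = min(spec.fin_depth, spec.stem_length)
        span = r + spec.fin_length
        for k in range(spec.fin_count):
            ang = 2.0 * np.pi * k / spec.fin_count + np.pi / 4.0
            c, s = np.cos(ang), np.sin(ang)
            half = np.array([span, spec.fin_thickness / 2.0, fin_depth / 2.0])
            center = np.array([0.0, 0.0, -spec.plate_thickness - fin_depth / 2.0])

            def fin_fn(p, c=c, s=s, half=half, center=center):
                q = np.empty_like(p)
                q[:, 0] = c * p[:, 0] + s * p[:, 1]
                q[:, 1] = -s * p[:, 0] + c * p[:, 1]
                q[:, 2] = p[:, 2]
                return (np.abs(q - center) - half).max(axis=1)

            fin = SolidModel(fin_fn, [[-span, -span, center[2] - half[2]],
                                      [span, span, center[2] + half[2]]], "fin")
            solid = solid.union(fin)
    solid.tag = f"implant_m{spec.model_id}"
    solid.spec = spec
    return solid


# ---------------------------------------------------------------------------
# Cavity and coverage
# ---------------------------------------------------------------------------

def carve_cavity(tibia_cut: SolidModel, implant: SolidModel,
                 check: bool = True) -> SolidModel:
    """Boolean-subtract the implant from the resected bone.

    With implicit solids the subtraction itself cannot fail; ``check``
    verifies that the implant actually overlaps the bone, which is the only
    way a meaningless (empty-cavity) result can arise.
    """
    if check:
        overlap = tibia_cut.intersection(implant)
        if overlap.volume(pitch=1.0) <= 0.0:
            raise GeometryError(
                "implant does not intersect the resected bone; check placement")
    out = tibia_cut.difference(implant, tag=f"{tibia_cut.tag}_cavity")
    for attr in ("cut_anchor", "cut_normal"):
        if hasattr(tibia_cut, attr):
            setattr(out, attr, getattr(tibia_cut, attr))
    return out


@dataclass(frozen=True)
class CoverageReport:
    coverage: float
    protrusion: bool


def check_coverage(cut_face: CutFace, implant: SolidModel,
                   sample: float = 0.25) -> CoverageReport:
    """Fraction of the resection face covered by the implant footprint, and
    whether any part of the footprint protrudes beyond the bone section."""
    u, v = cut_face.basis()
    lo, hi = implant.bounds
    bone_lo, bone_hi = cut_face._bone.bounds
    half = max(hi[0] - lo[0], hi[1] - lo[1],
               bone_hi[0] - bone_lo[0], bone_hi[1] - bone_lo[1]) / 2.0 + 2.0
    ticks = np.arange(-half, half + sample, sample)
    uu, vv = np.meshgrid(ticks, ticks, indexing="ij")
    uv = np.column_stack([uu.ravel(), vv.ravel()])
    face_mask = cut_face.contains_inplane(uv)
    pts = cut_face.anchor + uv[:, :1] * u + uv[:, 1:2] * v - 0.01 * cut_face.normal
    foot_mask = implant.contains(pts)
    n_face = int(face_mask.sum())
    if n_face == 0:
        raise GeometryError("cut face is empty")
    coverage = float(np.count_nonzero(face_mask & foot_mask) / n_face)
    protrusion = bool(np.any(foot_mask & ~face_mask))
    return CoverageReport(coverage=coverage, protrusion=protrusion)


# ---------------------------------------------------------------------------
# Read-back measurement helpers
# ---------------------------------------------------------------------------

def axis_extent(solid: SolidModel, axis: int = 2, probe: float = 0.5) -> tuple[float, float]:
    """(min, max) coordinate of the solid along ``axis``, bisected to ~1e-6 mm."""
    lo, hi = solid.bounds
    n = np.maximum(4, np.ceil((hi - lo) / probe).astype(int))
    axes = [np.linspace(lo[i], hi[i], n[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    inside = solid.contains(grid)
    if not inside.any():
        raise GeometryError(f"solid '{solid.tag}' appears empty")
    pts = grid[inside]
    out = []
    for sign in (-1.0, 1.0):
        coord = pts[:, axis] * sign
        # bisect along every near-extreme line: the global extreme may lie on
        # a neighbouring sample line, not the one holding the extreme sample
        seeds = pts[coord >= coord.max() - 1.5 * probe]
        p_in = seeds.copy()
        p_out = seeds.copy()
        p_out[:, axis] += sign * 2.0 * probe
        for _ in range(50):
            mid = 0.5 * (p_in + p_out)
            ok = solid.contains(mid)
            p_in[ok] = mid[ok]
            p_out[~ok] = mid[~ok]
        out.append(float((p_in[:, axis] * sign).max() * sign))
    return out[0], out[1]


def width_at(solid: SolidModel, z: float, axis: int = 0, probe: float = 0.2) -> float:
    """Extent of the solid cross-section at height ``z`` along ``axis``."""
    half = probe / 2.0
    bounds = solid.bounds.copy()
    bounds[0, 2], bounds[1, 2] = z - half, z + half
    slab = SolidModel(
        lambda p, s=solid, z=z, h=half: np.maximum(s.sdf(p), np.abs(p[:, 2] - z) - h),
        bounds, "slab")
    lo, hi = axis_extent(slab, axis=axis, probe=probe)
    return hi - lo
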