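"""Synthetic tibia phantom: geometry, ground-truth density field, CT rasterization.

The study pipeline needs a CT-like volume of a proximal tibia.  Patient scans
from the original imaging are not distributable, so this module generates a
tibia-like solid — superellipse cross-sections lofted along the shaft axis,
flaring from a circular diaphysis into a boxy plateau — together with an
analytic density field: a dense cortical shell over a cancellous interior
with a smooth radial density gradient.  Because the density field is known in
closed form at every point, every downstream stage (quadrature integration,
material mapping, mechanics) can be tested against exact ground truth.

Axis convention: z runs along the shaft, z = 0 at the distal (fixed) end and
z = shaft_length at the tibial plateau.  Units mm, densities g/cm^3, HU for
image intensities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import nibabel as nib
import numpy as np

from .geometry import GeometryError, SolidModel
from .materials import AIR_HU, PUBLISHED_TISSUE_THRESHOLD, DensityCalibration

__all__ = [
    "PhantomSpec",
    "CTVolume",
    "DensityGroundTruth",
    "generate_phantom_surface",
    "rasterize_phantom",
]

COMPARTMENT_AIR = 0
COMPARTMENT_CANCELLOUS = 1
COMPARTMENT_CORTICAL = 2

#: CT voxel spacing of the source imaging protocol (mm).
DEFAULT_CT_SPACING = (0.449, 0.449, 0.499)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic proximal tibia.

    Defaults describe an adult proximal tibia segment: ~120 mm of bone from
    the distal fixation plane to the plateau, a 72 x 48 mm plateau, an 11 mm
    diaphysis radius, a cortical shell thinning from 4.5 mm distally to
    1.5 mm at the metaphysis, and a cancellous interior whose density rises
    from 0.30 g/cm^3 at the core to 0.60 g/cm^3 under the cortex.  Noise is
    additive Gaussian in HU (truncated at +-4 SD), at a CT-realistic 15 HU.
    """

    shaft_length: float = 120.0
    plateau_width: float = 72.0
    plateau_depth: float = 48.0
    shaft_outer_radius: float = 11.0
    cortical_thickness_proximal: float = 1.5
    cortical_thickness_distal: float = 4.5
    cortical_density: float = 1.85
    cancellous_density_center: float = 0.30
    cancellous_density_edge: float = 0.60
    noise_sd: float = 15.0
    seed: int = 0

    #: fraction of shaft_length where the metaphyseal flare begins
    flare_start: float = 0.60
    #: medullary canal: marrow density and the normalized-radius fraction the
    #: canal occupies in the diaphysis (fades out through the metaphysis)
    marrow_density: float = 0.15
    canal_radius_fraction: float = 0.55
    #: epiphyseal densification: cancellous density multiplier reached at the
    #: plateau (subchondral bone) and the depth over which it ramps up
    epiphyseal_factor: float = 2.0
    epiphyseal_depth: float = 15.0

    def __post_init__(self):
        for name in ("shaft_length", "plateau_width", "plateau_depth",
                     "shaft_outer_radius", "cortical_thickness_proximal",
                     "cortical_thickness_distal"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be strictly positive")
        for name in ("cortical_thickness_proximal", "cortical_thickness_distal"):
            if getattr(self, name) >= self.shaft_outer_radius:
                raise GeometryError(f"{name} must be < shaft_outer_radius")
        if self.cortical_density <= PUBLISHED_TISSUE_THRESHOLD:
            raise GeometryError(
                f"cortical_density must exceed the tissue threshold "
                f"({PUBLISHED_TISSUE_THRESHOLD} g/cm^3)")
        for name in ("cancellous_density_center", "cancellous_density_edge"):
            if not (0 < getattr(self, name) < PUBLISHED_TISSUE_THRESHOLD):
                raise GeometryError(
                    f"{name} must lie in (0, {PUBLISHED_TISSUE_THRESHOLD}) g/cm^3")
        if self.noise_sd < 0:
            raise GeometryError("noise_sd must be >= 0")
        if not (0 < self.flare_start < 1):
            raise GeometryError("flare_start must lie in (0, 1)")
        if not (0 < self.marrow_density <= self.cancellous_density_center):
            raise GeometryError(
                "marrow_density must lie in (0, cancellous_density_center]")
        if not (0 < self.canal_radius_fraction < 1):
            raise GeometryError("canal_radius_fraction must lie in (0, 1)")
        if self.epiphyseal_factor < 1:
            raise GeometryError("epiphyseal_factor must be >= 1")
        if (self.cancellous_density_edge * self.epiphyseal_factor
                >= PUBLISHED_TISSUE_THRESHOLD):
            raise GeometryError(
                "subchondral density (edge x epiphyseal_factor) must stay "
                f"below the tissue threshold {PUBLISHED_TISSUE_THRESHOLD}")
        if self.epiphyseal_depth <= 0:
            raise GeometryError("epiphyseal_depth must be strictly positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _profile(spec: PhantomSpec, z: np.ndarray):
    """Cross-section half-widths (a, b) and superellipse exponent n at z.

    The diaphysis is circular (n = 2, radius = shaft_outer_radius); from
    ``flare_start`` the section flares quadratically to the plateau footprint
    and the exponent rises to 4 (boxy plateau)."""
    L = spec.shaft_length
    z0 = spec.flare_start * L
    s = np.clip((np.asarray(z, dtype=float) - z0) / (L - z0), 0.0, 1.0) ** 2
    r = spec.shaft_outer_radius
    a = r + (spec.plateau_width / 2.0 - r) * s
    b = r + (spec.plateau_depth / 2.0 - r) * s
    n = 2.0 + 2.0 * s
    return a, b, n


def _radial(spec: PhantomSpec, pts: np.ndarray):
    """Normalized superellipse radius (1 on the lateral surface) and the
    local min half-width used to convert it to an approximate distance."""
    a, b, n = _profile(spec, np.clip(pts[:, 2], 0.0, spec.shaft_length))
    with np.errstate(divide="ignore"):
        rhat = (np.abs(pts[:, 0] / a) ** n + np.abs(pts[:, 1] / b) ** n) ** (1.0 / n)
    return rhat, np.minimum(a, b)


def generate_phantom_surface(spec: PhantomSpec) -> SolidModel:
    """Closed tibia-like solid: watertight by construction (implicit)."""

    def fn(p):
        rhat, minab = _radial(spec, p)
        lateral = (rhat - 1.0) * minab
        return np.maximum(lateral,
                          np.maximum(-p[:, 2], p[:, 2] - spec.shaft_length))

    w, d = spec.plateau_width / 2.0, spec.plateau_depth / 2.0
    bounds = [[-w - 1.0, -d - 1.0, -1.0], [w + 1.0, d + 1.0, spec.shaft_length + 1.0]]
    solid = SolidModel(fn, bounds, tag="tibia")
    solid.spec = spec
    return solid


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


class DensityGroundTruth:
    """Analytic apparent-density field of the phantom.

    Compartments: a cortical shell (constant ``cortical_density``) within the
    local cortical thickness of the lateral surface or the distal end cap,
    and a cancellous interior with three anatomical trends, all smooth:

    * a radial gradient from ``cancellous_density_center`` at the axis to
      ``cancellous_density_edge`` at the endosteal boundary;
    * a medullary canal in the diaphysis — the core of the shaft holds
      marrow-equivalent density, fading out through the metaphyseal flare;
    * epiphyseal (subchondral) densification — cancellous density ramps up
      by ``epiphyseal_factor`` over the last ``epiphyseal_depth`` mm below
      the plateau, emulating the dense bone a proximal resection exposes.

    Outside the solid the density is zero.
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.solid = generate_phantom_surface(spec)

    def _shell_thickness(self, z: np.ndarray) -> np.ndarray:
        s = self.spec
        frac = np.clip(np.asarray(z, dtype=float) / s.shaft_length, 0.0, 1.0)
        return (s.cortical_thickness_distal
                + (s.cortical_thickness_proximal - s.cortical_thickness_distal) * frac)

    def inside(self, points) -> np.ndarray:
        return self.solid.contains(points)

    def compartment(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(len(pts), COMPARTMENT_AIR, dtype=np.int8)
        ins = self.inside(pts)
        rhat, minab = _radial(self.spec, pts)
        depth = (1.0 - rhat) * minab          # distance in from lateral surface
        shell = self._shell_thickness(pts[:, 2])
        cortical = ins & ((depth < shell)
                          | (pts[:, 2] < self.spec.cortical_thickness_distal))
        out[ins] = COMPARTMENT_CANCELLOUS
        out[cortical] = COMPARTMENT_CORTICAL
        return out

    def density(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        comp = self.compartment(pts)
        rhat, _ = _radial(self.spec, pts)
        s = self.spec
        rho = np.zeros(len(pts), dtype=float)
        canc = comp == COMPARTMENT_CANCELLOUS
        q = np.clip(rhat[canc], 0.0, 1.0)
        z = pts[canc, 2]
        base = (s.cancellous_density_center
                + (s.cancellous_density_edge - s.cancellous_density_center) * q ** 2)
        # medullary canal: marrow core in the diaphysis, fading through the
        # lower metaphyseal flare
        z0 = s.flare_start * s.shaft_length
        z1 = z0 + 0.4 * (s.shaft_length - z0)
        axial = 1.0 - _smoothstep((z - z0) / (z1 - z0))
        radial = 1.0 - _smoothstep((q - (s.canal_radius_fraction - 0.2)) / 0.4)
        base = base - (base - s.marrow_density) * radial * axial
        # subchondral densification toward the plateau
        ramp = _smoothstep((z - (s.shaft_length - s.epiphyseal_depth))
                           / s.epiphyseal_depth)
        base = base * (1.0 + (s.epiphyseal_factor - 1.0) * ramp)
        rho[canc] = base
        rho[comp == COMPARTMENT_CORTICAL] = s.cortical_density
        return rho


@dataclass
class CTVolume:
    """HU voxel grid with physical spacing and origin (mm).

    ``hu[i, j, k]`` is the intensity of the voxel whose center sits at
    ``origin + (i, j, k) * spacing``; axes are (x, y, z) with z along the
    shaft.  Background air is -1000 HU.
    """

    hu: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 3:
            raise ValueError("hu must be a 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self):
        return self.hu.shape

    def voxel_centers(self) -> np.ndarray:
        axes = [self.origin[i] + np.arange(self.hu.shape[i]) * self.spacing[i]
                for i in range(3)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def save_nifti(self, path, sidecar: dict | None = None) -> None:
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.hu.astype(np.float32), affine), str(path))
        if sidecar is not None:
            with open(str(path).replace(".nii.gz", "").replace(".nii", "")
                      + ".json", "w") as fh:
                json.dump(sidecar, fh, indent=2)

    @classmethod
    def load_nifti(cls, path) -> "CTVolume":
        img = nib.load(str(path))
        affine = img.affine
        return cls(hu=np.asarray(img.dataobj, dtype=float),
                   spacing=tuple(np.abs(np.diag(affine)[:3])),
                   origin=tuple(affine[:3, 3]))


def rasterize_phantom(spec: PhantomSpec,
                      calibration: DensityCalibration | None = None,
                      spacing: tuple[float, float, float] = DEFAULT_CT_SPACING,
                      margin: float = 4.0) -> tuple[CTVolume, DensityGroundTruth]:
    """Render the phantom to a CT-like HU volume with known ground truth.

    Each voxel center takes ``HU = calibration^-1(rho(x))`` inside the bone
    and -1000 HU (air) outside, plus optional truncated Gaussian noise.
    Returns the volume together with the analytic density field, so tests
    can compare any downstream density estimate to the truth.
    """
    calibration = calibration or DensityCalibration()
    gt = DensityGroundTruth(spec)
    lo = gt.solid.bounds[0] - margin
    hi = gt.solid.bounds[1] + margin
    spacing = tuple(float(s) for s in spacing)
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    origin = tuple(lo)

    axes = [origin[i] + np.arange(n[i]) * spacing[i] for i in range(3)]
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    comp = gt.compartment(centers)
    rho = gt.density(centers)
    hu = np.full(len(centers), AIR_HU)
    inside = comp != COMPARTMENT_AIR
    hu[inside] = calibration.hu(rho[inside])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, size=len(hu))
        np.clip(noise, -4.0 * spec.noise_sd, 4.0 * spec.noise_sd, out=noise)
        hu = hu + noise
    vol = CTVolume(hu=hu.reshape(tuple(n)), spacing=spacing, origin=origin)
    return vol, gt
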