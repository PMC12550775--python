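"""Generate the synthetic proximal-tibia CT volume.

Builds the default phantom — a tibia-like solid with cortical shell,
cancellous interior, medullary canal and subchondral densification — and
rasterizes it to a CT-like HU volume with known ground-truth density.
"""

import numpy as np

from stemfea import DensityCalibration, PhantomSpec, rasterize_phantom
from stemfea.phantom import generate_phantom_surface

spec = PhantomSpec(seed=42)
calib = DensityCalibration()

solid = generate_phantom_surface(spec)
surface = solid.surface(pitch=0.8)
print(f"phantom solid: watertight={surface.is_watertight}, "
      f"enclosed volume {surface.volume / 1000:.1f} cm^3")

ct, truth = rasterize_phantom(spec, calib, spacing=(0.9, 0.9, 1.0))
inside = truth.inside(ct.voxel_centers().reshape(-1, 3))
print(f"CT volume: {'x'.join(map(str, ct.shape))} voxels at "
      f"{ct.spacing} mm, {inside.mean() * 100:.1f}% bone")
hu = ct.hu.ravel()[inside]
print(f"bone HU range: [{hu.min():.0f}, {hu.max():.0f}]  "
      f"(densities {calib.density(hu.min()):.2f} to "
      f"{calib.density(hu.max()):.2f} g/cm^3 before noise)")

ct.save_nifti("phantom.nii.gz", sidecar=spec.to_dict())
solid.to_stl("phantom.stl")
print("wrote phantom.nii.gz (+ JSON sidecar) and phantom.stl")
# The HU range spans marrow (~ -850 HU) to cortical bone (~ +850 HU): the
# linear calibration maps each HU value back to an apparent density, which
# is what the material-mapping stage consumes.
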