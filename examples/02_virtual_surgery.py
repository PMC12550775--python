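"""Virtual knee-replacement surgery on the phantom tibia.

Resects the proximal tibia 2 mm below the plateau at 3 degrees of joint-line
obliquity, sizes a tibial baseplate to the resection face, attaches a
press-fit extension stem, checks coverage, and carves the implant cavity.
"""

import numpy as np

from stemfea import (ImplantSpec, PhantomSpec, ResectionPlan, build_implant,
                     carve_cavity, check_coverage, cut_face_of, resect_tibia)
from stemfea.phantom import generate_phantom_surface

tibia = generate_phantom_surface(PhantomSpec())
plan = ResectionPlan()          # 2 mm below the plateau, 3 deg JLO

cut = resect_tibia(tibia, plan)
face = cut_face_of(tibia, plan)
print(f"resection plane anchor {np.round(face.anchor, 1)} mm, "
      f"normal tilted {plan.jlo_angle_deg} deg from the shaft axis")
print(f"bone volume {tibia.volume() / 1000:.1f} -> {cut.volume() / 1000:.1f} cm^3")

spec = ImplantSpec.from_catalog(6, plate_width=58.0, plate_depth=38.0)
a = np.deg2rad(plan.jlo_angle_deg)
R = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])
implant = build_implant(spec).rotated(R).translated(face.anchor)
print(f"model {spec.model_id}: stem {spec.stem_length} mm x "
      f"{spec.stem_diameter} mm, plate {spec.plate_width} x {spec.plate_depth} mm")

report = check_coverage(face, implant)
print(f"coverage of the resection face: {report.coverage * 100:.1f}%, "
      f"protrusion: {report.protrusion}")

bone = carve_cavity(cut, implant)
print(f"bone after cavity carving: {bone.volume() / 1000:.1f} cm^3 "
      f"(implant displaced {(cut.volume() - bone.volume()) / 1000:.1f} cm^3)")
# The carved bone and the implant share their interface surface exactly,
# which is what lets the mesher render bonded contact by node sharing.
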