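"""Virtual orthopedic surgeries: derotation osteotomy, rectus transfer,
patella advancement, muscle release — with live bone morphometrics.
"""

import numpy as np

from capgap.fixtures import make_toy_model
from capgap.surgery import (
    apply_derotation_osteotomy,
    apply_patella_advancement,
    apply_strength_change,
    bone_morphometrics,
    rectus_transfer,
)
from capgap.model import musculotendon_geometry

model = make_toy_model(seed=0)
bm = bone_morphometrics(model, "thigh")
print(f"pre-op femur: anteversion {bm.anteversion_deg:.1f} deg, "
      f"neck-shaft {bm.neck_shaft_deg:.1f} deg")

# correct the anteversion to 0 by rotating the distal fragment about the shaft
post = apply_derotation_osteotomy(model, "thigh", [0, -0.2, 0], [0, 1, 0],
                                  np.radians(20.0))
bm2 = bone_morphometrics(post, "thigh")
print(f"after 20 deg derotation: anteversion {bm2.anteversion_deg:.1f} deg")

# rectus transfer: via point pinned mid-path, insertion moved to the
# hamstrings insertion, tendon slack length compensated
post2 = rectus_transfer(model)
q0 = np.zeros(4)
k = model.muscle_names.index("rectus_toy")
l0, _ = musculotendon_geometry(model, q0)
l1, _ = musculotendon_geometry(post2, q0)
m0, m1 = model.muscle("rectus_toy"), post2.muscle("rectus_toy")
print(f"rectus transfer: l_mt {l0[k]:.4f} -> {l1[k]:.4f} m, "
      f"l_ts {m0.l_ts:.4f} -> {m1.l_ts:.4f} m, "
      f"l_norm at reference {((l0[k]-m0.l_ts)/m0.l_mo):.4f} -> "
      f"{((l1[k]-m1.l_ts)/m1.l_mo):.4f}")
# Normalized fiber length at the reference posture is preserved exactly: the
# transfer changes the tendon path, not the fiber architecture.

post3 = apply_patella_advancement(model, delta_ligament_length=-0.02)
shift = post3.patella.path[:, 2:4] - model.patella.path[:, 2:4]
print(f"patella advancement (-2 cm ligament): mean patella shift "
      f"{1000 * np.linalg.norm(shift, axis=1).mean():.1f} mm over the knee arc")

released = apply_strength_change(model, "gastroc_toy", 0.0)
print(f"gastrocnemius release: F_max "
      f"{model.muscle('gastroc_toy').F_max:.0f} -> "
      f"{released.muscle('gastroc_toy').F_max:.0f} N")
print("lineage chain:", released.lineage, "->", released.name)
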