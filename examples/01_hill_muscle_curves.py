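"""Rigid-tendon Hill muscle mechanics: force-length curves and fiber state.

Builds the default normalized curve set, evaluates the calibration anchor
(passive force at 1.5 optimal fiber lengths), and shows the rigid-tendon
mapping from musculotendon length to normalized fiber length.
"""

import numpy as np

from capgap.model import (
    MuscleCurveSet,
    MuscleTendonActuator,
    PathPoint,
    evaluate_curve,
    fiber_state,
    muscle_force,
)

curves = MuscleCurveSet()
print("passive force at l_norm = 1.5:",
      round(float(evaluate_curve(curves, "passive", 1.5)), 4))
print("active force at l_norm = 1.0:",
      round(float(evaluate_curve(curves, "active", 1.0)), 4))
# ~0.50 and 1.0: a muscle stretched to 1.5 optimal lengths resists with about
# half its maximum isometric force; the active curve peaks at optimal length.

path = [PathPoint("a", [0, 0, 0], "origin"), PathPoint("a", [0.3, 0, 0], "insertion")]
m = MuscleTendonActuator("demo", path, F_max=1000.0, l_mo=0.10, l_ts=0.20)
for l_mt in (0.26, 0.30, 0.34):
    l, ln = fiber_state(l_mt, m)
    f_passive = muscle_force(m, curves, 0.0, ln)
    f_full = muscle_force(m, curves, 1.0, ln)
    print(f"l_mt={l_mt:.2f} m -> fiber {l:.3f} m (l_norm {ln:.2f}); "
          f"force at a=0: {f_passive:7.1f} N, at a=1: {f_full:7.1f} N")
# The tendon is rigid: fiber length is (l_mt - l_ts)/cos(alpha), so fiber
# kinematics follow the joint geometry directly, with no muscle dynamics.
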