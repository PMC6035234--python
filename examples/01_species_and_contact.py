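"""The two ellipsoid species and their hard-core contact function.

Builds the bifunctional A (2, 2, 10 sigma) and pentafunctional B
(1, 1, 5 sigma) particles, shows where their bonding sites sit, and
evaluates the Perram--Wertheim contact function F for a pair of poses:
F < 1 means overlap, F = 1 tangency, F > 1 separation.
"""
import numpy as np

from patchykin import Pose, build_species, pw_contact, world_sites

for label in "AB":
    sp = build_species(label)
    print(f"species {label}: semiaxes {sp.semiaxes}, mass {sp.mass} m, "
          f"valence {sp.valence}")
    print("  body-frame sites:\n", np.round(sp.site_local_positions, 3))

A, B = build_species("A"), build_species("B")
pose_a = Pose([0.0, 0.0, 0.0])
for dz in (20.0, 15.2, 12.0):
    pose_b = Pose([0.0, 0.0, dz])
    F = pw_contact(pose_a, A, pose_b, B)
    verdict = "separated" if F > 1 else ("tangent" if F == 1 else "OVERLAP")
    print(f"A-B centers {dz:5.1f} sigma apart along z: F = {F:6.3f} "
          f"({verdict})")
print("world-frame A sites at the origin pose:",
      np.round(world_sites(pose_a, A), 3).tolist())
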