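"""Build segment frames from markers and compute Z-X-Y joint angles.

Constructs a tiny two-frame trial in which the hallux is plantarflexed by
20 degrees relative to the forefoot between frames, and prints the Met_Hal
angle series.
"""

import numpy as np

from footkin import TrajectorySet, joint_angles, register_model, rotation_matrix

spec = register_model("new")

# neutral marker positions (mm; X anterior, Y up, Z lateral; right foot)
neutral = {
    "P1": [220.0, 30.0, -26.0],
    "H1": [170.0, 30.0, -26.0],
    "H2": [170.0, 30.0, 0.0],
    "H5": [170.0, 30.0, 34.0],
    "NV": [78.0, 30.0, -33.0],
    "B5": [80.0, 30.0, 33.0],
}

# frame 2: rotate the hallux markers by -20 deg about Z (plantarflexion)
# around the metatarsophalangeal line at x = 170
R = rotation_matrix("z", -20.0)
pivot = np.array([170.0, 30.0, 0.0])
frame2 = dict(neutral)
for m in ("P1", "H1", "H2", "H5"):
    frame2[m] = pivot + R @ (np.array(neutral[m]) - pivot)

traj = TrajectorySet(
    {m: np.stack([np.array(neutral[m]), np.array(frame2[m])]) for m in neutral},
    rate=100.0,
)
angles = joint_angles(traj, spec, joints=("Met_Hal",))

series = angles["Met_Hal"]
for i in range(series.n_frames):
    dfpf, evinv, abdadd = series.angles[i]
    print(f"frame {i}: DfPf={dfpf:+7.3f}  EvInv={evinv:+7.3f}  AbdAdd={abdadd:+7.3f} deg")

# The second frame shows DfPf = -20 deg (plantarflexion of the hallux
# relative to the forefoot); the other two components stay at zero because
# the imposed rotation was purely sagittal.
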