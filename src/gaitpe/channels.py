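"""The 15 kinematic channels of a gait cycle.

A gait lab records the angular trajectory of five lower-limb joints
(pelvis, hip, knee, ankle, forefoot) in three planes of movement:
abduction-adduction (coronal), flexion-extension (sagittal) and
medial-lateral rotation (horizontal).  Every feature table in this
package is indexed by these 5 x 3 = 15 channels, always in the fixed
order of :data:`CHANNELS`.
"""

from __future__ import annotations

from enum import Enum
from typing import NamedTuple


class Joint(str, Enum):
    PELVIS = "pelvis"
    HIP = "hip"
    KNEE = "knee"
    ANKLE = "ankle"
    FOREFOOT = "forefoot"


class Plane(str, Enum):
    ABDUCTION_ADDUCTION = "abduction_adduction"
    FLEXION_EXTENSION = "flexion_extension"
    ROTATION = "rotation"


class Channel(NamedTuple):
    """One joint/plane pair, e.g. hip flexion-extension."""

    joint: Joint
    plane: Plane

    @property
    def label(self) -> str:
        return f"{self.joint.value}_{self.plane.value}"

    @classmethod
    def from_label(cls, label: str) -> "Channel":
        joint_str, _, plane_str = label.partition("_")
        return cls(Joint(joint_str), Plane(plane_str))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: The 15 channels in canonical order (joint-major, plane order as in Plane).
CHANNELS: tuple[Channel, ...] = tuple(
    Channel(j, p) for j in Joint for p in Plane
)

CHANNEL_LABELS: tuple[str, ...] = tuple(c.label for c in CHANNELS)

#: The nine Movement Analysis Profile items, each paired with the kinematic
#: channel it summarises.  MAP scores pelvic tilt/obliquity/rotation, hip
#: flexion/abduction/rotation, knee flexion, ankle dorsi-plantar flexion and
#: foot progression; the pairing below maps each item to the joint/plane
#: whose entropy is its natural predictor.  The pairing is configurable in
#: the model-fitting functions.
MAP_ITEMS: tuple[str, ...] = (
    "map_pelvic_tilt",
    "map_pelvic_obliquity",
    "map_pelvic_rotation",
    "map_hip_flexion",
    "map_hip_abduction",
    "map_hip_rotation",
    "map_knee_flexion",
    "map_ankle_flexion",
    "map_foot_progression",
)

MAP_CHANNEL_PAIRING: dict[str, Channel] = {
    "map_pelvic_tilt": Channel(Joint.PELVIS, Plane.FLEXION_EXTENSION),
    "map_pelvic_obliquity": Channel(Joint.PELVIS, Plane.ABDUCTION_ADDUCTION),
    "map_pelvic_rotation": Channel(Joint.PELVIS, Plane.ROTATION),
    "map_hip_flexion": Channel(Joint.HIP, Plane.FLEXION_EXTENSION),
    "map_hip_abduction": Channel(Joint.HIP, Plane.ABDUCTION_ADDUCTION),
    "map_hip_rotation": Channel(Joint.HIP, Plane.ROTATION),
    "map_knee_flexion": Channel(Joint.KNEE, Plane.FLEXION_EXTENSION),
    "map_ankle_flexion": Channel(Joint.ANKLE, Plane.FLEXION_EXTENSION),
    "map_foot_progression": Channel(Joint.FOREFOOT, Plane.ROTATION),
}
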