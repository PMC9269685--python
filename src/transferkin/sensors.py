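"""Depth-sensor models and joint vocabularies.

Each supported sensor SDK reports a fixed set of named joint centers (its
*joint vocabulary*): the Kinect V2 SDK, the Azure body-tracking SDK and the
Nuitrack SDK for the RealSense D435 each use their own naming scheme for the
same anatomy (``SpineBase`` vs ``Pelvis`` vs ``Waist``).  Joint names are
matched case-insensitively with underscores/hyphens stripped, so
``SHOULDER_LEFT`` and ``ShoulderLeft`` refer to the same joint.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import VocabularyError

__all__ = [
    "Sensor",
    "SensorModel",
    "get_sensor_model",
    "normalize_joint_name",
    "KINECT_V2",
    "KINECT_AZURE",
    "REALSENSE_NUITRACK",
]


class Sensor(str, Enum):
    KINECT_V2 = "kinect_v2"
    KINECT_AZURE = "kinect_azure"
    REALSENSE_NUITRACK = "realsense_nuitrack"


def normalize_joint_name(name: str) -> str:
    """Canonical lookup key: lower-case, underscores/hyphens/spaces removed."""
    return str(name).strip().lower().replace("_", "").replace("-", "").replace(" ", "")


@dataclass(frozen=True)
class SensorModel:
    """A sensor type with its fixed joint vocabulary and nominal frame rate."""

    sensor: Sensor
    joint_vocabulary: tuple[str, ...]
    nominal_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")

    @property
    def name(self) -> str:
        return self.sensor.value

    @property
    def _lookup(self) -> dict[str, str]:
        return {normalize_joint_name(j): j for j in self.joint_vocabulary}

    def resolve_joint(self, raw: str) -> str:
        """Map a raw joint label to its vocabulary spelling.

        Raises :class:`VocabularyError` naming the offender if the joint is
        not part of this sensor's vocabulary.
        """
        key = normalize_joint_name(raw)
        try:
            return self._lookup[key]
        except KeyError:
            raise VocabularyError(
                f"joint {raw!r} is not in the {self.name} vocabulary "
                f"(known: {', '.join(self.joint_vocabulary)})"
            ) from None

    def __contains__(self, raw: str) -> bool:
        return normalize_joint_name(raw) in self._lookup


# Upper-body vocabularies. Only the trunk/shoulder/elbow joints enter the
# kinematic features; heads and necks are carried through untouched.
KINECT_V2 = SensorModel(
    Sensor.KINECT_V2,
    (
        "SpineBase",
        "SpineMid",
        "SpineShoulder",
        "Neck",
        "Head",
        "LeftShoulder",
        "RightShoulder",
        "LeftElbow",
        "RightElbow",
        "LeftWrist",
        "RightWrist",
    ),
)

KINECT_AZURE = SensorModel(
    Sensor.KINECT_AZURE,
    (
        "Pelvis",
        "SpineNavel",
        "SpineChest",
        "Neck",
        "Head",
        "ClavicleLeft",
        "ClavicleRight",
        "ShoulderLeft",
        "ShoulderRight",
        "ElbowLeft",
        "ElbowRight",
        "WristLeft",
        "WristRight",
    ),
)

REALSENSE_NUITRACK = SensorModel(
    Sensor.REALSENSE_NUITRACK,
    (
        "Waist",
        "Torso",
        "Neck",
        "Head",
        "LeftCollar",
        "RightCollar",
        "LeftShoulder",
        "RightShoulder",
        "LeftElbow",
        "RightElbow",
        "LeftWrist",
        "RightWrist",
    ),
)

_MODELS = {
    Sensor.KINECT_V2: KINECT_V2,
    Sensor.KINECT_AZURE: KINECT_AZURE,
    Sensor.REALSENSE_NUITRACK: REALSENSE_NUITRACK,
}

_ALIASES = {
    "kinect_v2": Sensor.KINECT_V2,
    "v2": Sensor.KINECT_V2,
    "kinect_azure": Sensor.KINECT_AZURE,
    "azure": Sensor.KINECT_AZURE,
    "realsense_nuitrack": Sensor.REALSENSE_NUITRACK,
    "realsense": Sensor.REALSENSE_NUITRACK,
    "nuitrack": Sensor.REALSENSE_NUITRACK,
}


def get_sensor_model(sensor: Sensor | SensorModel | str) -> SensorModel:
    """Resolve a sensor given as enum, model, or short name ('azure', 'v2', ...)."""
    if isinstance(sensor, SensorModel):
        return sensor
    if isinstance(sensor, Sensor):
        return _MODELS[sensor]
    key = str(sensor).strip().lower()
    if key in _ALIASES:
        return _MODELS[_ALIASES[key]]
    raise VocabularyError(
        f"unknown sensor {sensor!r}; expected one of {sorted(_ALIASES)}"
    )
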