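"""Harmonize sensor-specific joint vocabularies onto the canonical 5-joint set.

All four kinematic features are computed from five joint centers: the pelvis
(spine base / waist), the upper spine (top of the trunk), both shoulders and
the leading-side elbow.  The Kinect V2 reports all five directly.  The Azure
has no upper-spine joint; it is approximated as the midpoint of the two
clavicle joints (named *SpineUpper*).  The RealSense/Nuitrack map likewise
carries left/right collar joints whose midpoint stands in for the upper
spine — the same combining rule as the Azure, adopted here for symmetry (the
single-point alternative is not supported; see the methods note).

A derived joint is valid only when every source joint is tracked.
Harmonization is per-frame and stateless.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import MappingError
from .io import SkeletonSequence
from .sensors import Sensor, SensorModel, get_sensor_model

__all__ = [
    "CANONICAL_JOINTS",
    "CanonicalFrame",
    "CanonicalSequence",
    "JointMapping",
    "builtin_mapping",
    "harmonize",
    "mapping_to_yaml",
]

#: canonical joints, in order: trunk bottom, trunk top, both shoulders,
#: leading elbow. ``shoulder_left``/``elbow_left`` name the *leading* side
#: slots; with ``side="right"`` the left/right source joints are mirrored
#: into them.
CANONICAL_JOINTS = (
    "pelvis",
    "spine_upper",
    "shoulder_left",
    "shoulder_right",
    "elbow_left",
)


@dataclass(frozen=True)
class CanonicalFrame:
    """One harmonized frame: the five canonical joint positions (mm)."""

    timestamp: float
    pelvis: np.ndarray
    spine_upper: np.ndarray
    shoulder_left: np.ndarray
    shoulder_right: np.ndarray
    elbow_left: np.ndarray
    validity: dict[str, bool] = field(default_factory=dict)

    def position(self, joint: str) -> np.ndarray:
        return getattr(self, joint)

    def is_valid(self, *joints: str) -> bool:
        return all(self.validity.get(j, False) for j in joints)


@dataclass
class CanonicalSequence:
    """Array-backed harmonized recording (canonical joints only)."""

    timestamps: np.ndarray
    positions: dict[str, np.ndarray]  # canonical joint -> (n, 3) mm
    valid: dict[str, np.ndarray]  # canonical joint -> (n,) bool
    sensor: SensorModel | None = None
    side: str = "left"
    trial_id: str = "trial"
    subject_id: str = "subject"

    @property
    def n_frames(self) -> int:
        return int(self.timestamps.shape[0])

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> CanonicalFrame:
        return CanonicalFrame(
            timestamp=float(self.timestamps[i]),
            validity={j: bool(self.valid[j][i]) for j in CANONICAL_JOINTS},
            **{j: self.positions[j][i] for j in CANONICAL_JOINTS},
        )


@dataclass(frozen=True)
class JointMapping:
    """How one sensor's joints produce the canonical set.

    ``direct`` maps canonical name -> source joint; ``derived`` maps
    canonical name -> (rule, source joints).  The only combining rule is
    ``midpoint``.  Every canonical joint is produced exactly once.
    """

    sensor: SensorModel
    direct: dict[str, str]
    derived: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        produced = sorted(list(self.direct) + list(self.derived))
        if produced != sorted(CANONICAL_JOINTS):
            raise MappingError(
                f"mapping must produce each canonical joint exactly once; got {produced}"
            )
        for src in list(self.direct.values()) + [
            s for _, sources in self.derived.values() for s in sources
        ]:
            self.sensor.resolve_joint(src)


_SIDED = {
    "left": {"shoulder_left": "left", "shoulder_right": "right", "elbow_left": "left"},
    "right": {"shoulder_left": "right", "shoulder_right": "left", "elbow_left": "right"},
}


def builtin_mapping(sensor: Sensor | SensorModel | str, side: str = "left") -> JointMapping:
    """The built-in mapping for one of the three supported sensors.

    ``side`` is the leading (transfer-direction) side; ``"right"`` mirrors
    the shoulder/elbow sources.
    """
    model = get_sensor_model(sensor)
    if side not in _SIDED:
        raise MappingError(f"side must be 'left' or 'right', got {side!r}")
    s = _SIDED[side]

    def cap(word: str) -> str:
        return word.capitalize()

    if model.sensor is Sensor.KINECT_V2:
        direct = {
            "pelvis": "SpineBase",
            "spine_upper": "SpineShoulder",
            "shoulder_left": f"{cap(s['shoulder_left'])}Shoulder",
            "shoulder_right": f"{cap(s['shoulder_right'])}Shoulder",
            "elbow_left": f"{cap(s['elbow_left'])}Elbow",
        }
        derived: dict[str, tuple[str, tuple[str, ...]]] = {}
    elif model.sensor is Sensor.KINECT_AZURE:
        direct = {
            "pelvis": "Pelvis",
            "shoulder_left": f"Shoulder{cap(s['shoulder_left'])}",
            "shoulder_right": f"Shoulder{cap(s['shoulder_right'])}",
            "elbow_left": f"Elbow{cap(s['elbow_left'])}",
        }
        derived = {"spine_upper": ("midpoint", ("ClavicleLeft", "ClavicleRight"))}
    elif model.sensor is Sensor.REALSENSE_NUITRACK:
        direct = {
            "pelvis": "Waist",
            "shoulder_left": f"{cap(s['shoulder_left'])}Shoulder",
            "shoulder_right": f"{cap(s['shoulder_right'])}Shoulder",
            "elbow_left": f"{cap(s['elbow_left'])}Elbow",
        }
        derived = {"spine_upper": ("midpoint", ("LeftCollar", "RightCollar"))}
    else:  # pragma: no cover - enum is closed
        raise MappingError(f"unsupported sensor {model.name}")
    return JointMapping(sensor=model, direct=direct, derived=derived)


def harmonize(
    seq: SkeletonSequence,
    side: str = "left",
    mapping: JointMapping | None = None,
) -> CanonicalSequence:
    """Map a sensor recording onto the canonical 5-joint representation."""
    if mapping is None:
        mapping = builtin_mapping(seq.sensor, side=side)
    if mapping.sensor.sensor != seq.sensor.sensor:
        raise MappingError(
            f"mapping is for {mapping.sensor.name}, recording is {seq.sensor.name}"
        )
    n = seq.n_frames
    positions: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}

    def source(joint: str) -> tuple[np.ndarray, np.ndarray]:
        name = seq.sensor.resolve_joint(joint)
        if name not in seq.positions:
            raise MappingError(
                f"recording lacks joint {name!r} required by the {seq.sensor.name} mapping"
            )
        return seq.positions[name], seq.valid[name]

    for canonical, src in mapping.direct.items():
        pos, vld = source(src)
        positions[canonical] = pos.copy()
        valid[canonical] = vld.copy()
    for canonical, (rule, sources) in mapping.derived.items():
        if rule != "midpoint":
            raise MappingError(f"unknown combining rule {rule!r}")
        srcs = [source(s) for s in sources]
        vld = np.logical_and.reduce([v for _, v in srcs])
        pos = np.mean([p for p, _ in srcs], axis=0)
        pos[~vld] = np.nan
        positions[canonical] = pos
        valid[canonical] = vld

    # degenerate trunk (spine_upper == pelvis) is forbidden downstream
    both = valid["pelvis"] & valid["spine_upper"]
    collapsed = both & np.all(
        positions["spine_upper"] == positions["pelvis"], axis=1
    )
    if collapsed.any():
        valid["pelvis"] = valid["pelvis"] & ~collapsed
        valid["spine_upper"] = valid["spine_upper"] & ~collapsed

    return CanonicalSequence(
        timestamps=seq.timestamps.copy(),
        positions=positions,
        valid=valid,
        sensor=seq.sensor,
        side=side,
        trial_id=seq.trial_id,
        subject_id=seq.subject_id,
    )


def mapping_to_yaml(mapping: JointMapping) -> str:
    """Serialize a mapping to documented YAML for audit."""
    doc = {
        "sensor": mapping.sensor.name,
        "direct": dict(mapping.direct),
        "derived": {
            canonical: {"rule": rule, "sources": list(sources)}
            for canonical, (rule, sources) in mapping.derived.items()
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)
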