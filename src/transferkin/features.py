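"""The four lift-phase kinematic features.

All features are computed over the lift phase on the *raw* (unfiltered)
joint coordinates; filtering is only ever used for phase detection.

DSWP
    Displacement of the pelvis (spine base / waist) joint center along the
    transfer (x) axis: final minus initial lift-phase position, reported in
    centimetres (tracked internally in mm).
TF (trunk flexion)
    Angle between the trunk vector (pelvis -> upper spine) and the lab
    vertical y-axis, degrees.
LE (elevation)
    Angle between the trunk vector and the leading upper-arm vector
    (shoulder -> elbow), degrees.
LPOE (plane of elevation)
    Angle between the chest normal — cross(trunk, shoulder-across) — and
    the leading upper-arm vector, both projected onto the transverse plane.
    The transverse plane is body-referenced (normal = trunk vector) by
    default; ``transverse="lab"`` uses the lab horizontal plane instead.

Angle features are the arithmetic means of per-frame angles over the lift
window (both endpoints included); all angles are unsigned, in [0, 180]
degrees.  Frames with an untracked or geometrically degenerate joint are
excluded per feature, and the dropped fraction is reported; more than 25%
dropped flags the trial as low quality.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, TransferKinError
from .harmonize import CanonicalFrame, CanonicalSequence
from .segmentation import PhaseSegmentation

__all__ = [
    "FeatureSet",
    "TrunkBasis",
    "angle_between",
    "dswp",
    "trunk_flexion",
    "elevation",
    "plane_of_elevation",
    "extract_features",
]

FEATURE_NAMES = ("dswp", "lpoe", "le", "tf")
LOW_QUALITY_DROP_FRACTION = 0.25
_EPS = 1e-9

Y_UP = np.array([0.0, 1.0, 0.0])


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two 3-vectors, degrees in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu <= _EPS or nv <= _EPS:
        raise DegenerateGeometryError("angle undefined for a zero vector")
    c = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


@dataclass(frozen=True)
class TrunkBasis:
    """Trunk-referenced basis of one frame.

    ``trunk_vector``: pelvis -> upper spine; ``shoulder_across``: left -> right
    shoulder; ``chest_normal``: cross(trunk, across), orthogonal to both.
    """

    trunk_vector: np.ndarray
    shoulder_across: np.ndarray
    chest_normal: np.ndarray

    @classmethod
    def from_frame(cls, frame: CanonicalFrame) -> "TrunkBasis":
        trunk = frame.spine_upper - frame.pelvis
        across = frame.shoulder_right - frame.shoulder_left
        if np.linalg.norm(trunk) <= _EPS:
            raise DegenerateGeometryError("degenerate trunk vector")
        if np.linalg.norm(across) <= _EPS:
            raise DegenerateGeometryError("degenerate shoulder-across vector")
        normal = np.cross(trunk, across)
        if np.linalg.norm(normal) <= _EPS:
            raise DegenerateGeometryError("trunk and shoulder axes are collinear")
        return cls(trunk_vector=trunk, shoulder_across=across, chest_normal=normal)


def trunk_flexion(frame: CanonicalFrame) -> float:
    """TF of one frame: angle between trunk vector and the vertical, degrees."""
    return angle_between(frame.spine_upper - frame.pelvis, Y_UP)


def elevation(frame: CanonicalFrame) -> float:
    """LE of one frame: angle between trunk and upper-arm vectors, degrees."""
    return angle_between(
        frame.spine_upper - frame.pelvis, frame.elbow_left - frame.shoulder_left
    )


def plane_of_elevation(frame: CanonicalFrame, transverse: str = "trunk") -> float:
    """LPOE of one frame, degrees.

    Projects the chest normal and the upper-arm vector onto the transverse
    plane and returns the angle between the projections.  Raises
    :class:`DegenerateGeometryError` when the upper arm is (near) parallel
    to the plane normal, which collapses its projection.
    """
    basis = TrunkBasis.from_frame(frame)
    if transverse == "trunk":
        plane_normal = basis.trunk_vector
    elif transverse == "lab":
        plane_normal = Y_UP
    else:
        raise TransferKinError(f"transverse must be 'trunk' or 'lab', got {transverse!r}")
    nhat = plane_normal / np.linalg.norm(plane_normal)

    def project(v: np.ndarray) -> np.ndarray:
        return v - np.dot(v, nhat) * nhat

    arm = frame.elbow_left - frame.shoulder_left
    arm_p = project(arm)
    chest_p = project(basis.chest_normal)
    if np.linalg.norm(arm_p) <= 1e-6 * max(np.linalg.norm(arm), 1.0):
        raise DegenerateGeometryError(
            "upper arm is parallel to the transverse-plane normal; projection degenerate"
        )
    if np.linalg.norm(chest_p) <= _EPS:
        raise DegenerateGeometryError("chest normal projection degenerate")
    return angle_between(chest_p, arm_p)


def dswp(pelvis_x: np.ndarray, seg: PhaseSegmentation) -> float:
    """DSWP in cm from the raw pelvis x-series (mm) and a lift segmentation.

    The sign convention follows the transfer direction, so a completed
    transfer is positive regardless of the lab-frame travel direction.
    """
    x = np.asarray(pelvis_x, dtype=float)
    i0, i1 = seg.lift_start_idx, seg.lift_end_idx
    if not (0 <= i0 < i1 < len(x)):
        raise TransferKinError("segmentation indices do not fit the series")
    x0, x1 = x[i0], x[i1]
    if not (np.isfinite(x0) and np.isfinite(x1)):
        # fall back to nearest tracked samples inside the lift window
        inside = np.arange(i0, i1 + 1)
        tracked = inside[np.isfinite(x[inside])]
        if tracked.size < 2:
            raise TransferKinError("no tracked pelvis samples in the lift window")
        x0, x1 = x[tracked[0]], x[tracked[-1]]
    return seg.direction * float(x1 - x0) / 10.0


@dataclass
class FeatureSet:
    """The four lift-phase scalars of one trial, with quality metadata."""

    dswp: float  # cm
    lpoe: float  # degrees
    le: float  # degrees
    tf: float  # degrees
    n_lift_frames: int = 0
    trial_id: str = "trial"
    subject_id: str = "subject"
    sensor: str = ""
    side: str = "left"
    dropped_fraction: dict[str, float] = field(default_factory=dict)
    missing: dict[str, str] = field(default_factory=dict)

    @property
    def low_quality(self) -> bool:
        return any(
            f > LOW_QUALITY_DROP_FRACTION for f in self.dropped_fraction.values()
        )

    def as_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "subject_id": self.subject_id,
            "sensor": self.sensor,
            "side": self.side,
            "dswp": self.dswp,
            "lpoe": self.lpoe,
            "le": self.le,
            "tf": self.tf,
            "n_lift_frames": self.n_lift_frames,
            "low_quality": self.low_quality,
        }


def _angles_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Row-wise unsigned angles between (n,3) arrays; NaN where degenerate."""
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    ok = (nu > _EPS) & (nv > _EPS)
    c = np.full(len(u), np.nan)
    c[ok] = np.einsum("ij,ij->i", u[ok], v[ok]) / (nu[ok] * nv[ok])
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def extract_features(
    transfer: CanonicalSequence,
    seg: PhaseSegmentation,
    transverse: str = "trunk",
) -> FeatureSet:
    """Compute the FeatureSet of one harmonized, segmented transfer.

    A feature with zero valid lift-phase frames is set to NaN and recorded
    in ``missing`` with a reason instead of raising.
    """
    sl = seg.lift_slice
    pos = {j: transfer.positions[j][sl] for j in transfer.positions}
    vld = {j: transfer.valid[j][sl] for j in transfer.valid}
    n = seg.n_lift_frames

    trunk = pos["spine_upper"] - pos["pelvis"]
    arm = pos["elbow_left"] - pos["shoulder_left"]
    across = pos["shoulder_right"] - pos["shoulder_left"]

    ok_trunk = vld["pelvis"] & vld["spine_upper"]
    ok_arm = vld["shoulder_left"] & vld["elbow_left"]
    ok_all = ok_trunk & ok_arm & vld["shoulder_right"]

    tf_frames = _angles_deg(trunk, np.broadcast_to(Y_UP, trunk.shape))
    le_frames = _angles_deg(trunk, arm)

    chest = np.cross(trunk, across)
    if transverse == "trunk":
        plane_normal = trunk
    elif transverse == "lab":
        plane_normal = np.broadcast_to(Y_UP, trunk.shape)
    else:
        raise TransferKinError(f"transverse must be 'trunk' or 'lab', got {transverse!r}")
    nn = np.linalg.norm(plane_normal, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        nhat = plane_normal / np.where(nn > _EPS, nn, np.nan)
    arm_p = arm - np.einsum("ij,ij->i", arm, nhat)[:, None] * nhat
    chest_p = chest - np.einsum("ij,ij->i", chest, nhat)[:, None] * nhat
    # degenerate projections (arm parallel to the plane normal) drop the frame
    proj_ok = np.linalg.norm(arm_p, axis=1) > 1e-6 * np.maximum(
        np.linalg.norm(arm, axis=1), 1.0
    )
    lpoe_frames = _angles_deg(chest_p, arm_p)

    values: dict[str, float] = {}
    dropped: dict[str, float] = {}
    missing: dict[str, str] = {}

    for name, frames, ok in (
        ("tf", tf_frames, ok_trunk),
        ("le", le_frames, ok_arm & ok_trunk),
        ("lpoe", lpoe_frames, ok_all & proj_ok),
    ):
        use = ok & np.isfinite(frames)
        dropped[name] = 1.0 - use.sum() / n
        if use.sum() == 0:
            values[name] = float("nan")
            missing[name] = "no valid lift-phase frames"
        else:
            values[name] = float(frames[use].mean())

    pelvis_x = transfer.positions["pelvis"][:, 0].copy()
    pelvis_x[~transfer.valid["pelvis"]] = np.nan
    dropped["dswp"] = 1.0 - vld["pelvis"].sum() / n
    try:
        values["dswp"] = dswp(pelvis_x, seg)
    except TransferKinError as exc:
        values["dswp"] = float("nan")
        missing["dswp"] = str(exc)

    return FeatureSet(
        dswp=values["dswp"],
        lpoe=values["lpoe"],
        le=values["le"],
        tf=values["tf"],
        n_lift_frames=n,
        trial_id=transfer.trial_id,
        subject_id=transfer.subject_id,
        sensor=transfer.sensor.name if transfer.sensor else "",
        side=transfer.side,
        dropped_fraction=dropped,
        missing=missing,
    )
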