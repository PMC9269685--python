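"""Synthetic paired-sensor transfer generator with known ground truth.

The generator renders a minimal rigid-segment upper body (pelvis, trunk,
shoulder girdle, leading upper arm) through a plateau - rise - plateau
pelvis trajectory, then degrades it with a per-sensor noise model (Gaussian
jitter, a pelvis-only reporting lag, per-frame-per-joint dropout, optional
bias).  Every trial carries its closed-form ground truth: the pelvis x
follows a C1 smoothstep from 0 to ``pelvis_travel`` during the lift, and
the three angle profiles ramp smoothly during the pre/post phases but hold
their prescribed values over a window slightly wider than the lift, so the
analytic lift-phase means are exactly ``tf_peak``, ``le_mean`` and
``lpoe_mean`` and the true DSWP is ``pelvis_travel / 10`` cm.

Default magnitudes are calibrated to realistic able-bodied transfers
(DSWP ~ 47.75 cm, LPOE ~ 84 deg, LE ~ 45 deg, TF ~ 31 deg).

Session simulation draws per-subject feature means from between-subject
distributions and per-trial deviations from within-subject distributions,
renders each trial through every sensor's noise model, and builds the
matching ground-truth score table.  Random streams are split per
(subject, trial) for the motion and per (subject, trial, sensor) for the
noise, so adding a sensor never perturbs existing trials.  "Predicted"
score tables are synthetic stand-ins for ML classifier output: ground truth
with items flipped at a per-sensor error rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agreement import MODELED_ITEMS, ScoreTable, ground_truth_table
from .errors import TransferKinError
from .features import FeatureSet
from .io import SkeletonSequence
from .sensors import Sensor, SensorModel, get_sensor_model

__all__ = [
    "TransferProfile",
    "SensorNoiseModel",
    "SessionDesign",
    "SimulatedTrial",
    "SimulatedSession",
    "simulate_trial",
    "simulate_session",
]

# rigid-segment constants (mm)
TRUNK_LENGTH = 500.0
SHOULDER_HALF_WIDTH = 180.0
UPPER_ARM_LENGTH = 300.0
CLAVICLE_HALF_WIDTH = 60.0
PELVIS_REST = np.array([0.0, 500.0, 2000.0])  # seated pelvis in camera frame

# stable per-sensor stream keys (appending a sensor must not shift others)
_SENSOR_STREAM_KEY = {
    Sensor.KINECT_V2: 1,
    Sensor.KINECT_AZURE: 2,
    Sensor.REALSENSE_NUITRACK: 3,
}


@dataclass(frozen=True)
class TransferProfile:
    """Kinematic prescription of one transfer trial."""

    pelvis_travel: float = 477.5  # mm along +x
    pre_s: float = 2.0
    lift_s: float = 1.0
    post_s: float = 2.0
    tf_peak: float = 30.58  # deg, held through the lift
    le_mean: float = 44.83  # deg
    lpoe_mean: float = 84.38  # deg
    side: str = "left"
    rate: float = 30.0  # Hz

    def __post_init__(self) -> None:
        if min(self.pre_s, self.lift_s, self.post_s) <= 0:
            raise TransferKinError("phase durations must be positive")
        if self.pelvis_travel <= 100.0:
            raise TransferKinError("pelvis_travel must exceed the 100 mm noise floor")
        for name in ("tf_peak", "le_mean", "lpoe_mean"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise TransferKinError(f"{name} must lie in (0, 180) deg, got {v}")
        if self.rate <= 0:
            raise TransferKinError("rate must be positive")


@dataclass(frozen=True)
class SensorNoiseModel:
    """Measurement degradation of one sensor."""

    jitter_sd: float = 0.0  # mm, isotropic per joint per frame
    pelvis_lag: float = 0.0  # s, pelvis joint reported late
    dropout_prob: float = 0.0  # per frame per joint
    bias: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise TransferKinError("jitter_sd must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise TransferKinError("dropout_prob must be in [0, 1)")


@dataclass(frozen=True)
class SessionDesign:
    """Multi-subject, multi-trial, multi-sensor study design."""

    n_subjects: int = 7
    trials_per_subject: int = 10
    sensors: dict[str, SensorNoiseModel] = field(
        default_factory=lambda: {
            "kinect_azure": SensorNoiseModel(jitter_sd=2.0),
            "kinect_v2": SensorNoiseModel(jitter_sd=4.0, pelvis_lag=0.033),
        }
    )
    base_profile: TransferProfile = field(default_factory=TransferProfile)
    # between-/within-subject SDs of the profile parameters
    between_subject_sd: dict[str, float] = field(
        default_factory=lambda: {
            "pelvis_travel": 40.0,
            "tf_peak": 5.0,
            "le_mean": 4.0,
            "lpoe_mean": 4.0,
        }
    )
    within_subject_sd: dict[str, float] = field(
        default_factory=lambda: {
            "pelvis_travel": 20.0,
            "tf_peak": 3.0,
            "le_mean": 2.5,
            "lpoe_mean": 2.5,
        }
    )
    #: transfer type per trial within each subject; cycled/truncated to
    #: trials_per_subject. 'good' unless emulating improper-technique blocks.
    plan: tuple[str, ...] = ("good",)
    #: probability that a synthetic "predicted" item score differs from truth
    score_error_rate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise TransferKinError("reliability designs need n_subjects >= 2")
        if self.trials_per_subject < 1:
            raise TransferKinError("trials_per_subject must be >= 1")

    def trial_types(self) -> list[str]:
        reps = -(-self.trials_per_subject // len(self.plan))
        return list(self.plan * reps)[: self.trials_per_subject]


@dataclass
class SimulatedTrial:
    """One rendered trial: sensor recording plus analytic ground truth."""

    sequence: SkeletonSequence
    truth: FeatureSet
    truth_lift: tuple[int, int]  # noise-free lift window (frame indices)
    profile: TransferProfile


@dataclass
class SimulatedSession:
    recordings: dict[str, list[SkeletonSequence]]  # sensor -> trials
    truth_features: pd.DataFrame
    truth_lift: dict[str, tuple[int, int]]  # trial_id -> window
    truth_scores: ScoreTable
    predicted_scores: dict[str, ScoreTable]  # sensor -> synthetic predictions
    design: SessionDesign


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _hold_profile(
    t: np.ndarray, t0: float, t1: float, rise_s: float, rest: float, held: float
) -> np.ndarray:
    """rest -> held before t0, constant held on [t0, t1], held -> rest after."""
    up = _smoothstep((t - (t0 - rise_s)) / rise_s)
    down = _smoothstep((t - t1) / rise_s)
    return rest + (held - rest) * (up - down)


def _canonical_motion(profile: TransferProfile) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Noise-free canonical joint trajectories (mm) and timestamps."""
    rate = profile.rate
    n = int(round((profile.pre_s + profile.lift_s + profile.post_s) * rate)) + 1
    t = np.arange(n) / rate
    t0, t1 = profile.pre_s, profile.pre_s + profile.lift_s

    u = (t - t0) / profile.lift_s
    x = profile.pelvis_travel * _smoothstep(u)
    pelvis = PELVIS_REST + np.column_stack([x, np.zeros(n), np.zeros(n)])

    # angle profiles hold their lift value over a window wider than the lift
    margin = 0.15
    rise = max(0.3, 0.5 * min(profile.pre_s, profile.post_s))
    theta = np.radians(
        _hold_profile(t, t0 - margin, t1 + margin, rise, 0.0, profile.tf_peak)
    )
    eta = np.radians(
        _hold_profile(t, t0 - margin, t1 + margin, rise, 150.0, profile.le_mean)
    )
    phi = np.radians(
        np.full(n, profile.lpoe_mean)  # plane of elevation held constant
    )

    # trunk leans toward the camera (-z): rotation about the x-axis
    trunk_dir = np.column_stack([np.zeros(n), np.cos(theta), -np.sin(theta)])
    spine_upper = pelvis + TRUNK_LENGTH * trunk_dir

    across_hat = np.tile([-1.0, 0.0, 0.0], (n, 1))  # left -> right shoulders
    shoulder_left = spine_upper - SHOULDER_HALF_WIDTH * across_hat
    shoulder_right = spine_upper + SHOULDER_HALF_WIDTH * across_hat

    chest_normal = np.cross(trunk_dir, across_hat)
    chest_hat = chest_normal / np.linalg.norm(chest_normal, axis=1, keepdims=True)
    arm_dir = (
        np.cos(eta)[:, None] * trunk_dir
        + np.sin(eta)[:, None]
        * (np.cos(phi)[:, None] * chest_hat + np.sin(phi)[:, None] * across_hat)
    )
    elbow_left = shoulder_left + UPPER_ARM_LENGTH * arm_dir

    canon = {
        "pelvis": pelvis,
        "spine_upper": spine_upper,
        "shoulder_left": shoulder_left,
        "shoulder_right": shoulder_right,
        "elbow_left": elbow_left,
        "_across_hat": across_hat,
    }
    return t, canon


def _native_joints(
    canon: dict[str, np.ndarray], model: SensorModel, side: str
) -> tuple[dict[str, np.ndarray], str]:
    """Render canonical joints under the sensor's native joint names.

    Returns the joint dict and the native name of the pelvis joint (needed
    for the pelvis-lag noise).  For midpoint-derived upper-spine joints the
    two source joints are placed symmetrically about the true point.
    """
    lead, trail = ("Left", "Right") if side == "left" else ("Right", "Left")
    across = canon["_across_hat"]
    offset = CLAVICLE_HALF_WIDTH * across
    if model.sensor is Sensor.KINECT_V2:
        joints = {
            "SpineBase": canon["pelvis"],
            "SpineShoulder": canon["spine_upper"],
            f"{lead}Shoulder": canon["shoulder_left"],
            f"{trail}Shoulder": canon["shoulder_right"],
            f"{lead}Elbow": canon["elbow_left"],
        }
        return joints, "SpineBase"
    if model.sensor is Sensor.KINECT_AZURE:
        joints = {
            "Pelvis": canon["pelvis"],
            "ClavicleLeft": canon["spine_upper"] - offset,
            "ClavicleRight": canon["spine_upper"] + offset,
            f"Shoulder{lead}": canon["shoulder_left"],
            f"Shoulder{trail}": canon["shoulder_right"],
            f"Elbow{lead}": canon["elbow_left"],
        }
        return joints, "Pelvis"
    joints = {
        "Waist": canon["pelvis"],
        "LeftCollar": canon["spine_upper"] - offset,
        "RightCollar": canon["spine_upper"] + offset,
        f"{lead}Shoulder": canon["shoulder_left"],
        f"{trail}Shoulder": canon["shoulder_right"],
        f"{lead}Elbow": canon["elbow_left"],
    }
    return joints, "Waist"


def _truth_lift_indices(profile: TransferProfile) -> tuple[int, int]:
    rate = profile.rate
    t0, t1 = profile.pre_s, profile.pre_s + profile.lift_s
    n = int(round((profile.pre_s + profile.lift_s + profile.post_s) * rate)) + 1
    t = np.arange(n) / rate
    i0 = int(np.nonzero(t <= t0 + 1e-9)[0][-1])
    i1 = int(np.nonzero(t >= t1 - 1e-9)[0][0])
    return i0, i1


def simulate_trial(
    profile: TransferProfile,
    noise: SensorNoiseModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    sensor: SensorModel | str = "kinect_azure",
    trial_id: str = "trial",
    subject_id: str = "subject",
) -> SimulatedTrial:
    """Render one trial through one sensor's noise model.

    Same seed (and arguments) -> bit-identical output.
    """
    model = get_sensor_model(sensor)
    noise = noise or SensorNoiseModel()
    rng = np.random.default_rng(seed)
    t, canon = _canonical_motion(profile)
    joints, pelvis_name = _native_joints(canon, model, profile.side)
    n = len(t)

    positions: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for name in joints:
        pos = joints[name].copy()
        if name == pelvis_name and noise.pelvis_lag != 0.0:
            lagged_t = np.clip(t - noise.pelvis_lag, t[0], t[-1])
            pos = np.column_stack(
                [np.interp(lagged_t, t, pos[:, k]) for k in range(3)]
            )
        if name in noise.bias:
            pos = pos + np.asarray(noise.bias[name], dtype=float)
        if noise.jitter_sd > 0:
            pos = pos + rng.normal(0.0, noise.jitter_sd, size=(n, 3))
        v = np.ones(n, dtype=bool)
        if noise.dropout_prob > 0:
            v = rng.random(n) >= noise.dropout_prob
            pos[~v] = np.nan
        positions[name] = pos
        valid[name] = v

    seq = SkeletonSequence(
        sensor=model,
        timestamps=t,
        positions=positions,
        valid=valid,
        trial_id=trial_id,
        subject_id=subject_id,
    )
    i0, i1 = _truth_lift_indices(profile)
    truth = FeatureSet(
        dswp=profile.pelvis_travel / 10.0,
        lpoe=profile.lpoe_mean,
        le=profile.le_mean,
        tf=profile.tf_peak,
        n_lift_frames=i1 - i0 + 1,
        trial_id=trial_id,
        subject_id=subject_id,
        sensor=model.name,
        side=profile.side,
    )
    return SimulatedTrial(sequence=seq, truth=truth, truth_lift=(i0, i1), profile=profile)


#: kinematic consequences of each improper technique, applied to the profile
_IMPROPER_PROFILE_EFFECTS = {
    "good": {},
    "trunk": {"tf_peak": 0.35},  # barely leans: trunk flexion capped low
    "arm": {"lpoe_mean": 1.3},  # leading arm swung out wide
    "feet": {},  # feet placement is invisible to the 5-joint model
    "fist": {},  # hand grip likewise
}


def _apply_type(profile: TransferProfile, ttype: str) -> TransferProfile:
    changes = {
        name: getattr(profile, name) * factor
        for name, factor in _IMPROPER_PROFILE_EFFECTS.get(ttype, {}).items()
    }
    if changes:
        profile = replace(profile, **changes)
    return profile


def _clip_profile_value(name: str, value: float) -> float:
    if name == "pelvis_travel":
        return max(value, 150.0)
    return float(np.clip(value, 5.0, 175.0))


def simulate_session(
    design: SessionDesign, seed: int | np.random.SeedSequence = 0
) -> SimulatedSession:
    """Simulate a full multi-subject, multi-sensor session."""
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    varied = ("pelvis_travel", "tf_peak", "le_mean", "lpoe_mean")
    base = design.base_profile
    types = design.trial_types()

    recordings: dict[str, list[SkeletonSequence]] = {s: [] for s in design.sensors}
    truth_rows = []
    truth_lift: dict[str, tuple[int, int]] = {}
    plan_rows = []

    for si in range(design.n_subjects):
        subj_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(1, si))
        )
        subj_means = {
            name: getattr(base, name)
            + design.between_subject_sd.get(name, 0.0) * subj_rng.standard_normal()
            for name in varied
        }
        subject_id = f"s{si + 1:02d}"
        for ti in range(design.trials_per_subject):
            trial_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=root.entropy, spawn_key=(2, si, ti))
            )
            params = {
                name: _clip_profile_value(
                    name,
                    subj_means[name]
                    + design.within_subject_sd.get(name, 0.0)
                    * trial_rng.standard_normal(),
                )
                for name in varied
            }
            ttype = types[ti]
            profile = _apply_type(replace(base, **params), ttype)
            trial_id = f"{subject_id}_t{ti + 1:02d}"
            plan_rows.append(
                {"trial_id": trial_id, "subject": subject_id, "transfer_type": ttype}
            )
            for sensor_name, noise in design.sensors.items():
                model = get_sensor_model(sensor_name)
                stream = _SENSOR_STREAM_KEY[model.sensor]
                sensor_seed = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(3, si, ti, stream)
                )
                trial = simulate_trial(
                    profile,
                    noise,
                    seed=sensor_seed,
                    sensor=model,
                    trial_id=trial_id,
                    subject_id=subject_id,
                )
                recordings[sensor_name].append(trial.sequence)
            i0, i1 = _truth_lift_indices(profile)
            truth_lift[trial_id] = (i0, i1)
            truth_rows.append(
                {
                    "trial_id": trial_id,
                    "subject_id": subject_id,
                    "transfer_type": ttype,
                    "dswp": profile.pelvis_travel / 10.0,
                    "lpoe": profile.lpoe_mean,
                    "le": profile.le_mean,
                    "tf": profile.tf_peak,
                }
            )

    plan = pd.DataFrame(plan_rows)
    truth_scores = ground_truth_table(plan)
    predicted: dict[str, ScoreTable] = {}
    for sensor_name in design.sensors:
        rate = design.score_error_rate.get(sensor_name, 0.0)
        model = get_sensor_model(sensor_name)
        stream = _SENSOR_STREAM_KEY[model.sensor]
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(4, stream))
        )
        scores = truth_scores.scores.to_numpy().copy()
        if rate > 0:
            flips = rng.random(scores.shape) < rate
            scores = np.where(flips, 1 - scores, scores)
        predicted[sensor_name] = ScoreTable.from_arrays(
            scores,
            trial_ids=list(truth_scores.scores.index),
            subjects=truth_scores.meta["subject"].tolist(),
            transfer_types=truth_scores.meta["transfer_type"].tolist(),
        )

    return SimulatedSession(
        recordings=recordings,
        truth_features=pd.DataFrame(truth_rows),
        truth_lift=truth_lift,
        truth_scores=truth_scores,
        predicted_scores=predicted,
        design=design,
    )
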