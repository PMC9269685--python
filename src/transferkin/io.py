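"""Skeletal recording data model and CSV I/O.

A recording is a time-ordered sequence of frames, each holding the 3D
positions (mm, camera frame: y up, x horizontal along the transfer
direction, z depth) of a sensor's joint centers plus a per-joint tracked /
missing flag.  Sequences are array-backed: timestamps as a 1-D array and,
per joint, an ``(n, 3)`` position array with a boolean validity vector.
Missing samples are stored as NaN with ``valid=False`` — they are retained,
never silently dropped.

The canonical on-disk layout is long-format CSV::

    timestamp,joint,x,y,z,valid

A wide layout (``timestamp,<Joint>_x,<Joint>_y,<Joint>_z[,<Joint>_valid]``)
is auto-detected on read.  Gzip compression is transparent (by file
extension).  Multi-trial session files add ``trial_id`` / ``subject_id``
columns.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError
from .sensors import SensorModel, get_sensor_model

__all__ = [
    "SkeletonFrame",
    "SkeletonSequence",
    "read_recording",
    "read_session",
    "write_recording",
    "write_session",
    "align_pair",
    "AlignedPair",
]

@dataclass(frozen=True)
class SkeletonFrame:
    """One time sample: joint positions (mm) and per-joint validity."""

    timestamp: float
    joints: dict[str, np.ndarray]
    validity: dict[str, bool]

    def position(self, joint: str) -> np.ndarray:
        return self.joints[joint]


@dataclass
class SkeletonSequence:
    """Array-backed, time-ordered skeletal recording from one sensor."""

    sensor: SensorModel
    timestamps: np.ndarray
    positions: dict[str, np.ndarray]  # joint -> (n, 3) mm, NaN where invalid
    valid: dict[str, np.ndarray]  # joint -> (n,) bool
    trial_id: str = "trial"
    subject_id: str = "subject"
    parse_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        n = self.timestamps.shape[0]
        if n < 2:
            raise FormatError("a recording needs at least 2 frames")
        if not np.all(np.diff(self.timestamps) > 0):
            raise FormatError("timestamps must be strictly increasing")
        for joint in list(self.positions):
            resolved = self.sensor.resolve_joint(joint)
            if resolved != joint:  # normalize spelling to the vocabulary's
                self.positions[resolved] = self.positions.pop(joint)
                if joint in self.valid:
                    self.valid[resolved] = self.valid.pop(joint)
            joint = resolved
            pos = np.asarray(self.positions[joint], dtype=float)
            if pos.shape != (n, 3):
                raise FormatError(
                    f"joint {joint!r}: expected shape {(n, 3)}, got {pos.shape}"
                )
            v = np.asarray(
                self.valid.get(joint, np.ones(n, dtype=bool)), dtype=bool
            )
            # a sample is only tracked if all three coordinates are finite
            v = v & np.isfinite(pos).all(axis=1)
            pos = pos.copy()
            pos[~v] = np.nan
            self.positions[joint] = pos
            self.valid[joint] = v

    @property
    def n_frames(self) -> int:
        return int(self.timestamps.shape[0])

    @property
    def joints(self) -> tuple[str, ...]:
        return tuple(self.positions)

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(
            timestamp=float(self.timestamps[i]),
            joints={j: self.positions[j][i] for j in self.positions},
            validity={j: bool(self.valid[j][i]) for j in self.positions},
        )

    def __len__(self) -> int:
        return self.n_frames

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SkeletonSequence):
            return NotImplemented
        if self.sensor.sensor != other.sensor.sensor:
            return False
        if set(self.positions) != set(other.positions):
            return False
        if not np.array_equal(self.timestamps, other.timestamps):
            return False
        for j in self.positions:
            if not np.array_equal(self.valid[j], other.valid[j]):
                return False
            if not np.array_equal(
                self.positions[j], other.positions[j], equal_nan=True
            ):
                return False
        return True

    def to_frame_table(self, include_ids: bool = False) -> pd.DataFrame:
        """Long-format table (one row per frame per joint)."""
        parts = []
        for joint in self.positions:
            pos = self.positions[joint]
            parts.append(
                pd.DataFrame(
                    {
                        "timestamp": self.timestamps,
                        "joint": joint,
                        "x": pos[:, 0],
                        "y": pos[:, 1],
                        "z": pos[:, 2],
                        "valid": self.valid[joint].astype(int),
                    }
                )
            )
        table = pd.concat(parts, ignore_index=True)
        table = table.sort_values(
            ["timestamp", "joint"], kind="stable"
        ).reset_index(drop=True)
        if include_ids:
            table.insert(0, "subject_id", self.subject_id)
            table.insert(0, "trial_id", self.trial_id)
        return table


def _sequence_from_long(
    table: pd.DataFrame,
    sensor: SensorModel,
    trial_id: str = "trial",
    subject_id: str = "subject",
) -> SkeletonSequence:
    for col in ("timestamp", "joint", "x", "y", "z"):
        if col not in table.columns:
            raise FormatError(f"long-format recording is missing column {col!r}")
    joints_raw = table["joint"].astype(str).unique()
    joint_map = {j: sensor.resolve_joint(j) for j in joints_raw}
    table = table.assign(joint=table["joint"].astype(str).map(joint_map))

    timestamps = np.asarray(
        pd.to_numeric(table["timestamp"], errors="raise"), dtype=float
    )
    ts_unique = pd.unique(timestamps)
    if not np.all(np.diff(ts_unique) > 0):
        raise FormatError("non-monotonic timestamps in recording")
    n = ts_unique.shape[0]
    idx = {t: i for i, t in enumerate(ts_unique)}

    positions: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    malformed = 0
    for joint, grp in table.groupby("joint", sort=False):
        pos = np.full((n, 3), np.nan)
        vld = np.zeros(n, dtype=bool)
        coords = np.column_stack(
            [pd.to_numeric(grp[c], errors="coerce") for c in ("x", "y", "z")]
        )
        malformed += int(
            (~np.isfinite(coords)).any(axis=1).sum()
            - grp[["x", "y", "z"]].isna().any(axis=1).sum()
        )
        rows = np.fromiter((idx[t] for t in grp["timestamp"].astype(float)), int)
        flag = (
            pd.to_numeric(grp["valid"], errors="coerce").fillna(0).to_numpy() != 0
            if "valid" in grp.columns
            else np.ones(len(grp), dtype=bool)
        )
        pos[rows] = coords
        vld[rows] = flag & np.isfinite(coords).all(axis=1)
        positions[joint] = pos
        valid[joint] = vld

    seq = SkeletonSequence(
        sensor=sensor,
        timestamps=ts_unique,
        positions=positions,
        valid=valid,
        trial_id=str(trial_id),
        subject_id=str(subject_id),
    )
    seq.parse_report = {
        "n_frames": n,
        "malformed_samples": malformed,
        "missing_per_joint": {j: int((~valid[j]).sum()) for j in valid},
    }
    return seq


def _sequence_from_wide(
    table: pd.DataFrame, sensor: SensorModel, trial_id: str, subject_id: str
) -> SkeletonSequence:
    if "timestamp" not in table.columns:
        raise FormatError("wide-format recording is missing a 'timestamp' column")
    long_rows = []
    joints = sorted(
        {
            c[: -len(suffix)]
            for c in table.columns
            for suffix in ("_x", "_y", "_z")
            if c.endswith(suffix)
        }
    )
    if not joints:
        raise FormatError("no '<joint>_x/_y/_z' columns found in wide recording")
    for joint in joints:
        cols = {}
        for axis in ("x", "y", "z"):
            name = f"{joint}_{axis}"
            if name not in table.columns:
                raise FormatError(f"wide recording lacks column {name!r}")
            cols[axis] = pd.to_numeric(table[name], errors="coerce")
        part = pd.DataFrame(
            {"timestamp": table["timestamp"], "joint": joint, **cols}
        )
        vcol = f"{joint}_valid"
        if vcol in table.columns:
            part["valid"] = table[vcol]
        long_rows.append(part)
    return _sequence_from_long(
        pd.concat(long_rows, ignore_index=True), sensor, trial_id, subject_id
    )


def read_recording(
    path: str | Path,
    sensor: SensorModel | str,
    trial_id: str | None = None,
    subject_id: str | None = None,
) -> SkeletonSequence:
    """Read one recording CSV (long or wide layout, auto-detected).

    Frames whose numeric fields are malformed are flagged missing, not
    dropped; ``seq.parse_report`` summarizes missing counts per joint.
    """
    sensor = get_sensor_model(sensor)
    table = pd.read_csv(path, float_precision="round_trip")
    table.columns = [str(c).strip() for c in table.columns]
    if "joint" in table.columns:
        if "trial_id" in table.columns and table["trial_id"].nunique() > 1:
            raise FormatError(
                "recording contains multiple trial_ids; use read_session()"
            )
        tid = trial_id or (
            str(table["trial_id"].iloc[0]) if "trial_id" in table.columns else Path(path).stem
        )
        sid = subject_id or (
            str(table["subject_id"].iloc[0])
            if "subject_id" in table.columns
            else "subject"
        )
        return _sequence_from_long(table, sensor, tid, sid)
    return _sequence_from_wide(
        table, sensor, trial_id or Path(path).stem, subject_id or "subject"
    )


def read_session(path: str | Path, sensor: SensorModel | str) -> list[SkeletonSequence]:
    """Read a multi-trial long-format file carrying a ``trial_id`` column."""
    sensor = get_sensor_model(sensor)
    table = pd.read_csv(path, float_precision="round_trip")
    table.columns = [str(c).strip() for c in table.columns]
    if "trial_id" not in table.columns:
        return [read_recording(path, sensor)]
    out = []
    for tid, grp in table.groupby("trial_id", sort=False):
        sid = str(grp["subject_id"].iloc[0]) if "subject_id" in grp.columns else "subject"
        out.append(_sequence_from_long(grp, sensor, str(tid), sid))
    return out


def write_recording(seq: SkeletonSequence, path: str | Path) -> None:
    """Write long-format CSV; re-reading reproduces the sequence exactly."""
    table = seq.to_frame_table(include_ids=False)
    try:
        table.to_csv(path, index=False)
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write recording to {path}: {exc}") from exc


def write_session(seqs: list[SkeletonSequence], path: str | Path) -> None:
    """Write several trials to one file with trial_id / subject_id columns."""
    table = pd.concat(
        [s.to_frame_table(include_ids=True) for s in seqs], ignore_index=True
    )
    table.to_csv(path, index=False)


@dataclass(frozen=True)
class AlignedPair:
    """Frame pairs from two recordings matched on a common time base."""

    a: SkeletonSequence
    b: SkeletonSequence
    indices_a: np.ndarray
    indices_b: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.indices_a.shape[0])

    def __len__(self) -> int:
        return self.n_pairs


def align_pair(
    a: SkeletonSequence,
    b: SkeletonSequence,
    max_skew: float | None = None,
    offset_b: float = 0.0,
) -> AlignedPair:
    """Match frames of two recordings by nearest timestamp.

    Matching is mutual nearest-neighbour within ``max_skew`` seconds, so the
    pair count is symmetric in the argument order.  ``offset_b`` is added to
    b's clock first (constant inter-laptop clock offset, if known).  The
    default tolerance is half the coarser sensor's nominal frame period.

    Raises :class:`AlignmentError` when the recordings do not overlap in time.
    """
    if max_skew is None:
        max_skew = 0.5 / min(a.sensor.nominal_rate, b.sensor.nominal_rate)
    ta = a.timestamps
    tb = b.timestamps + offset_b
    if ta[0] > tb[-1] or tb[0] > ta[-1]:
        raise AlignmentError("recordings do not overlap in time")

    def nearest(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(dst, src)
        pos = np.clip(pos, 1, len(dst) - 1)
        left, right = dst[pos - 1], dst[pos]
        take_left = (src - left) <= (right - src)
        return np.where(take_left, pos - 1, pos)

    nn_ab = nearest(ta, tb)  # for each a frame, nearest b frame
    nn_ba = nearest(tb, ta)
    ia = np.arange(len(ta))
    mutual = nn_ba[nn_ab] == ia
    within = np.abs(ta - tb[nn_ab]) <= max_skew + 1e-12
    keep = mutual & within
    return AlignedPair(a=a, b=b, indices_a=ia[keep], indices_b=nn_ab[keep])
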