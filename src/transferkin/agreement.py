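"""Binary TAI item-score agreement and accuracy.

The Transfer Assessment Instrument (TAI) scores each checklist item 1
(properly executed) or 0 (improperly executed).  Eleven items are modeled
(items 1, 2 and 7-15).  This module compares two predicted score tables
item by item (percent agreement), and predicted tables against ground
truth stratified by transfer type (confusion accuracy), and builds the
ground-truth table implied by a transfer-type plan: a ``good`` trial scores
1 on every item, while each improper technique zeroes its targeted item(s)
— feet off the ground -> item 7, no trunk lean -> item 13, leading arm too
far out -> items 9 and 12 (arm position before/after the transfer), fist
grip -> item 11.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AgreementError

__all__ = [
    "MODELED_ITEMS",
    "TRANSFER_TYPES",
    "DEFAULT_TARGET_MAP",
    "ScoreTable",
    "AgreementReport",
    "AccuracyReport",
    "percent_agreement",
    "accuracy_vs_truth",
    "ground_truth_table",
]

#: the TAI items covered by the auto-scoring models
MODELED_ITEMS = (1, 2, 7, 8, 9, 10, 11, 12, 13, 14, 15)

TRANSFER_TYPES = ("good", "feet", "trunk", "arm", "fist")

#: items zeroed in the ground truth for each improper transfer type
DEFAULT_TARGET_MAP: dict[str, tuple[int, ...]] = {
    "good": (),
    "feet": (7,),
    "trunk": (13,),
    "arm": (9, 12),
    "fist": (11,),
}


def _item_columns(items=MODELED_ITEMS) -> list[str]:
    return [f"item_{i}" for i in items]


@dataclass
class ScoreTable:
    """Trials x TAI-items grid of binary scores plus trial metadata."""

    scores: pd.DataFrame  # index: trial_id, columns: item_<k>, values in {0, 1}
    meta: pd.DataFrame  # index: trial_id, columns: subject, transfer_type

    def __post_init__(self) -> None:
        expected = _item_columns()
        if list(self.scores.columns) != expected:
            raise AgreementError(
                f"score columns must be exactly {expected}, got {list(self.scores.columns)}"
            )
        vals = self.scores.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise AgreementError("score entries must be 0 or 1")
        if not self.scores.index.equals(self.meta.index):
            raise AgreementError("scores and metadata must share trial ids")

    @property
    def items(self) -> tuple[int, ...]:
        return MODELED_ITEMS

    @property
    def n_trials(self) -> int:
        return len(self.scores)

    @classmethod
    def from_arrays(
        cls,
        scores: np.ndarray,
        trial_ids=None,
        subjects=None,
        transfer_types=None,
    ) -> "ScoreTable":
        scores = np.asarray(scores, dtype=int)
        n = scores.shape[0]
        if scores.shape[1] != len(MODELED_ITEMS):
            raise AgreementError(
                f"expected {len(MODELED_ITEMS)} item columns, got {scores.shape[1]}"
            )
        idx = pd.Index(
            trial_ids if trial_ids is not None else [f"t{i:04d}" for i in range(n)],
            name="trial_id",
        )
        meta = pd.DataFrame(
            {
                "subject": subjects if subjects is not None else ["s1"] * n,
                "transfer_type": transfer_types
                if transfer_types is not None
                else ["good"] * n,
            },
            index=idx,
        )
        return cls(
            scores=pd.DataFrame(scores, index=idx, columns=_item_columns()), meta=meta
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        df = pd.read_csv(path)
        if "trial_id" not in df.columns:
            raise AgreementError("score CSV needs a trial_id column")
        df = df.set_index("trial_id")
        meta = pd.DataFrame(
            {
                "subject": df.get("subject", pd.Series("s1", index=df.index)),
                "transfer_type": df.get(
                    "transfer_type", pd.Series("good", index=df.index)
                ),
            },
            index=df.index,
        )
        missing = [c for c in _item_columns() if c not in df.columns]
        if missing:
            raise AgreementError(f"score CSV is missing item columns: {missing}")
        return cls(scores=df[_item_columns()].astype(int), meta=meta)

    def to_csv(self, path: str | Path) -> None:
        out = pd.concat([self.meta, self.scores], axis=1)
        out.to_csv(path, index=True)


@dataclass
class AgreementReport:
    """Per-item agreement counts/percentages plus overall mean and STD."""

    per_item: pd.DataFrame  # item, n_agree, n_disagree, percent_agreement
    overall_mean_percent: float
    overall_std_percent: float
    overall_mean_agree: float
    overall_std_agree: float
    n_trials: int


@dataclass
class AccuracyReport:
    """Percent accuracy vs ground truth per (item, transfer type)."""

    accuracy: pd.DataFrame  # index: item, columns: transfer types, values %
    confusion: dict = field(default_factory=dict)  # (type, item) -> counts dict
    warnings: list[str] = field(default_factory=list)


def _check_aligned(a: ScoreTable, b: ScoreTable) -> None:
    if not a.scores.index.equals(b.scores.index):
        raise AgreementError("score tables cover different trials")
    if list(a.scores.columns) != list(b.scores.columns):
        raise AgreementError("score tables cover different items")


def percent_agreement(a: ScoreTable, b: ScoreTable) -> AgreementReport:
    """Per-item percent agreement between two score tables (symmetric)."""
    _check_aligned(a, b)
    n = a.n_trials
    if n == 0:
        raise AgreementError("empty score tables")
    equal = (a.scores.to_numpy() == b.scores.to_numpy()).sum(axis=0)
    per_item = pd.DataFrame(
        {
            "item": list(MODELED_ITEMS),
            "n_agree": equal.astype(int),
            "n_disagree": (n - equal).astype(int),
            "percent_agreement": 100.0 * equal / n,
        }
    )
    return AgreementReport(
        per_item=per_item,
        overall_mean_percent=float(per_item["percent_agreement"].mean()),
        overall_std_percent=float(per_item["percent_agreement"].std(ddof=1)),
        overall_mean_agree=float(per_item["n_agree"].mean()),
        overall_std_agree=float(per_item["n_agree"].std(ddof=1)),
        n_trials=n,
    )


def accuracy_vs_truth(pred: ScoreTable, truth: ScoreTable) -> AccuracyReport:
    """Confusion-matrix accuracy of predicted scores per transfer-type stratum.

    For each (transfer type, item) cell, accuracy is 100 x matches / stratum
    size; the full 2x2 confusion counts are retained (with truth 1 = positive
    class, i.e. properly executed).
    """
    _check_aligned(pred, truth)
    types = [t for t in TRANSFER_TYPES if t in set(truth.meta["transfer_type"])]
    extra = sorted(set(truth.meta["transfer_type"]) - set(TRANSFER_TYPES))
    types += extra
    notes: list[str] = []
    acc = pd.DataFrame(index=pd.Index(list(MODELED_ITEMS), name="item"), dtype=float)
    confusion: dict = {}
    for ttype in types:
        mask = (truth.meta["transfer_type"] == ttype).to_numpy()
        if mask.sum() == 0:
            notes.append(f"empty stratum {ttype!r} omitted")
            continue
        p = pred.scores.to_numpy()[mask]
        t = truth.scores.to_numpy()[mask]
        acc[ttype] = 100.0 * (p == t).mean(axis=0)
        for j, item in enumerate(MODELED_ITEMS):
            confusion[(ttype, item)] = {
                "tp": int(((p[:, j] == 1) & (t[:, j] == 1)).sum()),
                "tn": int(((p[:, j] == 0) & (t[:, j] == 0)).sum()),
                "fp": int(((p[:, j] == 1) & (t[:, j] == 0)).sum()),
                "fn": int(((p[:, j] == 0) & (t[:, j] == 1)).sum()),
            }
    return AccuracyReport(accuracy=acc, confusion=confusion, warnings=notes)


def ground_truth_table(
    plan: pd.DataFrame,
    target_map: dict[str, tuple[int, ...]] | None = None,
) -> ScoreTable:
    """Ground-truth scores implied by a transfer-type plan.

    ``plan`` needs a ``transfer_type`` column (and optionally ``trial_id``,
    ``subject``).  Unknown types raise :class:`AgreementError`.  The
    item-targeting map is overridable (e.g. to also zero item 10 for the
    fist condition).
    """
    target_map = dict(DEFAULT_TARGET_MAP if target_map is None else target_map)
    if "transfer_type" not in plan.columns:
        raise AgreementError("plan needs a transfer_type column")
    unknown = sorted(set(plan["transfer_type"]) - set(target_map))
    if unknown:
        raise AgreementError(f"unknown transfer type(s) {unknown}")
    n = len(plan)
    scores = np.ones((n, len(MODELED_ITEMS)), dtype=int)
    col_of = {item: j for j, item in enumerate(MODELED_ITEMS)}
    for row, ttype in enumerate(plan["transfer_type"]):
        for item in target_map[ttype]:
            scores[row, col_of[item]] = 0
    return ScoreTable.from_arrays(
        scores,
        trial_ids=plan["trial_id"].tolist() if "trial_id" in plan.columns else None,
        subjects=plan["subject"].tolist() if "subject" in plan.columns else None,
        transfer_types=plan["transfer_type"].tolist(),
    )
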