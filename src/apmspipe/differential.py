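"""Differential bait-prey interaction calling across a treatment condition.

A four-gate cascade decides, for every prey, whether its association with
the bait changes upon treatment (here: AtRA-induced myeloid
differentiation):

1. **IgG gate** — the prey must be at least ``igg_fc``-fold (default 1.5)
   enriched in all bait IPs over pooled IgG controls, i.e. be a plausible
   interactor at all.
2. **Ratio gate** — the untreated/treated group-mean ratio (both floored)
   must change at least ``ratio_fc``-fold in either direction (>= 2 or
   <= 0.5 by default).
3. **Consistency gate** — every matched biological pair that detects the
   prey must agree with the global direction; opposite-direction pairs
   mark likely false positives.
4. **Presence gate** — the prey must be detected (count > 0) in more than
   one bait sample.

Gates are evaluated in this fixed order and the first failure is recorded,
so rejection reasons are auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .design_io import (
    ENUM_REGISTRY,
    Condition,
    CountMatrix,
    SampleManifest,
    ValidationError,
)
from .quantitation import DEFAULT_FLOOR

__all__ = [
    "Direction",
    "RejectionStage",
    "DifferentialRecord",
    "differential_cascade",
]

logger = logging.getLogger(__name__)


class Direction(str, Enum):
    UP_IN_UNTREATED = "up_in_untreated"
    UP_IN_TREATED = "up_in_treated"
    NOT_DETECTED = "not_detected"


class RejectionStage(str, Enum):
    IGG_GATE = "igg_gate"
    RATIO_GATE = "ratio_gate"
    CONSISTENCY_GATE = "consistency_gate"
    PRESENCE_GATE = "presence_gate"
    NONE = "none"


class DiffVerdict(str, Enum):
    SELECTIVE = "selective"
    REJECTED = "rejected"


ENUM_REGISTRY["Direction"] = Direction
ENUM_REGISTRY["RejectionStage"] = RejectionStage
ENUM_REGISTRY["DiffVerdict"] = DiffVerdict


@dataclass(frozen=True)
class DifferentialRecord:
    protein_id: str
    igg_fold_change: float
    condition_ratio: float
    direction: Direction
    pair_directions: tuple[tuple[str, Direction], ...]
    consistent: bool
    n_samples_detected: int
    verdict: DiffVerdict
    rejection_stage: RejectionStage

    # --- TSV hooks (pair_directions is nested) ------------------------------

    def to_row(self) -> dict:
        d = {
            "protein_id": self.protein_id,
            "igg_fold_change": self.igg_fold_change,
            "condition_ratio": self.condition_ratio,
            "direction": self.direction.value,
            "pair_directions": ";".join(
                f"{pid}:{dirn.value}" for pid, dirn in self.pair_directions
            ),
            "consistent": str(self.consistent),
            "n_samples_detected": self.n_samples_detected,
            "verdict": self.verdict.value,
            "rejection_stage": self.rejection_stage.value,
        }
        return d

    @classmethod
    def row_columns(cls) -> list[str]:
        return [
            "protein_id",
            "igg_fold_change",
            "condition_ratio",
            "direction",
            "pair_directions",
            "consistent",
            "n_samples_detected",
            "verdict",
            "rejection_stage",
        ]

    @classmethod
    def from_row(cls, row: Mapping[str, str]) -> "DifferentialRecord":
        pd_field = str(row["pair_directions"])
        pairs: tuple[tuple[str, Direction], ...] = ()
        if pd_field:
            pairs = tuple(
                (tok.split(":")[0], Direction(tok.split(":")[1]))
                for tok in pd_field.split(";")
            )
        return cls(
            protein_id=str(row["protein_id"]),
            igg_fold_change=float(row["igg_fold_change"]),
            condition_ratio=float(row["condition_ratio"]),
            direction=Direction(row["direction"]),
            pair_directions=pairs,
            consistent=str(row["consistent"]) == "True",
            n_samples_detected=int(row["n_samples_detected"]),
            verdict=DiffVerdict(row["verdict"]),
            rejection_stage=RejectionStage(row["rejection_stage"]),
        )


def _ratio_direction(
    ratio: float, dead_zone: tuple[float, float]
) -> Direction:
    lo, hi = dead_zone
    if ratio >= hi:
        return Direction.UP_IN_UNTREATED
    if ratio <= lo:
        return Direction.UP_IN_TREATED
    return Direction.NOT_DETECTED


def differential_cascade(
    matrix: CountMatrix,
    manifest: SampleManifest,
    floor: float = DEFAULT_FLOOR,
    igg_fc: float = 1.5,
    ratio_fc: float = 2.0,
    dead_zone: tuple[float, float] = (0.83, 1.2),
) -> list[DifferentialRecord]:
    """Run the four-gate differential cascade on every protein.

    The condition ratio is untreated-group mean over treated-group mean,
    both floored.  Pair directions use floored per-pair ratios; a pair
    whose ratio falls inside ``dead_zone`` (exclusive) — or with no
    detection at all — counts as not_detected and does not vote.  With no
    matched pairs in the manifest the consistency gate is skipped with a
    warning.
    """
    untx = manifest.bait_samples(Condition.UNTREATED)
    trt = manifest.bait_samples(Condition.TREATED)
    if not untx or not trt:
        raise ValidationError("need bait samples in both conditions")
    baits = manifest.bait_samples()
    ctrls = manifest.control_samples()
    pairs = manifest.pairs()
    if not pairs:
        logger.warning("no matched pairs in manifest; consistency gate skipped")

    bait_mean = matrix.group_mean(baits)
    ctrl_mean = matrix.group_mean(ctrls)
    untx_mean = matrix.group_mean(untx)
    trt_mean = matrix.group_mean(trt)
    detected = (matrix.subset(baits) > 0).sum(axis=1)
    df = matrix.df

    records = []
    for pid in matrix.proteins:
        igg_fold = max(float(bait_mean[pid]), floor) / max(float(ctrl_mean[pid]), floor)
        ratio = max(float(untx_mean[pid]), floor) / max(float(trt_mean[pid]), floor)
        if ratio >= ratio_fc:
            direction = Direction.UP_IN_UNTREATED
        elif ratio <= 1.0 / ratio_fc:
            direction = Direction.UP_IN_TREATED
        else:
            direction = Direction.NOT_DETECTED

        pair_dirs = []
        for pair_id, (s_untx, s_trt) in pairs.items():
            a = int(df.loc[pid, s_untx])
            b = int(df.loc[pid, s_trt])
            if a == 0 and b == 0:
                pair_dirs.append((pair_id, Direction.NOT_DETECTED))
                continue
            pr = max(float(a), floor) / max(float(b), floor)
            pair_dirs.append((pair_id, _ratio_direction(pr, dead_zone)))
        voting = [d for _, d in pair_dirs if d is not Direction.NOT_DETECTED]
        consistent = all(d == direction for d in voting)

        n_det = int(detected[pid])

        stage = RejectionStage.NONE
        if igg_fold < igg_fc:
            stage = RejectionStage.IGG_GATE
        elif direction is Direction.NOT_DETECTED:
            stage = RejectionStage.RATIO_GATE
        elif pairs and not consistent:
            stage = RejectionStage.CONSISTENCY_GATE
        elif n_det <= 1:
            stage = RejectionStage.PRESENCE_GATE

        records.append(
            DifferentialRecord(
                protein_id=pid,
                igg_fold_change=igg_fold,
                condition_ratio=ratio,
                direction=direction,
                pair_directions=tuple(pair_dirs),
                consistent=consistent,
                n_samples_detected=n_det,
                verdict=(
                    DiffVerdict.SELECTIVE
                    if stage is RejectionStage.NONE
                    else DiffVerdict.REJECTED
                ),
                rejection_stage=stage,
            )
        )
    return records
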