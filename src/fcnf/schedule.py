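"""Run schedules for block-design neurofeedback experiments.

A neurofeedback run is a sequence of whole-brain acquisitions ("volumes").
Each volume belongs to exactly one block: an initial fixation block, then
alternating feedback ("fcnf") and transfer/control ("nonf") mini-blocks.
The feedback value shown at volume ``t`` is computed from a moving window
of the ``L`` most recent volumes (the current volume included), so the
window generally mixes volumes from both conditions; this module does the
per-volume bookkeeping of that mixture.

Volume indices are 1-based throughout: the window at volume ``t`` covers
volumes ``t - L + 1 .. t`` inclusive, which is the only convention under
which the first volume of a 20-volume mini-block contributes a 1:19 ratio
of feedback to non-feedback volumes and the last volume 20:0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FIXATION = "fixation"
FCNF = "fcnf"
NONF = "nonf"
CONDITIONS = (FIXATION, FCNF, NONF)

__all__ = [
    "FIXATION",
    "FCNF",
    "NONF",
    "CONDITIONS",
    "BlockSpec",
    "RunSchedule",
    "WindowComposition",
    "build_run_schedule",
    "window_composition",
    "counterbalanced_starts",
]


@dataclass(frozen=True)
class BlockSpec:
    """A contiguous stretch of volumes in one condition."""

    condition: str
    length: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition label {self.condition!r}")
        if self.length < 1:
            raise ValueError("block length must be >= 1")


@dataclass(frozen=True)
class WindowComposition:
    """Condition counts inside one moving window."""

    n_fcnf: int
    n_nonf: int
    n_fixation: int
    window_length: int

    def __post_init__(self) -> None:
        if self.n_fcnf + self.n_nonf + self.n_fixation != self.window_length:
            raise ValueError("window composition counts must sum to the window length")


class RunSchedule:
    """Per-volume condition labels and block membership for one run.

    Parameters
    ----------
    labels
        One condition label per volume, in acquisition order.
    block_index
        Per-volume block identifier, non-decreasing; volumes sharing a
        block index share a label. Block 1 is the first block of the run
        (the fixation block when present).
    """

    def __init__(self, labels: Sequence[str], block_index: Sequence[int]):
        labels = np.asarray(labels, dtype=object)
        block_index = np.asarray(block_index, dtype=np.int64)
        if labels.size == 0:
            raise ValueError("empty schedule")
        if labels.shape != block_index.shape:
            raise ValueError("labels and block_index must have equal length")
        if np.any(np.diff(block_index) < 0):
            raise ValueError("block_index must be non-decreasing")
        for lab in np.unique(labels):
            if lab not in CONDITIONS:
                raise ValueError(f"unknown condition label {lab!r}")
        # volumes in one block must share one label
        for b in np.unique(block_index):
            if len(set(labels[block_index == b])) != 1:
                raise ValueError(f"block {b} carries more than one condition label")
        self.labels = labels
        self.block_index = block_index

    # -- basic accessors ---------------------------------------------------

    @property
    def n_volumes(self) -> int:
        return int(self.labels.size)

    def condition_at(self, t: int) -> str:
        """Condition label at 1-based volume index ``t``."""
        if not 1 <= t <= self.n_volumes:
            raise IndexError(f"volume {t} outside run of {self.n_volumes} volumes")
        return str(self.labels[t - 1])

    def blocks(self) -> list[BlockSpec]:
        """Reconstruct the block list from the per-volume representation."""
        out: list[BlockSpec] = []
        for b in np.unique(self.block_index):
            mask = self.block_index == b
            out.append(BlockSpec(str(self.labels[mask][0]), int(mask.sum())))
        return out

    def mini_blocks(self) -> list[int]:
        """Block indices of the non-fixation mini-blocks, in run order."""
        return [
            int(b)
            for b in np.unique(self.block_index)
            if self.labels[self.block_index == b][0] != FIXATION
        ]

    def position_in_block(self) -> np.ndarray:
        """1-based position of each volume inside its own block."""
        pos = np.empty(self.n_volumes, dtype=np.int64)
        for b in np.unique(self.block_index):
            mask = self.block_index == b
            pos[mask] = np.arange(1, mask.sum() + 1)
        return pos

    def with_swapped_conditions(self) -> "RunSchedule":
        """The counterbalanced variant: mini-block order exchanged.

        Every fcnf mini-block becomes a nonf mini-block and vice versa,
        but each condition keeps its own block length, so that in an
        asymmetric design (40-volume feedback blocks, 20-volume no-NF
        blocks) the swapped schedule changes the start condition rather
        than which condition gets the longer blocks.
        """
        lengths = {}
        for blk in self.blocks():
            lengths.setdefault(blk.condition, blk.length)
        swap = {FCNF: NONF, NONF: FCNF}
        out = []
        for blk in self.blocks():
            if blk.condition == FIXATION:
                out.append(blk)
            else:
                other = swap[blk.condition]
                out.append(BlockSpec(other, lengths.get(other, blk.length)))
        return RunSchedule.from_blocks(out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RunSchedule):
            return NotImplemented
        return bool(
            np.array_equal(self.labels, other.labels)
            and np.array_equal(self.block_index, other.block_index)
        )

    def __repr__(self) -> str:
        return f"RunSchedule({self.n_volumes} volumes, {len(self.blocks())} blocks)"

    # -- construction ------------------------------------------------------

    @classmethod
    def from_blocks(cls, blocks: Iterable[BlockSpec]) -> "RunSchedule":
        labels: list[str] = []
        index: list[int] = []
        for i, blk in enumerate(blocks, start=1):
            labels.extend([blk.condition] * blk.length)
            index.extend([i] * blk.length)
        if not labels:
            raise ValueError("empty schedule")
        return cls(labels, index)

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"volume": np.arange(1, self.n_volumes + 1), "condition": self.labels}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RunSchedule":
        df = pd.read_csv(path, sep="\t")
        labels = df.sort_values("volume")["condition"].to_numpy(dtype=object)
        # rebuild block indices from label run-lengths
        change = np.flatnonzero(labels[1:] != labels[:-1])
        index = np.zeros(labels.size, dtype=np.int64)
        index[change + 1] = 1
        return cls(labels, np.cumsum(index) + 1)

    def to_json_blocks(self) -> str:
        return json.dumps(
            [{"condition": b.condition, "length": b.length} for b in self.blocks()]
        )

    @classmethod
    def from_json_blocks(cls, text: str) -> "RunSchedule":
        return cls.from_blocks(
            BlockSpec(d["condition"], d["length"]) for d in json.loads(text)
        )


def build_run_schedule(
    fixation_len: int,
    n_pairs: int,
    fcnf_len: int,
    nonf_len: int,
    start_condition: str = FCNF,
) -> RunSchedule:
    """Build a fixation block followed by alternating mini-block pairs.

    The standard design is ``build_run_schedule(20, 7, 20, 20, "fcnf")``:
    a 20-volume fixation cross, then seven feedback and seven no-feedback
    mini-blocks of 20 volumes each in alternating order (300 volumes).
    The extended design uses 40-volume feedback blocks and five pairs.
    """
    if start_condition not in (FCNF, NONF):
        raise ValueError("start_condition must be 'fcnf' or 'nonf'")
    if min(fixation_len, n_pairs, fcnf_len, nonf_len) < 0:
        raise ValueError("lengths must be non-negative")
    if n_pairs == 0 and fixation_len == 0:
        raise ValueError("empty schedule")
    blocks: list[BlockSpec] = []
    if fixation_len > 0:
        blocks.append(BlockSpec(FIXATION, fixation_len))
    first, second = (
        (FCNF, NONF) if start_condition == FCNF else (NONF, FCNF)
    )
    lengths = {FCNF: fcnf_len, NONF: nonf_len}
    for _ in range(n_pairs):
        for cond in (first, second):
            if lengths[cond] > 0:
                blocks.append(BlockSpec(cond, lengths[cond]))
    return RunSchedule.from_blocks(blocks)


def window_composition(schedule: RunSchedule, t: int, L: int) -> WindowComposition:
    """Condition counts in the window of ``L`` volumes ending at volume ``t``.

    The window includes the current volume. Windows that would reach back
    before the first volume of the run are undefined: each run opens with a
    fixation block at least as long as the window, so the first feedback
    value already has a full window and there is no carry-over across runs.
    """
    if L < 1:
        raise ValueError("window length must be >= 1")
    if t > schedule.n_volumes:
        raise IndexError(f"volume {t} outside run of {schedule.n_volumes} volumes")
    if t < L:
        raise ValueError("window not yet filled")
    window = schedule.labels[t - L : t]
    return WindowComposition(
        n_fcnf=int(np.sum(window == FCNF)),
        n_nonf=int(np.sum(window == NONF)),
        n_fixation=int(np.sum(window == FIXATION)),
        window_length=L,
    )


def counterbalanced_starts(n_subjects: int, seed: int) -> list[str]:
    """Assign start conditions with an enforced 50/50 split.

    Exactly ``floor(n/2)`` subjects start with one condition and the rest
    with the other; which subjects get which is a seeded random shuffle.
    For odd cohorts the extra subject's condition is itself randomized.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    half = n_subjects // 2
    starts = [FCNF] * half + [NONF] * half
    if n_subjects % 2:
        starts.append(FCNF if rng.random() < 0.5 else NONF)
    rng.shuffle(starts)
    return starts
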