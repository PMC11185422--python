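"""Trial-level data model, CSV I/O, summary counts, and participant screening.

The canonical on-disk format is a headered UTF-8 CSV with one row per trial
and columns::

    participant_id, task, level_index, level_value, offset_orientation,
    op_interval, resp_orientation_op, resp_orientation_oa, resp_interval,
    session, block

``offset_orientation`` and the two orientation responses take values
``left``/``right``; ``op_interval`` and ``resp_interval`` take ``first``/
``second``. Correctness flags are derived on load and never stored, so a file
can never carry flags inconsistent with its responses.

Counts are collapsed across offset orientation, interval presentation order
and session into :class:`LevelSummary` joint-outcome tables
(orientation correct x interval correct), the unit every downstream analysis
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import ConditionLevel, Task

__all__ = [
    "CSV_COLUMNS",
    "TrialRecord",
    "LevelSummary",
    "ExclusionReport",
    "SchemaError",
    "ValidationError",
    "load_trials",
    "save_trials",
    "trials_to_frame",
    "frame_to_trials",
    "collapse_to_level_summaries",
    "screen_participants",
]

CSV_COLUMNS = [
    "participant_id",
    "task",
    "level_index",
    "level_value",
    "offset_orientation",
    "op_interval",
    "resp_orientation_op",
    "resp_orientation_oa",
    "resp_interval",
    "session",
    "block",
]

_ORIENTATIONS = {"left", "right"}
_INTERVALS = {"first", "second"}


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """A row holds a value outside its declared domain."""


@dataclass(frozen=True)
class TrialRecord:
    """One 2IFC trial: stimulus truth plus all three responses.

    The offset-absent-interval orientation response (``resp_orientation_oa``)
    is collected by the task and stored, but no analysis consumes it.
    """

    participant_id: str
    level: ConditionLevel
    offset_orientation: str
    op_interval: str
    resp_orientation_op: str
    resp_orientation_oa: str
    resp_interval: str
    session: int = 1
    block: int = 1

    def __post_init__(self) -> None:
        for name in ("offset_orientation", "resp_orientation_op", "resp_orientation_oa"):
            if getattr(self, name) not in _ORIENTATIONS:
                raise ValidationError(f"{name}={getattr(self, name)!r} not in {_ORIENTATIONS}")
        for name in ("op_interval", "resp_interval"):
            if getattr(self, name) not in _INTERVALS:
                raise ValidationError(f"{name}={getattr(self, name)!r} not in {_INTERVALS}")

    @property
    def ori_correct(self) -> bool:
        return self.resp_orientation_op == self.offset_orientation

    @property
    def int_correct(self) -> bool:
        return self.resp_interval == self.op_interval


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "participant_id": t.participant_id,
            "task": t.level.task.value,
            "level_index": t.level.index,
            "level_value": t.level.physical_value,
            "offset_orientation": t.offset_orientation,
            "op_interval": t.op_interval,
            "resp_orientation_op": t.resp_orientation_op,
            "resp_orientation_oa": t.resp_orientation_oa,
            "resp_interval": t.resp_interval,
            "session": t.session,
            "block": t.block,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    trials: list[TrialRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            level = ConditionLevel(Task(str(row.task)), int(row.level_index))
            trials.append(
                TrialRecord(
                    participant_id=str(row.participant_id),
                    level=level,
                    offset_orientation=str(row.offset_orientation),
                    op_interval=str(row.op_interval),
                    resp_orientation_op=str(row.resp_orientation_op),
                    resp_orientation_oa=str(row.resp_orientation_oa),
                    resp_interval=str(row.resp_interval),
                    session=int(row.session),
                    block=int(row.block),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return trials


def load_trials(path: str | Path, task_filter: Task | str | None = None) -> list[TrialRecord]:
    """Read a trial CSV, validating every row; row order is preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        raise ValidationError(f"{path}: empty dataset")
    if task_filter is not None:
        task_filter = Task(task_filter)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        df = df[df["task"] == task_filter.value].reset_index(drop=True)
    return frame_to_trials(df)


def save_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


@dataclass
class LevelSummary:
    """Joint outcome counts for one participant at one level.

    ``n11`` counts trials with orientation correct and interval correct,
    ``n10`` orientation correct / interval incorrect, ``n01`` orientation
    incorrect / interval correct, ``n00`` both incorrect. The same four
    counts restricted to trials with the offset in the first vs the second
    interval are kept alongside (``first`` / ``second``).
    """

    participant_id: str
    level: ConditionLevel
    n11: int = 0
    n10: int = 0
    n01: int = 0
    n00: int = 0
    first: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=int))
    second: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=int))

    @property
    def n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def counts(self) -> np.ndarray:
        """Joint counts as [n11, n10, n01, n00]."""
        return np.array([self.n11, self.n10, self.n01, self.n00], dtype=int)

    def restricted(self, position: str) -> "LevelSummary":
        """The sub-summary for trials with the offset in the given interval."""
        sub = self.first if position == "first" else self.second
        return LevelSummary(
            self.participant_id, self.level,
            n11=int(sub[0]), n10=int(sub[1]), n01=int(sub[2]), n00=int(sub[3]),
            first=sub.copy() if position == "first" else np.zeros(4, dtype=int),
            second=sub.copy() if position == "second" else np.zeros(4, dtype=int),
        )


def collapse_to_level_summaries(trials: Sequence[TrialRecord]) -> list[LevelSummary]:
    """Collapse trials across orientation, interval order and session.

    Returns one :class:`LevelSummary` per (participant, level) present in the
    data, ordered by participant then level index. All trials must belong to
    a single task.
    """
    if not trials:
        return []
    tasks = {t.level.task for t in trials}
    if len(tasks) > 1:
        raise ValueError(f"mixed tasks in input: {sorted(t.value for t in tasks)}")

    table: dict[tuple[str, int], LevelSummary] = {}
    for t in trials:
        key = (t.participant_id, t.level.index)
        if key not in table:
            table[key] = LevelSummary(t.participant_id, t.level)
        s = table[key]
        cell = (0 if t.ori_correct else 2) + (0 if t.int_correct else 1)
        attr = ("n11", "n10", "n01", "n00")[cell]
        setattr(s, attr, getattr(s, attr) + 1)
        pos = s.first if t.op_interval == "first" else s.second
        pos[cell] += 1
    return [table[k] for k in sorted(table)]


@dataclass(frozen=True)
class ExclusionReport:
    """Screening outcome for one participant in one task.

    A participant is excluded when either performance slope (orientation
    discrimination or OP-interval selection, regressed on scaled visibility
    level) yields BF10 <= 1/3, i.e. there is evidence *against* performance
    improving with more visible stimuli.
    """

    participant_id: str
    task: Task
    bf_orientation_slope: float
    bf_interval_slope: float

    #: exclusion threshold on BF10 (rule is "<=")
    THRESHOLD: float = field(default=1.0 / 3.0, repr=False)

    @property
    def excluded(self) -> bool:
        return (
            self.bf_orientation_slope <= self.THRESHOLD
            or self.bf_interval_slope <= self.THRESHOLD
        )

    @property
    def triggered_by(self) -> tuple[str, ...]:
        out = []
        if self.bf_orientation_slope <= self.THRESHOLD:
            out.append("orientation")
        if self.bf_interval_slope <= self.THRESHOLD:
            out.append("interval")
        return tuple(out)


def screen_participants(trials: Sequence[TrialRecord], task: Task | str) -> list[ExclusionReport]:
    """Compute per-participant slope Bayes factors and exclusion flags.

    For each participant, correctness (orientation; interval) is regressed on
    scaled level by per-participant maximum-likelihood logistic regression and
    the slope is scored with a Bayes factor (H1: positive slope, half-Gaussian
    prior sd 2.30; H0: point null), via :func:`vernier2ifc.bayes.slope_bf`.
    """
    from .bayes import slope_bf

    task = Task(task)
    trials = [t for t in trials if t.level.task is task]
    summaries = collapse_to_level_summaries(trials)
    by_part: dict[str, list[LevelSummary]] = {}
    for s in summaries:
        by_part.setdefault(s.participant_id, []).append(s)

    reports = []
    for pid in sorted(by_part):
        rows = by_part[pid]
        if len(rows) < 2:
            raise ValueError(f"participant {pid}: slope undefined with a single level")
        x = np.array([s.level.scaled_value for s in rows])
        n = np.array([s.n for s in rows])
        ori_k = np.array([s.n11 + s.n10 for s in rows])
        int_k = np.array([s.n11 + s.n01 for s in rows])
        bf_ori = slope_bf(x, ori_k, n)
        bf_int = slope_bf(x, int_k, n)
        reports.append(ExclusionReport(pid, task, bf_ori.bf10, bf_int.bf10))
    return reports


def apply_cross_task_exclusions(
    reports_by_task: dict[Task, list[ExclusionReport]],
) -> set[str]:
    """Participants excluded in *any* task (the stricter cross-task policy)."""
    out: set[str] = set()
    for reports in reports_by_task.values():
        out |= {r.participant_id for r in reports if r.excluded}
    return out
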