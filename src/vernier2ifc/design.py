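"""Experimental design constants for the 2IFC Vernier task.

Two visibility manipulations were used, block-wise interleaved:

* ``masked`` — the Vernier is followed by a metacontrast mask; visibility is
  controlled by the inter-stimulus interval (ISI), six levels linearly spaced
  from 16.7 to 100 ms.
* ``unmasked`` — the Vernier is shown unmasked for a very brief duration on a
  tachistoscope; eight duration levels logarithmically spaced from 980 to
  3000 microseconds.

Levels are indexed 1-based with index 1 the *hardest* (shortest ISI/duration),
so that "level i+1" is always the easier neighbour — the convention used by
the level-dependent Bayes-factor priors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Task",
    "ConditionLevel",
    "levels_for_task",
    "level_values",
    "scaled_levels",
    "default_trials_per_level",
    "mean_trials_per_level",
    "EASY_LEVEL_INDICES",
    "HARD_LEVEL_INDICES",
]


class Task(str, enum.Enum):
    MASKED = "masked"
    UNMASKED = "unmasked"


#: Number of visibility levels per task.
N_LEVELS = {Task.MASKED: 6, Task.UNMASKED: 8}

#: Subset definitions for the easy/hard refits: the two easiest levels
#: (ISI 83.3/100 ms, duration 2557/3000 us) and the two hardest
#: (ISI 16.7/33.3 ms, duration 980/1150 us).
EASY_LEVEL_INDICES = {Task.MASKED: (5, 6), Task.UNMASKED: (7, 8)}
HARD_LEVEL_INDICES = {Task.MASKED: (1, 2), Task.UNMASKED: (1, 2)}


def level_values(task: Task) -> np.ndarray:
    """Physical visibility values, hardest first.

    Masked: ISI in ms, linearly spaced 16.7..100.
    Unmasked: duration in microseconds, log-spaced 980..3000.
    """
    task = Task(task)
    if task is Task.MASKED:
        return np.linspace(16.7, 100.0, N_LEVELS[task])
    return np.geomspace(980.0, 3000.0, N_LEVELS[task])


def scaled_levels(task: Task) -> np.ndarray:
    """Level values divided by the largest value, giving covariates in (0, 1]."""
    v = level_values(task)
    return v / v[-1]


@dataclass(frozen=True)
class ConditionLevel:
    """One visibility level of one task (1-based index, 1 = hardest)."""

    task: Task
    index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        n = N_LEVELS[self.task]
        if not 1 <= self.index <= n:
            raise ValueError(
                f"level index {self.index} out of range 1..{n} for task {self.task.value}"
            )

    @property
    def physical_value(self) -> float:
        """ISI in ms (masked) or duration in microseconds (unmasked)."""
        return float(level_values(self.task)[self.index - 1])

    @property
    def scaled_value(self) -> float:
        return float(scaled_levels(self.task)[self.index - 1])


def levels_for_task(task: Task) -> list[ConditionLevel]:
    return [ConditionLevel(Task(task), i) for i in range(1, N_LEVELS[Task(task)] + 1)]


def default_trials_per_level(task: Task, n_participants: int = 12) -> list[int]:
    """Per-participant trial counts per level matching the study design.

    Masked: 5 participants ran 128 trials per ISI and 7 ran 144.
    Unmasked: 7 ran 128 trials per duration and 5 ran 144.
    """
    task = Task(task)
    n128 = 5 if task is Task.MASKED else 7
    counts = [128] * n128 + [144] * (n_participants - n128)
    return counts[:n_participants]


def mean_trials_per_level(counts: list[int]) -> float:
    """Participant-weighted mean number of trials per level."""
    return float(np.mean(counts))
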