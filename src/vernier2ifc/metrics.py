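"""Descriptive behavioral metrics of the 2IFC task.

All metrics are computed per participant per level from the joint-outcome
counts (orientation correct x interval correct), then aggregated as the
unweighted cross-participant mean with the standard error of the mean
(sample sd / sqrt(number of participants)). Cells with an empty denominator
(e.g. the Type-2 false-alarm rate of a participant with no incorrect
discriminations at a level) are flagged undefined and dropped from the group
mean; the number of dropped cells is recorded on the series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import LevelSummary, TrialRecord
from .design import Task

__all__ = [
    "MetricSeries",
    "BiasReport",
    "accuracy_by_level",
    "type2_rates",
    "conditional_accuracy",
    "response_bias",
    "split_by_op_position",
]


@dataclass
class MetricSeries:
    """One metric across levels: per-participant values and group summary."""

    metric_name: str
    level_indices: list[int]
    per_participant: dict[str, np.ndarray]  # participant -> per-level values (nan = undefined)
    n_dropped_cells: int = 0

    @property
    def group_mean(self) -> np.ndarray:
        stacked = np.vstack(list(self.per_participant.values()))
        with np.errstate(invalid="ignore"):
            return np.nanmean(stacked, axis=0)

    @property
    def group_sem(self) -> np.ndarray:
        stacked = np.vstack(list(self.per_participant.values()))
        out = np.full(stacked.shape[1], np.nan)
        for j in range(stacked.shape[1]):
            col = stacked[:, j]
            col = col[~np.isnan(col)]
            if col.size >= 2:
                out[j] = col.std(ddof=1) / np.sqrt(col.size)
            elif col.size == 1:
                out[j] = 0.0
        return out

    def to_frame(self, task: Task | None = None) -> pd.DataFrame:
        rows = []
        task_name = Task(task).value if task is not None else ""
        for pid, vals in self.per_participant.items():
            for lev, v in zip(self.level_indices, vals):
                rows.append(dict(metric=self.metric_name, task=task_name,
                                 level_index=lev, participant=pid,
                                 value=v, sem=np.nan))
        for lev, m, s in zip(self.level_indices, self.group_mean, self.group_sem):
            rows.append(dict(metric=self.metric_name, task=task_name,
                             level_index=lev, participant="GROUP", value=m, sem=s))
        return pd.DataFrame(rows)


def _ratio_series(
    summaries: Sequence[LevelSummary],
    name: str,
    num: callable,
    den: callable,
) -> MetricSeries:
    if not summaries:
        raise ValueError("no summaries")
    levels = sorted({s.level.index for s in summaries})
    parts = sorted({s.participant_id for s in summaries})
    values = {p: np.full(len(levels), np.nan) for p in parts}
    dropped = 0
    for s in summaries:
        d = den(s)
        j = levels.index(s.level.index)
        if d > 0:
            values[s.participant_id][j] = num(s) / d
        else:
            dropped += 1
    return MetricSeries(name, levels, values, n_dropped_cells=dropped)


def accuracy_by_level(summaries: Sequence[LevelSummary], which: str) -> MetricSeries:
    """Orientation ((n11+n10)/n) or interval ((n11+n01)/n) accuracy per level."""
    if which == "orientation":
        return _ratio_series(summaries, "orientation_accuracy",
                             lambda s: s.n11 + s.n10, lambda s: s.n)
    if which == "interval":
        return _ratio_series(summaries, "interval_accuracy",
                             lambda s: s.n11 + s.n01, lambda s: s.n)
    raise ValueError("which must be 'orientation' or 'interval'")


def type2_rates(summaries: Sequence[LevelSummary]) -> tuple[MetricSeries, MetricSeries]:
    """Type-2 hit and false-alarm rates.

    A Type-2 hit is choosing the OP interval on a discrimination-correct
    trial (HR = n11/(n11+n10)); a Type-2 false alarm is choosing it on a
    discrimination-incorrect trial (FAR = n01/(n01+n00)).
    """
    hr = _ratio_series(summaries, "type2_hit_rate",
                       lambda s: s.n11, lambda s: s.n11 + s.n10)
    far = _ratio_series(summaries, "type2_false_alarm_rate",
                        lambda s: s.n01, lambda s: s.n01 + s.n00)
    return hr, far


def conditional_accuracy(summaries: Sequence[LevelSummary]) -> tuple[MetricSeries, MetricSeries]:
    """Orientation accuracy conditional on the interval choice.

    Given OP chosen: n11/(n11+n01); given OA chosen: n10/(n10+n00).
    """
    given_op = _ratio_series(summaries, "accuracy_given_op_chosen",
                             lambda s: s.n11, lambda s: s.n11 + s.n01)
    given_oa = _ratio_series(summaries, "accuracy_given_oa_chosen",
                             lambda s: s.n10, lambda s: s.n10 + s.n00)
    return given_op, given_oa


def split_by_op_position(
    summaries: Sequence[LevelSummary],
) -> tuple[list[LevelSummary], list[LevelSummary]]:
    """Split each summary into offset-first and offset-second sub-summaries."""
    return (
        [s.restricted("first") for s in summaries],
        [s.restricted("second") for s in summaries],
    )


@dataclass
class BiasReport:
    """Group-level response-bias summary for one response type.

    Proportions are in percent. The t statistic tests the group mean against
    50% (two-tailed); the Bayes factor comes from the intercept-only
    hierarchical model (H0: point at 0.5; H1: Normal(0.5, 0.025))."""

    response: str  # "left" or "first"
    per_participant_pct: dict[str, float]
    mean_pct: float
    sd_pct: float
    t: float
    df: int
    p: float
    bf10: float | None = None
    extras: dict = field(default_factory=dict)


def response_bias(
    trials: Sequence[TrialRecord],
    fit_bf: bool = True,
    seed: int = 0,
    mcmc_kwargs: dict | None = None,
) -> tuple[BiasReport, BiasReport]:
    """Orientation-response ('left') and interval-response ('first') biases.

    Set ``fit_bf=False`` to skip the MCMC-based Bayes factor (t tests only).
    """
    from . import bayes

    if not trials:
        raise ValueError("no trials")
    tasks = {t.level.task for t in trials}
    if len(tasks) > 1:
        raise ValueError("trials of one task expected")

    parts = sorted({t.participant_id for t in trials})
    if len(parts) < 2:
        raise ValueError("t test needs at least 2 participants")

    reports = []
    for response, getter in (
        ("left", lambda t: t.resp_orientation_op == "left"),
        ("first", lambda t: t.resp_interval == "first"),
    ):
        props = {}
        counts_k, counts_n = [], []
        for p in parts:
            pt = [t for t in trials if t.participant_id == p]
            k = sum(getter(t) for t in pt)
            props[p] = 100.0 * k / len(pt)
            counts_k.append(k)
            counts_n.append(len(pt))
        vals = np.array(list(props.values()))
        t_stat, df, p_val = bayes.one_sample_t(vals, popmean=50.0)

        bf10 = None
        if fit_bf:
            post = bayes.fit_hier_logistic(
                x=np.zeros(len(parts)), k=np.array(counts_k), n=np.array(counts_n),
                participant=parts,
                spec=bayes.LogisticModelSpec(include_slope=False),
                seed=seed, **(mcmc_kwargs or {}),
            )
            draws = bayes.posterior_predict_draws(post, 0.0)
            m, s = float(draws.mean()), float(draws.std(ddof=1))
            res = bayes.bayes_factor(
                m, s,
                h0=bayes.PriorSpec("point", 0.5),
                h1=bayes.PriorSpec("normal", 0.5, 0.025),
            )
            bf10 = res.bf10

        reports.append(BiasReport(
            response=response, per_participant_pct=props,
            mean_pct=float(vals.mean()), sd_pct=float(vals.std(ddof=1)),
            t=t_stat, df=df, p=p_val, bf10=bf10,
        ))
    return reports[0], reports[1]
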