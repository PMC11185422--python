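"""Synthetic trial-level datasets from a ground-truth observer.

The generator emulates the study design — 12 participants, 6 ISI levels
(masked) or 8 duration levels (unmasked), 128 or 144 trials per level per
participant (participant-weighted means 137 and 135), offset orientations and
interval orders exactly balanced within each level — with every response
produced by one of the seven Bayesian observers at per-participant evidence
strengths and read-out noise sigma_D.

Optional lapses (a trial's responses replaced by bias-weighted coin flips)
and response biases extend the generative model beyond the observers; their
defaults are zero, so by default the generator *is* the observer, and the
generated joint outcome frequencies converge to the observer's prediction
table. The generator makes no attempt to imitate session fatigue or learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TrialRecord, collapse_to_level_summaries
from .design import (
    ConditionLevel,
    Task,
    default_trials_per_level,
    levels_for_task,
)
from .fitting import FitResult, ParticipantData, fit_observer
from .observers import ObserverSpec, choose_op, inject_noise, simulate_trials

__all__ = ["GroundTruth", "generate_dataset", "recovery_experiment", "default_ground_truth"]


@dataclass
class GroundTruth:
    """Generative configuration for one synthetic cohort."""

    task: Task
    observer: ObserverSpec
    #: per participant: nondecreasing strength vector, one entry per level
    c_per_participant: list[np.ndarray]
    #: per participant read-out noise: a scalar, or one value per level
    #: (e.g. to concentrate noise in the hard conditions)
    sigma_d_per_participant: list[float | np.ndarray]
    trials_per_level: list[int] = field(default_factory=list)
    lapse_rate: float = 0.0
    orientation_bias: float = 0.5  # P(lapse orientation response = "left")
    interval_bias: float = 0.5     # P(lapse interval response = "first")
    n_sessions: int = 3

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        if not self.trials_per_level:
            self.trials_per_level = default_trials_per_level(
                self.task, len(self.c_per_participant)
            )
        if len(self.sigma_d_per_participant) != len(self.c_per_participant):
            raise ValueError("sigma_d_per_participant length mismatch")
        if not 0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        n_levels = len(levels_for_task(self.task))
        for c in self.c_per_participant:
            c = np.asarray(c, dtype=float)
            if c.size != n_levels:
                raise ValueError("c vector length must equal the number of levels")
            if np.any(np.diff(c) < 0):
                raise ValueError("c must be nondecreasing toward easier levels")

    @property
    def n_participants(self) -> int:
        return len(self.c_per_participant)


def default_ground_truth(
    task: Task | str = Task.MASKED,
    model_id: int = 3,
    sigma_d: float = 0.2,
    n_participants: int = 12,
    seed: int = 0,
) -> GroundTruth:
    """A realistic cohort: strengths spanning near-threshold (accuracy about
    0.58 at the hardest level) to clearly visible, with mild per-participant
    variation, driven by the marginalizing-confidence observer on the
    diagonal evidence space."""
    task = Task(task)
    rng = np.random.default_rng(seed)
    n_levels = len(levels_for_task(task))
    base = np.linspace(0.3, 2.5, n_levels)
    cs, sigmas = [], []
    for _ in range(n_participants):
        jitter = rng.normal(0.0, 0.1, size=n_levels)
        c = np.maximum.accumulate(np.clip(base + jitter, 0.0, 5.0))
        cs.append(np.round(c, 1))  # keep strengths on the simulation grid
        sigmas.append(sigma_d)
    return GroundTruth(task, ObserverSpec(model_id), cs, sigmas)


def generate_dataset(truth: GroundTruth, seed: int = 0) -> list[TrialRecord]:
    """Simulate the full cohort; fully reproducible from the master seed.

    Per-participant random streams are spawned deterministically from the
    master seed. Within each level, offset orientations and interval orders
    are balanced exactly (up to an odd trial) and shuffled.
    """
    master = np.random.SeedSequence(seed)
    streams = master.spawn(truth.n_participants)
    levels = levels_for_task(truth.task)
    trials: list[TrialRecord] = []
    for j, (c_vec, sigma, ss) in enumerate(
        zip(truth.c_per_participant, truth.sigma_d_per_participant, streams)
    ):
        rng = np.random.default_rng(ss)
        pid = f"P{j + 1:02d}"
        n_per_level = truth.trials_per_level[j]
        sigma_by_level = np.broadcast_to(
            np.asarray(sigma, dtype=float), (len(levels),)
        )
        for level, c, s in zip(levels, np.asarray(c_vec, dtype=float), sigma_by_level):
            spec = ObserverSpec(truth.observer.model_id, float(s), truth.observer.c_grid)
            trials.extend(
                _simulate_level(pid, level, spec, float(c), n_per_level, truth, rng)
            )
    return trials


def _simulate_level(
    pid: str,
    level: ConditionLevel,
    spec: ObserverSpec,
    c: float,
    n: int,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    # balanced factors: orientation x op-interval position
    true_left = np.zeros(n, dtype=bool)
    true_left[: n // 2] = True
    op_first = np.tile([True, False], (n + 1) // 2)[:n]
    rng.shuffle(true_left)
    rng.shuffle(op_first)

    sim = simulate_trials(spec, c, n, rng, true_left=true_left)
    d_noisy = inject_noise(sim["D"], spec.sigma_d, rng)
    op_chosen = choose_op(d_noisy, rng)

    resp_op = np.where(sim["chose_left_op"], "left", "right")
    resp_oa = np.where(sim["chose_left_oa"], "left", "right")
    # interval response: map the OP/OA choice onto first/second given position
    resp_first = np.where(op_first, op_chosen, ~op_chosen)

    if truth.lapse_rate > 0:
        lapse = rng.random(n) < truth.lapse_rate
        resp_op = np.where(
            lapse, np.where(rng.random(n) < truth.orientation_bias, "left", "right"),
            resp_op,
        )
        resp_oa = np.where(
            lapse, np.where(rng.random(n) < truth.orientation_bias, "left", "right"),
            resp_oa,
        )
        resp_first = np.where(
            lapse, rng.random(n) < truth.interval_bias, resp_first
        )

    session = rng.integers(1, truth.n_sessions + 1, size=n)
    out = []
    for i in range(n):
        out.append(
            TrialRecord(
                participant_id=pid,
                level=level,
                offset_orientation="left" if true_left[i] else "right",
                op_interval="first" if op_first[i] else "second",
                resp_orientation_op=str(resp_op[i]),
                resp_orientation_oa=str(resp_oa[i]),
                resp_interval="first" if resp_first[i] else "second",
                session=int(session[i]),
                block=1,
            )
        )
    return out


@dataclass
class RecoveryReport:
    """Parameter-recovery outcome of one generate-and-fit experiment."""

    truth: GroundTruth
    fits_ideal: list[FitResult]
    fits_noisy: list[FitResult]
    c_errors: np.ndarray       # (participants, levels) c_hat - c_true
    sigma_errors: np.ndarray   # (participants,) sigma_hat - sigma_true

    @property
    def c_rmse(self) -> float:
        return float(np.sqrt(np.mean(self.c_errors**2)))

    @property
    def median_abs_sigma_error(self) -> float:
        return float(np.median(np.abs(self.sigma_errors)))


def recovery_experiment(
    truth: GroundTruth,
    fit_model: ObserverSpec,
    seed: int = 0,
    n_sim: int = 20_000,
    cv_resamples: int = 5,
    run_cv: bool = False,
) -> RecoveryReport:
    """Generate a cohort from ``truth``, fit ``fit_model`` (ideal and noisy)
    to every participant, and report strength and noise recovery errors."""
    from .observers import simulate_prediction_table

    trials = generate_dataset(truth, seed=seed)
    summaries = collapse_to_level_summaries(trials)
    table = simulate_prediction_table(
        ObserverSpec(fit_model.model_id, 0.0, fit_model.c_grid),
        n_sim=n_sim, seed=seed + 1,
    )
    by_part: dict[str, list] = {}
    for s in summaries:
        by_part.setdefault(s.participant_id, []).append(s)

    fits_ideal, fits_noisy, c_err, s_err = [], [], [], []
    for j, pid in enumerate(sorted(by_part)):
        pdata = ParticipantData.from_summaries(by_part[pid])
        fi = fit_observer(table, pdata, "ideal", run_cv=run_cv,
                          cv_resamples=cv_resamples, cv_seed=seed + 2 + j)
        fn = fit_observer(table, pdata, "noisy", run_cv=run_cv,
                          cv_resamples=cv_resamples, cv_seed=seed + 2 + j)
        fits_ideal.append(fi)
        fits_noisy.append(fn)
        c_err.append(fn.c_hat - np.asarray(truth.c_per_participant[j], dtype=float))
        s_err.append(fn.sigma_d_hat - float(np.mean(truth.sigma_d_per_participant[j])))
    return RecoveryReport(truth, fits_ideal, fits_noisy,
                          np.vstack(c_err), np.array(s_err))
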