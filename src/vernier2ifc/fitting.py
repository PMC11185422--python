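"""Fitting Bayesian observers to 2IFC behavior.

Per participant and task, the procedure is:

1. *Percent-correct preprocessing* — orientation accuracy per level is
   smoothed through a two-parameter logistic psychometric function of scaled
   level (maximum likelihood) and floored at 0.5, because the observers are
   only defined for accuracies in [0.5, 1].
2. *Evidence strengths* — one strength c per level is chosen on the simulated
   0..5 grid to maximize the binomial likelihood of the (smoothed) correct/
   incorrect counts against the observer's orientation-accuracy curve at
   sigma_D = 0, under the constraint that easier levels get strengths at
   least as large as harder ones. The constrained discrete optimum is found
   exactly by monotone dynamic programming.
3. *Read-out noise* — sigma_D is fitted by grid search (0..1 step 0.01 for
   confidence observers, 0..10 step 0.1 for visibility observers) maximizing
   the four-outcome multinomial likelihood of the joint counts, with the
   strengths held fixed. Ideal fits clamp sigma_D at 0.
4. *Scores* — the multinomial log likelihood, BIC = -2 logL + k ln(n), and a
   10-fold cross-validated log likelihood: per resample the folds are
   rebalanced per level, sigma_D is refitted on 9 folds and the held-out
   fold scored; fold likelihoods are combined as log(mean fold likelihood)
   (via log-sum-exp; the mean of fold log likelihoods is available as an
   alternative) and averaged over 50 resamples. For ideal observers no
   parameter is refitted per fold, so the CV score equals the full-data log
   likelihood exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, logsumexp

from .data import LevelSummary
from .design import EASY_LEVEL_INDICES, HARD_LEVEL_INDICES, Task
from .observers import PredictionTable

__all__ = [
    "ParticipantData",
    "FitResult",
    "SubsetEligibilityError",
    "parametric_percent_correct",
    "effective_counts",
    "fit_evidence_strengths",
    "joint_log_likelihood",
    "fit_sigma_d",
    "bic",
    "cv_logl",
    "fit_observer",
    "fit_subset",
]

#: probability floor applied before taking logs in the multinomial likelihood
PROB_EPS = 1e-6


@dataclass
class ParticipantData:
    """One participant's joint-outcome counts per level, hardest first."""

    participant_id: str
    task: Task
    level_indices: np.ndarray  # (L,)
    counts: np.ndarray         # (L, 4): n11, n10, n01, n00

    @classmethod
    def from_summaries(cls, summaries: Sequence[LevelSummary]) -> "ParticipantData":
        pids = {s.participant_id for s in summaries}
        if len(pids) != 1:
            raise ValueError("summaries must belong to a single participant")
        rows = sorted(summaries, key=lambda s: s.level.index)
        return cls(
            participant_id=rows[0].participant_id,
            task=rows[0].level.task,
            level_indices=np.array([s.level.index for s in rows]),
            counts=np.vstack([s.counts for s in rows]),
        )

    @property
    def n_per_level(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def ori_accuracy(self) -> np.ndarray:
        return (self.counts[:, 0] + self.counts[:, 1]) / self.n_per_level

    def scaled_levels(self) -> np.ndarray:
        from .design import scaled_levels

        all_scaled = scaled_levels(self.task)
        return all_scaled[self.level_indices - 1]

    def restrict(self, level_indices: Sequence[int]) -> "ParticipantData":
        mask = np.isin(self.level_indices, list(level_indices))
        if not mask.any():
            raise ValueError("empty level subset")
        return ParticipantData(self.participant_id, self.task,
                               self.level_indices[mask], self.counts[mask])


@dataclass
class FitResult:
    """One observer fitted to one participant's data."""

    model_id: int
    variant: str               # "ideal" | "noisy"
    participant_id: str
    c_hat: np.ndarray          # per level, nondecreasing hardest -> easiest
    sigma_d_hat: float
    logl: float
    bic: float
    k: int
    n_total: int
    cv_logl_mean: float | None = None
    cv_logl_sem: float | None = None
    cv_scores: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# percent-correct preprocessing
# ---------------------------------------------------------------------------


def parametric_percent_correct(
    x: np.ndarray, n_correct: np.ndarray, n: np.ndarray
) -> np.ndarray:
    """Fitted per-level orientation accuracies, floored at 0.5.

    Fits logit(p) = alpha + beta * x by maximum likelihood on the per-level
    correct counts and returns the fitted values. Complete separation falls
    back to a half-count smoothed refit.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 levels")
    X = sm.add_constant(x)
    endog = np.column_stack([n_correct, n - n_correct]).astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        params = np.asarray(res.params, dtype=float)
        if not (np.all(np.isfinite(params)) and np.all(np.abs(params) < 50)):
            raise ValueError("separation")
    except Exception:
        warnings.warn("separation in psychometric fit; using smoothed counts",
                      stacklevel=2)
        endog = np.column_stack([n_correct + 0.5, n - n_correct + 0.5]).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        params = np.asarray(res.params, dtype=float)
    fitted = expit(params[0] + params[1] * x)
    return np.maximum(fitted, 0.5)


def effective_counts(n: np.ndarray, p_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer correct/incorrect targets from smoothed accuracies."""
    n = np.asarray(n)
    n_corr = np.rint(n * np.asarray(p_hat)).astype(int)
    return n_corr, n - n_corr


# ---------------------------------------------------------------------------
# constrained evidence-strength estimation
# ---------------------------------------------------------------------------


def fit_evidence_strengths(
    p_correct_grid: np.ndarray,
    n_correct: np.ndarray,
    n_incorrect: np.ndarray,
    c_grid: np.ndarray,
) -> np.ndarray:
    """Monotone maximum-likelihood assignment of grid strengths to levels.

    Maximizes sum_l [n_correct_l log P(correct|c_l) + n_incorrect_l
    log P(incorrect|c_l)] over nondecreasing (hardest -> easiest) strength
    vectors on the grid, exactly, by dynamic programming. Ties prefer the
    smaller strength.
    """
    p = np.clip(np.asarray(p_correct_grid, dtype=float), PROB_EPS, 1 - PROB_EPS)
    c_grid = np.asarray(c_grid, dtype=float)
    n_correct = np.asarray(n_correct, dtype=float)
    n_incorrect = np.asarray(n_incorrect, dtype=float)
    L, K = n_correct.size, p.size
    # scores[l, k]: likelihood contribution of level l at grid point k
    scores = (n_correct[:, None] * np.log(p)[None, :]
              + n_incorrect[:, None] * np.log(1 - p)[None, :])

    best = scores[0].copy()
    # choice[l, k]: best grid index for level l-1 given level l sits at k
    choice = np.zeros((L, K), dtype=int)
    for l in range(1, L):
        run = np.empty(K)
        arg = np.empty(K, dtype=int)
        run[0], arg[0] = best[0], 0
        for k in range(1, K):
            if best[k] > run[k - 1]:  # strict: keep the smaller index on ties
                run[k], arg[k] = best[k], k
            else:
                run[k], arg[k] = run[k - 1], arg[k - 1]
        choice[l] = arg
        best = scores[l] + run

    ks = np.empty(L, dtype=int)
    ks[-1] = int(np.argmax(best))  # first maximum = smallest strength
    for l in range(L - 1, 0, -1):
        ks[l - 1] = choice[l][ks[l]]
    return c_grid[ks]


# ---------------------------------------------------------------------------
# likelihood, noise fitting, information criteria
# ---------------------------------------------------------------------------


def _joint_probs(
    table: PredictionTable, c_hat: np.ndarray, sigma_d: float
) -> np.ndarray:
    return np.vstack([table.joint(float(c), float(sigma_d)) for c in c_hat])


def joint_log_likelihood(
    table: PredictionTable,
    c_hat: np.ndarray,
    sigma_d: float,
    counts: np.ndarray,
    outcomes: str = "all",
) -> float:
    """Multinomial log likelihood of joint counts under the observer.

    ``outcomes='incorrect_only'`` restricts to the two incorrect-orientation
    outcomes, using probabilities conditional on an incorrect orientation
    response. Probabilities are floored at ``PROB_EPS`` before the log.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(c_hat), 4):
        raise ValueError("counts must be (n_levels, 4) matching c_hat")
    probs = _joint_probs(table, c_hat, sigma_d)
    if outcomes == "incorrect_only":
        denom = probs[:, 2] + probs[:, 3]
        probs = probs[:, 2:] / np.maximum(denom, PROB_EPS)[:, None]
        counts = counts[:, 2:]
    elif outcomes != "all":
        raise ValueError("outcomes must be 'all' or 'incorrect_only'")
    if np.any((probs < PROB_EPS) & (counts > 0)):
        warnings.warn("probability floor hit in likelihood evaluation", stacklevel=2)
    return float(np.sum(counts * np.log(np.maximum(probs, PROB_EPS))))


def fit_sigma_d(
    table: PredictionTable,
    c_hat: np.ndarray,
    counts: np.ndarray,
    outcomes: str = "all",
) -> tuple[float, float]:
    """Grid argmax of the joint likelihood over sigma_D, strengths fixed.

    Returns (sigma_d_hat, logL at the optimum); ties take the smaller sigma.
    """
    lls = np.array([
        joint_log_likelihood(table, c_hat, float(s), counts, outcomes)
        for s in table.sigma_values
    ])
    j = int(np.argmax(lls))
    return float(table.sigma_values[j]), float(lls[j])


def bic(logl: float, k: int, n_total: int) -> float:
    """-2 logL + k ln(n_total)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return -2.0 * logl + k * np.log(n_total)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _fold_counts(
    counts: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Random per-level balanced split of joint counts into fold count arrays.

    Returns (folds, L, 4); per level the fold trial totals differ by <= 1.
    """
    L = counts.shape[0]
    out = np.zeros((folds, L, 4), dtype=int)
    for l in range(L):
        cells = np.repeat(np.arange(4), counts[l].astype(int))
        rng.shuffle(cells)
        fold_ids = np.arange(cells.size) % folds
        # offset so the "short" folds rotate across levels
        fold_ids = (fold_ids + rng.integers(folds)) % folds
        for f in range(folds):
            sel = cells[fold_ids == f]
            out[f, l] = np.bincount(sel, minlength=4)
    return out


def cv_logl(
    table: PredictionTable,
    c_hat: np.ndarray,
    counts: np.ndarray,
    variant: str = "noisy",
    folds: int = 10,
    resamples: int = 50,
    seed: int = 0,
    outcomes: str = "all",
    combine: str = "log_mean_lik",
) -> tuple[float, np.ndarray]:
    """Cross-validated log likelihood; (mean score, per-resample scores).

    For the ideal observer sigma_D is clamped at 0, nothing is refitted per
    fold, and the score equals the full-data log likelihood (one "resample").
    For the noisy observer, per resample: folds are redrawn balanced per
    level, sigma_D is fitted on the 9 training folds and the held-out fold's
    likelihood is computed; fold likelihoods combine as log of their mean
    (``combine='mean_log_lik'`` averages the fold log likelihoods instead).
    """
    if combine not in ("log_mean_lik", "mean_log_lik"):
        raise ValueError("combine must be 'log_mean_lik' or 'mean_log_lik'")
    counts = np.asarray(counts)
    if variant == "ideal":
        score = joint_log_likelihood(table, c_hat, 0.0, counts, outcomes)
        return score, np.array([score])
    rng = np.random.default_rng(seed)
    scores = np.empty(resamples)
    for r in range(resamples):
        fold_arr = _fold_counts(counts, folds, rng)
        fold_lls = np.empty(folds)
        for f in range(folds):
            train = counts - fold_arr[f]
            s_hat, _ = fit_sigma_d(table, c_hat, train, outcomes)
            fold_lls[f] = joint_log_likelihood(table, c_hat, s_hat, fold_arr[f], outcomes)
        if combine == "log_mean_lik":
            scores[r] = logsumexp(fold_lls) - np.log(folds)
        else:
            scores[r] = fold_lls.mean()
    return float(scores.mean()), scores


# ---------------------------------------------------------------------------
# top-level per-participant fits
# ---------------------------------------------------------------------------


class SubsetEligibilityError(ValueError):
    """Participant fails the accuracy criterion of an easy/hard subset."""


def fit_observer(
    table: PredictionTable,
    data: ParticipantData,
    variant: str = "ideal",
    cv_folds: int = 10,
    cv_resamples: int = 50,
    cv_seed: int = 0,
    outcomes: str = "all",
    run_cv: bool = True,
) -> FitResult:
    """Full fitting pipeline for one observer on one participant."""
    if variant not in ("ideal", "noisy"):
        raise ValueError("variant must be 'ideal' or 'noisy'")
    x = data.scaled_levels()
    n = data.n_per_level
    p_hat = parametric_percent_correct(x, data.counts[:, 0] + data.counts[:, 1], n)
    n_corr, n_inc = effective_counts(n, p_hat)
    c_hat = fit_evidence_strengths(
        table.p_orientation_correct(), n_corr, n_inc, table.c_values
    )
    if variant == "ideal":
        sigma_hat = 0.0
        logl = joint_log_likelihood(table, c_hat, 0.0, data.counts, outcomes)
    else:
        sigma_hat, logl = fit_sigma_d(table, c_hat, data.counts, outcomes)
    k = len(c_hat) + (1 if variant == "noisy" else 0)
    result = FitResult(
        model_id=table.model_id, variant=variant,
        participant_id=data.participant_id,
        c_hat=c_hat, sigma_d_hat=sigma_hat, logl=logl,
        bic=bic(logl, k, data.n_total), k=k, n_total=data.n_total,
        extras={"percent_correct": p_hat},
    )
    if run_cv:
        mean, scores = cv_logl(
            table, c_hat, data.counts, variant,
            folds=cv_folds, resamples=cv_resamples, seed=cv_seed, outcomes=outcomes,
        )
        result.cv_logl_mean = mean
        result.cv_scores = scores
        result.cv_logl_sem = (
            float(scores.std(ddof=1) / np.sqrt(scores.size)) if scores.size > 1 else 0.0
        )
    return result


def fit_subset(
    table: PredictionTable,
    data: ParticipantData,
    subset: str,
    variant: str = "noisy",
    accuracy_threshold: float = 0.70,
    **fit_kwargs,
) -> FitResult:
    """Refit on a data subset: incorrect-orientation trials only, or the
    easy/hard level pairs.

    Easy subsets require pooled orientation accuracy >= the threshold over
    the subset levels, hard subsets require it to be below; ineligible
    participants raise :class:`SubsetEligibilityError` so drivers can drop
    and log them. Strengths are refit on the subset; for ``incorrect_only``
    the likelihood uses probabilities conditional on an incorrect response.
    """
    if subset == "incorrect_only":
        n_incorrect = data.counts[:, 2] + data.counts[:, 3]
        if n_incorrect.sum() == 0:
            raise ValueError("no incorrect-orientation trials in subset")
        return fit_observer(table, data, variant, outcomes="incorrect_only", **fit_kwargs)
    if subset not in ("easy", "hard"):
        raise ValueError("subset must be 'incorrect_only', 'easy' or 'hard'")
    idx = (EASY_LEVEL_INDICES if subset == "easy" else HARD_LEVEL_INDICES)[data.task]
    sub = data.restrict(idx)
    pooled_acc = (sub.counts[:, 0] + sub.counts[:, 1]).sum() / sub.n_total
    if subset == "easy" and pooled_acc < accuracy_threshold:
        raise SubsetEligibilityError(
            f"{data.participant_id}: accuracy {pooled_acc:.3f} below "
            f"{accuracy_threshold:.0%} in easy conditions"
        )
    if subset == "hard" and pooled_acc >= accuracy_threshold:
        raise SubsetEligibilityError(
            f"{data.participant_id}: accuracy {pooled_acc:.3f} at or above "
            f"{accuracy_threshold:.0%} in hard conditions"
        )
    return fit_observer(table, sub, variant, **fit_kwargs)
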