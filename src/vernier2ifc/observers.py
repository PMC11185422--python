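"""Seven Bayesian observers for the 2IFC Vernier task, in 2D-SDT evidence space.

Evidence lives in a plane whose axes carry evidence for a leftward and a
rightward offset. A stimulus of strength ``c`` is a bivariate Gaussian source
with identity covariance centered at ``[c, 0]`` (left) or ``[0, c]`` (right).
The neutral (offset-absent) Vernier is represented either at the origin
(models 1, 2, 5) or on the main diagonal at ``[c/2, c/2]`` (models 3, 4, 6, 7),
in which case the origin represents the absence of any stimulus.

On each trial the observer draws one evidence sample per interval, decides the
offset orientation per interval (posterior over left/right, prior 0.5 each; the
no-stimulus hypothesis has prior 0), and then selects the interval where the
offset was "more visible" through a decision variable ``D``:

* confidence observers (1-4) compare the posterior confidence in the chosen
  orientation across intervals,
* visibility observers (5-7) compare the posterior probability that the sample
  contained *any* offset, i.e. ``1 - p(neutral | d)``.

``D`` is a log ratio in every model, with OP chosen iff ``D > 0`` after adding
Gaussian read-out noise ``delta ~ N(0, sigma_D)`` (an exact tie is broken by
a fair coin); the noise models degraded conscious access to the evidence and
never touches the orientation response.

Observers marginalize over a discrete grid of candidate strengths (uniform
prior over the grid) or first point-estimate the most likely strength
("hierarchical"); model 5 has a single neutral source, so the two strategies
coincide and it is implemented as one computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MODEL_ATTRIBUTES",
    "ObserverSpec",
    "TrialOutcome",
    "PredictionTable",
    "default_c_grid",
    "default_sigma_grid",
    "source_mean",
    "sample_evidence",
    "orientation_decision",
    "interval_decision",
    "inject_noise",
    "choose_op",
    "simulate_trials",
    "simulate_prediction_table",
]

_LOG2PI = np.log(2.0 * np.pi)

#: model_id -> (placement, strategy, judgment). Model 5's strategy is not
#: applicable: with a single neutral source the marginalizing and hierarchical
#: variants are the same observer.
MODEL_ATTRIBUTES = {
    1: ("origin", "marginalize", "confidence"),
    2: ("origin", "hierarchical", "confidence"),
    3: ("diagonal", "marginalize", "confidence"),
    4: ("diagonal", "hierarchical", "confidence"),
    5: ("origin", None, "visibility"),
    6: ("diagonal", "marginalize", "visibility"),
    7: ("diagonal", "hierarchical", "visibility"),
}


def default_c_grid() -> np.ndarray:
    """Candidate evidence strengths 0..5 in steps of 0.1 (51 values)."""
    return np.round(np.arange(0, 51) * 0.1, 10)


def default_sigma_grid(model_id: int) -> np.ndarray:
    """Read-out noise grid: 0..1 step 0.01 for confidence observers,
    0..10 step 0.1 for visibility observers (these are more robust to noise)."""
    if MODEL_ATTRIBUTES[model_id][2] == "confidence":
        return np.round(np.arange(0, 101) * 0.01, 10)
    return np.round(np.arange(0, 101) * 0.1, 10)


@dataclass(frozen=True)
class ObserverSpec:
    """Configuration of one observer: model identity, read-out noise, c grid."""

    model_id: int
    sigma_d: float = 0.0
    c_grid: np.ndarray = field(default_factory=default_c_grid)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_ATTRIBUTES:
            raise ValueError(f"model_id must be 1..7, got {self.model_id}")
        if self.sigma_d < 0:
            raise ValueError("sigma_d must be nonnegative")
        object.__setattr__(self, "c_grid", np.asarray(self.c_grid, dtype=float))
        if self.c_grid.size == 0:
            raise ValueError("empty c_grid")

    @property
    def placement(self) -> str:
        return MODEL_ATTRIBUTES[self.model_id][0]

    @property
    def strategy(self) -> str | None:
        return MODEL_ATTRIBUTES[self.model_id][1]

    @property
    def judgment(self) -> str:
        return MODEL_ATTRIBUTES[self.model_id][2]


def source_mean(placement: str, source_kind: str, c: float) -> np.ndarray:
    """Mean of the bivariate Gaussian evidence source (covariance is identity).

    ``left`` -> [c, 0]; ``right`` -> [0, c]; ``neutral`` -> [0, 0] (origin
    placement) or [c/2, c/2] (diagonal placement); ``absent`` -> [0, 0].
    """
    if c < 0:
        raise ValueError("negative evidence strength")
    if source_kind == "left":
        return np.array([c, 0.0])
    if source_kind == "right":
        return np.array([0.0, c])
    if source_kind == "neutral":
        return np.array([c / 2, c / 2]) if placement == "diagonal" else np.array([0.0, 0.0])
    if source_kind == "absent":
        return np.array([0.0, 0.0])
    raise ValueError(f"unknown source kind {source_kind!r}")


def sample_evidence(
    spec: ObserverSpec, c: float, true_orientation: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two intervals' evidence samples (d_op, d_oa), independently."""
    mu_op = source_mean(spec.placement, true_orientation, c)
    mu_oa = source_mean(spec.placement, "neutral", c)
    return rng.standard_normal(2) + mu_op, rng.standard_normal(2) + mu_oa


# ---------------------------------------------------------------------------
# vectorized per-interval machinery
# ---------------------------------------------------------------------------


def _log_densities(d: np.ndarray, c_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log bivariate-normal densities of samples d (n, 2) under the left,
    right and diagonal-neutral sources at every grid strength; (n, K) each."""
    x = d[:, 0:1]
    y = d[:, 1:2]
    c = c_grid[None, :]
    base = -0.5 * (x**2 + y**2) - _LOG2PI
    ll_left = base + c * x - 0.5 * c**2
    ll_right = base + c * y - 0.5 * c**2
    ll_neutral = base + 0.5 * c * (x + y) - 0.25 * c**2
    return ll_left, ll_right, ll_neutral


@dataclass
class _IntervalState:
    """Everything one interval contributes to the trial's decisions."""

    chose_left: np.ndarray      # bool (n,)
    log_conf: np.ndarray        # log posterior of the chosen orientation
    log_vis: np.ndarray | None  # log(1 - p(neutral | d)), visibility models
    c_hat: np.ndarray | None    # estimated strength, hierarchical models


def _process_interval(
    spec: ObserverSpec, d: np.ndarray, rng: np.random.Generator
) -> _IntervalState:
    K = spec.c_grid.size
    logK = np.log(K)
    ll_L, ll_R, ll_N = _log_densities(d, spec.c_grid)

    hierarchical = spec.strategy == "hierarchical"
    if hierarchical:
        # argmax takes the first (smallest) grid strength on exact ties
        iL = np.argmax(ll_L, axis=1)
        iR = np.argmax(ll_R, axis=1)
        sL = ll_L[np.arange(len(d)), iL]
        sR = ll_R[np.arange(len(d)), iR]
    else:
        sL = logsumexp(ll_L, axis=1) - logK
        sR = logsumexp(ll_R, axis=1) - logK
        iL = iR = None

    chose_left = sL > sR
    ties = sL == sR
    if np.any(ties):
        chose_left = np.where(ties, rng.random(len(d)) < 0.5, chose_left)

    norm = np.logaddexp(sL, sR)
    log_conf = np.where(chose_left, sL, sR) - norm

    c_hat = None
    if hierarchical:
        k_star = np.where(chose_left, iL, iR)
        c_hat = spec.c_grid[k_star]

    log_vis = None
    if spec.judgment == "visibility":
        # signal hypothesis: prior 0.5 split evenly over the two orientations;
        # neutral hypothesis: prior 0.5 (the common 0.5 cancels in the
        # normalized posterior and is omitted)
        if spec.model_id == 5:
            lpN = -0.5 * (d[:, 0] ** 2 + d[:, 1] ** 2) - _LOG2PI
            lpS = np.logaddexp(
                logsumexp(ll_L, axis=1) - logK, logsumexp(ll_R, axis=1) - logK
            ) - np.log(2.0)
        elif spec.model_id == 6:
            lpN = logsumexp(ll_N, axis=1) - logK
            lpS = np.logaddexp(
                logsumexp(ll_L, axis=1) - logK, logsumexp(ll_R, axis=1) - logK
            ) - np.log(2.0)
        else:  # model 7: everything at the estimated strength of the chosen S
            rows = np.arange(len(d))
            lpN = ll_N[rows, k_star]
            lpS = np.logaddexp(ll_L[rows, k_star], ll_R[rows, k_star]) - np.log(2.0)
        log_vis = lpS - np.logaddexp(lpN, lpS)

    return _IntervalState(chose_left, log_conf, log_vis, c_hat)


def _decision_variable(spec: ObserverSpec, op: _IntervalState, oa: _IntervalState) -> np.ndarray:
    if spec.judgment == "confidence":
        return op.log_conf - oa.log_conf
    return op.log_vis - oa.log_vis


def inject_noise(D: np.ndarray, sigma_d: float, rng: np.random.Generator) -> np.ndarray:
    """Add read-out noise delta ~ N(0, sigma_d) to the decision variable."""
    if sigma_d < 0:
        raise ValueError("sigma_d must be nonnegative")
    if sigma_d == 0:
        return np.asarray(D, dtype=float)
    return np.asarray(D, dtype=float) + sigma_d * rng.standard_normal(np.shape(D))


def choose_op(D_noisy: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """OP-interval choice: D_noisy > 0, with exact ties broken by a fair coin.

    Ties are measure-zero for continuous D, but hierarchical observers
    collapse confidence to exactly 0.5 with positive probability at zero
    evidence strength; a deterministic tie rule would then bias the 2IFC
    choice away from chance, so ties get the same coin treatment as tied
    orientation posteriors.
    """
    D_noisy = np.asarray(D_noisy, dtype=float)
    out = D_noisy > 0
    ties = D_noisy == 0
    if np.any(ties):
        out = np.where(ties, rng.random(D_noisy.shape) < 0.5, out)
    return out


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------


@dataclass
class TrialOutcome:
    """Full outcome of one simulated trial."""

    s_chosen_op: str
    s_chosen_oa: str
    D: float
    D_noisy: float
    chose_op: bool
    c_hat_op: float | None = None
    c_hat_oa: float | None = None

    @property
    def interval_choice(self) -> str:
        return "OP" if self.chose_op else "OA"


def orientation_decision(
    spec: ObserverSpec, d: np.ndarray, rng: np.random.Generator | None = None
) -> tuple[str, float, float | None]:
    """Orientation choice for one evidence sample.

    Returns ``(s_chosen, posterior_of_chosen, c_hat)``; ``c_hat`` is None for
    marginalizing observers. Exact posterior ties are broken by a fair coin.
    """
    rng = rng or np.random.default_rng()
    st = _process_interval(spec, np.asarray(d, dtype=float).reshape(1, 2), rng)
    s = "left" if st.chose_left[0] else "right"
    c_hat = float(st.c_hat[0]) if st.c_hat is not None else None
    return s, float(np.exp(st.log_conf[0])), c_hat


def interval_decision(
    spec: ObserverSpec,
    d_op: np.ndarray,
    d_oa: np.ndarray,
    rng: np.random.Generator | None = None,
) -> TrialOutcome:
    """Run both intervals through the observer and select the more-visible one.

    ``D`` is the log-ratio decision variable of the model family; the OP
    interval is chosen iff ``D_noisy > 0``, with an exact tie broken by a
    fair coin (see :func:`choose_op`).
    """
    rng = rng or np.random.default_rng()
    op = _process_interval(spec, np.asarray(d_op, dtype=float).reshape(1, 2), rng)
    oa = _process_interval(spec, np.asarray(d_oa, dtype=float).reshape(1, 2), rng)
    D = float(_decision_variable(spec, op, oa)[0])
    D_noisy = float(inject_noise(np.array([D]), spec.sigma_d, rng)[0])
    return TrialOutcome(
        s_chosen_op="left" if op.chose_left[0] else "right",
        s_chosen_oa="left" if oa.chose_left[0] else "right",
        D=D,
        D_noisy=D_noisy,
        chose_op=bool(choose_op(np.array([D_noisy]), rng)[0]),
        c_hat_op=float(op.c_hat[0]) if op.c_hat is not None else None,
        c_hat_oa=float(oa.c_hat[0]) if oa.c_hat is not None else None,
    )


# ---------------------------------------------------------------------------
# batch simulation
# ---------------------------------------------------------------------------


def simulate_trials(
    spec: ObserverSpec,
    c: float,
    n: int,
    rng: np.random.Generator,
    true_left: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Simulate ``n`` trials at strength ``c`` (noise NOT yet injected).

    Returns arrays: ``ori_correct`` (bool), ``D`` (float), ``chose_left_op``,
    ``chose_left_oa`` (bool). ``true_left`` fixes the per-trial stimulus
    orientation; by default orientations are drawn fairly.
    """
    if true_left is None:
        true_left = rng.random(n) < 0.5
    mu_left = source_mean(spec.placement, "left", c)
    mu_right = source_mean(spec.placement, "right", c)
    mu_neutral = source_mean(spec.placement, "neutral", c)
    d_op = rng.standard_normal((n, 2)) + np.where(true_left[:, None], mu_left, mu_right)
    d_oa = rng.standard_normal((n, 2)) + mu_neutral
    op = _process_interval(spec, d_op, rng)
    oa = _process_interval(spec, d_oa, rng)
    return {
        "ori_correct": op.chose_left == true_left,
        "D": _decision_variable(spec, op, oa),
        "chose_left_op": op.chose_left,
        "chose_left_oa": oa.chose_left,
    }


@dataclass
class PredictionTable:
    """Monte-Carlo joint-outcome probabilities for one observer.

    ``probs[i, j]`` holds ``[p11, p10, p01, p00]`` at ``c_values[i]`` and
    ``sigma_values[j]`` (first digit: orientation correct, second: interval
    correct). Common random numbers are used across sigma at fixed c, so the
    orientation-correct marginal is bit-identical down the sigma axis.
    """

    model_id: int
    c_values: np.ndarray
    sigma_values: np.ndarray
    probs: np.ndarray  # (n_c, n_sigma, 4)
    n_sim: int
    seed: int

    def c_index(self, c: float) -> int:
        i = int(np.argmin(np.abs(self.c_values - c)))
        if abs(self.c_values[i] - c) > 1e-9:
            raise KeyError(f"c={c} not on the simulated grid")
        return i

    def sigma_index(self, sigma: float) -> int:
        j = int(np.argmin(np.abs(self.sigma_values - sigma)))
        if abs(self.sigma_values[j] - sigma) > 1e-9:
            raise KeyError(f"sigma={sigma} not on the simulated grid")
        return j

    def joint(self, c: float, sigma: float) -> np.ndarray:
        return self.probs[self.c_index(c), self.sigma_index(sigma)]

    def p_orientation_correct(self) -> np.ndarray:
        """P(orientation correct | c), independent of sigma by construction."""
        return self.probs[:, 0, 0] + self.probs[:, 0, 1]

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, c in enumerate(self.c_values):
            for j, s in enumerate(self.sigma_values):
                p = self.probs[i, j]
                rows.append(
                    dict(model_id=self.model_id, c=c, sigma_d=s,
                         p11=p[0], p10=p[1], p01=p[2], p00=p[3],
                         n_sim=self.n_sim, seed=self.seed)
                )
        return pd.DataFrame(rows)


def simulate_prediction_table(
    spec: ObserverSpec,
    c_values: Sequence[float] | None = None,
    sigma_values: Sequence[float] | None = None,
    n_sim: int = 100_000,
    seed: int = 0,
) -> PredictionTable:
    """Tabulate joint outcome probabilities over a (c, sigma_D) grid.

    Per c, ``n_sim`` trials are simulated once at sigma_D = 0; the same noise
    draws are then reused for every sigma (common random numbers), which keeps
    the orientation marginal identical across sigma and makes interval
    accuracy exactly monotone comparisons meaningful.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    c_values = np.asarray(c_values if c_values is not None else spec.c_grid, dtype=float)
    sigma_values = np.asarray(
        sigma_values if sigma_values is not None else default_sigma_grid(spec.model_id),
        dtype=float,
    )
    rng = np.random.default_rng(seed)
    probs = np.empty((c_values.size, sigma_values.size, 4))
    for i, c in enumerate(c_values):
        sim = simulate_trials(spec, float(c), n_sim, rng)
        z = rng.standard_normal(n_sim)
        tie_coin = rng.random(n_sim) < 0.5
        ori = sim["ori_correct"]
        D = sim["D"]
        for j, s in enumerate(sigma_values):
            D_noisy = D + s * z
            int_correct = (D_noisy > 0) | ((D_noisy == 0) & tie_coin)
            probs[i, j, 0] = np.mean(ori & int_correct)
            probs[i, j, 1] = np.mean(ori & ~int_correct)
            probs[i, j, 2] = np.mean(~ori & int_correct)
            probs[i, j, 3] = np.mean(~ori & ~int_correct)
    return PredictionTable(spec.model_id, c_values, sigma_values, probs, n_sim, seed)
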