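"""Hierarchical Bayesian logistic regression and Dienes-style Bayes factors.

Every inferential claim in the pipeline runs through this module:

* Per-level performance is modelled with a Bayesian mixed-effects logistic
  regression (participants as random effects)::

      Correct ~ Bernoulli(p),  logit p = a_j + b_j * level
      a_j ~ Normal(abar, sigma_a),  b_j ~ Normal(bbar, sigma_b)
      abar ~ Normal(0, 0.25), bbar ~ Normal(0, 1),
      sigma_a, sigma_b ~ Exponential(1)

  Levels enter scaled by the largest level value, so the covariate lies in
  (0, 1]. The ``abar`` prior places the group-level threshold in the 0.38-0.62
  probability range with 95% probability. The posterior is sampled with an
  affine-invariant ensemble MCMC sampler (emcee) and checked with split-R-hat
  and effective-sample-size diagnostics.

* Evidence for/against a hypothesis is summarized by a Bayes factor computed
  with the Dienes calculator: the effect estimate (mean, sd) is treated as a
  Normal likelihood and integrated against each hypothesis' prior (a point,
  a Normal, or a half-Normal), BF10 = marginal(H1) / marginal(H0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, stats
from scipy.special import expit

__all__ = [
    "PriorSpec",
    "BFResult",
    "LogisticModelSpec",
    "LogisticPosterior",
    "prior_threshold_interval",
    "marginal_likelihood",
    "log_marginal_likelihood",
    "bayes_factor",
    "one_sample_t",
    "slope_bf",
    "fit_hier_logistic",
    "posterior_predict",
    "bf_above_chance",
    "bf_difference",
    "SLOPE_H1_SD",
    "EXCLUSION_BF_THRESHOLD",
]

#: half-Gaussian prior sd for the positive-slope hypothesis in the
#: participant exclusion screen
SLOPE_H1_SD = 2.30
#: BF10 at or below this value counts as evidence for a null/negative slope
EXCLUSION_BF_THRESHOLD = 1.0 / 3.0


# ---------------------------------------------------------------------------
# priors, marginal likelihoods, Bayes factors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """A hypothesis prior: point mass, Normal, or one-tailed half-Normal."""

    kind: str  # point | normal | half_normal_upper | half_normal_lower
    center: float
    sd: float = 0.0

    _KINDS = ("point", "normal", "half_normal_upper", "half_normal_lower")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.kind != "point" and self.sd <= 0:
            raise ValueError("sd must be positive for non-point priors")

    def pdf(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if self.kind == "point":
            raise ValueError("point prior has no density")
        dens = stats.norm.pdf(theta, self.center, self.sd)
        if self.kind == "normal":
            return dens
        if self.kind == "half_normal_upper":
            return np.where(theta >= self.center, 2.0 * dens, 0.0)
        return np.where(theta <= self.center, 2.0 * dens, 0.0)

    def logpdf(self, theta: float) -> float:
        if self.kind == "point":
            raise ValueError("point prior has no density")
        if self.kind == "half_normal_upper" and theta < self.center:
            return -np.inf
        if self.kind == "half_normal_lower" and theta > self.center:
            return -np.inf
        dens = stats.norm.logpdf(theta, self.center, self.sd)
        if self.kind == "normal":
            return float(dens)
        return float(dens + np.log(2.0))

    @property
    def support(self) -> tuple[float, float]:
        if self.kind == "point":
            return (self.center, self.center)
        if self.kind == "half_normal_upper":
            return (self.center, np.inf)
        if self.kind == "half_normal_lower":
            return (-np.inf, self.center)
        return (-np.inf, np.inf)


@dataclass(frozen=True)
class BFResult:
    """Bayes factor BF10 = marginal(H1)/marginal(H0) for one effect summary.

    ``log_bf10`` stays finite when the ratio itself under- or overflows.
    """

    bf10: float
    obs_mean: float
    obs_sd: float
    h0: PriorSpec
    h1: PriorSpec
    log_bf10: float = np.nan


def prior_threshold_interval(sd: float, mass: float = 0.95) -> tuple[float, float]:
    """Central ``mass`` interval of inverse-logit(X), X ~ Normal(0, sd).

    Used to read the group-threshold prior on the probability scale: sd = 0.25
    gives (0.38, 0.62) at 95% mass.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    if sd == 0:
        return (0.5, 0.5)
    alpha = (1.0 - mass) / 2.0
    lo, hi = stats.norm.ppf([alpha, 1.0 - alpha], loc=0.0, scale=sd)
    return (float(expit(lo)), float(expit(hi)))


def log_marginal_likelihood(obs_mean: float, obs_sd: float, prior: PriorSpec) -> float:
    """Log of the integral of Normal(obs_mean; theta, obs_sd) against the prior.

    The integrand (a Gaussian product, possibly truncated) is unimodal; it is
    integrated by adaptive quadrature after shifting by its log maximum, so
    marginals far in a hypothesis' tail (which underflow as plain densities)
    remain usable in Bayes-factor ratios.
    """
    if not (np.isfinite(obs_mean) and np.isfinite(obs_sd)) or obs_sd <= 0:
        raise ValueError("obs_mean and obs_sd must be finite with obs_sd > 0")
    if prior.kind == "point":
        return float(stats.norm.logpdf(obs_mean, prior.center, obs_sd))

    lo_s, hi_s = prior.support
    # mode and scale of the Gaussian product, clipped to the prior support
    prec = 1.0 / obs_sd**2 + 1.0 / prior.sd**2
    mode = (obs_mean / obs_sd**2 + prior.center / prior.sd**2) / prec
    scale = 1.0 / np.sqrt(prec)
    mode = float(np.clip(mode, lo_s, hi_s))
    lo = max(lo_s, mode - 15.0 * scale)
    hi = min(hi_s, mode + 15.0 * scale)

    def log_integrand(theta: float) -> float:
        lp = prior.logpdf(theta)
        if not np.isfinite(lp):
            return -np.inf
        return float(stats.norm.logpdf(obs_mean, theta, obs_sd)) + lp

    shift = log_integrand(mode)
    if not np.isfinite(shift):  # mode on a support boundary of measure zero
        shift = 0.0
    val, _ = integrate.quad(
        lambda t: np.exp(log_integrand(t) - shift), lo, hi,
        points=[mode] if lo < mode < hi else None,
        epsrel=1e-10, epsabs=0, limit=200,
    )
    return float(np.log(val) + shift)


def marginal_likelihood(obs_mean: float, obs_sd: float, prior: PriorSpec) -> float:
    """Integral of Normal(obs_mean; theta, obs_sd) against the prior.

    Point priors evaluate the Normal density at the point; Normal priors
    agree with the closed form Normal(obs_mean; center, sqrt(obs_sd^2+sd^2)).
    """
    return float(np.exp(log_marginal_likelihood(obs_mean, obs_sd, prior)))


def bayes_factor(obs_mean: float, obs_sd: float, h0: PriorSpec, h1: PriorSpec) -> BFResult:
    """BF10 for an effect summarized as (mean, sd); swapping H0/H1 inverts it."""
    lm1 = log_marginal_likelihood(obs_mean, obs_sd, h1)
    lm0 = log_marginal_likelihood(obs_mean, obs_sd, h0)
    with np.errstate(over="ignore"):
        bf10 = float(np.exp(lm1 - lm0))
    return BFResult(bf10=bf10, obs_mean=obs_mean,
                    obs_sd=obs_sd, h0=h0, h1=h1, log_bf10=float(lm1 - lm0))


def one_sample_t(
    values: Sequence[float] | None = None,
    *,
    mean: float | None = None,
    sd: float | None = None,
    n: int | None = None,
    popmean: float = 50.0,
) -> tuple[float, int, float]:
    """Two-tailed one-sample t test against ``popmean``.

    Accepts either raw per-participant values or the summary (mean, sd, n).
    Returns (t, df, p).
    """
    if values is not None:
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ValueError("need at least 2 participants")
        if values.std(ddof=1) == 0:  # degenerate: all participants identical
            t = 0.0 if values.mean() == popmean else np.inf * np.sign(values.mean() - popmean)
            return float(t), values.size - 1, 1.0 if t == 0 else 0.0
        t, p = stats.ttest_1samp(values, popmean)
        return float(t), values.size - 1, float(p)
    if mean is None or sd is None or n is None:
        raise ValueError("provide values or all of (mean, sd, n)")
    if n < 2:
        raise ValueError("need at least 2 participants")
    t = (mean - popmean) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


# ---------------------------------------------------------------------------
# per-participant slope screening
# ---------------------------------------------------------------------------


def _ml_logistic(x: np.ndarray, k: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """ML logistic regression of binomial counts on x; (slope, slope SE).

    Complete separation (diverging estimate / unstable SE) falls back to a
    smoothed refit adding half a success and half a failure per cell.
    """
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(x, dtype=float))
    endog = np.column_stack([k, n - k]).astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        slope, se = float(res.params[1]), float(res.bse[1])
        if np.isfinite(slope) and np.isfinite(se) and abs(slope) < 20 and se < 50:
            return slope, se
    except Exception:
        pass
    warnings.warn("separation in logistic fit; using smoothed counts", stacklevel=2)
    endog = np.column_stack([k + 0.5, n - k + 0.5]).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    return float(res.params[1]), float(res.bse[1])


def slope_bf(x: np.ndarray, k: np.ndarray, n: np.ndarray) -> BFResult:
    """Bayes factor for a positive performance slope across visibility levels.

    ``x`` are scaled levels, ``k`` successes out of ``n`` trials per level.
    H1: positive slope (upper half-Gaussian, mean 0, sd 2.30); H0: point at 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 levels to estimate a slope")
    slope, se = _ml_logistic(x, np.asarray(k), np.asarray(n))
    return bayes_factor(
        slope, se,
        h0=PriorSpec("point", 0.0),
        h1=PriorSpec("half_normal_upper", 0.0, SLOPE_H1_SD),
    )


# ---------------------------------------------------------------------------
# hierarchical logistic model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticModelSpec:
    """Priors and structure of the mixed-effects logistic model."""

    include_slope: bool = True
    prior_abar_sd: float = 0.25
    prior_bbar_sd: float = 1.0
    # sigma_a, sigma_b ~ Exponential(1); fixed by the model definition


@dataclass
class LogisticPosterior:
    """Posterior draws plus sampler diagnostics for one fitted model."""

    abar: np.ndarray
    bbar: np.ndarray | None
    sigma_a: np.ndarray
    sigma_b: np.ndarray | None
    a: np.ndarray  # (n_draws, J)
    b: np.ndarray | None
    participants: list[str]
    include_slope: bool
    rhat_max: float
    ess_min: float
    warnings: list[str] = field(default_factory=list)


def _log_prob_factory(spec, x, k, n, pidx, J):
    """Vectorized log posterior over walker ensembles.

    Non-centered parameterization: participant effects enter as standardized
    offsets z with a_j = abar + sigma_a * z_j (likewise for slopes), which
    decorrelates the hierarchy and lets the ensemble sampler mix. Parameter
    vector: [abar, (bbar), log sigma_a, (log sigma_b), za_1..J, (zb_1..J)];
    sigmas carry the Exponential(1) prior plus the log-scale Jacobian.
    """
    if spec.include_slope:
        def log_prob(theta: np.ndarray) -> np.ndarray:
            theta = np.atleast_2d(theta)
            abar, bbar = theta[:, 0], theta[:, 1]
            lsa, lsb = theta[:, 2], theta[:, 3]
            sa, sb = np.exp(lsa), np.exp(lsb)
            za = theta[:, 4:4 + J]
            zb = theta[:, 4 + J:4 + 2 * J]
            a = abar[:, None] + sa[:, None] * za
            b = bbar[:, None] + sb[:, None] * zb
            eta = a[:, pidx] + b[:, pidx] * x[None, :]
            ll = np.sum(k[None, :] * eta - n[None, :] * np.logaddexp(0.0, eta), axis=1)
            lp = (
                -0.5 * (abar / spec.prior_abar_sd) ** 2
                - 0.5 * (bbar / spec.prior_bbar_sd) ** 2
                + (-sa + lsa) + (-sb + lsb)
                - 0.5 * np.sum(za**2, axis=1)
                - 0.5 * np.sum(zb**2, axis=1)
            )
            return ll + lp
    else:
        def log_prob(theta: np.ndarray) -> np.ndarray:
            theta = np.atleast_2d(theta)
            abar, lsa = theta[:, 0], theta[:, 1]
            sa = np.exp(lsa)
            za = theta[:, 2:2 + J]
            a = abar[:, None] + sa[:, None] * za
            eta = a[:, pidx]
            ll = np.sum(k[None, :] * eta - n[None, :] * np.logaddexp(0.0, eta), axis=1)
            lp = (
                -0.5 * (abar / spec.prior_abar_sd) ** 2
                + (-sa + lsa)
                - 0.5 * np.sum(za**2, axis=1)
            )
            return ll + lp
    return log_prob


def fit_hier_logistic(
    x: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    participant: Sequence[str],
    spec: LogisticModelSpec | None = None,
    seed: int = 0,
    n_walkers: int = 64,
    n_steps: int = 2000,
    n_burn: int | None = None,
) -> LogisticPosterior:
    """Sample the mixed-effects logistic posterior from aggregated counts.

    One input cell per (participant, level): scaled level ``x``, successes
    ``k`` out of ``n``. For the intercept-only response-bias model pass
    ``spec=LogisticModelSpec(include_slope=False)``.
    """
    import emcee

    spec = spec or LogisticModelSpec()
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    participant = list(participant)
    parts = sorted(set(participant))
    J = len(parts)
    if J < 2:
        raise ValueError("hierarchical model needs at least 2 participants")
    if spec.include_slope and len(set(np.round(x, 12))) < 2:
        raise ValueError("slope model needs at least 2 distinct levels")
    pidx = np.array([parts.index(p) for p in participant])

    # moment-matched starting point: per-participant empirical logits
    emp = np.zeros(J)
    for j in range(J):
        m = pidx == j
        emp[j] = np.log((k[m].sum() + 0.5) / (n[m].sum() - k[m].sum() + 0.5))
    if spec.include_slope:
        ndim = 4 + 2 * J
        center = np.concatenate([[emp.mean(), 0.0, np.log(0.5), np.log(0.5)],
                                 np.zeros(2 * J)])
    else:
        ndim = 2 + J
        center = np.concatenate([[emp.mean(), np.log(0.5)], np.zeros(J)])

    rng = np.random.default_rng(seed)
    p0 = center[None, :] + 0.1 * rng.standard_normal((n_walkers, ndim))
    log_prob = _log_prob_factory(spec, x, k, n, pidx, J)
    # differential-evolution moves handle the correlated hierarchical
    # geometry far better than the default stretch move
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob,
                                    vectorize=True, moves=moves)
    sampler.random_state = np.random.RandomState(seed + 1)
    sampler.run_mcmc(p0, n_steps, progress=False)

    n_burn = n_burn if n_burn is not None else n_steps // 2
    chain = sampler.get_chain(discard=n_burn)  # (steps, walkers, ndim)

    rhat_max, ess_min, warns = _diagnostics(chain)
    flat = chain.reshape(-1, ndim)
    if spec.include_slope:
        sa, sb = np.exp(flat[:, 2]), np.exp(flat[:, 3])
        post = LogisticPosterior(
            abar=flat[:, 0], bbar=flat[:, 1],
            sigma_a=sa, sigma_b=sb,
            a=flat[:, 0:1] + sa[:, None] * flat[:, 4:4 + J],
            b=flat[:, 1:2] + sb[:, None] * flat[:, 4 + J:],
            participants=parts, include_slope=True,
            rhat_max=rhat_max, ess_min=ess_min, warnings=warns,
        )
    else:
        sa = np.exp(flat[:, 1])
        post = LogisticPosterior(
            abar=flat[:, 0], bbar=None,
            sigma_a=sa, sigma_b=None,
            a=flat[:, 0:1] + sa[:, None] * flat[:, 2:], b=None,
            participants=parts, include_slope=False,
            rhat_max=rhat_max, ess_min=ess_min, warnings=warns,
        )
    return post


def _diagnostics(chain: np.ndarray) -> tuple[float, float, list[str]]:
    """Split-R-hat and bulk ESS over the walker ensemble (walkers as chains)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        arr = np.moveaxis(chain, 1, 0)  # (walkers, steps, ndim)
        ds = az.convert_to_dataset(arr)
        rhat_max = float(az.rhat(ds).x.max())
        ess_min = float(az.ess(ds).x.min())
    warns = []
    if not np.isfinite(rhat_max) or rhat_max >= 1.01:
        warns.append(f"split-R-hat {rhat_max:.4f} >= 1.01: chains may not have mixed")
    return rhat_max, ess_min, warns


def posterior_predict(posterior: LogisticPosterior, level: float) -> tuple[float, float]:
    """Population-level predictive (mean, sd) on the probability scale.

    Summarizes inverse-logit(abar + bbar * level) over posterior draws.
    """
    if not 0 < level <= 1:
        warnings.warn(f"scaled level {level} outside (0, 1]: extrapolating", stacklevel=2)
    draws = posterior_predict_draws(posterior, level)
    return float(draws.mean()), float(draws.std(ddof=1))


def posterior_predict_draws(posterior: LogisticPosterior, level: float) -> np.ndarray:
    eta = posterior.abar
    if posterior.include_slope:
        eta = eta + posterior.bbar * level
    return expit(eta)


# ---------------------------------------------------------------------------
# level-dependent Bayes-factor analyses
# ---------------------------------------------------------------------------

#: H0 for above-chance performance: tightly centered at chance
H0_CHANCE = PriorSpec("normal", 0.5, 0.005)
#: H1 sd at the easiest level, above-chance family
EASIEST_SD_CHANCE = 0.25
#: H1 sd at the easiest level, difference families (HR-FAR, conditional)
EASIEST_SD_DIFF = 0.5
#: floor for a level-dependent H1 sd when the easier neighbour predicts
#: performance at or below the reference point
H1_SD_FLOOR = 1e-3


def _level_h1_sds(anchor: np.ndarray, easiest_sd: float, reference: float) -> np.ndarray:
    """Half the excess of the easier neighbour's prediction over ``reference``;
    the easiest level uses ``easiest_sd``. Non-positive excesses are floored."""
    anchor = np.asarray(anchor, dtype=float)
    sds = np.empty_like(anchor)
    sds[:-1] = (anchor[1:] - reference) / 2.0
    sds[-1] = easiest_sd
    low = sds < H1_SD_FLOOR
    if np.any(low[:-1]):
        warnings.warn("H1 sd floored at some level(s): easier neighbour predicts "
                      "no excess over the reference", stacklevel=2)
    sds[low] = H1_SD_FLOOR
    return sds


def bf_above_chance(
    pred_means: Sequence[float], pred_sds: Sequence[float]
) -> list[BFResult]:
    """Per-level BF for above-chance performance, hardest level first.

    H0: Normal(0.5, 0.005). H1: upper half-Normal at 0.5 whose sd at level i
    is half of (predicted performance at the easier level i+1 minus 0.5);
    the easiest level uses sd 0.25.
    """
    means = np.asarray(pred_means, dtype=float)
    sds = np.asarray(pred_sds, dtype=float)
    h1_sds = _level_h1_sds(means, EASIEST_SD_CHANCE, reference=0.5)
    out = []
    for m, s, h1sd in zip(means, sds, h1_sds):
        out.append(bayes_factor(m, s, H0_CHANCE,
                                PriorSpec("half_normal_upper", 0.5, h1sd)))
    return out


_DIFF_FAMILIES = ("type2_HRFAR", "conditional", "interval_order")


def bf_difference(
    pred_a: Sequence[tuple[float, float]],
    pred_b: Sequence[tuple[float, float]],
    family: str,
) -> list[BFResult]:
    """Per-level BF for an A-B difference of population-level predictions.

    The observation at each level is the predictive (mean, sd) of the
    difference (independent posteriors: mean difference, sds in quadrature).
    Families:

    * ``type2_HRFAR`` / ``conditional`` — H0 point at 0; H1 upper half-Normal
      whose sd at level i is half the predicted difference at the easier
      level i+1 (easiest-level sd 0.5).
    * ``interval_order`` — H0 point at 0; H1 two-tailed Normal(0, 0.1).
    """
    if family not in _DIFF_FAMILIES:
        raise ValueError(f"family must be one of {_DIFF_FAMILIES}")
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("pred_a and pred_b must be matched (mean, sd) sequences")
    d_mean = a[:, 0] - b[:, 0]
    d_sd = np.sqrt(a[:, 1] ** 2 + b[:, 1] ** 2)
    h0 = PriorSpec("point", 0.0)
    out = []
    if family == "interval_order":
        h1 = PriorSpec("normal", 0.0, 0.1)
        return [bayes_factor(m, s, h0, h1) for m, s in zip(d_mean, d_sd)]
    h1_sds = _level_h1_sds(d_mean, EASIEST_SD_DIFF, reference=0.0)
    for m, s, h1sd in zip(d_mean, d_sd, h1_sds):
        out.append(bayes_factor(m, s, h0, PriorSpec("half_normal_upper", 0.0, h1sd)))
    return out
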